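"""Shared fixtures: small synthetic datasets generated at test time."""

from __future__ import annotations

import pytest

from panani.synthetic import (ClusterPlantSpec, DEPlantSpec,
                              EnrichmentPlantSpec, PangenomeConfig,
                              simulate_de_table, simulate_pangenome)

CLUSTER_FAMILIES = tuple(f"CLU{i:02d}" for i in range(1, 12))


def make_cluster_config(**overrides) -> PangenomeConfig:
    """11 genomes; 11-member cluster complete in the reference plus two
    other genomes, a 4-member subset in one, absent from the remaining
    seven — so the ten analyzed genomes split 2 complete / 1 partial /
    7 absent."""
    defaults = dict(
        n_genomes=11, n_core=80, n_accessory=10, n_specific_per_genome=5,
        divergence=0.05, n_contigs_per_genome=2,
        cluster_spec=ClusterPlantSpec(
            member_families=CLUSTER_FAMILIES,
            complete_genomes=("G00", "G01", "G02"),
            partial_genomes={"G03": CLUSTER_FAMILIES[:4]}),
        seed=0)
    defaults.update(overrides)
    return PangenomeConfig(**defaults)


@pytest.fixture(scope="session")
def small_pangenome():
    """3 genomes x 20 core families: cheap enough for many tests."""
    config = PangenomeConfig(n_genomes=3, n_core=20, n_accessory=0,
                             n_specific_per_genome=2, divergence=0.03,
                             gene_length=300, seed=7)
    return config, *simulate_pangenome(config)


@pytest.fixture(scope="session")
def cluster_run():
    """Orthology chain on the 11-genome planted-cluster pangenome, shared
    by the conservation and acceptance tests (expensive: built once)."""
    from panani.align import all_vs_all_protein_hits
    from panani.cluster import ClusterSpec, classify_cluster
    from panani.orthology import (best_hit_per_target_genome, build_cogs,
                                  reciprocal_pairs)
    config = make_cluster_config()
    genomes, genes, proteomes, truth = simulate_pangenome(config)
    genome_of = {g.gene_id: g.genome_id for g in genes}
    hits = all_vs_all_protein_hits(proteomes)
    best = best_hit_per_target_genome(hits, genome_of)
    cogs = build_cogs(reciprocal_pairs(best, genome_of), genome_of)
    spec = ClusterSpec(
        "planted_cluster", truth.reference_genome,
        tuple(truth.cluster_genes_by_genome[truth.reference_genome]))
    report = classify_cluster(spec, cogs, genes,
                              [g.genome_id for g in genomes])
    return report, truth


@pytest.fixture(scope="session")
def de_dataset():
    """Single-genome dataset with the planted 90-up / 28-down DE table."""
    config = PangenomeConfig(
        n_genomes=1, n_core=200, n_accessory=0, n_specific_per_genome=0,
        divergence=0.0, gene_length=300,
        de_spec=DEPlantSpec(n_up=90, n_down=28),
        enrichment_spec=EnrichmentPlantSpec(),
        seed=13)
    genomes, genes, proteomes, truth = simulate_pangenome(config)
    table = simulate_de_table(truth, config)
    return config, truth, table
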