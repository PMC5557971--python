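"""Simulator contracts: determinism, conservation, divergence calibration."""

import numpy as np
import pytest
from Bio.Seq import Seq

from panani.errors import ConfigError, InputError
from panani.synthetic import (ClusterPlantSpec, DEPlantSpec, PangenomeConfig,
                              mutate_sequence, simulate_de_table,
                              simulate_domain_annotation, simulate_pangenome)

from conftest import CLUSTER_FAMILIES, make_cluster_config


class TestMutateSequence:
    def test_zero_rate_identity(self):
        assert mutate_sequence("ACGT", 0.0, 5) == "ACGT"

    def test_empty_input(self):
        assert mutate_sequence("", 0.1, 5) == ""

    def test_rate_within_binomial_bounds(self):
        seq = "A" * 10000
        out = mutate_sequence(seq, 0.1, seed=42)
        observed = sum(a != b for a, b in zip(seq, out)) / len(seq)
        sd = (0.1 * 0.9 / len(seq)) ** 0.5
        assert abs(observed - 0.1) < 3 * sd

    def test_length_preserved_and_deterministic(self):
        seq = "ACGT" * 250
        a = mutate_sequence(seq, 0.2, 7)
        b = mutate_sequence(seq, 0.2, 7)
        assert a == b and len(a) == len(seq)

    def test_invalid_alphabet_rejected(self):
        with pytest.raises(InputError):
            mutate_sequence("ACGU", 0.1, 1)

    def test_invalid_rate_rejected(self):
        with pytest.raises(InputError):
            mutate_sequence("ACGT", 0.7, 1)


class TestSimulatePangenome:
    def test_zero_divergence_identical_core_genes(self):
        config = PangenomeConfig(n_genomes=3, n_core=5, n_accessory=0,
                                 n_specific_per_genome=0, divergence=0.0,
                                 seed=1)
        genomes, genes, proteomes, truth = simulate_pangenome(config)
        assert len(genomes) == 3
        by_family = {}
        for gene in genes:
            by_family.setdefault(
                truth.family_of_gene[gene.gene_id], set()).add(gene.protein)
        assert len(by_family) == 5
        assert all(len(v) == 1 for v in by_family.values())
        assert len(truth.core_family_ids) == 5

    def test_determinism_byte_identical(self, tmp_path):
        from panani.synthetic import write_dataset
        config = PangenomeConfig(n_genomes=2, n_core=6, n_specific_per_genome=1,
                                 divergence=0.05, gene_length=300, seed=7)
        out = []
        for run in ("a", "b"):
            data = simulate_pangenome(config)
            paths = write_dataset(tmp_path / run, *data)
            out.append({k: p.read_bytes() for k, p in paths.items()})
        assert out[0] == out[1]

    def test_gene_counts_conserved(self, small_pangenome):
        config, genomes, genes, proteomes, truth = small_pangenome
        for genome in genomes:
            count = sum(g.genome_id == genome.genome_id for g in genes)
            assert count == config.n_core + config.n_specific_per_genome
        assert set(truth.family_of_gene) == {g.gene_id for g in genes}

    def test_coordinates_valid_and_non_overlapping(self, small_pangenome):
        _, genomes, genes, _, _ = small_pangenome
        genome_map = {g.genome_id: g for g in genomes}
        spans = {}
        for gene in genes:
            contig = genome_map[gene.genome_id].contig_seq(gene.contig_id)
            assert 1 <= gene.start <= gene.end <= len(contig)
            spans.setdefault((gene.genome_id, gene.contig_id), []).append(
                (gene.start, gene.end))
        for key, pairs in spans.items():
            pairs.sort()
            assert all(pairs[i][1] < pairs[i + 1][0]
                       for i in range(len(pairs) - 1))

    def test_proteins_are_cds_translations(self, small_pangenome):
        _, genomes, genes, proteomes, _ = small_pangenome
        genome_map = {g.genome_id: g for g in genomes}
        for gene in genes[:20]:
            cds = gene.cds(genome_map[gene.genome_id])
            translated = str(Seq(cds).translate(table=11)).rstrip("*")
            assert "*" not in translated
            assert proteomes[gene.genome_id][gene.gene_id] == translated

    def test_divergence_calibration_against_mismatch_oracle(self):
        """Mean within-family nucleotide identity tracks the two-lineage
        expectation; the oracle is a direct per-site mismatch count."""
        per_site_match = {}
        for divergence in (0.0, 0.05, 0.10):
            config = PangenomeConfig(n_genomes=6, n_core=30, n_accessory=0,
                                     n_specific_per_genome=0,
                                     divergence=divergence, gene_length=300,
                                     seed=21)
            genomes, genes, _, truth = simulate_pangenome(config)
            genome_map = {g.genome_id: g for g in genomes}
            by_family = {}
            for gene in genes:
                by_family.setdefault(
                    truth.family_of_gene[gene.gene_id], []).append(
                        gene.cds(genome_map[gene.genome_id]))
            matches = total = 0
            for fam, seqs in by_family.items():
                for a, b in zip(seqs, seqs[1:]):
                    matches += sum(x == y for x, y in zip(a, b))
                    total += len(a)
            per_site_match[divergence] = matches / total
        # both lineages mutate independently at rate d; a site matches if
        # both untouched, or changes coincide (prob d*d/3 given both hit)
        for d, observed in per_site_match.items():
            expected = (1 - d) ** 2 + 2 * d * (1 - d) * 0 + d * d * (1 / 3)
            # stop-codon redraws perturb a handful of codons; allow 1%
            assert observed == pytest.approx(expected, abs=0.01)
        assert per_site_match[0.0] == 1.0

    def test_identity_non_increasing_in_divergence(self):
        identities = []
        for divergence in (0.02, 0.08, 0.15):
            config = PangenomeConfig(n_genomes=4, n_core=20, n_accessory=0,
                                     n_specific_per_genome=0,
                                     divergence=divergence, gene_length=300,
                                     seed=33)
            genomes, genes, _, truth = simulate_pangenome(config)
            genome_map = {g.genome_id: g for g in genomes}
            by_family = {}
            for gene in genes:
                by_family.setdefault(
                    truth.family_of_gene[gene.gene_id], []).append(
                        gene.cds(genome_map[gene.genome_id]))
            matches = total = 0
            for seqs in by_family.values():
                for a, b in zip(seqs, seqs[1:]):
                    matches += sum(x == y for x, y in zip(a, b))
                    total += len(a)
            identities.append(matches / total)
        assert identities == sorted(identities, reverse=True)

    def test_planted_cluster_contiguous_and_co_oriented(self):
        config = make_cluster_config(n_core=20, n_accessory=0,
                                     n_specific_per_genome=2)
        genomes, genes, _, truth = simulate_pangenome(config)
        gene_by_id = {g.gene_id: g for g in genes}
        for genome_id in ("G00", "G01", "G02"):
            members = [gene_by_id[g]
                       for g in truth.cluster_genes_by_genome[genome_id]]
            assert len(members) == len(CLUSTER_FAMILIES)
            assert len({m.contig_id for m in members}) == 1
            assert len({m.strand for m in members}) == 1
            siblings = sorted(
                (g for g in genes
                 if (g.genome_id, g.contig_id) ==
                    (members[0].genome_id, members[0].contig_id)),
                key=lambda g: g.start)
            idx = sorted(siblings.index(m) for m in members)
            assert idx == list(range(idx[0], idx[0] + len(members)))

    def test_contradictory_cluster_config_names_field(self):
        with pytest.raises(ConfigError, match="complete_genomes"):
            PangenomeConfig(
                n_genomes=3,
                cluster_spec=ClusterPlantSpec(
                    member_families=("F1", "F2"),
                    complete_genomes=("G00", "G99"))).validate()

    def test_invalid_gene_length_rejected(self):
        with pytest.raises(ConfigError, match="gene_length"):
            PangenomeConfig(gene_length=100).validate()


class TestSimulateDeTable:
    def test_planted_counts_exact(self, de_dataset):
        config, truth, table = de_dataset
        alpha = config.de_spec.alpha
        significant = table[table["q_value"] < alpha]
        assert (significant["log2(fold_change)"] > 0).sum() == 90
        assert (significant["log2(fold_change)"] < 0).sum() == 28
        assert (table["q_value"] >= alpha).sum() == len(table) - 118

    def test_zero_de_spec_nothing_significant(self):
        config = PangenomeConfig(n_genomes=1, n_core=30, divergence=0.0,
                                 n_specific_per_genome=0, gene_length=300,
                                 de_spec=DEPlantSpec(n_up=0, n_down=0), seed=2)
        _, _, _, truth = simulate_pangenome(config)
        table = simulate_de_table(truth, config)
        assert (table["q_value"] < 0.05).sum() == 0

    def test_deterministic_given_seed(self):
        config = PangenomeConfig(n_genomes=1, n_core=40, divergence=0.0,
                                 n_specific_per_genome=0, gene_length=300,
                                 de_spec=DEPlantSpec(n_up=5, n_down=3), seed=4)
        tables = []
        for _ in range(2):
            _, _, _, truth = simulate_pangenome(config)
            tables.append(simulate_de_table(truth, config).to_csv())
        assert tables[0] == tables[1]

    def test_oversized_de_spec_rejected(self):
        config = PangenomeConfig(n_genomes=1, n_core=10, divergence=0.0,
                                 n_specific_per_genome=0, gene_length=300,
                                 de_spec=DEPlantSpec(n_up=90, n_down=28),
                                 seed=0)
        _, _, _, truth = simulate_pangenome(config)
        with pytest.raises(ConfigError, match="de_spec"):
            simulate_de_table(truth, config)


class TestDomainAnnotation:
    def test_planted_pfam_maps_to_enriched_term(self, de_dataset):
        config, truth, _ = de_dataset
        domains, pfam2go = simulate_domain_annotation(truth, config)
        spec = config.enrichment_spec
        assert pfam2go[spec.pfam_id] == {spec.term_id}
        up = [g for g, label in truth.de_labels.items() if label == "up"]
        up_rate = sum(spec.pfam_id in domains[g] for g in up) / len(up)
        rest = [g for g in domains if truth.de_labels.get(g) != "up"]
        rest_rate = sum(spec.pfam_id in domains[g] for g in rest) / len(rest)
        assert up_rate > rest_rate
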