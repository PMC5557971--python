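"""Synthetic pangenomes with planted truth.

Generates multi-genome datasets in which every downstream answer is known
by construction: gene families descend from common ancestral coding
sequences by independent per-site substitution (a Jukes-Cantor-like
model, no indels), core families contribute exactly one gene to every
genome, accessory families to a random subset, and each genome carries a
set of strain-specific genes drawn fresh (unrelated to any ancestor).  A
resistance-like gene cluster can be planted contiguous and co-oriented in
chosen genomes (complete or as a stated subset), a GO term can be planted
enriched among up-regulated genes via Pfam domain assignments, and a
differential-expression table in the Cuffdiff ``gene_exp.diff`` dialect
is produced with q-values below the significance threshold exactly for
the planted DE genes.

All randomness flows from one integer seed through a single
``numpy.random.Generator``; identical configurations reproduce
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .errors import ConfigError, InputError
from .io import GeneModel, GenomeRecord, write_fasta, write_gene_table

_BASES = np.array(list("ACGT"))
_STOPS = {"TAA", "TAG", "TGA"}  # translation table 11
_SENSE_CODONS = [a + b + c
                 for a in "ACGT" for b in "ACGT" for c in "ACGT"
                 if a + b + c not in _STOPS]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClusterPlantSpec:
    """A gene cluster planted in a subset of genomes.

    ``member_families`` are the ordered family ids of the cluster;
    ``complete_genomes`` carry all members contiguously and co-oriented
    (the first listed genome is the reference); ``partial_genomes`` maps a
    genome id to the subset of member families it carries.
    """

    member_families: tuple[str, ...]
    complete_genomes: tuple[str, ...]
    partial_genomes: Mapping[str, tuple[str, ...]] = field(default_factory=dict)


@dataclass(frozen=True)
class EnrichmentPlantSpec:
    """One GO term planted over-represented among up-regulated genes."""

    term_id: str = "GO:0005507"
    pfam_id: str = "PF04234"
    de_fraction: float = 0.30          # fraction of up-DE genes carrying it
    background_fraction: float = 0.05  # fraction of other genes carrying it
    n_decoy_pfams: int = 40            # unrelated Pfam/GO pairs
    decoy_fraction: float = 0.05       # per-gene probability of each decoy


@dataclass(frozen=True)
class DEPlantSpec:
    n_up: int = 90
    n_down: int = 28
    alpha: float = 0.05  # planted significance threshold


@dataclass(frozen=True)
class PangenomeConfig:
    n_genomes: int = 10
    n_core: int = 80
    n_accessory: int = 0
    n_specific_per_genome: int = 5
    gene_length: int = 900             # mean CDS length, nt, multiple of 3
    divergence: float = 0.05           # per-site substitution probability
    n_contigs_per_genome: int = 2
    cluster_spec: ClusterPlantSpec | None = None
    enrichment_spec: EnrichmentPlantSpec | None = None
    de_spec: DEPlantSpec | None = None
    seed: int = 0

    @property
    def genome_ids(self) -> list[str]:
        return [f"G{i:02d}" for i in range(self.n_genomes)]

    @property
    def reference_genome(self) -> str:
        return self.genome_ids[0]

    def validate(self) -> None:
        for name in ("n_genomes", "n_core", "n_accessory",
                     "n_specific_per_genome", "n_contigs_per_genome"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.n_genomes < 1:
            raise ConfigError("n_genomes must be >= 1")
        if self.n_contigs_per_genome < 1:
            raise ConfigError("n_contigs_per_genome must be >= 1")
        if not (0.0 <= self.divergence <= 0.5):
            raise ConfigError("divergence must be in [0, 0.5]")
        if self.gene_length < 33 or self.gene_length % 3 != 0:
            raise ConfigError("gene_length must be >= 33 and divisible by 3")
        if self.cluster_spec is not None:
            ids = set(self.genome_ids)
            cs = self.cluster_spec
            if len(cs.member_families) < 2:
                raise ConfigError("cluster_spec.member_families: needs >= 2")
            for g in cs.complete_genomes:
                if g not in ids:
                    raise ConfigError(
                        f"cluster_spec.complete_genomes: unknown genome {g!r}")
            if self.reference_genome not in cs.complete_genomes:
                raise ConfigError(
                    "cluster_spec.complete_genomes: must include the "
                    f"reference genome {self.reference_genome!r}")
            for g, subset in cs.partial_genomes.items():
                if g not in ids:
                    raise ConfigError(
                        f"cluster_spec.partial_genomes: unknown genome {g!r}")
                if g in cs.complete_genomes:
                    raise ConfigError(
                        f"cluster_spec.partial_genomes: genome {g!r} is "
                        f"already listed as complete")
                unknown = set(subset) - set(cs.member_families)
                if unknown:
                    raise ConfigError(
                        f"cluster_spec.partial_genomes[{g!r}]: families "
                        f"{sorted(unknown)} are not cluster members")
        if self.de_spec is not None:
            if self.de_spec.n_up < 0 or self.de_spec.n_down < 0:
                raise ConfigError("de_spec counts must be >= 0")
            if not (0.0 < self.de_spec.alpha < 1.0):
                raise ConfigError("de_spec.alpha must be in (0, 1)")


@dataclass
class PlantedTruth:
    """Ground truth recorded while generating a synthetic pangenome."""

    family_of_gene: dict[str, str]
    core_family_ids: set[str]
    specific_gene_ids: set[str]
    cluster_status_by_genome: dict[str, str]
    genes_by_genome: dict[str, list[str]]
    cluster_genes_by_genome: dict[str, list[str]]
    reference_genome: str
    enriched_term_id: str | None = None
    de_labels: dict[str, str | None] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# sequence-level primitives
# ---------------------------------------------------------------------------

def _as_rng(seed: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def random_coding_sequence(n_codons: int, rng: np.random.Generator) -> str:
    """ATG + random sense codons + TAA."""
    if n_codons < 3:
        raise InputError("a coding sequence needs >= 3 codons")
    middle = rng.choice(len(_SENSE_CODONS), size=n_codons - 2)
    return "ATG" + "".join(_SENSE_CODONS[i] for i in middle) + "TAA"


def mutate_sequence(seq: str, divergence: float,
                    seed: int | np.random.Generator) -> str:
    """Substitute each site independently with probability ``divergence``.

    A substituted site becomes one of the three other bases, uniformly.
    Deterministic given the seed; the empty sequence maps to itself.
    """
    if not (0.0 <= divergence <= 0.5):
        raise InputError("divergence must be in [0, 0.5]")
    if not seq:
        return ""
    bad = set(seq) - set("ACGT")
    if bad:
        raise InputError(f"invalid base(s) {sorted(bad)}")
    rng = _as_rng(seed)
    arr = np.array(list(seq))
    hit = rng.random(len(arr)) < divergence
    if hit.any():
        base_index = np.searchsorted(_BASES, arr[hit])
        offsets = rng.integers(1, 4, size=int(hit.sum()))
        arr[hit] = _BASES[(base_index + offsets) % 4]
    return "".join(arr)


def _fix_internal_stops(seq: str, rng: np.random.Generator) -> str:
    """Redraw internal stop codons to random sense codons (table 11)."""
    codons = [seq[i:i + 3] for i in range(0, len(seq), 3)]
    for i in range(1, len(codons) - 1):
        if codons[i] in _STOPS:
            codons[i] = _SENSE_CODONS[int(rng.integers(len(_SENSE_CODONS)))]
    return "".join(codons)


def _translate(cds: str) -> str:
    protein = str(Seq(cds).translate(table=11))
    return protein[:-1] if protein.endswith("*") else protein


def simulate_genome_pair(
    length: int, divergence: float, seed: int,
) -> tuple[GenomeRecord, GenomeRecord, str, str]:
    """One random genome and a copy diverged at the given per-site rate.

    Returns (genome_a, genome_b, seq_a, seq_b); the two sequences are
    positionally homologous (no rearrangement, no indels), which makes the
    exact per-site identity of any window computable by mismatch counting.
    """
    rng = np.random.default_rng(seed)
    seq_a = "".join(rng.choice(_BASES, size=length))
    seq_b = mutate_sequence(seq_a, divergence, rng)
    return (
        GenomeRecord("A", [("A_c1", seq_a)]),
        GenomeRecord("B", [("B_c1", seq_b)]),
        seq_a, seq_b,
    )


# ---------------------------------------------------------------------------
# pangenome simulation
# ---------------------------------------------------------------------------

def _ancestral_families(config: PangenomeConfig, rng: np.random.Generator
                        ) -> tuple[dict[str, str], dict[str, set[str]],
                                   dict[str, str], dict[str, str]]:
    """Ancestral CDS, carrier set, strand and upstream spacer per family.

    Strand and spacer are drawn once for the ancestor and inherited:
    orthologs of closely related strains keep their order, orientation and
    intergenic context, which is what makes whole-genome fragment ANI
    meaningful on the simulated genomes.
    """
    mean_codons = config.gene_length // 3
    lo = max(11, int(mean_codons * 0.8))
    hi = max(lo + 1, int(mean_codons * 1.2) + 1)

    sequences: dict[str, str] = {}
    presence: dict[str, set[str]] = {}
    strands: dict[str, str] = {}
    spacers: dict[str, str] = {}
    genome_ids = config.genome_ids

    def new_family(fam: str) -> None:
        sequences[fam] = random_coding_sequence(int(rng.integers(lo, hi)), rng)
        strands[fam] = "+" if rng.random() < 0.5 else "-"
        spacers[fam] = "".join(
            rng.choice(_BASES, size=int(rng.integers(20, 201))))

    for i in range(config.n_core):
        fam = f"CORE{i:04d}"
        new_family(fam)
        presence[fam] = set(genome_ids)
    for i in range(config.n_accessory):
        fam = f"ACC{i:04d}"
        new_family(fam)
        size = int(rng.integers(1, max(2, config.n_genomes)))
        carriers = rng.choice(config.n_genomes, size=size, replace=False)
        presence[fam] = {genome_ids[int(j)] for j in carriers}
    if config.cluster_spec is not None:
        cs = config.cluster_spec
        block_strand = "+" if rng.random() < 0.5 else "-"
        for fam in cs.member_families:
            new_family(fam)
            strands[fam] = block_strand  # co-oriented operon-like block
            carriers = set(cs.complete_genomes)
            for g, subset in cs.partial_genomes.items():
                if fam in subset:
                    carriers.add(g)
            presence[fam] = carriers
    return sequences, presence, strands, spacers


def simulate_pangenome(config: PangenomeConfig) -> tuple[
        list[GenomeRecord], list[GeneModel],
        dict[str, dict[str, str]], PlantedTruth]:
    """Generate genomes, gene table, proteomes and the planted truth.

    Gene families share an ancestral order, orientation and intergenic
    context across genomes (closely related strains are collinear); each
    genome's gene and spacer copies are independently mutated from the
    ancestor at ``config.divergence`` per site, internal stops are redrawn
    to sense codons, and genes sit on contigs with >= 20 nt spacers and
    1-based inclusive coordinates.  Strands are drawn uniformly once for
    the ancestor — planted-cluster members share one strand and stay
    contiguous in the genomes flagged complete (or partial).  Strain-
    specific genes are fresh sequences inserted per genome.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    genome_ids = config.genome_ids
    cluster = config.cluster_spec
    cluster_families = list(cluster.member_families) if cluster else []

    sequences, presence, strands, spacers = _ancestral_families(config, rng)

    # ancestral layout: shuffled singleton families with the cluster kept
    # as one block
    loose = sorted(set(sequences) - set(cluster_families))
    layout_units: list[list[str]] = [[f] for f in loose]
    order = rng.permutation(len(layout_units))
    layout_units = [layout_units[int(i)] for i in order]
    if cluster_families:
        pos = int(rng.integers(0, len(layout_units) + 1))
        layout_units.insert(pos, list(cluster_families))

    genomes: list[GenomeRecord] = []
    genes: list[GeneModel] = []
    proteomes: dict[str, dict[str, str]] = {}
    family_of_gene: dict[str, str] = {}
    specific_ids: set[str] = set()
    genes_by_genome: dict[str, list[str]] = {}
    cluster_genes_by_genome: dict[str, list[str]] = {g: [] for g in genome_ids}
    mean_codons = config.gene_length // 3

    for genome_id in genome_ids:
        # units present in this genome, cluster kept as a block
        units: list[tuple[list[str], bool]] = []  # (family ids, is_cluster)
        for unit in layout_units:
            if unit == cluster_families:
                kept = [f for f in cluster_families if genome_id in presence[f]]
                if kept:
                    units.append((kept, True))
            else:
                if genome_id in presence[unit[0]]:
                    units.append((unit, False))
        # strain-specific genes as fresh singleton units with their own
        # strand and spacer (genome-private insertions)
        specific_units: dict[str, tuple[str, str, str]] = {}
        for s in range(config.n_specific_per_genome):
            fam = f"SPEC_{genome_id}_{s:03d}"
            n_codons = int(rng.integers(max(11, int(mean_codons * 0.8)),
                                        max(12, int(mean_codons * 1.2) + 1)))
            specific_units[fam] = (
                random_coding_sequence(n_codons, rng),
                "+" if rng.random() < 0.5 else "-",
                "".join(rng.choice(_BASES, size=int(rng.integers(20, 201)))))
            at = int(rng.integers(0, len(units) + 1))
            units.insert(at, ([fam], False))

        # distribute units over contigs in near-equal consecutive chunks
        n_contigs = config.n_contigs_per_genome
        bounds = np.linspace(0, len(units), n_contigs + 1).astype(int)
        contigs: list[tuple[str, str]] = []
        genome_genes: list[GeneModel] = []
        gene_counter = 0
        proteome: dict[str, str] = {}
        for ci in range(n_contigs):
            chunk = units[bounds[ci]:bounds[ci + 1]]
            contig_id = f"{genome_id}_c{ci + 1}"
            parts: list[str] = []
            pos = 0
            for fams, is_cluster in chunk:
                for fam in fams:
                    if fam in specific_units:
                        cds, strand, spacer = specific_units[fam]
                    else:
                        spacer = mutate_sequence(spacers[fam],
                                                 config.divergence, rng)
                        strand = strands[fam]
                        cds = mutate_sequence(sequences[fam],
                                              config.divergence, rng)
                        cds = _fix_internal_stops(cds, rng)
                    parts.append(spacer)
                    pos += len(spacer)
                    oriented = cds if strand == "+" else str(
                        Seq(cds).reverse_complement())
                    start = pos + 1
                    end = pos + len(oriented)
                    parts.append(oriented)
                    pos = end
                    gene_id = f"{genome_id}_g{gene_counter:04d}"
                    gene_counter += 1
                    gene = GeneModel(
                        gene_id=gene_id, genome_id=genome_id,
                        contig_id=contig_id, start=start, end=end,
                        strand=strand, protein=_translate(cds))
                    genome_genes.append(gene)
                    proteome[gene_id] = gene.protein
                    family_of_gene[gene_id] = fam
                    if fam in specific_units:
                        specific_ids.add(gene_id)
                    if is_cluster:
                        cluster_genes_by_genome[genome_id].append(gene_id)
            tail = int(rng.integers(20, 201))
            parts.append("".join(rng.choice(_BASES, size=tail)))
            contigs.append((contig_id, "".join(parts)))
        genomes.append(GenomeRecord(genome_id=genome_id, contigs=contigs))
        genes.extend(genome_genes)
        proteomes[genome_id] = proteome
        genes_by_genome[genome_id] = [g.gene_id for g in genome_genes]

    cluster_status: dict[str, str] = {}
    for genome_id in genome_ids:
        if cluster is None:
            cluster_status[genome_id] = "absent"
        elif genome_id in cluster.complete_genomes:
            cluster_status[genome_id] = "complete"
        elif cluster.partial_genomes.get(genome_id):
            cluster_status[genome_id] = "partial"
        else:
            cluster_status[genome_id] = "absent"

    truth = PlantedTruth(
        family_of_gene=family_of_gene,
        core_family_ids={f"CORE{i:04d}" for i in range(config.n_core)},
        specific_gene_ids=specific_ids,
        cluster_status_by_genome=cluster_status,
        genes_by_genome=genes_by_genome,
        cluster_genes_by_genome=cluster_genes_by_genome,
        reference_genome=config.reference_genome,
        enriched_term_id=(config.enrichment_spec.term_id
                          if config.enrichment_spec else None),
    )
    return genomes, genes, proteomes, truth


# ---------------------------------------------------------------------------
# differential expression
# ---------------------------------------------------------------------------

_DE_COLUMNS = ["test_id", "gene_id", "gene", "locus", "sample_1", "sample_2",
               "status", "value_1", "value_2", "log2(fold_change)",
               "test_stat", "p_value", "q_value", "significant"]


def simulate_de_table(truth: PlantedTruth, config: PangenomeConfig) -> pd.DataFrame:
    """One ``gene_exp.diff``-dialect row per focal-genome gene.

    Exactly ``de_spec.n_up`` genes get q < alpha with positive log2 fold
    change and ``de_spec.n_down`` get q < alpha with negative fold change;
    all other genes get q strictly above alpha.  Updates
    ``truth.de_labels``.  Deterministic given ``config.seed``.
    """
    if config.de_spec is None:
        raise ConfigError("de_spec is required to simulate a DE table")
    spec = config.de_spec
    rng = np.random.default_rng((config.seed + 0x9E3779B1) % 2**31)
    focal_genes = truth.genes_by_genome[truth.reference_genome]
    n_de = spec.n_up + spec.n_down
    if n_de > len(focal_genes):
        raise ConfigError(
            f"de_spec: {n_de} DE genes exceed the {len(focal_genes)} genes "
            f"of the focal genome")
    chosen = rng.choice(len(focal_genes), size=n_de, replace=False)
    up = {focal_genes[int(i)] for i in chosen[:spec.n_up]}
    down = {focal_genes[int(i)] for i in chosen[spec.n_up:]}
    truth.de_labels = {
        g: ("up" if g in up else "down" if g in down else None)
        for g in focal_genes}

    alpha = spec.alpha
    rows = []
    for gene in focal_genes:
        value_1 = float(np.exp(rng.normal(3.0, 1.0)))
        if gene in up:
            lfc = float(rng.uniform(1.0, 5.0))
            q = alpha * rng.random()                      # strictly < alpha
        elif gene in down:
            lfc = float(-rng.uniform(1.0, 5.0))
            q = alpha * rng.random()
        else:
            lfc = float(rng.normal(0.0, 0.2))
            q = alpha + (1.0 - alpha) * rng.random()
            if q <= alpha:                                # float edge guard
                q = alpha + (1.0 - alpha) * 0.5
        value_2 = value_1 * 2.0 ** lfc
        rows.append({
            "test_id": gene, "gene_id": gene, "gene": gene,
            "locus": "-", "sample_1": "control", "sample_2": "treated",
            "status": "OK", "value_1": round(value_1, 4),
            "value_2": round(value_2, 4),
            "log2(fold_change)": round(lfc, 4),
            "test_stat": 0.0, "p_value": q, "q_value": q,
            "significant": "yes" if q < alpha else "no",
        })
    return pd.DataFrame(rows, columns=_DE_COLUMNS)


# ---------------------------------------------------------------------------
# domain annotation / planted enrichment
# ---------------------------------------------------------------------------

def simulate_domain_annotation(
    truth: PlantedTruth, config: PangenomeConfig,
) -> tuple[dict[str, set[str]], dict[str, set[str]]]:
    """Pfam domains per focal-genome gene plus a pfam2go mapping.

    The planted Pfam (mapping to the enriched GO term) is given to
    ``de_fraction`` of the up-regulated genes and ``background_fraction``
    of all other genes; decoy Pfam/GO pairs are sprinkled uniformly.
    Requires ``truth.de_labels`` (run :func:`simulate_de_table` first).
    """
    if config.enrichment_spec is None:
        raise ConfigError("enrichment_spec is required for domain annotation")
    if not truth.de_labels:
        raise ConfigError("truth.de_labels empty: simulate the DE table first")
    spec = config.enrichment_spec
    rng = np.random.default_rng((config.seed + 0x7F4A7C15) % 2**31)
    focal_genes = truth.genes_by_genome[truth.reference_genome]

    pfam2go: dict[str, set[str]] = {spec.pfam_id: {spec.term_id}}
    decoys = []
    for i in range(spec.n_decoy_pfams):
        acc = f"PF9{i:04d}"
        decoys.append(acc)
        pfam2go[acc] = {f"GO:9{i:06d}"}

    domains: dict[str, set[str]] = {g: set() for g in focal_genes}
    for gene in focal_genes:
        planted_p = (spec.de_fraction if truth.de_labels.get(gene) == "up"
                     else spec.background_fraction)
        if rng.random() < planted_p:
            domains[gene].add(spec.pfam_id)
        hits = rng.random(len(decoys)) < spec.decoy_fraction
        for acc, hit in zip(decoys, hits):
            if hit:
                domains[gene].add(acc)
    return domains, pfam2go


# ---------------------------------------------------------------------------
# lightweight enrichment simulations (no sequences)
# ---------------------------------------------------------------------------

def simulate_enrichment_dataset(
    n_background: int, n_de: int, n_terms: int,
    seed: int | np.random.Generator,
    planted: EnrichmentPlantSpec | None = None,
) -> tuple[set[str], set[str], dict[str, set[str]], str | None]:
    """Gene universe with random term assignments for calibration studies.

    Terms are assigned to genes independently (per-term frequency drawn
    uniformly in [0.02, 0.10]); DE genes are a uniform random subset.  With
    ``planted``, one extra term is given to ``de_fraction`` of DE genes and
    ``background_fraction`` of the rest.  Returns
    (de genes, background genes, gene -> term set, planted term id or None).
    """
    rng = _as_rng(seed)
    genes = [f"g{i:05d}" for i in range(n_background)]
    de = {genes[int(i)]
          for i in rng.choice(n_background, size=n_de, replace=False)}
    gene_to_go: dict[str, set[str]] = {g: set() for g in genes}
    freqs = rng.uniform(0.02, 0.10, size=n_terms)
    for t in range(n_terms):
        term = f"GO:{t:07d}"
        hits = rng.random(n_background) < freqs[t]
        for g, hit in zip(genes, hits):
            if hit:
                gene_to_go[g].add(term)
    planted_term = None
    if planted is not None:
        planted_term = planted.term_id
        for g in genes:
            p = planted.de_fraction if g in de else planted.background_fraction
            if rng.random() < p:
                gene_to_go[g].add(planted_term)
    return de, set(genes), gene_to_go, planted_term


# ---------------------------------------------------------------------------
# dataset export
# ---------------------------------------------------------------------------

def write_dataset(
    outdir: str | Path,
    genomes: Sequence[GenomeRecord],
    genes: Sequence[GeneModel],
    proteomes: Mapping[str, Mapping[str, str]],
    truth: PlantedTruth,
    de_table: pd.DataFrame | None = None,
    domains: Mapping[str, set[str]] | None = None,
    pfam2go: Mapping[str, set[str]] | None = None,
) -> dict[str, Path]:
    """Write genome FASTAs, proteome FASTA, gene table, truth tables and —
    when provided — the DE table, gene->Pfam table and pfam2go file.
    Returns {artifact name: path}."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for genome in genomes:
        p = outdir / f"{genome.genome_id}.fna"
        write_fasta(genome.contigs, p)
        paths[f"genome:{genome.genome_id}"] = p
    prot_path = outdir / "proteomes.faa"
    records = [(gid, seq)
               for genome_id in sorted(proteomes)
               for gid, seq in sorted(proteomes[genome_id].items())]
    write_fasta(records, prot_path)
    paths["proteomes"] = prot_path
    gene_path = outdir / "genes.tsv"
    write_gene_table(genes, gene_path)
    paths["gene_table"] = gene_path

    truth_path = outdir / "truth_families.tsv"
    pd.DataFrame(
        sorted(truth.family_of_gene.items()), columns=["gene_id", "family_id"],
    ).to_csv(truth_path, sep="\t", index=False)
    paths["truth_families"] = truth_path
    status_path = outdir / "truth_cluster_status.tsv"
    pd.DataFrame(
        sorted(truth.cluster_status_by_genome.items()),
        columns=["genome", "status"],
    ).to_csv(status_path, sep="\t", index=False)
    paths["truth_cluster_status"] = status_path

    if de_table is not None:
        de_path = outdir / "gene_exp.diff"
        de_table.to_csv(de_path, sep="\t", index=False)
        paths["de_table"] = de_path
    if domains is not None:
        dom_path = outdir / "gene_pfam.tsv"
        rows = [(g, acc) for g in sorted(domains) for acc in sorted(domains[g])]
        pd.DataFrame(rows, columns=["gene_id", "pfam_acc"]).to_csv(
            dom_path, sep="\t", index=False)
        paths["gene_pfam"] = dom_path
    if pfam2go is not None:
        p2g_path = outdir / "pfam2go.txt"
        with open(p2g_path, "w") as fh:
            fh.write("!version date: synthetic mapping\n")
            for acc in sorted(pfam2go):
                for term in sorted(pfam2go[acc]):
                    fh.write(f"Pfam:{acc} {acc} > GO:synthetic term ; {term}\n")
        paths["pfam2go"] = p2g_path
    return paths
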