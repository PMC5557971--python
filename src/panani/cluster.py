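"""Conservation classification of a named reference gene cluster.

Given an ordered list of reference-genome genes that form a contiguous
cluster (e.g. a metal-resistance efflux operon), each other genome is
classified by how much of the cluster it carries: a member is *present*
in a genome when the member's ortholog cluster (COG) contains at least
one gene of that genome; a genome is *complete* when its presence
fraction reaches the completeness threshold (default 1.0, i.e. every
member), *absent* when no member is present, and *partial* otherwise.
Optionally, *complete* additionally requires the present orthologs to be
consecutive and co-oriented on a single contig (synteny).

The reference genome itself is excluded from the status counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .align import NucleotideAlignParams, local_align_nucleotide
from .errors import ConfigError
from .io import GeneModel, GenomeRecord, genes_by_contig
from .orthology import COG

COMPLETE = "complete"
PARTIAL = "partial"
ABSENT = "absent"


@dataclass(frozen=True)
class ClusterSpec:
    cluster_id: str
    reference_genome: str
    members: tuple[str, ...]            # ordered reference gene ids
    completeness_threshold: float = 1.0
    contiguity_required: bool = False

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ConfigError(
                f"cluster {self.cluster_id!r}: needs >= 2 members")
        if not (0.0 < self.completeness_threshold <= 1.0):
            raise ConfigError(
                f"cluster {self.cluster_id!r}: completeness_threshold must "
                f"be in (0, 1]")


@dataclass
class ConservationReport:
    cluster_id: str
    status_by_genome: dict[str, str]
    presence_by_genome: dict[str, list[bool]]  # per spec-member order
    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = {s: 0 for s in (COMPLETE, PARTIAL, ABSENT)}
        for status in self.status_by_genome.values():
            self.counts[status] += 1


def _member_cogs(spec: ClusterSpec, cogs: Sequence[COG],
                 genes: Sequence[GeneModel]) -> dict[str, COG | None]:
    ref_genes = {g.gene_id for g in genes if g.genome_id == spec.reference_genome}
    gene_to_cog: dict[str, COG] = {}
    for cog in cogs:
        for _, gene_id in cog.members:
            gene_to_cog[gene_id] = cog
    out: dict[str, COG | None] = {}
    for member in spec.members:
        if member not in ref_genes:
            raise ConfigError(
                f"cluster {spec.cluster_id!r}: member {member!r} is not a "
                f"gene of reference genome {spec.reference_genome!r}")
        out[member] = gene_to_cog.get(member)  # None: no ortholog anywhere
    return out


def _is_contiguous(ortholog_genes: list[GeneModel],
                   genome_genes: Sequence[GeneModel]) -> bool:
    """True iff the genes sit consecutively and co-oriented on one contig."""
    contigs = {g.contig_id for g in ortholog_genes}
    if len(contigs) != 1:
        return False
    if len({g.strand for g in ortholog_genes}) != 1:
        return False
    by_contig = genes_by_contig(genome_genes)
    key = (ortholog_genes[0].genome_id, ortholog_genes[0].contig_id)
    ordered = by_contig[key]
    positions = sorted(ordered.index(g) for g in ortholog_genes)
    return positions == list(range(positions[0], positions[0] + len(positions)))


def classify_cluster(
    spec: ClusterSpec,
    cogs: Sequence[COG],
    genes: Sequence[GeneModel],
    genome_ids: Sequence[str],
) -> ConservationReport:
    """Classify every non-reference genome as complete / partial / absent."""
    member_cog = _member_cogs(spec, cogs, genes)
    genes_of_genome: dict[str, list[GeneModel]] = {}
    for g in genes:
        genes_of_genome.setdefault(g.genome_id, []).append(g)
    gene_by_id = {g.gene_id: g for g in genes}

    status: dict[str, str] = {}
    presence: dict[str, list[bool]] = {}
    for genome_id in genome_ids:
        if genome_id == spec.reference_genome:
            continue
        row: list[bool] = []
        ortholog_genes: list[GeneModel] = []
        for member in spec.members:
            cog = member_cog[member]
            hit_genes = [] if cog is None else [
                gene_by_id[gid] for gg, gid in cog.members if gg == genome_id]
            row.append(bool(hit_genes))
            ortholog_genes.extend(hit_genes)
        fraction = sum(row) / len(row)
        if fraction == 0.0:
            verdict = ABSENT
        elif fraction >= spec.completeness_threshold:
            verdict = COMPLETE
            if spec.contiguity_required and not _is_contiguous(
                    ortholog_genes, genes_of_genome.get(genome_id, [])):
                verdict = PARTIAL
        else:
            verdict = PARTIAL
        status[genome_id] = verdict
        presence[genome_id] = row
    return ConservationReport(
        cluster_id=spec.cluster_id,
        status_by_genome=status, presence_by_genome=presence)


def ortholog_identity_profile(
    spec: ClusterSpec,
    cogs: Sequence[COG],
    genes: Sequence[GeneModel],
    genomes: Mapping[str, GenomeRecord],
    params: NucleotideAlignParams | None = None,
) -> dict[str, dict[str, float]]:
    """Nucleotide percent identity of each cluster member vs its orthologs.

    The reference coding sequence is locally aligned (both strands) against
    each ortholog's coding sequence; the best identity per genome is
    reported, NaN where the ortholog is missing.  Coverage of the reference
    CDS is implicit in the local alignment (full-length fragment).
    """
    params = params or NucleotideAlignParams()
    member_cog = _member_cogs(spec, cogs, genes)
    gene_by_id = {g.gene_id: g for g in genes}
    profile: dict[str, dict[str, float]] = {}
    for member in spec.members:
        ref_cds = gene_by_id[member].cds(genomes[spec.reference_genome])
        row: dict[str, float] = {}
        cog = member_cog[member]
        targets: dict[str, list[str]] = {}
        if cog is not None:
            for genome_id, gene_id in cog.members:
                if genome_id != spec.reference_genome:
                    targets.setdefault(genome_id, []).append(gene_id)
        for genome_id in sorted(genomes):
            if genome_id == spec.reference_genome:
                continue
            best = math.nan
            for gene_id in targets.get(genome_id, ()):
                cds = gene_by_id[gene_id].cds(genomes[genome_id])
                result = local_align_nucleotide(ref_cds, cds, params)
                if result is not None and not (best >= result.percent_identity):
                    best = result.percent_identity
            row[genome_id] = best
        profile[member] = row
    return profile
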