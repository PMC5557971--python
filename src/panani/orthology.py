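"""Best-reciprocal-hit orthology and pangenome partitioning.

Acceptance rule for a best hit: hits from a query gene to one target
genome are first gated (external tabular input: e-value <= 1e-5;
internal aligner input: raw score >= floor), the top survivor by score is
kept only if the second-best hit *from the same target genome* scores
strictly below 90% of it — a tied or near-tied second best voids the
call.  A BRBH pair exists when two genes are each other's accepted best
in the partner genome.

Clusters of orthologous genes (COGs) are connected components of the
BRBH graph (a strict-clique mode is available for sensitivity analysis).
Core COGs have exactly one member in every genome; all other COGs are
accessory; "specific" genes have no accepted cross-genome hit at all
(a looser no-BRBH definition is available via flag); genes with hits but
no COG membership are reported separately as "unresolved".

Within-genome (paralog) hits are ignored entirely.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .errors import InputError, ValidationError
from .io import HitRecord


@dataclass(frozen=True)
class BrbhParams:
    max_evalue: float = 1e-5         # gate for external tabular hits
    second_best_ratio: float = 0.90  # second best must be < ratio * best
    min_score: float = 300.0         # gate for internal-mode raw scores
    score_field: str = "bit_score"   # informational; HitRecord.bit_score holds
                                     # either bits (external) or raw SW score

    def __post_init__(self) -> None:
        if self.max_evalue <= 0:
            raise InputError("max_evalue must be positive")
        if not (0.0 < self.second_best_ratio <= 1.0):
            raise InputError("second_best_ratio must be in (0, 1]")


@dataclass
class COG:
    """One cluster of orthologous genes: >=2 members from >=2 genomes."""

    cog_id: str
    members: list[tuple[str, str]]  # (genome_id, gene_id)

    @property
    def genomes(self) -> set[str]:
        return {g for g, _ in self.members}

    @property
    def gene_ids(self) -> set[str]:
        return {g for _, g in self.members}


@dataclass
class PangenomePartition:
    core_cogs: list[COG]
    accessory_cogs: list[COG]
    specific_genes: list[str]
    unresolved_genes: list[str]

    @property
    def core_count(self) -> int:
        return len(self.core_cogs)


def _passes_gate(hit: HitRecord, params: BrbhParams) -> bool:
    if hit.internal_mode:
        return hit.bit_score >= params.min_score
    return hit.e_value <= params.max_evalue


def best_hit_per_target_genome(
    hits: Iterable[HitRecord],
    gene_to_genome: Mapping[str, str],
    params: BrbhParams | None = None,
) -> dict[tuple[str, str], str]:
    """Accepted best hit for every (query gene, target genome).

    Within-genome hits are discarded; gated-out hits are discarded; several
    hits to the same subject gene collapse to the strongest.  The remaining
    best hit for a (query, target genome) pair is accepted only when the
    second-best subject in that genome scores strictly below
    ``second_best_ratio`` times the best score.  Returns
    {(query gene, target genome): subject gene} with unaccepted pairs absent.
    """
    params = params or BrbhParams()
    # best score per (query, subject) after the gate
    per_subject: dict[tuple[str, str], float] = {}
    for hit in hits:
        qg = gene_to_genome.get(hit.query_gene_id)
        sg = gene_to_genome.get(hit.subject_gene_id)
        if qg is None or sg is None:
            raise ValidationError(
                f"hit references gene(s) missing from the gene table: "
                f"{hit.query_gene_id!r} -> {hit.subject_gene_id!r}")
        if qg == sg:
            continue  # paralog hits never participate
        if not _passes_gate(hit, params):
            continue
        key = (hit.query_gene_id, hit.subject_gene_id)
        score = hit.bit_score
        if key not in per_subject or score > per_subject[key]:
            per_subject[key] = score

    by_query_genome: dict[tuple[str, str], list[tuple[float, str]]] = {}
    for (query, subject), score in per_subject.items():
        by_query_genome.setdefault(
            (query, gene_to_genome[subject]), []).append((score, subject))

    accepted: dict[tuple[str, str], str] = {}
    for key, scored in by_query_genome.items():
        scored.sort(key=lambda t: (-t[0], t[1]))
        best_score, best_subject = scored[0]
        if len(scored) > 1:
            second_score = scored[1][0]
            if not (second_score < params.second_best_ratio * best_score):
                continue  # ambiguous best: strict "<" boundary
        accepted[key] = best_subject
    return accepted


def reciprocal_pairs(
    best_hits: Mapping[tuple[str, str], str],
    gene_to_genome: Mapping[str, str],
) -> set[tuple[str, str]]:
    """Symmetric, deduplicated BRBH pairs (stored with sorted gene ids)."""
    pairs: set[tuple[str, str]] = set()
    for (query, target_genome), subject in best_hits.items():
        back = best_hits.get((subject, gene_to_genome[query]))
        if back == query:
            pairs.add((query, subject) if query < subject else (subject, query))
    return pairs


def build_cogs(
    pairs: Iterable[tuple[str, str]],
    gene_to_genome: Mapping[str, str],
    strict_clique: bool = False,
) -> list[COG]:
    """Group BRBH pairs into COGs.

    Default: connected components of the BRBH graph.  ``strict_clique``
    instead keeps only maximal components that are cliques, splitting
    non-clique components into their individual BRBH pairs — a deliberately
    conservative alternative for sensitivity analysis.  Singletons are never
    COGs.
    """
    graph = nx.Graph()
    graph.add_edges_from(pairs)
    components: list[set[str]] = [set(c) for c in nx.connected_components(graph)]
    if strict_clique:
        refined: list[set[str]] = []
        for comp in components:
            sub = graph.subgraph(comp)
            k = len(comp)
            if sub.number_of_edges() == k * (k - 1) // 2:
                refined.append(comp)
            else:
                refined.extend({a, b} for a, b in sub.edges())
        components = refined
    cogs: list[COG] = []
    for members in sorted(components, key=lambda c: min(c)):
        if len(members) < 2:
            continue
        member_list = sorted((gene_to_genome[g], g) for g in members)
        cogs.append(COG(cog_id="", members=member_list))
    for i, cog in enumerate(cogs, start=1):
        cog.cog_id = f"COG{i:05d}"
    return cogs


def partition_pangenome(
    cogs: Sequence[COG],
    all_genes: Mapping[str, str],          # gene id -> genome id
    accepted_hits: Mapping[tuple[str, str], str] | set[tuple[str, str]],
    genome_list: Sequence[str],
    specific_by_no_brbh: bool = False,
) -> PangenomePartition:
    """Partition every gene into core / accessory / specific / unresolved.

    Core COGs have exactly one member in every genome of ``genome_list``
    (a genome represented twice demotes the COG to accessory).  Specific
    genes have no accepted cross-genome hit under the gate (default), or —
    with ``specific_by_no_brbh`` — merely no BRBH partner.
    """
    if len(genome_list) < 2:
        raise InputError("pangenome partition is undefined for < 2 genomes")
    genome_set = set(genome_list)
    for cog in cogs:
        for genome_id, gene_id in cog.members:
            if gene_id not in all_genes:
                raise ValidationError(
                    f"{cog.cog_id}: member {gene_id!r} absent from gene set")
            if genome_id not in genome_set:
                raise ValidationError(
                    f"{cog.cog_id}: genome {genome_id!r} not in genome list")

    core: list[COG] = []
    accessory: list[COG] = []
    for cog in cogs:
        counts = {g: 0 for g in genome_list}
        for genome_id, _ in cog.members:
            counts[genome_id] += 1
        if all(c == 1 for c in counts.values()):
            core.append(cog)
        else:
            accessory.append(cog)

    clustered = {gene for cog in cogs for _, gene in cog.members}
    if isinstance(accepted_hits, Mapping):
        with_hits = {q for (q, _tg) in accepted_hits}
        with_hits |= set(accepted_hits.values())
    else:
        with_hits = {g for pair in accepted_hits for g in pair}
    if specific_by_no_brbh:
        in_pairs = clustered  # every BRBH member is clustered by construction
        specific = sorted(g for g in all_genes if g not in in_pairs)
        unresolved: list[str] = []
    else:
        specific = sorted(g for g in all_genes
                          if g not in clustered and g not in with_hits)
        unresolved = sorted(g for g in all_genes
                            if g not in clustered and g in with_hits)
    return PangenomePartition(
        core_cogs=core, accessory_cogs=accessory,
        specific_genes=specific, unresolved_genes=unresolved)
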