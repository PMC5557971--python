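"""Functional enrichment and positional (per-contig) enrichment tests.

GO annotation is transferred to genes through their Pfam domains and the
community pfam2go mapping.  Over-representation of a GO term among
differentially expressed (DE) genes is scored with the exact upper-tail
hypergeometric probability, Bonferroni-corrected over the terms actually
observed in the tested gene set, and reported alongside the fold
enrichment (k/n)/(K/N).  The background is all protein-coding genes of
the focal genome, annotated or not (an annotated-only background is
available by flag).

Positional enrichment of DE genes on one contig versus another is a 2x2
Pearson chi-squared test with one degree of freedom, optionally with the
Yates continuity correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from scipy.stats import chi2

from .errors import InputError
from .io import DERecord


# ---------------------------------------------------------------------------
# annotation transfer
# ---------------------------------------------------------------------------

@dataclass
class GoAnnotation:
    gene_to_go: dict[str, set[str]]
    unmapped_pfams: set[str]  # accessions seen on genes but absent from pfam2go


def annotate_genes_go(
    domain_table: Mapping[str, set[str]],
    pfam2go_map: Mapping[str, set[str]],
) -> GoAnnotation:
    """Transfer GO terms to genes via their Pfam accessions.

    A gene's GO set is the union over its domains of the mapped GO ids.
    Genes without mapped domains get the empty set but stay in the
    background; unmapped accessions are collected in a warning summary.
    """
    gene_to_go: dict[str, set[str]] = {}
    unmapped: set[str] = set()
    for gene, accessions in domain_table.items():
        terms: set[str] = set()
        for acc in accessions:
            mapped = pfam2go_map.get(acc)
            if mapped is None:
                unmapped.add(acc)
            else:
                terms |= mapped
        gene_to_go[gene] = terms
    return GoAnnotation(gene_to_go=gene_to_go, unmapped_pfams=unmapped)


# ---------------------------------------------------------------------------
# exact hypergeometric tail
# ---------------------------------------------------------------------------

def _log_choose(n: int, k: int) -> float:
    return math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """Exact P(X >= k) for X ~ Hypergeometric(N population, K marked, n drawn).

    Computed by summing pmf terms in log space (lgamma) for stability.
    """
    for name, v in (("k", k), ("K", K), ("n", n), ("N", N)):
        if not isinstance(v, (int,)) or v < 0:
            raise InputError(f"{name} must be a non-negative integer")
    if K > N or n > N or k > min(n, K):
        raise InputError(
            f"inconsistent counts: k={k}, K={K}, n={n}, N={N} "
            f"(need K <= N, n <= N, k <= min(n, K))")
    if k == 0:
        return 1.0
    hi = min(n, K)
    lo = max(0, n - (N - K))
    log_denominator = _log_choose(N, n)
    terms = [
        math.exp(_log_choose(K, x) + _log_choose(N - K, n - x) - log_denominator)
        for x in range(max(k, lo), hi + 1)
    ]
    return min(1.0, max(0.0, math.fsum(terms)))


# ---------------------------------------------------------------------------
# gene-set over-representation
# ---------------------------------------------------------------------------

@dataclass
class GeneSetTest:
    term_id: str
    k: int                 # DE genes carrying the term
    n: int                 # DE genes in the background
    K: int                 # background genes carrying the term
    N: int                 # background size
    fold_enrichment: float
    p_raw: float
    p_adj: float


def enrich_gene_set(
    de_genes: Iterable[str],
    background_genes: Iterable[str],
    gene_to_go: Mapping[str, set[str]],
    annotated_only_background: bool = False,
) -> list[GeneSetTest]:
    """Hypergeometric over-representation of GO terms among DE genes.

    One test per term observed at least once in the DE set; Bonferroni
    multiplier m = number of terms tested; rows sorted by adjusted p then
    term id.  An empty DE set yields an empty result.
    """
    background = set(background_genes)
    de = set(de_genes)
    if not de <= background:
        raise InputError("DE genes must be a subset of the background")
    if annotated_only_background:
        background = {g for g in background if gene_to_go.get(g)}
        de = de & background
    if not de:
        return []
    N, n = len(background), len(de)
    term_K: dict[str, int] = {}
    term_k: dict[str, int] = {}
    for gene in background:
        for term in gene_to_go.get(gene, ()):
            term_K[term] = term_K.get(term, 0) + 1
            if gene in de:
                term_k[term] = term_k.get(term, 0) + 1
    m = len(term_k)
    results = []
    for term, k in term_k.items():
        K = term_K[term]
        p_raw = hypergeom_upper_tail(k, K, n, N)
        results.append(GeneSetTest(
            term_id=term, k=k, n=n, K=K, N=N,
            fold_enrichment=(k / n) / (K / N),
            p_raw=p_raw, p_adj=min(1.0, p_raw * m),
        ))
    results.sort(key=lambda t: (t.p_adj, t.term_id))
    return results


# ---------------------------------------------------------------------------
# DE-gene selection
# ---------------------------------------------------------------------------

@dataclass
class DESelection:
    up: set[str]
    down: set[str]
    ambiguous: set[str]  # significant q but log2FC exactly 0


def select_de_genes(records: Sequence[DERecord], alpha: float = 0.05) -> DESelection:
    """Split genes into up-/down-regulated sets at a strict q < alpha gate.

    Rows with q exactly alpha are excluded; significant rows with a
    log2 fold change of exactly zero land in the ``ambiguous`` warning
    bucket, assigned to neither direction.  Infinite fold changes keep
    their sign.
    """
    up: set[str] = set()
    down: set[str] = set()
    ambiguous: set[str] = set()
    for rec in records:
        if not rec.q_value < alpha:
            continue
        if rec.log2_fold_change > 0:
            up.add(rec.gene_id)
        elif rec.log2_fold_change < 0:
            down.add(rec.gene_id)
        else:
            ambiguous.add(rec.gene_id)
    return DESelection(up=up, down=down, ambiguous=ambiguous)


# ---------------------------------------------------------------------------
# positional chi-squared
# ---------------------------------------------------------------------------

@dataclass
class ContigEnrichmentTest:
    table: tuple[tuple[int, int], tuple[int, int]]  # [[de_A, rest_A], [de_B, rest_B]]
    statistic: float
    dof: int
    p_value: float
    yates: bool


def contig_chi_squared(
    de_on_a: int, genes_on_a: int, de_on_b: int, genes_on_b: int,
    yates: bool = False,
) -> ContigEnrichmentTest:
    """Pearson chi-squared (df=1) for DE-gene concentration on contig B vs A.

    Builds the 2x2 table [[de_A, genes_A - de_A], [de_B, genes_B - de_B]];
    the statistic is the textbook sum of (O - E)^2 / E over the four cells
    (with the optional Yates |O - E| - 1/2 continuity correction); p is the
    chi-squared upper tail.
    """
    if de_on_a > genes_on_a or de_on_b > genes_on_b:
        raise InputError("DE counts cannot exceed the total gene counts")
    if min(de_on_a, genes_on_a, de_on_b, genes_on_b) < 0:
        raise InputError("counts must be non-negative")
    observed = [[de_on_a, genes_on_a - de_on_a],
                [de_on_b, genes_on_b - de_on_b]]
    total = genes_on_a + genes_on_b
    col_sums = [observed[0][0] + observed[1][0], observed[0][1] + observed[1][1]]
    row_sums = [genes_on_a, genes_on_b]
    stat = 0.0
    for i in range(2):
        for j in range(2):
            expected = row_sums[i] * col_sums[j] / total
            if expected == 0:
                raise InputError(
                    "a cell has expected count 0; use an exact test instead")
            diff = abs(observed[i][j] - expected)
            if yates:
                diff = max(0.0, diff - 0.5)
            stat += diff * diff / expected
    return ContigEnrichmentTest(
        table=((observed[0][0], observed[0][1]),
               (observed[1][0], observed[1][1])),
        statistic=stat, dof=1, p_value=float(chi2.sf(stat, 1)), yates=yates,
    )
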