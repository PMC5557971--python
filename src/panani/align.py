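"""Internal pairwise local alignment (protein and nucleotide).

The pipeline can run without an external search tool: protein orthology
mode uses Smith-Waterman under BLOSUM80 with affine gaps, and nucleotide
ANIb fragment mode uses match/mismatch scoring over both strands.
External tabular hit files remain a first-class alternative input.

Gap convention: a gap of length L costs ``open + extend * L`` (the first
gapped position pays both the opening and one extension).

Internal-mode statistics: true Karlin-Altschul e-values are not computed.
``all_vs_all_protein_hits`` fills ``bit_score`` with the raw
Smith-Waterman score, fills ``e_value`` with a length-normalized
surrogate ``len(q) * len(s) * 2**(-score)`` and flags each record with
``internal_mode=True``; downstream best-reciprocal-hit filtering then
gates on a minimum raw score rather than on e-values.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from functools import lru_cache
from typing import Mapping

from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from .errors import InputError
from .io import HitRecord

_AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX*")
_NT_ALPHABET = set("ACGTN")


@dataclass(frozen=True)
class ProteinAlignParams:
    """Smith-Waterman parameters for protein mode."""

    matrix: str = "BLOSUM80"
    gap_open: float = 10.0
    gap_extend: float = 1.0
    # Reporting floor for internal-mode hits.  Chance local alignments of
    # unrelated ~300-residue proteins under this scoring reach raw scores of
    # ~150-220 across an all-vs-all search (shuffle null, see tests), while
    # genuine orthologs at <= 0.15 per-site divergence score > 1000; the
    # default sits above the chance regime with a wide margin.
    min_score: float = 300.0
    min_shared_kmers: int = 2     # seed prefilter for all-vs-all searches
    kmer_size: int = 5


@dataclass(frozen=True)
class NucleotideAlignParams:
    """Scoring and seeding parameters for nucleotide fragment mode."""

    match: float = 2.0
    mismatch: float = 3.0         # penalty (positive number)
    gap_open: float = 5.0
    gap_extend: float = 2.0
    kmer_size: int = 11           # anchor seed length
    exhaustive_below: int = 5000  # full DP when the target is shorter


@dataclass
class AlignmentResult:
    """Outcome of one local alignment.

    ``percent_identity`` is the fraction of alignment columns (gap columns
    included) that are identical matches; ``query_coverage`` is the portion
    of the query sequence inside the locally aligned region.
    """

    score: float
    percent_identity: float
    query_coverage: float
    aligned_length: int


_EMPTY = AlignmentResult(score=0.0, percent_identity=0.0,
                         query_coverage=0.0, aligned_length=0)


@lru_cache(maxsize=8)
def _protein_aligner(matrix: str, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


@lru_cache(maxsize=8)
def _nucleotide_aligner(match: float, mismatch: float, gap_open: float,
                        gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = match
    aligner.mismatch_score = -mismatch
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def _summarize(alignment, query_len: int) -> AlignmentResult:
    counts = alignment.counts()
    ident, mism, gaps = counts.identities, counts.mismatches, counts.gaps
    cols = ident + mism + gaps
    if cols == 0:
        return _EMPTY
    qblocks = alignment.aligned[0]  # first sequence passed to align()
    span = qblocks[-1][1] - qblocks[0][0]
    return AlignmentResult(
        score=float(alignment.score),
        percent_identity=100.0 * ident / cols,
        query_coverage=span / query_len,
        aligned_length=int(cols),
    )


def _best_alignment(aligner, query: str, subject: str):
    alignments = aligner.align(query, subject)
    if alignments.score <= 0:
        return None
    return alignments[0]


def local_align_protein(
    a: str, b: str, params: ProteinAlignParams | None = None,
) -> AlignmentResult:
    """Optimal Smith-Waterman local alignment of two protein sequences.

    Returns the zero/empty result when no positive-scoring local alignment
    exists.  Coverage is reported for ``a``.
    """
    params = params or ProteinAlignParams()
    for name, seq in (("a", a), ("b", b)):
        if not seq:
            raise InputError(f"sequence {name} is empty")
        bad = set(seq) - _AA_ALPHABET
        if bad:
            raise InputError(f"sequence {name}: invalid residue(s) {sorted(bad)}")
    aligner = _protein_aligner(params.matrix, params.gap_open, params.gap_extend)
    best = _best_alignment(aligner, a, b)
    if best is None:
        return _EMPTY
    return _summarize(best, len(a))


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def _kmer_index(seq: str, k: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = {}
    for j in range(len(seq) - k + 1):
        index.setdefault(seq[j:j + k], []).append(j)
    return index


def _anchor_windows(fragment: str, index: Mapping[str, list[int]],
                    k: int, target_len: int, n_windows: int = 3,
                    bucket: int = 150, pad: int = 100
                    ) -> list[tuple[int, tuple[int, int]]]:
    """Vote on alignment diagonals with k-mer anchors.

    Returns ``(votes, (lo, hi))`` candidate target windows (0-based
    half-open), strongest first.  A true diagonal near a bucket edge splits
    its votes over two adjacent buckets; both survive and are merged by the
    caller.
    """
    votes: Counter[int] = Counter()
    for i in range(len(fragment) - k + 1):
        for j in index.get(fragment[i:i + k], ()):
            votes[(j - i) // bucket] += 1
    windows = []
    for b, n in votes.most_common(n_windows):
        lo = max(0, b * bucket - pad)
        hi = min(target_len, (b + 1) * bucket + len(fragment) + pad)
        windows.append((n, (lo, hi)))
    return windows


def _merge_windows(windows: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for lo, hi in sorted(windows):
        if merged and lo <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], hi))
        else:
            merged.append((lo, hi))
    return merged


def local_align_nucleotide(
    fragment: str, target: str, params: NucleotideAlignParams | None = None,
    target_index: Mapping[str, list[int]] | None = None,
) -> AlignmentResult | None:
    """Best local alignment of ``fragment`` against ``target`` over BOTH
    strands (the reverse complement of the fragment is also searched).

    Short targets (below ``params.exhaustive_below``) are aligned with
    exhaustive dynamic programming; longer targets are first anchored with
    shared k-mers and the fragment is aligned against the few best candidate
    windows.  Returns ``None`` when no positive-scoring hit is found.

    ``target_index`` optionally supplies a precomputed k-mer index of the
    target (as built by the ANIb layer when one subject serves many
    fragments).
    """
    params = params or NucleotideAlignParams()
    if not fragment:
        raise InputError("fragment is empty")
    if not target:
        raise InputError("target is empty")
    for name, seq in (("fragment", fragment), ("target", target)):
        bad = set(seq) - _NT_ALPHABET
        if bad:
            raise InputError(f"{name}: invalid base(s) {sorted(bad)}")
    aligner = _nucleotide_aligner(params.match, params.mismatch,
                                  params.gap_open, params.gap_extend)
    orientations = (fragment, _revcomp(fragment))
    best: AlignmentResult | None = None
    if len(target) < params.exhaustive_below and target_index is None:
        candidates = [(orient, target) for orient in orientations]
    else:
        index = target_index if target_index is not None else _kmer_index(
            target, params.kmer_size)
        voted: list[tuple[int, str, tuple[int, int]]] = []
        for orient in orientations:
            for n, window in _anchor_windows(orient, index, params.kmer_size,
                                             len(target)):
                voted.append((n, orient, window))
        if not voted:
            return None
        # drop windows far below the strongest evidence (wrong strand, noise)
        top = max(n for n, _, _ in voted)
        keep: dict[str, list[tuple[int, int]]] = {}
        for n, orient, window in voted:
            if n >= max(3, 0.1 * top) or n == top:
                keep.setdefault(orient, []).append(window)
        candidates = [
            (orient, target[lo:hi])
            for orient, windows in keep.items()
            for lo, hi in _merge_windows(windows)
        ]
    for orient, window in candidates:
        alignment = _best_alignment(aligner, orient, window)
        if alignment is None:
            continue
        result = _summarize(alignment, len(fragment))
        if best is None or result.score > best.score:
            best = result
    return best


# ---------------------------------------------------------------------------
# all-vs-all protein search (internal mode)
# ---------------------------------------------------------------------------

def _protein_kmers(seq: str, k: int) -> set[str]:
    return {seq[i:i + k] for i in range(len(seq) - k + 1)}


def _candidate_pairs(
    proteomes: Mapping[str, Mapping[str, str]], params: ProteinAlignParams,
) -> list[tuple[tuple[str, str], tuple[str, str]]]:
    """Cross-genome gene pairs sharing at least ``min_shared_kmers`` k-mers."""
    postings: dict[str, list[tuple[str, str]]] = {}
    for genome_id, genes in proteomes.items():
        for gene_id, seq in genes.items():
            for kmer in _protein_kmers(seq, params.kmer_size):
                postings.setdefault(kmer, []).append((genome_id, gene_id))
    shared: Counter[tuple[tuple[str, str], tuple[str, str]]] = Counter()
    for members in postings.values():
        if len(members) < 2:
            continue
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                a, b = members[i], members[j]
                if a[0] == b[0]:
                    continue  # within-genome pairs are never searched
                shared[(a, b) if a <= b else (b, a)] += 1
    return sorted(p for p, c in shared.items() if c >= params.min_shared_kmers)


def _hit_from_alignment(alignment, query_id: str, subject_id: str,
                        qlen: int, slen: int) -> HitRecord:
    counts = alignment.counts()
    cols = counts.identities + counts.mismatches + counts.gaps
    qblocks, sblocks = alignment.aligned
    score = float(alignment.score)
    return HitRecord(
        query_gene_id=query_id, subject_gene_id=subject_id,
        percent_identity=round(100.0 * counts.identities / cols, 2),
        alignment_length=int(cols), mismatches=int(counts.mismatches),
        gap_opens=max(len(qblocks) - 1, 0),
        q_start=int(qblocks[0][0]) + 1, q_end=int(qblocks[-1][1]),
        s_start=int(sblocks[0][0]) + 1, s_end=int(sblocks[-1][1]),
        e_value=float(qlen) * float(slen) * 2.0 ** (-score),
        bit_score=score, internal_mode=True,
    )


def _mirror(hit: HitRecord) -> HitRecord:
    return HitRecord(
        query_gene_id=hit.subject_gene_id, subject_gene_id=hit.query_gene_id,
        percent_identity=hit.percent_identity,
        alignment_length=hit.alignment_length, mismatches=hit.mismatches,
        gap_opens=hit.gap_opens,
        q_start=hit.s_start, q_end=hit.s_end,
        s_start=hit.q_start, s_end=hit.q_end,
        e_value=hit.e_value, bit_score=hit.bit_score, internal_mode=True,
    )


def all_vs_all_protein_hits(
    proteomes: Mapping[str, Mapping[str, str]],
    params: ProteinAlignParams | None = None,
) -> list[HitRecord]:
    """Cross-genome all-vs-all protein search with the internal aligner.

    ``proteomes`` maps genome id -> {gene id -> amino-acid sequence}.  Every
    ordered cross-genome pair whose Smith-Waterman score reaches
    ``params.min_score`` yields one :class:`HitRecord`; local-alignment score
    symmetry means each unordered pair is aligned once and mirrored.  Results
    are independent of genome input order up to record reordering (records
    are emitted in sorted pair order).
    """
    params = params or ProteinAlignParams()
    if len(proteomes) < 2:
        raise InputError("all-vs-all search needs at least 2 genomes")
    hits: list[HitRecord] = []
    for (ga, gene_a), (gb, gene_b) in _candidate_pairs(proteomes, params):
        seq_a, seq_b = proteomes[ga][gene_a], proteomes[gb][gene_b]
        aligner = _protein_aligner(params.matrix, params.gap_open,
                                   params.gap_extend)
        best = _best_alignment(aligner, seq_a, seq_b)
        if best is None or best.score < params.min_score:
            continue
        hit = _hit_from_alignment(best, gene_a, gene_b, len(seq_a), len(seq_b))
        hits.append(hit)
        hits.append(_mirror(hit))
    return hits
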