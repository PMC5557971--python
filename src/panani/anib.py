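"""Goris-style ANIb between genome pairs and the pairwise matrix.

The query genome is cut into consecutive fixed-length fragments (default
1020 nt).  Each fragment is locally aligned against the whole subject
genome over both strands; fragments whose best hit reaches the identity
and fragment-coverage thresholds (defaults 30% and 0.70) contribute their
percent identity, and ANIb is the arithmetic mean of the contributing
identities.  A pair with no qualifying fragment has *undefined* ANIb,
represented as NaN and reported in the matrix warnings — it is never
silently coerced to a number, because averaging zeros would bias the
downstream distances.

ANIb is asymmetric (query fragments vs subject genome); both directions
are kept in the matrix and only averaged when converting to the symmetric
distance d(i,j) = 1 - mean(ANIb(i,j), ANIb(j,i)) / 100 that feeds
neighbor joining.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .align import NucleotideAlignParams, local_align_nucleotide, _kmer_index
from .errors import InputError, ValidationError
from .io import GenomeRecord


@dataclass(frozen=True)
class AnibParams:
    fragment_length: int = 1020
    min_identity: float = 30.0        # percent
    min_coverage: float = 0.70        # fraction of the fragment
    min_terminal_fragment: int = 100  # shorter contig remainders are dropped
    alignment: NucleotideAlignParams = field(default_factory=NucleotideAlignParams)

    def __post_init__(self) -> None:
        if self.fragment_length <= 0:
            raise InputError("fragment_length must be positive")
        if not (0.0 <= self.min_identity <= 100.0):
            raise InputError("min_identity must be a percentage in [0, 100]")
        if not (0.0 <= self.min_coverage <= 1.0):
            raise InputError("min_coverage must be a fraction in [0, 1]")
        if self.min_terminal_fragment < 0:
            raise InputError("min_terminal_fragment must be >= 0")


@dataclass
class Fragment:
    """One query window, 1-based inclusive on its contig."""

    contig_id: str
    start: int
    end: int
    sequence: str


@dataclass
class ANIMatrix:
    """Asymmetric pairwise ANIb values in percent; diagonal exactly 100.

    Undefined pairs (no qualifying fragment) are NaN; each is listed in
    ``warnings``.
    """

    genome_ids: list[str]
    values: np.ndarray
    warnings: list[str] = field(default_factory=list)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        q, s = pair
        return float(self.values[self.genome_ids.index(q),
                                 self.genome_ids.index(s)])


def fragment_genome(genome: GenomeRecord, params: AnibParams | None = None) -> list[Fragment]:
    """Cut each contig into consecutive non-overlapping windows.

    Windows of ``fragment_length`` start at position 1; a terminal remainder
    is kept iff it is at least ``min_terminal_fragment`` long.
    """
    params = params or AnibParams()
    fragments: list[Fragment] = []
    for contig_id, seq in genome.contigs:
        pos = 1
        n = len(seq)
        while pos <= n:
            end = min(pos + params.fragment_length - 1, n)
            length = end - pos + 1
            if length == params.fragment_length or length >= params.min_terminal_fragment:
                fragments.append(Fragment(contig_id, pos, end, seq[pos - 1:end]))
            pos = end + 1
    return fragments


def _subject_indexes(subject: GenomeRecord, params: AnibParams):
    """One k-mer index per subject contig, shared by all query fragments."""
    return [(seq, _kmer_index(seq, params.alignment.kmer_size))
            for _, seq in subject.contigs]


def _qualifying_identities(query: GenomeRecord, subject: GenomeRecord,
                           params: AnibParams,
                           indexes=None) -> list[float]:
    identities: list[float] = []
    if indexes is None:
        indexes = _subject_indexes(subject, params)
    for fragment in fragment_genome(query, params):
        best = None
        for seq, index in indexes:
            hit = local_align_nucleotide(fragment.sequence, seq,
                                         params.alignment, target_index=index)
            if hit is not None and (best is None or hit.score > best.score):
                best = hit
        if (best is not None
                and best.percent_identity >= params.min_identity
                and best.query_coverage >= params.min_coverage):
            identities.append(best.percent_identity)
    return identities


def anib_pair(query: GenomeRecord, subject: GenomeRecord,
              params: AnibParams | None = None, _indexes=None) -> float:
    """ANIb of ``query`` against ``subject`` in percent.

    Returns NaN (the undefined marker) when no fragment qualifies.
    Identical genome objects short-circuit to exactly 100.
    """
    params = params or AnibParams()
    if query.genome_id == subject.genome_id and query.contigs == subject.contigs:
        return 100.0
    identities = _qualifying_identities(query, subject, params, _indexes)
    if not identities:
        return math.nan
    return float(np.mean(identities))


def anib_matrix(genomes: list[GenomeRecord],
                params: AnibParams | None = None) -> ANIMatrix:
    """All ordered pairs; diagonal 100; undefined pairs collected as warnings."""
    params = params or AnibParams()
    if len(genomes) < 2:
        raise InputError("ANIb matrix needs at least 2 genomes")
    ids = [g.genome_id for g in genomes]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate genome ids")
    k = len(genomes)
    values = np.full((k, k), np.nan)
    warnings: list[str] = []
    indexes = {g.genome_id: _subject_indexes(g, params) for g in genomes}
    for i, gq in enumerate(genomes):
        for j, gs in enumerate(genomes):
            if i == j:
                values[i, j] = 100.0
                continue
            values[i, j] = anib_pair(gq, gs, params,
                                     _indexes=indexes[gs.genome_id])
            if math.isnan(values[i, j]):
                warnings.append(
                    f"ANIb undefined for ({ids[i]}, {ids[j]}): "
                    f"no fragment passed the identity/coverage thresholds")
    return ANIMatrix(genome_ids=ids, values=values, warnings=warnings)


def ani_to_distance(matrix: ANIMatrix) -> tuple[list[str], np.ndarray]:
    """Symmetric distances d(i,j) = 1 - mean(ANIb(i,j), ANIb(j,i)) / 100.

    Raises on undefined entries, listing the offending pairs.
    """
    v = matrix.values
    bad = [
        (matrix.genome_ids[i], matrix.genome_ids[j])
        for i in range(len(matrix.genome_ids))
        for j in range(len(matrix.genome_ids))
        if i < j and (math.isnan(v[i, j]) or math.isnan(v[j, i]))
    ]
    if bad:
        raise ValidationError(f"undefined ANIb for pair(s): {bad}")
    mean = (v + v.T) / 2.0
    d = 1.0 - mean / 100.0
    np.fill_diagonal(d, 0.0)
    return list(matrix.genome_ids), d
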