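"""Readers and writers for every external format the pipeline touches.

Formats: FASTA (genomes, proteomes), the TSV gene table, BLAST tabular
"outfmt 6" hit files, the pfam2go flat file, Cuffdiff ``gene_exp.diff``-style
differential-expression tables, newick trees and labeled TSV matrices.

Conventions: coordinates are 1-based inclusive throughout; gene, contig and
genome identifiers are opaque case-sensitive strings; readers reject
structurally invalid input instead of silently repairing it.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqIO.FastaIO import FastaWriter
from Bio.SeqRecord import SeqRecord

from .errors import FormatError, ValidationError

_NUC_ALPHABET = set("ACGTN")


# ---------------------------------------------------------------------------
# domain records
# ---------------------------------------------------------------------------

@dataclass
class GenomeRecord:
    """A (possibly multi-contig) genome assembly."""

    genome_id: str
    contigs: list[tuple[str, str]]  # ordered (contig_id, sequence)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for cid, seq in self.contigs:
            if cid in seen:
                raise ValidationError(
                    f"genome {self.genome_id!r}: duplicate contig id {cid!r}")
            seen.add(cid)
            if not seq:
                raise ValidationError(
                    f"genome {self.genome_id!r}: contig {cid!r} is empty")
            bad = set(seq) - _NUC_ALPHABET
            if bad:
                raise ValidationError(
                    f"genome {self.genome_id!r}: contig {cid!r} has invalid "
                    f"characters {sorted(bad)}")

    def contig_seq(self, contig_id: str) -> str:
        for cid, seq in self.contigs:
            if cid == contig_id:
                return seq
        raise KeyError(contig_id)

    @property
    def length(self) -> int:
        return sum(len(s) for _, s in self.contigs)


@dataclass
class GeneModel:
    """One protein-coding gene located on a contig (1-based inclusive)."""

    gene_id: str
    genome_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    protein: str = ""

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(
                f"gene {self.gene_id!r}: unknown strand {self.strand!r}")
        if not (1 <= self.start <= self.end):
            raise ValidationError(
                f"gene {self.gene_id!r}: invalid coordinates "
                f"{self.start}..{self.end} (1-based inclusive)")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def cds(self, genome: GenomeRecord) -> str:
        """Coding sequence in reading orientation."""
        seq = genome.contig_seq(self.contig_id)[self.start - 1:self.end]
        if self.strand == "-":
            seq = str(Seq(seq).reverse_complement())
        return seq


@dataclass
class HitRecord:
    """One pairwise protein similarity hit (outfmt-6 column order)."""

    query_gene_id: str
    subject_gene_id: str
    percent_identity: float
    alignment_length: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    e_value: float
    bit_score: float
    internal_mode: bool = False  # bit_score holds a raw SW score

    def __post_init__(self) -> None:
        if not (0.0 <= self.percent_identity <= 100.0):
            raise ValidationError(
                f"hit {self.query_gene_id}->{self.subject_gene_id}: "
                f"identity {self.percent_identity} outside [0, 100]")
        if self.e_value < 0:
            raise ValidationError(
                f"hit {self.query_gene_id}->{self.subject_gene_id}: "
                f"negative e-value {self.e_value}")
        if not math.isfinite(self.bit_score):
            raise ValidationError(
                f"hit {self.query_gene_id}->{self.subject_gene_id}: "
                f"non-finite score")


@dataclass
class DERecord:
    """One gene's differential-expression result (Cuffdiff dialect)."""

    gene_id: str
    value_1: float
    value_2: float
    log2_fold_change: float
    q_value: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.q_value <= 1.0):
            raise ValidationError(
                f"gene {self.gene_id!r}: q-value {self.q_value} outside [0, 1]")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into ``[(id, SEQUENCE), ...]``.

    Sequences are uppercased on read.  Duplicate ids, empty sequences and
    malformed headers raise :class:`FormatError` with the offending line
    number.
    """
    path = Path(path)
    header_lines: list[int] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(">"):
                if line[1:].strip() == "":
                    raise FormatError(f"{path.name}:{lineno}: malformed header")
                header_lines.append(lineno)
            elif line.strip() and not header_lines:
                raise FormatError(
                    f"{path.name}:{lineno}: sequence data before first header")
    records: list[tuple[str, str]] = []
    seen: dict[str, int] = {}
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta")):
        lineno = header_lines[i]
        if rec.id in seen:
            raise FormatError(
                f"{path.name}:{lineno}: duplicate id {rec.id!r} "
                f"(first seen at line {seen[rec.id]})")
        seen[rec.id] = lineno
        seq = str(rec.seq).upper()
        if not seq:
            raise FormatError(f"{path.name}:{lineno}: empty sequence {rec.id!r}")
        records.append((rec.id, seq))
    return records


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    """Write ``(id, sequence)`` pairs as FASTA wrapped at 80 columns."""
    seq_records = [SeqRecord(Seq(s), id=i, description="") for i, s in records]
    with open(path, "w") as fh:
        FastaWriter(fh, wrap=80).write_file(seq_records)


def read_genome_fasta(path: str | Path, genome_id: str | None = None) -> GenomeRecord:
    """Read one genome FASTA (contigs) into a :class:`GenomeRecord`."""
    path = Path(path)
    gid = genome_id if genome_id is not None else path.stem
    return GenomeRecord(genome_id=gid, contigs=read_fasta(path))


# ---------------------------------------------------------------------------
# gene table
# ---------------------------------------------------------------------------

_GENE_TABLE_COLS = ["genome", "contig", "gene_id", "start", "end", "strand"]


def read_gene_table(
    path: str | Path,
    genomes: Mapping[str, GenomeRecord] | None = None,
    proteomes: Mapping[str, str] | None = None,
) -> list[GeneModel]:
    """Read the TSV gene table (genome, contig, gene_id, start, end, strand).

    When ``genomes`` is given, contig existence and ``end <= contig length``
    are checked.  ``proteomes`` (gene id -> amino-acid sequence) optionally
    attaches protein sequences.  Errors carry the 1-based data row number.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _GENE_TABLE_COLS if c not in df.columns]
    if missing:
        raise FormatError(f"{path.name}: missing column(s) {missing}")
    genes: list[GeneModel] = []
    seen: dict[str, int] = {}
    for row_no, row in enumerate(df.itertuples(index=False), start=1):
        try:
            start, end = int(row.start), int(row.end)
        except ValueError as exc:
            raise FormatError(f"{path.name}: row {row_no}: {exc}") from exc
        if row.gene_id in seen:
            raise ValidationError(
                f"{path.name}: row {row_no}: duplicate gene_id {row.gene_id!r} "
                f"(first at row {seen[row.gene_id]})")
        seen[row.gene_id] = row_no
        try:
            gene = GeneModel(
                gene_id=row.gene_id, genome_id=row.genome, contig_id=row.contig,
                start=start, end=end, strand=row.strand,
                protein=(proteomes or {}).get(row.gene_id, ""),
            )
        except ValidationError as exc:
            raise ValidationError(f"{path.name}: row {row_no}: {exc}") from exc
        if genomes is not None:
            genome = genomes.get(gene.genome_id)
            if genome is None:
                raise ValidationError(
                    f"{path.name}: row {row_no}: unknown genome {gene.genome_id!r}")
            try:
                clen = len(genome.contig_seq(gene.contig_id))
            except KeyError:
                raise ValidationError(
                    f"{path.name}: row {row_no}: unknown contig "
                    f"{gene.contig_id!r} in genome {gene.genome_id!r}") from None
            if gene.end > clen:
                raise ValidationError(
                    f"{path.name}: row {row_no}: end {gene.end} exceeds contig "
                    f"length {clen}")
        genes.append(gene)
    return genes


def write_gene_table(genes: Sequence[GeneModel], path: str | Path) -> None:
    df = pd.DataFrame(
        [(g.genome_id, g.contig_id, g.gene_id, g.start, g.end, g.strand)
         for g in genes],
        columns=_GENE_TABLE_COLS,
    )
    df.to_csv(path, sep="\t", index=False)


def genes_by_genome(genes: Iterable[GeneModel]) -> dict[str, list[GeneModel]]:
    out: dict[str, list[GeneModel]] = {}
    for g in genes:
        out.setdefault(g.genome_id, []).append(g)
    return out


def genes_by_contig(genes: Iterable[GeneModel]) -> dict[tuple[str, str], list[GeneModel]]:
    """Group by (genome, contig), sorted by start coordinate."""
    out: dict[tuple[str, str], list[GeneModel]] = {}
    for g in genes:
        out.setdefault((g.genome_id, g.contig_id), []).append(g)
    for key in out:
        out[key].sort(key=lambda g: g.start)
    return out


# ---------------------------------------------------------------------------
# BLAST tabular ("outfmt 6")
# ---------------------------------------------------------------------------

def read_tabular_hits(path: str | Path) -> list[HitRecord]:
    """Parse a 12-column tab-separated hit file; row order is preserved."""
    path = Path(path)
    hits: list[HitRecord] = []
    with open(path) as fh:
        for row_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise FormatError(
                    f"{path.name}: row {row_no}: expected 12 columns, "
                    f"got {len(fields)}")
            try:
                hits.append(HitRecord(
                    query_gene_id=fields[0], subject_gene_id=fields[1],
                    percent_identity=float(fields[2]),
                    alignment_length=int(fields[3]), mismatches=int(fields[4]),
                    gap_opens=int(fields[5]), q_start=int(fields[6]),
                    q_end=int(fields[7]), s_start=int(fields[8]),
                    s_end=int(fields[9]), e_value=float(fields[10]),
                    bit_score=float(fields[11]),
                ))
            except ValueError as exc:
                raise FormatError(f"{path.name}: row {row_no}: {exc}") from exc
    return hits


def write_tabular_hits(hits: Sequence[HitRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write("\t".join(map(str, (
                h.query_gene_id, h.subject_gene_id, h.percent_identity,
                h.alignment_length, h.mismatches, h.gap_opens, h.q_start,
                h.q_end, h.s_start, h.s_end, h.e_value, h.bit_score))) + "\n")


# ---------------------------------------------------------------------------
# pfam2go
# ---------------------------------------------------------------------------

_PFAM2GO_RE = re.compile(
    r"^Pfam:(?P<acc>PF\d{5})\s+\S+\s*>\s*GO:.*?\s*;\s*(?P<go>GO:\d{7})\s*$")


def read_pfam2go(path: str | Path) -> dict[str, set[str]]:
    """Parse the community pfam2go mapping into Pfam accession -> GO id set.

    Lines look like ``Pfam:PF04234 CopC > GO:copper ion binding ; GO:0005507``;
    ``!`` comment lines are skipped.  One Pfam accession may map to many GO
    terms (mappings on repeated lines are unioned) and vice versa.
    """
    path = Path(path)
    mapping: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("!"):
                continue
            m = _PFAM2GO_RE.match(line)
            if m is None:
                raise FormatError(f"{path.name}:{lineno}: malformed mapping line")
            mapping.setdefault(m.group("acc"), set()).add(m.group("go"))
    return mapping


def read_gene_pfam_table(path: str | Path) -> dict[str, set[str]]:
    """Read a two-column TSV (gene_id, pfam_acc) into gene -> Pfam-accession set.

    A gene may appear on several rows (one per domain).
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("gene_id", "pfam_acc"):
        if col not in df.columns:
            raise FormatError(f"{path.name}: missing column {col!r}")
    table: dict[str, set[str]] = {}
    for row in df.itertuples(index=False):
        table.setdefault(row.gene_id, set())
        if isinstance(row.pfam_acc, str) and row.pfam_acc:
            table[row.gene_id].add(row.pfam_acc)
    return table


# ---------------------------------------------------------------------------
# differential-expression table (Cuffdiff gene_exp.diff dialect)
# ---------------------------------------------------------------------------

_DE_REQUIRED = {"gene_id", "log2(fold_change)", "q_value"}


def read_de_table(path: str | Path) -> list[DERecord]:
    """Read a ``gene_exp.diff``-style TSV.

    Requires at least ``gene_id``, ``log2(fold_change)`` and ``q_value``
    columns; unknown extra columns are ignored.  ``inf``/``-inf`` fold-change
    markers are mapped to IEEE infinities and retained.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = _DE_REQUIRED - set(df.columns)
    if missing:
        raise FormatError(f"{path.name}: missing column(s) {sorted(missing)}")

    def _float(x: str, default: float = math.nan) -> float:
        if x is None or (isinstance(x, float) and math.isnan(x)):
            return default
        return float(x)  # float() accepts "inf"/"-inf"

    records: list[DERecord] = []
    for row_no, d in enumerate(df.to_dict(orient="records"), start=1):
        try:
            records.append(DERecord(
                gene_id=d["gene_id"],
                value_1=_float(d.get("value_1")),
                value_2=_float(d.get("value_2")),
                log2_fold_change=_float(d["log2(fold_change)"]),
                q_value=float(d["q_value"]),
            ))
        except (ValueError, KeyError) as exc:
            raise FormatError(f"{path.name}: row {row_no}: {exc}") from exc
    return records


# ---------------------------------------------------------------------------
# newick
# ---------------------------------------------------------------------------

_NEWICK_UNSAFE = re.compile(r"[\s()\[\]{}:;,']")


def _newick_label(label: str) -> str:
    if _NEWICK_UNSAFE.search(label):
        return "'" + label.replace("'", "''") + "'"
    return label


def newick_string(tree) -> str:
    """Serialize a :class:`panani.njtree.PhyloTree` (or node) to newick.

    Branch lengths are printed with 10 significant digits; labels containing
    whitespace or newick metacharacters are single-quoted.
    """
    root = getattr(tree, "root", tree)

    def fmt(node) -> str:
        if not node.children:
            body = _newick_label(node.name)
        else:
            body = "(" + ",".join(fmt(c) for c in node.children) + ")"
            if node.name:
                body += _newick_label(node.name)
        if node.length is not None:
            body += f":{node.length:.10g}"
        return body

    if root.children:
        inner = ",".join(fmt(c) for c in root.children)
        return f"({inner});"
    return fmt(root) + ";"


def write_newick(tree, path: str | Path) -> None:
    Path(path).write_text(newick_string(tree) + "\n")


# ---------------------------------------------------------------------------
# labeled matrices
# ---------------------------------------------------------------------------

def write_matrix_tsv(
    labels: Sequence[str], values: np.ndarray, path: str | Path,
    na_rep: str = "NA",
) -> None:
    """Write a labeled square matrix as TSV; NaN entries become ``na_rep``."""
    df = pd.DataFrame(np.asarray(values, dtype=float),
                      index=list(labels), columns=list(labels))
    df.to_csv(path, sep="\t", na_rep=na_rep, index_label="")


def read_matrix_tsv(path: str | Path) -> tuple[list[str], np.ndarray]:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    labels = [str(x) for x in df.index]
    if labels != [str(c) for c in df.columns]:
        raise FormatError(f"{Path(path).name}: row and column labels differ")
    return labels, df.to_numpy(dtype=float)
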