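"""Readers and writers for the external formats the toolkit consumes.

Covers FASTA/FASTQ sequence files, BLAST tabular hits in the extended
``outfmt 6`` dialect (with aligned ``qseq``/``sseq`` columns), coding-feature
annotations (GFF3 or NCBI 5-column feature table), and the long-format CSV
tables for melt curves, amplification curves, and per-sample detections.

External files keep their native conventions (1-based inclusive coordinates,
``sstart > send`` for minus-strand subjects); helpers expose normalized
0-based half-open spans with explicit strand.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

from . import iupac


# ---------------------------------------------------------------------------
# validation errors
# ---------------------------------------------------------------------------

class ValidationError(ValueError):
    """Base class for input-validation failures."""


class DuplicateIdError(ValidationError):
    pass


class EmptySequenceError(ValidationError):
    pass


class IllegalCharacterError(ValidationError):
    pass


class FormatError(ValidationError):
    """Structural problem in a tabular or annotation file."""


# ---------------------------------------------------------------------------
# sequences
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SequenceRecord:
    """A nucleotide sequence with its identifier.

    Sequences are stored upper-case over the IUPAC alphabet (degenerate
    codes allowed); 'U' is folded to 'T' on construction.
    """

    id: str
    description: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("sequence record id must be non-empty")
        seq = iupac.normalize_sequence(self.sequence)
        if len(seq) == 0:
            raise EmptySequenceError(f"record {self.id!r} has an empty sequence")
        bad = set(seq) - iupac.IUPAC_CODES
        if bad:
            raise IllegalCharacterError(
                f"record {self.id!r} contains non-IUPAC characters: {sorted(bad)}"
            )
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)

    def reverse_complement(self) -> "SequenceRecord":
        return SequenceRecord(self.id, self.description,
                              iupac.reverse_complement(self.sequence))


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into validated records, preserving file order.

    Wrapped lines are concatenated and case is folded to upper. Raises
    DuplicateIdError, EmptySequenceError, or IllegalCharacterError on the
    corresponding defects.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise DuplicateIdError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(SequenceRecord(rec.id, rec.description, str(rec.seq)))
    return records


def read_fastq(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTQ file (qualities discarded; reads are used as sequences)."""
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fastq"):
        if rec.id in seen:
            raise DuplicateIdError(f"duplicate read id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(SequenceRecord(rec.id, rec.description, str(rec.seq)))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path,
                width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id if not rec.description or rec.description == rec.id \
                else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# BLAST tabular (extended outfmt 6)
# ---------------------------------------------------------------------------

BLAST_COLUMNS = (
    "qseqid sseqid pident length mismatch gapopen "
    "qstart qend sstart send evalue bitscore qseq sseq"
).split()

_ALIGN_ALPHABET = iupac.IUPAC_CODES | {"-"}


@dataclass
class AlignmentHit:
    """One read-vs-reference local alignment from BLAST tabular output.

    Coordinates are the native BLAST convention: 1-based inclusive, with
    ``sstart > send`` encoding a minus-strand subject. ``qseq``/``sseq`` are
    the aligned strings with '-' gap characters.
    """

    query_id: str
    subject_id: str
    pident: float
    length: int
    mismatch: int
    gapopen: int
    qstart: int
    qend: int
    sstart: int
    send: int
    evalue: float
    bitscore: float
    qseq: str
    sseq: str
    pident_flagged: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        self.qseq = iupac.normalize_sequence(self.qseq)
        self.sseq = iupac.normalize_sequence(self.sseq)
        if len(self.qseq) != self.length or len(self.sseq) != self.length:
            raise FormatError(
                f"hit {self.query_id}/{self.subject_id}: aligned string length "
                f"({len(self.qseq)}/{len(self.sseq)}) != length column ({self.length})"
            )
        if self.qstart > self.qend:
            raise FormatError(
                f"hit {self.query_id}/{self.subject_id}: qstart > qend"
            )
        bad = (set(self.qseq) | set(self.sseq)) - _ALIGN_ALPHABET
        if bad:
            raise IllegalCharacterError(
                f"hit {self.query_id}/{self.subject_id}: illegal alignment "
                f"characters {sorted(bad)}"
            )
        if self.evalue < 0:
            raise FormatError("evalue must be >= 0")
        # pident consistency is a soft check: flag, never drop.
        if abs(self.recomputed_pident() - self.pident) > 0.01:
            self.pident_flagged = True

    @property
    def is_minus_strand(self) -> bool:
        return self.sstart > self.send

    def subject_span(self) -> tuple[int, int]:
        """Strand-agnostic subject interval, 0-based half-open."""
        lo, hi = sorted((self.sstart, self.send))
        return lo - 1, hi

    def gap_columns(self) -> int:
        return sum(1 for q, s in zip(self.qseq, self.sseq) if q == "-" or s == "-")

    def identical_columns(self) -> int:
        return sum(1 for q, s in zip(self.qseq, self.sseq)
                   if q != "-" and s != "-" and q == s)

    def recomputed_pident(self) -> float:
        """Percent identity recomputed from the aligned strings (BLAST rule:
        exact character matches over all alignment columns)."""
        return 100.0 * self.identical_columns() / self.length


def _parse_blast_row(fields: Sequence[str], lineno: int) -> AlignmentHit:
    if len(fields) != len(BLAST_COLUMNS):
        if len(fields) == 12:
            raise FormatError(
                f"line {lineno}: 12-column outfmt 6 detected; this toolkit "
                f"requires the extended dialect with qseq/sseq columns "
                f"(per-column bases are needed for mismatch reanalysis). "
                f"Re-run BLASTn with -outfmt '6 {' '.join(BLAST_COLUMNS)}'."
            )
        raise FormatError(
            f"line {lineno}: expected {len(BLAST_COLUMNS)} columns, "
            f"got {len(fields)}"
        )
    try:
        return AlignmentHit(
            query_id=fields[0], subject_id=fields[1],
            pident=float(fields[2]), length=int(fields[3]),
            mismatch=int(fields[4]), gapopen=int(fields[5]),
            qstart=int(fields[6]), qend=int(fields[7]),
            sstart=int(fields[8]), send=int(fields[9]),
            evalue=float(fields[10]), bitscore=float(fields[11]),
            qseq=fields[12], sseq=fields[13],
        )
    except ValueError as exc:
        if isinstance(exc, ValidationError):
            raise
        raise FormatError(f"line {lineno}: non-numeric field ({exc})") from exc


def read_blast_tab(path: str | Path) -> list[AlignmentHit]:
    """Parse extended outfmt 6 BLAST tabular output.

    Every row is validated; rows whose pident column disagrees with the
    identity recomputed from qseq/sseq by more than 0.01 are kept but carry
    ``pident_flagged=True``.
    """
    hits: list[AlignmentHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            hits.append(_parse_blast_row(line.split("\t"), lineno))
    return hits


def write_blast_tab(hits: Iterable[AlignmentHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write("\t".join(str(v) for v in (
                h.query_id, h.subject_id, f"{h.pident:.3f}", h.length,
                h.mismatch, h.gapopen, h.qstart, h.qend, h.sstart, h.send,
                f"{h.evalue:.2g}", f"{h.bitscore:.1f}", h.qseq, h.sseq,
            )) + "\n")


# ---------------------------------------------------------------------------
# coding-feature annotations
# ---------------------------------------------------------------------------

CODING_KINDS = ("CDS", "rRNA", "tRNA")


@dataclass(frozen=True)
class CodingInterval:
    """A coding feature on a reference sequence (1-based inclusive)."""

    subject_id: str
    start: int
    end: int
    feature_kind: str
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValidationError(
                f"{self.subject_id}: invalid interval {self.start}..{self.end}"
            )
        if self.feature_kind not in CODING_KINDS:
            raise ValidationError(f"unsupported feature kind {self.feature_kind!r}")
        if self.strand not in ("+", "-"):
            raise ValidationError(f"invalid strand {self.strand!r}")

    def span(self) -> tuple[int, int]:
        """0-based half-open interval."""
        return self.start - 1, self.end


def _read_gff3(fh: io.TextIOBase) -> list[CodingInterval]:
    out = []
    for lineno, line in enumerate(fh, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 8:
            raise FormatError(f"GFF3 line {lineno}: expected >=8 columns")
        seqid, _source, ftype, start, end, _score, strand = fields[:7]
        if ftype not in CODING_KINDS:
            continue
        out.append(CodingInterval(seqid, int(start), int(end), ftype,
                                  strand if strand in "+-" else "+"))
    return out


def _read_feature_table(fh: io.TextIOBase) -> list[CodingInterval]:
    """NCBI 5-column feature table (.tbl): '>Feature seqid' headers, then
    'start<TAB>end<TAB>key' lines; start > end encodes the minus strand;
    qualifier lines (leading tabs) are skipped."""
    out = []
    seqid: str | None = None
    for lineno, line in enumerate(fh, start=1):
        line = line.rstrip("\n")
        if not line:
            continue
        if line.startswith(">Feature"):
            seqid = line.split(None, 1)[1].strip()
            continue
        if line.startswith("\t"):
            continue  # qualifier line
        fields = line.split("\t")
        if len(fields) < 3 or not fields[2]:
            continue  # continuation interval of a joined feature
        if seqid is None:
            raise FormatError(f"feature-table line {lineno}: interval before "
                              f"any '>Feature' header")
        kind = fields[2]
        if kind not in CODING_KINDS:
            continue
        a = int(fields[0].lstrip("<>"))
        b = int(fields[1].lstrip("<>"))
        strand = "+" if a <= b else "-"
        lo, hi = sorted((a, b))
        out.append(CodingInterval(seqid, lo, hi, kind, strand))
    return out


def read_annotations(path: str | Path,
                     dialect: str = "gff3",
                     reference_lengths: dict[str, int] | None = None,
                     ) -> list[CodingInterval]:
    """Read coding features (CDS, rRNA, tRNA) from an annotation file.

    Parameters
    ----------
    dialect : {"gff3", "genbank_feature_table"}
    reference_lengths : optional subject_id -> length map for cross-checking;
        intervals exceeding the declared length, or on unknown subjects,
        raise FormatError.
    """
    with open(path) as fh:
        if dialect == "gff3":
            intervals = _read_gff3(fh)
        elif dialect == "genbank_feature_table":
            intervals = _read_feature_table(fh)
        else:
            raise ValueError(f"unknown annotation dialect {dialect!r}")
    if reference_lengths is not None:
        for iv in intervals:
            if iv.subject_id not in reference_lengths:
                raise FormatError(
                    f"annotation subject {iv.subject_id!r} not in reference FASTA"
                )
            if iv.end > reference_lengths[iv.subject_id]:
                raise FormatError(
                    f"{iv.subject_id}: feature end {iv.end} exceeds sequence "
                    f"length {reference_lengths[iv.subject_id]}"
                )
    return intervals


def write_gff3(intervals: Iterable[CodingInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for iv in intervals:
            fh.write(f"{iv.subject_id}\tgutreads\t{iv.feature_kind}\t"
                     f"{iv.start}\t{iv.end}\t.\t{iv.strand}\t.\t.\n")


# ---------------------------------------------------------------------------
# long-format CSV tables (melt, amplification, detections)
# ---------------------------------------------------------------------------

MELT_COLUMNS = ["sample_id", "assay_id", "replicate_id", "temperature",
                "fluorescence"]
AMP_COLUMNS = ["sample_id", "assay_id", "replicate_id", "cycle", "fluorescence"]
DETECTION_COLUMNS = ["sample_id", "species", "read_count"]

SERIES_KEY = ["sample_id", "assay_id", "replicate_id"]


def _require_columns(df: pd.DataFrame, columns: Sequence[str], what: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise FormatError(f"{what}: missing column(s) {missing}")


def validate_melt_table(df: pd.DataFrame, min_points: int = 20) -> pd.DataFrame:
    _require_columns(df, MELT_COLUMNS, "melt table")
    for key, grp in df.groupby(SERIES_KEY, sort=False):
        t = grp["temperature"].to_numpy()
        if len(t) < min_points:
            raise FormatError(f"melt series {key}: only {len(t)} points "
                              f"(minimum {min_points})")
        if not (t[1:] > t[:-1]).all():
            raise FormatError(f"melt series {key}: temperatures not strictly "
                              f"increasing")
    return df


def validate_amp_table(df: pd.DataFrame) -> pd.DataFrame:
    _require_columns(df, AMP_COLUMNS, "amplification table")
    for key, grp in df.groupby(SERIES_KEY, sort=False):
        c = grp["cycle"].to_numpy()
        if (c < 1).any():
            raise FormatError(f"amplification series {key}: cycles must be >= 1")
        if not (c[1:] == c[:-1] + 1).all():
            raise FormatError(f"amplification series {key}: cycles not "
                              f"consecutive integers")
    return df


def read_melt_csv(path: str | Path) -> pd.DataFrame:
    return validate_melt_table(pd.read_csv(path))


def read_amp_csv(path: str | Path) -> pd.DataFrame:
    return validate_amp_table(pd.read_csv(path))


def write_melt_csv(df: pd.DataFrame, path: str | Path) -> None:
    validate_melt_table(df)[MELT_COLUMNS].to_csv(path, index=False)


def write_amp_csv(df: pd.DataFrame, path: str | Path) -> None:
    validate_amp_table(df)[AMP_COLUMNS].to_csv(path, index=False)


def read_detection_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, DETECTION_COLUMNS, "detection table")
    df["read_count"] = df["read_count"].astype(int)
    if "is_predator" in df.columns:
        df["is_predator"] = df["is_predator"].astype(bool)
    return df


def write_detection_csv(df: pd.DataFrame, path: str | Path) -> None:
    _require_columns(df, DETECTION_COLUMNS, "detection table")
    cols = DETECTION_COLUMNS + (["is_predator"] if "is_predator" in df.columns
                                else [])
    df[cols].to_csv(path, index=False)
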