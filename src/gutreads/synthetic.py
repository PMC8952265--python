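"""Synthetic inputs with known ground truth for every part of the toolkit.

Generates annotated reference databases, degraded gut-content read mixtures
(a dominant predator plus trace prey, with a truncated-lognormal fragment
length distribution mimicking digestion), melt curves built from sigmoid
dissociation transitions, and saturating-exponential qPCR amplification
curves. Also provides the local-alignment oracle (a Smith–Waterman stand-in
for BLASTn at desk scale) and an exact hit synthesizer for error-free reads.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import Align

from . import iupac
from .io_formats import (AlignmentHit, CodingInterval, SequenceRecord,
                         write_fasta, write_gff3)
from .lazaro import LazaroConfig, ReferenceDB, Taxon, _merged_spans

_BASES = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# reference database
# ---------------------------------------------------------------------------

def make_reference_db(seed: int, n_species: int, genome_len: int = 16000,
                      coding_fraction: float = 0.9) -> ReferenceDB:
    """Random annotated mitogenome-like references, one per species.

    Each genome is an i.i.d. random sequence (pairwise identity ~25%, far
    below any assignment threshold), tiled with coding blocks (CDS, rRNA,
    tRNA in rotation) covering about ``coding_fraction`` of its length.
    """
    if n_species < 1:
        raise ValueError("n_species must be >= 1")
    rng = np.random.default_rng(seed)
    records, taxonomy, coding = [], {}, {}
    kinds = ["CDS", "CDS", "rRNA", "CDS", "tRNA"]
    n_blocks = 10
    for i in range(n_species):
        sid = f"mito_{i:02d}"
        seq = "".join(rng.choice(_BASES, size=genome_len))
        records.append(SequenceRecord(sid, f"synthetic mitogenome {i}", seq))
        taxonomy[sid] = Taxon(f"Species_{i:02d}", f"Genus_{i:02d}", "Synthfam")
        intervals = []
        if coding_fraction > 0:
            block = genome_len // n_blocks
            for b in range(n_blocks):
                lo = b * block
                span = int(round(block * coding_fraction))
                if span >= 1:
                    intervals.append(CodingInterval(
                        sid, lo + 1, min(lo + span, genome_len),
                        kinds[b % len(kinds)], "+" if b % 2 == 0 else "-"))
        coding[sid] = intervals
    return ReferenceDB(records, taxonomy, coding)


def write_reference_db(db: ReferenceDB, outdir) -> dict[str, str]:
    """Write FASTA + GFF3 + taxonomy CSV; returns the paths."""
    from pathlib import Path
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fasta = outdir / "references.fasta"
    gff = outdir / "references.gff3"
    tax = outdir / "taxonomy.csv"
    write_fasta(db.records, fasta)
    write_gff3([iv for ivs in db.coding.values() for iv in ivs], gff)
    pd.DataFrame(
        [{"subject_id": sid, "species": t.species, "genus": t.genus,
          "family": t.family} for sid, t in sorted(db.taxonomy.items())]
    ).to_csv(tax, index=False)
    return {"fasta": str(fasta), "gff3": str(gff), "taxonomy": str(tax)}


def load_reference_db(fasta, gff3, taxonomy_csv) -> ReferenceDB:
    from .io_formats import read_annotations, read_fasta
    records = read_fasta(fasta)
    lengths = {r.id: len(r) for r in records}
    intervals = read_annotations(gff3, "gff3", reference_lengths=lengths)
    coding: dict[str, list[CodingInterval]] = {r.id: [] for r in records}
    for iv in intervals:
        coding[iv.subject_id].append(iv)
    tax = pd.read_csv(taxonomy_csv)
    taxonomy = {row.subject_id: Taxon(row.species, row.genus, row.family)
                for row in tax.itertuples()}
    return ReferenceDB(records, taxonomy, coding)


# ---------------------------------------------------------------------------
# gut-content read simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GutCommunitySpec:
    """Composition of a simulated predator-gut DNA community.

    ``proportions`` maps species to its share of the DNA (must sum to 1;
    the predator typically >= 0.9, prey at trace levels). Fragment lengths
    follow a lognormal truncated to [min_len, max_len] — digestion is
    modeled purely as length attenuation. Defaults: median fragment ~90 bp
    (log-sd 0.45) truncated to 30-150 bp, matching short-insert degraded
    templates sequenced at 150 bp.
    """

    seed: int
    proportions: Mapping[str, float]
    n_reads: int
    min_len: int = 30
    max_len: int = 150
    length_log_mean: float = math.log(90.0)
    length_log_sd: float = 0.45
    error_rate: float = 0.0

    def __post_init__(self) -> None:
        total = sum(self.proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"proportions must sum to 1 (got {total})")
        if any(not (0 < p <= 1) for p in self.proportions.values()):
            raise ValueError("each proportion must be in (0, 1]")
        if self.min_len < 20:
            raise ValueError("min_len must be >= 20")
        if self.max_len < self.min_len:
            raise ValueError("max_len must be >= min_len")
        if not (0 <= self.error_rate < 1):
            raise ValueError("error_rate must be in [0, 1)")


def _truncated_lognormal(rng: np.random.Generator, n: int, mu: float,
                         sigma: float, lo: int, hi: int) -> np.ndarray:
    out = np.empty(n, dtype=int)
    filled = 0
    while filled < n:
        draw = rng.lognormal(mu, sigma, size=2 * (n - filled))
        keep = draw[(draw >= lo) & (draw <= hi)][: n - filled]
        out[filled:filled + len(keep)] = keep.astype(int)
        filled += len(keep)
    return out


def simulate_gut_reads(spec: GutCommunitySpec,
                       db: ReferenceDB) -> tuple[list[SequenceRecord],
                                                 pd.DataFrame]:
    """Draw reads from uniformly random positions/strands of each species'
    reference, species chosen multinomially by proportion.

    Returns the reads and a truth table (read_id, species, subject_id,
    start, end [0-based half-open on the reference], strand, length,
    n_errors) consistent with the emitted sequences.
    """
    species_of = {t.species: sid for sid, t in db.taxonomy.items()}
    unknown = set(spec.proportions) - set(species_of)
    if unknown:
        raise ValueError(f"proportions for unknown species: {sorted(unknown)}")
    rng = np.random.default_rng(spec.seed)
    names = sorted(spec.proportions)
    probs = np.array([spec.proportions[s] for s in names])
    choices = rng.choice(len(names), size=spec.n_reads, p=probs)
    lengths = _truncated_lognormal(rng, spec.n_reads, spec.length_log_mean,
                                   spec.length_log_sd, spec.min_len,
                                   spec.max_len)
    seqs = {sid: db.record(sid).sequence for sid in species_of.values()}
    reads, rows = [], []
    for i in range(spec.n_reads):
        sp = names[choices[i]]
        sid = species_of[sp]
        ref = seqs[sid]
        length = int(min(lengths[i], len(ref)))
        start = int(rng.integers(0, len(ref) - length + 1))
        frag = ref[start:start + length]
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            frag = iupac.reverse_complement(frag)
        n_err = 0
        if spec.error_rate > 0:
            frag_arr = np.array(list(frag))
            hit = rng.random(length) < spec.error_rate
            for j in np.flatnonzero(hit):
                alts = [b for b in "ACGT" if b != frag_arr[j]]
                frag_arr[j] = alts[int(rng.integers(0, 3))]
            n_err = int(hit.sum())
            frag = "".join(frag_arr)
        rid = f"read_{i:06d}"
        reads.append(SequenceRecord(rid, f"{sp} {strand}", frag))
        rows.append({"read_id": rid, "species": sp, "subject_id": sid,
                     "start": start, "end": start + length, "strand": strand,
                     "length": length, "n_errors": n_err})
    return reads, pd.DataFrame(rows)


def truth_species_summary(truth: pd.DataFrame, db: ReferenceDB,
                          cfg: LazaroConfig = LazaroConfig()) -> pd.DataFrame:
    """Per-species ground truth: total reads and reads that satisfy every
    detection requirement (length >= min_overlap, error-free when the
    identity threshold is 100%, and coding-feature overlap >= the configured
    fraction of the read span)."""
    rows = []
    for sp, grp in truth.groupby("species", sort=True):
        qualifying = 0
        for row in grp.itertuples():
            if row.length < cfg.min_overlap:
                continue
            if cfg.min_identity >= 100.0 and row.n_errors > 0:
                continue
            spans = _merged_spans(db.coding.get(row.subject_id, []),
                                  cfg.coding_kinds)
            cov = sum(max(0, min(row.end, b) - max(row.start, a))
                      for a, b in spans)
            if cov >= cfg.coding_overlap_fraction * row.length:
                qualifying += 1
        rows.append({"species": sp, "total_reads": len(grp),
                     "qualifying_reads": qualifying,
                     "expected_detected": qualifying >= cfg.min_reads_per_species})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# alignment: exact truth-based hits and the Smith-Waterman oracle
# ---------------------------------------------------------------------------

def _hit_from_alignment(read_id: str, subject_id: str, qseq: str, sseq: str,
                        qstart: int, qend: int, sstart: int, send: int,
                        score: float) -> AlignmentHit:
    length = len(qseq)
    ident = sum(1 for a, b in zip(qseq, sseq) if a != "-" and a == b)
    mismatch = sum(1 for a, b in zip(qseq, sseq)
                   if a != "-" and b != "-" and a != b)
    gapopen = 0
    in_gap = False
    for a, b in zip(qseq, sseq):
        if a == "-" or b == "-":
            if not in_gap:
                gapopen += 1
            in_gap = True
        else:
            in_gap = False
    return AlignmentHit(read_id, subject_id, round(100.0 * ident / length, 3),
                        length, mismatch, gapopen, qstart, qend, sstart, send,
                        0.0, float(score), qseq, sseq)


def hits_from_truth(reads: Sequence[SequenceRecord], truth: pd.DataFrame,
                    db: ReferenceDB) -> list[AlignmentHit]:
    """Synthesize the full-length alignment hit of each read at its source
    locus, exactly as a local aligner would report it for an error-free read
    (query always forward; minus-strand source encoded as sstart > send).

    Substitution errors are carried through as mismatch columns; terminal
    errors would be trimmed by a real local aligner, so exact agreement with
    ``oracle_align`` is only guaranteed at error rate 0.
    """
    by_id = {r.id: r for r in reads}
    hits = []
    for row in truth.itertuples():
        read = by_id[row.read_id]
        ref = db.record(row.subject_id).sequence
        segment = ref[row.start:row.end]
        L = len(ref)
        if row.strand == "+":
            sseq = segment
            sstart, send = row.start + 1, row.end
        else:
            sseq = iupac.reverse_complement(segment)
            sstart, send = row.end, row.start + 1
        qseq = read.sequence
        matches = sum(1 for a, b in zip(qseq, sseq) if a == b)
        score = matches - (len(qseq) - matches)
        hits.append(_hit_from_alignment(read.id, row.subject_id, qseq, sseq,
                                        1, len(qseq), sstart, send, score))
    return hits


_ALIGNER = Align.PairwiseAligner(mode="local", match_score=1,
                                 mismatch_score=-1, open_gap_score=-2,
                                 extend_gap_score=-2)


def _best_local(read: str, ref: str):
    alns = _ALIGNER.align(read, ref)
    return alns[0]


def oracle_align(reads: Sequence[SequenceRecord], db: ReferenceDB,
                 min_score: float = 20.0) -> list[AlignmentHit]:
    """Exhaustive local alignment of every read against both strands of every
    reference (match +1, mismatch −1, gap −2), emitting the best hit per
    (read, reference) with BLAST-style coordinates. A desk-scale stand-in
    for BLASTn, intended for <= ~10 species x a few thousand reads.
    """
    hits: list[AlignmentHit] = []
    refs = [(r.id, r.sequence, iupac.reverse_complement(r.sequence))
            for r in db.records]
    for read in reads:
        for sid, fwd, rev in refs:
            L = len(fwd)
            best = None  # (score, strand, alignment)
            for strand, seq in (("+", fwd), ("-", rev)):
                aln = _best_local(read.sequence, seq)
                if best is None or aln.score > best[0]:
                    best = (aln.score, strand, aln)
            score, strand, aln = best
            if score < min_score:
                continue
            qseq, sseq = str(aln[0]), str(aln[1])
            # strip the flanking unaligned context the Alignment string keeps
            qblocks, sblocks = aln.aligned
            qstart, qend = int(qblocks[0][0]) + 1, int(qblocks[-1][1])
            a, b = int(sblocks[0][0]), int(sblocks[-1][1])
            if strand == "+":
                sstart, send = a + 1, b
            else:
                sstart, send = L - a, L - b + 1
            hits.append(_hit_from_alignment(read.id, sid, qseq, sseq,
                                            qstart, qend, sstart, send, score))
    return hits


# ---------------------------------------------------------------------------
# melt-curve simulation
# ---------------------------------------------------------------------------

MELT_T_START = 60.0
MELT_T_END = 95.0
MELT_READINGS_PER_C = 6

#: the default scan grid: 60-95 degC at 6 readings per degree (211 points)
def melt_grid() -> np.ndarray:
    n = int((MELT_T_END - MELT_T_START) * MELT_READINGS_PER_C) + 1
    return MELT_T_START + np.arange(n) / MELT_READINGS_PER_C


@dataclass(frozen=True)
class MeltTransition:
    """One duplex dissociation: a sigmoid drop of amplitude ``amplitude``
    centred at ``tm`` with width ``width`` (the −dF/dT peak height is
    amplitude / (4 * width))."""

    tm: float
    amplitude: float
    width: float = 0.5

    def __post_init__(self) -> None:
        if not (MELT_T_START < self.tm < MELT_T_END):
            raise ValueError("tm must lie inside the 60-95 degC scan")
        if self.width <= 0:
            raise ValueError("width must be positive")


def melt_fluorescence(transitions: Sequence[MeltTransition],
                      temperatures: np.ndarray | None = None,
                      drift_intercept: float = 5.0,
                      drift_slope: float = -0.01,
                      noise_sd: float = 0.0,
                      rng: np.random.Generator | None = None
                      ) -> tuple[np.ndarray, np.ndarray]:
    """F(T) = drift(T) + sum_i A_i / (1 + exp((T - Tm_i)/s_i)) + noise."""
    t = melt_grid() if temperatures is None else np.asarray(temperatures)
    f = drift_intercept + drift_slope * t
    for tr in transitions:
        f = f + tr.amplitude / (1.0 + np.exp((t - tr.tm) / tr.width))
    if noise_sd > 0:
        if rng is None:
            raise ValueError("noise requires a Generator")
        f = f + rng.normal(0.0, noise_sd, size=len(t))
    return t, f


def simulate_melt(assays: Mapping[tuple[str, str, str],
                                  Sequence[MeltTransition]],
                  seed: int,
                  noise_sd: float = 0.005,
                  drift_intercept: float = 5.0,
                  drift_slope: float = -0.01) -> pd.DataFrame:
    """Long-format melt table for (sample, assay, replicate) series on the
    standard 211-point grid; deterministic per seed."""
    rng = np.random.default_rng(seed)
    frames = []
    for (sample, assay, rep), transitions in sorted(assays.items()):
        t, f = melt_fluorescence(transitions, noise_sd=noise_sd, rng=rng,
                                 drift_intercept=drift_intercept,
                                 drift_slope=drift_slope)
        frames.append(pd.DataFrame({
            "sample_id": sample, "assay_id": assay, "replicate_id": rep,
            "temperature": t, "fluorescence": f}))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# qPCR amplification simulation
# ---------------------------------------------------------------------------

def qpcr_fluorescence(n0: float, efficiency: float, plateau: float = 2.0,
                      noise_sd: float = 0.0, cycles: int = 40,
                      rng: np.random.Generator | None = None
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Saturating exponential F_c = P * n0 * E^c / (P + n0 * E^c) + noise."""
    if n0 < 0:
        raise ValueError("n0 must be >= 0")
    if not (1.0 < efficiency <= 2.0):
        raise ValueError("efficiency must be in (1, 2]")
    c = np.arange(1, cycles + 1, dtype=float)
    x = n0 * efficiency ** c
    f = plateau * x / (plateau + x)
    if noise_sd > 0:
        if rng is None:
            raise ValueError("noise requires a Generator")
        f = f + rng.normal(0.0, noise_sd, size=cycles)
    return c, f


def simulate_qpcr(series: Mapping[tuple[str, str, str],
                                  tuple[float, float]],
                  seed: int, plateau: float = 2.0, noise_sd: float = 0.0,
                  cycles: int = 40) -> pd.DataFrame:
    """Long-format amplification table; each series maps its key to
    (n0, efficiency)."""
    rng = np.random.default_rng(seed)
    frames = []
    for (sample, assay, rep), (n0, eff) in sorted(series.items()):
        c, f = qpcr_fluorescence(n0, eff, plateau, noise_sd, cycles, rng)
        frames.append(pd.DataFrame({
            "sample_id": sample, "assay_id": assay, "replicate_id": rep,
            "cycle": c.astype(int), "fluorescence": f}))
    return pd.concat(frames, ignore_index=True)
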