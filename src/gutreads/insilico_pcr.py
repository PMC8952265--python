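"""IUPAC-aware primer-template matching and in-silico amplicon extraction.

Emulates an ecoPCR-style ungapped sliding comparison: a primer binds where
the number of mismatching positions is at most ``max_mismatches`` and its
3'-terminal ``anchored_3prime`` bases all match. Degenerate codes on either
side match iff their expansions intersect. Useful for predicting which
templates a metabarcoding primer pair will and will not amplify.
"""

from __future__ import annotations

from dataclasses import dataclass

from . import iupac
from .io_formats import SequenceRecord


@dataclass(frozen=True)
class PrimerSpec:
    """A PCR primer written 5'->3' with its binding stringency."""

    name: str
    sequence: str
    max_mismatches: int = 2
    anchored_3prime: int = 2

    def __post_init__(self) -> None:
        seq = iupac.normalize_sequence(self.sequence)
        if len(seq) < 10:
            raise ValueError("primer sequence must be >= 10 bases")
        if not set(seq) <= iupac.IUPAC_CODES:
            raise ValueError(f"primer {self.name!r}: non-IUPAC characters")
        if self.max_mismatches < 0:
            raise ValueError("max_mismatches must be >= 0")
        if not (0 <= self.anchored_3prime < len(seq)):
            raise ValueError("anchored_3prime must be < primer length")
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PrimerBindingSite:
    """A primer binding location on one strand of a template.

    ``position`` is the 0-based start of the binding window on the stated
    strand (for the minus strand, coordinates are along the reverse
    complement of the template).
    """

    template_id: str
    position: int
    strand: str  # '+' or '-'
    mismatch_count: int
    three_prime_ok: bool


def _count_mismatches(primer: str, window: str, anchor: int,
                      max_mm: int) -> tuple[int, bool] | None:
    """Ungapped comparison of primer vs an equal-length template window.

    Returns (mismatches, anchor_ok) or None when the site fails either the
    mismatch budget or the 3'-anchor requirement.
    """
    n = len(primer)
    anchor_ok = all(iupac.bases_match(primer[i], window[i])
                    for i in range(n - anchor, n))
    if not anchor_ok:
        return None
    mm = sum(1 for p, t in zip(primer, window) if not iupac.bases_match(p, t))
    if mm > max_mm:
        return None
    return mm, True


def _scan_strand(primer: PrimerSpec, seq: str, template_id: str,
                 strand: str) -> list[PrimerBindingSite]:
    n = len(primer)
    sites = []
    for pos in range(len(seq) - n + 1):
        res = _count_mismatches(primer.sequence, seq[pos:pos + n],
                                primer.anchored_3prime, primer.max_mismatches)
        if res is not None:
            sites.append(PrimerBindingSite(template_id, pos, strand,
                                           res[0], res[1]))
    return sites


def primer_scan(primer: PrimerSpec,
                template: SequenceRecord) -> list[PrimerBindingSite]:
    """All binding sites of a primer on both strands of a template."""
    if len(template) < len(primer):
        raise ValueError("template shorter than primer")
    fwd = _scan_strand(primer, template.sequence, template.id, "+")
    rev = _scan_strand(primer, iupac.reverse_complement(template.sequence),
                       template.id, "-")
    return fwd + rev


@dataclass(frozen=True)
class Amplicon:
    """An in-silico PCR product (primers included), on plus-strand coordinates
    of the template (0-based half-open)."""

    template_id: str
    start: int
    end: int
    fwd_strand: str  # strand the forward primer binds ('+' normal orientation)
    sequence: str

    def __len__(self) -> int:
        return self.end - self.start


def in_silico_amplicon(fwd: PrimerSpec, rev: PrimerSpec,
                       template: SequenceRecord,
                       min_len: int = 1,
                       max_len: int = 10_000) -> list[Amplicon]:
    """Enumerate amplicons a primer pair would produce from a template.

    A product requires a forward-primer site and a reverse-primer site on the
    opposite strand, downstream of it in proper orientation, with total
    length (primers included) within [min_len, max_len]. Both template
    orientations are scanned, so a pair annotated against the minus strand is
    found symmetrically (its sequence is emitted reverse-complemented).
    """
    L = len(template)
    out: list[Amplicon] = []
    fwd_sites = primer_scan(fwd, template)
    rev_sites = primer_scan(rev, template)
    for f in fwd_sites:
        for r in rev_sites:
            if f.strand == r.strand:
                continue
            if f.strand == "+":
                # rev binds minus strand at minus-coordinate r.position:
                # plus-strand interval [L - r.position - len(rev), L - r.position)
                end = L - r.position
                start = f.position
                if end - len(rev) < start + len(fwd):
                    continue  # overlapping/behind: not a proper orientation
                length = end - start
                if min_len <= length <= max_len:
                    out.append(Amplicon(template.id, start, end, "+",
                                        template.sequence[start:end]))
            else:
                # fwd on minus strand, rev on plus: the product is the reverse
                # complement of the plus-strand span.
                end = L - f.position
                start = r.position
                if end - len(fwd) < start + len(rev):
                    continue
                length = end - start
                if min_len <= length <= max_len:
                    out.append(Amplicon(
                        template.id, start, end, "-",
                        iupac.reverse_complement(template.sequence[start:end])))
    out.sort(key=lambda a: (a.start, a.end, a.fwd_strand))
    return out
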