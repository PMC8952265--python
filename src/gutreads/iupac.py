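"""IUPAC nucleotide alphabet utilities.

Degenerate single-letter codes (R, Y, S, W, K, M, B, D, H, V, N) each denote
a set of canonical bases. A reported alignment mismatch against such a code
may be a "false mismatch": the query base can be contained in the set the
reference symbol denotes. All comparisons here are case-insensitive and 'U'
is treated as 'T'.
"""

from __future__ import annotations

EXPANSIONS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

IUPAC_CODES: frozenset[str] = frozenset(EXPANSIONS)
CANONICAL: frozenset[str] = frozenset("ACGT")
DEGENERATE: frozenset[str] = IUPAC_CODES - CANONICAL

_COMPLEMENT = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}


def normalize(base: str) -> str:
    """Fold case and map RNA 'U' to 'T'."""
    b = base.upper()
    return "T" if b == "U" else b


def normalize_sequence(seq: str) -> str:
    return seq.upper().replace("U", "T")


def is_iupac(base: str) -> bool:
    return normalize(base) in IUPAC_CODES


def expand(base: str) -> frozenset[str]:
    """Canonical bases denoted by an IUPAC symbol.

    Raises KeyError for characters outside the alphabet.
    """
    return EXPANSIONS[normalize(base)]


def bases_match(a: str, b: str) -> bool:
    """True iff the expansions of the two symbols intersect.

    For canonical bases this is plain equality; a degenerate symbol matches
    any base in (or any symbol overlapping) its denoted set.
    """
    return not EXPANSIONS[normalize(a)].isdisjoint(EXPANSIONS[normalize(b)])


def complement(base: str) -> str:
    return _COMPLEMENT[normalize(base)]


def reverse_complement(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(normalize_sequence(seq)))
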