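"""Small sequence helpers shared across modules."""

from __future__ import annotations

from itertools import groupby

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: IUPAC nucleotide codes -> the set of concrete bases each matches.
IUPAC_SETS: dict[str, frozenset[str]] = {
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


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGTN string."""
    return seq.translate(_COMPLEMENT)[::-1]


def iupac_match(seq: str, pattern: str) -> bool:
    """True if ``seq`` matches the IUPAC ``pattern`` position by position.

    An ``N`` in the *sequence* never matches: ambiguous genomic bases are
    treated conservatively as non-matching.
    """
    if len(seq) != len(pattern):
        return False
    return all(b in IUPAC_SETS[p] for b, p in zip(seq, pattern))


def is_iupac(pattern: str) -> bool:
    return bool(pattern) and all(c in IUPAC_SETS for c in pattern)


def gc_count(seq: str) -> int:
    return seq.count("G") + seq.count("C")


def max_identical_run(seq: str) -> int:
    """Length of the longest run of a single repeated base."""
    if not seq:
        return 0
    return max(sum(1 for _ in grp) for _, grp in groupby(seq))
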