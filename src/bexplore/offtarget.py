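"""Genome-wide mismatch search and CFD off-target scoring.

The scanner enumerates every genomic locus, on either strand, whose
protospacer-length sequence lies within a mismatch budget of a query
protospacer and whose adjacent PAM satisfies the chosen policy. It is a
vectorized sliding-window comparison (numpy), so whole small genomes are
scanned in one pass per strand.

Each hit is scored with a CFD-style (cutting frequency determination)
multiplicative model: a perfect match with a canonical PAM scores 1.0,
and every mismatch contributes a position- and base-pair-specific
multiplier in [0, 1], times a PAM-variant multiplier. The penalty table
is data, not code: a table ships with the package and can be replaced
via ``--cfd-table`` (TSV: position, query_base, genomic_base,
multiplier; PAM rows use position 0 with the variant in query_base).

The shipped default table is *synthetic*: a smooth position-dependent
penalty profile (mismatches nearer the PAM penalised more, transversions
more than transitions) with canonical-PAM multiplier 1 and strongly
down-weighted non-canonical PAMs. It reproduces the qualitative shape of
published mismatch-activity data and is intended as a sane default and
test harness, not as a refit of any published coefficient set; users with
a preferred published table should supply it as a file.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .editors import BaseEditor
from .errors import ConfigError
from .io import GenomeIndex, PathLike
from .screening import CandidateGuide
from ._seq import IUPAC_SETS, revcomp

logger = logging.getLogger(__name__)

_BASES = "ACGT"

#: Length of the protospacer segment the CFD model is defined over.
CFD_LENGTH = 20


# ---------------------------------------------------------------------------
# CFD table

@dataclass
class CfdTable:
    """Mismatch and PAM multipliers for the CFD product model.

    ``mismatch_penalties`` maps (protospacer position 1..20 counted from
    the PAM-distal end, query base, genomic base) to a multiplier in
    [0, 1]; identity pairs implicitly have multiplier 1.
    ``pam_penalties`` maps a PAM variant (first base wildcarded to N for
    3-nt PAMs, e.g. "NGG") to a multiplier.
    """

    mismatch_penalties: dict[tuple[int, str, str], float]
    pam_penalties: dict[str, float]

    def __post_init__(self) -> None:
        for key, mult in self.mismatch_penalties.items():
            if not 0.0 <= mult <= 1.0:
                raise ConfigError(f"CFD multiplier {mult} for {key} outside [0,1]")
        for pam, mult in self.pam_penalties.items():
            if not 0.0 <= mult <= 1.0:
                raise ConfigError(f"CFD PAM multiplier {mult} for {pam} outside [0,1]")

    def mismatch(self, position: int, query_base: str, genomic_base: str) -> float:
        if query_base == genomic_base:
            return 1.0
        try:
            return self.mismatch_penalties[(position, query_base, genomic_base)]
        except KeyError:
            raise ConfigError(
                f"CFD table has no entry for position {position}, "
                f"query {query_base}, genomic {genomic_base}") from None

    def pam(self, pam_sequence: str) -> float:
        key = pam_sequence
        if len(key) == 3:
            key = "N" + key[1:]
        try:
            return self.pam_penalties[key]
        except KeyError:
            raise ConfigError(f"CFD table has no PAM entry for {pam_sequence!r}") from None


def load_cfd_table(source: PathLike) -> CfdTable:
    """Load a CFD table from TSV (position, query_base, genomic_base,
    multiplier); PAM rows carry position 0 and the variant in query_base."""
    mismatch: dict[tuple[int, str, str], float] = {}
    pam: dict[str, float] = {}
    with open(source) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0] in ("position", "pos"):  # header
                continue
            if len(parts) != 4:
                raise ConfigError(f"{source}:{line_no}: expected 4 columns")
            pos = int(parts[0])
            if pos == 0:
                pam[parts[1].upper()] = float(parts[3])
            else:
                mismatch[(pos, parts[1].upper(), parts[2].upper())] = float(parts[3])
    return CfdTable(mismatch, pam)


def default_cfd_table() -> CfdTable:
    """The packaged synthetic default table (see module docstring)."""
    ref = resources.files("bexplore.data") / "cfd_synthetic_default.tsv"
    with resources.as_file(ref) as path:
        return load_cfd_table(path)


def uniform_cfd_table(penalty: float = 0.5, pam_penalty: float = 1.0) -> CfdTable:
    """A flat table (every mismatch the same multiplier): useful for tests
    and for reasoning about the scanner independently of table contents."""
    mismatch = {(pos, q, g): penalty
                for pos in range(1, CFD_LENGTH + 1)
                for q in _BASES for g in _BASES if q != g}
    pam = {f"N{a}{b}": pam_penalty for a in _BASES for b in _BASES}
    return CfdTable(mismatch, pam)


def cfd_score(query_protospacer: str, hit: "OffTargetHit",
              table: CfdTable) -> float:
    """CFD score of one hit: product of per-mismatch multipliers times the
    PAM multiplier. No mismatches with a canonical PAM gives 1.0.

    The model is defined over 20 nt; longer guides are scored on their
    PAM-proximal 20 nt. Shorter guides fall back to ``0.5**n_mismatches``
    (with the PAM multiplier) and log a warning.
    """
    query = query_protospacer.upper()
    site = hit.site_sequence.upper()
    if len(query) != len(site):
        raise ConfigError("query and hit sequences differ in length")
    if len(query) < CFD_LENGTH:
        logger.warning("guide shorter than %d nt: scoring 0.5^mismatches",
                       CFD_LENGTH)
        n_mm = sum(q != s for q, s in zip(query, site))
        return (0.5 ** n_mm) * table.pam(hit.pam_sequence)
    if len(query) > CFD_LENGTH:          # PAM-proximal 20 nt
        query = query[-CFD_LENGTH:]
        site = site[-CFD_LENGTH:]
    score = table.pam(hit.pam_sequence)
    for i, (q, s) in enumerate(zip(query, site), start=1):
        if q != s:
            score *= table.mismatch(i, q, s)
    return score


# ---------------------------------------------------------------------------
# Mismatch scanner

@dataclass(frozen=True)
class OffTargetHit:
    chrom: str
    start: int          # 1-based inclusive plus-strand span
    end: int
    strand: str
    site_sequence: str  # protospacer-length sequence on the hit strand, 5'->3'
    pam_sequence: str
    n_mismatches: int
    cfd: float = float("nan")


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _pam_mask(enc: np.ndarray, pattern: str, offset: int, n_windows: int
              ) -> np.ndarray:
    """Boolean array over window starts: PAM at ``offset`` from window
    start matches ``pattern``."""
    ok = np.ones(n_windows, dtype=bool)
    for j, sym in enumerate(pattern):
        allowed = np.zeros(256, dtype=bool)
        for b in IUPAC_SETS[sym]:
            allowed[ord(b)] = True
        ok &= allowed[enc[offset + j: offset + j + n_windows]]
    return ok


def _scan_strand(seq: str, query: str, pam_patterns: Sequence[str] | None,
                 max_mm: int) -> list[tuple[int, int, str, str]]:
    """One-strand scan. Returns (0-based window start, n_mismatches,
    site_sequence, pam_sequence) tuples. ``pam_patterns=None`` disables
    the PAM constraint (PAM reported as trailing sequence or '')."""
    L = len(query)
    P = len(pam_patterns[0]) if pam_patterns else 0
    n_windows = len(seq) - L - P + 1
    if n_windows <= 0:
        return []
    enc = _encode(seq)
    qenc = _encode(query)
    # mismatch counts per window; 'N' in the genome never matches the query
    mm = np.zeros(n_windows, dtype=np.int16)
    for j in range(L):
        mm += enc[j:j + n_windows] != qenc[j]
    keep = mm <= max_mm
    if pam_patterns:
        pam_ok = np.zeros(n_windows, dtype=bool)
        for pat in pam_patterns:
            pam_ok |= _pam_mask(enc, pat, L, n_windows)
        keep &= pam_ok
    out = []
    for i in np.nonzero(keep)[0]:
        i = int(i)
        out.append((i, int(mm[i]), seq[i:i + L], seq[i + L:i + L + P]))
    return out


def _resolve_pam_patterns(pam_policy: str, pam_pattern: str | None
                          ) -> list[str] | None:
    if pam_policy == "any":
        return None
    if pam_pattern is None:
        raise ConfigError("pam_policy requires the editor's PAM pattern")
    if pam_policy == "strict":
        return [pam_pattern]
    if pam_policy == "relaxed":
        pats = [pam_pattern]
        if pam_pattern.upper() == "NGG":
            pats.append("NAG")
        return pats
    raise ConfigError(f"unknown pam_policy {pam_policy!r}")


def find_offtargets(guide: CandidateGuide, genome: GenomeIndex,
                    max_mm: int = 4, pam_policy: str = "strict",
                    pam_pattern: str | None = None,
                    table: CfdTable | None = None) -> list[OffTargetHit]:
    """Every locus within ``max_mm`` mismatches of the guide's protospacer.

    Both strands of every chromosome are scanned; the on-target locus
    itself (same span and strand) is excluded, exact duplicates elsewhere
    are included. ``pam_policy`` is ``strict`` (editor pattern only),
    ``relaxed`` (adds NAG for NGG editors), or ``any`` (no PAM
    constraint — with ``max_mm=0`` this doubles as the exact-repeat
    counter). If ``table`` is given each hit carries its CFD score.
    """
    if max_mm < 0:
        raise ConfigError("max_mm must be >= 0")
    patterns = _resolve_pam_patterns(pam_policy, pam_pattern)
    query = guide.protospacer
    L = len(query)
    P = len(patterns[0]) if patterns else 0
    hits: list[OffTargetHit] = []
    for chrom, seq in genome.sequences.items():
        # plus strand: protospacer then PAM, left to right
        for i, n_mm, site_seq, pam_seq in _scan_strand(seq, query, patterns, max_mm):
            start, end = i + 1, i + L
            hits.append(OffTargetHit(chrom, start, end, "+", site_seq,
                                     pam_seq, n_mm))
        # minus strand: scan the reverse complement, map coordinates back
        rc = revcomp(seq)
        n = len(seq)
        for i, n_mm, site_seq, pam_seq in _scan_strand(rc, query, patterns, max_mm):
            start = n - (i + L) + 1
            end = n - i
            hits.append(OffTargetHit(chrom, start, end, "-", site_seq,
                                     pam_seq, n_mm))
    hits = [h for h in hits if not _is_on_target(h, guide)]
    hits.sort(key=lambda h: (h.chrom, h.start, h.strand))
    if table is not None:
        hits = [OffTargetHit(h.chrom, h.start, h.end, h.strand,
                             h.site_sequence, h.pam_sequence, h.n_mismatches,
                             cfd_score(query, h, table)) for h in hits]
    return hits


def _guide_chrom(guide: CandidateGuide, default: str) -> str:
    if guide.chrom:
        return guide.chrom
    # site ids synthesized as "chrom:pos" let us recover the chromosome;
    # otherwise assume the single-chromosome case handled by span equality
    if ":" in guide.site_id:
        return guide.site_id.split(":", 1)[0]
    return default


def _is_on_target(hit: OffTargetHit, guide: CandidateGuide) -> bool:
    return (hit.start, hit.end, hit.strand) == (*guide.span, guide.strand) \
        and hit.chrom == _guide_chrom(guide, hit.chrom)


def offtarget_feature(guide: CandidateGuide, genome: GenomeIndex,
                      max_mm: int = 4, table: CfdTable | None = None,
                      pam_policy: str = "strict",
                      pam_pattern: str | None = None) -> float:
    """Mean CFD over all off-target hits; 0.0 when there are none (an
    unambiguous guide is the best case)."""
    if table is None:
        table = default_cfd_table()
    hits = find_offtargets(guide, genome, max_mm=max_mm,
                           pam_policy=pam_policy, pam_pattern=pam_pattern,
                           table=table)
    if not hits:
        return 0.0
    return float(np.mean([h.cfd for h in hits]))
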