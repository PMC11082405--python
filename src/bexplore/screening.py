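"""Editability screening: five sequential checks per target site.

Given a target site and an editor, the screen decides whether the site is
editable and, if so, enumerates every usable protospacer placement:

1. *Base match* — the reference base must be the editor's target base on
   one strand (C or G for a CBE, A or T for an ABE); this fixes the design
   strand. Otherwise: ``base_match_error``.
2. *PAM search* — every placement that puts the target base at protospacer
   position p in [1, spacer_length] with the PAM immediately 3' of the
   protospacer on the design strand is examined; if no placement's PAM
   matches the editor's pattern: ``no_PAM``.
3. *Activity window* — among PAM-bearing placements, only those with the
   target inside [window_start, window_end] are candidates; if none:
   ``activity_window_error``.
4. *Homopolymer* — candidates whose protospacer contains a run of 7 or
   more identical bases are dropped; if none survive:
   ``continuous_identical_base_error``.
5. *GC content* — candidates with protospacer GC outside [30%, 75%]
   (inclusive bounds) are dropped; if none survive: ``GC_ratio_error``.

GC and homopolymer are computed over the protospacer only (the spacer is
what hybridizes), excluding the PAM. The first failing stage labels the
site. Placements running past a chromosome boundary, or containing an N
in the protospacer or PAM, are skipped.
"""

from __future__ import annotations

from dataclasses import dataclass

from .editors import BaseEditor, EditorClass
from .io import (FAIL_BASE_MATCH, FAIL_GC, FAIL_HOMOPOLYMER, FAIL_NO_PAM,
                 FAIL_WINDOW, GenomeIndex, TargetSite)
from ._seq import gc_count, iupac_match, max_identical_run, revcomp

#: Inclusive GC-content bounds on the protospacer, as percentages.
GC_MIN_PCT = 30
GC_MAX_PCT = 75

#: Longest tolerated run of identical bases in the protospacer.
MAX_IDENTICAL_RUN = 6


@dataclass(frozen=True)
class CandidateGuide:
    """One protospacer placement covering the target base.

    ``protospacer`` is read 5'->3' on the design strand;
    ``protospacer_start``/``protospacer_end`` are the 1-based inclusive
    plus-strand genomic span regardless of strand. ``target_window_pos``
    is the target base's position within the protospacer, 1-based from
    the PAM-distal (5') end.
    """

    site_id: str
    strand: str
    protospacer: str
    pam: str
    protospacer_start: int
    protospacer_end: int
    target_window_pos: int
    chrom: str = ""

    @property
    def span(self) -> tuple[int, int]:
        return self.protospacer_start, self.protospacer_end


@dataclass
class ScreeningOutcome:
    site_id: str
    status: str                    # "editable" | "failed"
    fail_reason: str               # one of the five labels, or ""
    candidates: list[CandidateGuide]


def match_target_base(site: TargetSite, editor: BaseEditor) -> str | None:
    """Design strand for ``site`` under ``editor``, or None (base mismatch).

    The editor deaminates its target base; if the reference base is that
    base the design strand is '+', if it is its complement the editable
    base lies on the minus strand and the design strand is '-'.
    """
    if editor.editor_class is EditorClass.CBE:
        return {"C": "+", "G": "-"}.get(site.ref_base)
    return {"A": "+", "T": "-"}.get(site.ref_base)


def enumerate_placements(site: TargetSite, editor: BaseEditor,
                         genome: GenomeIndex, strand: str
                         ) -> tuple[list[CandidateGuide], str | None]:
    """All window-compatible PAM-bearing placements, or a failure label.

    Returns ``(candidates, None)`` on success, ``([], "no_PAM")`` if no
    placement in the searchable range has a matching PAM, and
    ``([], "activity_window_error")`` if PAMs exist only at placements
    that leave the target outside the activity window.
    """
    L = editor.spacer_length
    P = len(editor.pam_pattern)
    chrom_len = genome.lengths[site.chrom]
    seq = genome.sequences[site.chrom]
    t = site.pos  # 1-based plus-strand coordinate of the target base

    any_pam = False
    candidates: list[CandidateGuide] = []
    for p in range(1, L + 1):
        if strand == "+":
            start = t - (p - 1)
            end = start + L - 1
            pam_start, pam_end = end + 1, end + P
            if start < 1 or pam_end > chrom_len:
                continue
            proto = seq[start - 1:end]
            pam = seq[pam_end - P:pam_end]
        else:
            # protospacer position 1 sits at the highest plus coordinate
            start = t - L + p
            end = start + L - 1
            pam_start, pam_end = start - P, start - 1
            if pam_start < 1 or end > chrom_len:
                continue
            proto = revcomp(seq[start - 1:end])
            pam = revcomp(seq[pam_start - 1:pam_end])
        if "N" in proto or "N" in pam:
            continue
        if proto[p - 1] != editor.target_base:
            continue
        if not iupac_match(pam, editor.pam_pattern):
            continue
        any_pam = True
        if editor.window_start <= p <= editor.window_end:
            candidates.append(CandidateGuide(
                site_id=site.site_id, strand=strand, protospacer=proto,
                pam=pam, protospacer_start=start, protospacer_end=end,
                target_window_pos=p, chrom=site.chrom))
    if not any_pam:
        return [], FAIL_NO_PAM
    if not candidates:
        return [], FAIL_WINDOW
    return candidates, None


def passes_homopolymer(protospacer: str) -> bool:
    return max_identical_run(protospacer) <= MAX_IDENTICAL_RUN


def passes_gc(protospacer: str) -> bool:
    # integer comparison avoids float-boundary artefacts at exactly 30%/75%
    gc100 = 100 * gc_count(protospacer)
    n = len(protospacer)
    return GC_MIN_PCT * n <= gc100 <= GC_MAX_PCT * n


def apply_sequence_filters(candidates: list[CandidateGuide]
                           ) -> tuple[list[CandidateGuide], str | None]:
    """Homopolymer then GC filter; the label names the stage that emptied
    the candidate list."""
    kept = [c for c in candidates if passes_homopolymer(c.protospacer)]
    if not kept:
        return [], FAIL_HOMOPOLYMER
    kept = [c for c in kept if passes_gc(c.protospacer)]
    if not kept:
        return [], FAIL_GC
    return kept, None


def screen_site(site: TargetSite, editor: BaseEditor,
                genome: GenomeIndex) -> ScreeningOutcome:
    """Run the five checks in order; first failure labels the site."""
    strand = match_target_base(site, editor)
    if strand is None:
        return ScreeningOutcome(site.site_id, "failed", FAIL_BASE_MATCH, [])
    candidates, fail = enumerate_placements(site, editor, genome, strand)
    if fail is not None:
        return ScreeningOutcome(site.site_id, "failed", fail, [])
    kept, fail = apply_sequence_filters(candidates)
    if fail is not None:
        return ScreeningOutcome(site.site_id, "failed", fail, [])
    return ScreeningOutcome(site.site_id, "editable", "", kept)
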