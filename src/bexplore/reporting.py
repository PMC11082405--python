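"""Summary tables over pipeline outputs.

Two summaries back the usual figures: the distribution of editable sites
by their number of feasible gRNAs, and the breakdown of failed sites by
failure cause (with the combined PAM-absence + activity-window share,
typically the dominant reason sites are uneditable).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Union

from .errors import BexploreError
from .io import FAIL_LABELS, FAIL_NO_PAM, FAIL_WINDOW
from .screening import ScreeningOutcome
from ._utils import percent


@dataclass
class CategoryTable:
    """Sites binned by feasible-gRNA count k."""

    counts: dict[int, int]          # k -> number of sites with k guides
    total_sites: int
    total_guides: int
    percentages: dict[int, float]   # k -> percent of sites, 2 decimals


def summarize_feasible_counts(
        source: Union[Iterable[ScreeningOutcome], Mapping[int, int]]
) -> CategoryTable:
    """Category table from screening outcomes or a raw {k: n_sites} map.

    Only editable sites contribute. Percentages are of total sites,
    rounded half-up to 2 decimals.
    """
    if isinstance(source, Mapping):
        counts = {int(k): int(v) for k, v in source.items() if v}
        if any(v < 0 for v in source.values()):
            raise BexploreError("feasible-count table has negative entries")
    else:
        tally: Counter[int] = Counter()
        for outcome in source:
            if outcome.status == "editable":
                tally[len(outcome.candidates)] += 1
        counts = dict(tally)
    if not counts:
        raise BexploreError("no editable sites: category table is empty")
    total_sites = sum(counts.values())
    total_guides = sum(k * n for k, n in counts.items())
    percentages = {k: percent(n, total_sites, 2)
                   for k, n in sorted(counts.items())}
    return CategoryTable(dict(sorted(counts.items())), total_sites,
                         total_guides, percentages)


@dataclass
class FailureTable:
    counts: dict[str, int]
    percentages: dict[str, float]           # of failed sites, 2 decimals
    pam_or_window_pct: float                # combined no_PAM + window share


def summarize_failures(
        fail_reasons: Union[Iterable[str], Mapping[str, int]]
) -> FailureTable:
    """Per-label failure counts/percentages from a label multiset or a
    {label: count} map; unknown labels are rejected."""
    if isinstance(fail_reasons, Mapping):
        counts = {str(k): int(v) for k, v in fail_reasons.items() if v}
    else:
        counts = dict(Counter(fail_reasons))
    unknown = set(counts) - set(FAIL_LABELS)
    if unknown:
        raise BexploreError(f"unknown failure label(s): {sorted(unknown)}")
    if not counts or sum(counts.values()) == 0:
        raise BexploreError("no failed sites: failure table is empty")
    total = sum(counts.values())
    percentages = {label: percent(n, total, 2) for label, n in counts.items()}
    pam_window = counts.get(FAIL_NO_PAM, 0) + counts.get(FAIL_WINDOW, 0)
    return FailureTable(counts, percentages, percent(pam_window, total, 1))
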