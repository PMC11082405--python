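"""Candidate evaluation and robust rank aggregation (RRA).

Each surviving candidate is scored on five features, all "smaller is
better":

1. bases identical to the editor's target base inside the activity
   window (bystander potential; the count includes the target itself, a
   constant +1 that cannot change the ordering);
2. protospacer GC fraction (high GC tolerates mismatches, raising
   off-target risk);
3. exact occurrences of the protospacer in the genome, both strands
   (includes the on-target copy, so always >= 1);
4. background SNPs overlapping the protospacer's genomic span;
5. mean CFD off-target score.

Candidates are ranked per feature within their site (ascending, ties
averaged), ranks are normalized by the number of candidates m at the
site, and the five normalized ranks are aggregated with RRA: for sorted
normalized ranks r(1) <= ... <= r(5) the score is

    min_k  BetaCDF(r(k); k, 5 - k + 1),

the smallest probability that the k-th order statistic of five
independent uniforms would be at most r(k). Smaller scores mean a
candidate sits improbably high across the five lists. No multiplicity
correction is applied to the minimum: scores are used purely ordinally
to pick a winner. Exact score ties break deterministically by lower
off-target score, then smaller genomic start, then '+' strand.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import beta as beta_dist
from scipy.stats import rankdata

from .editors import BaseEditor
from .errors import BexploreError
from .io import GenomeIndex, SnpTrack
from .offtarget import CfdTable, find_offtargets, offtarget_feature
from .screening import CandidateGuide, ScreeningOutcome
from ._seq import gc_count

import logging

logger = logging.getLogger(__name__)

FEATURE_NAMES = ("same_base_in_window", "gc_fraction", "repeat_count",
                 "snp_count", "offtarget_score")

N_FEATURES = len(FEATURE_NAMES)


@dataclass(frozen=True)
class GuideFeatures:
    same_base_in_window: int
    gc_fraction: float
    repeat_count: int
    snp_count: int
    offtarget_score: float

    def as_vector(self) -> tuple[float, ...]:
        return (self.same_base_in_window, self.gc_fraction,
                self.repeat_count, self.snp_count, self.offtarget_score)


@dataclass
class GuideRanking:
    per_feature_ranks: dict[str, float]
    normalized_ranks: dict[str, float]
    rra_score: float
    is_best: bool


@dataclass
class OfftargetConfig:
    """Settings shared by the off-target feature computations."""

    max_mm: int = 4
    pam_policy: str = "strict"
    table: CfdTable | None = None


def compute_features(guide: CandidateGuide, editor: BaseEditor,
                     genome: GenomeIndex, snp_track: SnpTrack | None = None,
                     offtarget_cfg: OfftargetConfig | None = None
                     ) -> GuideFeatures:
    """The five evaluation features for one screened candidate."""
    cfg = offtarget_cfg or OfftargetConfig()
    window_seq = guide.protospacer[editor.window_start - 1:editor.window_end]
    same_base = window_seq.count(editor.target_base)

    gc = gc_count(guide.protospacer) / len(guide.protospacer)

    # exact occurrences genome-wide on both strands: the scanner excludes
    # the on-target locus, so add it back
    repeats = 1 + len(find_offtargets(guide, genome, max_mm=0,
                                      pam_policy="any"))

    if snp_track is None:
        logger.warning("no SNP track supplied: snp_count set to 0 for %s",
                       guide.site_id)
        snps = 0
    else:
        chrom = guide.chrom or next(iter(genome.sequences))
        snps = snp_track.count(chrom, *guide.span)

    offt = offtarget_feature(guide, genome, max_mm=cfg.max_mm,
                             table=cfg.table, pam_policy=cfg.pam_policy,
                             pam_pattern=editor.pam_pattern)
    return GuideFeatures(same_base, gc, repeats, snps, offt)


def rra_aggregate(normalized_rank_vectors: np.ndarray) -> np.ndarray:
    """RRA score per candidate from an (n_candidates, 5) array of
    normalized ranks in (0, 1]."""
    vectors = np.asarray(normalized_rank_vectors, dtype=float)
    if vectors.ndim != 2 or vectors.shape[1] != N_FEATURES:
        raise BexploreError(
            f"expected an (n, {N_FEATURES}) array of normalized ranks")
    if np.any(vectors <= 0) or np.any(vectors > 1):
        raise BexploreError("normalized ranks must lie in (0, 1]")
    r = np.sort(vectors, axis=1)
    k = np.arange(1, N_FEATURES + 1)
    cdf = beta_dist.cdf(r, k[None, :], N_FEATURES - k[None, :] + 1)
    return cdf.min(axis=1)


def _tie_break_key(guide: CandidateGuide, features: GuideFeatures):
    return (features.offtarget_score, guide.protospacer_start,
            0 if guide.strand == "+" else 1)


def rank_candidates(guides: list[CandidateGuide],
                    features: list[GuideFeatures]) -> list[GuideRanking]:
    """Per-feature ranks (ascending = better, ties averaged), normalized
    by the site's candidate count, aggregated by RRA; exactly one
    candidate is flagged best."""
    if len(guides) != len(features) or not guides:
        raise BexploreError("need one feature vector per candidate")
    m = len(guides)
    matrix = np.array([f.as_vector() for f in features], dtype=float)
    ranks = np.column_stack([rankdata(matrix[:, j], method="average")
                             for j in range(N_FEATURES)])
    normalized = ranks / m
    scores = rra_aggregate(normalized)

    order = sorted(range(m), key=lambda i: (scores[i],
                                            _tie_break_key(guides[i], features[i])))
    best_index = order[0]
    out = []
    for i in range(m):
        out.append(GuideRanking(
            per_feature_ranks=dict(zip(FEATURE_NAMES, ranks[i])),
            normalized_ranks=dict(zip(FEATURE_NAMES, normalized[i])),
            rra_score=float(scores[i]),
            is_best=(i == best_index)))
    return out


def select_best(outcome: ScreeningOutcome, features: list[GuideFeatures]
                ) -> tuple[CandidateGuide, list[GuideRanking]]:
    """Best guide of an editable site plus the full ranking table."""
    if outcome.status != "editable":
        raise BexploreError(f"site {outcome.site_id} is not editable")
    rankings = rank_candidates(outcome.candidates, features)
    best = next(g for g, r in zip(outcome.candidates, rankings) if r.is_best)
    return best, rankings
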