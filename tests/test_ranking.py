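import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bexplore.errors import BexploreError
from bexplore.io import GenomeIndex, SnpTrack
from bexplore.ranking import (GuideFeatures, OfftargetConfig,
                              compute_features, rank_candidates,
                              rra_aggregate, select_best)
from bexplore.screening import CandidateGuide, ScreeningOutcome

from ._oracles import rra_exact

PROTO = "GACCCATGACGTTACCAGTC"


def _guide(proto=PROTO, start=1, strand="+", site="chr1:5") -> CandidateGuide:
    return CandidateGuide(site, strand, proto, "AGG", start,
                          start + len(proto) - 1, 5, chrom="chr1")


def _features(i, offt=0.0):
    return GuideFeatures(same_base_in_window=i, gc_fraction=0.4,
                         repeat_count=1, snp_count=0, offtarget_score=offt)


class TestComputeFeatures:
    def test_window_bystander_count_includes_target(self, be3, uniform_table):
        # window 4-8 content of PROTO is "CCATG": two Cs, one of them the target
        genome = GenomeIndex({"chr1": PROTO + "AGG" + "T" * 20})
        feats = compute_features(_guide(), be3, genome,
                                 offtarget_cfg=OfftargetConfig(table=uniform_table))
        assert PROTO[3:8] == "CCATG"
        assert feats.same_base_in_window == 2
        assert feats.repeat_count == 1

    def test_gc_fraction_of_at_only_spacer_is_zero(self, be3, uniform_table):
        proto = "ATATATATATATATATATAT"
        genome = GenomeIndex({"chr1": proto + "AGG" + "C" * 20})
        feats = compute_features(_guide(proto), be3, genome,
                                 offtarget_cfg=OfftargetConfig(table=uniform_table))
        assert feats.gc_fraction == 0.0

    def test_repeat_count_counts_both_strands(self, be3, uniform_table):
        from bexplore._seq import revcomp
        seq = PROTO + "AGG" + "TTTT" + revcomp(PROTO) + "TTTT" + PROTO
        genome = GenomeIndex({"chr1": seq})
        feats = compute_features(_guide(), be3, genome,
                                 offtarget_cfg=OfftargetConfig(table=uniform_table))
        assert feats.repeat_count == 3

    def test_snps_inside_guide_span_counted(self, be3, uniform_table):
        genome = GenomeIndex({"chr1": PROTO + "AGG" + "T" * 20})
        track = SnpTrack({"chr1": [3, 17, 25]})        # two inside span 1-20
        feats = compute_features(_guide(), be3, genome, snp_track=track,
                                 offtarget_cfg=OfftargetConfig(table=uniform_table))
        assert feats.snp_count == 2

    def test_missing_snp_track_warns_and_zeroes(self, be3, uniform_table,
                                                caplog):
        genome = GenomeIndex({"chr1": PROTO + "AGG" + "T" * 20})
        with caplog.at_level("WARNING"):
            feats = compute_features(_guide(), be3, genome,
                                     offtarget_cfg=OfftargetConfig(
                                         table=uniform_table))
        assert feats.snp_count == 0 and "SNP track" in caplog.text


class TestRraAggregate:
    def test_matches_binomial_tail_oracle(self):
        cases = [
            [0.25] * 5,                       # ranked first everywhere, m=4
            [0.2, 0.4, 0.6, 0.8, 1.0],
            [1.0, 1.0, 1.0, 1.0, 1.0],
            [0.5, 0.25, 1.0, 0.75, 0.25],
        ]
        got = rra_aggregate(np.array(cases))
        for scores, ranks in zip(got, cases):
            assert scores == pytest.approx(rra_exact(ranks), rel=1e-12)

    def test_first_everywhere_scores_smallest_order_statistic(self):
        # min_k P(Bin(5, 1/4) >= k) is attained at k=5: (1/4)^5
        (score,) = rra_aggregate(np.array([[0.25] * 5]))
        assert score == pytest.approx(0.25 ** 5)

    def test_single_candidate_scores_one(self):
        (score,) = rra_aggregate(np.array([[1.0] * 5]))
        assert score == 1.0

    def test_dominance_monotone(self):
        a, b = [0.2, 0.4, 0.4, 0.6, 0.8], [0.4, 0.4, 0.6, 0.8, 1.0]
        sa, sb = rra_aggregate(np.array([a, b]))
        assert sa <= sb

    def test_rejects_out_of_range_ranks(self):
        with pytest.raises(BexploreError, match="normalized ranks"):
            rra_aggregate(np.array([[0.0, 0.5, 0.5, 0.5, 0.5]]))
        with pytest.raises(BexploreError, match="normalized ranks"):
            rra_aggregate(np.array([[1.5, 0.5, 0.5, 0.5, 0.5]]))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0.01, 1.0), min_size=5, max_size=5))
    def test_agrees_with_exact_oracle_on_random_vectors(self, ranks):
        (score,) = rra_aggregate(np.array([ranks]))
        assert score == pytest.approx(rra_exact(ranks), rel=1e-9)


class TestSelectBest:
    def _outcome(self, guides):
        return ScreeningOutcome("s", "editable", "", guides)

    def test_single_candidate_is_best(self):
        guides = [_guide()]
        best, rankings = select_best(self._outcome(guides), [_features(1)])
        assert best is guides[0] and rankings[0].is_best
        assert rankings[0].rra_score == 1.0

    def test_winner_minimizes_rra(self):
        guides = [_guide(start=1), _guide(start=30), _guide(start=60)]
        feats = [_features(3, 0.9), _features(1, 0.1), _features(2, 0.5)]
        best, rankings = select_best(self._outcome(guides), feats)
        assert best is guides[1]
        assert sum(r.is_best for r in rankings) == 1
        scores = [r.rra_score for r in rankings]
        assert scores[1] == min(scores)

    def test_permuting_candidates_preserves_winner_and_scores(self):
        guides = [_guide(start=1), _guide(start=30), _guide(start=60)]
        feats = [_features(3, 0.9), _features(1, 0.1), _features(2, 0.5)]
        best_a, rank_a = select_best(self._outcome(guides), feats)
        order = [2, 0, 1]
        best_b, rank_b = select_best(
            self._outcome([guides[i] for i in order]),
            [feats[i] for i in order])
        assert (best_a.protospacer_start == best_b.protospacer_start)
        assert sorted(r.rra_score for r in rank_a) == \
            pytest.approx(sorted(r.rra_score for r in rank_b))

    def test_adding_dominated_candidate_keeps_winner(self):
        guides = [_guide(start=1), _guide(start=30)]
        feats = [_features(1, 0.1), _features(2, 0.5)]
        best_small, _ = select_best(self._outcome(guides), feats)
        guides_aug = guides + [_guide(start=60)]
        feats_aug = feats + [_features(5, 0.9)]    # dominated by both
        best_aug, _ = select_best(self._outcome(guides_aug), feats_aug)
        assert best_aug.protospacer_start == best_small.protospacer_start

    def test_identical_feature_vectors_tie_break_by_start_then_strand(self):
        guides = [_guide(start=50), _guide(start=10)]
        feats = [_features(1, 0.2), _features(1, 0.2)]
        best, _ = select_best(self._outcome(guides), feats)
        assert best.protospacer_start == 10
        guides = [_guide(start=10, strand="-"), _guide(start=10, strand="+")]
        best, _ = select_best(self._outcome(guides), feats)
        assert best.strand == "+"
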