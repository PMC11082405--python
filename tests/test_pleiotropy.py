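import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bexplore.errors import BexploreError, NonConvertibleEffectError
from bexplore.io import GwasRecord
from bexplore.pleiotropy import (WeakPleiotropyCriteria, bin_strength,
                                 classify_association, convert_beta,
                                 pleiotropy_profile, qq_points, screen_weak,
                                 strength_bin)


def _rec(snp, pheno, beta_obs, p, phi=0.3, theta=0.4):
    return GwasRecord(snp, "chr1", 100, pheno, beta_obs, p, phi, theta, "A")


def _profile_records(snp, n_promote, n_inhibit, n_null, effect=0.05):
    recs = []
    k = 0
    for _ in range(n_promote):
        recs.append(_rec(snp, f"ph{k}", effect, 0.001)); k += 1
    for _ in range(n_inhibit):
        recs.append(_rec(snp, f"ph{k}", -effect, 0.001)); k += 1
    for _ in range(n_null):
        recs.append(_rec(snp, f"ph{k}", 0.0001, 0.7)); k += 1
    return recs


class TestConvertBeta:
    def test_zero_effect_maps_to_zero(self):
        for phi, theta in [(0.1, 0.2), (0.5, 0.5), (0.9, 0.8)]:
            assert convert_beta(0.0, phi, theta) == 0.0

    def test_hand_evaluated_denominator(self):
        # phi=theta=0.5 kills the linear term:
        # D = 0.25 - 0.084 * 0.25 * 0.25 * 0.01
        expected = 0.1 / (0.25 - 0.084 * 0.25 * 0.25 * 0.1 ** 2)
        assert convert_beta(0.1, 0.5, 0.5) == pytest.approx(expected, rel=1e-12)
        assert convert_beta(0.1, 0.5, 0.5) == pytest.approx(0.40008, abs=5e-6)

    @pytest.mark.parametrize("phi", [0.1, 0.3, 0.5, 0.7, 0.9])
    @pytest.mark.parametrize("theta", [0.1, 0.5, 0.9])
    def test_small_effect_slope_is_reciprocal_variance(self, phi, theta):
        eps = 1e-8
        slope = convert_beta(eps, phi, theta) / eps
        assert slope == pytest.approx(1.0 / (phi * (1.0 - phi)), abs=1e-6)

    def test_strictly_increasing_near_zero(self):
        for phi in (0.2, 0.5, 0.8):
            for theta in (0.2, 0.8):
                grid = [convert_beta(b, phi, theta)
                        for b in (-1e-3, -1e-4, 0.0, 1e-4, 1e-3)]
                assert all(a < b for a, b in zip(grid, grid[1:]))

    def test_non_positive_denominator_raises_with_inputs(self):
        with pytest.raises(NonConvertibleEffectError) as err:
            convert_beta(100.0, 0.5, 0.5)
        assert err.value.beta_obs == 100.0

    @pytest.mark.parametrize("phi, theta", [(0.0, 0.5), (1.0, 0.5),
                                            (0.5, 0.0), (0.5, 1.0)])
    def test_domain_errors(self, phi, theta):
        with pytest.raises(BexploreError):
            convert_beta(0.1, phi, theta)


class TestClassify:
    @pytest.mark.parametrize("beta, p, expected", [
        (0.3, 0.01, "promotion"),
        (-0.2, 0.04, "inhibition"),
        (0.5, 0.2, "nonsignificant"),
        (0.5, 0.05, "nonsignificant"),     # threshold is strict
        (0.0, 0.01, "nonsignificant"),
    ])
    def test_sign_and_threshold(self, beta, p, expected):
        assert classify_association(beta, p) == expected


class TestProfile:
    def test_promotion_inhibition_counts_recovered(self):
        recs = _profile_records("rs1", 17, 3, 111)
        prof = pleiotropy_profile("rs1", recs)
        assert (prof.n_promote, prof.n_inhibit) == (17, 3)
        assert prof.n_significant == 20 and prof.strength_bin == "10-20"
        assert prof.n_phenotypes_tested == 131

    def test_heavily_pleiotropic_snp_binned_high(self):
        prof = pleiotropy_profile("rs2", _profile_records("rs2", 27, 0, 104))
        assert prof.n_significant == 27 and prof.strength_bin == ">20"

    def test_all_null_snp(self):
        recs = [_rec("rs3", f"ph{k}", 0.01, 1.0) for k in range(10)]
        prof = pleiotropy_profile("rs3", recs)
        assert (prof.n_promote, prof.n_inhibit) == (0, 0)
        assert prof.strength_bin == "<10"

    def test_unconvertible_records_excluded_and_logged(self, caplog):
        recs = _profile_records("rs4", 2, 0, 3) + [_rec("rs4", "bad", 100.0,
                                                        0.001, 0.5, 0.5)]
        with caplog.at_level("WARNING"):
            prof = pleiotropy_profile("rs4", recs)
        assert prof.n_phenotypes_tested == 5
        assert "non-convertible" in caplog.text

    def test_invariant_promote_plus_inhibit_is_significant(self):
        rng = np.random.default_rng(5)
        recs = [_rec("rs5", f"ph{k}", float(rng.normal(0, 0.05)),
                     float(rng.uniform())) for k in range(50)]
        prof = pleiotropy_profile("rs5", recs)
        assert prof.n_promote + prof.n_inhibit == prof.n_significant
        assert prof.n_significant <= prof.n_phenotypes_tested


class TestBinsAndScreen:
    def test_strength_bin_edges(self):
        assert strength_bin(9) == "<10"
        assert strength_bin(10) == "10-20"
        assert strength_bin(20) == "10-20"
        assert strength_bin(21) == ">20"

    def test_percentages_match_published_style_rounding(self):
        profiles = []
        for n, count in [(5, 577), (15, 121), (25, 9)]:
            profiles += [_mk_profile(f"s{n}_{i}", n) for i in range(count)]
        counts, pct = bin_strength(profiles)
        assert counts == {"<10": 577, "10-20": 121, ">20": 9}
        assert pct == {"<10": 81.6, "10-20": 17.1, ">20": 1.3}

    def test_single_profile_is_hundred_percent(self):
        counts, pct = bin_strength([_mk_profile("s", 3)])
        assert pct["<10"] == 100.0

    def test_rounded_percentages_sum_to_about_100(self):
        profiles = [_mk_profile(f"s{i}", n)
                    for i, n in enumerate([5] * 10 + [15] * 10 + [25] * 10)]
        _, pct = bin_strength(profiles)
        # equal tertiles round to 33.3 each: the sum sits exactly at the
        # 0.1 boundary, so allow for float representation of 99.9
        assert sum(pct.values()) == pytest.approx(100.0, abs=0.1 + 1e-9)

    def test_weak_screen_default_keeps_at_most_one_significant(self):
        profiles = [_mk_profile("keep0", 0), _mk_profile("keep1", 1),
                    _mk_profile("drop", 20)]
        assert screen_weak(profiles) == ["keep0", "keep1"]
        assert screen_weak(profiles, WeakPleiotropyCriteria(25)) == \
            ["keep0", "keep1", "drop"]


def _mk_profile(snp, n_sig):
    from bexplore.pleiotropy import PleiotropyProfile
    return PleiotropyProfile(snp, 131, n_sig, n_sig, 0, strength_bin(n_sig))


class TestQq:
    def test_single_point(self):
        ((e, o),) = qq_points([0.5])
        assert e == pytest.approx(-math.log10(0.5))
        assert o == pytest.approx(-math.log10(0.5))

    def test_uniform_grid_lies_on_diagonal(self):
        pts = qq_points([0.625, 0.125, 0.875, 0.375])
        for e, o in pts:
            assert e == pytest.approx(o)

    def test_enriched_small_p_above_diagonal(self):
        pvals = [0.125, 0.375, 0.625, 0.875]
        pts = qq_points([1e-6] + pvals[1:])
        assert pts[0][1] > pts[0][0]

    def test_zero_p_clamped_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            pts = qq_points([0.0, 0.5])
        assert math.isfinite(pts[0][1]) and "clamped" in caplog.text

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.lists(st.floats(1e-12, 1.0), min_size=1, max_size=40))
    def test_observed_sorted_and_paired_by_order(self, pvals):
        pts = qq_points(pvals)
        observed = [o for _, o in pts]
        assert observed == sorted(observed, reverse=True)
        assert len(pts) == len(pvals)
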