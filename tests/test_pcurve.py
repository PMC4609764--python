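"""pp-value construction, Fisher combination and the three skew tests."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pcurve_meta import (
    EffectEstimate,
    EmptyPCurveError,
    PCurveConfig,
    fisher_combine,
    fisher_pvalue,
    ncp_for_power,
    pp_33,
    pp_left,
    pp_right,
    run_pcurve,
    select_significant,
    two_sided_p,
    winsorize,
)
from pcurve_meta.pcurve import (
    INFERENCE_EVIDENTIAL,
    INFERENCE_INCONCLUSIVE,
    _two_sided_power,
    implied_effect,
)

from oracles import chi2_sf_even_df, power_two_sided_z


def effect_from_p(sid, p, sign=-1.0):
    """Build an EffectEstimate whose two-sided p is exactly `p`."""
    from scipy import stats

    z = sign * stats.norm.isf(p / 2.0)
    se = 0.05
    d = z * se
    return EffectEstimate(sid, d, se**2, se, z, two_sided_p(z))


class TestSelection:
    def test_six_of_ten_retained(self):
        ps = [0.01, 0.02, 0.03, 0.04, 0.045, 0.049, 0.06, 0.2, 0.5, 0.9]
        effects = [effect_from_p(f"S{i}", p) for i, p in enumerate(ps)]
        included, excluded = select_significant(effects)
        assert len(included) == 6
        assert excluded == 4
        assert [e.study_id for e in included] == [f"S{i}" for i in range(6)]

    def test_boundary_alpha_excluded(self):
        effects = [effect_from_p("a", 0.05), effect_from_p("b", 0.01)]
        included, excluded = select_significant(effects)
        assert [e.study_id for e in included] == ["b"]
        assert excluded == 1

    def test_all_nonsignificant_raises(self):
        effects = [effect_from_p("a", 0.3), effect_from_p("b", 0.06)]
        with pytest.raises(EmptyPCurveError):
            select_significant(effects)

    def test_wrong_direction_excluded_with_warning(self):
        effects = [effect_from_p("a", 0.01), effect_from_p("b", 0.01, sign=+1.0)]
        with pytest.warns(UserWarning, match="opposite"):
            included, excluded = select_significant(effects)
        assert [e.study_id for e in included] == ["a"]
        assert excluded == 1


class TestPPValues:
    @pytest.mark.parametrize("p, expected", [(0.025, 0.5), (0.01, 0.2), (0.0004, 0.008)])
    def test_pp_right_is_division_by_alpha(self, p, expected):
        assert pp_right(p) == pytest.approx(expected)

    def test_pp_right_domain(self):
        with pytest.raises(ValueError):
            pp_right(0.05)
        with pytest.raises(ValueError):
            pp_right(0.0)

    @pytest.mark.parametrize("x, expected", [(0.8, 0.2), (0.5, 0.5), (0.998, 0.002)])
    def test_pp_left_is_complement(self, x, expected):
        assert pp_left(x) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "x, expected", [(0.5, 0.5), (0.001, 0.01), (0.999, 0.99), (0.008, 0.01)]
    )
    def test_winsorize_clamps(self, x, expected):
        assert winsorize(x) == expected

    @given(st.floats(min_value=1e-6, max_value=0.0499, exclude_max=True))
    @settings(max_examples=60, deadline=None)
    def test_left_right_complement_before_winsorizing(self, p):
        r = pp_right(p)
        assert pp_left(r) + r == pytest.approx(1.0, abs=1e-12)

    @given(
        st.floats(min_value=1e-5, max_value=0.049),
        st.floats(min_value=1e-5, max_value=0.049),
    )
    @settings(max_examples=60, deadline=None)
    def test_channel_monotonicity(self, p1, p2):
        """pp_right increases with p; pp_left and pp_33 decrease."""
        if p1 == p2:
            return
        lo, hi = sorted((p1, p2))
        ncp = 1.5285687127
        assert pp_right(lo) < pp_right(hi)
        assert pp_left(pp_right(lo)) > pp_left(pp_right(hi))
        assert pp_33(lo, ncp) > pp_33(hi, ncp)


class TestNcpCalibration:
    def test_null_identity(self):
        cfg = PCurveConfig(power_ref=0.05, alpha=0.05)
        assert ncp_for_power(config=cfg) == pytest.approx(0.0, abs=1e-6)

    def test_third_power_value(self):
        delta = ncp_for_power()
        assert delta == pytest.approx(1.5286, abs=1e-3)
        # solved power is exact to the stated tolerance
        assert _two_sided_power(delta, 0.05) == pytest.approx(1 / 3, abs=1e-10)

    def test_eighty_power_matches_textbook_approximation(self):
        cfg = PCurveConfig(power_ref=0.80)
        # z_{0.975} + z_{0.80}; the ignored opposite tail is ~1e-6
        assert ncp_for_power(config=cfg) == pytest.approx(2.80158, abs=2e-3)

    def test_grid_search_oracle(self):
        """Dense grid over delta evaluating the power formula with erf only."""
        grid = np.arange(0.0, 5.0, 1e-4)
        powers = np.array([power_two_sided_z(d, 0.05) for d in grid])
        best = grid[np.argmin(np.abs(powers - 1 / 3))]
        assert ncp_for_power() == pytest.approx(best, abs=1e-3)

    def test_implied_effect_scaling(self):
        delta = 1.5285687127
        assert implied_effect(delta, 40, 40) == pytest.approx(
            delta * math.sqrt(2 / 40)
        )


class TestPP33:
    def test_boundary_maps_to_zero(self):
        delta = ncp_for_power()
        assert pp_33(0.0499999, delta) == pytest.approx(0.0, abs=1e-4)

    def test_tiny_p_maps_to_one(self):
        delta = ncp_for_power()
        assert pp_33(1e-12, delta) == pytest.approx(1.0, abs=1e-6)

    def test_frozen_folded_normal_value(self):
        assert pp_33(0.025, 1.5284) == pytest.approx(0.286, abs=1e-3)

    def test_monte_carlo_oracle(self):
        """pp_33 equals the simulated conditional exceedance probability.

        Draw z ~ Normal(ncp, 1), keep the two-sided significant ones, and
        count the fraction with p at least as large as the observed p.
        """
        from scipy import stats

        rng = np.random.default_rng(777)
        delta = ncp_for_power()
        z = rng.normal(delta, 1.0, size=2_000_000)
        z_crit = stats.norm.isf(0.025)
        sig_p = 2.0 * stats.norm.sf(np.abs(z[np.abs(z) > z_crit]))
        for p_obs in (0.025, 0.01, 0.04):
            frac = np.mean(sig_p >= p_obs)
            mc_se = math.sqrt(frac * (1 - frac) / sig_p.size)
            assert pp_33(p_obs, delta) == pytest.approx(frac, abs=3 * mc_se + 1e-4)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            pp_33(0.06, 1.5)


class TestFisher:
    def test_unity_pps_give_zero_chi2(self):
        t = fisher_combine([1.0, 1.0])
        assert t.chi2 == 0.0
        assert t.df == 4
        assert t.p == 1.0

    def test_hand_evaluated_pair(self):
        t = fisher_combine([0.2, 0.5])
        assert t.chi2 == pytest.approx(4.60517, abs=1e-4)
        assert t.df == 4
        assert t.p == pytest.approx(0.330259, abs=1e-5)

    def test_df_is_twice_count(self):
        for k in (1, 3, 6, 10):
            assert fisher_combine([0.5] * k).df == 2 * k

    def test_zero_pp_rejected(self):
        with pytest.raises(ValueError):
            fisher_combine([0.5, 0.0])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            fisher_combine([])

    @given(
        st.lists(st.floats(min_value=0.01, max_value=0.99), min_size=1, max_size=12)
    )
    @settings(max_examples=80, deadline=None)
    def test_p_matches_even_df_series(self, pps):
        t = fisher_combine(pps)
        assert t.p == pytest.approx(chi2_sf_even_df(t.chi2, t.df), abs=1e-10)

    def test_monte_carlo_null_distribution(self):
        """-2 sum ln U over k uniforms is chi-square on 2k df."""
        rng = np.random.default_rng(4242)
        k = 6
        chi2 = -2.0 * np.log(rng.uniform(size=(20000, k))).sum(axis=1)
        x = 14.0
        frac = np.mean(chi2 > x)
        mc_se = math.sqrt(frac * (1 - frac) / 20000)
        assert fisher_pvalue(x, 2 * k) == pytest.approx(frac, abs=3 * mc_se)


class TestRunPCurve:
    def test_six_barely_significant_studies_flag_left_skew(self):
        effects = [effect_from_p(f"S{i}", 0.049) for i in range(6)]
        res = run_pcurve(effects)
        right = res.test("right_skew")
        left = res.test("left_skew")
        assert right.chi2 == pytest.approx(-12 * math.log(0.98), abs=1e-6)
        assert right.p == pytest.approx(1.0, abs=1e-4)
        assert left.chi2 == pytest.approx(-12 * math.log(0.02), abs=1e-6)
        assert left.p < 1e-4
        assert "p-hacked" in res.inference

    def test_single_strong_study_contains_evidential_value(self):
        res = run_pcurve([effect_from_p("only", 0.001)])
        right = res.test("right_skew")
        assert right.df == 2
        assert right.chi2 == pytest.approx(-2 * math.log(0.02), abs=1e-6)
        assert right.p == pytest.approx(math.exp(-right.chi2 / 2), abs=1e-10)
        assert res.inference == INFERENCE_EVIDENTIAL

    def test_df_equals_twice_included(self):
        ps = [0.01, 0.02, 0.03, 0.2, 0.5]
        effects = [effect_from_p(f"S{i}", p) for i, p in enumerate(ps)]
        res = run_pcurve(effects)
        assert res.n_significant == 3
        assert res.n_excluded == 2
        assert all(t.df == 6 for t in res.tests)

    def test_moderate_p_values_inconclusive(self):
        effects = [effect_from_p(f"S{i}", p) for i, p in enumerate([0.02, 0.03])]
        res = run_pcurve(effects)
        assert res.inference == INFERENCE_INCONCLUSIVE

    def test_all_three_tests_always_reported(self):
        res = run_pcurve([effect_from_p("a", 0.01)])
        assert {t.label for t in res.tests} == {
            "right_skew", "flatter_than_33", "left_skew"
        }

    @given(
        st.lists(
            st.floats(min_value=1e-6, max_value=0.0499), min_size=1, max_size=10
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_winsorization_bounds_chi2(self, ps):
        effects = [effect_from_p(f"S{i}", p) for i, p in enumerate(ps)]
        res = run_pcurve(effects)
        k = res.n_significant
        lo = -2 * k * math.log(0.99)
        hi = -2 * k * math.log(0.01)
        for t in res.tests:
            assert lo - 1e-9 <= t.chi2 <= hi + 1e-9

    def test_pp_sets_carry_winsor_flags(self):
        res = run_pcurve([effect_from_p("a", 0.0004)])
        s = res.pp_values[0]
        assert s.pp_right == 0.01
        assert s.winsorized["right"]
        assert s.pp_left == 0.99
        assert s.winsorized["left"]
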