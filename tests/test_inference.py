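import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from repmetrics import inference as inf
from repmetrics.inference import (
    DEFAULT_CAUCHY_SCALE,
    d33,
    fixed_effect_meta,
    jzs_bf10,
    meta_bf10,
    noncentral_power,
    replication_bf,
    sceptical_p,
    sceptical_p_from_z,
    small_telescope_p,
)


class TestPower:
    def test_null_effect_power_is_alpha(self):
        assert noncentral_power(0.0, 50, 0.05) == pytest.approx(0.05, abs=1e-12)

    def test_huge_effect_power_is_one(self):
        assert noncentral_power(5.0, 50, 0.05) == pytest.approx(1.0, abs=1e-6)

    def test_against_monte_carlo_rejection_rate(self):
        # 100k simulated studies at delta = 0.5, n = 25
        rng = np.random.default_rng(99)
        n, delta = 25, 0.5
        means = rng.normal(delta, 1 / math.sqrt(n), size=100_000)
        sds = np.sqrt(rng.chisquare(n - 1, size=100_000) / (n - 1))
        t = means / (sds / math.sqrt(n))
        rate = (t > stats.t.isf(0.05, n - 1)).mean()
        assert abs(noncentral_power(delta, n, 0.05) - rate) < 0.005


class TestD33:
    @pytest.mark.parametrize("n", [25, 50, 75, 100])
    def test_defining_power_recovery(self, n):
        assert noncentral_power(d33(n), n, 0.05) == pytest.approx(1 / 3, abs=1e-8)

    def test_strictly_decreasing_in_sample_size(self):
        vals = [d33(n) for n in (25, 50, 75, 100)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_matches_brute_force_grid_search(self):
        # independent oracle: dense delta grid, pick the power closest to 1/3
        grid = np.arange(0.2, 0.3, 1e-6)
        powers = noncentral_power(grid, 25, 0.05)
        oracle = grid[np.argmin(np.abs(powers - 1 / 3))]
        assert d33(25) == pytest.approx(oracle, abs=1e-5)


class TestSmallTelescope:
    def test_benchmark_scaled_t_sits_near_median(self):
        n_r, bench = 100, 0.25
        p = small_telescope_p((bench * math.sqrt(n_r), n_r), bench)
        assert abs(p - 0.5) < 0.02

    def test_far_negative_t_is_certain_failure(self):
        assert small_telescope_p((-30.0, 50), 0.3) < 1e-10

    def test_strictly_increasing_in_t(self):
        t = np.linspace(-3, 4, 40)
        p = small_telescope_p((t, np.full_like(t, 60)), 0.2)
        assert np.all(np.diff(p) > 0)

    def test_nonpositive_benchmark_rejected(self):
        with pytest.raises(ValueError):
            small_telescope_p((1.0, 50), 0.0)


class TestFixedEffectMeta:
    def test_identical_studies_halve_variance(self):
        res = fixed_effect_meta((2.0, 50), (2.0, 50))
        d = 2.0 / math.sqrt(50)
        v = 1 / 50 + d**2 / 100
        assert res.d_combined == pytest.approx(d, rel=1e-12)
        assert res.se_combined == pytest.approx(math.sqrt(v / 2), rel=1e-12)

    def test_hand_computed_oracle(self):
        # spreadsheet-style recomputation from the defining formulas
        d_o, n_o, d_r, n_r = 0.5, 25, 0.3, 50
        v_o = 1 / n_o + d_o**2 / (2 * n_o)
        v_r = 1 / n_r + d_r**2 / (2 * n_r)
        w_o, w_r = 1 / v_o, 1 / v_r
        d_c = (w_o * d_o + w_r * d_r) / (w_o + w_r)
        se = 1 / math.sqrt(w_o + w_r)
        res = fixed_effect_meta((d_o * math.sqrt(n_o), n_o), (d_r * math.sqrt(n_r), n_r))
        assert res.d_combined == pytest.approx(d_c, abs=1e-12)
        assert res.se_combined == pytest.approx(se, abs=1e-12)
        assert res.z == pytest.approx(d_c / se, abs=1e-12)
        assert res.p == pytest.approx(stats.norm.sf(d_c / se), abs=1e-12)

    def test_combined_effect_between_inputs(self, rng):
        t_o = rng.normal(1, 1.5, 50)
        t_r = rng.normal(1, 1.5, 50)
        res = fixed_effect_meta((t_o, np.full(50, 30.0)), (t_r, np.full(50, 60.0)))
        d_o, d_r = t_o / math.sqrt(30), t_r / math.sqrt(60)
        lo, hi = np.minimum(d_o, d_r), np.maximum(d_o, d_r)
        assert np.all(res.d_combined >= lo - 1e-12) and np.all(res.d_combined <= hi + 1e-12)

    def test_se_shrinks_with_more_data(self):
        small = fixed_effect_meta((1.0, 25), (1.0, 50))
        big = fixed_effect_meta((1.0, 25), (1.0, 500))
        assert big.se_combined < small.se_combined


def trapezoid_jzs(t, n, scale=DEFAULT_CAUCHY_SCALE):
    """Fixed-grid trapezoid oracle on delta in [-20, 20], 200,001 points."""
    delta = np.linspace(-20, 20, 200001)
    f = stats.nct.pdf(t, n - 1, delta * math.sqrt(n)) * stats.cauchy.pdf(delta, scale=scale)
    assert not np.isnan(f).any()
    return np.trapezoid(f, delta) / stats.t.pdf(t, n - 1)


class TestJzsBF:
    def test_null_t_favours_null(self):
        assert jzs_bf10(0.0, 100) < 1.0

    def test_increasing_in_t_two_sided(self):
        t = np.arange(0.0, 5.1, 0.5)
        bf = jzs_bf10(t, np.full_like(t, 50.0), one_sided=False)
        assert np.all(np.diff(bf) > 0)

    def test_matches_trapezoid_oracle(self):
        t, n = 2.5, 50
        assert jzs_bf10(t, n) == pytest.approx(trapezoid_jzs(t, n), rel=1e-5)

    def test_one_sided_folds_the_prior(self):
        # positive t: ~ twice the two-sided BF times posterior positive mass
        two = jzs_bf10(2.5, 50, one_sided=False)
        one = jzs_bf10(2.5, 50, one_sided=True)
        assert two < one < 2 * two * 1.01
        assert jzs_bf10(-2.5, 50, one_sided=True) < 0.1

    @pytest.mark.parametrize("t,n", [(50.0, 10000), (-50.0, 25), (0.0, 2), (50.0, 500)])
    def test_extreme_inputs_stay_finite(self, t, n):
        bf = jzs_bf10(t, n)
        assert np.isfinite(bf) and bf > 0


class TestReplicationBF:
    def test_point_null_prior_limit(self):
        # original posterior concentrated at delta = 0 => BF -> 1
        assert replication_bf((0.0, 5000), (1.0, 100)) == pytest.approx(1.0, abs=0.01)

    def test_consistent_strong_pair_supports_effect(self):
        assert replication_bf((4.0, 50), (5.0, 100)) > 1.0

    def test_null_replication_against_positive_posterior(self):
        assert replication_bf((4.0, 50), (0.0, 100)) < 1.0

    def test_savage_dickey_identity(self):
        # independent adaptive-quadrature route to the same density ratio
        def sd_oracle(t_o, n_o, t_r, n_r):
            from scipy.integrate import quad

            def prior_orig(d):
                return stats.nct.pdf(t_o, n_o - 1, d * math.sqrt(n_o)) * stats.cauchy.pdf(
                    d, scale=DEFAULT_CAUCHY_SCALE
                )

            def joint(d):
                return prior_orig(d) * stats.nct.pdf(t_r, n_r - 1, d * math.sqrt(n_r))

            z_o, _ = quad(prior_orig, -10, 10, limit=200)
            z_or, _ = quad(joint, -10, 10, limit=200)
            return (prior_orig(0.0) / z_o) / (joint(0.0) / z_or)

        rng = np.random.default_rng(17)
        for _ in range(5):
            t_o = float(rng.uniform(1.8, 3.5))
            n_o = int(rng.integers(20, 76))
            t_r = float(rng.uniform(-1, 4))
            mine = replication_bf((t_o, n_o), (t_r, 2 * n_o))
            assert mine == pytest.approx(sd_oracle(t_o, n_o, t_r, 2 * n_o), rel=1e-4)


class TestMetaBF:
    def test_concordant_studies_accumulate_evidence(self):
        # pooling always beats the weaker study; it beats both when the
        # replication's standardized effect is not smaller than the
        # original's (a weaker replication dilutes a strong original)
        for t_o in (2.0, 3.0, 4.0):
            for t_r in (2.0, 3.0, 4.0):
                both = meta_bf10((t_o, 50), (t_r, 100))
                single_o, single_r = jzs_bf10(t_o, 50), jzs_bf10(t_r, 100)
                assert both > min(single_o, single_r)
                if t_r / math.sqrt(100) >= t_o / math.sqrt(50):
                    assert both > max(single_o, single_r)

    def test_uninformative_replication_limit(self):
        # a t_r = 0 study still pulls toward the null, but its influence
        # vanishes monotonically as its sample size shrinks toward 2
        j = jzs_bf10(3.0, 50)
        ratios = [meta_bf10((3.0, 50), (0.0, n_r)) / j for n_r in (5, 3, 2)]
        assert all(a < b for a, b in zip(ratios, ratios[1:]))
        assert 0.75 < ratios[-1] < 1.0

    def test_matches_trapezoid_oracle(self):
        t_o, n_o, t_r, n_r = 2.2, 40, 1.1, 80
        delta = np.linspace(-20, 20, 200001)
        f = (
            stats.nct.pdf(t_o, n_o - 1, delta * math.sqrt(n_o))
            * stats.nct.pdf(t_r, n_r - 1, delta * math.sqrt(n_r))
            * stats.cauchy.pdf(delta, scale=DEFAULT_CAUCHY_SCALE)
        )
        oracle = np.trapezoid(f, delta) / (
            stats.t.pdf(t_o, n_o - 1) * stats.t.pdf(t_r, n_r - 1)
        )
        assert meta_bf10((t_o, n_o), (t_r, n_r)) == pytest.approx(oracle, rel=1e-5)


class TestScepticalP:
    def test_null_replication_cannot_succeed(self):
        assert sceptical_p_from_z(2.5, 0.0, 2.0) >= 0.5

    def test_nonpositive_original_cannot_succeed(self):
        assert sceptical_p_from_z(-1.0, 3.0, 2.0) >= 0.5
        assert sceptical_p_from_z(2.0, -3.0, 2.0) >= 0.5

    def test_strictly_decreasing_in_replication_z(self):
        z_r = np.linspace(0.1, 6, 60)
        p = sceptical_p_from_z(np.full_like(z_r, 2.5), z_r, np.full_like(z_r, 2.0))
        assert np.all(np.diff(p) < 0)

    def test_bounded_by_original_evidence(self):
        # z_sceptical < z_o: even an infinitely strong replication cannot
        # push the sceptical p below the original study's own p-value
        p = sceptical_p_from_z(2.0, 50.0, 2.0)
        assert p > stats.norm.sf(2.0)

    def test_closed_form_equals_prior_construction(self):
        """Two-step oracle: root-find the sufficiently sceptical prior
        variance at level alpha, then the prior-predictive conflict with the
        replication; the sceptical p solves conflict-p == alpha."""
        from scipy.optimize import brentq

        def oracle(z_o, z_r, c):
            se_o2 = 1.0  # arbitrary unit; c fixes the replication variance
            se_r2 = se_o2 / c

            def conflict_minus_alpha(alpha):
                z_a = stats.norm.isf(alpha)
                if z_o <= z_a:  # no sceptical prior exists at this level
                    return alpha  # positive => pushes the root upward
                tau2 = se_o2 / (z_o**2 / z_a**2 - 1.0)
                z_conf = z_r * math.sqrt(se_r2) / math.sqrt(se_r2 + tau2)
                return stats.norm.sf(z_conf) - alpha

            return brentq(conflict_minus_alpha, 1e-12, 0.5 - 1e-12, xtol=1e-14)

        for z_o in (1.8, 2.5, 4.0):
            for z_r in (1.0, 2.2, 5.0):
                for c in (0.5, 1.0, 2.0):
                    assert sceptical_p_from_z(z_o, z_r, c) == pytest.approx(
                        oracle(z_o, z_r, c), abs=1e-6
                    )

    def test_summary_interface_matches_z_interface(self):
        t_o, n_o, t_r, n_r = 2.4, 25, 2.0, 50
        d_o, d_r = t_o / math.sqrt(n_o), t_r / math.sqrt(n_r)
        se_o = math.sqrt(1 / n_o + d_o**2 / (2 * n_o))
        se_r = math.sqrt(1 / n_r + d_r**2 / (2 * n_r))
        expected = sceptical_p_from_z(d_o / se_o, d_r / se_r, se_o**2 / se_r**2)
        assert sceptical_p((t_o, n_o), (t_r, n_r)) == pytest.approx(expected, rel=1e-12)

    def test_invalid_variance_ratio(self):
        with pytest.raises(ValueError):
            sceptical_p_from_z(2.0, 2.0, 0.0)


class TestProperties:
    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(
        t=st.floats(-50, 50),
        n=st.integers(2, 10000),
        kind=st.sampled_from(["jzs", "meta", "rep"]),
    )
    def test_bayes_factors_finite_positive_under_stress(self, t, n, kind):
        if kind == "jzs":
            bf = jzs_bf10(t, n)
        elif kind == "meta":
            bf = meta_bf10((t, n), (t / 2, max(2, n // 2)))
        else:
            bf = replication_bf((2.5, 50), (t, n))
        assert np.isfinite(bf) and bf > 0

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        z_o=st.floats(-10, 10),
        z_r=st.floats(-10, 10),
        c=st.floats(0.01, 100),
    )
    def test_sceptical_p_is_a_probability(self, z_o, z_r, c):
        p = sceptical_p_from_z(z_o, z_r, c)
        assert 0.0 < p <= 1.0
        if z_o > 0 and z_r > 0:
            assert p < 0.5 or np.isclose(p, 0.5)
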