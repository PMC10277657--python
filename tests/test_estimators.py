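"""MR estimators against closed-form oracles and simulation properties."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mrbias import estimators as est
from mrbias.estimators import InsufficientInstrumentsError

from conftest import make_harmonised


class TestWaldRatio:
    @pytest.mark.parametrize("bx,sx,by,sy,beta,se", [
        (0.1, 0.02, 0.05, 0.01, 0.5, 0.1),
        (0.1, 0.02, 0.0, 0.01, 0.0, 0.1),
        (-0.1, 0.02, 0.05, 0.01, -0.5, 0.1),
    ])
    def test_closed_form(self, bx, sx, by, sy, beta, se):
        b, s = est.wald_ratio(bx, sx, by, sy)
        assert b == pytest.approx(beta, abs=1e-12)
        assert s == pytest.approx(se, abs=1e-12)

    def test_zero_exposure_effect_errors(self):
        with pytest.raises(ZeroDivisionError):
            est.wald_ratio(0.0, 0.02, 0.05, 0.01)


class TestIVW:
    def test_two_variant_weighted_least_squares(self):
        h = make_harmonised([0.1, 0.2], [0.05, 0.10], 0.01)
        e, d = est.ivw(h)
        assert e.beta == pytest.approx(0.5, abs=1e-12)
        assert d.Q == pytest.approx(0.0, abs=1e-10)

    def test_single_variant_equals_wald_ratio(self):
        h = make_harmonised([0.1], [0.05], 0.01)
        e, _ = est.ivw(h)
        wb, ws = est.wald_ratio(0.1, 0.0, 0.05, 0.01)
        assert e.beta == pytest.approx(wb, abs=1e-14)
        assert e.se == pytest.approx(ws, abs=1e-14)

    def test_q_from_spread_ratios(self):
        # Wald ratios 0.5 and 0.7 with equal bx and ratio-se 0.1:
        # Q = ((0.5-0.6)/0.1)^2 + ((0.7-0.6)/0.1)^2 = 2
        h = make_harmonised([0.1, 0.1], [0.05, 0.07], 0.01)
        e, d = est.ivw(h)
        assert e.beta == pytest.approx(0.6, abs=1e-12)
        assert d.Q == pytest.approx(2.0, abs=1e-10)

    def test_mre_se_floor_at_fixed_effect(self):
        h = make_harmonised([0.1, 0.2], [0.05, 0.10], 0.01)  # Q = 0
        mre, _ = est.ivw(h, random_effects=True)
        fe, _ = est.ivw(h, random_effects=False)
        assert mre.se == pytest.approx(fe.se, abs=1e-14)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(2, 12), st.integers(0, 10_000))
    def test_mre_se_never_below_fixed(self, L, seed):
        rng = np.random.default_rng(seed)
        h = make_harmonised(rng.uniform(0.05, 0.3, L),
                            rng.normal(0, 0.1, L),
                            rng.uniform(0.005, 0.05, L))
        mre, _ = est.ivw(h, random_effects=True)
        fe, _ = est.ivw(h, random_effects=False)
        assert mre.se >= fe.se - 1e-15

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(2, 8), st.floats(-2, 2), st.integers(0, 10_000))
    def test_q_zero_iff_ratios_equal(self, L, ratio, seed):
        rng = np.random.default_rng(seed)
        bx = rng.uniform(0.05, 0.3, L)
        h_equal = make_harmonised(bx, ratio * bx, rng.uniform(0.005, 0.05, L))
        _, d = est.ivw(h_equal)
        assert d.Q == pytest.approx(0.0, abs=1e-9)
        h_spread = make_harmonised(bx, ratio * bx + np.linspace(0.01, 0.05, L),
                                   0.01)
        _, d2 = est.ivw(h_spread)
        assert d2.Q > 1e-6

    def test_all_zero_exposure_effects_error(self):
        h = make_harmonised([0.0, 0.0], [0.05, 0.02], 0.01)
        with pytest.raises(ZeroDivisionError):
            est.ivw(h)


class TestMREgger:
    def test_equal_weight_ols_closed_form(self, toy_harmonised):
        # Sxy/Sxx = 0.01/0.02 = 0.5; intercept = 0.12 - 0.5*0.2 = 0.02
        e, d = est.mr_egger(toy_harmonised)
        assert e.beta == pytest.approx(0.5, abs=1e-10)
        assert d.egger_intercept == pytest.approx(0.02, abs=1e-10)

    def test_no_pleiotropy_zero_intercept(self):
        bx = np.array([0.1, 0.15, 0.2, 0.3])
        h = make_harmonised(bx, 0.4 * bx, 0.01)
        e, d = est.mr_egger(h)
        assert e.beta == pytest.approx(0.4, abs=1e-10)
        assert d.egger_intercept == pytest.approx(0.0, abs=1e-10)

    def test_constrained_intercept_reproduces_fixed_effect_ivw(self):
        rng = np.random.default_rng(5)
        h = make_harmonised(rng.uniform(0.05, 0.3, 6),
                            rng.normal(0.05, 0.03, 6),
                            rng.uniform(0.005, 0.05, 6))
        e0, _ = est.mr_egger(h, fit_intercept=False)
        fe, _ = est.ivw(h, random_effects=False)
        assert e0.beta == pytest.approx(fe.beta, abs=1e-12)

    def test_orientation_invariance(self):
        # flipping the sign of (bx, by) jointly must not change the fit
        h1 = make_harmonised([0.1, -0.2, 0.3], [0.07, -0.12, 0.17], 0.01)
        h2 = make_harmonised([0.1, 0.2, 0.3], [0.07, 0.12, 0.17], 0.01)
        e1, d1 = est.mr_egger(h1)
        e2, d2 = est.mr_egger(h2)
        assert e1.beta == pytest.approx(e2.beta, abs=1e-12)
        assert d1.egger_intercept == pytest.approx(d2.egger_intercept, abs=1e-12)

    def test_too_few_instruments(self):
        h = make_harmonised([0.1, 0.2], [0.05, 0.1], 0.01)
        with pytest.raises(InsufficientInstrumentsError):
            est.mr_egger(h)

    def test_directional_pleiotropy_intercept_recovery(self):
        # ratio-level simulation oracle: 30% of instruments carry a positive
        # direct outcome effect; intercept estimates its average, and the
        # intercept test rejects more often than the nominal 5%
        rng = np.random.default_rng(42)
        L, theta, pleio = 30, 0.3, 0.08
        n_pleio = 9
        rejections, intercepts = [], []
        for _ in range(150):
            bx = rng.uniform(0.05, 0.3, L)
            direct = np.zeros(L)
            direct[:n_pleio] = pleio
            sy = np.full(L, 0.01)
            by = theta * bx + direct + rng.normal(0, sy)
            h = make_harmonised(bx, by, sy)
            _, d = est.mr_egger(h)
            intercepts.append(d.egger_intercept)
            rejections.append(d.egger_intercept_pvalue < 0.05)
        mean_pleio = n_pleio * pleio / L
        assert np.mean(intercepts) == pytest.approx(mean_pleio, abs=0.01)
        assert np.mean(rejections) > 0.10  # clearly above the nominal 5%


class TestWeightedMedian:
    def test_middle_ratio_with_equal_weights(self):
        h = make_harmonised([0.1, 0.1, 0.1], [0.04, 0.05, 0.06], 0.01)
        e = est.weighted_median(h, n_boot=200, seed=1)
        assert e.beta == pytest.approx(0.5, abs=1e-12)

    def test_degenerate_identical_ratios(self):
        bx = np.array([0.1, 0.2, 0.3])
        h = make_harmonised(bx, 0.3 * bx, 0.005)
        e = est.weighted_median(h, n_boot=300, seed=2)
        assert e.beta == pytest.approx(0.3, abs=1e-12)
        assert e.se < 0.1

    def test_breakdown_resists_40pct_contamination(self):
        # 10 instruments, 4 contaminated by +1.0: the weighted median stays
        # within Monte-Carlo error of the clean value (simulation oracle)
        rng = np.random.default_rng(7)
        theta = 0.5
        clean_est, contam_est = [], []
        for i in range(60):
            bx = np.full(10, 0.2)  # equal weights: valid majority by weight
            sy = np.full(10, 0.005)
            by = theta * bx + rng.normal(0, sy)
            h = make_harmonised(bx, by, sy)
            clean_est.append(est.weighted_median(h, 100, seed=i).beta)
            by_c = by.copy()
            by_c[:4] += 1.0 * bx[:4]  # ratios shifted by +1.0
            h_c = make_harmonised(bx, by_c, sy)
            contam_est.append(est.weighted_median(h_c, 100, seed=i).beta)
        mc_se = np.std(clean_est) / np.sqrt(len(clean_est))
        assert abs(np.mean(contam_est) - np.mean(clean_est)) < max(6 * mc_se, 0.03)

    def test_seed_required_and_reproducible(self, toy_harmonised):
        with pytest.raises(ValueError):
            est.weighted_median(toy_harmonised, n_boot=50)
        e1 = est.weighted_median(toy_harmonised, n_boot=50, seed=3)
        e2 = est.weighted_median(toy_harmonised, n_boot=50, seed=3)
        assert e1.se == e2.se


class TestInstrumentStrength:
    def test_f_and_r2(self):
        h = make_harmonised([0.10, 0.10], [0.0, 0.0], 0.01,
                            se_x=[0.02, 0.01], eaf=[0.5, 0.5])
        s = est.instrument_strength(h)
        assert s.F[0] == pytest.approx(25.0)
        assert s.mean_F == pytest.approx((25 + 100) / 2)
        # R2_j = 2*0.5*0.5*0.01 = 0.005 each
        assert s.total_R2 == pytest.approx(0.01, abs=1e-12)

    def test_missing_eaf_gives_missing_r2(self):
        h = make_harmonised([0.1], [0.0], 0.01, se_x=[0.02])
        s = est.instrument_strength(h)
        assert s.total_R2 is None
        assert np.isfinite(s.mean_F)


class TestEstimateDifference:
    def test_equal_betas_zero_z(self, toy_harmonised):
        e, _ = est.ivw(toy_harmonised)
        d = est.estimate_difference(e, e)
        assert d.z == pytest.approx(0.0)

    def test_z_closed_form(self):
        a = est.MREstimate("ivw_mre", 0.3, 0.1, 0, 0, 1, 5, "binary~quantitative")
        b = est.MREstimate("ivw_mre", 0.0, 0.1, 0, 0, 1, 5, "binary~quantitative")
        d = est.estimate_difference(a, b)
        assert d.z == pytest.approx(0.3 / np.sqrt(0.02), abs=1e-6)
        assert d.z == pytest.approx(2.121, abs=1e-3)

    def test_scale_mismatch_errors(self):
        a = est.MREstimate("ivw_mre", 0.3, 0.1, 0, 0, 1, 5, "binary~quantitative")
        b = est.MREstimate("ivw_mre", 0.3, 0.1, 0, 0, 1, 5, "quantitative~binary")
        with pytest.raises(ValueError, match="scale"):
            est.estimate_difference(a, b)
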