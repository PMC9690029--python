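"""The five causal estimators against closed forms, oracles and simulations."""

import numpy as np
import pytest
from scipy import stats

from bimr.estimators import (
    EstimationError,
    contamination_mixture,
    egger,
    ivw,
    weighted_median,
)
from bimr.simulate import SyntheticTruth, simulate_summary_arrays
from conftest import instruments_from_arrays, make_instruments, random_instrument_set


class TestIVW:
    def test_single_instrument_degenerates_to_wald(self):
        inst = make_instruments([0.1], [0.01], [0.05], [0.01])
        with pytest.warns(UserWarning, match="Wald"):
            est = ivw(inst)
        assert est.theta == pytest.approx(0.5)
        assert est.method == "wald"

    def test_two_instrument_closed_form(self):
        # weights (0.1/0.01)^2 = (0.2/0.02)^2 = 100; ratios 0.5 and 0.4
        inst = make_instruments([0.1, 0.2], [0.01, 0.01], [0.05, 0.08], [0.01, 0.02])
        est = ivw(inst, model="fixed")
        assert est.theta == pytest.approx(0.45)
        assert est.se == pytest.approx(1 / np.sqrt(200))

    def test_homogeneous_ratios_collapse(self):
        inst = make_instruments([0.1, 0.2, 0.3], 0.01, [0.05, 0.10, 0.15], 0.01)
        fixed = ivw(inst, model="fixed")
        random = ivw(inst, model="random")
        assert fixed.theta == pytest.approx(0.5)
        assert random.se == pytest.approx(fixed.se)  # Q = 0 => no inflation

    def test_matches_wls_through_origin_oracle(self, rng):
        """IVW equals weighted least squares of outcome on exposure betas
        through the origin, solved by the normal equations."""
        for _ in range(25):
            inst = random_instrument_set(rng)
            bx = np.array([i.beta_exposure for i in inst])
            by = np.array([i.beta_outcome for i in inst])
            w = 1 / np.array([i.se_outcome for i in inst]) ** 2
            theta_wls = np.sum(w * bx * by) / np.sum(w * bx * bx)
            assert ivw(inst, model="fixed").theta == pytest.approx(theta_wls, abs=1e-12)

    def test_random_se_never_below_fixed(self, rng):
        for _ in range(20):
            inst = random_instrument_set(rng)
            assert ivw(inst, "random").se >= ivw(inst, "fixed").se - 1e-15

    def test_exposure_recoding_equivariance(self, rng):
        inst = random_instrument_set(rng, j=10)
        flipped = make_instruments(
            [-i.beta_exposure for i in inst], [i.se_exposure for i in inst],
            [-i.beta_outcome for i in inst], [i.se_outcome for i in inst],
        )
        assert ivw(inst).theta == pytest.approx(ivw(flipped).theta, abs=1e-14)

    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError):
            ivw(make_instruments([0.1], [0.01], [0.05], [0.01]), model="bogus")


class TestEgger:
    def test_noiseless_proportional_effects(self):
        bx = np.array([0.05, 0.1, 0.15, 0.2, -0.12])
        theta = 0.3
        inst = make_instruments(bx, 0.01, theta * bx, 0.01)
        res = egger(inst)
        assert res.slope.theta == pytest.approx(theta, abs=1e-12)
        assert res.intercept == pytest.approx(0.0, abs=1e-12)
        assert res.residual_q == pytest.approx(0.0, abs=1e-18)

    def test_two_instruments_rejected(self):
        with pytest.raises(EstimationError, match="3"):
            egger(make_instruments([0.1, 0.2], 0.01, [0.05, 0.1], 0.01))

    def test_noiseless_constant_pleiotropy_recovered_exactly(self):
        # Gamma_j = alpha + theta*gamma_j with gamma_j > 0: intercept = alpha
        bx = np.array([0.05, 0.1, 0.15, 0.2, 0.25])
        alpha, theta = 0.02, 0.3
        inst = make_instruments(bx, 0.01, alpha + theta * bx, 0.01)
        res = egger(inst)
        assert res.slope.theta == pytest.approx(theta, abs=1e-12)
        assert res.intercept == pytest.approx(alpha, abs=1e-12)

    def test_exposure_recoding_equivariance(self, rng):
        inst = random_instrument_set(rng, j=8)
        flipped = make_instruments(
            [-i.beta_exposure for i in inst], [i.se_exposure for i in inst],
            [-i.beta_outcome for i in inst], [i.se_outcome for i in inst],
        )
        a, b = egger(inst), egger(flipped)
        assert a.slope.theta == pytest.approx(b.slope.theta, abs=1e-12)
        assert a.intercept == pytest.approx(b.intercept, abs=1e-12)

    def test_directional_pleiotropy_intercept_recovery(self):
        """Mean Egger intercept over replicates sits within 3 MC SEs of the
        generating pleiotropy mean; a reduced-replicate version of the
        known-truth simulation (the full run lives in the acceptance suite)."""
        alpha_mean, n_rep = 0.02, 200
        truth = SyntheticTruth(
            theta=0.27, n_snps=20, pleiotropy_mode="directional",
            alpha_mean=alpha_mean, alpha_sd=0.005, invalid_fraction=1.0,
        )
        rng = np.random.default_rng(77)
        intercepts = []
        for _ in range(n_rep):
            arr = simulate_summary_arrays(truth, rng)
            intercepts.append(egger(instruments_from_arrays(arr)).intercept)
        mean, mc_se = np.mean(intercepts), np.std(intercepts, ddof=1) / np.sqrt(n_rep)
        assert abs(mean - alpha_mean) < 3 * mc_se


class TestWeightedMedian:
    def test_equal_weights_gives_middle_ratio(self):
        inst = make_instruments([0.1, 0.1, 0.1], 0.01, [0.01, 0.04, 0.09], 0.01)
        est = weighted_median(inst, n_boot=200, seed=1)
        assert est.theta == pytest.approx(0.4)

    def test_degenerate_identical_ratios(self):
        inst = make_instruments([0.1, 0.2, 0.4], 0.01, [0.05, 0.10, 0.20], 0.01)
        est = weighted_median(inst, n_boot=500, seed=2)
        assert est.theta == pytest.approx(0.5)
        # bootstrap SE approaches the sampling SE of the ratio components
        assert 0 < est.se < 0.2

    def test_matches_cumulative_weight_scan_oracle(self, rng):
        """Brute-force evaluation of the interpolation definition."""
        for _ in range(25):
            inst = random_instrument_set(rng)
            ratio = np.array([i.wald_ratio for i in inst])
            w = 1 / np.array([i.wald_se for i in inst]) ** 2
            order = np.argsort(ratio)
            r, wn = ratio[order], w[order] / w.sum()
            s = np.cumsum(wn) - wn / 2
            if 0.5 <= s[0]:
                expected = r[0]
            elif 0.5 >= s[-1]:
                expected = r[-1]
            else:
                expected = float(np.interp(0.5, s, r))
            est = weighted_median(inst, n_boot=100, seed=0)
            assert est.theta == pytest.approx(expected, abs=1e-12)

    def test_estimate_within_ratio_range(self, rng):
        for _ in range(10):
            inst = random_instrument_set(rng)
            ratios = [i.wald_ratio for i in inst]
            est = weighted_median(inst, n_boot=100, seed=3)
            assert min(ratios) - 1e-12 <= est.theta <= max(ratios) + 1e-12

    def test_seed_reproducibility(self, rng):
        inst = random_instrument_set(rng)
        a = weighted_median(inst, n_boot=300, seed=9)
        b = weighted_median(inst, n_boot=300, seed=9)
        assert (a.theta, a.se) == (b.theta, b.se)

    def test_minimum_instruments_and_boot(self):
        inst = make_instruments([0.1, 0.2], 0.01, [0.05, 0.1], 0.01)
        with pytest.raises(EstimationError):
            weighted_median(inst, n_boot=200, seed=1)
        inst3 = make_instruments([0.1, 0.2, 0.3], 0.01, [0.05, 0.1, 0.15], 0.01)
        with pytest.raises(EstimationError):
            weighted_median(inst3, n_boot=50, seed=1)


class TestContaminationMixture:
    def test_uncontaminated_limit(self):
        c = 0.3
        bx = np.array([0.1, 0.15, 0.2, 0.25])
        inst = make_instruments(bx, 0.01, c * bx, 0.001)
        res = contamination_mixture(inst, psi=0.5)
        assert res.theta_hat == pytest.approx(c, abs=0.01)
        assert all(res.valid_flags)
        assert any(lo <= res.theta_hat <= hi for lo, hi in res.ci_set)

    def test_symmetric_contamination_two_modes(self):
        c = 0.5
        bx = np.full(8, 0.2)
        by = np.array([c, c, c, c, -c, -c, -c, -c]) * 0.2
        inst = make_instruments(bx, 0.01, by, 0.004)
        grid = np.linspace(-1.5, 1.5, 3001)
        res = contamination_mixture(inst, psi=0.05, grid=grid)
        assert abs(abs(res.theta_hat) - c) < 0.05  # lands on one of the modes
        assert len(res.ci_set) >= 2  # disconnected confidence set

    def test_contaminated_recovery(self):
        """20 valid + 10 invalid instruments: the estimate stays near the truth."""
        theta, n_rep = 0.27, 100
        truth = SyntheticTruth(
            theta=theta, n_snps=30, pleiotropy_mode="directional",
            alpha_mean=0.05, alpha_sd=0.01, invalid_fraction=1 / 3,
        )
        rng = np.random.default_rng(13)
        ests = []
        for _ in range(n_rep):
            arr = simulate_summary_arrays(truth, rng)
            ests.append(contamination_mixture(instruments_from_arrays(arr)).theta_hat)
        mean, mc_se = np.mean(ests), np.std(ests, ddof=1) / np.sqrt(n_rep)
        assert abs(mean - theta) < max(3 * mc_se, 0.01)

    def test_narrow_grid_warns(self):
        inst = make_instruments([0.1, 0.2, 0.3], 0.01, [0.05, 0.1, 0.15], 0.01)
        with pytest.warns(UserWarning, match="grid"):
            contamination_mixture(inst, psi=0.1, grid=np.linspace(5, 6, 50))

    def test_auto_psi_is_ratio_sd_scaled(self, rng):
        inst = random_instrument_set(rng, j=10)
        ratios = np.array([i.wald_ratio for i in inst])
        res = contamination_mixture(inst, psi="auto")
        assert res.psi == pytest.approx(1.5 * np.std(ratios, ddof=1))


class TestCalibration:
    def test_type_i_error_all_estimators_reasonable(self):
        """Null effect, valid instruments: rejection near the nominal level.

        Reduced-replicate sanity check; the 1,000-replicate IVW version runs
        in the acceptance suite.
        """
        truth = SyntheticTruth(theta=0.0, n_snps=31)
        rng = np.random.default_rng(5)
        n_rep = 300
        rejections = 0
        for _ in range(n_rep):
            arr = simulate_summary_arrays(truth, rng)
            est = ivw(instruments_from_arrays(arr), model="random")
            rejections += est.pvalue < 0.05
        rate = rejections / n_rep
        assert 0.02 <= rate <= 0.09

    def test_or_scale_is_exp_of_log_scale(self, rng):
        inst = random_instrument_set(rng)
        for est in (ivw(inst), ivw(inst, "fixed"), weighted_median(inst, 100, 0),
                    egger(inst).slope):
            or_, lo, hi = est.or_scale
            assert or_ == pytest.approx(np.exp(est.theta))
            assert lo == pytest.approx(np.exp(est.ci_low))
            assert hi == pytest.approx(np.exp(est.ci_high))
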