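"""GWLR: kernel identities, local IRLS vs independent MLE, AICc, bandwidth."""

import numpy as np
import pandas as pd
import pytest
from helpers import logistic_mle
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import spearmanr

from geoscreen import (
    CoefficientSurface,
    KernelSpec,
    SyntheticCohortSpec,
    bisquare_weight,
    fit_gwlr,
    gwlr_aicc,
    local_inference,
    local_logistic_fit,
    select_bandwidth,
    simulate_cohort,
    true_surface_at,
    weight_vector,
)
from geoscreen.gwlr import GWLRResult, LocalFit
from geoscreen.synthetic import CovariateSpec


class TestBisquareKernel:
    @pytest.mark.parametrize("d, b, expected", [
        (0.0, 2.0, 1.0),
        (2.0, 2.0, 0.0),
        (1.0, 2.0, 0.5625),   # (1 - 0.25)^2
        (5.0, 2.0, 0.0),
    ])
    def test_exact_values(self, d, b, expected):
        assert bisquare_weight(d, b) == pytest.approx(expected)

    def test_invalid_bandwidth_rejected(self):
        with pytest.raises(ValueError):
            bisquare_weight(1.0, 0.0)
        with pytest.raises(ValueError):
            bisquare_weight(-1.0, 2.0)

    @given(st.floats(0.1, 1e4))
    @settings(max_examples=50, deadline=None)
    def test_shape_properties_on_dense_grid(self, b):
        """Continuous, 1 at d=0, non-increasing on [0,b], compact support."""
        d = np.linspace(0.0, 2.0 * b, 801)
        w = bisquare_weight(d, b)
        assert w[0] == 1.0
        assert np.all(np.diff(w[d <= b]) <= 1e-12)
        assert np.all(w[d >= b] == 0.0)
        assert np.all((0.0 <= w) & (w <= 1.0))


class TestWeightVector:
    def test_collinear_hand_values(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]])
        w = weight_vector(pts, 0, KernelSpec(bandwidth=2.0))
        np.testing.assert_allclose(w, [1.0, 0.5625, 0.0])

    def test_huge_bandwidth_gives_near_unit_weights(self):
        rng = np.random.default_rng(0)
        pts = rng.uniform(0, 10, size=(30, 2))
        dmax = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1)).max()
        w = weight_vector(pts, 3, KernelSpec(bandwidth=1000.0 * dmax))
        assert np.all(w > 0.999996)  # (1 - 1e-6)^4 bound

    def test_duplicate_coordinates_weighted_equally(self):
        pts = np.array([[1.0, 1.0], [1.0, 1.0], [1.0, 1.0], [5.0, 5.0]])
        w = weight_vector(pts, 0, KernelSpec(bandwidth=10.0))
        assert w[0] == w[1] == w[2] == 1.0

    def test_adaptive_bandwidth_is_kth_neighbour_distance(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0], [4.0, 0.0]])
        w = weight_vector(pts, 0, KernelSpec(bandwidth=2, mode="adaptive"))
        # 2nd NN of point 0 is at distance 2 -> it sits exactly on the support edge
        np.testing.assert_allclose(w, [1.0, 0.5625, 0.0, 0.0])


class TestLocalLogisticFit:
    def test_uniform_weights_match_independent_mle(self, flat_cohort_500):
        _, coh = flat_cohort_500
        coh = coh.head(200)
        X = np.column_stack([np.ones(len(coh)), coh["x1"], coh["x2"]])
        y = coh["y"].to_numpy(float)
        fit = local_logistic_fit(X, y, np.ones(len(coh)))
        oracle = logistic_mle(X, y)
        assert fit.converged
        np.testing.assert_allclose(fit.beta, oracle, atol=1e-6)

    def test_statsmodels_cross_check(self, flat_cohort_500):
        sm = pytest.importorskip("statsmodels.api")
        _, coh = flat_cohort_500
        X = np.column_stack([np.ones(len(coh)), coh["x1"], coh["x2"]])
        y = coh["y"].to_numpy(float)
        fit = local_logistic_fit(X, y, np.ones(len(coh)))
        ref = sm.Logit(y, X).fit(disp=0)
        np.testing.assert_allclose(fit.beta, ref.params, atol=1e-6)
        np.testing.assert_allclose(fit.se, ref.bse, rtol=1e-4)

    def test_single_class_outcome_non_estimable(self):
        X = np.column_stack([np.ones(10), np.arange(10.0)])
        fit = local_logistic_fit(X, np.ones(10), np.ones(10))
        assert not fit.converged and fit.beta is None
        assert "single-class" in fit.message

    def test_zero_weight_rows_equivalent_to_deletion(self):
        rng = np.random.default_rng(1)
        X = np.column_stack([np.ones(80), rng.normal(size=80)])
        y = (rng.uniform(size=80) < 0.4).astype(float)
        w = np.concatenate([np.ones(50), np.zeros(30)])
        full = local_logistic_fit(X, y, w)
        sub = local_logistic_fit(X[:50], y[:50], np.ones(50))
        np.testing.assert_allclose(full.beta, sub.beta, atol=1e-10)

    def test_rank_deficiency_non_estimable(self):
        X = np.column_stack([np.ones(20), np.ones(20)])  # duplicated intercept
        y = np.tile([0.0, 1.0], 10)
        fit = local_logistic_fit(X, y, np.ones(20))
        assert not fit.converged and "rank" in fit.message


class TestLocalInference:
    def _fit(self, beta, se):
        f = LocalFit(location=(0, 0), names=["intercept", "x1"])
        f.beta = np.array([0.0, beta])
        f.cov = np.diag([1.0, se ** 2])
        f.converged = True
        return f

    def test_null_coefficient_p_is_one(self):
        f = local_inference(self._fit(0.0, 1.0))
        assert f.p_values[1] == pytest.approx(1.0)
        assert not f.significant[1]

    def test_wald_boundary_not_significant_under_strict_less(self):
        se = 0.5
        f = local_inference(self._fit(1.959963984540054 * se, se))
        assert f.p_values[1] == pytest.approx(0.05, abs=1e-9)
        assert not f.significant[1]  # p == alpha is not p < alpha

    def test_vacuous_alpha_flags_everything(self):
        # any p strictly below 1 (i.e. any nonzero estimate) passes alpha=1
        f = self._fit(0.01, 1.0)
        f.beta[0] = 1e-6
        assert local_inference(f, alpha=1.0).significant.all()

    def test_non_converged_flags_forced_false(self):
        f = LocalFit(location=(0, 0), names=["intercept"])
        f = local_inference(f)
        assert not f.significant.any()


class TestFitGwlr:
    def test_flat_kernel_limit_matches_global_mle(self, flat_cohort_500):
        _, coh = flat_cohort_500
        pts = coh[["x_coord", "y_coord"]].to_numpy()
        dmax = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1)).max()
        res = fit_gwlr(coh, ["x1", "x2"], KernelSpec(bandwidth=1e6 * dmax))
        oracle = np.exp(logistic_mle(
            np.column_stack([np.ones(len(coh)), coh["x1"], coh["x2"]]),
            coh["y"].to_numpy(float)))
        assert len(res.fits) == len(coh)
        for f in res.fits:
            np.testing.assert_allclose(f.odds_ratios, oracle, atol=1e-3)

    def test_flat_kernel_effective_params_equals_parameter_count(self, flat_cohort_500):
        _, coh = flat_cohort_500
        pts = coh[["x_coord", "y_coord"]].to_numpy()
        dmax = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1)).max()
        res = fit_gwlr(coh, ["x1", "x2"], KernelSpec(bandwidth=1e6 * dmax))
        assert res.effective_params == pytest.approx(3.0, abs=0.05)

    def test_two_cluster_parameter_recovery(self, two_cluster_cohort):
        """Step-surface truth (OR 2 vs 4) recovered by cluster-wise medians and
        by rank correlation between true and estimated coefficient surfaces."""
        spec, coh = two_cluster_cohort
        res = fit_gwlr(coh, ["x1"], KernelSpec(bandwidth=80.0))
        fr = res.to_frame()
        med_a = fr.loc[coh["centre_id"].to_numpy() == 0, "or_x1"].median()
        med_b = fr.loc[coh["centre_id"].to_numpy() == 1, "or_x1"].median()
        assert 1.5 < med_a < 2.7
        assert 3.0 < med_b < 5.3
        truth = true_surface_at(spec.surfaces[1], coh[["x_coord", "y_coord"]].to_numpy())
        rho = spearmanr(truth, fr["beta_x1"]).statistic
        assert rho > 0.5

    def test_translation_and_scale_invariance(self, small_spatial_cohort):
        _, coh = small_spatial_cohort
        coh = coh.head(120)
        res = fit_gwlr(coh, ["x1"], KernelSpec(bandwidth=300.0))
        shifted = coh.copy()
        shifted["x_coord"] += 1e4
        shifted["y_coord"] -= 500.0
        res_shift = fit_gwlr(shifted, ["x1"], KernelSpec(bandwidth=300.0))
        scaled = coh.copy()
        scaled[["x_coord", "y_coord"]] *= 3.0
        res_scale = fit_gwlr(scaled, ["x1"], KernelSpec(bandwidth=900.0))
        for a, b, c in zip(res.fits, res_shift.fits, res_scale.fits):
            np.testing.assert_allclose(a.beta, b.beta, atol=1e-8)
            np.testing.assert_allclose(a.beta, c.beta, atol=1e-8)

    def test_geographic_coordinate_names_rejected(self, small_spatial_cohort):
        _, coh = small_spatial_cohort
        coh = coh.rename(columns={"x_coord": "lon", "y_coord": "lat"})
        with pytest.raises(ValueError, match="planar"):
            fit_gwlr(coh, ["x1"], KernelSpec(bandwidth=100.0),
                     x_col="lon", y_col="lat")

    def test_adaptive_neighbour_count_floor_enforced(self, small_spatial_cohort):
        _, coh = small_spatial_cohort
        with pytest.raises(ValueError, match="parameters"):
            fit_gwlr(coh, ["x1"], KernelSpec(bandwidth=2, mode="adaptive"))

    def test_result_frame_one_row_per_observation(self, small_spatial_cohort):
        _, coh = small_spatial_cohort
        coh = coh.head(80)
        res = fit_gwlr(coh, ["x1"], KernelSpec(bandwidth=500.0))
        fr = res.to_frame()
        assert len(fr) == 80
        assert {"or_x1", "p_x1", "significant_x1", "converged"} <= set(fr.columns)
        sig = fr["p_x1"] < 0.05
        assert (fr.loc[fr["converged"], "significant_x1"]
                == sig[fr["converged"]]).all()


class TestAicc:
    def test_hand_evaluated_formula(self):
        res = GWLRResult(fits=[], kernel=KernelSpec(bandwidth=1.0), names=[],
                         effective_params=3.0, global_deviance=100.0, n_fitted=100)
        assert gwlr_aicc(res) == pytest.approx(100 + 6 + 24 / 96)  # 106.25

    def test_penalty_blow_up_returns_infinity(self):
        res = GWLRResult(fits=[], kernel=KernelSpec(bandwidth=1.0), names=[],
                         effective_params=99.0, global_deviance=10.0, n_fitted=100)
        assert gwlr_aicc(res) == float("inf")

    def test_noise_covariate_never_helps_in_flat_limit(self):
        """Statistical tendency over 20 seeds (majority rule): adding a pure
        noise covariate does not decrease flat-kernel AICc."""
        wins = 0
        for seed in range(20):
            spec = SyntheticCohortSpec(
                n_participants=120,
                surfaces=[CoefficientSurface.constant("intercept", -0.5),
                          CoefficientSurface.constant("x1", 0.6)],
                covariate_specs=[CovariateSpec("x1", ("normal", 0.0, 1.0))],
                n_centres=2, seed=seed)
            coh = simulate_cohort(spec)
            rng = np.random.default_rng(1000 + seed)
            coh["noise"] = rng.normal(size=len(coh))
            big = KernelSpec(bandwidth=1e8)
            base = fit_gwlr(coh, ["x1"], big).aicc
            noisy = fit_gwlr(coh, ["x1", "noise"], big).aicc
            wins += noisy >= base
        assert wins > 10


class TestSelectBandwidth:
    def test_golden_section_beats_grid_oracle(self, small_spatial_cohort):
        _, coh = small_spatial_cohort
        best, trace = select_bandwidth(coh, ["x1"], mode="fixed")
        lo = min(b for b, _ in trace)
        hi = max(b for b, _ in trace)
        grid = np.linspace(lo, hi, 20)
        grid_best = min(fit_gwlr(coh, ["x1"], KernelSpec(bandwidth=b)).aicc for b in grid)
        sel = fit_gwlr(coh, ["x1"], best).aicc
        tol = 1e-2 * (hi - lo)  # golden-section bracket tolerance, AICc is smooth
        assert sel <= grid_best + max(1.0, tol)

    def test_flat_truth_favours_large_bandwidths(self):
        spec = SyntheticCohortSpec(
            n_participants=250,
            surfaces=[CoefficientSurface.constant("intercept", -1.0),
                      CoefficientSurface.constant("x1", 0.5)],
            covariate_specs=[CovariateSpec("x1", ("normal", 0.0, 1.0))],
            n_centres=4, centre_spread=60.0, seed=21)
        coh = simulate_cohort(spec)
        best, trace = select_bandwidth(coh, ["x1"], mode="fixed")
        lo = min(b for b, _ in trace)
        hi = max(b for b, _ in trace)
        assert best.bandwidth > lo + 2.0 / 3.0 * (hi - lo)

    def test_adaptive_mode_returns_integer_neighbour_count(self, small_spatial_cohort):
        _, coh = small_spatial_cohort
        coh = coh.head(150)
        best, _ = select_bandwidth(coh, ["x1"], mode="adaptive")
        assert best.mode == "adaptive"
        assert best.bandwidth == int(best.bandwidth)
        assert 4 <= best.bandwidth <= len(coh) - 1
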