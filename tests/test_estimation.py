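"""FIML likelihood, optimization, sandwich errors and standardization."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lcmsr.estimation import (
    FitOptions,
    PanelData,
    _loglik_and_grad,
    _per_person_scores,
    baseline_fit,
    fiml_loglik,
    fit,
    fit_multigroup,
    sandwich_se,
    saturated_fit,
    standardize,
    start_values,
)
from lcmsr.estimator import LCMSR
from lcmsr.model_spec import (
    ModelSpec,
    PathSpec,
    build_univariate,
    canonical_bivariate,
    compile_spec,
    split_groups,
)
from lcmsr.synthetic import GeneratorConfig, default_parameters, simulate_panel

from conftest import simulate_small


def two_wave_ar_ram():
    """Two-wave level-1 model: y2's residual regressed on y1's."""
    spec = build_univariate("Y", 1, 2, bursts=[[1, 2]])
    return compile_spec(spec)


class TestImpliedMoments:
    def test_two_wave_autoregression_closed_form(self):
        ram = two_wave_ar_ram()
        vals = {"resvar_Y_1": 2.0, "resvar_Y_2": 1.5, "ar_Y_1": 0.6,
                "omean_Y_1": 1.0, "omean_Y_2": -0.5}
        theta = np.array([vals[l] for l in ram.labels])
        mu, sigma = ram.implied_moments(theta)
        np.testing.assert_allclose(mu, [1.0, -0.5])
        np.testing.assert_allclose(sigma[0, 0], 2.0)
        np.testing.assert_allclose(sigma[0, 1], 0.6 * 2.0)
        np.testing.assert_allclose(sigma[1, 1], 0.6**2 * 2.0 + 1.5)

    def test_implied_cov_symmetric_pd_at_truth(self, canonical_ram, theta_true):
        mu, sigma = canonical_ram.implied_moments(theta_true)
        np.testing.assert_allclose(sigma, sigma.T)
        assert np.linalg.eigvalsh(sigma).min() > 0


class TestFIMLLoglik:
    def test_complete_data_equals_mvn_logpdf(self, canonical_ram, theta_true, complete_panel):
        data = PanelData(complete_panel)
        mu, sigma = canonical_ram.implied_moments(theta_true)
        direct = stats.multivariate_normal.logpdf(data.values, mu, sigma).sum()
        ll = fiml_loglik(canonical_ram, theta_true, data)
        assert ll == pytest.approx(direct, rel=1e-10)

    def test_single_observation_univariate_density(self):
        spec = ModelSpec(
            ["y1"],
            [],
            [PathSpec("y1", "y1", "variance", label="v"),
             PathSpec("y1", "y1", "mean", label="m")],
        )
        ram = compile_spec(spec)
        y, m, v = 1.3, 0.4, 2.2
        ll = fiml_loglik(ram, np.array([v, m]), np.array([[y]]))
        assert ll == pytest.approx(-0.5 * (np.log(2 * np.pi * v) + (y - m) ** 2 / v))

    def test_pattern_grouped_equals_per_person(self, canonical_ram, theta_true, missing_panel):
        data = PanelData(missing_panel)
        grouped = fiml_loglik(canonical_ram, theta_true, data)
        naive = fiml_loglik(canonical_ram, theta_true, data, grouped=False)
        assert grouped == pytest.approx(naive, rel=1e-13)

    def test_nonpd_point_rejected_not_raised(self):
        ram = two_wave_ar_ram()
        vals = {"resvar_Y_1": 1.0, "resvar_Y_2": -0.5, "ar_Y_1": 0.0,
                "omean_Y_1": 0.0, "omean_Y_2": 0.0}
        theta = np.array([vals[l] for l in ram.labels])
        assert fiml_loglik(ram, theta, np.array([[0.1, 0.2]])) == -np.inf


class TestGradient:
    def test_analytic_gradient_matches_finite_differences(self, missing_panel):
        spec = canonical_bivariate(n_waves=6, bursts=[[1, 2, 3], [4, 5, 6]])
        ram = compile_spec(spec)
        panel = simulate_small(99, n_persons=80, retention=np.array([1, 1, 0.9, 0.85, 0.8, 0.7]))
        data = PanelData(panel).select(spec.observed_vars)
        rng = np.random.default_rng(5)
        theta = start_values(ram, data)
        theta += rng.normal(0, 0.02, theta.shape)
        for j, lab in enumerate(ram.labels):
            if lab in ram.variance_labels:
                theta[j] = abs(theta[j]) + 0.05
        _, grad = _loglik_and_grad(ram, theta, data)
        for j in rng.choice(ram.n_free, 12, replace=False):
            h = 1e-6 * (1 + abs(theta[j]))
            tp, tm = theta.copy(), theta.copy()
            tp[j] += h
            tm[j] -= h
            fd = (fiml_loglik(ram, tp, data) - fiml_loglik(ram, tm, data)) / (2 * h)
            assert grad[j] == pytest.approx(fd, rel=1e-5, abs=1e-7)

    def test_per_person_scores_sum_to_gradient(self):
        spec = canonical_bivariate(n_waves=6, bursts=[[1, 2, 3], [4, 5, 6]])
        ram = compile_spec(spec)
        panel = simulate_small(7, n_persons=60, retention=np.array([1, 1, 0.9, 0.85, 0.8, 0.7]))
        data = PanelData(panel).select(spec.observed_vars)
        theta = start_values(ram, data)
        _, grad = _loglik_and_grad(ram, theta, data)
        scores = _per_person_scores(ram, theta, data)
        np.testing.assert_allclose(scores.sum(axis=0), grad, rtol=1e-8, atol=1e-8)


class TestFit:
    def test_saturated_loglik_matches_closed_form(self, complete_panel):
        data = PanelData(complete_panel)
        sat = saturated_fit(data)
        mu = data.values.mean(axis=0)
        D = data.values - mu
        S = D.T @ D / data.n_persons
        sign, logdet = np.linalg.slogdet(S)
        n, p = data.values.shape
        ll = -0.5 * n * (p * np.log(2 * np.pi) + logdet + p)
        assert sat.loglik == pytest.approx(ll, rel=1e-10)

    def test_em_saturated_agrees_with_fiml_optimum_property(self, missing_panel):
        # EM saturated log-likelihood must dominate any structured model
        data = PanelData(missing_panel)
        sat = saturated_fit(data)
        spec = canonical_bivariate()
        res = fit(spec, data, options=FitOptions(se="none", standardized=False))
        assert sat.loglik >= res.loglik

    def test_refit_from_solution_is_fixed_point(self):
        panel = simulate_small(11)
        spec = canonical_bivariate(n_waves=6, bursts=[[1, 2, 3], [4, 5, 6]])
        res = fit(spec, panel, options=FitOptions(se="none", standardized=False))
        res2 = fit(spec, panel, start=res.theta, options=FitOptions(se="none", standardized=False))
        # refitting may polish marginally further but never degrades
        assert res2.loglik >= res.loglik - 1e-6
        assert abs(res2.loglik - res.loglik) < 1e-3
        np.testing.assert_allclose(res2.theta, res.theta, atol=2e-2)

    def test_loglik_not_below_start(self):
        panel = simulate_small(13)
        spec = canonical_bivariate(n_waves=6, bursts=[[1, 2, 3], [4, 5, 6]])
        ram = compile_spec(spec)
        data = PanelData(panel).select(spec.observed_vars)
        ll0 = fiml_loglik(ram, start_values(ram, data), data)
        res = fit(ram, data, options=FitOptions(se="none", standardized=False))
        assert res.loglik >= ll0

    def test_empty_and_all_missing_inputs_rejected(self):
        spec = canonical_bivariate(n_waves=6, bursts=[[1, 2, 3], [4, 5, 6]])
        with pytest.raises(ValueError):
            fit(spec, pd.DataFrame(columns=spec.observed_vars))
        panel = simulate_small(3, n_persons=20)
        panel["FI2"] = np.nan
        with pytest.raises(ValueError, match="entirely missing"):
            fit(spec, panel)

    def test_slope_coding_affine_recode_is_likelihood_invariant(self):
        # recoding slope loadings c -> c - 3 shifts the intercept mean by
        # 3*slope mean but cannot change the achievable maximum likelihood
        panel = simulate_small(17, n_persons=120)
        ls_cols = [c for c in panel.columns if c.startswith("LS")]
        spec = build_univariate("LS", 3, 6, bursts=[[1, 2, 3], [4, 5, 6]])
        res = fit(spec, panel[ls_cols], options=FitOptions(se="none", standardized=False))
        shifted = spec.copy()
        shifted.paths = [
            PathSpec(p.src, p.dst, p.kind, value=p.value - 3.0)
            if (p.kind == "loading" and p.src.startswith("S_") and p.value is not None)
            else p
            for p in shifted.paths
        ]
        # with coding starting at -3 the zero-loading wave now loads -3
        extra = []
        for b, waves in enumerate(shifted.meta["bursts"], start=1):
            extra.append(PathSpec(f"S_LS{b}", f"LS{waves[0]}", "loading", value=-3.0))
        shifted.paths.extend(extra)
        res2 = fit(shifted, panel[ls_cols], options=FitOptions(se="none", standardized=False))
        assert res2.loglik == pytest.approx(res.loglik, abs=1e-4)


class TestSandwich:
    def test_ses_positive_and_finite(self, canonical_fit):
        assert canonical_fit.se is not None
        assert np.all(canonical_fit.se > 0)
        assert np.all(np.isfinite(canonical_fit.se))

    def test_single_person_rejected(self):
        spec = canonical_bivariate(n_waves=6, bursts=[[1, 2, 3], [4, 5, 6]])
        ram = compile_spec(spec)
        panel = simulate_small(23, n_persons=40)
        data = PanelData(panel).select(spec.observed_vars)
        theta = start_values(ram, data)
        one = PanelData(data.values[:1], columns=data.columns)
        with pytest.raises(np.linalg.LinAlgError):
            sandwich_se(ram, theta, one)

    def test_sandwich_close_to_inverse_information_when_correct(self):
        # correctly specified Gaussian model: sandwich and inverse-information
        # SEs estimate the same limit; individual ratios carry fourth-moment
        # sampling noise, so check the bulk tightly and the extremes loosely
        spec = canonical_bivariate(n_waves=6, bursts=[[1, 2, 3], [4, 5, 6]])
        panel = simulate_small(31, n_persons=5000)
        res_sw = fit(spec, panel, options=FitOptions(se="sandwich", standardized=False))
        res_h = fit(spec, panel, options=FitOptions(se="hessian", standardized=False))
        ratio = res_sw.se / res_h.se
        assert abs(np.median(ratio) - 1.0) < 0.05
        assert np.all(ratio > 0.7) and np.all(ratio < 1.3)


class TestStandardize:
    def test_covariances_become_correlations_in_unit_interval(self, canonical_fit):
        std = canonical_fit.standardized.set_index("label")
        for lab in std.index:
            if lab.startswith(("wcov", "icov")):
                assert -1.0 <= std.loc[lab, "std_estimate"] <= 1.0
                assert std.loc[lab, "is_standardized"]

    def test_means_flagged_unstandardized(self, canonical_fit):
        std = canonical_fit.standardized.set_index("label")
        for lab in std.index:
            if lab.startswith(("imean", "smean")):
                assert not std.loc[lab, "is_standardized"]
                assert std.loc[lab, "std_estimate"] == std.loc[lab, "estimate"]

    def test_correlation_definition(self, canonical_fit):
        est = canonical_fit.estimates
        std = canonical_fit.standardized.set_index("label")
        c = est["icov_FI1_FI2"]
        r = c / np.sqrt(est["ivar_FI_1"] * est["ivar_FI_2"])
        assert std.loc["icov_FI1_FI2", "std_estimate"] == pytest.approx(r)


class TestMultiGroup:
    def test_independent_groups_equal_separate_fits(self):
        spec = canonical_bivariate(n_waves=6, bursts=[[1, 2, 3], [4, 5, 6]])
        p1 = simulate_small(41, n_persons=120)[spec.observed_vars]
        p2 = simulate_small(42, n_persons=100)[spec.observed_vars]
        gs = split_groups(spec, ["a", "b"])
        opts = FitOptions(se="none", standardized=False)
        joint = fit_multigroup(gs, {"a": p1, "b": p2}, options=opts)
        f1 = fit(spec, p1, options=opts)
        f2 = fit(spec, p2, options=opts)
        assert joint.loglik == pytest.approx(f1.loglik + f2.loglik, abs=1e-3)
        assert joint.n_free == 2 * spec.n_free

    def test_equality_constraint_reduces_parameters_and_loglik(self):
        spec = canonical_bivariate(n_waves=6, bursts=[[1, 2, 3], [4, 5, 6]])
        p1 = simulate_small(43, n_persons=120)[spec.observed_vars]
        p2 = simulate_small(44, n_persons=100)[spec.observed_vars]
        opts = FitOptions(se="none", standardized=False)
        free = fit_multigroup(split_groups(spec, ["a", "b"]), {"a": p1, "b": p2}, options=opts)
        eq = fit_multigroup(
            split_groups(spec, ["a", "b"], equal=["ar", "cl"]),
            {"a": p1, "b": p2},
            options=opts,
        )
        assert eq.n_free < free.n_free
        assert eq.loglik <= free.loglik + 1e-6


class TestEstimatorFacade:
    def test_sklearn_contract(self, complete_panel):
        from sklearn.base import clone

        est = LCMSR(se="none", standardized=False, max_iter=2000)
        assert clone(est).get_params()["se"] == "none"
        spec = canonical_bivariate(n_waves=6, bursts=[[1, 2, 3], [4, 5, 6]])
        small = simulate_small(51, n_persons=100)
        model = LCMSR(spec=spec, se="none", standardized=False).fit(small)
        assert model.converged_
        assert model.df_ == 12 * 13 // 2 + 12 - spec.n_free
        assert set(model.params_) == set(spec.free_labels())
        # score returns the mean per-person log-likelihood
        assert model.score(small) == pytest.approx(model.loglik_ / len(small))
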