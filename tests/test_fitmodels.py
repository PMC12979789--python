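import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

import statsmodels.api as sm

from metascope.fitmodels import (
    SeparationError,
    SmoothModelSpec,
    SmoothTerm,
    build_spline_basis,
    compare_bic,
    concurvity,
    fit_binomial_smooth,
    predict_curve,
)


class TestSplineBasis:
    def test_partition_of_unity_cubic(self, rng):
        x = rng.uniform(0, 10, 200)
        b = build_spline_basis(x, k=7)
        B = b.transform(rng.uniform(0, 10, 500))
        assert np.allclose(B.sum(axis=1), 1.0, atol=1e-10)

    def test_partition_of_unity_cyclic(self, rng):
        x = rng.uniform(0, 365, 300)
        b = build_spline_basis(x, k=9, kind="cyclic", period=366.0)
        B = b.transform(rng.uniform(0, 1000, 300))  # wraps
        assert np.allclose(B.sum(axis=1), 1.0, atol=1e-10)

    def test_penalty_null_space_contains_linear(self, rng):
        x = rng.uniform(0, 10, 100)
        b = build_spline_basis(x, k=7)
        # coefficients interpolating a linear function represent that line
        beta = 2.0 + 0.5 * b.knots
        assert beta @ b.penalty @ beta == pytest.approx(0.0, abs=1e-8)

    def test_penalty_positive_for_curvature(self, rng):
        x = rng.uniform(0, 10, 100)
        b = build_spline_basis(x, k=7)
        beta = b.knots**2
        assert beta @ b.penalty @ beta > 1.0

    def test_exact_representation_in_span(self, rng):
        # unpenalized LS on data from a function in the basis span is exact
        x = rng.uniform(0, 10, 400)
        b = build_spline_basis(x, k=5)
        beta_true = np.array([0.3, -1.0, 2.0, 0.5, 1.5])
        y = b.transform(x) @ beta_true
        B = b.transform(x)
        beta_hat, *_ = np.linalg.lstsq(B, y, rcond=None)
        assert np.allclose(B @ beta_hat, y, atol=1e-9)

    def test_linear_data_reproduced(self, rng):
        x = rng.uniform(0, 10, 100)
        b = build_spline_basis(x, k=4)
        y = 1.0 + 3.0 * x
        B = b.transform(x)
        beta, *_ = np.linalg.lstsq(B, y, rcond=None)
        assert np.allclose(B @ beta, y, atol=1e-9)

    def test_too_few_unique_x(self):
        with pytest.raises(ValueError, match="unique x"):
            build_spline_basis(np.array([1.0, 2.0, 3.0]), k=7)

    def test_k_minimum(self):
        with pytest.raises(ValueError):
            build_spline_basis(np.arange(10.0), k=2)


def _logistic_data(n=2000, beta=1.2, seed=0, intercept=-0.5):
    rng = np.random.default_rng(seed)
    x = rng.uniform(-2, 2, n)
    eta = intercept + beta * x
    y = (rng.random(n) < expit(eta)).astype(int)
    return pd.DataFrame({"x": x, "y": y})


class TestFitBinomialSmooth:
    spec = SmoothModelSpec(outcome="y", smooth_terms=[SmoothTerm("x", k=7)])

    def test_agrees_with_glm_on_linear_truth(self):
        agree = []
        for seed in range(5):
            df = _logistic_data(seed=seed)
            m = fit_binomial_smooth(df, self.spec)
            curve = predict_curve(m, "x", grid_size=50)
            X = sm.add_constant(df["x"])
            glm = sm.GLM(df["y"], X, family=sm.families.Binomial()).fit()
            pred = glm.get_prediction(sm.add_constant(pd.Series(curve.grid, name="x")))
            ci = pred.conf_int()
            inside = (curve.probability >= ci[:, 0] - 0.03) & (
                curve.probability <= ci[:, 1] + 0.03
            )
            agree.append(inside.mean())
        assert np.mean(agree) >= 0.9

    def test_single_class_separation_error(self):
        df = pd.DataFrame({"x": np.linspace(0, 1, 50), "y": 0})
        with pytest.raises(SeparationError):
            fit_binomial_smooth(df, self.spec)

    def test_degenerate_random_intercept_harmless(self):
        df = _logistic_data(seed=3)
        df["grp"] = "only_one_level"
        base = fit_binomial_smooth(df, self.spec, lam={"s(x)": 1.0})
        spec_ri = SmoothModelSpec(
            outcome="y",
            smooth_terms=[SmoothTerm("x", k=7)],
            random_intercepts=["grp"],
        )
        with_ri = fit_binomial_smooth(df, spec_ri, lam={"s(x)": 1.0, "ri(grp)": 1.0})
        p = len(base.coef)
        assert np.allclose(with_ri.coef[:p], base.coef, atol=1e-6)

    def test_deviance_not_worse_than_null(self):
        df = _logistic_data(seed=5)
        m = fit_binomial_smooth(df, self.spec)
        assert m.deviance <= m.null_deviance + 1e-9
        assert 0.0 <= m.r_squared <= 1.0

    def test_infinite_penalty_matches_parametric_glm(self):
        df = _logistic_data(seed=7)
        m = fit_binomial_smooth(df, self.spec, lam=1e9)
        curve = predict_curve(m, "x", grid_size=40)
        glm = sm.GLM(df["y"], sm.add_constant(df["x"]), family=sm.families.Binomial()).fit()
        eta_glm = glm.params[0] + glm.params[1] * curve.grid
        assert np.allclose(curve.log_odds, eta_glm, atol=1e-4)

    def test_edf_bounded_by_basis_size(self):
        df = _logistic_data(seed=9)
        m = fit_binomial_smooth(df, self.spec)
        assert m.edf["s(x)"] <= 7 - 1 + 1e-9
        assert np.isfinite(m.bic)

    def test_random_intercept_shrinkage(self):
        rng = np.random.default_rng(42)
        n_groups, per = 15, 300
        sigma_g = 0.8
        effects = rng.normal(0, sigma_g, n_groups)
        g = np.repeat(np.arange(n_groups), per)
        x = rng.uniform(-2, 2, n_groups * per)
        y = (rng.random(n_groups * per) < expit(0.2 + 0.8 * x + effects[g])).astype(int)
        df = pd.DataFrame({"x": x, "y": y, "grp": g.astype(str)})
        spec = SmoothModelSpec(
            outcome="y", smooth_terms=[SmoothTerm("x", k=7)], random_intercepts=["grp"]
        )
        m = fit_binomial_smooth(df, spec)
        sigma2_hat = 1.0 / m.lam["ri(grp)"]
        assert 0.5 * sigma_g**2 <= sigma2_hat <= 1.5 * sigma_g**2


class TestPredictCurve:
    def test_flat_when_no_signal(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(
            {"x": rng.uniform(0, 1, 3000), "y": (rng.random(3000) < 0.3).astype(int)}
        )
        m = fit_binomial_smooth(df, SmoothModelSpec("y", [SmoothTerm("x", k=7)]))
        curve = predict_curve(m, "x")
        assert np.all(np.abs(curve.probability - df["y"].mean()) < 0.06)

    def test_grid_endpoints(self):
        df = _logistic_data(seed=1)
        m = fit_binomial_smooth(df, SmoothModelSpec("y", [SmoothTerm("x", k=7)]))
        c = predict_curve(m, "x")
        assert c.grid[0] == pytest.approx(df["x"].min())
        assert c.grid[-1] == pytest.approx(df["x"].max())

    def test_extrapolation_refused(self):
        df = _logistic_data(seed=1)
        m = fit_binomial_smooth(df, SmoothModelSpec("y", [SmoothTerm("x", k=7)]))
        with pytest.raises(ValueError, match="extrapolates"):
            predict_curve(m, "x", grid=np.linspace(-5, 5, 20))
        predict_curve(m, "x", grid=np.linspace(-5, 5, 20), force=True)

    def test_monotone_truth_no_large_reversals(self):
        for seed in range(3):
            df = _logistic_data(n=4000, beta=1.5, seed=seed)
            m = fit_binomial_smooth(df, SmoothModelSpec("y", [SmoothTerm("x", k=7)]))
            c = predict_curve(m, "x")
            rng_span = c.log_odds.max() - c.log_odds.min()
            drops = np.clip(-np.diff(c.log_odds), 0, None)
            # cumulative reversal within any descent below 5% of range
            assert drops.sum() < 0.05 * rng_span

    def test_probability_logodds_consistency(self):
        df = _logistic_data(seed=2)
        m = fit_binomial_smooth(df, SmoothModelSpec("y", [SmoothTerm("x", k=7)]))
        c = predict_curve(m, "x")
        assert np.allclose(logit(c.probability), c.log_odds, atol=1e-6)
        assert np.all((c.probability > 0) & (c.probability < 1))

    def test_unknown_variable(self):
        df = _logistic_data(seed=2)
        m = fit_binomial_smooth(df, SmoothModelSpec("y", [SmoothTerm("x", k=7)]))
        with pytest.raises(ValueError, match="not a covariate"):
            predict_curve(m, "z")


class TestConcurvity:
    def test_duplicated_covariate(self):
        df = _logistic_data(n=1500, seed=4)
        df["x2"] = df["x"]
        spec = SmoothModelSpec("y", [SmoothTerm("x", k=5), SmoothTerm("x2", k=5)])
        m = fit_binomial_smooth(df, spec, lam=1.0)
        c = concurvity(m)
        assert c["s(x)"] > 0.95 and c["s(x2)"] > 0.95

    def test_independent_covariates_low(self):
        rng = np.random.default_rng(11)
        n = 2000
        df = pd.DataFrame(
            {
                "a": rng.uniform(0, 1, n),
                "b": rng.uniform(0, 1, n),
            }
        )
        df["y"] = (rng.random(n) < expit(2.0 * df["a"] - 1.0)).astype(int)
        spec = SmoothModelSpec("y", [SmoothTerm("a", k=5), SmoothTerm("b", k=5)])
        m = fit_binomial_smooth(df, spec, lam=1.0)
        c = concurvity(m)
        assert all(0.0 <= v <= 1.0 for v in c.values())
        assert c["s(a)"] < 0.2

    def test_needs_two_smooths(self):
        df = _logistic_data(seed=6)
        m = fit_binomial_smooth(df, SmoothModelSpec("y", [SmoothTerm("x", k=5)]), lam=1.0)
        with pytest.raises(ValueError):
            concurvity(m)


class TestCompareBic:
    def test_identical_models(self):
        df = _logistic_data(seed=8)
        spec = SmoothModelSpec("y", [SmoothTerm("x", k=7)])
        a = fit_binomial_smooth(df, spec, lam=1.0)
        b = fit_binomial_smooth(df, spec, lam=1.0)
        out = compare_bic(a, b)
        assert out["delta_bic"] == pytest.approx(0.0, abs=1e-9)

    def test_different_outcomes_error(self):
        a = fit_binomial_smooth(_logistic_data(seed=1), SmoothModelSpec("y", [SmoothTerm("x", k=5)]), lam=1.0)
        b = fit_binomial_smooth(_logistic_data(seed=2), SmoothModelSpec("y", [SmoothTerm("x", k=5)]), lam=1.0)
        with pytest.raises(ValueError):
            compare_bic(a, b)

    def test_noise_smooth_does_not_win(self):
        rng = np.random.default_rng(3)
        deltas = []
        for seed in range(5):
            df = _logistic_data(n=2500, seed=seed)
            df["noise"] = rng.uniform(0, 1, len(df))
            base = fit_binomial_smooth(df, SmoothModelSpec("y", [SmoothTerm("x", k=5)]))
            extra = fit_binomial_smooth(
                df, SmoothModelSpec("y", [SmoothTerm("x", k=5), SmoothTerm("noise", k=5)])
            )
            deltas.append(extra.bic - base.bic)
        assert np.mean(deltas) > -1.0  # adding pure noise does not help on average
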