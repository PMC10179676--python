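import math
import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from iuiselect import GEEError, fit_gee, select_significant, wald_report
from iuiselect.gee import GEEFit, simulate_exchangeable_logit
from iuiselect.thresholds import BinaryDesign


def make_design(flags: dict, outcome, cluster):
    frame = (pd.DataFrame(flags, dtype=float) if flags
             else pd.DataFrame(index=range(len(outcome))))
    return BinaryDesign(
        flags=frame,
        outcome=np.asarray(outcome),
        cluster_id=np.asarray(cluster, dtype=object),
    )


def continuous_design(X, y, cluster):
    """Design carrying continuous covariates (bypasses the flag check)."""
    obj = BinaryDesign.__new__(BinaryDesign)
    obj.flags = pd.DataFrame(X)
    obj.outcome = np.asarray(y)
    obj.cluster_id = np.asarray(cluster, dtype=object)
    return obj


class TestFitBasics:
    def test_intercept_only_closed_form(self):
        y = [1, 0, 0, 0] * 8  # mean 0.25
        design = make_design({}, y, list(range(32)))
        fit = fit_gee(design, correlation="independence")
        assert fit.coefficients[0] == pytest.approx(
            math.log(0.25 / 0.75), abs=1e-8)

    def test_singleton_independence_equals_glm(self, rng):
        import statsmodels.api as sm
        n = 120
        x = rng.normal(size=n)
        p = 1 / (1 + np.exp(-(-0.5 + 0.8 * x)))
        y = (rng.random(n) < p).astype(int)
        design = continuous_design({"x": x}, y, np.arange(n))
        fit = fit_gee(design, correlation="independence", tol=1e-12)
        ref = sm.GLM(y, sm.add_constant(x),
                     family=sm.families.Binomial()).fit(tol=1e-12)
        np.testing.assert_allclose(fit.coefficients, ref.params, atol=1e-8)

    def test_constant_outcome_rejected(self):
        design = make_design({"a": [0, 1, 0, 1]}, [0, 0, 0, 0],
                             ["u", "u", "v", "v"])
        with pytest.raises(GEEError, match="constant"):
            fit_gee(design)

    def test_single_cluster_rejected(self):
        design = make_design({"a": [0, 1]}, [0, 1], ["u", "u"])
        with pytest.raises(GEEError, match="clusters"):
            fit_gee(design)

    def test_collinear_columns_named(self):
        a = [0, 1, 0, 1, 1, 0, 1, 0]
        design = make_design({"a": a, "b": a}, [0, 1, 1, 0, 1, 0, 0, 1],
                             list("aabbccdd"))
        with pytest.raises(GEEError, match="collinear"):
            fit_gee(design)

    def test_separation_raises(self):
        flags = [0] * 10 + [1] * 10
        y = flags[:]  # flag perfectly predicts outcome
        design = make_design({"a": flags}, y, list(range(20)))
        with pytest.raises(GEEError, match="separat"):
            fit_gee(design)

    def test_missing_rows_excluded(self, rng):
        flags = rng.binomial(1, 0.5, size=40).astype(float)
        y = rng.binomial(1, 0.4, size=40)
        flags[3] = np.nan
        design = make_design({"a": flags}, y, list(np.arange(40) // 2))
        fit = fit_gee(design)
        assert fit.n_excluded == 1
        assert fit.n_obs == 39


class TestAgainstReferenceGEE:
    """Equivalence oracle: an independent reference GEE implementation."""

    def test_small_datasets_match_statsmodels(self):
        import statsmodels.api as sm
        rng = np.random.default_rng(20230430)
        n_checked = 0
        for _ in range(80):
            n_clusters = int(rng.integers(10, 21))
            size = int(rng.integers(2, 5))
            d = simulate_exchangeable_logit(
                n_clusters, size, [-0.4, 0.7, -0.5], 0.3, rng)
            if not 0.2 < d.outcome.mean() < 0.8:
                continue
            X = np.column_stack([np.ones(len(d.outcome)),
                                 d.flags.to_numpy()])
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                try:
                    ref = sm.GEE(
                        d.outcome, X, groups=np.asarray(d.cluster_id),
                        family=sm.families.Binomial(),
                        cov_struct=sm.cov_struct.Exchangeable(),
                    ).fit(maxiter=300, ctol=1e-10)
                    fit = fit_gee(d, "exchangeable", max_iter=300, tol=1e-10)
                except (GEEError, np.linalg.LinAlgError, ValueError):
                    continue
            np.testing.assert_allclose(
                fit.coefficients, ref.params, rtol=1e-4, atol=1e-6)
            np.testing.assert_allclose(
                fit.robust_se, ref.bse, rtol=1e-4, atol=1e-6)
            n_checked += 1
            if n_checked == 50:
                break
        assert n_checked == 50

    def test_alpha_matches_statsmodels(self, rng):
        import statsmodels.api as sm
        d = simulate_exchangeable_logit(100, 4, [-1.0, 0.5, 0.3], 0.4, rng)
        fit = fit_gee(d, "exchangeable", max_iter=200, tol=1e-10)
        X = np.column_stack([np.ones(len(d.outcome)), d.flags.to_numpy()])
        m = sm.GEE(d.outcome, X, groups=np.asarray(d.cluster_id),
                   family=sm.families.Binomial(),
                   cov_struct=sm.cov_struct.Exchangeable())
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m.fit(maxiter=300, ctol=1e-10)
        assert fit.alpha == pytest.approx(float(m.cov_struct.dep_params),
                                          abs=1e-6)


class TestInvariants:
    def test_estimating_equation_residual_small(self, rng):
        d = simulate_exchangeable_logit(80, 4, [-1.0, 0.6, -0.4], 0.3, rng)
        fit = fit_gee(d, tol=1e-10, max_iter=200)
        # recompute the score at beta-hat with standalone code
        X = np.column_stack([np.ones(len(d.outcome)), d.flags.to_numpy()])
        y = np.asarray(d.outcome, dtype=float)
        mu = 1 / (1 + np.exp(-(X @ fit.coefficients)))
        w = np.sqrt(mu * (1 - mu))
        a = fit.alpha
        score = np.zeros(X.shape[1])
        Bscale = 0.0
        for g in np.unique(np.asarray(d.cluster_id)):
            m = np.asarray(d.cluster_id) == g
            n_i = m.sum()
            R = (1 - a) * np.eye(n_i) + a * np.ones((n_i, n_i))
            W = X[m] * w[m, None]
            z = (y[m] - mu[m]) / w[m]
            Rinv = np.linalg.inv(R)
            score += W.T @ Rinv @ z
            Bscale += np.abs(W.T @ Rinv @ W).max()
        assert np.abs(score).max() < 1e-6 * Bscale

    def test_sandwich_symmetric_psd(self, rng):
        d = simulate_exchangeable_logit(60, 3, [-0.8, 0.5, 0.2], 0.2, rng)
        fit = fit_gee(d)
        cov = fit.robust_covariance
        np.testing.assert_allclose(cov, cov.T, atol=1e-12)
        assert np.linalg.eigvalsh(cov).min() >= -1e-10

    def test_alpha_vanishes_under_independence(self):
        rng = np.random.default_rng(5)
        d = simulate_exchangeable_logit(2000, 4, [-1.5, 0.4, 0.3], 0.0, rng)
        fit = fit_gee(d)
        assert abs(fit.alpha) < 0.05

    def test_bias_shrinks_with_cluster_count(self):
        beta = np.array([-1.2, 0.7, -0.5])
        biases = []
        for n_clusters, seed in ((100, 11), (400, 12), (1600, 13)):
            rng = np.random.default_rng(seed)
            est = []
            for _ in range(60):
                d = simulate_exchangeable_logit(n_clusters, 4, beta, 0.3, rng)
                est.append(fit_gee(d).coefficients)
            biases.append(np.abs(np.mean(est, axis=0) - beta).max())
        assert biases[0] > biases[1] > biases[2]
        assert biases[2] < 0.02


class TestWaldReport:
    def _fit(self, coefs, ses, names=None):
        p = len(coefs)
        return GEEFit(
            names=names or ["intercept"] + [f"b{i}" for i in range(1, p)],
            coefficients=np.asarray(coefs, dtype=float),
            robust_covariance=np.diag(np.asarray(ses, dtype=float) ** 2),
            alpha=0.0, dispersion=1.0, n_clusters=10, n_obs=20,
            n_excluded=0, iterations=3, converged=True,
            correlation="exchangeable")

    def test_zero_coefficient(self):
        report = wald_report(self._fit([0.0], [1.0]))
        assert report.loc[0, "odds_ratio"] == 1.0
        assert report.loc[0, "p"] == pytest.approx(1.0)

    def test_tiny_se_limit(self):
        report = wald_report(self._fit([math.log(2.0)], [1e-12]))
        assert report.loc[0, "odds_ratio"] == pytest.approx(2.0)
        assert report.loc[0, "p"] < 1e-300

    def test_zero_se_signalled(self):
        with pytest.raises(GEEError, match="zero robust SE"):
            wald_report(self._fit([1.0], [0.0]))

    def test_ci_matches_quantile_computation(self, rng):
        d = simulate_exchangeable_logit(50, 4, [-1.0, 0.5, 0.2], 0.2, rng)
        fit = fit_gee(d)
        report = wald_report(fit)
        z = stats.norm.ppf(0.975)
        for i in range(len(fit.names)):
            lo = math.exp(fit.coefficients[i] - z * fit.robust_se[i])
            hi = math.exp(fit.coefficients[i] + z * fit.robust_se[i])
            assert report.loc[i, "ci_low"] == pytest.approx(lo, rel=1e-12)
            assert report.loc[i, "ci_high"] == pytest.approx(hi, rel=1e-12)
            assert lo < math.exp(fit.coefficients[i]) < hi

    def test_unconverged_fit_rejected(self):
        fit = self._fit([0.0], [1.0])
        fit.converged = False
        with pytest.raises(GEEError, match="converged"):
            wald_report(fit)


class TestSelectSignificant:
    def _report(self, terms, ps):
        return pd.DataFrame({"term": terms, "p": ps})

    def test_example_pvalues(self):
        report = self._report(
            ["intercept", "a", "b", "c", "d"],
            [0.5, 0.001, 0.687, 0.023, 0.920])
        assert select_significant(report) == {"a", "c"}

    def test_all_half(self):
        report = self._report(["intercept", "a", "b"], [0.5, 0.5, 0.5])
        assert select_significant(report) == set()

    def test_alpha_one_selects_all_but_intercept(self):
        report = self._report(["intercept", "a", "b"], [0.9, 0.9, 0.9])
        assert select_significant(report, alpha_level=1.0) == {"a", "b"}
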