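import numpy as np
import pytest
from scipy.optimize import minimize

from penomics import penalized as pen
from penomics.dataio import DataError
from penomics.penalized import PenaltySpec
from penomics.simulate import SimulationSpec, simulate_dataset

from conftest import standardized_columns, tiny_dataset


def brute_cox_nll(time, event, eta):
    """Explicit risk-set summation of the Breslow partial likelihood."""
    ll = 0.0
    for i in range(len(eta)):
        if event[i]:
            ll += eta[i] - np.log(np.sum(np.exp(eta[time >= time[i]])))
    return -ll


def logistic_nll(y, eta):
    return float(np.sum(np.logaddexp(0.0, eta) - y * eta))


class TestNegativeLoglik:
    def test_logistic_null_is_n_log2(self, logistic_dataset):
        D, _ = logistic_dataset
        v = pen.negative_loglik("logistic", D, 0.0, np.zeros(D.X.n_features))
        assert v == pytest.approx(D.n_samples * np.log(2.0))

    def test_cox_three_subjects_null_is_log6(self):
        D = tiny_dataset(
            np.zeros((3, 2)), time=np.array([1.0, 2.0, 3.0]), event=np.array([1, 1, 1])
        )
        v = pen.negative_loglik("cox", D, 0.0, np.zeros(2))
        assert v == pytest.approx(np.log(6.0))

    def test_logistic_doubling_samples_doubles_value(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((20, 3))
        y = rng.integers(0, 2, 20).astype(float)
        y[:2] = [0, 1]
        D1 = tiny_dataset(X, y=y)
        D2 = tiny_dataset(np.vstack([X, X]), y=np.concatenate([y, y]))
        beta = rng.standard_normal(3) / 2
        v1 = pen.negative_loglik("logistic", D1, 0.3, beta)
        v2 = pen.negative_loglik("logistic", D2, 0.3, beta)
        assert v2 == pytest.approx(2 * v1)

    @pytest.mark.parametrize("seed", range(5))
    def test_cox_matches_brute_force_risk_sets(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(5, 50)
        time = np.round(rng.exponential(5, n), 1)  # rounding induces ties
        event = rng.integers(0, 2, n).astype(float)
        event[0] = 1
        X = rng.standard_normal((n, 3))
        beta = rng.standard_normal(3) / 2
        D = tiny_dataset(X, time=time, event=event)
        v = pen.negative_loglik("cox", D, 0.0, beta)
        assert v == pytest.approx(brute_cox_nll(time, event, X @ beta), rel=1e-10)

    def test_wrong_length_rejected(self, logistic_dataset):
        D, _ = logistic_dataset
        with pytest.raises(ValueError):
            pen.negative_loglik("logistic", D, 0.0, np.zeros(3))


class TestFitOracles:
    """Every small-p fit must match direct numerical minimization of the
    written objective."""

    def test_logistic_ridge_p1_matches_grid(self):
        rng = np.random.default_rng(10)
        n = 60
        X = standardized_columns(rng, n, 1)
        y = (rng.random(n) < 1 / (1 + np.exp(-1.2 * X[:, 0]))).astype(float)
        D = tiny_dataset(X, y=y)
        lam = 0.1
        f = pen.fit("logistic", D, PenaltySpec("ridge", lam), lambda_=lam)

        def obj(v):
            b0, b1 = v
            return logistic_nll(y, b0 + X[:, 0] * b1) / n + lam * b1**2

        res = minimize(obj, [0.0, 0.0], method="Nelder-Mead", options={"xatol": 1e-10, "fatol": 1e-14})
        ours = obj([f.intercept, f.coefficients[0]])
        assert ours == pytest.approx(res.fun, abs=1e-4)
        assert f.coefficients[0] == pytest.approx(res.x[1], abs=1e-3)

    def test_logistic_lasso_p2_matches_minimizer(self):
        rng = np.random.default_rng(11)
        n = 80
        X = standardized_columns(rng, n, 2)
        y = (rng.random(n) < 1 / (1 + np.exp(-(X[:, 0] - 0.5 * X[:, 1])))).astype(float)
        D = tiny_dataset(X, y=y)
        lam = 0.05
        f = pen.fit("logistic", D, PenaltySpec("lasso", lam), lambda_=lam)

        def obj(v):
            return logistic_nll(y, v[0] + X @ v[1:]) / n + lam * np.abs(v[1:]).sum()

        res = minimize(obj, [0.0, 0.0, 0.0], method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 20000})
        assert obj([f.intercept, *f.coefficients]) <= res.fun + 1e-4

    def test_cox_lasso_p2_beats_local_grid(self):
        rng = np.random.default_rng(12)
        n = 20
        X = standardized_columns(rng, n, 2)
        time = rng.exponential(1 / np.exp(0.8 * X[:, 0]), n)
        event = np.ones(n)
        D = tiny_dataset(X, time=time, event=event)
        lam = 0.08
        f = pen.fit("cox", D, PenaltySpec("lasso", lam), lambda_=lam)

        def obj(b):
            return brute_cox_nll(time, event, X @ b) / n + lam * np.abs(b).sum()

        b_hat = f.coefficients
        ours = obj(b_hat)
        grid = np.linspace(-0.05, 0.05, 201)
        best = min(
            obj(b_hat + np.array([d1, d2])) for d1 in grid[::10] for d2 in grid[::10]
        )
        # fine 201-point 1-D slices through the solution
        for axis in range(2):
            for d in grid:
                step = np.zeros(2)
                step[axis] = d
                best = min(best, obj(b_hat + step))
        assert ours <= best + 1e-6

    def test_ridge_lambda0_equals_mle(self):
        """Unpenalized limit agrees with independent maximum likelihood."""
        import statsmodels.api as sm

        rng = np.random.default_rng(13)
        n = 100
        X = rng.standard_normal((n, 2))
        y = (rng.random(n) < 1 / (1 + np.exp(-(0.3 + X[:, 0])))).astype(float)
        D = tiny_dataset(X, y=y)
        f = pen.fit("logistic", D, PenaltySpec("ridge", 0.0), lambda_=0.0)
        ml = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
        assert f.intercept == pytest.approx(ml.params[0], abs=1e-4)
        assert np.allclose(f.coefficients, ml.params[1:], atol=1e-4)

    def test_cox_ridge_lambda0_equals_partial_mle(self):
        import pandas as pd
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(14)
        n = 80
        X = rng.standard_normal((n, 2))
        time = rng.exponential(1 / np.exp(0.7 * X[:, 0]), n)  # distinct times
        event = np.ones(n)
        D = tiny_dataset(X, time=time, event=event)
        f = pen.fit("cox", D, PenaltySpec("ridge", 0.0), lambda_=0.0)
        cph = CoxPHFitter()
        cph.fit(
            pd.DataFrame({"a": X[:, 0], "b": X[:, 1], "time": time, "event": event}),
            duration_col="time",
            event_col="event",
        )
        assert np.allclose(f.coefficients, cph.params_.to_numpy(), atol=1e-4)

    def test_logistic_lasso_matches_sklearn(self, logistic_dataset):
        """Cross-check against an independent l1 solver on the standardized
        problem (liblinear minimizes sum-loss + ||b||_1 / C)."""
        from sklearn.linear_model import LogisticRegression

        D, _ = logistic_dataset
        lam = 0.03
        f = pen.fit("logistic", D, PenaltySpec("lasso", lam), lambda_=lam)
        X = D.X.values
        Xs = (X - X.mean(0)) / X.std(0)
        sk = LogisticRegression(
            C=1.0 / (D.n_samples * lam), l1_ratio=1.0, penalty="elasticnet",
            solver="saga", tol=1e-10, max_iter=100000,
        )
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sk.fit(Xs, D.outcome.y)
        beta_sk = sk.coef_[0] / X.std(0)
        assert np.allclose(beta_sk, f.coefficients, atol=2e-3)

    def test_cox_lasso_matches_coxnet(self, cox_dataset):
        """Cross-check against the glmnet-style Cox elastic-net solver."""
        sksurv = pytest.importorskip("sksurv.linear_model")
        from sksurv.util import Surv

        D, _ = cox_dataset
        lam = 0.05
        f = pen.fit("cox", D, PenaltySpec("lasso", lam), lambda_=lam)
        X = D.X.values
        Xs = (X - X.mean(0)) / X.std(0)
        y = Surv.from_arrays(D.outcome.event.astype(bool), D.outcome.time)
        cn = sksurv.CoxnetSurvivalAnalysis(
            alphas=[lam], l1_ratio=1.0, normalize=False, tol=1e-9, fit_baseline_model=False
        )
        cn.fit(Xs, y)
        beta_cn = cn.coef_[:, 0] / X.std(0)
        assert np.allclose(beta_cn, f.coefficients, atol=2e-3)


class TestLambdaPath:
    def test_empty_active_set_at_lambda_max(self, logistic_dataset):
        D, _ = logistic_dataset
        spec = PenaltySpec("lasso", "cv")
        lmax = pen.lambda_max("logistic", D, spec)
        f = pen.fit("logistic", D, spec, lambda_=lmax * (1 + 1e-8))
        assert f.active_set == []
        f2 = pen.fit("logistic", D, spec, lambda_=lmax * 0.9)
        assert f2.active_set != []

    def test_path_strictly_decreasing_and_starts_at_max(self, cox_dataset):
        D, _ = cox_dataset
        spec = PenaltySpec("lasso", "cv")
        path = pen.lambda_path("cox", D, spec)
        assert np.all(np.diff(path.values) < 0)
        assert path.lambda_max == pytest.approx(pen.lambda_max("cox", D, spec))

    def test_all_zero_matrix_rejected(self):
        D = tiny_dataset(np.zeros((10, 2)), y=np.array([0, 1] * 5, float))
        with pytest.raises(DataError):
            pen.lambda_path("logistic", D, PenaltySpec("lasso", "cv"))

    def test_warm_path_consistent_with_cold_fits(self, logistic_dataset):
        D, _ = logistic_dataset
        spec = PenaltySpec("lasso", "cv")
        path = pen.lambda_path("logistic", D, spec, n_values=10)
        warm = pen.fit_path("logistic", D, spec, path=path)
        for lam, wf in zip(path.values[::4], warm[::4]):
            cold = pen.fit("logistic", D, spec, lambda_=float(lam))
            assert np.allclose(cold.coefficients, wf.coefficients, atol=1e-5)


class TestKKT:
    @pytest.mark.parametrize("family,seed", [("logistic", 0), ("logistic", 1), ("cox", 2)])
    def test_lasso_kkt_small_violation(self, family, seed):
        D, _ = simulate_dataset(
            SimulationSpec(
                n_samples=100,
                n_features=30,
                true_support=(0, 1),
                true_coefficients=(1.2, -1.0),
                outcome_model=family,
                seed=seed,
            )
        )
        spec = PenaltySpec("lasso", "cv")
        lmax = pen.lambda_max(family, D, spec)
        for frac in (0.5, 0.1, 0.02):
            f = pen.fit(family, D, spec, lambda_=lmax * frac)
            assert f.converged
            assert pen.kkt_max_violation(family, D, f) < 1e-6

    def test_adaptive_kkt_and_subset(self, logistic_dataset):
        D, _ = logistic_dataset
        first = pen.fit("logistic", D, PenaltySpec("lasso", 0.03), lambda_=0.03)
        aspec = pen.adaptive_weights(first)
        f = pen.fit("logistic", D, aspec, lambda_=0.01)
        assert pen.kkt_max_violation("logistic", D, f) < 1e-6
        assert set(f.active_set) <= set(first.active_set)

    def test_ridge_coefficients_shrink_monotonically(self, logistic_dataset):
        D, _ = logistic_dataset
        lams = np.exp(np.linspace(np.log(0.01), np.log(100), 12))
        maxcoef = [
            np.max(np.abs(pen.fit("logistic", D, PenaltySpec("ridge", l), lambda_=float(l)).coefficients))
            for l in lams
        ]
        assert all(a >= b - 1e-9 for a, b in zip(maxcoef, maxcoef[1:]))
        assert maxcoef[-1] < 1e-2


class TestAdaptiveWeights:
    def test_definition_with_absolute_value(self):
        from test_report import make_fit

        first = make_fit("logistic", ["a", "b", "c"], [0.5, 0.0, -0.2])
        spec = pen.adaptive_weights(first)
        assert spec.weights == {"a": 0.5, "c": 0.2}
        assert spec.excluded_features == ("b",)
        pf = spec.penalty_factors(["a", "b", "c"])
        assert pf[0] == pytest.approx(2.0)
        assert np.isinf(pf[1])
        assert pf[2] == pytest.approx(5.0)

    def test_empty_first_stage_signals(self):
        from test_report import make_fit

        first = make_fit("logistic", ["a"], [0.0])
        with pytest.raises(pen.NothingToRefitError):
            pen.adaptive_weights(first)

    def test_requires_lasso_first_stage(self):
        from test_report import make_fit

        first = make_fit("logistic", ["a"], [0.5])
        first.penalty = PenaltySpec("ridge", 0.1)
        with pytest.raises(ValueError):
            pen.adaptive_weights(first)

    def test_excluded_features_stay_zero(self, logistic_dataset):
        D, _ = logistic_dataset
        first = pen.fit("logistic", D, PenaltySpec("lasso", 0.05), lambda_=0.05)
        aspec = pen.adaptive_weights(first)
        f = pen.fit("logistic", D, aspec, lambda_=1e-6)
        excluded = set(aspec.excluded_features)
        for fid, b in zip(f.feature_ids, f.coefficients):
            if fid in excluded:
                assert b == 0.0


class TestCVTune:
    def test_deterministic_given_seed(self, logistic_dataset):
        D, _ = logistic_dataset
        spec = PenaltySpec("lasso", "cv")
        l1, c1 = pen.cv_tune("logistic", D, spec, n_folds=5, seed=3)
        l2, c2 = pen.cv_tune("logistic", D, spec, n_folds=5, seed=3)
        assert l1 == l2 and np.array_equal(c1, c2)

    def test_pure_noise_prefers_heavy_shrinkage(self):
        """Under the null the CV deviance curve should keep lambda large."""
        hits = 0
        for seed in range(8):
            D, _ = simulate_dataset(
                SimulationSpec(n_samples=120, n_features=30, seed=500 + seed)
            )
            spec = PenaltySpec("lasso", "cv")
            lam, curve = pen.cv_tune("logistic", D, spec, n_folds=5, seed=seed)
            grid = curve[:, 0]
            hits += lam >= grid[len(grid) // 3]  # in the largest-lambda third
        assert hits >= 5

    def test_strong_signal_recovered(self):
        D, truth = simulate_dataset(
            SimulationSpec(
                n_samples=400, n_features=30, true_support=(4,),
                true_coefficients=(2.0,), seed=77,
            )
        )
        spec = PenaltySpec("lasso", "cv")
        lam, _ = pen.cv_tune("logistic", D, spec, n_folds=10, seed=0)
        f = pen.fit("logistic", D, spec, lambda_=lam)
        assert truth.support_ids[0] in f.active_set

    def test_cox_fold_events_guarded(self):
        D, _ = simulate_dataset(
            SimulationSpec(n_samples=60, n_features=5, outcome_model="cox", seed=8)
        )
        lam, curve = pen.cv_tune("cox", D, PenaltySpec("lasso", "cv"), n_folds=4, seed=1)
        assert np.isfinite(curve[:, 1]).all()


class TestErrorsAndEdges:
    def test_negative_lambda_rejected(self, logistic_dataset):
        D, _ = logistic_dataset
        with pytest.raises(ValueError):
            pen.fit("logistic", D, PenaltySpec("lasso", 0.1), lambda_=-0.5)
        with pytest.raises(ValueError):
            pen.fit("logistic", D, PenaltySpec("lasso", 0.1), lambda_=0.0)

    def test_family_outcome_mismatch(self, logistic_dataset):
        D, _ = logistic_dataset
        with pytest.raises(DataError):
            pen.fit("cox", D, PenaltySpec("lasso", 0.1), lambda_=0.1)

    def test_penaltyspec_invariants(self):
        with pytest.raises(ValueError):
            PenaltySpec("adaptive_lasso", 0.1)  # weights required
        with pytest.raises(ValueError):
            PenaltySpec("lasso", 0.1, weights={"a": 1.0})
        with pytest.raises(ValueError):
            PenaltySpec("adaptive_lasso", 0.1, weights={"a": -1.0})
        with pytest.raises(ValueError):
            PenaltySpec("lasso", "maybe")
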