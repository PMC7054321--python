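"""Pathwise penalized estimation for logistic and Cox families.

Three penalties are supported — ridge (l2), lasso (l1) and adaptive lasso
(weighted l1 with weights from a first-stage lasso) — fitted by iteratively
reweighted least squares with an inner cyclic coordinate descent using
soft-thresholding for the l1 parts.  The internal objective is

    (1/n) * negative log-(partial-)likelihood + lambda * penalty(beta),

i.e. the loss is scaled by the sample size; an unscaled formulation differs
only by the reparameterization lambda_unscaled = n * lambda.  Cox partial
likelihoods use the Breslow approximation for tied event times; the logistic
intercept is never penalized.

Continuous covariates are standardized to zero mean / unit variance before
penalization and the coefficients are mapped back to the original covariate
scale; 0/1 indicator covariates are left untouched by default so that their
coefficients keep the per-alteration interpretation.  Clinical covariates,
when present, enter unpenalized.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional, Sequence, Union

import numpy as np
import pandas as pd

from ._cd import cd_solve
from .dataio import (
    AnalysisDataset,
    BinaryOutcome,
    DataError,
    MolecularMatrix,
    SurvivalOutcome,
)

Family = Literal["logistic", "cox"]
PenaltyKind = Literal["ridge", "lasso", "adaptive_lasso"]

_MAX_TOTAL_SWEEPS = 100_000
_COEF_TOL = 1e-7
_MIN_IRLS_WEIGHT = 1e-9


class NothingToRefitError(ValueError):
    """First-stage lasso selected nothing; there is no adaptive model to fit."""


class ConvergenceError(RuntimeError):
    pass


@dataclass
class PenaltySpec:
    """Penalty family, tuning parameter and (adaptive) weights.

    ``weights`` maps feature_id -> w_j = |first-stage lasso coefficient|;
    the applied penalty factor is 1/w_j.  ``excluded_features`` receive an
    infinite penalty and are pinned at zero.
    """

    penalty: PenaltyKind
    lambda_: Union[float, str] = "cv"
    weights: Optional[dict[str, float]] = None
    excluded_features: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.penalty == "adaptive_lasso":
            if self.weights is None:
                raise ValueError("adaptive_lasso requires first-stage weights")
            if any(w <= 0 for w in self.weights.values()):
                raise ValueError("adaptive weights must be strictly positive")
        elif self.weights is not None:
            raise ValueError("weights are only meaningful for adaptive_lasso")
        if isinstance(self.lambda_, str) and self.lambda_ != "cv":
            raise ValueError("lambda_ must be a positive number or 'cv'")

    def penalty_factors(self, feature_ids: Sequence[str]) -> np.ndarray:
        pf = np.ones(len(feature_ids))
        if self.penalty == "adaptive_lasso":
            for j, fid in enumerate(feature_ids):
                if fid in self.weights:  # type: ignore[operator]
                    pf[j] = 1.0 / self.weights[fid]  # type: ignore[index]
                else:
                    pf[j] = np.inf
        excluded = set(self.excluded_features)
        for j, fid in enumerate(feature_ids):
            if fid in excluded:
                pf[j] = np.inf
        return pf

    @property
    def is_l1(self) -> bool:
        return self.penalty in ("lasso", "adaptive_lasso")


@dataclass
class FitResult:
    """A fitted penalized model on the original covariate scale."""

    family: Family
    intercept: float
    coefficients: np.ndarray
    feature_ids: list[str]
    lambda_used: float
    penalty: PenaltySpec
    objective_value: float
    converged: bool
    n_sweeps: int
    clinical_coefficients: Optional[dict[str, float]] = None
    cv_curve: Optional["np.ndarray"] = None

    @property
    def active_set(self) -> list[str]:
        return [f for f, b in zip(self.feature_ids, self.coefficients) if b != 0.0]

    def coefficient_of(self, feature_id: str) -> float:
        return float(self.coefficients[self.feature_ids.index(feature_id)])


@dataclass
class LambdaPath:
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) and not np.all(np.diff(self.values) < 0):
            raise ValueError("lambda path must be strictly decreasing")

    @property
    def lambda_max(self) -> float:
        return float(self.values[0])

    @property
    def n_values(self) -> int:
        return len(self.values)


# ---------------------------------------------------------------------------
# likelihoods and IRLS working quantities
# ---------------------------------------------------------------------------


def _logistic_nll(y: np.ndarray, eta: np.ndarray) -> float:
    # -sum y*eta - log(1 + e^eta), stable via log1p(exp(-|eta|)) + max(eta, 0)
    return float(np.sum(np.logaddexp(0.0, eta) - y * eta))


def _cox_order(time: np.ndarray, event: np.ndarray):
    order = np.argsort(time, kind="stable")
    return order, time[order], event[order]


def _cox_nll(time: np.ndarray, event: np.ndarray, eta: np.ndarray) -> float:
    """Negative Breslow log partial likelihood of the linear predictor."""
    order, t, d = _cox_order(time, event)
    e = eta[order]
    e = e - e.max()  # PL invariant to constant shifts; keeps exp in range
    ex = np.exp(e)
    # risk-set sum for each subject: sum of exp(eta) over t_j >= t_i (ties share)
    rcs = np.cumsum(ex[::-1])[::-1]
    first = np.searchsorted(t, t, side="left")
    logrisk = np.log(rcs[first])
    ll = np.sum(d * (e - logrisk))
    return float(-ll)


def _cox_score_weights(time: np.ndarray, event: np.ndarray, eta: np.ndarray):
    """Per-subject score g_i = d NLL's negative / d eta_i and diagonal Hessian
    weights of the Breslow partial likelihood, in original subject order."""
    n = len(eta)
    order, t, d = _cox_order(time, event)
    e = eta[order]
    shift = e.max()
    ex = np.exp(e - shift)
    rcs = np.cumsum(ex[::-1])[::-1]  # risk-set sums at each sorted position
    first = np.searchsorted(t, t, side="left")
    S = rcs[first]  # shared risk-set sum for tied times
    # cum1_i = sum over events m with t_m <= t_i of 1/S_m  (and 1/S_m^2 for cum2)
    inc1 = np.where(d > 0, 1.0 / S, 0.0)
    inc2 = np.where(d > 0, 1.0 / S**2, 0.0)
    c1 = np.cumsum(inc1)
    c2 = np.cumsum(inc2)
    last = np.searchsorted(t, t, side="right") - 1
    cum1 = c1[last]
    cum2 = c2[last]
    g_sorted = d - ex * cum1
    w_sorted = ex * cum1 - ex**2 * cum2
    g = np.empty(n)
    w = np.empty(n)
    g[order] = g_sorted
    w[order] = w_sorted
    return g, w


def _working(family: str, yinfo, eta: np.ndarray):
    """IRLS weights and working response at the current linear predictor."""
    if family == "logistic":
        y = yinfo
        p = 1.0 / (1.0 + np.exp(-eta))
        w = p * (1.0 - p)
        w = np.maximum(w, _MIN_IRLS_WEIGHT)
        z = eta + (y - p) / w
    elif family == "cox":
        time, event = yinfo
        g, w = _cox_score_weights(time, event, eta)
        w = np.maximum(w, _MIN_IRLS_WEIGHT)
        z = eta + g / w
    elif family == "gaussian":
        w = np.ones_like(eta)
        z = yinfo
    else:
        raise ValueError(f"unknown family {family!r}")
    return w, z


def _nll(family: str, yinfo, eta: np.ndarray) -> float:
    if family == "logistic":
        return _logistic_nll(yinfo, eta)
    if family == "cox":
        return _cox_nll(yinfo[0], yinfo[1], eta)
    if family == "gaussian":
        return float(0.5 * np.sum((yinfo - eta) ** 2))
    raise ValueError(f"unknown family {family!r}")


def _nll_gradient(family: str, yinfo, eta: np.ndarray) -> np.ndarray:
    """d NLL / d eta, per subject."""
    if family == "logistic":
        p = 1.0 / (1.0 + np.exp(-eta))
        return p - yinfo
    if family == "cox":
        g, _ = _cox_score_weights(yinfo[0], yinfo[1], eta)
        return -g
    if family == "gaussian":
        return eta - yinfo
    raise ValueError(f"unknown family {family!r}")


def negative_loglik(
    family: Family,
    D: AnalysisDataset,
    intercept: float,
    coefficients: np.ndarray,
) -> float:
    """Negative log-likelihood (logistic) or negative Breslow log partial
    likelihood (Cox) of the given linear model on the dataset."""
    X = D.X.values
    coefficients = np.asarray(coefficients, dtype=float)
    if coefficients.shape != (D.X.n_features,):
        raise ValueError("coefficient length must equal the number of features")
    if not np.isfinite(X).all():
        raise DataError("non-finite covariates")
    eta = intercept + X @ coefficients
    return _nll(family, _yinfo(family, D), eta)


def _yinfo(family: str, D: AnalysisDataset):
    if family == "logistic":
        if not isinstance(D.outcome, BinaryOutcome):
            raise DataError("logistic family requires a binary outcome")
        return D.outcome.y
    if family == "cox":
        if not isinstance(D.outcome, SurvivalOutcome):
            raise DataError("cox family requires a survival outcome")
        return (D.outcome.time, D.outcome.event)
    raise ValueError(f"unknown family {family!r}")


# ---------------------------------------------------------------------------
# design preparation: standardization + unpenalized clinical block
# ---------------------------------------------------------------------------


@dataclass
class _Design:
    Xs: np.ndarray            # internal (standardized) design, molecular + clinical
    feature_ids: list[str]    # molecular feature ids (first block of columns)
    clinical_ids: list[str]   # unpenalized clinical columns (second block)
    center: np.ndarray
    scale: np.ndarray         # original = internal / scale (per column)
    pf: np.ndarray            # penalty factors for the full column set
    use_intercept: bool

    @property
    def p_mol(self) -> int:
        return len(self.feature_ids)


def _prepare_design(
    family: str,
    D: AnalysisDataset,
    penalty: PenaltySpec,
    standardize_binary: bool = False,
) -> _Design:
    Xm = D.X.values.astype(float)
    ids = list(D.X.feature_ids)
    blocks = [Xm]
    clin_ids: list[str] = []
    if D.clinical_covariates is not None:
        blocks.append(D.clinical_covariates.to_numpy(dtype=float))
        clin_ids = list(D.clinical_covariates.columns)
    X = np.concatenate(blocks, axis=1)
    n, p = X.shape

    is_binary = np.array([np.isin(np.unique(X[:, j]), (0.0, 1.0)).all() for j in range(p)])
    do_std = ~is_binary if not standardize_binary else np.ones(p, dtype=bool)
    center = np.where(do_std, X.mean(axis=0), 0.0)
    sd = X.std(axis=0)  # 1/n variance, glmnet convention
    scale = np.where(do_std & (sd > 0), sd, 1.0)
    Xs = (X - center) / scale

    pf_mol = penalty.penalty_factors(ids)
    pf = np.concatenate([pf_mol, np.zeros(len(clin_ids))])
    return _Design(
        Xs=np.asfortranarray(Xs),  # column access dominates the CD kernel
        feature_ids=ids,
        clinical_ids=clin_ids,
        center=center,
        scale=scale,
        pf=pf,
        use_intercept=(family == "logistic" or family == "gaussian"),
    )


def _irls_fit(
    family: str,
    yinfo,
    design: _Design,
    lam: float,
    l1: bool,
    beta0: Optional[np.ndarray] = None,
    b0_init: float = 0.0,
    coef_tol: float = _COEF_TOL,
    max_total_sweeps: int = _MAX_TOTAL_SWEEPS,
):
    """Outer IRLS loop around the coordinate-descent kernel.

    Returns internal-scale (b0, beta, converged, total_sweeps).
    """
    X = design.Xs
    n, p = X.shape
    beta = np.zeros(p) if beta0 is None else beta0.copy()
    b0 = b0_init
    total = 0
    converged = False
    max_outer = 100 if family != "gaussian" else 1
    for _ in range(max_outer):
        eta = b0 + X @ beta
        w, z = _working(family, yinfo, eta)
        beta_old = beta.copy()
        b0_old = b0
        budget = max(max_total_sweeps - total, 1)
        b0, sweeps = cd_solve(
            X, w, z, beta, b0, lam, design.pf, l1, design.use_intercept,
            coef_tol, min(budget, 10_000),
        )
        total += sweeps
        delta = max(
            np.max(np.abs(beta - beta_old), initial=0.0), abs(b0 - b0_old)
        )
        if family == "gaussian" or delta < coef_tol * max(1.0, np.max(np.abs(beta), initial=1.0)):
            converged = True
            break
        if total >= max_total_sweeps:
            break
    return b0, beta, converged, total


def _objective(family, yinfo, design: _Design, b0, beta, lam, l1) -> float:
    n = design.Xs.shape[0]
    eta = b0 + design.Xs @ beta
    pen_mask = np.isfinite(design.pf) & (design.pf > 0)
    if l1:
        pen = np.sum(design.pf[pen_mask] * np.abs(beta[pen_mask]))
    else:
        pen = np.sum(design.pf[pen_mask] * beta[pen_mask] ** 2)
    return _nll(family, yinfo, eta) / n + lam * pen


def _null_model(family, yinfo, design: _Design):
    """Fit only the unpenalized block (intercept + clinical) — the model at
    lambda = infinity; used for lambda_max and warm starts."""
    if len(design.clinical_ids) == 0:
        # closed-form / trivial null
        if family == "logistic":
            ybar = float(np.mean(yinfo))
            ybar = min(max(ybar, 1e-12), 1 - 1e-12)
            return float(np.log(ybar / (1 - ybar))), np.zeros(design.Xs.shape[1])
        if family == "gaussian":
            return float(np.mean(yinfo)), np.zeros(design.Xs.shape[1])
        return 0.0, np.zeros(design.Xs.shape[1])
    # lasso at a huge lambda keeps only pf=0 columns active
    saved_pf = design.pf
    b0, beta, _, _ = _irls_fit(family, yinfo, design, lam=1e10, l1=True)
    assert design.pf is saved_pf
    return b0, beta


def lambda_max(family: Family, D: AnalysisDataset, penalty: PenaltySpec) -> float:
    """Smallest lambda at which every penalized coefficient is zero."""
    design = _prepare_design(family, D, penalty)
    yinfo = _yinfo(family, D)
    return _lambda_max_design(family, yinfo, design)


def _lambda_max_design(family, yinfo, design: _Design) -> float:
    n = design.Xs.shape[0]
    b0, beta = _null_model(family, yinfo, design)
    eta = b0 + design.Xs @ beta
    grad = design.Xs.T @ _nll_gradient(family, yinfo, eta) / n
    pen = np.isfinite(design.pf) & (design.pf > 0)
    if not pen.any():
        raise DataError("no penalized features")
    vals = np.abs(grad[pen]) / design.pf[pen]
    lmax = float(np.max(vals))
    if lmax <= 0:
        raise DataError("all-zero gradient at the null model (constant covariates?)")
    return lmax


def lambda_path(
    family: Family,
    D: AnalysisDataset,
    penalty: PenaltySpec,
    n_values: int = 100,
    eps: Optional[float] = None,
) -> LambdaPath:
    """Log-spaced path from lambda_max down to eps * lambda_max.

    eps defaults to 1e-2 when p > n and 1e-3 otherwise.  For ridge the path
    starts at 100x the lasso lambda_max since the l2 solution never hits
    exact zero.
    """
    if np.all(D.X.values == 0):
        raise DataError("all-zero covariate matrix")
    if eps is None:
        eps = 1e-2 if D.X.n_features > D.X.n_samples else 1e-3
    lmax = lambda_max(family, D, penalty)
    if penalty.penalty == "ridge":
        lmax = lmax * 100.0
    grid = np.exp(np.linspace(np.log(lmax), np.log(lmax * eps), n_values))
    return LambdaPath(grid)


def fit(
    family: Family,
    D: AnalysisDataset,
    penalty: PenaltySpec,
    lambda_: Optional[float] = None,
    seed: int = 0,
    n_folds_tune: int = 10,
) -> FitResult:
    """Fit one penalized model.

    ``lambda_`` overrides the spec's value; ``lambda_ = "cv"`` (or spec value
    "cv") triggers 10-fold cross-validated tuning by held-out deviance.
    """
    lam = lambda_ if lambda_ is not None else penalty.lambda_
    if lam == "cv":
        lam, _curve = cv_tune(family, D, penalty, n_folds=n_folds_tune, seed=seed)
    lam = float(lam)
    if penalty.is_l1 and lam <= 0:
        raise ValueError("lambda must be > 0 for l1 penalties")
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    _validate_outcome(family, D)
    design = _prepare_design(family, D, penalty)
    yinfo = _yinfo(family, D)
    b0, beta, converged, sweeps = _irls_fit(family, yinfo, design, lam, penalty.is_l1)
    return _package_fit(family, design, penalty, yinfo, b0, beta, lam, converged, sweeps)


def _validate_outcome(family, D):
    if family == "cox":
        if not isinstance(D.outcome, SurvivalOutcome):
            raise DataError("cox family requires a survival outcome")
        if D.outcome.event.sum() < 1:
            raise DataError("no events in the survival outcome")
    elif family == "logistic":
        if not isinstance(D.outcome, BinaryOutcome):
            raise DataError("logistic family requires a binary outcome")


def _package_fit(family, design, penalty, yinfo, b0, beta, lam, converged, sweeps):
    obj = _objective(family, yinfo, design, b0, beta, lam, penalty.is_l1)
    p_mol = design.p_mol
    coef_orig = beta / design.scale
    b0_orig = b0 - float(np.sum(beta * design.center / design.scale))
    clin = None
    if design.clinical_ids:
        clin = {
            cid: float(coef_orig[p_mol + k]) for k, cid in enumerate(design.clinical_ids)
        }
    return FitResult(
        family=family,
        intercept=float(b0_orig) if design.use_intercept else 0.0,
        coefficients=coef_orig[:p_mol],
        feature_ids=design.feature_ids,
        lambda_used=lam,
        penalty=penalty,
        objective_value=float(obj),
        converged=bool(converged),
        n_sweeps=int(sweeps),
        clinical_coefficients=clin,
    )


def fit_path(
    family: Family,
    D: AnalysisDataset,
    penalty: PenaltySpec,
    path: Optional[LambdaPath] = None,
    stop_early: bool = False,
    devmax: float = 0.99,
    fdev: float = 1e-5,
    coef_tol: float = _COEF_TOL,
) -> list[FitResult]:
    """Fit the whole lambda path with warm starts (largest lambda first).

    With ``stop_early`` the path is truncated, as pathwise solvers
    conventionally do, once the fit explains more than ``devmax`` of the
    null deviance or the per-step gain in deviance explained drops below
    ``fdev`` — the saturated flat tail carries no information and dominates
    run time.
    """
    _validate_outcome(family, D)
    if path is None:
        path = lambda_path(family, D, penalty)
    design = _prepare_design(family, D, penalty)
    yinfo = _yinfo(family, D)
    results = []
    beta = None
    b0 = 0.0
    if stop_early:
        b0n, bn = _null_model(family, yinfo, design)
        nll_null = _nll(family, yinfo, b0n + design.Xs @ bn)
    ratio_prev = 0.0
    for lam in path.values:
        b0, beta, converged, sweeps = _irls_fit(
            family, yinfo, design, float(lam), penalty.is_l1, beta0=beta,
            b0_init=b0, coef_tol=coef_tol,
        )
        results.append(
            _package_fit(family, design, penalty, yinfo, b0, beta, float(lam), converged, sweeps)
        )
        if stop_early and nll_null > 0:
            ratio = 1.0 - _nll(family, yinfo, b0 + design.Xs @ beta) / nll_null
            if ratio > devmax:
                break
            if len(results) > 1 and ratio - ratio_prev < fdev * max(ratio, fdev):
                break
            ratio_prev = ratio
    return results


# ---------------------------------------------------------------------------
# cross-validated tuning
# ---------------------------------------------------------------------------


def _stratified_folds(strata: np.ndarray, n_folds: int, rng: np.random.Generator) -> np.ndarray:
    """Fold label per sample, balanced within each stratum."""
    n = len(strata)
    assignment = np.empty(n, dtype=int)
    for value in np.unique(strata):
        idx = np.flatnonzero(strata == value)
        rng.shuffle(idx)
        assignment[idx] = np.arange(len(idx)) % n_folds
    return assignment


def _subset_dataset(D: AnalysisDataset, mask: np.ndarray) -> AnalysisDataset:
    ids = [s for s, m in zip(D.X.sample_ids, mask) if m]
    X = MolecularMatrix(ids, D.X.feature_ids, D.X.values[mask], D.X.kind)
    if isinstance(D.outcome, BinaryOutcome):
        out = BinaryOutcome(ids, D.outcome.y[mask], D.outcome.positive_label)
    else:
        out = SurvivalOutcome(ids, D.outcome.time[mask], D.outcome.event[mask])
    clin = None
    if D.clinical_covariates is not None:
        clin = D.clinical_covariates.iloc[np.flatnonzero(mask)].copy()
        clin.index = pd.Index(ids)
    return AnalysisDataset(X, out, clin)


def cv_folds(D: AnalysisDataset, n_folds: int, seed: int) -> np.ndarray:
    """Deterministic stratified fold assignment (by class or event status)."""
    rng = np.random.default_rng(seed)
    if isinstance(D.outcome, BinaryOutcome):
        strata = D.outcome.y
    else:
        strata = D.outcome.event
    for _ in range(20):
        assignment = _stratified_folds(strata, n_folds, rng)
        ok = True
        for k in range(n_folds):
            tr = strata[assignment != k]
            if isinstance(D.outcome, BinaryOutcome) and len(np.unique(tr)) < 2:
                ok = False
            if isinstance(D.outcome, SurvivalOutcome) and tr.sum() < 1:
                ok = False
        if ok:
            return assignment
    raise DataError("could not build folds with both outcome classes / events in training")


def cv_tune(
    family: Family,
    D: AnalysisDataset,
    penalty: PenaltySpec,
    n_folds: int = 10,
    seed: int = 0,
    path: Optional[LambdaPath] = None,
):
    """Select lambda by K-fold cross-validated deviance.

    Logistic: mean held-out binomial deviance.  Cox: the cross-validated
    partial-likelihood deviance of Verweij & van Houwelingen,
    -2 * [PL_all(beta_{-k}) - PL_train(beta_{-k})] summed over folds, which
    stays well-defined when held-out risk sets are small.  Ties among
    minimizing lambdas break toward the largest (most parsimonious) value.

    Path fits during tuning use a relaxed coordinate tolerance (1e-5): the
    held-out deviance curve is insensitive at that precision and the final
    model is always refit at the default 1e-7 tolerance.
    """
    path_tol = 1e-5
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    if path is None:
        # the grid comes from the full data, truncated where the full-data
        # fit saturates; every fold is then scored on the same grid
        full = fit_path(family, D, penalty, stop_early=penalty.is_l1, coef_tol=path_tol)
        path = LambdaPath(np.array([f.lambda_used for f in full]))
    assignment = cv_folds(D, n_folds, seed)
    n = D.n_samples
    yinfo_all = _yinfo(family, D)
    crit = np.zeros(path.n_values)
    for k in range(n_folds):
        train = assignment != k
        D_tr = _subset_dataset(D, train)
        fits = fit_path(family, D_tr, penalty, path=path, coef_tol=path_tol)
        for i, f in enumerate(fits):
            eta_all = f.intercept + D.X.values @ f.coefficients
            if f.clinical_coefficients:
                eta_all = eta_all + D.clinical_covariates.to_numpy() @ np.array(
                    [f.clinical_coefficients[c] for c in D.clinical_covariates.columns]
                )
            if family == "logistic":
                y_te = yinfo_all[~train]
                eta_te = eta_all[~train]
                p = 1.0 / (1.0 + np.exp(-eta_te))
                p = np.clip(p, 1e-12, 1 - 1e-12)
                dev = -2.0 * np.mean(y_te * np.log(p) + (1 - y_te) * np.log(1 - p))
                crit[i] += dev / n_folds
            else:
                time, event = yinfo_all
                pl_all = -_cox_nll(time, event, eta_all)
                pl_tr = -_cox_nll(time[train], event[train], eta_all[train])
                crit[i] += -2.0 * (pl_all - pl_tr) / n
    best = np.min(crit)
    # largest lambda within numerical tie of the minimum
    idx = int(np.flatnonzero(crit <= best + 1e-12)[0])
    curve = np.column_stack([path.values, crit])
    return float(path.values[idx]), curve


def adaptive_weights(first_stage: FitResult) -> PenaltySpec:
    """Turn a lasso fit into the adaptive-lasso penalty: w_j = |beta_j^lasso|,
    zero-coefficient features excluded (infinite penalty)."""
    if first_stage.penalty.penalty != "lasso":
        raise ValueError("adaptive weights require a first-stage lasso fit")
    active = {
        fid: abs(float(b))
        for fid, b in zip(first_stage.feature_ids, first_stage.coefficients)
        if b != 0.0
    }
    if not active:
        raise NothingToRefitError("first-stage lasso selected no features")
    excluded = tuple(f for f in first_stage.feature_ids if f not in active)
    return PenaltySpec(
        penalty="adaptive_lasso", lambda_="cv", weights=active, excluded_features=excluded
    )


# ---------------------------------------------------------------------------
# KKT certification
# ---------------------------------------------------------------------------


def kkt_max_violation(family: Family, D: AnalysisDataset, result: FitResult) -> float:
    """Largest violation of the l1 stationarity conditions at the solution.

    For each penalized coordinate j (internal standardized scale, gradient of
    (1/n) NLL): inactive -> max(|g_j| - lam*pf_j, 0); active -> |g_j +
    lam*pf_j*sign(beta_j)|.  The unpenalized block contributes |g_j|.
    """
    if not result.penalty.is_l1:
        raise ValueError("KKT certification applies to l1 penalties")
    design = _prepare_design(family, D, result.penalty)
    yinfo = _yinfo(family, D)
    n = design.Xs.shape[0]
    beta_int = np.concatenate(
        [
            result.coefficients * design.scale[: design.p_mol],
            np.array(
                [result.clinical_coefficients[c] for c in design.clinical_ids]
                if design.clinical_ids
                else []
            )
            * design.scale[design.p_mol :],
        ]
    )
    b0_int = result.intercept + float(
        np.sum(beta_int * design.center / design.scale))
    eta = b0_int + design.Xs @ beta_int
    g = design.Xs.T @ _nll_gradient(family, yinfo, eta) / n
    lam = result.lambda_used
    viol = 0.0
    for j in range(len(beta_int)):
        pfj = design.pf[j]
        if not np.isfinite(pfj):
            continue
        if pfj == 0:
            viol = max(viol, abs(g[j]))
        elif beta_int[j] == 0.0:
            viol = max(viol, abs(g[j]) - lam * pfj)
        else:
            viol = max(viol, abs(g[j] + lam * pfj * np.sign(beta_int[j])))
    if design.use_intercept:
        grad_eta = _nll_gradient(family, yinfo, eta)
        viol = max(viol, abs(float(np.mean(grad_eta))))
    return float(viol)
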