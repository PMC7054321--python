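"""Post-selection ("selective") p-values for lasso-selected features.

Naive p-values computed by refitting only the selected features are
anti-conservative: the same data chose the features and now tests them.
The polyhedral approach conditions on the selection event instead.  For a
Gaussian response y ~ N(mu, sigma^2 I) and the lasso at fixed lambda, the
event {active set E, signs s} is exactly an affine set {A y <= b}; for each
selected feature the distribution of the least-squares contrast eta'y,
conditional on that event (and on the component of y orthogonal to eta), is
a Gaussian truncated to an interval [V-, V+] that is computable from A, b.
The reported p-value is the two-sided truncated-Gaussian pivot
2 * min(F, 1 - F).

Logistic and Cox fits are handled through their one-step weighted
least-squares linearization at the lasso solution: the IRLS working
response and weights at the solution define a weighted Gaussian problem
whose lasso KKT conditions coincide with the fitted model's, so the
selection event carries over; the noise scale of the working model is the
standard GLM convention sigma = 1.  The adaptive lasso reduces to a plain
lasso event after rescaling the design columns by the adaptive weights.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.special import log_ndtr

from . import penalized as pen
from .dataio import AnalysisDataset
from .penalized import FitResult

# truncation intervals narrower than this (in sd units) are numerically
# degenerate: the pivot is unidentifiable and the feature gets a flagged p
_MIN_INTERVAL_SD = 1e-8


@dataclass
class SelectiveInferenceResult:
    feature_ids: list[str]
    coefficients: np.ndarray
    p_values: np.ndarray
    truncation_bounds: list[tuple[float, float]]
    lambda_used: float
    sigma_used: float
    observed: np.ndarray = None  # eta_j' y per reported feature

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "feature_id": self.feature_ids,
                "coefficient": self.coefficients,
                "p_value": self.p_values,
                "V_minus": [b[0] for b in self.truncation_bounds],
                "V_plus": [b[1] for b in self.truncation_bounds],
            }
        )


def _truncnorm_two_sided_p(x: float, lo: float, hi: float, sd: float) -> float:
    """2 * min(F, 1-F) for x ~ N(0, sd^2) truncated to [lo, hi].

    Computed in log space from both tails so that far-out intervals (where
    Phi differences underflow) stay accurate.
    """
    a, b, t = lo / sd, hi / sd, x / sd
    # F = (Phi(t) - Phi(a)) / (Phi(b) - Phi(a)), via log Phi for the lower
    # tail and log Phi(-.) for the upper tail, whichever is better placed
    if a == -np.inf and b == np.inf:
        F = np.exp(log_ndtr(t))
        return float(2 * min(F, 1 - F))

    def diff_cdf(u, v):  # Phi(v) - Phi(u), u <= v, stable both tails
        if u > v:
            return 0.0
        if v <= 0:  # both in lower tail: use log Phi
            lv, lu = log_ndtr(v), log_ndtr(u)
            return float(np.exp(lv) * -np.expm1(lu - lv))
        if u >= 0:  # both in upper tail: Phi(v)-Phi(u) = Phi(-u)-Phi(-v)
            lu, lv = log_ndtr(-u), log_ndtr(-v)
            return float(np.exp(lu) * -np.expm1(lv - lu))
        return float(np.exp(log_ndtr(v)) - np.exp(log_ndtr(u)))

    denom = diff_cdf(a, b)
    if denom <= 0:
        return float("nan")
    F = diff_cdf(a, min(t, b)) / denom
    F = min(max(F, 0.0), 1.0)
    return float(2 * min(F, 1 - F))


def truncation_interval(
    A: np.ndarray, b: np.ndarray, y: np.ndarray, eta: np.ndarray
) -> tuple[float, float]:
    """[V-, V+] of eta'y over {A y <= b}, holding the orthogonal part fixed.

    Standard polyhedral-lemma algebra: with c = eta / |eta|^2 (the noise
    scale cancels for isotropic covariance) and z = y - c (eta'y), each
    constraint row bounds eta'y from below (negative A c) or above
    (positive A c).
    """
    ety = float(eta @ y)
    c = eta / float(eta @ eta)
    z = y - c * ety
    Ac = A @ c
    Az = A @ z
    resid = b - Az
    vminus, vplus = -np.inf, np.inf
    neg = Ac < 0
    pos = Ac > 0
    if neg.any():
        vminus = float(np.max(resid[neg] / Ac[neg]))
    if pos.any():
        vplus = float(np.min(resid[pos] / Ac[pos]))
    return vminus, vplus


def lasso_selection_constraints(
    X: np.ndarray, active: np.ndarray, signs: np.ndarray, lam: float
) -> tuple[np.ndarray, np.ndarray]:
    """Affine representation {A y <= b} of the lasso event {E, s} for the
    objective (1/2n)||y - X beta||^2 + lam * sum |beta_j|."""
    n, p = X.shape
    XE = X[:, active]
    M = np.linalg.inv(XE.T @ XE)
    rows_A = []
    rows_b = []
    # sign consistency of the active block
    S = np.diag(signs)
    A1 = -S @ M @ XE.T
    b1 = -n * lam * S @ M @ signs
    rows_A.append(A1)
    rows_b.append(b1)
    inactive = np.setdiff1d(np.arange(p), active)
    if len(inactive):
        Xm = X[:, inactive]
        P = XE @ M @ XE.T
        R = Xm.T @ (np.eye(n) - P) / (n * lam)
        XmXE_Ms = Xm.T @ XE @ M @ signs
        rows_A.append(R)
        rows_b.append(1.0 - XmXE_Ms)
        rows_A.append(-R)
        rows_b.append(1.0 + XmXE_Ms)
    return np.vstack(rows_A), np.concatenate(rows_b)


def selective_pvalues_gaussian(
    X: np.ndarray,
    y: np.ndarray,
    lam: float,
    sigma: Optional[float] = None,
    feature_ids: Optional[list[str]] = None,
    beta: Optional[np.ndarray] = None,
) -> SelectiveInferenceResult:
    """Selective p-values for a Gaussian-response lasso at fixed lambda.

    This is both the debugging family and the computational core that the
    logistic/Cox linearizations feed.  ``beta`` may pass in an existing
    solution of (1/2n)||y - X beta||^2 + lam sum|beta|; otherwise it is fit
    here.  sigma defaults to the residual estimate when n > p, else 1.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if beta is None:
        beta = _gaussian_lasso(X, y, lam)
    active = np.flatnonzero(beta)
    if len(active) == 0:
        raise pen.NothingToRefitError("empty active set: nothing to test")
    signs = np.sign(beta[active])
    if sigma is None:
        if n > p + 1:
            XE = X[:, active]
            resid = y - XE @ np.linalg.lstsq(XE, y, rcond=None)[0]
            sigma = float(np.sqrt(resid @ resid / (n - len(active))))
        else:
            sigma = 1.0
    A, b = lasso_selection_constraints(X, active, signs, lam)
    XE = X[:, active]
    M = np.linalg.inv(XE.T @ XE)
    if feature_ids is None:
        feature_ids = [f"f{j}" for j in range(p)]

    ids, coefs, pvals, bounds, observed = [], [], [], [], []
    for idx, j in enumerate(active):
        eta = XE @ M[:, idx]
        tau = sigma * float(np.sqrt(eta @ eta))
        vminus, vplus = truncation_interval(A, b, y, eta)
        obs = float(eta @ y)
        ids.append(feature_ids[j])
        coefs.append(float(beta[j]))
        bounds.append((vminus, vplus))
        observed.append(obs)
        if vplus - vminus < _MIN_INTERVAL_SD * tau:
            pvals.append(np.nan)  # degenerate truncation, flagged
        else:
            pvals.append(_truncnorm_two_sided_p(obs, vminus, vplus, tau))
    return SelectiveInferenceResult(
        feature_ids=ids,
        coefficients=np.asarray(coefs),
        p_values=np.asarray(pvals),
        truncation_bounds=bounds,
        lambda_used=float(lam),
        sigma_used=float(sigma),
        observed=np.asarray(observed),
    )


def _gaussian_lasso(X: np.ndarray, y: np.ndarray, lam: float) -> np.ndarray:
    """Solve (1/2n)||y - X beta||^2 + lam sum|beta| (no intercept)."""
    from ._cd import cd_solve

    n, p = X.shape
    beta = np.zeros(p)
    cd_solve(
        np.asfortranarray(X), np.ones(n), y.astype(float), beta, 0.0,
        float(lam), np.ones(p), True, False, 1e-10, 100_000,
    )
    return beta


def selective_pvalues(
    family: str,
    D: AnalysisDataset,
    fit: FitResult,
    lam: Optional[float] = None,
    sigma: float = 1.0,
) -> SelectiveInferenceResult:
    """Selective p-values for a lasso / adaptive-lasso GLM fit at fixed lambda.

    The weighted working problem at the solution — X~ = W^{1/2} X_s,
    y~ = W^{1/2} z, with (W, z) the IRLS weights and working response and
    X_s the internally standardized design (columns rescaled by the adaptive
    weights when applicable) — shares its lasso KKT system with the original
    fit, so the selection event {E, s} is encoded on the working response
    and the pivot computed there.  The logistic intercept is profiled out by
    residualizing against the weighted constant column.
    """
    if not fit.penalty.is_l1:
        raise ValueError("selective inference applies to lasso / adaptive lasso fits")
    lam = float(lam if lam is not None else fit.lambda_used)
    active_ids = fit.active_set
    if not active_ids:
        raise pen.NothingToRefitError("empty active set: nothing to test")

    if fit.feature_ids != D.X.feature_ids:
        # e.g. the fit ran on the post-screening feature subset
        from .dataio import AnalysisDataset, MolecularMatrix

        cols = [D.X.feature_ids.index(f) for f in fit.feature_ids]
        D = AnalysisDataset(
            MolecularMatrix(
                D.X.sample_ids, list(fit.feature_ids), D.X.values[:, cols], D.X.kind
            ),
            D.outcome,
            D.clinical_covariates,
        )

    design = pen._prepare_design(family, D, fit.penalty)
    yinfo = pen._yinfo(family, D)
    # internal-scale solution and linear predictor
    beta_int = fit.coefficients * design.scale[: design.p_mol]
    blocks = [beta_int]
    if design.clinical_ids:
        blocks.append(
            np.array([fit.clinical_coefficients[c] for c in design.clinical_ids])
            * design.scale[design.p_mol :]
        )
    beta_full = np.concatenate(blocks)
    if design.use_intercept:
        b0_int = fit.intercept + float(
            np.sum(beta_full * design.center / design.scale)
        )
    else:
        # Cox: shift-invariant partial likelihood, and no intercept column in
        # the working regression to absorb a centering constant
        b0_int = 0.0
    eta_lin = b0_int + design.Xs @ beta_full
    w, z = pen._working(family, yinfo, eta_lin)

    sw = np.sqrt(w)
    Xw = design.Xs * sw[:, None]
    yw = sw * z

    # adaptive lasso: scale columns by w_j so the penalty is uniform lam
    pf = design.pf
    keep = np.isfinite(pf) & (pf > 0)
    col_scale = 1.0 / pf[keep]  # = adaptive weight w_j (1 for plain lasso)
    Xpen = Xw[:, keep] * col_scale[None, :]
    kept_idx = np.flatnonzero(keep)

    # profile out the unpenalized block (intercept and/or clinical columns)
    unpen_cols = []
    if design.use_intercept:
        unpen_cols.append(sw)
    for j in np.flatnonzero(np.isfinite(pf) & (pf == 0)):
        unpen_cols.append(Xw[:, j])
    if unpen_cols:
        U = np.column_stack(unpen_cols)
        Q, _ = np.linalg.qr(U)
        Xpen = Xpen - Q @ (Q.T @ Xpen)
        yw = yw - Q @ (Q.T @ yw)

    # internal coefficients on the rescaled columns: theta_j = beta_j / w_j
    theta = beta_full[kept_idx] / col_scale
    names = (design.feature_ids + design.clinical_ids)
    kept_names = [names[j] for j in kept_idx]
    res = selective_pvalues_gaussian(
        Xpen, yw, lam, sigma=sigma, feature_ids=kept_names, beta=theta
    )
    # report coefficients on the original covariate scale
    coef_map = dict(zip(fit.feature_ids, fit.coefficients))
    res.coefficients = np.array([coef_map.get(f, np.nan) for f in res.feature_ids])
    return res
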