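"""Univariate screening with Benjamini-Hochberg false-discovery-rate control.

Each feature is fit alone against the outcome — logistic regression for a
binary endpoint, Cox regression for survival — and its two-sided Wald
p-value enters a BH step-up selection at FDR level q (default 0.05).  Only
features passing the screen are carried into the penalized multivariate fit.

Degenerate univariate fits (zero-variance feature, perfect separation,
non-convergence) are flagged with a missing p-value: they are excluded from
the number of tests m and are never selected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError as _LifelinesConvergence
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .dataio import AnalysisDataset, BinaryOutcome, DataError, SurvivalOutcome

# |coef| or SE beyond this in a single-covariate fit signals separation /
# divergence rather than information
_DIVERGENCE_LIMIT = 1e2


@dataclass
class ScreenResult:
    """Per-feature p-values, BH-adjusted q-values and the selection they imply.

    ``selected`` is equivalent whether thresholded on adjusted q-values
    (q <= q_threshold) or through the raw-p step-up rule; both views are
    reported.  Missing (flagged) p-values are NaN and never selected.
    """

    feature_ids: list[str]
    p_values: np.ndarray
    q_values: np.ndarray
    selected: np.ndarray
    q_threshold: float

    @property
    def selected_ids(self) -> list[str]:
        return [f for f, s in zip(self.feature_ids, self.selected) if s]

    @property
    def n_tested(self) -> int:
        return int(np.sum(~np.isnan(self.p_values)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature_id": self.feature_ids,
                "p_value": self.p_values,
                "q_value": self.q_values,
                "selected": self.selected,
            }
        )


def _logistic_univariate_p(x: np.ndarray, y: np.ndarray, clinical=None) -> float:
    cols = [x] if clinical is None else [x] + [clinical[:, k] for k in range(clinical.shape[1])]
    X = sm.add_constant(np.column_stack(cols))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
    except (PerfectSeparationError, np.linalg.LinAlgError, ValueError):
        return np.nan
    coef, se = res.params[1], res.bse[1]
    if not np.isfinite(coef) or not np.isfinite(se):
        return np.nan
    if abs(coef) > _DIVERGENCE_LIMIT or se > _DIVERGENCE_LIMIT:
        return np.nan  # separation: Wald statistic meaningless
    return float(res.pvalues[1])


def _cox_univariate_p(x, time, event, clinical=None) -> float:
    data = {"x": x, "time": time, "event": event}
    if clinical is not None:
        for k in range(clinical.shape[1]):
            data[f"c{k}"] = clinical[:, k]
    df = pd.DataFrame(data)
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="time", event_col="event")
    except (_LifelinesConvergence, np.linalg.LinAlgError, ValueError):
        return np.nan
    coef = float(cph.params_["x"])
    se = float(cph.standard_errors_["x"])
    if not np.isfinite(coef) or not np.isfinite(se):
        return np.nan
    if abs(coef) > _DIVERGENCE_LIMIT or se > _DIVERGENCE_LIMIT:
        return np.nan
    return float(cph.summary.loc["x", "p"])


def univariate_pvalues(
    D: AnalysisDataset,
    family: str,
    include_clinical: bool = False,
) -> np.ndarray:
    """Two-sided Wald p-value of each feature's coefficient in a
    single-covariate model (plus, optionally, unpenalized clinical terms).

    Constant features and degenerate fits yield NaN.
    """
    if family == "logistic" and not isinstance(D.outcome, BinaryOutcome):
        raise DataError("logistic screening requires a binary outcome")
    if family == "cox" and not isinstance(D.outcome, SurvivalOutcome):
        raise DataError("cox screening requires a survival outcome")
    if family not in ("logistic", "cox"):
        raise ValueError(f"unknown family {family!r}")

    clinical = None
    if include_clinical and D.clinical_covariates is not None:
        clinical = D.clinical_covariates.to_numpy(dtype=float)

    X = D.X.values
    p = np.full(D.X.n_features, np.nan)
    for j in range(D.X.n_features):
        x = X[:, j]
        if np.ptp(x) == 0:
            continue  # zero variance: no information, flagged
        if family == "logistic":
            p[j] = _logistic_univariate_p(x, D.outcome.y, clinical)
        else:
            p[j] = _cox_univariate_p(x, D.outcome.time, D.outcome.event, clinical)
    return p


def bh_select(
    p_values: np.ndarray,
    q: float = 0.05,
    feature_ids=None,
) -> ScreenResult:
    """Benjamini-Hochberg step-up selection at FDR level q.

    Sort the m non-missing p-values ascending, find the largest rank i with
    p_(i) <= i*q/m and select every feature with p <= p_(i); adjusted
    q-values are the monotone-enforced minima of m*p_(i)/i, capped at 1.
    """
    p_values = np.asarray(p_values, dtype=float)
    if not 0 < q < 1:
        raise ValueError(f"q must be in (0, 1), got {q}")
    valid = ~np.isnan(p_values)
    if ((p_values[valid] < 0) | (p_values[valid] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if feature_ids is None:
        feature_ids = [f"f{j}" for j in range(len(p_values))]

    qvals = np.full(len(p_values), np.nan)
    selected = np.zeros(len(p_values), dtype=bool)
    if valid.any():
        rej, q_adj, _, _ = multipletests(p_values[valid], alpha=q, method="fdr_bh")
        qvals[valid] = q_adj
        selected[valid] = rej
    return ScreenResult(
        feature_ids=list(feature_ids),
        p_values=p_values,
        q_values=qvals,
        selected=selected,
        q_threshold=q,
    )


def screen(
    D: AnalysisDataset,
    family: str,
    q: float = 0.05,
    include_clinical: bool = False,
) -> ScreenResult:
    """Univariate fits followed by BH selection — the optional first step of
    the pipeline."""
    p = univariate_pvalues(D, family, include_clinical=include_clinical)
    return bh_select(p, q=q, feature_ids=D.X.feature_ids)
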