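"""K-fold cross-validation of the configured pipeline and its metrics.

Prediction power is estimated by refitting the ENTIRE pipeline — screening
(if enabled), tuning and penalized fitting — inside each training fold and
scoring the held-out samples, so no information leaks from test to train.
Binary models report accuracy, sensitivity, specificity and AUC; survival
models report Harrell's C-index.  AUC is stored in [0, 1] and multiplied by
100 only for display.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional, Union

import numpy as np
from lifelines.utils import concordance_index
from sklearn.metrics import roc_auc_score

from . import penalized as pen
from .dataio import (
    AnalysisDataset,
    BinaryOutcome,
    DataError,
    MolecularMatrix,
)
from .penalized import FitResult, PenaltySpec
from .screen import screen as run_screen


class MetricError(ValueError):
    pass


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney AUC: fraction of (positive, negative) pairs ranked
    correctly, ties counting one half."""
    labels = np.asarray(labels, dtype=float)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(labels)) < 2:
        raise MetricError("AUC needs both classes present")
    return float(roc_auc_score(labels, scores))


def confusion_metrics(
    scores: np.ndarray,
    labels: np.ndarray,
    threshold: float = 0.5,
    threshold_scale: Literal["probability", "linear_predictor"] = "probability",
) -> tuple[float, float, float]:
    """(accuracy, sensitivity, specificity) at ``score > threshold``.

    ``threshold_scale`` is declarative only — the caller must supply scores
    on that same scale; classification uses a strict inequality.  A class
    absent from ``labels`` makes the corresponding rate NaN.
    """
    if not np.isfinite(threshold):
        raise MetricError("threshold must be finite")
    labels = np.asarray(labels, dtype=float)
    pred = (np.asarray(scores, dtype=float) > threshold).astype(float)
    tp = float(np.sum((pred == 1) & (labels == 1)))
    tn = float(np.sum((pred == 0) & (labels == 0)))
    fp = float(np.sum((pred == 1) & (labels == 0)))
    fn = float(np.sum((pred == 0) & (labels == 1)))
    n_pos, n_neg = tp + fn, tn + fp
    accuracy = (tp + tn) / len(labels)
    sensitivity = tp / n_pos if n_pos > 0 else np.nan
    specificity = tn / n_neg if n_neg > 0 else np.nan
    return accuracy, sensitivity, specificity


def c_index(times: np.ndarray, events: np.ndarray, risk_scores: np.ndarray) -> float:
    """Harrell's concordance over comparable pairs.

    Subject i anchors a comparable pair with j when i has an observed event
    and either t_i < t_j, or t_i = t_j with j censored; the pair is
    concordant when the earlier subject carries the higher risk score, and
    tied risks count one half.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=float)
    risk_scores = np.asarray(risk_scores, dtype=float)
    # lifelines scores concordance of *survival-time* predictions, so pass
    # the negated risk (higher risk = shorter predicted survival)
    try:
        return float(concordance_index(times, -risk_scores, events))
    except ZeroDivisionError:
        raise MetricError("no comparable pairs") from None


@dataclass
class PipelineConfig:
    """What to run inside each fold: optional FDR screen, then a penalized fit."""

    family: Literal["logistic", "cox"]
    penalty: Literal["ridge", "lasso", "adaptive_lasso"] = "lasso"
    lambda_: Union[float, str] = "cv"
    fdr_q: Optional[float] = None  # None disables screening
    n_folds_tune: int = 10
    threshold: float = 0.5
    threshold_scale: Literal["probability", "linear_predictor"] = "probability"


@dataclass
class CVReport:
    family: str
    n_folds: int
    per_fold: list[dict]
    aggregate: dict
    fold_assignment_seed: int
    performed: bool = True

    def display(self) -> dict:
        """Aggregate metrics with AUC scaled x100, as conventionally printed."""
        out = dict(self.aggregate)
        if "auc" in out and out["auc"] is not None and np.isfinite(out["auc"]):
            out["auc"] = out["auc"] * 100.0
        return out


def fit_pipeline(D: AnalysisDataset, config: PipelineConfig, seed: int = 0) -> FitResult:
    """Run screen (optional) -> penalized fit (with adaptive refit when asked)
    on one dataset."""
    work = D
    if config.fdr_q is not None:
        sr = run_screen(D, config.family, q=config.fdr_q)
        if not sr.selected.any():
            raise pen.NothingToRefitError("no features passed FDR screening")
        keep = np.asarray(sr.selected)
        M = MolecularMatrix(
            D.X.sample_ids,
            [f for f, k in zip(D.X.feature_ids, keep) if k],
            D.X.values[:, keep],
            D.X.kind,
        )
        work = AnalysisDataset(M, D.outcome, D.clinical_covariates)

    if config.penalty == "adaptive_lasso":
        first = pen.fit(
            config.family, work, PenaltySpec("lasso", "cv"),
            seed=seed, n_folds_tune=config.n_folds_tune,
        )
        spec = pen.adaptive_weights(first)
        if config.lambda_ != "cv":
            spec.lambda_ = config.lambda_
        return pen.fit(config.family, work, spec, seed=seed, n_folds_tune=config.n_folds_tune)
    spec = PenaltySpec(config.penalty, config.lambda_)
    return pen.fit(config.family, work, spec, seed=seed, n_folds_tune=config.n_folds_tune)


def predict_scores(
    fit: FitResult, D: AnalysisDataset, scale: str = "linear_predictor"
) -> np.ndarray:
    """Linear predictor (or predicted probability, logistic) for each sample,
    mapping the fit's features into the dataset's columns by ID."""
    pos = {f: j for j, f in enumerate(D.X.feature_ids)}
    eta = np.full(D.n_samples, fit.intercept, dtype=float)
    for f, b in zip(fit.feature_ids, fit.coefficients):
        if b != 0.0:
            if f not in pos:
                raise DataError(f"dataset lacks model feature {f!r}")
            eta += b * D.X.values[:, pos[f]]
    if fit.clinical_coefficients:
        for c, b in fit.clinical_coefficients.items():
            eta += b * D.clinical_covariates[c].to_numpy(dtype=float)
    if scale == "probability":
        return 1.0 / (1.0 + np.exp(-eta))
    return eta


def kfold_cv(
    D: AnalysisDataset,
    config: PipelineConfig,
    n_folds: int = 5,
    seed: int = 0,
) -> CVReport:
    """Estimate prediction power by stratified K-fold cross-validation.

    ``n_folds = 1`` is the documented no-op: the report comes back flagged
    as not performed.  A fold whose training part degenerates after
    stratification (single class / no events) raises an error naming it.
    """
    if n_folds == 1:
        return CVReport(
            family=config.family, n_folds=1, per_fold=[], aggregate={},
            fold_assignment_seed=seed, performed=False,
        )
    if not 2 <= n_folds <= D.n_samples:
        raise ValueError("n_folds must be 1 or in [2, n_samples]")
    assignment = pen.cv_folds(D, n_folds, seed)
    per_fold = []
    for k in range(n_folds):
        train = assignment != k
        test = ~train
        D_tr = pen._subset_dataset(D, train)
        D_te = pen._subset_dataset(D, test)
        if isinstance(D.outcome, BinaryOutcome):
            if len(np.unique(D_tr.outcome.y)) < 2:
                raise DataError(f"fold {k}: training data has a single outcome class")
        try:
            f = fit_pipeline(D_tr, config, seed=seed)
        except pen.NothingToRefitError:
            # nothing survived screening/selection in this fold: constant score
            f = None
        metrics: dict = {"fold": k, "n_test": int(test.sum())}
        if config.family == "logistic":
            scores = (
                predict_scores(f, D_te, scale=config.threshold_scale)
                if f is not None
                else np.zeros(D_te.n_samples)
            )
            y_te = D_te.outcome.y
            acc, sens, spec = confusion_metrics(
                scores, y_te, config.threshold, config.threshold_scale
            )
            metrics.update(accuracy=acc, sensitivity=sens, specificity=spec)
            metrics["auc"] = auc(scores, y_te) if len(np.unique(y_te)) == 2 else np.nan
        else:
            scores = (
                predict_scores(f, D_te) if f is not None else np.zeros(D_te.n_samples)
            )
            try:
                metrics["c_index"] = c_index(D_te.outcome.time, D_te.outcome.event, scores)
            except MetricError:
                metrics["c_index"] = np.nan
        per_fold.append(metrics)

    keys = [k for k in per_fold[0] if k not in ("fold", "n_test")]
    aggregate = {k: float(np.nanmean([m[k] for m in per_fold])) for k in keys}
    return CVReport(
        family=config.family,
        n_folds=n_folds,
        per_fold=per_fold,
        aggregate=aggregate,
        fold_assignment_seed=seed,
    )
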