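"""Multivariate model reports: effect sizes, scoring and classification.

Selected features are reported with their coefficient and its
exponentiated effect size — a hazard ratio for Cox models, an odds ratio
for logistic models — rounded to three decimals for display while full
precision is kept internally.  The report doubles as a serializable
prediction model: ``linear_predictor`` scores a new covariate row and
``classify`` thresholds the score (strictly greater-than) on either the
probability or the linear-predictor scale.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Union

import numpy as np
import pandas as pd

from .penalized import FitResult


@dataclass
class ModelReport:
    """Per-feature effect sizes plus everything needed to score new samples."""

    family: str
    feature_ids: list[str]
    coefficients: np.ndarray
    effect_sizes: np.ndarray
    intercept: float  # 0.0 and inapplicable for Cox
    p_values: Optional[np.ndarray] = None
    threshold: float = 0.5
    threshold_scale: str = "probability"

    @property
    def effect_label(self) -> str:
        return "hazard_ratio" if self.family == "cox" else "odds_ratio"

    @property
    def intercept_applicable(self) -> bool:
        return self.family != "cox"

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "feature_id": self.feature_ids,
                "coefficient": np.round(self.coefficients, 3),
                self.effect_label: np.round(self.effect_sizes, 3),
            }
        )
        if self.p_values is not None:
            df["p_value"] = self.p_values
        return df

    def to_json(self, path: Union[str, Path, None] = None) -> str:
        payload = {
            "family": self.family,
            "intercept": self.intercept,
            "coefficients": dict(zip(self.feature_ids, map(float, self.coefficients))),
            "threshold": self.threshold,
            "threshold_scale": self.threshold_scale,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: Union[str, Path]) -> "ModelReport":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        payload = json.loads(text)
        coefs = np.array(list(payload["coefficients"].values()), dtype=float)
        return cls(
            family=payload["family"],
            feature_ids=list(payload["coefficients"].keys()),
            coefficients=coefs,
            effect_sizes=np.exp(coefs),
            intercept=float(payload["intercept"]),
            threshold=float(payload["threshold"]),
            threshold_scale=payload["threshold_scale"],
        )


def effect_sizes(
    fit: FitResult,
    p_values: Optional[Mapping[str, float]] = None,
    threshold: float = 0.5,
    threshold_scale: str = "probability",
    include_inactive: bool = False,
) -> ModelReport:
    """Build the model report: effect = exp(coefficient) per active feature."""
    if include_inactive:
        ids = list(fit.feature_ids)
        coefs = np.asarray(fit.coefficients, dtype=float)
    else:
        ids = fit.active_set
        coefs = np.array([fit.coefficient_of(f) for f in ids])
    pv = None
    if p_values is not None:
        pv = np.array([p_values.get(f, np.nan) for f in ids])
    return ModelReport(
        family=fit.family,
        feature_ids=ids,
        coefficients=coefs,
        effect_sizes=np.exp(coefs),
        intercept=fit.intercept if fit.family != "cox" else 0.0,
        p_values=pv,
        threshold=threshold,
        threshold_scale=threshold_scale,
    )


def linear_predictor(model: ModelReport, x_new: Mapping[str, float]) -> float:
    """intercept + sum_j coefficient_j * x_j — the log-odds (logistic) or
    log-relative-hazard (Cox) of a new covariate row."""
    missing = [f for f in model.feature_ids if f not in x_new]
    if missing:
        raise KeyError(f"x_new lacks model features: {missing}")
    s = model.intercept
    for f, b in zip(model.feature_ids, model.coefficients):
        s += b * float(x_new[f])
    return float(s)


def classify(
    model: ModelReport,
    x_new: Mapping[str, float],
    threshold: Optional[float] = None,
    scale: Optional[str] = None,
) -> int:
    """1 iff the sample's score strictly exceeds the threshold on the
    declared scale (``probability`` applies expit to the linear predictor)."""
    threshold = model.threshold if threshold is None else threshold
    scale = model.threshold_scale if scale is None else scale
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    if scale not in ("probability", "linear_predictor"):
        raise ValueError(f"unknown threshold scale {scale!r}")
    eta = linear_predictor(model, x_new)
    score = 1.0 / (1.0 + math.exp(-eta)) if scale == "probability" else eta
    return int(score > threshold)
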