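"""Seeded synthetic molecular datasets with known ground truth.

The generator emulates the two covariate shapes the pipeline consumes —
sparse 0/1 mutation indicators with per-gene prevalence of a few percent,
and Gaussian expression Z-scores (so that roughly 4.6% of entries exceed
|Z| > 2, the usual abnormality call) — and two outcome mechanisms: a sparse
logistic model for binary endpoints and an exponential-baseline proportional
hazards model with independent exponential censoring for survival endpoints.
Ground truth (support, coefficients, achieved censoring) is always returned
alongside so tests never have to re-derive it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .dataio import (
    AnalysisDataset,
    BinaryOutcome,
    DataError,
    MolecularMatrix,
    SurvivalOutcome,
    write_matrix,
)

FeatureModel = Literal["binary_prevalence", "gaussian_zscore"]
OutcomeModel = Literal["logistic", "cox"]


@dataclass
class SimulationSpec:
    """Everything needed to draw one dataset reproducibly.

    Defaults reflect the data shapes of tumor molecular-profiling cohorts:
    mutation prevalences drawn uniformly in 1-10% per gene, unit-scale
    Z-scores, exponential baseline hazard 0.1 (median survival ~ 6.9 time
    units at the null) and censoring rate 0.04 (roughly 30% censored under
    the null model).
    """

    n_samples: int = 200
    n_features: int = 50
    true_support: tuple[int, ...] = ()
    true_coefficients: tuple[float, ...] = ()
    feature_model: FeatureModel = "gaussian_zscore"
    prevalence: Union[float, Sequence[float], None] = None  # binary model only
    outcome_model: OutcomeModel = "logistic"
    logistic_intercept: float = 0.0
    baseline_hazard: float = 0.1
    censoring_rate: float = 0.04
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.true_support) != len(self.true_coefficients):
            raise ValueError("true_support and true_coefficients must align")
        if len(set(self.true_support)) != len(self.true_support):
            raise ValueError("duplicate indices in true_support")
        if any(j < 0 or j >= self.n_features for j in self.true_support):
            raise ValueError("true_support index out of range")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be > 0")
        if self.censoring_rate < 0:
            raise ValueError("censoring_rate must be >= 0")

    def prevalences(self, rng: np.random.Generator) -> np.ndarray:
        if self.prevalence is None:
            pi = rng.uniform(0.01, 0.10, size=self.n_features)
        elif np.isscalar(self.prevalence):
            pi = np.full(self.n_features, float(self.prevalence))
        else:
            pi = np.asarray(self.prevalence, dtype=float)
            if len(pi) != self.n_features:
                raise ValueError("per-feature prevalence length mismatch")
        if not ((pi > 0) & (pi < 1)).all():
            raise ValueError("prevalences must lie in (0, 1)")
        return pi


@dataclass
class GroundTruth:
    support: tuple[int, ...]
    support_ids: tuple[str, ...]
    coefficients: tuple[float, ...]
    censoring_fraction: Optional[float]
    seed: int

    def to_json(self) -> str:
        return json.dumps(
            {
                "support": list(self.support),
                "support_ids": list(self.support_ids),
                "coefficients": list(self.coefficients),
                "censoring_fraction": self.censoring_fraction,
                "seed": self.seed,
            },
            indent=2,
        )


def simulate_dataset(spec: SimulationSpec) -> tuple[AnalysisDataset, GroundTruth]:
    """Draw one dataset from the spec; bit-identical for a fixed seed."""
    rng = np.random.default_rng(spec.seed)
    n, p = spec.n_samples, spec.n_features
    sample_ids = [f"S{i:04d}" for i in range(n)]
    feature_ids = [f"G{j:04d}" for j in range(p)]

    if spec.feature_model == "binary_prevalence":
        pi = spec.prevalences(rng)
        X = (rng.random((n, p)) < pi).astype(float)
        kind = "binary_indicator"
    else:
        X = rng.standard_normal((n, p))
        kind = "continuous_zscore"

    beta = np.zeros(p)
    for j, b in zip(spec.true_support, spec.true_coefficients):
        beta[j] = b
    eta = X @ beta

    censoring_fraction: Optional[float] = None
    if spec.outcome_model == "logistic":
        prob = 1.0 / (1.0 + np.exp(-(spec.logistic_intercept + eta)))
        y = (rng.random(n) < prob).astype(float)
        if y.min() == y.max():
            raise DataError(
                "simulated binary outcome degenerate (single class); "
                "adjust intercept/effects or seed"
            )
        outcome: Union[BinaryOutcome, SurvivalOutcome] = BinaryOutcome(sample_ids, y)
    elif spec.outcome_model == "cox":
        # exponential PH: T ~ Exp(h0 * exp(eta)); C ~ Exp(censoring_rate)
        hazard = spec.baseline_hazard * np.exp(eta)
        T = rng.exponential(1.0 / hazard)
        if spec.censoring_rate > 0:
            C = rng.exponential(1.0 / spec.censoring_rate, size=n)
        else:
            C = np.full(n, np.inf)
        time = np.minimum(T, C)
        event = (T <= C).astype(float)
        if event.sum() < 1:
            raise DataError("no events under this spec; lower the censoring rate")
        outcome = SurvivalOutcome(sample_ids, time, event)
        censoring_fraction = float(1.0 - event.mean())
    else:
        raise ValueError(f"unknown outcome_model {spec.outcome_model!r}")

    M = MolecularMatrix(sample_ids, feature_ids, X, kind)
    truth = GroundTruth(
        support=tuple(spec.true_support),
        support_ids=tuple(feature_ids[j] for j in spec.true_support),
        coefficients=tuple(spec.true_coefficients),
        censoring_fraction=censoring_fraction,
        seed=spec.seed,
    )
    return AnalysisDataset(M, outcome), truth


def achieved_censoring(dataset: AnalysisDataset) -> float:
    """Fraction of censored (event = 0) samples."""
    if not isinstance(dataset.outcome, SurvivalOutcome):
        raise DataError("achieved_censoring requires a survival outcome")
    return float(1.0 - dataset.outcome.event.mean())


def write_dataset(
    dataset: AnalysisDataset, truth: GroundTruth, out_dir: Union[str, Path]
) -> dict[str, Path]:
    """Emit the standard text artifacts: matrix TSV, clinical TSV, truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    matrix_path = out / "matrix.tsv"
    clinical_path = out / "clinical.tsv"
    truth_path = out / "ground_truth.json"
    write_matrix(dataset.X, matrix_path)
    if isinstance(dataset.outcome, BinaryOutcome):
        clin = pd.DataFrame(
            {"sample_id": dataset.X.sample_ids, "status": dataset.outcome.y.astype(int)}
        )
    else:
        clin = pd.DataFrame(
            {
                "sample_id": dataset.X.sample_ids,
                "time": dataset.outcome.time,
                "event": dataset.outcome.event.astype(int),
            }
        )
    clin.to_csv(clinical_path, sep="\t", index=False)
    truth_path.write_text(truth.to_json())
    return {"matrix": matrix_path, "clinical": clinical_path, "truth": truth_path}
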