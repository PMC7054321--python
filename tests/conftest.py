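import numpy as np
import pytest

from penomics.dataio import (
    AnalysisDataset,
    BinaryOutcome,
    MolecularMatrix,
    SurvivalOutcome,
)
from penomics.simulate import SimulationSpec, simulate_dataset


@pytest.fixture(scope="session")
def logistic_dataset():
    """Moderate logistic dataset with two strong signals."""
    D, truth = simulate_dataset(
        SimulationSpec(
            n_samples=150,
            n_features=12,
            true_support=(0, 1),
            true_coefficients=(1.5, -1.5),
            seed=42,
        )
    )
    return D, truth


@pytest.fixture(scope="session")
def cox_dataset():
    """Moderate survival dataset with one strong signal and ~25% censoring."""
    D, truth = simulate_dataset(
        SimulationSpec(
            n_samples=150,
            n_features=10,
            true_support=(0,),
            true_coefficients=(1.5,),
            outcome_model="cox",
            seed=7,
        )
    )
    return D, truth


def standardized_columns(rng, n, p):
    """Gaussian design with exactly zero mean and unit (1/n) variance per
    column, so the solver's internal standardization is the identity and
    brute-force oracles can work with the written objective directly."""
    X = rng.standard_normal((n, p))
    X = X - X.mean(axis=0)
    X = X / X.std(axis=0)
    return X


def tiny_dataset(X, y=None, time=None, event=None):
    ids = [f"s{i}" for i in range(X.shape[0])]
    fids = [f"g{j}" for j in range(X.shape[1])]
    M = MolecularMatrix(ids, fids, X, "continuous_zscore")
    if y is not None:
        return AnalysisDataset(M, BinaryOutcome(ids, y))
    return AnalysisDataset(M, SurvivalOutcome(ids, time, event))
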