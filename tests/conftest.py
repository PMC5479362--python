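import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", deadline=None, derandomize=True)
settings.load_profile("deterministic")

from copulacd import (CorrelationMatrix, DAG, ExperimentConfig, MixedDataset,
                      run_experiment)

# benchmark DAGs used by the oracle-recovery tests: name -> (nodes, edges, coefs)
BENCHMARK_DAGS = {
    "chain3": ("ABC", [("A", "B"), ("B", "C")]),
    "collider3": ("ABC", [("A", "B"), ("C", "B")]),
    "fork3": ("ABC", [("B", "A"), ("B", "C")]),
    "chain4": ("ABCD", [("A", "B"), ("B", "C"), ("C", "D")]),
    "diamond4": ("ABCD", [("A", "B"), ("A", "C"), ("B", "D"), ("C", "D")]),
    "collider4": ("ABCD", [("A", "B"), ("C", "B"), ("C", "D")]),
}


def linear_sem_correlation(dag: DAG, coef: float = 0.6) -> CorrelationMatrix:
    """Exact correlation matrix of a linear-Gaussian SEM on ``dag``.

    Every edge gets weight ``coef``; exogenous noise has unit variance.
    """
    nodes = dag.nodes
    idx = {v: i for i, v in enumerate(nodes)}
    d = len(nodes)
    B = np.zeros((d, d))
    for a, b in dag.edges:
        B[idx[b], idx[a]] = coef
    T = np.linalg.inv(np.eye(d) - B)
    cov = T @ T.T
    sd = np.sqrt(np.diag(cov))
    corr = cov / np.outer(sd, sd)
    np.fill_diagonal(corr, 1.0)
    return CorrelationMatrix(corr, nodes, 10_000)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_mixed_dataset():
    frame = pd.DataFrame({
        "G": [0, 1, 1, 0, 1, 0, 1, 1],
        "X": [0.3, np.nan, 1.2, -0.5, 2.2, 0.1, -1.0, 0.7],
        "Y": [1.0, 2.0, np.nan, 0.0, 3.0, -1.0, 0.5, 1.5],
    })
    return MixedDataset(frame, {"G": "discrete", "X": "continuous",
                                "Y": "continuous"})


# ---------------------------------------------------------------------------
# the benchmark grid shared by the estimator-ordering and sample-size-trend
# acceptance tests (heavy; computed once per session)
# ---------------------------------------------------------------------------

GRID_SEED = 20
GRID_REPS = 50


@pytest.fixture(scope="session")
def missing_data_grid():
    """High-correlation regime, 30% MCAR missingness, n = 100..1000,
    EM vs the three Spearman alternatives, 50 replicates per cell (BCCD)."""
    config = ExperimentConfig(
        regimes=("high",), missing_rates=(0.30,),
        sample_sizes=(100, 250, 500, 1000), repetitions=GRID_REPS,
        estimators=("em", "spearman-mean", "spearman-listwise",
                    "spearman-pairwise"),
        algorithms=("bccd",), base_seed=GRID_SEED)
    return run_experiment(config)


@pytest.fixture(scope="session")
def complete_data_grid():
    """High-correlation regime, no missing values, n = 1000: EM, unadjusted
    and adjusted pairwise Spearman, 50 replicates per cell (BCCD)."""
    config = ExperimentConfig(
        regimes=("high",), missing_rates=(0.0,), sample_sizes=(1000,),
        repetitions=GRID_REPS, estimators=None,  # per-rate default trio
        algorithms=("bccd",), base_seed=GRID_SEED)
    return run_experiment(config)
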