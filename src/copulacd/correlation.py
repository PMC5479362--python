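"""Correlation estimation under missing data.

The preferred estimator is maximum likelihood for a multivariate Gaussian
under missing-at-random data, computed with EM on the normal-score
transformed table and normalised to unit diagonal.  The comparison
estimators — pairwise Spearman (optionally with the 2*sin(pi*rho/6)
Gaussian-consistency adjustment), listwise-deletion Spearman and
mean-imputation Spearman — implicitly assume MCAR and may produce indefinite
matrices, which are then projected to the nearest positive-definite
correlation matrix.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.correlation_tools import corr_nearest

from .data import MixedDataset, TransformedDataset

__all__ = [
    "CorrelationMatrix",
    "EMResult",
    "em_correlation",
    "spearman_pairwise",
    "listwise_correlation",
    "mean_impute_correlation",
    "nearest_positive_definite",
]

logger = logging.getLogger(__name__)

PD_FLOOR = 1e-8  # smallest admissible eigenvalue after projection
SYM_TOL = 1e-10


@dataclass(frozen=True)
class CorrelationMatrix:
    """Correlation matrix plus the effective sample size used to score it."""

    values: np.ndarray
    names: tuple[str, ...]
    sample_size: int
    estimator: str = "unknown"

    def __init__(self, values, names, sample_size, estimator="unknown"):
        values = np.asarray(values, dtype=float)
        names = tuple(names)
        if values.shape != (len(names), len(names)):
            raise ValueError("matrix shape does not match variable names")
        if not np.allclose(values, values.T, atol=SYM_TOL):
            raise ValueError("correlation matrix is not symmetric")
        if not np.allclose(np.diag(values), 1.0, atol=1e-8):
            raise ValueError("correlation matrix must have unit diagonal")
        values = (values + values.T) / 2.0
        np.fill_diagonal(values, 1.0)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "names", names)
        object.__setattr__(self, "sample_size", int(sample_size))
        object.__setattr__(self, "estimator", str(estimator))

    @property
    def d(self) -> int:
        return len(self.names)

    def min_eigenvalue(self) -> float:
        return float(np.linalg.eigvalsh(self.values)[0])

    def is_positive_definite(self, floor: float = 0.0) -> bool:
        return self.min_eigenvalue() > floor

    def submatrix(self, subset) -> np.ndarray:
        idx = [self.names.index(v) for v in subset]
        return self.values[np.ix_(idx, idx)]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.names, columns=self.names)

    def to_csv(self, path, sidecar: bool = True) -> None:
        path = Path(path)
        self.to_dataframe().to_csv(path)
        if sidecar:
            meta = {"estimator": self.estimator, "sample_size": self.sample_size}
            path.with_suffix(path.suffix + ".json").write_text(
                json.dumps(meta, indent=1) + "\n")

    @classmethod
    def from_csv(cls, path) -> "CorrelationMatrix":
        path = Path(path)
        df = pd.read_csv(path, index_col=0)
        sidecar = path.with_suffix(path.suffix + ".json")
        estimator, m = "unknown", 0
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
            estimator = meta.get("estimator", "unknown")
            m = int(meta.get("sample_size", 0))
        return cls(df.to_numpy(), tuple(df.columns), m, estimator)


@dataclass(frozen=True)
class EMResult:
    """Outcome of the EM covariance estimation."""

    correlation: CorrelationMatrix
    iterations: int
    loglik_trace: np.ndarray
    converged: bool


def _as_matrix(data) -> tuple[np.ndarray, tuple[str, ...]]:
    if isinstance(data, (MixedDataset, TransformedDataset)):
        return data.values, data.names
    if isinstance(data, pd.DataFrame):
        return data.to_numpy(dtype=float), tuple(map(str, data.columns))
    arr = np.asarray(data, dtype=float)
    return arr, tuple(f"X{i}" for i in range(arr.shape[1]))


def _drop_empty_rows(x: np.ndarray) -> np.ndarray:
    keep = ~np.all(np.isnan(x), axis=1)
    dropped = int((~keep).sum())
    if dropped:
        logger.info("dropping %d all-missing rows", dropped)
    return x[keep]


def effective_sample_size(data) -> int:
    """Rows retained after dropping all-missing rows (estimator-independent)."""
    x, _ = _as_matrix(data)
    return int((~np.all(np.isnan(x), axis=1)).sum())


# ---------------------------------------------------------------------------
# EM
# ---------------------------------------------------------------------------


def em_correlation(data, tol: float = 1e-6, max_iter: int = 500) -> EMResult:
    """Gaussian MLE of the correlation matrix under MAR missingness, via EM.

    E-step: per missing pattern, conditional means and covariances of the
    missing block given the observed block.  M-step: pooled first and second
    moments.  The mean vector is estimated jointly but only the correlation is
    returned.  The observed-data log-likelihood is tracked per iteration and
    must be non-decreasing (classic EM guarantee).

    Convergence: relative log-likelihood change below ``tol``.  Non-convergence
    within ``max_iter`` is flagged on the result, not raised.
    """
    x, names = _as_matrix(data)
    x = _drop_empty_rows(x)
    n, d = x.shape
    mask = np.isnan(x)
    observed_per_var = (~mask).sum(axis=0)
    if np.any(observed_per_var < 2):
        bad = [names[i] for i in np.where(observed_per_var < 2)[0]]
        raise ValueError(f"variables observed fewer than twice: {bad}")

    # init: column means / mean-imputed covariance
    mu = np.nanmean(x, axis=0)
    x0 = np.where(mask, mu, x)
    sigma = np.cov(x0, rowvar=False, bias=True)
    # guard against an initially singular start
    w = np.linalg.eigvalsh(sigma)
    if w[0] <= 1e-10:
        sigma += (1e-10 - w[0] + 1e-12) * np.eye(d)

    # group rows by missing pattern
    patterns, inverse = np.unique(mask, axis=0, return_inverse=True)
    groups = [np.where(inverse == k)[0] for k in range(len(patterns))]

    trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        s1 = np.zeros(d)
        s2 = np.zeros((d, d))
        loglik = 0.0
        for pat, rows in zip(patterns, groups):
            o = np.where(~pat)[0]
            m = np.where(pat)[0]
            xo = x[np.ix_(rows, o)]
            soo = sigma[np.ix_(o, o)]
            try:
                cho = np.linalg.cholesky(soo)
            except np.linalg.LinAlgError:
                soo = soo + 1e-10 * np.eye(len(o))
                cho = np.linalg.cholesky(soo)
            dev = xo - mu[o]
            solved = np.linalg.solve(cho, dev.T)  # L^{-1} dev^T
            loglik += (-0.5 * len(rows) * (len(o) * np.log(2 * np.pi)
                                           + 2 * np.log(np.diag(cho)).sum())
                       - 0.5 * np.einsum("ij,ij->", solved, solved))
            xhat = np.array(x[rows], copy=True)
            if m.size:
                smo = sigma[np.ix_(m, o)]
                beta = np.linalg.solve(soo, smo.T).T          # m x o
                cond_mean = mu[m] + dev @ beta.T
                xhat[:, m] = cond_mean
                cond_cov = sigma[np.ix_(m, m)] - beta @ smo.T
                s2[np.ix_(m, m)] += len(rows) * cond_cov
            s1 += xhat.sum(axis=0)
            s2 += xhat.T @ xhat
        trace.append(loglik)
        mu_new = s1 / n
        sigma_new = s2 / n - np.outer(mu_new, mu_new)
        mu, sigma = mu_new, (sigma_new + sigma_new.T) / 2.0
        if len(trace) >= 2:
            prev, cur = trace[-2], trace[-1]
            if cur + 1e-9 * (abs(prev) + 1.0) < prev:
                raise AssertionError(
                    "EM observed-data log-likelihood decreased "
                    f"({prev} -> {cur}); this indicates a bug")
            if abs(cur - prev) < tol * (abs(prev) + 1.0):
                converged = True
                break
    if not converged:
        logger.warning("EM did not converge in %d iterations", max_iter)

    sd = np.sqrt(np.diag(sigma))
    corr = sigma / np.outer(sd, sd)
    np.fill_diagonal(corr, 1.0)
    corr = (corr + corr.T) / 2.0
    # numerical safety net: floor the spectrum
    if np.linalg.eigvalsh(corr)[0] <= PD_FLOOR:
        corr = _project_pd(corr, PD_FLOOR)
    cm = CorrelationMatrix(corr, names, n, "em")
    return EMResult(cm, it, np.asarray(trace), converged)


# ---------------------------------------------------------------------------
# Spearman-based comparison estimators
# ---------------------------------------------------------------------------


def _spearman_frame(frame: pd.DataFrame, min_periods: int = 3) -> np.ndarray:
    corr = frame.corr(method="spearman", min_periods=min_periods).to_numpy()
    if np.isnan(corr).any():
        warnings.warn(
            "variable pairs with fewer than "
            f"{min_periods} complete cases (or constant ranks); "
            "their correlation entries are set to 0", stacklevel=3)
        corr = np.where(np.isnan(corr), 0.0, corr)
    np.fill_diagonal(corr, 1.0)
    return corr


def _to_frame(data) -> pd.DataFrame:
    if isinstance(data, (MixedDataset, TransformedDataset)):
        return data.frame
    if isinstance(data, pd.DataFrame):
        return data
    x, names = _as_matrix(data)
    return pd.DataFrame(x, columns=names)


def spearman_adjustment(rho):
    """Gaussian-consistency map for Spearman's rho: S = 2*sin(pi*rho/6)."""
    return 2.0 * np.sin(np.pi * np.asarray(rho) / 6.0)


def spearman_pairwise(data, adjusted: bool = False,
                      min_periods: int = 3) -> CorrelationMatrix:
    """Pairwise-complete Spearman correlation, optionally adjusted.

    Each entry uses the rows where both variables are observed.  The result is
    not guaranteed positive (semi)definite; see
    :func:`nearest_positive_definite`.
    """
    frame = _to_frame(data)
    corr = _spearman_frame(frame, min_periods)
    tag = "spearman-adjusted" if adjusted else "spearman-pairwise"
    if adjusted:
        corr = spearman_adjustment(corr)
        np.fill_diagonal(corr, 1.0)
    m = effective_sample_size(data)
    return CorrelationMatrix(corr, frame.columns, m, tag)


def listwise_correlation(data, min_rows: int = 3) -> CorrelationMatrix:
    """Spearman correlation over rows with no missing entry."""
    frame = _to_frame(data)
    complete = frame.dropna()
    if complete.shape[0] < min_rows:
        raise ValueError(
            f"only {complete.shape[0]} complete rows; need at least {min_rows}")
    corr = _spearman_frame(complete, min_periods=min_rows)
    m = effective_sample_size(data)
    return CorrelationMatrix(corr, frame.columns, m, "spearman-listwise")


def mean_impute_correlation(data) -> CorrelationMatrix:
    """Spearman correlation after imputing each missing cell at its column mean."""
    frame = _to_frame(data)
    if frame.isna().all().any():
        bad = list(frame.columns[frame.isna().all()])
        raise ValueError(f"all-missing column(s): {bad}")
    filled = frame.fillna(frame.mean())
    corr = _spearman_frame(filled, min_periods=3)
    m = effective_sample_size(data)
    return CorrelationMatrix(corr, frame.columns, m, "spearman-mean")


# ---------------------------------------------------------------------------
# Nearest positive-definite projection
# ---------------------------------------------------------------------------


def _project_pd(matrix: np.ndarray, floor: float) -> np.ndarray:
    with warnings.catch_warnings():
        # boundary cases legitimately stop at the iteration cap; the
        # eigenvalue floor below guarantees the constraints regardless
        warnings.simplefilter("ignore")
        out = corr_nearest(matrix, threshold=floor, n_fact=1000)
    out = np.asarray((out + out.T) / 2.0)
    np.fill_diagonal(out, 1.0)
    # corr_nearest clips eigenvalues; re-floor if normalisation nudged them
    w, v = np.linalg.eigh(out)
    if w[0] < floor:
        w = np.clip(w, floor, None)
        out = (v * w) @ v.T
        sd = np.sqrt(np.diag(out))
        out = out / np.outer(sd, sd)
        np.fill_diagonal(out, 1.0)
    return out


def nearest_positive_definite(matrix, floor: float = PD_FLOOR,
                              sample_size: int | None = None,
                              ) -> CorrelationMatrix:
    """Project a symmetric matrix to the nearest correlation matrix.

    Alternating-projection (Higham-style) search for the closest matrix in
    Frobenius norm with unit diagonal and eigenvalues >= ``floor``.  Inputs
    already satisfying the constraints are returned unchanged up to tolerance.
    """
    if isinstance(matrix, CorrelationMatrix):
        names, m = matrix.names, matrix.sample_size
        tag = matrix.estimator + "+pd"
        mat = matrix.values
    else:
        mat = np.asarray(matrix, dtype=float)
        names = tuple(f"X{i}" for i in range(mat.shape[0]))
        m = sample_size or 0
        tag = "pd-projection"
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValueError("expected a square matrix")
    if not np.allclose(mat, mat.T, atol=1e-8):
        raise ValueError("input matrix is not symmetric")
    if sample_size is not None:
        m = sample_size
    work = np.array(mat, copy=True)
    np.fill_diagonal(work, 1.0)
    if np.linalg.eigvalsh(work)[0] >= floor and np.allclose(np.diag(mat), 1.0):
        return CorrelationMatrix(work, names, m, tag)
    return CorrelationMatrix(_project_pd(work, floor), names, m, tag)
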