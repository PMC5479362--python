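"""Gaussian-copula normal-score transform.

Each variable is mapped through its rescaled empirical CDF and the standard
normal quantile function.  Discrete and continuous variables are treated
identically (both are rank-transformed); missing values are ignored when
ranking and stay missing in the output.  Because ranks are invariant under
strictly increasing maps, the transform of g(X) equals the transform of X for
any strictly monotone g — this is what lets the method undo unknown marginal
distortions such as cubing.
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from scipy.special import ndtri

from .data import MixedDataset, TransformedDataset

__all__ = ["empirical_cdf", "normal_scores", "transform_dataset"]


def empirical_cdf(column: np.ndarray, *, method: str = "midrank") -> np.ndarray:
    """Rescaled empirical CDF of one column, NaN-preserving.

    With ``method="midrank"`` (default) a non-missing value receives
    mid-rank / (n + 1), where n counts non-missing entries and tied values
    share their average rank; every output lies strictly inside (0, 1).
    ``method="strict"`` uses the strict-inequality count (#{x_j < x}) / (n+1),
    clamped to [1/(n+1), n/(n+1)] so the column minimum keeps a finite
    normal score.
    """
    column = np.asarray(column, dtype=float)
    if column.ndim != 1:
        raise ValueError("expected a 1-d column")
    obs = ~np.isnan(column)
    vals = column[obs]
    n = vals.size
    if np.unique(vals).size < 2:
        raise ValueError("constant column: normal scores are undefined")
    out = np.full(column.shape, np.nan)
    if method == "midrank":
        out[obs] = stats.rankdata(vals, method="average") / (n + 1)
    elif method == "strict":
        less = stats.rankdata(vals, method="min") - 1  # #{x_j < x}
        p = less / (n + 1)
        out[obs] = np.clip(p, 1 / (n + 1), n / (n + 1))
    else:
        raise ValueError(f"unknown method {method!r}")
    return out


def normal_scores(column: np.ndarray, *, method: str = "midrank") -> np.ndarray:
    """Standard-normal quantiles of the rescaled empirical CDF.

    Monotone in the input: x < y implies score(x) <= score(y), with equality
    exactly under ties.
    """
    return ndtri(empirical_cdf(column, method=method))


def transform_dataset(data: MixedDataset, *, method: str = "midrank",
                      ) -> TransformedDataset:
    """Column-wise normal-score transform of a mixed dataset.

    Discrete and continuous variables are both rank-transformed; the missing
    pattern is unchanged.  Columns that are constant on their observed part
    are reported together in a single error.
    """
    out = data.frame.copy()
    failures = []
    for c in data.names:
        try:
            out[c] = normal_scores(data.frame[c].to_numpy(), method=method)
        except ValueError:
            failures.append(c)
    if failures:
        raise ValueError(
            "normal scores undefined for constant column(s): "
            + ", ".join(repr(c) for c in failures))
    return TransformedDataset(out)
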