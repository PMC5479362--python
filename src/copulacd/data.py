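"""Tabular containers: mixed discrete/continuous datasets with missingness.

A :class:`MixedDataset` is a subjects-by-variables table where each column is
flagged ``discrete`` or ``continuous`` and missing cells are explicit.  The
normal-score transform produces a :class:`TransformedDataset` with the same
missingness pattern.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = ["MixedDataset", "TransformedDataset", "read_dataset", "write_dataset"]

VALID_KINDS = ("discrete", "continuous")
DEFAULT_SENTINELS = ("", "NA")


@dataclass(frozen=True)
class MixedDataset:
    """Subjects x variables table with per-variable type flags.

    Parameters
    ----------
    frame : pandas.DataFrame
        Numeric values; missing cells are NaN.  Discrete variables are stored
        as (float-coded) category codes.
    meta : mapping of column name to ``"discrete"`` or ``"continuous"``.
    """

    frame: pd.DataFrame
    meta: dict[str, str]

    def __init__(self, frame: pd.DataFrame, meta: Mapping[str, str]):
        frame = frame.astype(float)
        meta = dict(meta)
        if list(frame.columns) != [str(c) for c in frame.columns]:
            frame = frame.rename(columns=str)
        missing_meta = [c for c in frame.columns if c not in meta]
        if missing_meta:
            raise ValueError(f"metadata missing for columns: {missing_meta}")
        unknown = [c for c in meta if c not in frame.columns]
        if unknown:
            raise ValueError(f"metadata names unknown columns: {unknown}")
        bad = {c: k for c, k in meta.items() if k not in VALID_KINDS}
        if bad:
            raise ValueError(f"invalid variable kinds: {bad}")
        if len(set(frame.columns)) != frame.shape[1]:
            raise ValueError("duplicate column names")
        for c, k in meta.items():
            if k == "discrete":
                col = frame[c].to_numpy()
                obs = col[~np.isnan(col)]
                if obs.size and not np.allclose(obs, np.round(obs)):
                    raise ValueError(
                        f"discrete column {c!r} has non-integer category codes")
        object.__setattr__(self, "frame", frame)
        object.__setattr__(self, "meta", meta)

    # -- basic views -------------------------------------------------------

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.frame.columns)

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy(dtype=float)

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean array, True where the cell is missing."""
        return np.isnan(self.values)

    @property
    def n_rows(self) -> int:
        return int(self.frame.shape[0])

    def kinds(self) -> tuple[str, ...]:
        return tuple(self.meta[c] for c in self.names)

    def discrete_columns(self) -> tuple[str, ...]:
        return tuple(c for c in self.names if self.meta[c] == "discrete")

    def continuous_columns(self) -> tuple[str, ...]:
        return tuple(c for c in self.names if self.meta[c] == "continuous")

    def missing_counts(self) -> pd.Series:
        return self.frame.isna().sum()

    def with_values(self, values: np.ndarray) -> "MixedDataset":
        frame = pd.DataFrame(values, columns=self.frame.columns,
                             index=self.frame.index)
        return MixedDataset(frame, self.meta)


@dataclass(frozen=True)
class TransformedDataset:
    """Normal-score transformed table; missing pattern mirrors the input."""

    frame: pd.DataFrame

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.frame.columns)

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy(dtype=float)

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.values)

    @property
    def n_rows(self) -> int:
        return int(self.frame.shape[0])


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------


def _read_meta(meta_path: str | Path) -> dict[str, str]:
    meta_path = Path(meta_path)
    if meta_path.suffix.lower() == ".json":
        meta = json.loads(meta_path.read_text())
        if not isinstance(meta, dict):
            raise ValueError("metadata JSON must map column -> kind")
        return {str(k): str(v) for k, v in meta.items()}
    df = pd.read_csv(meta_path, dtype=str)
    cols = [c.lower() for c in df.columns]
    if "variable" in cols and "kind" in cols:
        df.columns = cols
        return dict(zip(df["variable"], df["kind"]))
    if df.shape[1] == 2:
        return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))
    raise ValueError(
        "metadata CSV needs columns 'variable' and 'kind' (or exactly two columns)")


def read_dataset(csv_path: str | Path, meta_path: str | Path,
                 missing_sentinel: Sequence[str] = DEFAULT_SENTINELS) -> MixedDataset:
    """Read a dataset CSV (header row required) plus its variable metadata."""
    frame = pd.read_csv(csv_path, na_values=list(missing_sentinel),
                        keep_default_na=False)
    for c in frame.columns:
        try:
            frame[c] = pd.to_numeric(frame[c])
        except (ValueError, TypeError) as err:
            raise ValueError(f"unparseable cell in column {c!r}: {err}") from err
    return MixedDataset(frame, _read_meta(meta_path))


def write_dataset(data: MixedDataset, csv_path: str | Path,
                  meta_path: str | Path | None = None,
                  missing_sentinel: str = "NA") -> None:
    data.frame.to_csv(csv_path, index=False, na_rep=missing_sentinel)
    if meta_path is not None:
        Path(meta_path).write_text(json.dumps(data.meta, indent=1) + "\n")
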