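"""Model-style front end: build a discovery model from data, ``fit()`` it,
inspect a results object.

``BCCD`` is the proposed three-step method (normal-score transform, EM or a
comparison estimator for the correlation matrix, Bayesian constraint-based
search); ``PC`` is the comparison algorithm run from the same correlation
matrices.  Both accept a :class:`~copulacd.data.MixedDataset` or a pandas
DataFrame plus per-variable type metadata.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .bccd import (BackgroundKnowledge, BCCDOutput, DEFAULT_ORIENT_THRESHOLD,
                   DEFAULT_THRESHOLD, MAX_COND, estimate_correlation, run_bccd)
from .correlation import CorrelationMatrix, EMResult, effective_sample_size
from .data import MixedDataset, read_dataset
from .graphs import PAG
from .pc import run_pc

__all__ = ["BCCD", "PC", "BCCDResults", "PCResults"]


def _coerce_dataset(data, metadata: Mapping[str, str] | None) -> MixedDataset:
    if isinstance(data, MixedDataset):
        return data
    if isinstance(data, pd.DataFrame):
        if metadata is None:
            # infer: integer-valued columns with few levels are discrete
            metadata = {}
            for c in data.columns:
                col = data[c].dropna().to_numpy(dtype=float)
                few = np.unique(col).size <= max(10, int(np.sqrt(col.size)) // 2)
                integral = col.size and np.allclose(col, np.round(col))
                metadata[str(c)] = "discrete" if (integral and few) else "continuous"
        return MixedDataset(data, metadata)
    raise TypeError("data must be a MixedDataset or pandas DataFrame")


class _DiscoveryModel:
    """Shared constructor logic for the two discovery models."""

    def __init__(self, data, metadata: Mapping[str, str] | None = None,
                 background: BackgroundKnowledge | None = None):
        self.data = _coerce_dataset(data, metadata)
        if background is not None:
            background.validate(self.data.names)
        self.background = background

    @classmethod
    def from_csv(cls, csv_path, meta_path, background_path=None, **kwargs):
        background = (BackgroundKnowledge.from_file(background_path)
                      if background_path else None)
        return cls(read_dataset(csv_path, meta_path), background=background,
                   **kwargs)

    @property
    def nobs(self) -> int:
        return effective_sample_size(self.data)

    @property
    def names(self) -> tuple[str, ...]:
        return self.data.names


class BCCD(_DiscoveryModel):
    """Bayesian constraint-based causal discovery for hybrid, incomplete data.

    Examples
    --------
    >>> model = BCCD(frame, metadata={"G": "discrete", "X": "continuous"})
    >>> results = model.fit(estimator="em", threshold=0.6)
    >>> print(results.summary())
    """

    def fit(self, estimator: str = "em",
            threshold: float = DEFAULT_THRESHOLD,
            orientation_threshold: float = DEFAULT_ORIENT_THRESHOLD,
            max_cond: int = MAX_COND,
            transform_method: str = "midrank",
            em_tol: float = 1e-6, em_max_iter: int = 500) -> "BCCDResults":
        out = run_bccd(self.data, estimator=estimator, threshold=threshold,
                       orientation_threshold=orientation_threshold,
                       max_cond=max_cond, background=self.background,
                       transform_method=transform_method,
                       em_tol=em_tol, em_max_iter=em_max_iter)
        return BCCDResults(self, out,
                           dict(estimator=estimator, threshold=threshold,
                                orientation_threshold=orientation_threshold,
                                max_cond=max_cond))


class PC(_DiscoveryModel):
    """PC algorithm run from a (missing-data-aware) correlation matrix."""

    def fit(self, alpha: float = 0.05, estimator: str = "em",
            max_cond: int | None = None) -> "PCResults":
        corr, em_res = estimate_correlation(self.data, estimator)
        pag = run_pc(corr, self.nobs, alpha=alpha, max_cond=max_cond)
        return PCResults(self, pag, corr, em_res,
                         dict(alpha=alpha, estimator=estimator))


@dataclass
class _ResultsBase:
    model: _DiscoveryModel
    pag: PAG = None  # type: ignore[assignment]

    def edge_lines(self) -> list[str]:
        return self.pag.to_edge_lines(getattr(self, "edge_reliability", None))

    def plot(self, ax=None, seed: int = 0):
        """Draw the output PAG (circle marks drawn as open dots)."""
        import matplotlib.pyplot as plt
        import networkx as nx

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 5))
        g = nx.Graph()
        g.add_nodes_from(self.pag.nodes)
        g.add_edges_from(tuple(sorted(e)) for e in self.pag.edges())
        pos = nx.spring_layout(g, seed=seed)
        nx.draw_networkx(g, pos=pos, ax=ax, node_color="#dbe9f6",
                         edge_color="#888888")
        labels = {tuple(sorted(e)): self.pag.edge_token(*sorted(e))
                  for e in self.pag.edges()}
        nx.draw_networkx_edge_labels(g, pos=pos, edge_labels=labels, ax=ax,
                                     font_size=8)
        ax.set_axis_off()
        return ax


class BCCDResults(_ResultsBase):
    """Fitted PAG, statement reliabilities and diagnostics."""

    def __init__(self, model: BCCD, output: BCCDOutput, options: dict):
        self.model = model
        self.output = output
        self.pag = output.pag
        self.correlation: CorrelationMatrix = output.correlation
        self.skeleton = output.skeleton
        self.edge_reliability = output.edge_reliability
        self.em_result: EMResult | None = output.em_result
        self.options = options

    @property
    def reliabilities(self) -> pd.DataFrame:
        return self.output.reliabilities.to_dataframe()

    def summary(self) -> str:
        from statsmodels.iolib.table import SimpleTable

        opt = self.options
        head = [
            ("Model:", "BCCD (Gaussian copula + EM)" if opt["estimator"] == "em"
             else f"BCCD ({opt['estimator']})"),
            ("No. observations:", str(self.model.nobs)),
            ("No. variables:", str(len(self.model.names))),
            ("Deletion threshold:", f"{opt['threshold']:.2f}"),
            ("Orientation threshold:", f"{opt['orientation_threshold']:.2f}"),
            ("Edges:", str(len(self.pag.edges()))),
        ]
        if self.em_result is not None:
            head.append(("EM iterations:", str(self.em_result.iterations)))
            head.append(("EM converged:", str(self.em_result.converged)))
        rows = [[f"{a} {self.pag.edge_token(a, b)} {b}",
                 f"{100 * self.edge_reliability.get(frozenset((a, b)), np.nan):.1f}%"]
                for a, b in (tuple(sorted(e)) for e in sorted(
                    self.pag.edges(), key=lambda e: tuple(sorted(e))))]
        tables = [
            SimpleTable(head, title="BCCD causal discovery results"),
            SimpleTable(rows or [["(no edges)", ""]],
                        headers=["edge", "reliability"]),
        ]
        return "\n".join(str(t) for t in tables)

    def __repr__(self) -> str:
        return (f"<BCCDResults: {len(self.pag.edges())} edges over "
                f"{len(self.model.names)} variables>")


class PCResults(_ResultsBase):
    """PC output embedded in PAG marks, plus the correlation matrix used."""

    def __init__(self, model: PC, pag: PAG, corr: CorrelationMatrix,
                 em_result, options: dict):
        self.model = model
        self.pag = pag
        self.correlation = corr
        self.em_result = em_result
        self.options = options

    def summary(self) -> str:
        from statsmodels.iolib.table import SimpleTable

        head = [
            ("Model:", f"PC (alpha={self.options['alpha']})"),
            ("Correlation estimator:", self.options["estimator"]),
            ("No. observations:", str(self.model.nobs)),
            ("Edges:", str(len(self.pag.edges()))),
        ]
        rows = [[f"{a} {self.pag.edge_token(a, b)} {b}"]
                for a, b in (tuple(sorted(e)) for e in sorted(
                    self.pag.edges(), key=lambda e: tuple(sorted(e))))]
        tables = [SimpleTable(head, title="PC results"),
                  SimpleTable(rows or [["(no edges)"]], headers=["edge"])]
        return "\n".join(str(t) for t in tables)

    def __repr__(self) -> str:
        return (f"<PCResults: {len(self.pag.edges())} edges over "
                f"{len(self.model.names)} variables>")
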