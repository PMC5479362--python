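"""Conditional-Gaussian benchmark simulator.

The benchmark is the 9-variable, 10-arc Waste Incinerator network: three
binary root variables (Burning regime B, Filter state F, Waste type W) and six
continuous descendants (CO2 concentration C, Filter efficiency E, Metal in
waste MW, Light penetrability L, Dust emission D, Metals emission ME).  Each
continuous variable is linear-Gaussian in its parents, with binary parents
entering as 0/1 indicators, so the joint distribution is linear in the
exogenous variables and the implied correlation matrix is available in closed
form.

Two parameter presets are shipped: a ``medium`` regime (well-conditioned
continuous-part correlation matrix) and a ``high`` regime whose correlation
matrix is close to singular.  Benchmark data are optionally distorted by a
strictly monotone cube map and thinned by MCAR or MAR missingness.
"""

from __future__ import annotations

import importlib.resources
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .data import MixedDataset
from .graphs import DAG

__all__ = [
    "ConditionalGaussianNetwork",
    "waste_incinerator",
    "WASTE_NODES",
    "WASTE_EDGES",
    "sample_network",
    "distort",
    "inject_missing",
]

WASTE_NODES = ("B", "F", "W", "C", "E", "MW", "L", "D", "ME")
WASTE_EDGES = (
    ("B", "C"), ("F", "E"), ("W", "E"), ("W", "MW"),
    ("B", "D"), ("W", "D"), ("E", "D"),
    ("MW", "ME"), ("D", "ME"), ("D", "L"),
)


@dataclass(frozen=True)
class ConditionalGaussianNetwork:
    """Linear conditional-Gaussian network with binary discrete roots.

    ``discrete`` maps each discrete node to P(X = 1); ``continuous`` maps each
    continuous node to ``{"intercept": a, "parents": {name: coef}, "noise_sd": s}``.
    Discrete nodes must have no continuous parents.
    """

    dag: DAG
    discrete: dict[str, float]
    continuous: dict[str, dict]

    def __post_init__(self):
        for v, p in self.discrete.items():
            if not 0 < p < 1:
                raise ValueError(f"P({v}=1)={p} outside (0, 1)")
            if any(u in self.continuous for u in self.dag.parents(v)):
                raise ValueError(
                    f"discrete node {v} has a continuous parent "
                    "(conditional-Gaussian constraint)")
        for v, spec in self.continuous.items():
            if set(spec["parents"]) != self.dag.parents(v):
                raise ValueError(f"parent mismatch for {v}")
            if spec["noise_sd"] <= 0:
                raise ValueError(f"non-positive noise sd for {v}")

    @property
    def nodes(self) -> tuple[str, ...]:
        return self.dag.nodes

    def meta(self) -> dict[str, str]:
        return {v: ("discrete" if v in self.discrete else "continuous")
                for v in self.nodes}

    def topological_order(self) -> list[str]:
        order, placed = [], set()
        pending = list(self.nodes)
        while pending:
            for v in pending:
                if self.dag.parents(v) <= placed:
                    order.append(v)
                    placed.add(v)
                    pending.remove(v)
                    break
            else:  # pragma: no cover - DAG validation forbids this
                raise RuntimeError("cycle")
        return order

    # -- closed-form moments ------------------------------------------------

    def _exogenous_decomposition(self):
        """Total-effect matrix T with X = mean + T @ e, Var(e) diagonal."""
        nodes = self.nodes
        idx = {v: i for i, v in enumerate(nodes)}
        d = len(nodes)
        T = np.zeros((d, d))
        var_e = np.zeros(d)
        mean = np.zeros(d)
        for v in self.topological_order():
            i = idx[v]
            if v in self.discrete:
                p = self.discrete[v]
                T[i, i] = 1.0
                var_e[i] = p * (1 - p)
                mean[i] = p
            else:
                spec = self.continuous[v]
                mean[i] = spec["intercept"]
                for u, c in spec["parents"].items():
                    T[i] += c * T[idx[u]]
                    mean[i] += c * mean[idx[u]]
                T[i, i] = spec["noise_sd"]
                var_e[i] = 1.0
        return mean, T, var_e

    def analytic_moments(self) -> tuple[pd.Series, pd.DataFrame]:
        """Exact mean vector and covariance matrix of the joint distribution."""
        mean, T, var_e = self._exogenous_decomposition()
        cov = T @ np.diag(var_e) @ T.T
        return (pd.Series(mean, index=self.nodes),
                pd.DataFrame(cov, index=self.nodes, columns=self.nodes))

    def analytic_correlation(self) -> pd.DataFrame:
        _, cov = self.analytic_moments()
        sd = np.sqrt(np.diag(cov.to_numpy()))
        corr = cov.to_numpy() / np.outer(sd, sd)
        np.fill_diagonal(corr, 1.0)
        return pd.DataFrame(corr, index=self.nodes, columns=self.nodes)

    def continuous_condition_number(self) -> float:
        corr = self.analytic_correlation()
        cont = [v for v in self.nodes if v in self.continuous]
        sub = corr.loc[cont, cont].to_numpy()
        w = np.linalg.eigvalsh(sub)
        return float(w[-1] / w[0])


def _load_preset(name: str) -> dict:
    ref = importlib.resources.files("copulacd").joinpath(f"presets/{name}.json")
    return json.loads(ref.read_text())


def waste_incinerator(regime: str = "medium",
                      preset_path: str | Path | None = None,
                      ) -> ConditionalGaussianNetwork:
    """The 9-node, 10-arc benchmark network in a given correlation regime.

    ``medium`` gives a well-conditioned continuous-part correlation matrix
    (condition number < 30); ``high`` an almost singular one (> 1000).  A
    custom preset JSON may be supplied instead.
    """
    if preset_path is not None:
        spec = json.loads(Path(preset_path).read_text())
    else:
        if regime not in ("medium", "high"):
            raise ValueError("regime must be 'medium' or 'high'")
        spec = _load_preset(f"waste_{regime}")
    dag = DAG(WASTE_NODES, WASTE_EDGES)
    return ConditionalGaussianNetwork(dag, spec["discrete"], spec["continuous"])


def sample_network(net: ConditionalGaussianNetwork, n: int,
                   seed=None) -> MixedDataset:
    """Forward (ancestral-order) sampling; reproducible for a fixed seed."""
    if n < 1:
        raise ValueError("need n >= 1")
    rng = np.random.default_rng(seed)
    cols: dict[str, np.ndarray] = {}
    for v in net.topological_order():
        if v in net.discrete:
            cols[v] = (rng.random(n) < net.discrete[v]).astype(float)
        else:
            spec = net.continuous[v]
            x = np.full(n, float(spec["intercept"]))
            for u, c in spec["parents"].items():
                x = x + c * cols[u]
            x = x + spec["noise_sd"] * rng.standard_normal(n)
            cols[v] = x
    frame = pd.DataFrame({v: cols[v] for v in net.nodes})
    return MixedDataset(frame, net.meta())


def distort(data: MixedDataset, which: Iterable[str] | None = None,
            ) -> MixedDataset:
    """Apply the monotone cube distortion X -> X^3 to continuous columns.

    Ranks (and hence normal scores) are unchanged; discrete columns and the
    missingness pattern are untouched.
    """
    if which is None:
        which = data.continuous_columns()
    frame = data.frame.copy()
    for c in which:
        if data.meta[c] != "continuous":
            raise ValueError(f"refusing to distort discrete column {c!r}")
        frame[c] = frame[c] ** 3
    return MixedDataset(frame, data.meta)


def _repair_mask(mask: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Ensure no row and no column is fully masked."""
    n, d = mask.shape
    for i in np.where(mask.all(axis=1))[0]:
        mask[i, rng.integers(d)] = False
    for j in np.where(mask.all(axis=0))[0]:
        mask[rng.integers(n), j] = False
    return mask


def inject_missing(data: MixedDataset, rate: float, mechanism: str = "mcar",
                   seed=None, drivers: Sequence[str] | None = None,
                   slope: float = 1.5) -> MixedDataset:
    """Inject missing values at a marginal rate via MCAR or MAR masking.

    MCAR draws an i.i.d. Bernoulli(rate) mask per cell.  MAR keeps driver
    columns (default: the discrete roots present in the data, e.g. B and W)
    fully observed and masks each remaining column with probability
    ``expit(alpha_j + slope * z)`` of its standardised driver value z, with
    ``alpha_j`` calibrated so the overall marginal missing fraction matches
    ``rate``.  Neither mechanism leaves a row or column entirely missing.
    """
    if not 0 <= rate <= 0.9:
        raise ValueError("rate must be in [0, 0.9]")
    if rate == 0:
        return data.with_values(data.values)
    rng = np.random.default_rng(seed)
    values = data.values.copy()
    n, d = values.shape
    if mechanism == "mcar":
        mask = rng.random((n, d)) < rate
    elif mechanism == "mar":
        if drivers is None:
            drivers = [c for c in ("B", "W") if c in data.names] or \
                [data.names[0]]
        didx = [data.names.index(c) for c in drivers]
        targets = [j for j in range(d) if j not in didx]
        target_rate = rate * d / len(targets)
        if target_rate > 0.9:
            raise ValueError(
                "rate too high: target columns would be >90% missing")
        mask = np.zeros((n, d), dtype=bool)
        for k, j in enumerate(targets):
            z = values[:, didx[k % len(didx)]]
            sd = z.std()
            z = (z - z.mean()) / (sd if sd > 0 else 1.0)

            def marginal(alpha):
                return expit(alpha + slope * z).mean() - target_rate

            alpha = brentq(marginal, -40, 40)
            mask[:, j] = rng.random(n) < expit(alpha + slope * z)
    else:
        raise ValueError("mechanism must be 'mcar' or 'mar'")
    mask &= ~np.isnan(values)  # don't re-mask
    mask = _repair_mask(mask | np.isnan(values), rng) & ~np.isnan(values)
    values[mask] = np.nan
    return data.with_values(values)
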