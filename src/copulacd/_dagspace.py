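"""Cached enumeration of the DAG hypothesis space on small variable subsets.

Scoring windows contain at most five variables; all labeled DAGs on n <= 5
positions are enumerated once per process and stored as parent bitmasks,
together with the graph features needed to turn posterior weights into
statement reliabilities: per-DAG edge counts, d-separation indicators and
ancestor indicators.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

from .graphs import _enumerate_parent_masks, dseparated_mask

__all__ = ["DagSpace", "get_dagspace"]


class DagSpace:
    """All labeled DAGs on ``n`` positions plus precomputed query masks."""

    def __init__(self, n: int):
        if not 1 <= n <= 5:
            raise ValueError("DagSpace supports 1..5 positions")
        self.n = n
        masks = _enumerate_parent_masks(n)
        self.pmasks = np.array(masks, dtype=np.int64)       # (m, n)
        self.m = self.pmasks.shape[0]
        # flattened MI-table index: dag k, node i -> i * 2^n + parent mask
        self.flat_idx = (np.arange(n)[None, :] * (1 << n)
                         + self.pmasks).astype(np.int64)
        # edge counts
        self.edge_counts = np.array(
            [sum(int(p).bit_count() for p in row) for row in masks],
            dtype=np.int64)
        # ancestor indicator anc[a, b, k]: a is a proper ancestor of b in DAG k
        anc = np.zeros((n, n, self.m), dtype=bool)
        for k, row in enumerate(masks):
            anc_masks = _ancestor_masks(row)
            for b in range(n):
                am = anc_masks[b]
                while am:
                    a = (am & -am).bit_length() - 1
                    anc[a, b, k] = True
                    am &= am - 1
        self.anc = anc
        self._dsep_cache: dict[tuple[int, int, int], np.ndarray] = {}

    def dsep(self, x: int, y: int, zmask: int) -> np.ndarray:
        """Boolean array over DAGs: x d-separated from y given zmask."""
        if x > y:
            x, y = y, x
        key = (x, y, zmask)
        out = self._dsep_cache.get(key)
        if out is None:
            out = np.array(
                [dseparated_mask(tuple(row), x, y, zmask)
                 for row in self.pmasks.tolist()], dtype=bool)
            self._dsep_cache[key] = out
        return out

    def dsep_rest(self, x: int = 0, y: int = 1) -> np.ndarray:
        """d-separation of positions x, y given all remaining positions."""
        zmask = ((1 << self.n) - 1) & ~(1 << x) & ~(1 << y)
        return self.dsep(x, y, zmask)


def _ancestor_masks(pmask) -> list[int]:
    """For each node, the bitmask of its proper ancestors."""
    n = len(pmask)
    anc = list(pmask)
    changed = True
    while changed:
        changed = False
        for v in range(n):
            m = anc[v]
            acc = m
            while m:
                u = (m & -m).bit_length() - 1
                acc |= anc[u]
                m &= m - 1
            if acc != anc[v]:
                anc[v] = acc
                changed = True
    return anc


@lru_cache(maxsize=None)
def get_dagspace(n: int) -> DagSpace:
    return DagSpace(n)
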