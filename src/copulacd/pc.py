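"""PC algorithm run from a correlation matrix (comparison method).

Conditional independence is tested with Fisher's z on partial correlations
computed by submatrix inversion.  The skeleton phase is the stable
(order-independent) variant; v-structures are oriented from separating sets
and Meek's rules complete the CPDAG, which is embedded into PAG marks (tails
and arrowheads for compelled edges, circles for reversible ones) so that the
same accuracy metric serves both algorithms.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .correlation import CorrelationMatrix
from .graphs import Mark, PAG

__all__ = ["fisher_z_test", "run_pc"]


def partial_correlation(corr: CorrelationMatrix, i: str, j: str,
                        cond: Sequence[str]) -> float:
    """Partial correlation of i and j given ``cond`` via precision submatrix."""
    sub = corr.submatrix((i, j, *cond))
    try:
        prec = np.linalg.inv(sub)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            f"singular submatrix for partial correlation of ({i}, {j} | "
            f"{sorted(cond)})") from err
    return float(-prec[0, 1] / np.sqrt(prec[0, 0] * prec[1, 1]))


def fisher_z_test(corr: CorrelationMatrix, n: int, i: str, j: str,
                  cond: Sequence[str] = ()) -> float:
    """Two-sided p-value for zero partial correlation (Fisher z transform)."""
    cond = tuple(cond)
    if len(cond) > n - 3:
        raise ValueError("conditioning set too large for the sample size")
    r = partial_correlation(corr, i, j, cond)
    r = float(np.clip(r, -1 + 1e-15, 1 - 1e-15))
    z = np.arctanh(r) * np.sqrt(n - len(cond) - 3)
    return float(2 * stats.norm.sf(abs(z)))


def _meek_rules(directed: set[tuple[str, str]],
                undirected: set[frozenset[str]]) -> None:
    """Meek rules 1-4, applied in place until fixpoint."""

    def adjacent(a, b):
        return (a, b) in directed or (b, a) in directed or \
            frozenset((a, b)) in undirected

    changed = True
    while changed:
        changed = False
        for e in sorted(undirected, key=lambda e: tuple(sorted(e))):
            if e not in undirected:
                continue
            for a, b in itertools.permutations(sorted(e)):
                orient = False
                # R1: c -> a, a - b, c and b nonadjacent  =>  a -> b
                if any((c, a) in directed and not adjacent(c, b)
                       for c in _nodes_of(directed) if c not in (a, b)):
                    orient = True
                # R2: a -> c -> b and a - b  =>  a -> b
                if not orient and any(
                        (a, c) in directed and (c, b) in directed
                        for c in _nodes_of(directed) if c not in (a, b)):
                    orient = True
                # R3: a - c1 -> b, a - c2 -> b, c1, c2 nonadjacent  =>  a -> b
                if not orient:
                    cs = [c for c in _nodes_of(directed)
                          if frozenset((a, c)) in undirected
                          and (c, b) in directed]
                    if any(not adjacent(c1, c2)
                           for c1, c2 in itertools.combinations(cs, 2)):
                        orient = True
                # R4: a - d, d -> c, c -> b, a - c (or a adj c)  =>  a -> b
                if not orient:
                    for d, c in itertools.permutations(_nodes_of(directed), 2):
                        if (d, c) in directed and (c, b) in directed \
                                and frozenset((a, d)) in undirected \
                                and adjacent(a, c) and not adjacent(d, b):
                            orient = True
                            break
                if orient:
                    undirected.discard(e)
                    directed.add((a, b))
                    changed = True
                    break


def _nodes_of(directed: set[tuple[str, str]]) -> set[str]:
    return {v for e in directed for v in e}


@dataclass
class PCRun:
    pag: PAG
    sepsets: dict[frozenset[str], tuple[str, ...]]
    skeleton: set[frozenset[str]]


def run_pc(corr: CorrelationMatrix, n: int | None = None, alpha: float = 0.05,
           max_cond: int | None = None) -> PAG:
    """Standard PC from a correlation matrix; output in PAG mark vocabulary.

    Skeleton by level-wise pruning (stable variant: neighbour sets are frozen
    per level), collider orientation from separating sets, Meek rules, then
    compelled edges become tail/arrowhead and reversible ones circle/circle.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if n is None:
        n = corr.sample_size
    names = corr.names
    adj: dict[str, set[str]] = {v: set(names) - {v} for v in names}
    sepsets: dict[frozenset[str], tuple[str, ...]] = {}
    level = 0
    while True:
        snapshot = {v: set(adj[v]) for v in names}
        if max_cond is not None and level > max_cond:
            break
        if all(len(snapshot[x]) - 1 < level for x in names):
            break
        for x, y in itertools.combinations(names, 2):
            if y not in adj[x]:
                continue
            tested: set[tuple[str, ...]] = set()
            for a, b in ((x, y), (y, x)):
                cands = sorted(snapshot[a] - {b})
                if len(cands) < level:
                    continue
                for zs in itertools.combinations(cands, level):
                    if zs in tested:
                        continue
                    tested.add(zs)
                    if fisher_z_test(corr, n, x, y, zs) > alpha:
                        adj[x].discard(y)
                        adj[y].discard(x)
                        sepsets[frozenset((x, y))] = zs
                        break
                if y not in adj[x]:
                    break
        level += 1
    skeleton = {frozenset((x, y)) for x in names for y in adj[x]}
    # v-structures
    directed: set[tuple[str, str]] = set()
    for y in names:
        for x, z in itertools.combinations(sorted(adj[y]), 2):
            if z in adj[x]:
                continue
            if y not in sepsets.get(frozenset((x, z)), ()):
                directed.add((x, y))
                directed.add((z, y))
    undirected = {e for e in skeleton
                  if not any((a, b) in directed or (b, a) in directed
                             for a, b in [tuple(sorted(e))])}
    # collider conflicts can doubly orient an edge; keep as directed both ways
    # resolved to the lexicographically smaller direction for determinism
    both = {e for e in skeleton
            if tuple(sorted(e)) in directed and tuple(sorted(e))[::-1] in directed}
    for e in both:
        a, b = sorted(e)
        directed.discard((b, a))
    _meek_rules(directed, undirected)
    pag = PAG(names)
    for a, b in sorted(directed):
        pag.add_edge(a, b, Mark.TAIL, Mark.ARROW)
    for e in sorted(undirected, key=lambda e: tuple(sorted(e))):
        a, b = sorted(e)
        pag.add_edge(a, b, Mark.CIRCLE, Mark.CIRCLE)
    return pag
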