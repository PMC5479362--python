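"""Independent brute-force oracles used only by the test suite.

Everything here is deliberately naive (exhaustive enumeration, path listing,
generic numerical optimisation) and shares no code with the implementation
paths it checks.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy import optimize, stats

from copulacd.graphs import DAG, Mark, PAG


# ---------------------------------------------------------------------------
# DAG counting oracle: filter all 2^(n(n-1)) digraphs
# ---------------------------------------------------------------------------


def brute_force_dags(nodes: tuple[str, ...]) -> list[frozenset[tuple[str, str]]]:
    """All DAGs on ``nodes`` by filtering every digraph (n <= 4 feasible)."""
    pairs = [(a, b) for a in nodes for b in nodes if a != b]
    out = []
    for bits in itertools.product((0, 1), repeat=len(pairs)):
        edges = frozenset(p for p, bit in zip(pairs, bits) if bit)
        if _acyclic(nodes, edges):
            out.append(edges)
    return out


def _acyclic(nodes, edges) -> bool:
    children = {v: [] for v in nodes}
    for a, b in edges:
        children[a].append(b)

    state: dict[str, int] = {}

    def visit(v):
        state[v] = 1
        for c in children[v]:
            s = state.get(c)
            if s == 1:
                return False
            if s is None and not visit(c):
                return False
        state[v] = 2
        return True

    return all(visit(v) for v in nodes if v not in state)


# ---------------------------------------------------------------------------
# d-separation by path enumeration
# ---------------------------------------------------------------------------


def dsep_paths(dag: DAG, x: str, y: str, z: set[str]) -> bool:
    """d-separation decided by enumerating every simple path."""
    desc = {v: dag.descendants(v) | {v} for v in dag.nodes}
    nbrs = {v: dag.parents(v) | dag.children(v) for v in dag.nodes}

    def blocked(path) -> bool:
        for i in range(1, len(path) - 1):
            prev, v, nxt = path[i - 1], path[i], path[i + 1]
            collider = (prev, v) in dag.edges and (nxt, v) in dag.edges
            if collider:
                if not (desc[v] & z):
                    return True
            elif v in z:
                return True
        return False

    stack = [[x]]
    while stack:
        path = stack.pop()
        last = path[-1]
        if last == y:
            if not blocked(path):
                return False
            continue
        for w in nbrs[last]:
            if w not in path:
                stack.append(path + [w])
    return True


# ---------------------------------------------------------------------------
# MAG enumeration + m-separation: ground-truth-PAG oracle
# ---------------------------------------------------------------------------

NONE, RIGHT, LEFT, BIDIR = 0, 1, 2, 3  # pair states for (a, b), a < b


class _MAG:
    """Mixed graph with directed and bidirected edges (no selection bias)."""

    def __init__(self, nodes, assignment):
        self.nodes = tuple(nodes)
        self.directed: set[tuple[str, str]] = set()
        self.bidirected: set[frozenset[str]] = set()
        for (a, b), s in assignment.items():
            if s == RIGHT:
                self.directed.add((a, b))
            elif s == LEFT:
                self.directed.add((b, a))
            elif s == BIDIR:
                self.bidirected.add(frozenset((a, b)))

    def adjacent(self, v):
        out = set()
        for a, b in self.directed:
            if a == v:
                out.add(b)
            if b == v:
                out.add(a)
        for e in self.bidirected:
            if v in e:
                out |= set(e) - {v}
        return out

    def arrowhead_at(self, u, v) -> bool:
        """Arrowhead at the v end of edge u--v."""
        return (u, v) in self.directed or frozenset((u, v)) in self.bidirected

    def descendants(self, v):
        out = {v}
        frontier = {v}
        while frontier:
            nxt = {b for a, b in self.directed if a in frontier} - out
            out |= nxt
            frontier = nxt
        return out

    def is_ancestral(self) -> bool:
        for a, b in self.directed:
            if a in self.descendants(b) - {b}:
                return False
        for e in self.bidirected:
            a, b = tuple(e)
            if a in self.descendants(b) or b in self.descendants(a):
                return False
        return True

    def m_separated(self, x, y, z: set) -> bool:
        desc = {v: self.descendants(v) for v in self.nodes}
        nbrs = {v: self.adjacent(v) for v in self.nodes}

        def blocked(path):
            for i in range(1, len(path) - 1):
                prev, v, nxt = path[i - 1], path[i], path[i + 1]
                collider = (self.arrowhead_at(prev, v)
                            and self.arrowhead_at(nxt, v))
                if collider:
                    if not (desc[v] & z):
                        return True
                elif v in z:
                    return True
            return False

        stack = [[x]]
        while stack:
            path = stack.pop()
            last = path[-1]
            if last == y:
                if not blocked(path):
                    return False
                continue
            for w in nbrs[last]:
                if w not in path:
                    stack.append(path + [w])
        return True

    def is_maximal(self) -> bool:
        for x, y in itertools.combinations(self.nodes, 2):
            if y in self.adjacent(x):
                continue
            others = [v for v in self.nodes if v not in (x, y)]
            if not any(self.m_separated(x, y, set(zs))
                       for k in range(len(others) + 1)
                       for zs in itertools.combinations(others, k)):
                return False
        return True


def _ci_fingerprint(sep_fn, nodes) -> frozenset:
    stmts = set()
    for x, y in itertools.combinations(nodes, 2):
        others = [v for v in nodes if v not in (x, y)]
        for k in range(len(others) + 1):
            for zs in itertools.combinations(others, k):
                if sep_fn(x, y, set(zs)):
                    stmts.add((x, y, frozenset(zs)))
    return frozenset(stmts)


def pag_by_mag_enumeration(dag: DAG) -> PAG:
    """Ground-truth PAG by enumerating every MAG with the same independences.

    Feasible for <= 4 observed nodes.  Marks are the invariant endpoint
    features across the Markov-equivalence class of MAGs.
    """
    nodes = dag.nodes
    target = _ci_fingerprint(lambda x, y, z: dsep_paths(dag, x, y, z), nodes)
    pairs = list(itertools.combinations(nodes, 2))
    members = []
    for states in itertools.product((NONE, RIGHT, LEFT, BIDIR),
                                    repeat=len(pairs)):
        mag = _MAG(nodes, dict(zip(pairs, states)))
        if not mag.is_ancestral():
            continue
        if _ci_fingerprint(mag.m_separated, nodes) != target:
            continue
        if not mag.is_maximal():
            continue
        members.append(mag)
    assert members, "no MAG matches the DAG's independence fingerprint"
    pag = PAG(nodes)
    ref = members[0]
    for a, b in pairs:
        if b not in ref.adjacent(a):
            continue
        pag.add_edge(a, b)
        for u, v in ((a, b), (b, a)):
            heads = {m.arrowhead_at(u, v) for m in members}
            if heads == {True}:
                pag.set_mark(u, v, Mark.ARROW)
            elif heads == {False}:
                pag.set_mark(u, v, Mark.TAIL)
    return pag


# ---------------------------------------------------------------------------
# bivariate MAR maximum likelihood by direct numerical optimisation
# ---------------------------------------------------------------------------


def bivariate_mar_mle(x: np.ndarray) -> float:
    """MLE of the correlation from bivariate data with missing values.

    Maximises the observed-data log-likelihood over (mu1, mu2, log s1,
    log s2, atanh rho) with a generic optimiser; completely independent of
    the EM implementation.
    """
    both = x[~np.isnan(x).any(axis=1)]
    only1 = x[np.isnan(x[:, 1]) & ~np.isnan(x[:, 0]), 0]
    only2 = x[np.isnan(x[:, 0]) & ~np.isnan(x[:, 1]), 1]

    def negloglik(theta):
        m1, m2, ls1, ls2, zr = theta
        s1, s2, r = np.exp(ls1), np.exp(ls2), np.tanh(zr)
        cov = np.array([[s1 ** 2, r * s1 * s2], [r * s1 * s2, s2 ** 2]])
        ll = stats.multivariate_normal.logpdf(both, [m1, m2], cov).sum()
        ll += stats.norm.logpdf(only1, m1, s1).sum()
        ll += stats.norm.logpdf(only2, m2, s2).sum()
        return -ll

    start = np.array([np.nanmean(x[:, 0]), np.nanmean(x[:, 1]),
                      np.log(np.nanstd(x[:, 0])), np.log(np.nanstd(x[:, 1])),
                      0.0])
    res = optimize.minimize(negloglik, start, method="Nelder-Mead",
                            options={"xatol": 1e-10, "fatol": 1e-12,
                                     "maxiter": 20000, "maxfev": 20000})
    assert res.success or res.fun < negloglik(start)
    return float(np.tanh(res.x[4]))
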