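"""Graph machinery: DAGs, partial ancestral graphs, enumeration, d-separation,
oracle ground-truth PAG construction and structure-recovery metrics.

A DAG is the causal hypothesis; a PAG summarises an equivalence class of
maximal ancestral graphs with endpoint marks tail (``-``), arrowhead (``>``)
and circle (``o``).  The ground-truth PAG of a data-generating DAG is built
with an exact d-separation oracle (oracle FCI: skeleton search over all
conditioning sets of observed variables, unshielded-collider orientation,
then the non-selection orientation rules R1-R4 and R8-R10).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

import networkx as nx

__all__ = [
    "Mark",
    "DAG",
    "PAG",
    "EvaluationResult",
    "enumerate_dags",
    "d_separated",
    "ground_truth_pag",
    "pag_accuracy",
    "skeleton_precision_recall",
]


class Mark(Enum):
    """Endpoint mark of a PAG edge."""

    TAIL = "-"
    ARROW = ">"
    CIRCLE = "o"

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"Mark.{self.name}"


# ---------------------------------------------------------------------------
# DAG
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DAG:
    """Directed acyclic graph over named variables.

    Parameters
    ----------
    nodes : sequence of str
        Ordered variable names (order is preserved for reproducibility).
    edges : iterable of (str, str)
        Directed edges as ``(parent, child)`` pairs.
    """

    nodes: tuple[str, ...]
    edges: frozenset[tuple[str, str]]

    def __init__(self, nodes: Sequence[str], edges: Iterable[tuple[str, str]] = ()):
        object.__setattr__(self, "nodes", tuple(nodes))
        object.__setattr__(self, "edges", frozenset((str(a), str(b)) for a, b in edges))
        self._validate()

    @classmethod
    def _unchecked(cls, nodes: tuple[str, ...], edges: frozenset) -> "DAG":
        obj = object.__new__(cls)
        object.__setattr__(obj, "nodes", nodes)
        object.__setattr__(obj, "edges", edges)
        return obj

    def _validate(self) -> None:
        if len(set(self.nodes)) != len(self.nodes):
            raise ValueError("duplicate node names")
        node_set = set(self.nodes)
        for a, b in self.edges:
            if a == b:
                raise ValueError(f"self-loop on {a!r}")
            if a not in node_set or b not in node_set:
                raise ValueError(f"edge ({a!r}, {b!r}) references unknown node")
        if not self._is_acyclic():
            raise ValueError("graph contains a directed cycle")

    def _is_acyclic(self) -> bool:
        children: dict[str, list[str]] = {v: [] for v in self.nodes}
        indeg = {v: 0 for v in self.nodes}
        for a, b in self.edges:
            children[a].append(b)
            indeg[b] += 1
        stack = [v for v in self.nodes if indeg[v] == 0]
        seen = 0
        while stack:
            v = stack.pop()
            seen += 1
            for c in children[v]:
                indeg[c] -= 1
                if indeg[c] == 0:
                    stack.append(c)
        return seen == len(self.nodes)

    # -- queries ---------------------------------------------------------

    def parents(self, v: str) -> set[str]:
        return {a for a, b in self.edges if b == v}

    def children(self, v: str) -> set[str]:
        return {b for a, b in self.edges if a == v}

    def ancestors(self, v: str) -> set[str]:
        """Proper ancestors of ``v`` (excluding ``v``)."""
        out: set[str] = set()
        frontier = self.parents(v)
        while frontier:
            out |= frontier
            frontier = set().union(*(self.parents(u) for u in frontier)) - out
        return out

    def descendants(self, v: str) -> set[str]:
        out: set[str] = set()
        frontier = self.children(v)
        while frontier:
            out |= frontier
            frontier = set().union(*(self.children(u) for u in frontier)) - out
        return out

    def is_ancestor(self, x: str, y: str) -> bool:
        """True iff there is a directed path from ``x`` to ``y`` (x != y)."""
        return y in self.descendants(x)

    def skeleton(self) -> set[frozenset[str]]:
        return {frozenset((a, b)) for a, b in self.edges}

    def v_structures(self) -> set[tuple[str, str, str]]:
        """Unshielded colliders ``(a, c, b)`` with a->c<-b, a,b nonadjacent.

        Returned with ``a < b`` lexicographically; the collider is the middle
        element.
        """
        skel = self.skeleton()
        out = set()
        for c in self.nodes:
            pa = sorted(self.parents(c))
            for a, b in itertools.combinations(pa, 2):
                if frozenset((a, b)) not in skel:
                    out.add((a, c, b))
        return out

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g

    def __repr__(self) -> str:
        es = ", ".join(f"{a}->{b}" for a, b in sorted(self.edges))
        return f"DAG(nodes={list(self.nodes)}, edges=[{es}])"


# ---------------------------------------------------------------------------
# PAG
# ---------------------------------------------------------------------------


class PAG:
    """Partial ancestral graph: undirected skeleton plus endpoint marks.

    Edge between ``x`` and ``y`` carries a mark at each endpoint; ``mark(x, y)``
    is the mark at the *y* end of the edge (arrowhead at y means the edge
    points into y).
    """

    def __init__(self, nodes: Sequence[str]):
        self.nodes: tuple[str, ...] = tuple(nodes)
        if len(set(self.nodes)) != len(self.nodes):
            raise ValueError("duplicate node names")
        self._marks: dict[tuple[str, str], Mark] = {}

    # -- construction ----------------------------------------------------

    def add_edge(self, x: str, y: str, mark_x: Mark = Mark.CIRCLE,
                 mark_y: Mark = Mark.CIRCLE) -> None:
        if x == y:
            raise ValueError("self-loop")
        for v in (x, y):
            if v not in self.nodes:
                raise ValueError(f"unknown node {v!r}")
        self._marks[(y, x)] = mark_x  # mark at x end
        self._marks[(x, y)] = mark_y  # mark at y end

    def remove_edge(self, x: str, y: str) -> None:
        del self._marks[(x, y)]
        del self._marks[(y, x)]

    def set_mark(self, x: str, y: str, mark: Mark) -> None:
        """Set the mark at the ``y`` end of edge x--y."""
        if (x, y) not in self._marks:
            raise ValueError(f"no edge between {x!r} and {y!r}")
        self._marks[(x, y)] = mark

    # -- queries ---------------------------------------------------------

    def has_edge(self, x: str, y: str) -> bool:
        return (x, y) in self._marks

    def mark(self, x: str, y: str) -> Mark:
        """Mark at the ``y`` end of the edge between x and y."""
        return self._marks[(x, y)]

    def edges(self) -> set[frozenset[str]]:
        return {frozenset(k) for k in self._marks}

    def adjacent(self, v: str) -> set[str]:
        return {x for (x, y) in self._marks if y == v}

    def edge_marks(self) -> dict[frozenset[str], dict[str, Mark]]:
        out: dict[frozenset[str], dict[str, Mark]] = {}
        for (x, y), m in self._marks.items():
            out.setdefault(frozenset((x, y)), {})[y] = m
        return out

    def copy(self) -> "PAG":
        p = PAG(self.nodes)
        p._marks = dict(self._marks)
        return p

    def __eq__(self, other: object) -> bool:
        return (isinstance(other, PAG) and self.nodes == other.nodes
                and self._marks == other._marks)

    # -- serialization ---------------------------------------------------

    _LEFT = {Mark.TAIL: "-", Mark.CIRCLE: "o", Mark.ARROW: "<"}
    _RIGHT = {Mark.TAIL: "-", Mark.CIRCLE: "o", Mark.ARROW: ">"}
    _LEFT_INV = {v: k for k, v in _LEFT.items()}
    _RIGHT_INV = {v: k for k, v in _RIGHT.items()}

    def edge_token(self, x: str, y: str) -> str:
        """Text token for the edge x--y, e.g. ``-->``, ``o->``, ``o-o``."""
        return f"{self._LEFT[self.mark(y, x)]}-{self._RIGHT[self.mark(x, y)]}"

    def to_edge_lines(self, reliabilities: Mapping[frozenset[str], float] | None = None,
                      ) -> list[str]:
        lines = []
        for e in sorted(self.edges(), key=lambda e: tuple(sorted(e))):
            x, y = sorted(e)
            line = f"{x} {self.edge_token(x, y)} {y}"
            if reliabilities is not None and e in reliabilities:
                line += f" {100 * reliabilities[e]:.1f}%"
            lines.append(line)
        return lines

    def __repr__(self) -> str:
        return f"PAG({list(self.nodes)}; {'; '.join(self.to_edge_lines())})"

    def to_dot(self) -> str:
        """Graphviz DOT text (marks encoded as arrowtail/arrowhead)."""
        shape = {Mark.TAIL: "none", Mark.ARROW: "normal", Mark.CIRCLE: "odot"}
        out = ["digraph PAG {", "  edge [dir=both];"]
        for v in self.nodes:
            out.append(f'  "{v}";')
        for e in sorted(self.edges(), key=lambda e: tuple(sorted(e))):
            x, y = sorted(e)
            out.append(f'  "{x}" -> "{y}" [arrowtail={shape[self.mark(y, x)]}, '
                       f'arrowhead={shape[self.mark(x, y)]}];')
        out.append("}")
        return "\n".join(out)


# ---------------------------------------------------------------------------
# DAG enumeration
# ---------------------------------------------------------------------------

MAX_ENUM_NODES = 5

_ENUM_CACHE: dict[int, list[tuple[int, ...]]] = {}


def _enumerate_parent_masks(n: int) -> list[tuple[int, ...]]:
    """All labeled DAGs on ``n`` nodes as tuples of parent bitmasks.

    Iterates the 3^C(n,2) assignments of per-pair states (absent, i->j, j->i)
    and keeps the acyclic ones; two-cycles are excluded by construction.
    """
    if n in _ENUM_CACHE:
        return _ENUM_CACHE[n]
    pairs = list(itertools.combinations(range(n), 2))
    out: list[tuple[int, ...]] = []
    for states in itertools.product((0, 1, 2), repeat=len(pairs)):
        pmask = [0] * n
        for (i, j), s in zip(pairs, states):
            if s == 1:      # i -> j
                pmask[j] |= 1 << i
            elif s == 2:    # j -> i
                pmask[i] |= 1 << j
        # Kahn's algorithm on bitmasks: repeatedly retire nodes whose
        # remaining (active) parents are all retired.
        active = (1 << n) - 1
        progress = True
        while progress and active:
            progress = False
            for v in range(n):
                if active >> v & 1 and (pmask[v] & active) == 0:
                    active &= ~(1 << v)
                    progress = True
        if active == 0:
            out.append(tuple(pmask))
    _ENUM_CACHE[n] = out
    return out


def enumerate_dags(nodes: Sequence[str], *, allow_large: bool = False) -> list[DAG]:
    """Enumerate every labeled DAG on ``nodes`` exactly once.

    Refuses more than :data:`MAX_ENUM_NODES` nodes unless ``allow_large`` is
    set (the count grows super-exponentially: 29,281 DAGs already at n=5).
    """
    nodes = tuple(nodes)
    n = len(nodes)
    if n < 1:
        raise ValueError("need at least one node")
    if n > MAX_ENUM_NODES and not allow_large:
        raise ValueError(
            f"enumeration over {n} > {MAX_ENUM_NODES} nodes refused; "
            "pass allow_large=True to override")
    out = []
    for pmask in _enumerate_parent_masks(n):
        edges = frozenset(
            (nodes[i], nodes[j]) for j in range(n) for i in range(n)
            if pmask[j] >> i & 1)
        out.append(DAG._unchecked(nodes, edges))
    return out


# ---------------------------------------------------------------------------
# d-separation
# ---------------------------------------------------------------------------


def d_separated(dag: DAG, x: str, y: str, z: Iterable[str] = ()) -> bool:
    """True iff every path between x and y is blocked given conditioning set z."""
    z = set(z)
    for v in (x, y, *z):
        if v not in dag.nodes:
            raise ValueError(f"unknown variable {v!r}")
    if x == y:
        raise ValueError("x and y must differ")
    if x in z or y in z:
        raise ValueError("x and y must not be in the conditioning set")
    return nx.is_d_separator(dag.to_networkx(), {x}, {y}, z)


def dseparated_mask(pmask: Sequence[int], x: int, y: int, zmask: int) -> bool:
    """Bayes-ball d-separation on a bitmask DAG (positions, not names).

    ``pmask[v]`` is the parent bitmask of node v; ``zmask`` the conditioning
    set. Used by the scoring hot path and by the enumeration caches.
    """
    n = len(pmask)
    cmask = [0] * n
    for v in range(n):
        m = pmask[v]
        while m:
            u = (m & -m).bit_length() - 1
            cmask[u] |= 1 << v
            m &= m - 1
    # ancestors of z (for collider opening)
    anc_z = zmask
    frontier = zmask
    while frontier:
        nxt = 0
        m = frontier
        while m:
            v = (m & -m).bit_length() - 1
            nxt |= pmask[v]
            m &= m - 1
        frontier = nxt & ~anc_z
        anc_z |= nxt
    # reachable states: (node, direction) direction 0 = arrived via edge into
    # node's parent side (travelling "up"), 1 = arrived from a parent ("down")
    visited = [[False, False] for _ in range(n)]
    stack = [(x, 0), (x, 1)]
    while stack:
        v, d = stack.pop()
        if visited[v][d]:
            continue
        visited[v][d] = True
        if v == y and v != x:
            return False
        in_z = zmask >> v & 1
        if d == 0:
            # arrived travelling up (from a child) -- may continue to parents
            # and descend to children, provided v not in z
            if not in_z:
                m = pmask[v]
                while m:
                    u = (m & -m).bit_length() - 1
                    stack.append((u, 0))
                    m &= m - 1
                m = cmask[v]
                while m:
                    u = (m & -m).bit_length() - 1
                    stack.append((u, 1))
                    m &= m - 1
        else:
            # arrived from a parent (downwards). If v not in z, continue down;
            # if v is a collider whose ancestors meet z, bounce up.
            if not in_z:
                m = cmask[v]
                while m:
                    u = (m & -m).bit_length() - 1
                    stack.append((u, 1))
                    m &= m - 1
            if anc_z >> v & 1:
                m = pmask[v]
                while m:
                    u = (m & -m).bit_length() - 1
                    stack.append((u, 0))
                    m &= m - 1
    return True


# ---------------------------------------------------------------------------
# Oracle FCI (ground-truth PAG)
# ---------------------------------------------------------------------------


def _oracle_skeleton(dag: DAG, observed: tuple[str, ...]):
    """Skeleton + separating sets over observed variables via d-separation."""
    sepsets: dict[frozenset[str], set[str]] = {}
    adj: dict[str, set[str]] = {v: set() for v in observed}
    for x, y in itertools.combinations(observed, 2):
        others = [v for v in observed if v not in (x, y)]
        separated = False
        for k in range(len(others) + 1):
            for zs in itertools.combinations(others, k):
                if d_separated(dag, x, y, zs):
                    sepsets[frozenset((x, y))] = set(zs)
                    separated = True
                    break
            if separated:
                break
        if not separated:
            adj[x].add(y)
            adj[y].add(x)
    return adj, sepsets


def _apply_fci_rules(pag: PAG, sepsets: dict[frozenset[str], set[str]]) -> None:
    """Zhang orientation rules R1-R4, R8-R10 (no selection bias) to fixpoint."""
    A = Mark.ARROW
    T = Mark.TAIL
    C = Mark.CIRCLE

    def adjacent(v):
        return pag.adjacent(v)

    def is_pd_edge(u, v):
        # edge u *-* v potentially directed from u to v
        return (pag.has_edge(u, v) and pag.mark(v, u) is not A
                and pag.mark(u, v) is not T)

    def uncovered_pd_paths(a, c):
        """Uncovered potentially-directed paths from a to c (list of tuples)."""
        out = []
        def dfs(path):
            last = path[-1]
            if last == c:
                if len(path) >= 3:
                    out.append(tuple(path))
                return
            for w in sorted(adjacent(last)):
                if w in path:
                    continue
                if not is_pd_edge(last, w):
                    continue
                # uncovered: consecutive triple endpoints nonadjacent
                if len(path) >= 2 and pag.has_edge(path[-2], w):
                    continue
                if w == c and len(path) == 1:
                    continue  # need intermediate vertex
                dfs(path + [w])
        dfs([a])
        return out

    changed = True
    while changed:
        changed = False
        # R1: a*->b o-* c, a,c nonadjacent  =>  b -> c
        for b in pag.nodes:
            nbrs = sorted(adjacent(b))
            for a in nbrs:
                if pag.mark(a, b) is not A:
                    continue
                for c in nbrs:
                    if c == a or pag.has_edge(a, c):
                        continue
                    if pag.mark(c, b) is C:
                        pag.set_mark(c, b, T)
                        pag.set_mark(b, c, A)
                        changed = True
        # R2: (a->b*->c) or (a*->b->c) and a*-o c  =>  a*->c
        for a in pag.nodes:
            for c in sorted(adjacent(a)):
                if pag.mark(a, c) is not C:
                    continue
                for b in sorted(adjacent(a) & adjacent(c)):
                    chain1 = (pag.mark(a, b) is A and pag.mark(b, a) is T
                              and pag.mark(b, c) is A)
                    chain2 = (pag.mark(a, b) is A and pag.mark(b, c) is A
                              and pag.mark(c, b) is T)
                    if chain1 or chain2:
                        pag.set_mark(a, c, A)
                        changed = True
                        break
        # R3: a*->b<-*c, a*-o d o-*c, a,c nonadjacent, d*-o b  =>  d*->b
        for b in pag.nodes:
            nbrs_b = sorted(adjacent(b))
            for d in nbrs_b:
                if pag.mark(d, b) is not C:
                    continue
                for a, c in itertools.combinations(sorted(adjacent(d) & set(nbrs_b)), 2):
                    if pag.has_edge(a, c):
                        continue
                    if (pag.mark(a, b) is A and pag.mark(c, b) is A
                            and pag.mark(a, d) is C and pag.mark(c, d) is C):
                        pag.set_mark(d, b, A)
                        changed = True
                        break
        # R4: discriminating path <t, ..., a, b, c> for b; requires b o-* c
        for b in pag.nodes:
            for c in sorted(adjacent(b)):
                if pag.mark(c, b) is not C:
                    continue
                for a in sorted(adjacent(b) & adjacent(c)):
                    # a must be a collider on the path and a parent of c
                    if not (pag.mark(b, a) is A and pag.mark(a, c) is A
                            and pag.mark(c, a) is T):
                        continue
                    # search discriminating path t ... a b c
                    found = _discriminating_path(pag, a, b, c)
                    if found is None:
                        continue
                    t = found
                    if b in sepsets.get(frozenset((t, c)), set()):
                        # b -> c
                        pag.set_mark(c, b, T)
                        pag.set_mark(b, c, A)
                    else:
                        pag.set_mark(a, b, A)
                        pag.set_mark(b, a, A)
                        pag.set_mark(b, c, A)
                        pag.set_mark(c, b, A)
                    changed = True
        # R8: a -> b -> c and a o-> c  =>  a -> c (tail at a)
        for a in pag.nodes:
            for c in sorted(adjacent(a)):
                if not (pag.mark(a, c) is A and pag.mark(c, a) is C):
                    continue
                for b in sorted(adjacent(a) & adjacent(c)):
                    if (pag.mark(a, b) is A and pag.mark(b, a) is T
                            and pag.mark(b, c) is A and pag.mark(c, b) is T):
                        pag.set_mark(c, a, T)
                        changed = True
                        break
        # R9: a o-> c, uncovered pd path a..b..c with b, c nonadjacent => tail at a
        for a in pag.nodes:
            for c in sorted(adjacent(a)):
                if not (pag.mark(a, c) is A and pag.mark(c, a) is C):
                    continue
                for path in uncovered_pd_paths(a, c):
                    b = path[1]
                    if b != c and not pag.has_edge(b, c) and b != a:
                        pag.set_mark(c, a, T)
                        changed = True
                        break
        # R10: a o-> c, b -> c <- d, two uncovered pd paths a..b', a..d' with
        # b' adjacent start of path to b, d' to d, b' != d', b',d' nonadjacent
        for a in pag.nodes:
            for c in sorted(adjacent(a)):
                if not (pag.mark(a, c) is A and pag.mark(c, a) is C):
                    continue
                into_c = [v for v in adjacent(c)
                          if pag.mark(v, c) is A and pag.mark(c, v) is T
                          and v != a]
                done = False
                for b, d in itertools.permutations(into_c, 2):
                    p1s = uncovered_pd_paths(a, b) + (
                        [(a, b)] if is_pd_edge(a, b) else [])
                    p2s = uncovered_pd_paths(a, d) + (
                        [(a, d)] if is_pd_edge(a, d) else [])
                    for p1 in p1s:
                        for p2 in p2s:
                            mu, om = p1[1], p2[1]
                            if mu != om and not pag.has_edge(mu, om):
                                pag.set_mark(c, a, T)
                                changed = True
                                done = True
                                break
                        if done:
                            break
                    if done:
                        break
                if done:
                    break


def _discriminating_path(pag: PAG, a: str, b: str, c: str) -> str | None:
    """Find the origin t of a discriminating path <t,...,a,b,c> for b.

    Every vertex strictly between t and b must be a collider on the path and
    a parent of c; t is not adjacent to c.
    """
    # walk backwards from a: predecessors p with p*->a, a<->p or a collider,
    # each intermediate must be parent of c.
    A_ = Mark.ARROW
    T_ = Mark.TAIL
    stack = [(a, [c, b, a])]
    while stack:
        v, path = stack.pop()
        for p in sorted(pag.adjacent(v)):
            if p in path:
                continue
            if pag.mark(p, v) is not A_:
                continue  # need p *-> v
            if not pag.has_edge(p, c):
                if pag.mark(v, p) is A_:
                    # v <-> p would also be fine as collider; but p is endpoint
                    pass
                return p  # p = t, not adjacent to c
            # p must itself be a collider on the path and a parent of c
            if (pag.mark(v, p) is A_ and pag.mark(p, c) is A_
                    and pag.mark(c, p) is T_):
                stack.append((p, path + [p]))
    return None


def ground_truth_pag(dag: DAG, latent: Iterable[str] = ()) -> PAG:
    """Ground-truth PAG of ``dag`` over the observed variables.

    Uses an exact d-separation oracle: skeleton over all conditioning subsets
    of observed variables, unshielded-collider orientation from separating
    sets, then orientation rules R1-R4 and R8-R10 (selection-bias rules are
    not needed: no undirected edges can arise from a DAG with latents only).
    """
    latent = set(latent)
    unknown = latent - set(dag.nodes)
    if unknown:
        raise ValueError(f"latent names not in graph: {sorted(unknown)}")
    if latent == set(dag.nodes):
        raise ValueError("at least one variable must be observed")
    observed = tuple(v for v in dag.nodes if v not in latent)
    adj, sepsets = _oracle_skeleton(dag, observed)
    pag = PAG(observed)
    for x, y in itertools.combinations(observed, 2):
        if y in adj[x]:
            pag.add_edge(x, y)
    # unshielded colliders
    for y in observed:
        for x, z in itertools.combinations(sorted(adj[y]), 2):
            if z in adj[x]:
                continue
            if y not in sepsets[frozenset((x, z))]:
                pag.set_mark(x, y, Mark.ARROW)
                pag.set_mark(z, y, Mark.ARROW)
    _apply_fci_rules(pag, sepsets)
    return pag


# ---------------------------------------------------------------------------
# Evaluation metrics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EvaluationResult:
    """Structure-recovery metrics of an estimated PAG against the truth."""

    pag_accuracy: float
    precision: float
    recall: float

    def __post_init__(self):
        for name in ("pag_accuracy", "precision", "recall"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


def _check_same_nodes(estimated: PAG, truth: PAG) -> None:
    if set(estimated.nodes) != set(truth.nodes):
        raise ValueError("PAGs are defined over different node sets")


def pag_accuracy(estimated: PAG, truth: PAG) -> float:
    """Fraction of correctly reproduced endpoint marks.

    Counted over both endpoints of every edge in the union of the two edge
    sets; an edge present in only one graph contributes two incorrect
    endpoints.  Symmetric in its arguments; equals 1 iff the PAGs coincide.
    Two empty graphs agree vacuously (accuracy 1).
    """
    _check_same_nodes(estimated, truth)
    union = estimated.edges() | truth.edges()
    if not union:
        return 1.0
    total = 2 * len(union)
    correct = 0
    for e in union:
        if e not in estimated.edges() or e not in truth.edges():
            continue
        x, y = sorted(e)
        correct += estimated.mark(x, y) is truth.mark(x, y)
        correct += estimated.mark(y, x) is truth.mark(y, x)
    return correct / total


def skeleton_precision_recall(estimated: PAG, truth: PAG) -> tuple[float, float]:
    """Skeleton precision and recall of the estimated graph.

    Precision is 1 when no edges were inferred (vacuous truth); recall is 1
    when the true graph has no edges.
    """
    _check_same_nodes(estimated, truth)
    est, tru = estimated.edges(), truth.edges()
    hit = len(est & tru)
    precision = hit / len(est) if est else 1.0
    recall = hit / len(tru) if tru else 1.0
    return precision, recall


def evaluate_pag(estimated: PAG, truth: PAG) -> EvaluationResult:
    p, r = skeleton_precision_recall(estimated, truth)
    return EvaluationResult(pag_accuracy(estimated, truth), p, r)
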