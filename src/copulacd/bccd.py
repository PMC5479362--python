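"""Bayesian constraint-based causal discovery from a correlation matrix.

Every causal query is answered by Bayesian model averaging over all DAGs on a
small variable window (at most five variables, 29,281 DAGs).  Each DAG is
scored with a Gaussian BIC built from the mutual information implied by the
correlation matrix,

    I(X_i; X_Pa_i) = -1/2 * log( det S_{i,Pa_i} / det S_{Pa_i} ),
    BIC(G) = M * sum_i I(X_i; X_Pa_i) - (log M / 2) * Dim[G],

normalised by log-sum-exp into a posterior under a uniform prior.  The
reliability of a causal statement is the posterior mass of the DAGs that
entail it (independence via d-separation, causation via directed paths).

The search itself is two-staged: an adjacency phase deletes an edge once some
conditional-independence statement exceeds the reliability threshold, and an
orientation phase ranks ancestral ("cause") statements by reliability and
fixes endpoint marks greedily, skipping statements that conflict with marks
already set.  Optional background knowledge forbids ancestral relations; it
both vetoes the corresponding statements and removes the violating DAGs from
the hypothesis space before normalisation.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.special import logsumexp

from ._dagspace import DagSpace, get_dagspace
from .correlation import (CorrelationMatrix, PD_FLOOR, em_correlation,
                          listwise_correlation, mean_impute_correlation,
                          nearest_positive_definite, spearman_pairwise,
                          effective_sample_size)
from .data import MixedDataset
from .graphs import DAG, Mark, PAG
from .transform import transform_dataset

__all__ = [
    "CausalStatement",
    "ReliabilityTable",
    "ScoredDagSet",
    "BackgroundKnowledge",
    "mutual_information",
    "bic_score",
    "score_subset",
    "statement_reliability",
    "adjacency_search",
    "orient_edges",
    "run_bccd",
    "BCCDOutput",
    "ESTIMATORS",
]

DEFAULT_THRESHOLD = 0.6        # reliability needed to delete an edge
DEFAULT_ORIENT_THRESHOLD = 0.5  # reliability needed to fix an endpoint mark
MAX_COND = 3                   # |Z| <= 3 keeps windows at <= 5 variables


# ---------------------------------------------------------------------------
# statements
# ---------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class CausalStatement:
    """A statement whose reliability Bayesian averaging can score.

    ``independence`` / ``dependence`` concern X and Y given ``cond_set``;
    ``cause`` asserts that X is an ancestor of Y (a directed path exists).
    """

    kind: str
    x: str
    y: str
    cond_set: frozenset[str] = frozenset()

    def __post_init__(self):
        if self.kind not in ("independence", "dependence", "cause"):
            raise ValueError(f"unsupported statement kind {self.kind!r}")
        if self.x == self.y:
            raise ValueError("statement variables must differ")
        if self.x in self.cond_set or self.y in self.cond_set:
            raise ValueError("conditioning set must exclude the statement pair")
        object.__setattr__(self, "cond_set", frozenset(self.cond_set))

    def __str__(self) -> str:
        if self.kind == "cause":
            return f"{self.x} => {self.y}"
        sym = "_||_" if self.kind == "independence" else "~dep~"
        cond = f" | {{{', '.join(sorted(self.cond_set))}}}" if self.cond_set else ""
        return f"{self.x} {sym} {self.y}{cond}"


@dataclass
class ReliabilityTable:
    """Causal statements with posterior reliabilities and their windows."""

    entries: list[tuple[CausalStatement, float, tuple[str, ...]]] = field(
        default_factory=list)

    def add(self, statement: CausalStatement, probability: float,
            subset: tuple[str, ...]) -> None:
        if not -1e-9 <= probability <= 1 + 1e-9:
            raise ValueError("probability outside [0, 1]")
        self.entries.append((statement, float(np.clip(probability, 0, 1)),
                             tuple(subset)))

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            [{
                "kind": s.kind, "x": s.x, "y": s.y,
                "cond_set": ",".join(sorted(s.cond_set)),
                "reliability": p,
                "window": ",".join(w),
            } for s, p, w in self.entries])

    def best(self, statement: CausalStatement) -> float:
        """Maximum reliability of ``statement`` over all windows that scored it."""
        vals = [p for s, p, _ in self.entries if s == statement]
        if not vals:
            raise KeyError(f"statement never evaluated: {statement}")
        return max(vals)

    def __len__(self) -> int:
        return len(self.entries)


# ---------------------------------------------------------------------------
# background knowledge
# ---------------------------------------------------------------------------


class BackgroundKnowledge:
    """Forbidden-cause constraints: ``forbid X -> Y`` or ``forbid * -> Y``.

    A forbidden relation removes every DAG in which X is an ancestor of Y from
    the hypothesis space, and vetoes the corresponding "cause" statements
    during orientation.
    """

    def __init__(self, forbidden: Iterable[tuple[str, str]] = ()):
        self.forbidden: set[tuple[str, str]] = set()
        for x, y in forbidden:
            if x == y:
                raise ValueError(f"inconsistent constraint: forbid {x} -> {x}")
            self.forbidden.add((x, y))

    @classmethod
    def from_lines(cls, lines: Iterable[str]) -> "BackgroundKnowledge":
        out = []
        for ln, raw in enumerate(lines, 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 4 or parts[0] != "forbid" or parts[2] != "->":
                raise ValueError(
                    f"line {ln}: expected 'forbid X -> Y', got {raw!r}")
            out.append((parts[1], parts[3]))
        return cls(out)

    @classmethod
    def from_file(cls, path) -> "BackgroundKnowledge":
        return cls.from_lines(Path(path).read_text().splitlines())

    def forbids(self, x: str, y: str) -> bool:
        return (x, y) in self.forbidden or ("*", y) in self.forbidden

    def validate(self, names: Sequence[str]) -> None:
        known = set(names) | {"*"}
        bad = [(x, y) for x, y in self.forbidden
               if x not in known or y not in known or y == "*"]
        if bad:
            raise ValueError(f"background constraints name unknown variables: {bad}")

    def allowed_mask(self, space: DagSpace, subset: Sequence[str]) -> np.ndarray | None:
        """Boolean mask over the DAG space: True where no constraint is violated."""
        pairs = [(a, b) for a in range(len(subset)) for b in range(len(subset))
                 if a != b and self.forbids(subset[a], subset[b])]
        if not pairs:
            return None
        allowed = np.ones(space.m, dtype=bool)
        for a, b in pairs:
            allowed &= ~space.anc[a, b]
        return allowed

    def __bool__(self) -> bool:
        return bool(self.forbidden)


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

_SUBMASK_IDX: dict[int, list[np.ndarray]] = {}


def _subset_logdets(R: np.ndarray) -> np.ndarray:
    """log-determinants of every principal submatrix of R, indexed by bitmask."""
    s = R.shape[0]
    idx_lists = _SUBMASK_IDX.get(s)
    if idx_lists is None:
        idx_lists = [np.array([i for i in range(s) if mask >> i & 1])
                     for mask in range(1 << s)]
        _SUBMASK_IDX[s] = idx_lists
    ld = np.zeros(1 << s)
    # batch submatrices of equal size for np.linalg.slogdet
    by_size: dict[int, list[int]] = {}
    for mask in range(1, 1 << s):
        by_size.setdefault(int(mask).bit_count(), []).append(mask)
    for size, masks in by_size.items():
        if size == 1:
            continue  # unit diagonal -> logdet 0
        stack = np.stack([R[np.ix_(idx_lists[m], idx_lists[m])] for m in masks])
        sign, logdet = np.linalg.slogdet(stack)
        if np.any(sign <= 0):
            raise np.linalg.LinAlgError(
                "singular correlation submatrix; project the matrix to the "
                "nearest positive-definite correlation matrix first")
        ld[masks] = logdet
    return ld


def _mi_flat(R: np.ndarray) -> np.ndarray:
    """Flattened mutual-information table MI[i * 2^s + parent_mask]."""
    s = R.shape[0]
    ld = _subset_logdets(R)
    masks = np.arange(1 << s)
    out = np.empty(s << s)
    for i in range(s):
        out[i << s | masks] = -0.5 * (ld[masks | (1 << i)] - ld[masks])
    return out


def mutual_information(corr: CorrelationMatrix, i: str,
                       parents: Iterable[str]) -> float:
    """Gaussian mutual information between variable ``i`` and a parent set.

    ``-1/2 log( det S_{i,Pa} / det S_Pa )`` from the correlation matrix; zero
    for the empty parent set, nonnegative otherwise.
    """
    parents = tuple(parents)
    if i in parents:
        raise ValueError("variable cannot be its own parent")
    if not parents:
        return 0.0
    sub_pa = corr.submatrix(parents)
    sub_all = corr.submatrix((i, *parents))
    sign_pa, ld_pa = np.linalg.slogdet(sub_pa)
    sign_all, ld_all = np.linalg.slogdet(sub_all)
    if sign_pa <= 0 or sign_all <= 0:
        raise np.linalg.LinAlgError(
            "singular correlation submatrix; project the matrix to the "
            "nearest positive-definite correlation matrix first")
    return float(-0.5 * (ld_all - ld_pa))


def bic_score(corr: CorrelationMatrix, dag: DAG, M: int) -> float:
    """BIC approximation to the log marginal likelihood of ``dag``.

    ``M * sum_i I(X_i; Pa_i) - (log M / 2) * Dim[G]`` with ``Dim[G]`` the edge
    count (node variances are common to every DAG on the subset and cancel in
    the posterior normalisation).
    """
    missing = [v for v in dag.nodes if v not in corr.names]
    if missing:
        raise ValueError(f"DAG nodes not in correlation matrix: {missing}")
    fit = sum(mutual_information(corr, v, dag.parents(v)) for v in dag.nodes)
    return M * fit - 0.5 * math.log(M) * len(dag.edges)


@dataclass
class ScoredDagSet:
    """Every DAG on a variable window with BIC scores and posteriors."""

    subset: tuple[str, ...]
    sample_size: int
    log_scores: np.ndarray
    posteriors: np.ndarray
    space: DagSpace
    allowed: np.ndarray | None = None  # background-knowledge mask

    @property
    def dags(self) -> list[DAG]:
        out = []
        n = len(self.subset)
        for row in self.space.pmasks.tolist():
            edges = frozenset(
                (self.subset[i], self.subset[j])
                for j in range(n) for i in range(n) if row[j] >> i & 1)
            out.append(DAG._unchecked(self.subset, edges))
        return out

    def positions(self, names: Iterable[str]) -> list[int]:
        return [self.subset.index(v) for v in names]


def score_subset(corr: CorrelationMatrix, subset: Sequence[str], M: int,
                 background: BackgroundKnowledge | None = None) -> ScoredDagSet:
    """Score every DAG on ``subset`` and normalise to a posterior.

    Uniform prior over DAGs; posterior computed in log space with
    log-sum-exp.  Background knowledge (forbidden ancestral relations)
    restricts the hypothesis space before normalisation.
    """
    subset = tuple(subset)
    if not 1 <= len(subset) <= 5:
        raise ValueError("scoring windows are limited to 1..5 variables")
    if M < 2:
        raise ValueError("sample size must be at least 2")
    space = get_dagspace(len(subset))
    R = corr.submatrix(subset)
    mi = _mi_flat(R)
    scores = (M * mi[space.flat_idx].sum(axis=1)
              - 0.5 * math.log(M) * space.edge_counts)
    allowed = background.allowed_mask(space, subset) if background else None
    if allowed is not None:
        scores = np.where(allowed, scores, -np.inf)
    logpost = scores - logsumexp(scores)
    return ScoredDagSet(subset, M, scores, np.exp(logpost), space, allowed)


def statement_reliability(scored: ScoredDagSet,
                          statement: CausalStatement) -> float:
    """Posterior mass of the DAGs in the window entailing ``statement``."""
    for v in (statement.x, statement.y, *statement.cond_set):
        if v not in scored.subset:
            raise ValueError(f"statement variable {v!r} not in window")
    xpos, ypos = scored.positions((statement.x, statement.y))
    if statement.kind == "cause":
        mask = scored.space.anc[xpos, ypos]
    else:
        zmask = 0
        for z in statement.cond_set:
            zmask |= 1 << scored.subset.index(z)
        mask = scored.space.dsep(xpos, ypos, zmask)
        if statement.kind == "dependence":
            mask = ~mask
    return float(scored.posteriors[mask].sum())


# ---------------------------------------------------------------------------
# adjacency search
# ---------------------------------------------------------------------------


@dataclass
class SearchResult:
    skeleton: set[frozenset[str]]
    reliabilities: ReliabilityTable
    sepsets: dict[frozenset[str], tuple[str, ...]]
    windows: dict[tuple[str, ...], ScoredDagSet]


def _window(corr: CorrelationMatrix, subset: tuple[str, ...], M: int,
            background: BackgroundKnowledge | None,
            cache: dict[tuple[str, ...], ScoredDagSet]) -> ScoredDagSet:
    key = tuple(sorted(subset))
    scored = cache.get(key)
    if scored is None:
        scored = score_subset(corr, key, M, background)
        cache[key] = scored
    return scored


def adjacency_search(corr: CorrelationMatrix, M: int | None = None,
                     threshold: float = DEFAULT_THRESHOLD,
                     max_cond: int = MAX_COND,
                     background: BackgroundKnowledge | None = None,
                     ) -> SearchResult:
    """Delete edges whose conditional independence is sufficiently reliable.

    Starts from the complete graph.  For each still-adjacent pair (X, Y),
    conditioning sets Z are drawn in order of increasing size from the
    variables adjacent to X or Y in the current skeleton (PC-style, stable
    within a level); the window {X, Y} u Z is scored and the edge is removed
    as soon as the reliability of "X independent of Y given Z" exceeds the
    threshold.  All evaluated statements are recorded.
    """
    if M is None:
        M = corr.sample_size
    names = corr.names
    adj: dict[str, set[str]] = {v: set(names) - {v} for v in names}
    table = ReliabilityTable()
    sepsets: dict[frozenset[str], tuple[str, ...]] = {}
    windows: dict[tuple[str, ...], ScoredDagSet] = {}
    for level in range(0, max_cond + 1):
        snapshot = {v: set(adj[v]) for v in names}
        for x, y in itertools.combinations(names, 2):
            if y not in adj[x]:
                continue
            cands = sorted((snapshot[x] | snapshot[y]) - {x, y})
            if len(cands) < level:
                continue
            for zs in itertools.combinations(cands, level):
                scored = _window(corr, (x, y, *zs), M, background, windows)
                stmt = CausalStatement("independence", x, y, frozenset(zs))
                rel = statement_reliability(scored, stmt)
                table.add(stmt, rel, scored.subset)
                if rel > threshold:
                    adj[x].discard(y)
                    adj[y].discard(x)
                    sepsets[frozenset((x, y))] = zs
                    break
    skeleton = {frozenset((x, y)) for x in names for y in adj[x]}
    return SearchResult(skeleton, table, sepsets, windows)


# ---------------------------------------------------------------------------
# orientation
# ---------------------------------------------------------------------------


def causal_reliabilities(corr: CorrelationMatrix, M: int,
                         skeleton: set[frozenset[str]],
                         windows: dict[tuple[str, ...], ScoredDagSet],
                         background: BackgroundKnowledge | None = None,
                         ) -> ReliabilityTable:
    """Score ancestral ("cause") statements for every skeleton edge.

    Each statement is evaluated in all recorded search windows containing the
    pair, plus one canonical window per edge (the pair with up to three
    lexicographically first skeleton neighbours); the table keeps every
    window's value, and ranking later uses the maximum.
    """
    adj: dict[str, set[str]] = {}
    for e in skeleton:
        x, y = sorted(e)
        adj.setdefault(x, set()).add(y)
        adj.setdefault(y, set()).add(x)
    table = ReliabilityTable()
    for e in sorted(skeleton, key=lambda e: tuple(sorted(e))):
        x, y = sorted(e)
        nbrs = sorted((adj.get(x, set()) | adj.get(y, set())) - {x, y})
        canonical = tuple(sorted((x, y, *nbrs[:3])))
        _window(corr, canonical, M, background, windows)
        for key, scored in windows.items():
            if x not in key or y not in key:
                continue
            for a, b in ((x, y), (y, x)):
                stmt = CausalStatement("cause", a, b)
                table.add(stmt, statement_reliability(scored, stmt), key)
    return table


def orient_edges(skeleton: set[frozenset[str]],
                 reliabilities: ReliabilityTable,
                 background: BackgroundKnowledge | None = None,
                 threshold: float = DEFAULT_ORIENT_THRESHOLD,
                 nodes: Sequence[str] | None = None) -> PAG:
    """Orient skeleton endpoints from ranked ancestral statements.

    Statements are processed in decreasing reliability (ties broken
    lexicographically).  An accepted "X causes Y" sets a tail at the X end of
    edge X--Y; its complement sets an arrowhead.  A statement conflicting with
    an already-fixed mark is skipped; endpoints never touched stay circles.
    Statements at or below ``threshold`` are ignored.  Background knowledge
    vetoes forbidden "cause" statements before ranking.
    """
    if nodes is None:
        nodes = sorted({v for e in skeleton for v in e})
    pag = PAG(tuple(nodes))
    for e in sorted(skeleton, key=lambda e: tuple(sorted(e))):
        x, y = sorted(e)
        pag.add_edge(x, y)
    # pool: statement -> max reliability over windows, restricted to skeleton
    pooled: dict[CausalStatement, float] = {}
    for stmt, p, _w in reliabilities.entries:
        if stmt.kind != "cause":
            continue
        if frozenset((stmt.x, stmt.y)) not in skeleton:
            continue
        pooled[stmt] = max(pooled.get(stmt, 0.0), p)
    # candidate actions: "X causes Y" orients the full edge X -> Y (tail at
    # X, arrowhead at Y: an ancestor cannot in turn be caused by its
    # descendant); its complement only fixes the arrowhead at X.
    candidates: list[tuple[float, tuple, str, str, str]] = []
    for stmt, p in pooled.items():
        x, y = stmt.x, stmt.y
        vetoed = background is not None and background.forbids(x, y)
        if not vetoed:
            candidates.append((p, (x, y, "cause"), x, y, "cause"))
        candidates.append((1.0 - p, (x, y, "notcause"), x, y, "notcause"))
    candidates.sort(key=lambda c: (-c[0], c[1]))
    fixed: dict[tuple[str, str], Mark] = {}  # (edge-other, endpoint) -> mark

    def try_set(a: str, b: str, mark: Mark, updates) -> bool:
        # mark at the b end of edge a--b
        cur = fixed.get((a, b))
        if cur is not None and cur is not mark:
            return False
        updates.append((a, b, mark))
        return True

    for rel, _key, x, y, action in candidates:
        if rel <= threshold:
            continue
        updates: list[tuple[str, str, Mark]] = []
        if action == "cause":
            ok = try_set(y, x, Mark.TAIL, updates) and \
                try_set(x, y, Mark.ARROW, updates)
        else:
            ok = try_set(y, x, Mark.ARROW, updates)
        if not ok:
            continue  # conflicts with an earlier, more reliable statement
        for a, b, mark in updates:
            pag.set_mark(a, b, mark)
            fixed[(a, b)] = mark
    return pag


# ---------------------------------------------------------------------------
# end-to-end
# ---------------------------------------------------------------------------

ESTIMATORS = ("em", "spearman-pairwise", "spearman-adjusted",
              "spearman-mean", "spearman-listwise")


def estimate_correlation(data: MixedDataset, estimator: str = "em",
                         transform_method: str = "midrank",
                         em_tol: float = 1e-6, em_max_iter: int = 500):
    """Dispatch to one of the five correlation estimators.

    Returns ``(CorrelationMatrix, EMResult | None)``.  Non-EM estimators are
    projected to the nearest positive-definite correlation matrix when needed.
    """
    if estimator == "em":
        res = em_correlation(transform_dataset(data, method=transform_method),
                             tol=em_tol, max_iter=em_max_iter)
        return res.correlation, res
    if estimator == "spearman-pairwise":
        corr = spearman_pairwise(data, adjusted=False)
    elif estimator == "spearman-adjusted":
        corr = spearman_pairwise(data, adjusted=True)
    elif estimator == "spearman-mean":
        corr = mean_impute_correlation(data)
    elif estimator == "spearman-listwise":
        corr = listwise_correlation(data)
    else:
        raise ValueError(f"unknown estimator {estimator!r}; "
                         f"choose from {ESTIMATORS}")
    if not corr.is_positive_definite(PD_FLOOR):
        corr = nearest_positive_definite(corr)
    return corr, None


@dataclass
class BCCDOutput:
    """End-to-end result: PAG, reliabilities and intermediate artefacts."""

    pag: PAG
    reliabilities: ReliabilityTable
    edge_reliability: dict[frozenset[str], float]
    correlation: CorrelationMatrix
    skeleton: set[frozenset[str]]
    sepsets: dict[frozenset[str], tuple[str, ...]]
    em_result: object | None = None


def run_bccd(data: MixedDataset, estimator: str = "em",
             threshold: float = DEFAULT_THRESHOLD,
             orientation_threshold: float = DEFAULT_ORIENT_THRESHOLD,
             max_cond: int = MAX_COND,
             background: BackgroundKnowledge | None = None,
             transform_method: str = "midrank",
             em_tol: float = 1e-6, em_max_iter: int = 500) -> BCCDOutput:
    """Transform -> correlation -> adjacency search -> orientation."""
    if background is not None:
        background.validate(data.names)
    corr, em_res = estimate_correlation(data, estimator, transform_method,
                                        em_tol, em_max_iter)
    M = effective_sample_size(data)
    search = adjacency_search(corr, M, threshold=threshold, max_cond=max_cond,
                              background=background)
    causal = causal_reliabilities(corr, M, search.skeleton, search.windows,
                                  background)
    pag = orient_edges(search.skeleton, causal, background,
                       threshold=orientation_threshold, nodes=data.names)
    # edge reliability: confidence the dependence is real = 1 - best
    # independence reliability seen for the pair
    best_indep: dict[frozenset[str], float] = {}
    for stmt, p, _w in search.reliabilities.entries:
        if stmt.kind == "independence":
            key = frozenset((stmt.x, stmt.y))
            best_indep[key] = max(best_indep.get(key, 0.0), p)
    edge_rel = {e: 1.0 - best_indep.get(e, 0.0) for e in search.skeleton}
    table = ReliabilityTable(search.reliabilities.entries + causal.entries)
    return BCCDOutput(pag, table, edge_rel, corr, search.skeleton,
                      search.sepsets, em_res)
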