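"""Constraint-based causal structure learning for continuous abundance data.

The learning pipeline is the order-independent variant of the PC algorithm
("PC-stable"):

1. start from the complete undirected graph and delete edges by Gaussian
   (Fisher-z) conditional-independence tests, freezing the adjacency sets at
   the start of each conditioning-set size so that the result does not
   depend on the variable order;
2. orient unshielded triples into v-structures using the recorded
   separating sets;
3. complete the orientation with the Meek rules.

Surviving edges are annotated with the sign of the marginal Pearson
correlation of their endpoints, which is how edges are colored when the
network is visualized.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Callable, Dict, FrozenSet, Iterable, List, Optional, Sequence, Set, Tuple

import networkx as nx
import numpy as np
import pandas as pd

from .graph_core import EdgeAnnotation, GraphError, PartiallyDirectedGraph, apply_meek_rules

logger = logging.getLogger(__name__)

Pair = FrozenSet[str]
SepsetMap = Dict[Pair, FrozenSet[str]]

#: a conditional-independence oracle/test: (i, j, S) -> independent?
CITest = Callable[[str, str, FrozenSet[str]], bool]


class DataError(ValueError):
    """Raised for invalid or degenerate input data."""


@dataclass
class DataTable:
    """A samples x variables numeric matrix with names.

    ``values`` has one row per sample and one column per variable.  Missing
    values are rejected; constant columns are tolerated here (with a
    warning) and dropped by :func:`learn_cpdag` before testing.
    """

    values: np.ndarray
    variable_names: List[str]
    sample_ids: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DataError("values must be a 2-D samples x variables matrix")
        self.variable_names = [str(v) for v in self.variable_names]
        if len(self.variable_names) != self.values.shape[1]:
            raise DataError(
                f"{len(self.variable_names)} variable names for "
                f"{self.values.shape[1]} columns"
            )
        if len(set(self.variable_names)) != len(self.variable_names):
            raise DataError("duplicate variable names")
        if not self.sample_ids:
            self.sample_ids = [f"S{k + 1}" for k in range(self.values.shape[0])]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if len(self.sample_ids) != self.values.shape[0]:
            raise DataError("sample_ids length does not match number of rows")
        if not np.isfinite(self.values).all():
            raise DataError("missing or non-finite values in data table")
        const = self.constant_columns()
        if const:
            logger.warning("constant column(s) in data table: %s", ", ".join(const))
        if self.n_samples < self.n_variables + 3:
            logger.warning(
                "only %d samples for %d variables; at least n_variables + 3 "
                "samples are recommended",
                self.n_samples,
                self.n_variables,
            )

    # ------------------------------------------------------------------ views
    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_variables(self) -> int:
        return self.values.shape[1]

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self._index(name)]

    def _index(self, name: str) -> int:
        try:
            return self.variable_names.index(name)
        except ValueError:
            raise DataError(f"unknown variable {name!r}") from None

    def constant_columns(self) -> List[str]:
        spread = self.values.max(axis=0) - self.values.min(axis=0)
        return [v for v, s in zip(self.variable_names, spread) if s == 0.0]

    def select(self, names: Sequence[str]) -> "DataTable":
        idx = [self._index(n) for n in names]
        return DataTable(self.values[:, idx], list(names), list(self.sample_ids))

    def take_rows(self, idx: np.ndarray, sample_ids: Optional[List[str]] = None) -> "DataTable":
        ids = sample_ids or [self.sample_ids[k] for k in idx]
        return DataTable(self.values[idx], list(self.variable_names), ids)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "DataTable":
        return cls(df.to_numpy(dtype=float), list(map(str, df.columns)), list(map(str, df.index)))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.variable_names)


@dataclass(frozen=True)
class CITestResult:
    """Outcome of one Fisher-z conditional-independence test."""

    statistic: float
    p_value: float
    independent: bool


# ---------------------------------------------------------------------------
# Fisher-z testing machinery
# ---------------------------------------------------------------------------

_ATANH_CLIP = 1.0 - 1e-12
_PINV_RCOND = 1e-10


def _correlation_matrix(data: DataTable) -> np.ndarray:
    const = data.constant_columns()
    if const:
        raise DataError(f"zero-variance variable(s): {', '.join(const)}")
    return np.corrcoef(data.values, rowvar=False)


def _partial_corr_from_matrix(corr: np.ndarray, i: int, j: int, s: Tuple[int, ...]) -> float:
    if not s:
        r = corr[i, j]
    else:
        idx = (i, j) + s
        sub = corr[np.ix_(idx, idx)]
        try:
            prec = np.linalg.inv(sub)
        except np.linalg.LinAlgError:
            prec = np.linalg.pinv(sub, rcond=_PINV_RCOND)
        denom = prec[0, 0] * prec[1, 1]
        if denom <= 0 or not np.isfinite(denom):
            prec = np.linalg.pinv(sub, rcond=_PINV_RCOND)
            denom = prec[0, 0] * prec[1, 1]
        r = -prec[0, 1] / math.sqrt(denom)
    return float(min(1.0, max(-1.0, r)))


def partial_correlation(data: DataTable, i: str, j: str, S: Iterable[str] = ()) -> float:
    """Sample partial correlation of ``i`` and ``j`` given the set ``S``.

    Computed from the inverse of the relevant submatrix of the sample
    correlation matrix (pseudo-inverse when near-singular).  With an empty
    conditioning set this is the plain Pearson correlation.
    """
    S = frozenset(S)
    if i == j:
        raise DataError("i and j must differ")
    if i in S or j in S:
        raise DataError("conditioning set may not contain the tested variables")
    sub = data.select([i, j] + sorted(S))
    corr = _correlation_matrix(sub)
    return _partial_corr_from_matrix(corr, 0, 1, tuple(range(2, 2 + len(S))))


def _fisher_z(r: float, n_samples: int, cond_size: int, alpha: float) -> CITestResult:
    dof = n_samples - cond_size - 3
    if dof < 1:
        raise DataError(
            f"too few samples ({n_samples}) for a conditioning set of size {cond_size}"
        )
    r = min(_ATANH_CLIP, max(-_ATANH_CLIP, r))
    z = math.sqrt(dof) * math.atanh(r)
    p = math.erfc(abs(z) / math.sqrt(2.0))
    return CITestResult(statistic=z, p_value=p, independent=p > alpha)


def gaussian_ci_test(
    data: DataTable, i: str, j: str, S: Iterable[str] = (), alpha: float = 0.05
) -> CITestResult:
    """Fisher-z test of ``i`` independent of ``j`` given ``S`` at level alpha.

    The statistic is ``z = sqrt(n - |S| - 3) * atanh(r)`` with ``r`` the
    partial correlation; the p-value is two-sided standard normal.  A
    partial correlation of exactly +/-1 saturates to p = 0 (dependent)
    rather than raising.
    """
    S = frozenset(S)
    r = partial_correlation(data, i, j, S)
    return _fisher_z(r, data.n_samples, len(S), alpha)


def dsep_oracle(dag: PartiallyDirectedGraph) -> CITest:
    """A perfect conditional-independence oracle backed by d-separation.

    Useful for soundness checks: with this oracle in place of the data
    test, PC-stable must recover the exact CPDAG of ``dag``.
    """
    if not dag.is_dag:
        raise GraphError("the d-separation oracle needs a fully directed DAG")
    g = dag.to_networkx()

    def test(i: str, j: str, S: FrozenSet[str]) -> bool:
        return nx.is_d_separator(g, {i}, {j}, set(S))

    return test


# ---------------------------------------------------------------------------
# PC-stable
# ---------------------------------------------------------------------------

def _prepare(
    data: Optional[DataTable],
    alpha: float,
    ci_test: Optional[CITest],
    nodes: Optional[Sequence[str]],
) -> Tuple[List[str], Callable[[int, int, Tuple[int, ...]], bool], int]:
    """Resolve the node list and an index-based CI test closure."""
    if data is None and ci_test is None:
        raise DataError("either data or a ci_test with nodes must be supplied")
    if data is not None:
        names = list(data.variable_names)
        if ci_test is None:
            corr = _correlation_matrix(data)
            n = data.n_samples
            max_level = n - 4

            def fast_test(i: int, j: int, s: Tuple[int, ...]) -> bool:
                r = _partial_corr_from_matrix(corr, i, j, s)
                return _fisher_z(r, n, len(s), alpha).independent

            return names, fast_test, max_level
    else:
        if nodes is None:
            raise DataError("nodes must be given when learning from a CI oracle")
        names = list(nodes)

    assert ci_test is not None

    def wrapped(i: int, j: int, s: Tuple[int, ...]) -> bool:
        return ci_test(names[i], names[j], frozenset(names[k] for k in s))

    return names, wrapped, len(names)


def learn_skeleton(
    data: Optional[DataTable] = None,
    alpha: float = 0.05,
    max_cond_size: Optional[int] = None,
    *,
    ci_test: Optional[CITest] = None,
    nodes: Optional[Sequence[str]] = None,
) -> Tuple[PartiallyDirectedGraph, SepsetMap]:
    """PC-stable skeleton search.

    At each level l = 0, 1, 2, ... the adjacency sets used for conditioning
    are frozen before any deletion at that level, which makes the result
    independent of the variable order.  An edge {i, j} is deleted as soon as
    some subset S of adj(i)\\{j} or adj(j)\\{i} with |S| = l renders the pair
    independent; that first S is recorded in the returned separating-set map.

    A custom ``ci_test`` (e.g. :func:`dsep_oracle`) replaces the Gaussian
    test; then ``nodes`` must list the variables if no data table is given.
    """
    if not 0.0 < alpha < 1.0:
        raise DataError(f"alpha must lie in (0, 1), got {alpha}")
    names, test, level_cap = _prepare(data, alpha, ci_test, nodes)
    if max_cond_size is not None:
        level_cap = min(level_cap, max_cond_size)
    p = len(names)

    adj: List[Set[int]] = [set(range(p)) - {i} for i in range(p)]
    sepsets: Dict[FrozenSet[int], Tuple[int, ...]] = {}

    # every sweep and subset enumeration is ordered by variable *name*, so
    # the sepsets (not just the skeleton) are column-permutation invariant
    def by_name(indices) -> List[int]:
        return sorted(indices, key=names.__getitem__)

    level = 0
    while level <= level_cap:
        frozen = [set(a) for a in adj]
        if all(len(frozen[i] - {j}) < level for i in range(p) for j in frozen[i]):
            break
        for i in by_name(range(p)):
            for j in by_name(frozen[i]):
                if j not in adj[i]:
                    continue  # already removed at this level
                cands = by_name(frozen[i] - {j})
                if len(cands) < level:
                    continue
                for s in combinations(cands, level):
                    if test(i, j, s):
                        adj[i].discard(j)
                        adj[j].discard(i)
                        sepsets[frozenset((i, j))] = s
                        break
        level += 1

    undirected = {
        frozenset((names[i], names[j])) for i in range(p) for j in adj[i] if i < j
    }
    skeleton = PartiallyDirectedGraph(names, (), undirected)
    sepset_map: SepsetMap = {
        frozenset((names[i], names[j])): frozenset(names[k] for k in s)
        for pair, s in sepsets.items()
        for i, j in [tuple(pair)]
    }
    return skeleton, sepset_map


def orient_v_structures(
    skeleton: PartiallyDirectedGraph, sepsets: SepsetMap
) -> PartiallyDirectedGraph:
    """Orient unshielded triples i - j - k into colliders i -> j <- k.

    A triple is oriented iff j is absent from the separating set of the
    nonadjacent pair (i, k).  When two triples demand opposite directions
    for the same edge, the orientation fixed first wins and the conflict is
    logged; triples are visited in variable-*name* order so the outcome is
    invariant to the column order of the input table.
    """
    if not skeleton.is_skeleton:
        raise GraphError("orient_v_structures expects an all-undirected skeleton")
    nodes = skeleton.nodes
    visit = sorted(nodes)
    order = {v: k for k, v in enumerate(visit)}

    directed: Set[Tuple[str, str]] = set()
    undirected: Set[Pair] = set(skeleton.undirected_edges)

    def _has_directed_path(src: str, dst: str) -> bool:
        stack, seen = [src], {src}
        while stack:
            v = stack.pop()
            for a, b in directed:
                if a == v and b not in seen:
                    if b == dst:
                        return True
                    seen.add(b)
                    stack.append(b)
        return False

    def orient(tail: str, head: str) -> None:
        if (tail, head) in directed:
            return
        if (head, tail) in directed:
            logger.debug(
                "conflicting v-structure orientation %s -> %s dropped; "
                "keeping earlier %s -> %s",
                tail, head, head, tail,
            )
            return
        if _has_directed_path(head, tail):
            # inconsistent CI answers can propose a cycle-closing collider;
            # keep the earlier orientations and skip this one
            logger.debug(
                "orientation %s -> %s would close a directed cycle; skipped",
                tail, head,
            )
            return
        undirected.discard(frozenset((tail, head)))
        directed.add((tail, head))

    for j in visit:
        nb = sorted(skeleton.undirected_neighbors(j), key=order.__getitem__)
        for a in range(len(nb)):
            for b in range(a + 1, len(nb)):
                i, k = nb[a], nb[b]
                if skeleton.adjacent(i, k):
                    continue
                pair = frozenset((i, k))
                if pair not in sepsets:
                    raise GraphError(
                        f"no separating set recorded for removed pair ({i}, {k})"
                    )
                if j not in sepsets[pair]:
                    orient(i, j)
                    orient(k, j)

    return PartiallyDirectedGraph(nodes, directed, undirected, skeleton.annotations)


def orient_v_structures_majority(
    skeleton: PartiallyDirectedGraph,
    indep: Callable[[str, str, FrozenSet[str]], bool],
    max_cond_size: Optional[int] = None,
) -> PartiallyDirectedGraph:
    """Order-independent collider orientation by majority vote.

    For every unshielded triple i - j - k, all subsets of the skeleton
    neighborhoods of i and of k are tested for separating the pair; the
    triple is oriented as a collider i -> j <- k iff j appears in fewer
    than half of the separating sets found.  With a perfect independence
    oracle the vote is unanimous (colliders never appear in a separating
    set, non-colliders always do), so the rule is exact; on finite data it
    is markedly more robust than trusting the single recorded sepset.
    Cycle-closing and conflicting orientations are skipped as in
    :func:`orient_v_structures`.
    """
    if not skeleton.is_skeleton:
        raise GraphError("orientation expects an all-undirected skeleton")
    nodes = skeleton.nodes
    visit = sorted(nodes)
    order = {v: k for k, v in enumerate(visit)}

    directed: Set[Tuple[str, str]] = set()
    undirected: Set[Pair] = set(skeleton.undirected_edges)

    def _has_directed_path(src: str, dst: str) -> bool:
        stack, seen = [src], {src}
        while stack:
            v = stack.pop()
            for a, b in directed:
                if a == v and b not in seen:
                    if b == dst:
                        return True
                    seen.add(b)
                    stack.append(b)
        return False

    def orient(tail: str, head: str) -> None:
        if (tail, head) in directed or (head, tail) in directed:
            return
        if _has_directed_path(head, tail):
            logger.debug(
                "orientation %s -> %s would close a directed cycle; skipped",
                tail, head,
            )
            return
        undirected.discard(frozenset((tail, head)))
        directed.add((tail, head))

    def separating_sets(i: str, k: str) -> List[FrozenSet[str]]:
        found: Set[FrozenSet[str]] = set()
        for side in (i, k):
            other = k if side == i else i
            cands = sorted(skeleton.undirected_neighbors(side) - {other})
            cap = len(cands) if max_cond_size is None else min(len(cands), max_cond_size)
            for r in range(cap + 1):
                for s in combinations(cands, r):
                    fs = frozenset(s)
                    if fs not in found and indep(i, k, fs):
                        found.add(fs)
        return list(found)

    for j in visit:
        nb = sorted(skeleton.undirected_neighbors(j), key=order.__getitem__)
        for a in range(len(nb)):
            for b in range(a + 1, len(nb)):
                i, k = nb[a], nb[b]
                if skeleton.adjacent(i, k):
                    continue
                seps = separating_sets(i, k)
                if not seps:
                    continue  # pair is not separable after all; leave triple alone
                frac = sum(j in s for s in seps) / len(seps)
                if frac < 0.5:
                    orient(i, j)
                    orient(k, j)

    return PartiallyDirectedGraph(nodes, directed, undirected, skeleton.annotations)


def correlation_signs(data: DataTable, g: PartiallyDirectedGraph) -> Dict[Pair, EdgeAnnotation]:
    """Annotate every edge with the sign of the endpoints' Pearson correlation."""
    corr = np.corrcoef(data.values, rowvar=False)
    idx = {v: k for k, v in enumerate(data.variable_names)}
    out: Dict[Pair, EdgeAnnotation] = {}
    pairs = [frozenset(e) for e in g.directed_edges] + list(g.undirected_edges)
    for pair in pairs:
        a, b = sorted(pair)
        out[pair] = EdgeAnnotation(sign=int(np.sign(corr[idx[a], idx[b]])))
    return out


def learn_cpdag(
    data: Optional[DataTable] = None,
    alpha: float = 0.05,
    max_cond_size: Optional[int] = None,
    *,
    ci_test: Optional[CITest] = None,
    nodes: Optional[Sequence[str]] = None,
    annotate: bool = True,
    v_structure_rule: str = "majority",
) -> PartiallyDirectedGraph:
    """Full structure learning: skeleton, v-structures, Meek completion, signs.

    ``v_structure_rule`` selects how colliders are identified: ``majority``
    (default) re-tests all neighborhood subsets of each unshielded triple
    and votes (:func:`orient_v_structures_majority`), while ``sepset``
    trusts the single separating set recorded during skeleton search
    (:func:`orient_v_structures`).  Both agree under a perfect oracle.

    Constant columns are dropped (with a warning) before testing, since a
    zero-variance variable carries no dependence information.  The result is
    a CPDAG whose edges carry the marginal-correlation sign annotation when
    data are available.
    """
    if v_structure_rule not in ("majority", "sepset"):
        raise DataError(
            f"v_structure_rule must be 'majority' or 'sepset', got {v_structure_rule!r}"
        )
    if data is not None:
        const = data.constant_columns()
        if const:
            logger.warning("dropping constant column(s): %s", ", ".join(const))
            keep = [v for v in data.variable_names if v not in const]
            data = data.select(keep)
    skeleton, sepsets = learn_skeleton(
        data, alpha, max_cond_size, ci_test=ci_test, nodes=nodes
    )
    if v_structure_rule == "sepset":
        pdag = orient_v_structures(skeleton, sepsets)
    else:
        names, test, _ = _prepare(data, alpha, ci_test, nodes)
        pos = {v: k for k, v in enumerate(names)}

        def indep(i: str, j: str, s: FrozenSet[str]) -> bool:
            try:
                return test(pos[i], pos[j], tuple(sorted(pos[v] for v in s)))
            except DataError:
                return False  # conditioning set too large for the sample size

        pdag = orient_v_structures_majority(skeleton, indep, max_cond_size)
    cpdag = apply_meek_rules(pdag)
    if annotate and data is not None:
        cpdag = cpdag.with_annotations(correlation_signs(data, cpdag))
    return cpdag
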