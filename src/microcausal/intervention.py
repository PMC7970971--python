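"""Total causal effects by interventional calculus and influence scores.

Under a linear-Gaussian model, the effect of do(X_i = x) on X_n is linear in
x, and its slope equals the coefficient of X_i in the ordinary
least-squares regression of X_n on X_i together with the parents of X_i
(parent adjustment).  The slope does not depend on the intervention value,
so no such value appears anywhere in this API.

On a CPDAG some edges at the cause are undirected, leaving the parent set
ambiguous.  We enumerate every locally valid parent set (IDA-style) and
summarize the resulting multiset — by default its minimum-absolute-value
element, a conservative lower bound on the effect magnitude.

The *causal influence* of a node is the sum of the absolute total effects
it exerts on every other node, whether or not they are directly linked;
taking absolute values keeps positive and negative effects of a strong
node from canceling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import chain, combinations
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .graph_core import GraphError, PartiallyDirectedGraph, reachable_from
from .pc_stable import DataError, DataTable

logger = logging.getLogger(__name__)

#: summary rules for the CPDAG parent-set multiset
EFFECT_SUMMARIES = ("min_abs", "mean")

#: per-variable influence scores; index = variable names
InfluenceVector = pd.Series


@dataclass
class EffectMatrix:
    """All-pairs total causal effects; rows are causes, columns effects."""

    values: np.ndarray
    variable_names: List[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.variable_names)
        if self.values.shape != (n, n):
            raise ValueError("effect matrix must be square over the variable names")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("effect matrix diagonal must be zero")

    def effect(self, cause: str, effect: str) -> float:
        i = self.variable_names.index(cause)
        j = self.variable_names.index(effect)
        return float(self.values[i, j])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.variable_names, columns=self.variable_names
        )


# ---------------------------------------------------------------------------
# regression plumbing
# ---------------------------------------------------------------------------

def _design(data: DataTable, cause: str, parents: Sequence[str]) -> np.ndarray:
    cols = [data.column(cause)] + [data.column(p) for p in parents]
    return np.column_stack([np.ones(data.n_samples)] + cols)


def _gamma(data: DataTable, cause: str, effect: str, parents: Sequence[str]) -> float:
    """OLS coefficient of ``cause`` in effect ~ 1 + cause + parents."""
    a = _design(data, cause, parents)
    y = data.column(effect)
    coef, _, rank, _ = np.linalg.lstsq(a, y, rcond=None)
    if rank < a.shape[1]:
        raise DataError(
            "rank-deficient adjustment regression; collinear variables among "
            f"{[cause] + list(parents)}"
        )
    return float(coef[1])


def adjustment_effect(
    dag: PartiallyDirectedGraph, data: DataTable, cause: str, effect: str
) -> float:
    """Total causal effect of ``cause`` on ``effect`` in a fully directed DAG.

    Returns 0 when ``effect`` is a parent of ``cause`` (intervening on a
    node cannot move its parents in an acyclic model) and 0 when no
    directed path leads from cause to effect.  Otherwise the effect is the
    cause's coefficient in the parent-adjusted regression.
    """
    if not dag.is_dag:
        raise GraphError("adjustment_effect requires a fully directed DAG")
    if cause == effect:
        raise GraphError("cause and effect must differ")
    parents = sorted(dag.parents(cause), key=dag.nodes.index)
    if effect in parents:
        return 0.0
    if effect not in reachable_from(dag, cause):
        return 0.0
    return _gamma(data, cause, effect, parents)


# ---------------------------------------------------------------------------
# CPDAG-aware effects
# ---------------------------------------------------------------------------

def _valid_parent_sets(g: PartiallyDirectedGraph, cause: str) -> List[List[str]]:
    """Locally valid parent sets of ``cause`` in a CPDAG.

    Each subset T of the undirected neighbors may be added to the directed
    parents provided orienting T -> cause creates no new v-structure at the
    cause, i.e. every member of T is adjacent to every other chosen parent.
    """
    order = g.nodes.index
    directed = sorted(g.parents(cause), key=order)
    undirected = sorted(g.undirected_neighbors(cause), key=order)
    sets: List[List[str]] = []
    for r in range(len(undirected) + 1):
        for t in combinations(undirected, r):
            ok = True
            for u in t:
                for other in chain(directed, t):
                    if other != u and not g.adjacent(u, other):
                        ok = False
                        break
                if not ok:
                    break
            if ok:
                sets.append(sorted(chain(directed, t), key=order))
    return sets


def _semi_reachable(g: PartiallyDirectedGraph, node: str) -> Set[str]:
    """Nodes reachable along paths that never run against a directed edge."""
    seen: Set[str] = set()
    stack = [node]
    while stack:
        v = stack.pop()
        for c in g.children(v) | g.undirected_neighbors(v):
            if c not in seen:
                seen.add(c)
                stack.append(c)
    seen.discard(node)
    return seen


def _summarize(multiset: List[float], summary: str) -> float:
    if summary == "min_abs":
        return min(multiset, key=abs)
    if summary == "mean":
        return float(np.mean(multiset))
    raise ValueError(f"unknown summary {summary!r}; use one of {EFFECT_SUMMARIES}")


def causal_effect(
    g: PartiallyDirectedGraph,
    data: DataTable,
    cause: str,
    effect: str,
    summary: str = "min_abs",
    full: bool = False,
):
    """Total causal effect of ``cause`` on ``effect`` in a DAG or CPDAG.

    For a DAG this is :func:`adjustment_effect`.  For a CPDAG, the effect is
    computed under every locally valid parent set of the cause and the
    multiset summarized by ``summary`` ("min_abs" or "mean").  With
    ``full=True`` returns ``(value, multiset)`` for inspection.
    """
    if g.is_dag:
        value = adjustment_effect(g, data, cause, effect)
        return (value, [value]) if full else value
    if cause == effect:
        raise GraphError("cause and effect must differ")
    if effect not in _semi_reachable(g, cause):
        return (0.0, [0.0]) if full else 0.0
    multiset: List[float] = []
    for parents in _valid_parent_sets(g, cause):
        if effect in parents:
            multiset.append(0.0)
        else:
            multiset.append(_gamma(data, cause, effect, parents))
    value = _summarize(multiset, summary)
    return (value, multiset) if full else value


def causal_effect_matrix(
    g: PartiallyDirectedGraph,
    data: DataTable,
    summary: str = "min_abs",
) -> EffectMatrix:
    """All ordered-pair total effects; diagonal zero.

    Vectorized over effects: for each cause and each valid parent set, one
    least-squares solve yields the coefficients against every column at
    once.
    """
    if summary not in EFFECT_SUMMARIES:
        raise ValueError(f"unknown summary {summary!r}; use one of {EFFECT_SUMMARIES}")
    names = [v for v in g.nodes]
    missing = [v for v in names if v not in data.variable_names]
    if missing:
        raise DataError(f"graph nodes absent from data: {missing}")
    col = {v: data.variable_names.index(v) for v in names}
    x = data.values
    n = len(names)
    out = np.zeros((n, n))

    for ci, cause in enumerate(names):
        if g.is_dag:
            reach = reachable_from(g, cause)
            parent_sets = [sorted(g.parents(cause), key=g.nodes.index)]
        else:
            reach = _semi_reachable(g, cause)
            parent_sets = _valid_parent_sets(g, cause)
        if not reach:
            continue
        stacks = []
        for parents in parent_sets:
            a = np.column_stack(
                [np.ones(x.shape[0]), x[:, col[cause]]]
                + [x[:, col[p]] for p in parents]
            )
            coef, _, rank, _ = np.linalg.lstsq(a, x[:, [col[v] for v in names]], rcond=None)
            if rank < a.shape[1]:
                raise DataError(
                    "rank-deficient adjustment regression; collinear variables "
                    f"among {[cause] + list(parents)}"
                )
            gam = coef[1, :].copy()
            for ei, eff in enumerate(names):
                if eff == cause or eff in parents or eff not in reach:
                    gam[ei] = 0.0
            stacks.append(gam)
        grid = np.vstack(stacks)
        if summary == "min_abs":
            out[ci] = grid[np.argmin(np.abs(grid), axis=0), np.arange(n)]
        else:
            out[ci] = grid.mean(axis=0)
    return EffectMatrix(out, names)


# ---------------------------------------------------------------------------
# influence
# ---------------------------------------------------------------------------

def causal_influence(effects: EffectMatrix) -> InfluenceVector:
    """CI(B_i) = sum over j != i of |C(B_i, B_j)| — row sums of absolute effects."""
    totals = np.abs(effects.values).sum(axis=1)
    return pd.Series(totals, index=effects.variable_names, name="causal_influence")


def rank_by_influence(ci: InfluenceVector, top_k: Optional[int] = None) -> List[str]:
    """Variables in descending influence order; ties broken by input order."""
    order = {v: k for k, v in enumerate(ci.index)}
    ranked = sorted(ci.index, key=lambda v: (-ci[v], order[v]))
    return ranked[:top_k] if top_k is not None else ranked


def influence_change(
    ci_first: InfluenceVector, ci_second: InfluenceVector, top_k: Optional[int] = None
) -> pd.Series:
    """Signed per-variable change ``ci_first - ci_second``.

    With the healthy-cohort influences first, positive entries flag
    variables more influential in health, negative ones more influential in
    disease.  Sorted by descending signed change; variable sets must match.
    """
    if set(ci_first.index) != set(ci_second.index):
        raise ValueError("influence vectors cover different variable sets")
    delta = ci_first - ci_second.reindex(ci_first.index)
    delta = delta.sort_values(ascending=False, kind="stable")
    delta.name = "influence_change"
    return delta.iloc[:top_k] if top_k is not None else delta


def effect_tails(effects: EffectMatrix, fraction: float = 0.15) -> pd.DataFrame:
    """Flag the strongest pairwise effects: top/bottom ``fraction`` quantiles.

    Mirrors the histogram inspection of the all-pairs effect distribution:
    off-diagonal effects below the ``fraction`` quantile or above the
    ``1 - fraction`` quantile are returned with a ``tail`` label.
    """
    if not 0.0 < fraction < 0.5:
        raise ValueError("fraction must lie in (0, 0.5)")
    names = effects.variable_names
    n = len(names)
    mask = ~np.eye(n, dtype=bool)
    vals = effects.values[mask]
    lo, hi = np.quantile(vals, [fraction, 1.0 - fraction])
    rows = []
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            v = effects.values[i, j]
            if v <= lo or v >= hi:
                rows.append(
                    {
                        "cause": names[i],
                        "effect": names[j],
                        "value": v,
                        "tail": "bottom" if v <= lo else "top",
                    }
                )
    return pd.DataFrame(rows, columns=["cause", "effect", "value", "tail"])
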