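"""Outcome-augmented ("disease") networks and Y-structure enumeration.

*Context embedding* concatenates cohorts and appends an outcome column (0
for healthy, 1 for diseased, or an ordinal/continuous severity), so the
learned network contains an explicit outcome node and per-taxon effects on
it can be ranked.

A *Y-structure* is an unshielded collider X -> Z <- Y together with an
outgoing edge Z -> W (the *Y-leg*) where W is adjacent to neither X nor Y.
The Y-leg is provably unconfounded, which makes those edges the most
trustworthy causal claims in the network.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .graph_core import GraphError, PartiallyDirectedGraph
from .intervention import causal_effect
from .pc_stable import DataError, DataTable, learn_cpdag

logger = logging.getLogger(__name__)


@dataclass
class ContextTable:
    """A data table with one designated outcome column."""

    data: DataTable
    outcome: str

    def __post_init__(self) -> None:
        if self.outcome not in self.data.variable_names:
            raise DataError(f"outcome column {self.outcome!r} not in table")
        vals = np.unique(self.data.column(self.outcome))
        if len(vals) == 2 and not set(vals) <= {0.0, 1.0}:
            raise DataError(
                f"binary outcome must be coded {{0, 1}}, found values {vals.tolist()}"
            )

    @property
    def taxa(self) -> List[str]:
        return [v for v in self.data.variable_names if v != self.outcome]


def embed_context(
    cohorts: Sequence[Tuple[DataTable, float]], outcome_name: str = "disease"
) -> ContextTable:
    """Row-concatenate cohorts and append a per-sample outcome column.

    Each cohort is a ``(table, outcome_value)`` pair — e.g. the diseased
    cohort with value 1 and the healthy cohort with value 0.  Cohorts with
    differing variable sets are reduced to the intersection with a warning;
    duplicated sample ids across cohorts are an error.
    """
    if not cohorts:
        raise DataError("no cohorts supplied")
    common = [v for v in cohorts[0][0].variable_names]
    for table, _ in cohorts[1:]:
        present = set(table.variable_names)
        if set(common) != present:
            logger.warning(
                "cohorts differ in variables; keeping the %d common ones",
                len(set(common) & present),
            )
        common = [v for v in common if v in present]
    if outcome_name in common:
        raise DataError(f"variable {outcome_name!r} already present in the cohorts")

    seen: Set[str] = set()
    blocks, outcome, ids = [], [], []
    for table, value in cohorts:
        dup = seen & set(table.sample_ids)
        if dup:
            raise DataError(f"duplicated sample ids across cohorts: {sorted(dup)[:5]}")
        seen |= set(table.sample_ids)
        sub = table.select(common)
        blocks.append(sub.values)
        outcome.extend([float(value)] * sub.n_samples)
        ids.extend(sub.sample_ids)

    values = np.column_stack([np.vstack(blocks), np.asarray(outcome)])
    merged = DataTable(values, common + [outcome_name], ids)
    return ContextTable(merged, outcome_name)


def effects_on_outcome(
    g: PartiallyDirectedGraph,
    context: ContextTable,
    summary: str = "min_abs",
) -> pd.DataFrame:
    """Per-taxon total causal effect on the outcome node, ranked by |effect|.

    Returns a frame with columns ``cause``, ``effect_on_outcome`` and
    ``abs_rank`` (1 = strongest), sorted by descending absolute effect.
    """
    if context.outcome not in g.nodes:
        raise GraphError(f"outcome node {context.outcome!r} absent from the graph")
    rows = []
    for taxon in context.taxa:
        if taxon not in g.nodes:
            continue  # dropped (e.g. constant) during learning
        value = causal_effect(g, context.data, taxon, context.outcome, summary=summary)
        rows.append({"cause": taxon, "effect_on_outcome": value})
    frame = pd.DataFrame(rows, columns=["cause", "effect_on_outcome"])
    frame = frame.reindex(
        frame["effect_on_outcome"].abs().sort_values(ascending=False, kind="stable").index
    ).reset_index(drop=True)
    frame["abs_rank"] = np.arange(1, len(frame) + 1)
    return frame


@dataclass
class BootstrapEffectResult:
    """Sign-stability bootstrap of one pairwise effect."""

    p_value: float
    effects: np.ndarray
    n_replicates: int


def effect_pvalue_bootstrap(
    context: ContextTable,
    cause: str,
    outcome: Optional[str] = None,
    B: int = 100,
    alpha: float = 0.05,
    seed: Optional[int] = None,
    summary: str = "min_abs",
) -> BootstrapEffectResult:
    """Two-sided sign-stability bootstrap p-value for one effect.

    ``B`` row-resamples (with replacement, same n) each relearn the
    structure and recompute the effect.  The p-value is
    ``2 * min(#{effect <= 0}, #{effect >= 0}) / B`` clipped to [1/B, 1]: an
    effect whose sign survives resampling of both data and structure earns
    a small p.  Replicates whose structure has no directed path from cause
    to outcome (or lost a constant column) contribute effect 0.
    """
    outcome = outcome or context.outcome
    data = context.data
    for name in (cause, outcome):
        if name not in data.variable_names:
            raise DataError(f"variable {name!r} not in the context table")
    if B < 2:
        raise DataError("B must be at least 2")
    rng = np.random.default_rng(seed)
    n = data.n_samples
    effects = np.zeros(B)
    for b in range(B):
        idx = rng.integers(0, n, n)
        boot = data.take_rows(idx, sample_ids=[f"b{b}_{k}" for k in range(n)])
        try:
            g = learn_cpdag(boot, alpha, annotate=False)
            if cause in g.nodes and outcome in g.nodes:
                effects[b] = causal_effect(g, boot, cause, outcome, summary=summary)
        except DataError:
            effects[b] = 0.0
    lo = int(np.sum(effects <= 0))
    hi = int(np.sum(effects >= 0))
    p = 2.0 * min(lo, hi) / B
    p = min(1.0, max(1.0 / B, p))
    return BootstrapEffectResult(p_value=p, effects=effects, n_replicates=B)


# ---------------------------------------------------------------------------
# Y-structures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class YStructure:
    """Four nodes with X -> Z <- Y (X, Y nonadjacent) and leg Z -> W."""

    parents: Tuple[str, str]
    center: str
    leg_target: str

    @property
    def leg(self) -> Tuple[str, str]:
        return (self.center, self.leg_target)


def find_y_structures(g: PartiallyDirectedGraph) -> List[YStructure]:
    """Enumerate all Y-structures of a DAG or CPDAG.

    Only fully directed edges form the collider and the leg; undirected
    edges still count as adjacency for the non-adjacency requirements,
    which conservatively suppresses Y-legs whose unconfoundedness the data
    leave ambiguous.  Structures are deduplicated up to swapping the two
    collider parents.
    """
    order = {v: k for k, v in enumerate(g.nodes)}
    out: Set[YStructure] = set()
    for z in g.nodes:
        pa = sorted(g.parents(z), key=order.__getitem__)
        if len(pa) < 2:
            continue
        legs = sorted(g.children(z), key=order.__getitem__)
        for a in range(len(pa)):
            for b in range(a + 1, len(pa)):
                x, y = pa[a], pa[b]
                if g.adjacent(x, y):
                    continue
                for w in legs:
                    if w in (x, y):
                        continue
                    if g.adjacent(x, w) or g.adjacent(y, w):
                        continue
                    out.add(YStructure(parents=(x, y), center=z, leg_target=w))
    return sorted(
        out, key=lambda s: (order[s.center], order[s.leg_target], order[s.parents[0]])
    )


def y_leg_edges(structures: Sequence[YStructure]) -> Set[Tuple[str, str]]:
    """The distinct unconfounded leg edges across a set of Y-structures."""
    return {s.leg for s in structures}


def y_structures_table(structures: Sequence[YStructure]) -> pd.DataFrame:
    rows = [
        {
            "parent_1": s.parents[0],
            "parent_2": s.parents[1],
            "center": s.center,
            "leg_target": s.leg_target,
            "leg_edge": f"{s.center}->{s.leg_target}",
        }
        for s in structures
    ]
    return pd.DataFrame(
        rows, columns=["parent_1", "parent_2", "center", "leg_target", "leg_edge"]
    )
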