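"""Network-level statistical validation.

* bootstrap edge confidence — how often each adjacency (and each directed
  orientation) reappears when rows are resampled and the structure relearned;
* Gaussian network log-likelihood — the decomposable maximum-likelihood
  score of a DAG, each node scored by OLS on its parents;
* permutation significance — destroy all dependence by permuting each
  variable's values across samples, relearn and rescore N times; the
  fraction of null networks scoring above the observed one is the p-value;
* sensitivity scan — grow a perturbation (added, deleted or substituted
  samples) percent by percent until the relearned network first loses a
  high-confidence edge of the original.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Tuple

import numpy as np

from .graph_core import (
    GraphError,
    PartiallyDirectedGraph,
    consistent_extension,
)
from .pc_stable import DataError, DataTable, learn_cpdag

logger = logging.getLogger(__name__)

Pair = FrozenSet[str]

_VAR_FLOOR = 1e-12


@dataclass
class BootstrapConfidence:
    """Edge-stability frequencies from bootstrap replicates.

    ``adjacency`` maps an unordered pair to the fraction of replicates in
    which the pair was adjacent (any orientation); ``orientation`` maps a
    directed pair to the fraction of replicates containing that exact
    directed edge.  Adjacency is the default notion of "bootstrap value"
    because edge directions can flip across replicates even when the
    adjacency itself is stable.
    """

    adjacency: Dict[Pair, float]
    orientation: Dict[Tuple[str, str], float]
    n_replicates: int

    def confidence(self, a: str, b: str, directed: bool = False) -> float:
        if directed:
            return self.orientation.get((a, b), 0.0)
        return self.adjacency.get(frozenset((a, b)), 0.0)

    def summary(self, g: PartiallyDirectedGraph) -> Dict[str, float]:
        """Mean / median / sd of adjacency confidences over the edges of ``g``."""
        pairs = [frozenset(e) for e in g.directed_edges] + list(g.undirected_edges)
        vals = np.array([self.adjacency.get(p, 0.0) for p in pairs])
        if vals.size == 0:
            return {"mean": math.nan, "median": math.nan, "sd": math.nan}
        return {
            "mean": float(vals.mean()),
            "median": float(np.median(vals)),
            "sd": float(vals.std(ddof=0)),
        }


def bootstrap_edge_confidence(
    data: DataTable,
    alpha: float = 0.05,
    B: int = 200,
    seed: Optional[int] = None,
) -> BootstrapConfidence:
    """Relearn the CPDAG on ``B`` row-resamples and tabulate edge frequencies."""
    if B < 2:
        raise DataError("B must be at least 2")
    rng = np.random.default_rng(seed)
    n = data.n_samples
    adj_counts: Dict[Pair, int] = {}
    dir_counts: Dict[Tuple[str, str], int] = {}
    for b in range(B):
        idx = rng.integers(0, n, n)
        boot = data.take_rows(idx, sample_ids=[f"b{b}_{k}" for k in range(n)])
        try:
            g = learn_cpdag(boot, alpha, annotate=False)
        except DataError:
            continue
        for e in g.directed_edges:
            dir_counts[e] = dir_counts.get(e, 0) + 1
            pair = frozenset(e)
            adj_counts[pair] = adj_counts.get(pair, 0) + 1
        for pair in g.undirected_edges:
            adj_counts[pair] = adj_counts.get(pair, 0) + 1
    return BootstrapConfidence(
        adjacency={p: c / B for p, c in adj_counts.items()},
        orientation={e: c / B for e, c in dir_counts.items()},
        n_replicates=B,
    )


def gaussian_network_loglik(g: PartiallyDirectedGraph, data: DataTable) -> float:
    """Maximum-likelihood Gaussian log score of a DAG on the data.

    Decomposes over nodes: each node is regressed on its parents by OLS
    and contributes the Gaussian log-density at the fitted (MLE) residual
    variance.  A CPDAG is first oriented by :func:`consistent_extension`;
    all consistent extensions share the same score, so the choice is
    immaterial.
    """
    dag = g if g.is_dag else consistent_extension(g)
    n = data.n_samples
    total = 0.0
    for node in dag.nodes:
        y = data.column(node)
        parents = sorted(dag.parents(node), key=dag.nodes.index)
        if parents:
            a = np.column_stack(
                [np.ones(n)] + [data.column(p) for p in parents]
            )
            coef, _, _, _ = np.linalg.lstsq(a, y, rcond=None)
            resid = y - a @ coef
        else:
            resid = y - y.mean()
        var = float(np.mean(resid**2))
        if var < _VAR_FLOOR:
            logger.warning(
                "residual variance of %s below floor; clamping to %.0e",
                node,
                _VAR_FLOOR,
            )
            var = _VAR_FLOOR
        total += -0.5 * n * (math.log(2.0 * math.pi * var) + 1.0)
    return total


@dataclass
class PermutationResult:
    p_value: float
    observed_loglik: float
    null_logliks: np.ndarray


def permutation_significance(
    data: DataTable,
    alpha: float = 0.05,
    N: int = 1000,
    seed: Optional[int] = None,
) -> PermutationResult:
    """Permutation test of whether the learned network beats chance.

    Each round independently permutes every variable's values across
    samples (destroying all inter-variable dependence while preserving the
    marginals), relearns a network and rescores it.  The p-value is the
    fraction of permuted networks whose log-likelihood exceeds the
    observed network's.
    """
    if N < 10:
        raise DataError("N must be at least 10")
    rng = np.random.default_rng(seed)
    observed = gaussian_network_loglik(learn_cpdag(data, alpha, annotate=False), data)
    null = np.empty(N)
    for k in range(N):
        perm = np.column_stack(
            [rng.permutation(data.values[:, j]) for j in range(data.n_variables)]
        )
        table = DataTable(perm, list(data.variable_names), list(data.sample_ids))
        g = learn_cpdag(table, alpha, annotate=False)
        null[k] = gaussian_network_loglik(g, table)
    p = float(np.sum(null > observed) / N)
    return PermutationResult(p_value=p, observed_loglik=observed, null_logliks=null)


# ---------------------------------------------------------------------------
# sensitivity scan
# ---------------------------------------------------------------------------

SENSITIVITY_MODES = ("add", "delete", "substitute")


@dataclass
class PerturbationReport:
    """Outcome of one sensitivity scan.

    ``fraction_at_first_change`` is the percentage of perturbed samples at
    which the relearned network first lost a high-confidence edge of the
    baseline; ``exhausted`` flags a scan that ran out of samples without
    any significant change (fraction reported as 100).
    """

    mode: str
    fraction_at_first_change: float
    triggering_edges: List[Tuple[str, str]] = field(default_factory=list)
    steps: List[Dict] = field(default_factory=list)
    exhausted: bool = False


def _high_confidence_edges(
    baseline: PartiallyDirectedGraph,
    conf: BootstrapConfidence,
    threshold: float,
    directed: bool,
) -> List[Tuple[str, str]]:
    out = []
    for e in baseline.directed_edges:
        c = conf.confidence(*e, directed=directed)
        if c > threshold:
            out.append(e)
    if not directed:
        for pair in baseline.undirected_edges:
            a, b = sorted(pair)
            if conf.confidence(a, b) > threshold:
                out.append((a, b))
    return out


def _lost_edges(
    watch: List[Tuple[str, str]], g: PartiallyDirectedGraph, directed: bool
) -> List[Tuple[str, str]]:
    lost = []
    for a, b in watch:
        if a not in g.nodes or b not in g.nodes:
            lost.append((a, b))
        elif directed:
            if not g.has_directed_edge(a, b):
                lost.append((a, b))
        elif not g.adjacent(a, b):
            lost.append((a, b))
    return lost


def sensitivity_scan(
    data: DataTable,
    alpha: float = 0.05,
    mode: str = "add",
    step: float = 1.0,
    seed: Optional[int] = None,
    B: int = 200,
    confidence_threshold: float = 0.5,
    directed_edges_only: bool = False,
) -> PerturbationReport:
    """Perturb the data in ``step``-percent increments until the network breaks.

    Modes (each increment extends the previous perturbation):

    * ``add`` — append new rows drawn i.i.d. Gaussian with the mean and
      standard deviation of a randomly chosen existing sample, clipped at 0
      (abundances are nonnegative);
    * ``delete`` — remove randomly chosen rows;
    * ``substitute`` — for randomly chosen rows, replace every entry by a
      draw from that column's empirical distribution.

    A *significant change* is the loss, in the relearned network, of any
    baseline edge whose bootstrap confidence exceeds
    ``confidence_threshold`` (adjacency-based by default; set
    ``directed_edges_only`` to require the exact orientation).
    """
    if mode not in SENSITIVITY_MODES:
        raise DataError(f"mode must be one of {SENSITIVITY_MODES}, got {mode!r}")
    if step <= 0:
        raise DataError("step must be positive")
    rng = np.random.default_rng(seed)
    baseline = learn_cpdag(data, alpha, annotate=False)
    conf = bootstrap_edge_confidence(data, alpha, B=B, seed=seed)
    watch = _high_confidence_edges(baseline, conf, confidence_threshold, directed_edges_only)
    if not watch:
        logger.warning("no high-confidence edges to monitor; scan is vacuous")

    n = data.n_samples
    n_vars = data.n_variables
    values = data.values
    added_rows: List[np.ndarray] = []
    deleted: List[int] = []
    remaining = list(range(n))
    substituted: List[int] = []
    untouched = list(range(n))
    steps_log: List[Dict] = []

    frac = 0.0
    while True:
        frac = round(frac + step, 10)
        target = int(round(frac / 100.0 * n))
        if frac > 100.0 or (mode == "delete" and n - target < n_vars + 3):
            return PerturbationReport(
                mode=mode,
                fraction_at_first_change=100.0,
                steps=steps_log,
                exhausted=True,
            )
        if mode == "add":
            while len(added_rows) < target:
                row = values[rng.integers(0, n)]
                new = rng.normal(row.mean(), row.std(), size=n_vars)
                added_rows.append(np.clip(new, 0.0, None))
            ids = list(data.sample_ids) + [f"synth{k}" for k in range(len(added_rows))]
            perturbed = DataTable(
                np.vstack([values] + [r[None, :] for r in added_rows]),
                list(data.variable_names),
                ids,
            )
        elif mode == "delete":
            while len(deleted) < target and remaining:
                k = remaining.pop(rng.integers(0, len(remaining)))
                deleted.append(k)
            keep = np.array(sorted(remaining))
            perturbed = data.take_rows(keep)
        else:  # substitute
            while len(substituted) < target and untouched:
                k = untouched.pop(rng.integers(0, len(untouched)))
                substituted.append(k)
            sub = values.copy()
            for k in substituted:
                for j in range(n_vars):
                    sub[k, j] = values[rng.integers(0, n), j]
            perturbed = DataTable(sub, list(data.variable_names), list(data.sample_ids))

        try:
            g = learn_cpdag(perturbed, alpha, annotate=False)
            lost = _lost_edges(watch, g, directed_edges_only)
        except DataError as err:
            logger.warning("perturbed data became degenerate at %.1f%%: %s", frac, err)
            lost = list(watch)
        steps_log.append({"fraction": frac, "lost_edges": lost})
        if lost:
            return PerturbationReport(
                mode=mode,
                fraction_at_first_change=frac,
                triggering_edges=lost,
                steps=steps_log,
            )
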