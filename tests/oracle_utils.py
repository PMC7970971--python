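"""Independent brute-force oracles used to check the library.

Everything here is deliberately naive — enumeration and closed forms only —
and never calls the code paths it is used to verify.
"""

from __future__ import annotations

from itertools import combinations, permutations, product
from typing import Dict, List, Set, Tuple

import numpy as np

from microcausal import PartiallyDirectedGraph, WeightedDAG


def all_dags(n: int) -> List[PartiallyDirectedGraph]:
    """Every labeled DAG on n nodes, by enumerating pair states {none, ->, <-}."""
    names = [f"N{k}" for k in range(n)]
    pairs = list(combinations(range(n), 2))
    out = []
    for states in product((0, 1, 2), repeat=len(pairs)):
        edges = []
        for (i, j), s in zip(pairs, states):
            if s == 1:
                edges.append((names[i], names[j]))
            elif s == 2:
                edges.append((names[j], names[i]))
        if _is_acyclic(names, edges):
            out.append(PartiallyDirectedGraph(names, edges, ()))
    return out


def _is_acyclic(names, edges) -> bool:
    adj: Dict[str, Set[str]] = {v: set() for v in names}
    for a, b in edges:
        adj[a].add(b)
    color = {v: 0 for v in names}

    def dfs(v: str) -> bool:
        color[v] = 1
        for w in adj[v]:
            if color[w] == 1 or (color[w] == 0 and not dfs(w)):
                return False
        color[v] = 2
        return True

    return all(color[v] == 2 or dfs(v) for v in names)


def closure_by_matrix_powers(g: PartiallyDirectedGraph) -> Dict[str, Set[str]]:
    """Directed transitive closure via boolean powers of the adjacency matrix."""
    names = list(g.nodes)
    n = len(names)
    a = np.zeros((n, n), dtype=bool)
    for t, h in g.directed_edges:
        a[names.index(t), names.index(h)] = True
    reach = a.copy()
    power = a.copy()
    for _ in range(n - 1):
        power = power @ a
        reach |= power
    return {
        names[i]: {names[j] for j in range(n) if reach[i, j]} for i in range(n)
    }


def path_sum_effects(model: WeightedDAG) -> np.ndarray:
    """Total effects by explicit enumeration of all directed paths (DFS)."""
    names = list(model.nodes)
    idx = {v: k for k, v in enumerate(names)}
    children: Dict[str, List[str]] = {v: sorted(model.graph.children(v)) for v in names}
    out = np.zeros((len(names), len(names)))

    def dfs(start: str, v: str, prod: float) -> None:
        for c in children[v]:
            w = prod * model.coefficients[(v, c)]
            out[idx[start], idx[c]] += w
            dfs(start, c, w)

    for v in names:
        dfs(v, v, 1.0)
    np.fill_diagonal(out, 0.0)
    return out


def _vstructs(nodes, edges) -> Set[Tuple[str, str, str]]:
    eset = set(edges)
    adj = {frozenset(e) for e in edges}
    out = set()
    for a, c in eset:
        for b, c2 in eset:
            if c2 == c and a < b and frozenset((a, b)) not in adj:
                out.add((a, c, b))
    return out


def equivalence_class_cpdag(dag: PartiallyDirectedGraph) -> PartiallyDirectedGraph:
    """The CPDAG by brute force: enumerate every orientation of the skeleton,
    keep the acyclic ones with identical v-structures, and mark an edge
    directed only when the whole class agrees on its direction."""
    names = list(dag.nodes)
    base = sorted(tuple(sorted(e)) for e in dag.directed_edges)
    target_v = _vstructs(names, dag.directed_edges)
    members = []
    for flips in product((0, 1), repeat=len(base)):
        edges = [
            (a, b) if f == 0 else (b, a) for (a, b), f in zip(base, flips)
        ]
        if _is_acyclic(names, edges) and _vstructs(names, edges) == target_v:
            members.append(set(edges))
    directed, undirected = [], []
    for a, b in base:
        if all((a, b) in m for m in members):
            directed.append((a, b))
        elif all((b, a) in m for m in members):
            directed.append((b, a))
        else:
            undirected.append((a, b))
    return PartiallyDirectedGraph(names, directed, undirected)


def brute_force_y_structures(g: PartiallyDirectedGraph) -> Set[Tuple[str, str, str, str]]:
    """All (x, y, z, w), x < y, checked directly against the definition."""
    out = set()
    for x, y, z, w in permutations(g.nodes, 4):
        if x > y:
            continue
        if not (
            g.has_directed_edge(x, z)
            and g.has_directed_edge(y, z)
            and g.has_directed_edge(z, w)
        ):
            continue
        if g.adjacent(x, y) or g.adjacent(x, w) or g.adjacent(y, w):
            continue
        out.add((x, y, z, w))
    return out
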