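"""Partially directed graphs and generic operations on them.

A single container, :class:`PartiallyDirectedGraph`, houses the three graph
flavours the pipeline moves between:

* **skeleton** — only undirected edges (output of conditional-independence
  edge elimination);
* **CPDAG** — a mix of directed and undirected edges representing a Markov
  equivalence class of DAGs (same skeleton, same v-structures);
* **DAG** — only directed edges.

Graphs are value-semantic: every operation returns a new graph and never
mutates its input.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from graphlib import CycleError, TopologicalSorter
from typing import Dict, FrozenSet, Iterable, List, Sequence, Set, Tuple

import networkx as nx

logger = logging.getLogger(__name__)

Edge = Tuple[str, str]
Pair = FrozenSet[str]


class GraphError(ValueError):
    """Raised for structurally invalid graphs or graph queries."""


@dataclass(frozen=True)
class EdgeAnnotation:
    """Per-edge metadata: correlation sign and bootstrap confidence.

    ``sign`` is the sign of the marginal Pearson correlation of the two
    endpoint variables (+1, -1, or 0 for an exactly-zero correlation);
    ``confidence`` is a bootstrap adjacency frequency in [0, 1].
    """

    sign: int = 0
    confidence: float = 1.0

    def __post_init__(self) -> None:
        if self.sign not in (-1, 0, 1):
            raise ValueError(f"sign must be -1, 0 or +1, got {self.sign}")
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError(f"confidence must lie in [0, 1], got {self.confidence}")


class PartiallyDirectedGraph:
    """A graph over named nodes with directed and undirected edges.

    Parameters
    ----------
    nodes
        Ordered node names. The order is load-bearing: every deterministic
        tie-break in the package (orientation conflicts, free orientation
        choices in :func:`consistent_extension`, ranking ties) follows it.
    directed_edges
        Ordered pairs ``(tail, head)``.
    undirected_edges
        Unordered pairs; any 2-iterable is accepted.
    annotations
        Optional mapping from unordered node pair to :class:`EdgeAnnotation`.
    """

    def __init__(
        self,
        nodes: Sequence[str],
        directed_edges: Iterable[Edge] = (),
        undirected_edges: Iterable[Iterable[str]] = (),
        annotations: Dict[Pair, EdgeAnnotation] | None = None,
    ) -> None:
        self._nodes: Tuple[str, ...] = tuple(nodes)
        if len(set(self._nodes)) != len(self._nodes):
            raise GraphError("duplicate node names")
        node_set = set(self._nodes)
        directed = frozenset((str(a), str(b)) for a, b in directed_edges)
        undirected = frozenset(frozenset(e) for e in undirected_edges)

        for a, b in directed:
            if a == b:
                raise GraphError(f"self-loop on {a!r}")
            if a not in node_set or b not in node_set:
                raise GraphError(f"edge ({a!r}, {b!r}) uses unknown node")
        for e in undirected:
            if len(e) != 2:
                raise GraphError(f"undirected edge {set(e)} is not a pair")
            if not e <= node_set:
                raise GraphError(f"undirected edge {set(e)} uses unknown node")
        dir_pairs = {frozenset(e) for e in directed}
        overlap = dir_pairs & undirected
        if overlap:
            raise GraphError(f"pairs present both directed and undirected: {sorted(map(sorted, overlap))}")
        if len(dir_pairs) != len(directed):
            raise GraphError("edge directed in both orientations")

        self._directed = directed
        self._undirected = undirected
        self._annotations = dict(annotations or {})

        # adjacency caches
        self._parents: Dict[str, Set[str]] = {v: set() for v in self._nodes}
        self._children: Dict[str, Set[str]] = {v: set() for v in self._nodes}
        self._neighbors: Dict[str, Set[str]] = {v: set() for v in self._nodes}
        for a, b in directed:
            self._children[a].add(b)
            self._parents[b].add(a)
        for e in undirected:
            a, b = sorted(e)
            self._neighbors[a].add(b)
            self._neighbors[b].add(a)

        ts = TopologicalSorter({v: self._parents[v] for v in self._nodes})
        try:
            ts.prepare()
        except CycleError as err:
            raise GraphError("directed part contains a cycle") from err

    # ------------------------------------------------------------------ basic
    @property
    def nodes(self) -> Tuple[str, ...]:
        return self._nodes

    @property
    def directed_edges(self) -> FrozenSet[Edge]:
        return self._directed

    @property
    def undirected_edges(self) -> FrozenSet[Pair]:
        return self._undirected

    @property
    def annotations(self) -> Dict[Pair, EdgeAnnotation]:
        return dict(self._annotations)

    @property
    def is_dag(self) -> bool:
        return not self._undirected

    @property
    def is_skeleton(self) -> bool:
        return not self._directed

    def n_edges(self) -> int:
        return len(self._directed) + len(self._undirected)

    def parents(self, node: str) -> Set[str]:
        self._check(node)
        return set(self._parents[node])

    def children(self, node: str) -> Set[str]:
        self._check(node)
        return set(self._children[node])

    def undirected_neighbors(self, node: str) -> Set[str]:
        self._check(node)
        return set(self._neighbors[node])

    def adjacent(self, a: str, b: str) -> bool:
        """True if any edge — directed either way or undirected — joins a, b."""
        self._check(a)
        self._check(b)
        return (
            b in self._children[a]
            or b in self._parents[a]
            or b in self._neighbors[a]
        )

    def adjacencies(self, node: str) -> Set[str]:
        self._check(node)
        return self._parents[node] | self._children[node] | self._neighbors[node]

    def has_directed_edge(self, tail: str, head: str) -> bool:
        return (tail, head) in self._directed

    def has_undirected_edge(self, a: str, b: str) -> bool:
        return frozenset((a, b)) in self._undirected

    def _check(self, node: str) -> None:
        if node not in self._parents:
            raise GraphError(f"unknown node {node!r}")

    # ------------------------------------------------------------ derivations
    def skeleton(self) -> "PartiallyDirectedGraph":
        """Forget all orientations."""
        und = set(self._undirected) | {frozenset(e) for e in self._directed}
        return PartiallyDirectedGraph(self._nodes, (), und, self._annotations)

    def with_annotations(
        self, annotations: Dict[Pair, EdgeAnnotation]
    ) -> "PartiallyDirectedGraph":
        return PartiallyDirectedGraph(
            self._nodes, self._directed, self._undirected, annotations
        )

    def v_structures(self) -> Set[Tuple[str, str, str]]:
        """All unshielded colliders, as (parent_a, center, parent_b), a < b in node order."""
        order = {v: k for k, v in enumerate(self._nodes)}
        out: Set[Tuple[str, str, str]] = set()
        for center in self._nodes:
            pa = sorted(self._parents[center], key=order.__getitem__)
            for i in range(len(pa)):
                for j in range(i + 1, len(pa)):
                    a, b = pa[i], pa[j]
                    if not self.adjacent(a, b):
                        out.add((a, center, b))
        return out

    def topological_order(self) -> List[str]:
        if not self.is_dag:
            raise GraphError("topological order defined for DAGs only")
        ts = TopologicalSorter({v: self._parents[v] for v in self._nodes})
        order = {v: k for k, v in enumerate(self._nodes)}
        return [v for v in ts.static_order()]

    def to_networkx(self) -> nx.DiGraph:
        """Directed-part view as a networkx DiGraph (undirected edges dropped)."""
        g = nx.DiGraph()
        g.add_nodes_from(self._nodes)
        g.add_edges_from(self._directed)
        return g

    # ----------------------------------------------------------------- dunder
    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PartiallyDirectedGraph):
            return NotImplemented
        return (
            self._nodes == other._nodes
            and self._directed == other._directed
            and self._undirected == other._undirected
        )

    def __hash__(self) -> int:
        return hash((self._nodes, self._directed, self._undirected))

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (
            f"PartiallyDirectedGraph({len(self._nodes)} nodes, "
            f"{len(self._directed)} directed, {len(self._undirected)} undirected)"
        )


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def reachable_from(g: PartiallyDirectedGraph, node: str) -> Set[str]:
    """All nodes reachable from ``node`` along directed edges (node excluded).

    Undirected edges are never traversed; reachability is tail-to-head only.
    """
    g._check(node)
    seen: Set[str] = set()
    stack = [node]
    while stack:
        v = stack.pop()
        for c in g.children(v):
            if c not in seen:
                seen.add(c)
                stack.append(c)
    seen.discard(node)
    return seen


def mutilate(g: PartiallyDirectedGraph, node: str) -> PartiallyDirectedGraph:
    """Model an intervention do(node = x): delete every edge into ``node``.

    Defined on DAGs only; returns a new DAG with all other edges intact.
    """
    if not g.is_dag:
        raise GraphError("mutilation is defined on fully directed DAGs only")
    g._check(node)
    kept = {(a, b) for a, b in g.directed_edges if b != node}
    return PartiallyDirectedGraph(g.nodes, kept, (), g.annotations)


def apply_meek_rules(g: PartiallyDirectedGraph) -> PartiallyDirectedGraph:
    """Maximally orient a PDAG with the three Meek orientation rules.

    Rule 1: a -> b, b - c, a not adjacent to c        =>  b -> c
    Rule 2: b -> a -> c and b - c                     =>  b -> c
    Rule 3: b - a1 -> c, b - a2 -> c, b - c,
            a1 not adjacent to a2                     =>  b -> c

    Rules are swept in order 1, 2, 3 over undirected edges until a full
    sweep changes nothing; the maximally oriented PDAG is sweep-order
    invariant, so the schedule is an internal detail.  Adjacencies are
    never added or removed and directed edges are never reversed.
    """
    directed: Set[Edge] = set(g.directed_edges)
    undirected: Set[Pair] = set(g.undirected_edges)
    parents: Dict[str, Set[str]] = {v: g.parents(v) for v in g.nodes}
    children: Dict[str, Set[str]] = {v: g.children(v) for v in g.nodes}
    neigh: Dict[str, Set[str]] = {v: g.undirected_neighbors(v) for v in g.nodes}

    def adjacent(a: str, b: str) -> bool:
        return b in parents[a] or b in children[a] or b in neigh[a]

    def orient(tail: str, head: str) -> bool:
        # guard: on inconsistent (non-CPDAG) inputs a rule can propose a
        # cycle-closing orientation; skip it and keep going
        stack, seen = [head], {head}
        while stack:
            v = stack.pop()
            if v == tail:
                logger.debug(
                    "Meek orientation %s -> %s would close a cycle; skipped",
                    tail, head,
                )
                return False
            stack.extend(children[v] - seen)
            seen |= children[v]
        undirected.discard(frozenset((tail, head)))
        neigh[tail].discard(head)
        neigh[head].discard(tail)
        directed.add((tail, head))
        children[tail].add(head)
        parents[head].add(tail)
        return True

    changed = True
    while changed:
        changed = False
        for pair in sorted(undirected, key=lambda p: tuple(sorted(p))):
            if pair not in undirected:
                continue
            for b, c in (tuple(sorted(pair)), tuple(sorted(pair))[::-1]):
                fire = (
                    # Rule 1
                    any(not adjacent(a, c) for a in parents[b])
                    # Rule 2
                    or any(a in parents[c] for a in children[b])
                )
                if not fire:
                    # Rule 3
                    mids = [a for a in neigh[b] if a in parents[c]]
                    fire = any(
                        not adjacent(a1, a2)
                        for i, a1 in enumerate(mids)
                        for a2 in mids[i + 1 :]
                    )
                if fire:
                    if orient(b, c):
                        changed = True
                    break
    return PartiallyDirectedGraph(g.nodes, directed, undirected, g.annotations)


def cpdag_of_dag(dag: PartiallyDirectedGraph) -> PartiallyDirectedGraph:
    """The CPDAG (Markov-equivalence-class representative) of a DAG.

    Keeps the skeleton, pins the v-structure edges as directed, leaves all
    other edges undirected, and closes under the Meek rules.
    """
    if not dag.is_dag:
        raise GraphError("cpdag_of_dag requires a fully directed DAG")
    pinned: Set[Edge] = set()
    for a, center, b in dag.v_structures():
        pinned.add((a, center))
        pinned.add((b, center))
    undirected = {
        frozenset(e) for e in dag.directed_edges if e not in pinned
    }
    pdag = PartiallyDirectedGraph(dag.nodes, pinned, undirected, dag.annotations)
    return apply_meek_rules(pdag)


def consistent_extension(g: PartiallyDirectedGraph) -> PartiallyDirectedGraph:
    """Orient every undirected edge of a CPDAG into a DAG of its class.

    The returned DAG has the same skeleton and the same v-structures as the
    input (Dor–Tarsi peeling).  Free orientation choices are resolved by
    node order, so the output is deterministic.  Raises :class:`GraphError`
    when no consistent acyclic extension exists.
    """
    if g.is_dag:
        return g

    nodes = list(g.nodes)
    order = {v: k for k, v in enumerate(nodes)}
    parents = {v: g.parents(v) for v in nodes}
    children = {v: g.children(v) for v in nodes}
    neigh = {v: g.undirected_neighbors(v) for v in nodes}
    oriented: Set[Edge] = set(g.directed_edges)
    remaining = set(nodes)

    def adj(v: str) -> Set[str]:
        return (parents[v] | children[v] | neigh[v]) & remaining

    while remaining:
        # candidates scanned in reverse node order so that a free edge
        # between earlier A and later B orients tail-first (A -> B)
        sink = None
        for x in sorted(remaining, key=order.__getitem__, reverse=True):
            if children[x] & remaining:
                continue  # not a sink in the directed part
            ax = adj(x)
            if all(
                all(w == y or w in (parents[y] | children[y] | neigh[y]) for w in ax - {y})
                for y in neigh[x] & remaining
            ):
                sink = x
                break
        if sink is None:
            raise GraphError("no consistent acyclic extension exists")
        for y in sorted(neigh[sink] & remaining, key=order.__getitem__):
            oriented.add((y, sink))
        remaining.discard(sink)

    out = PartiallyDirectedGraph(g.nodes, oriented, (), g.annotations)
    return out
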