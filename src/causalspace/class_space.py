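"""Enumeration of labeled DAGs, their Markov equivalence classes, and the
covered-edge-reversal graph whose path components realize those classes.

The reversal graph is the combinatorial skeleton of the groupoid whose
invertible morphisms are covered-edge reversals: two DAGs lie in the same
Markov equivalence class iff they are joined by a chain of such reversals,
so the graph's path components (its pi_0) coincide with the signature
partition.  Enumeration is capped at five nodes (29281 DAGs), the range in
which exhaustive verification is tractable.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, product
from typing import Dict, FrozenSet, List, Sequence, Tuple

from .dag import Dag, EquivClassSignature, covered_edges, signature

__all__ = [
    "ClassPartition",
    "ReversalGraph",
    "enumerate_dags",
    "partition_by_equivalence",
    "class_members",
    "canonical_representative",
    "reversal_graph",
    "path_components",
]

ENUMERATION_MAX_NODES = 5


@dataclass(frozen=True)
class ClassPartition:
    """Markov equivalence classes of a DAG collection, keyed by signature."""

    classes: Dict[EquivClassSignature, FrozenSet[Dag]]
    universe_size: int

    def sizes(self) -> Tuple[int, ...]:
        return tuple(sorted(len(v) for v in self.classes.values()))


@dataclass(frozen=True)
class ReversalGraph:
    """Undirected graph on DAGs; edges join pairs differing by one
    covered-edge reversal."""

    vertices: Tuple[Dag, ...]
    edges: FrozenSet[FrozenSet[Dag]]


def enumerate_dags(nodes: Sequence[str], max_nodes: int = ENUMERATION_MAX_NODES) -> List[Dag]:
    """All labeled DAGs on ``nodes``, each exactly once, in a deterministic
    order (orientation states per unordered pair: absent, forward, backward)."""
    nodes = tuple(sorted(str(n) for n in nodes))
    if not 1 <= len(nodes) <= max_nodes:
        raise ValueError(f"node count must be between 1 and {max_nodes}")
    pairs = list(combinations(nodes, 2))
    out: List[Dag] = []
    for states in product(range(3), repeat=len(pairs)):
        edges = []
        for (a, b), s in zip(pairs, states):
            if s == 1:
                edges.append((a, b))
            elif s == 2:
                edges.append((b, a))
        try:
            out.append(Dag(nodes, edges))
        except ValueError:  # cyclic orientation
            continue
    return out


def partition_by_equivalence(dags: Sequence[Dag]) -> ClassPartition:
    """Group DAGs by their (skeleton, v-structures) signature."""
    if not dags:
        return ClassPartition(classes={}, universe_size=0)
    node_set = dags[0].nodes
    groups: Dict[EquivClassSignature, set] = {}
    for g in dags:
        if g.nodes != node_set:
            raise ValueError("mixed node sets in partition input")
        groups.setdefault(signature(g), set()).add(g)
    return ClassPartition(
        classes={sig: frozenset(v) for sig, v in groups.items()},
        universe_size=len(dags),
    )


def class_members(g: Dag) -> FrozenSet[Dag]:
    """All DAGs Markov equivalent to ``g``: the closure of ``g`` under
    covered-edge reversals (which is exactly the equivalence class)."""
    seen = {g}
    frontier = [g]
    while frontier:
        cur = frontier.pop()
        for e in covered_edges(cur):
            nxt = cur.with_reversed_edge(*e)
            if nxt not in seen:
                seen.add(nxt)
                frontier.append(nxt)
    return frozenset(seen)


def canonical_representative(members: FrozenSet[Dag]) -> Dag:
    """The member with lexicographically smallest sorted edge tuple."""
    return min(members, key=lambda d: d.sorted_edges())


def reversal_graph(partition: ClassPartition) -> ReversalGraph:
    """The covered-edge-reversal graph over every member DAG."""
    vertices = tuple(
        sorted(
            (d for members in partition.classes.values() for d in members),
            key=lambda d: d.sorted_edges(),
        )
    )
    vert_set = set(vertices)
    edges = set()
    for g in vertices:
        for e in covered_edges(g):
            g2 = g.with_reversed_edge(*e)
            if g2 in vert_set:
                edges.add(frozenset((g, g2)))
    return ReversalGraph(vertices=vertices, edges=frozenset(edges))


def path_components(graph: ReversalGraph) -> List[FrozenSet[Dag]]:
    """Connected components of the reversal graph via union-find,
    deterministically ordered by smallest member edge set."""
    parent = {v: v for v in graph.vertices}

    def find(v):
        root = v
        while parent[root] is not root:
            root = parent[root]
        while parent[v] is not root:
            parent[v], v = root, parent[v]
        return root

    for pair in graph.edges:
        a, b = tuple(pair)
        ra, rb = find(a), find(b)
        if ra is not rb:
            parent[ra] = rb
    comps: Dict[Dag, set] = {}
    for v in graph.vertices:
        comps.setdefault(find(v), set()).add(v)
    return sorted(
        (frozenset(c) for c in comps.values()),
        key=lambda c: min(d.sorted_edges() for d in c),
    )
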