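"""Causal DAGs and the structural predicates of Markov equivalence.

A causal DAG ``G = (V, E)`` encodes a family of probability distributions
through the conditional independences implied by d-separation.  Two DAGs are
*Markov equivalent* when they imply exactly the same independences, which by
the Verma-Pearl characterization happens precisely when they share a skeleton
(the undirected edge set) and the same v-structures (colliders ``X -> Z <- Y``
with X, Y non-adjacent).  A *covered edge* ``X -> Y`` is one with
``Pa(Y) = Pa(X) + {X}``; reversing a covered edge is exactly the move that
stays inside an equivalence class.

Everything downstream (transformation sequences, the class space, GES, the
string-diagram semantics) is built on the predicates in this module.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from itertools import chain, combinations
from typing import FrozenSet, Iterable, Iterator, Tuple

__all__ = [
    "Dag",
    "EquivClassSignature",
    "CiStatement",
    "covered_edges",
    "signature",
    "is_equivalent",
    "d_separated",
    "independence_statements",
    "is_independence_map",
]

Edge = Tuple[str, str]

#: hard cap for exhaustive independence-map checks (conditioning sets are
#: enumerated over the power set of V minus the pair).
INDEPENDENCE_MAP_MAX_NODES = 12


class Dag:
    """An immutable labeled directed acyclic graph.

    Parameters
    ----------
    nodes:
        Iterable of distinct string labels.  Stored canonically sorted.
    edges:
        Iterable of ``(parent, child)`` pairs.  At most one edge per
        unordered pair, no self loops, no directed cycles.
    """

    __slots__ = ("nodes", "edges", "_parents", "_hash")

    def __init__(self, nodes: Iterable[str], edges: Iterable[Edge] = ()):
        node_list = [str(n) for n in nodes]
        if len(set(node_list)) != len(node_list):
            raise ValueError("duplicate node labels")
        nodes_t = tuple(sorted(node_list))
        node_set = set(nodes_t)
        edge_set = set()
        for a, b in edges:
            a, b = str(a), str(b)
            if a == b:
                raise ValueError(f"self-loop on {a!r}")
            if a not in node_set or b not in node_set:
                raise ValueError(f"edge ({a!r}, {b!r}) uses undeclared node")
            if (a, b) in edge_set:
                raise ValueError(f"duplicate edge ({a!r}, {b!r})")
            if (b, a) in edge_set:
                raise ValueError(f"both orientations of {{{a!r}, {b!r}}} present")
            edge_set.add((a, b))
        object.__setattr__(self, "nodes", nodes_t)
        object.__setattr__(self, "edges", frozenset(edge_set))
        parents: dict[str, set[str]] = {n: set() for n in nodes_t}
        for a, b in edge_set:
            parents[b].add(a)
        object.__setattr__(
            self, "_parents", {n: frozenset(ps) for n, ps in parents.items()}
        )
        object.__setattr__(self, "_hash", hash((nodes_t, self.edges)))
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        indeg = {n: len(self._parents[n]) for n in self.nodes}
        ready = [n for n, d in indeg.items() if d == 0]
        children: dict[str, list[str]] = {n: [] for n in self.nodes}
        for a, b in self.edges:
            children[a].append(b)
        seen = 0
        while ready:
            n = ready.pop()
            seen += 1
            for c in children[n]:
                indeg[c] -= 1
                if indeg[c] == 0:
                    ready.append(c)
        if seen != len(self.nodes):
            cyc = sorted(n for n, d in indeg.items() if d > 0)
            raise ValueError(f"directed cycle among {cyc}")

    # -- structure accessors -------------------------------------------------

    def parents(self, node: str) -> FrozenSet[str]:
        return self._parents[node]

    def children(self, node: str) -> FrozenSet[str]:
        return frozenset(b for a, b in self.edges if a == node)

    def has_edge(self, a: str, b: str) -> bool:
        return (a, b) in self.edges

    def adjacent(self, a: str, b: str) -> bool:
        return (a, b) in self.edges or (b, a) in self.edges

    def topological_order(self) -> Tuple[str, ...]:
        indeg = {n: len(self._parents[n]) for n in self.nodes}
        ready = sorted((n for n, d in indeg.items() if d == 0), reverse=True)
        children: dict[str, list[str]] = {n: [] for n in self.nodes}
        for a, b in self.edges:
            children[a].append(b)
        out = []
        while ready:
            n = ready.pop()
            out.append(n)
            newly = []
            for c in children[n]:
                indeg[c] -= 1
                if indeg[c] == 0:
                    newly.append(c)
            for c in sorted(newly, reverse=True):
                ready.append(c)
            ready.sort(reverse=True)
        return tuple(out)

    def ancestors(self, seeds: Iterable[str]) -> FrozenSet[str]:
        """Seeds together with all their ancestors."""
        out = set()
        stack = list(seeds)
        while stack:
            n = stack.pop()
            if n in out:
                continue
            out.add(n)
            stack.extend(self._parents[n])
        return frozenset(out)

    # -- edge edits (return new Dags) ----------------------------------------

    def with_edge(self, a: str, b: str) -> "Dag":
        return Dag(self.nodes, self.edges | {(a, b)})

    def without_edge(self, a: str, b: str) -> "Dag":
        if (a, b) not in self.edges:
            raise ValueError(f"edge ({a!r}, {b!r}) not present")
        return Dag(self.nodes, self.edges - {(a, b)})

    def with_reversed_edge(self, a: str, b: str) -> "Dag":
        if (a, b) not in self.edges:
            raise ValueError(f"edge ({a!r}, {b!r}) not present")
        return Dag(self.nodes, (self.edges - {(a, b)}) | {(b, a)})

    # -- dunder --------------------------------------------------------------

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, Dag)
            and self.nodes == other.nodes
            and self.edges == other.edges
        )

    def __hash__(self) -> int:
        return self._hash

    def __repr__(self) -> str:
        es = ", ".join(f"{a}->{b}" for a, b in sorted(self.edges))
        return f"Dag({list(self.nodes)}, [{es}])"

    def sorted_edges(self) -> Tuple[Edge, ...]:
        return tuple(sorted(self.edges))


@dataclass(frozen=True)
class EquivClassSignature:
    """Canonical key of a Markov equivalence class.

    ``skeleton`` is the set of unordered adjacent pairs (stored as sorted
    2-tuples); ``v_structures`` the set of ``(x, z, y)`` colliders with
    ``x < y`` lexicographically and ``z`` the collision node.
    """

    skeleton: FrozenSet[Tuple[str, str]]
    v_structures: FrozenSet[Tuple[str, str, str]]

    def __post_init__(self) -> None:
        for x, z, y in self.v_structures:
            if x >= y:
                raise ValueError("v-structure endpoints not canonically ordered")
            if tuple(sorted((x, z))) not in self.skeleton or tuple(
                sorted((y, z))
            ) not in self.skeleton:
                raise ValueError("v-structure edge missing from skeleton")
            if tuple(sorted((x, y))) in self.skeleton:
                raise ValueError("v-structure endpoints are adjacent")


@dataclass(frozen=True)
class CiStatement:
    """A conditional-independence triple ``x _||_ y | z``."""

    x: str
    y: str
    z: FrozenSet[str]

    def __post_init__(self) -> None:
        if self.x == self.y:
            raise ValueError("x and y must differ")
        if self.x in self.z or self.y in self.z:
            raise ValueError("conditioning set contains an endpoint")


def covered_edges(g: Dag) -> FrozenSet[Edge]:
    """Edges ``X -> Y`` with ``Pa(Y) = Pa(X) | {X}``.

    These are exactly the edges whose reversal yields a Markov-equivalent DAG.
    """
    return frozenset(
        (x, y) for x, y in g.edges if g.parents(y) == g.parents(x) | {x}
    )


def signature(g: Dag) -> EquivClassSignature:
    """The (skeleton, v-structures) pair identifying ``g``'s equivalence class."""
    skel = frozenset(tuple(sorted(e)) for e in g.edges)
    vs = set()
    for z in g.nodes:
        ps = sorted(g.parents(z))
        for x, y in combinations(ps, 2):
            if not g.adjacent(x, y):
                vs.add((x, z, y))
    return EquivClassSignature(skeleton=skel, v_structures=frozenset(vs))


def is_equivalent(g: Dag, h: Dag) -> bool:
    """True iff ``g`` and ``h`` are Markov equivalent (same skeleton and
    v-structures)."""
    if g.nodes != h.nodes:
        raise ValueError("node sets differ")
    return signature(g) == signature(h)


def d_separated(g: Dag, x: str, y: str, z: Iterable[str]) -> bool:
    """d-separation of ``x`` and ``y`` given ``z`` in ``g``.

    Implemented by reachability in the moralized ancestral subgraph: restrict
    to ancestors of ``{x, y} | z``, marry co-parents, drop orientations,
    delete ``z``, and test connectivity.  Deterministic and equivalent to the
    path-blocking definition.
    """
    zset = frozenset(z)
    if x == y:
        raise ValueError("x and y must differ")
    if x in zset or y in zset:
        raise ValueError("conditioning set contains an endpoint")
    for n in chain((x, y), zset):
        if n not in g._parents:
            raise KeyError(f"unknown label {n!r}")
    anc = g.ancestors(chain((x, y), zset))
    # moral graph over the ancestral subgraph
    adj: dict[str, set[str]] = {n: set() for n in anc}
    for a, b in g.edges:
        if a in anc and b in anc:
            adj[a].add(b)
            adj[b].add(a)
    for n in anc:
        ps = [p for p in g.parents(n) if p in anc]
        for p, q in combinations(ps, 2):
            adj[p].add(q)
            adj[q].add(p)
    # reachability avoiding z
    stack = [x]
    seen = {x}
    while stack:
        n = stack.pop()
        for nb in adj[n]:
            if nb == y:
                return False
            if nb not in seen and nb not in zset:
                seen.add(nb)
                stack.append(nb)
    return True


def _subsets(items: Tuple[str, ...]) -> Iterator[FrozenSet[str]]:
    for k in range(len(items) + 1):
        for combo in combinations(items, k):
            yield frozenset(combo)


@lru_cache(maxsize=200_000)
def independence_statements(g: Dag) -> FrozenSet[Tuple[str, str, FrozenSet[str]]]:
    """All d-separation triples ``(x, y, z)`` with ``x < y``, over every
    conditioning subset.  Cached; intended for small node sets (the class
    space and transformation machinery reuse it heavily)."""
    out = set()
    for x, y in combinations(g.nodes, 2):
        rest = tuple(n for n in g.nodes if n != x and n != y)
        for zset in _subsets(rest):
            if d_separated(g, x, y, zset):
                out.add((x, y, zset))
    return frozenset(out)


def is_independence_map(g: Dag, h: Dag) -> bool:
    """True iff ``h`` is an independence map of ``g`` (written ``G <= H``):
    every independence implied by ``h`` also holds in ``g``.

    Checked over singleton pairs and all conditioning subsets, which suffices
    for the graphoid relation induced by d-separation.
    """
    if g.nodes != h.nodes:
        raise ValueError("node sets differ")
    if len(g.nodes) > INDEPENDENCE_MAP_MAX_NODES:
        raise ValueError(
            f"refusing independence-map check on more than "
            f"{INDEPENDENCE_MAP_MAX_NODES} nodes"
        )
    if len(g.nodes) <= 6:
        return independence_statements(h) <= independence_statements(g)
    for x, y in combinations(h.nodes, 2):
        rest = tuple(n for n in h.nodes if n != x and n != y)
        for zset in _subsets(rest):
            if d_separated(h, x, y, zset) and not d_separated(g, x, y, zset):
                return False
    return True
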