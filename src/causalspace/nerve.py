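"""Finite categories, their nerves, path components, and invariant-based
comparison of classifying spaces.

The nerve of a category C is the simplicial set whose n-simplices are
composable chains of n morphisms; face maps drop an end object or compose
two adjacent arrows, degeneracy maps insert an identity.  Its combinatorial
invariants -- path components (pi_0), nondegenerate simplex counts per
dimension, component sizes -- are invariants of the classifying space, so a
difference in any of them certifies that two classifying spaces are not
isomorphic (the converse is not decided here).

Categories may be *strict* (total, associative composition, validated) or
1-truncated graph presentations (identities plus generator arrows only),
which suffice for pi_0 and arise as the covered-edge-reversal groupoid's
skeleton.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, FrozenSet, Hashable, List, Mapping, Sequence, Tuple

__all__ = [
    "FiniteCategory",
    "TruncatedSimplicialSet",
    "SetValuedFunctor",
    "nerve",
    "is_degenerate",
    "pi0",
    "category_of_elements",
    "compare_invariants",
    "poset_category",
    "discrete_category",
    "category_from_graph",
]

DEFAULT_CHAIN_CAP = 100_000


@dataclass(frozen=True)
class FiniteCategory:
    """An explicit small category.

    ``morphisms`` maps morphism id -> (dom, cod); ``identities`` maps object
    -> its identity morphism id; ``composition`` maps ``(f, g)`` with
    ``cod f = dom g`` to the composite ``g o f`` (diagram order).  When
    ``strict`` is true the composition table must be total and associative;
    otherwise only identity laws are enforced and the structure is treated
    as a 1-truncated presentation (nerve available up to dimension 1).
    """

    objects: Tuple[Hashable, ...]
    morphisms: Mapping[Hashable, Tuple[Hashable, Hashable]]
    identities: Mapping[Hashable, Hashable]
    composition: Mapping[Tuple[Hashable, Hashable], Hashable]
    strict: bool = True

    def __post_init__(self) -> None:
        objset = set(self.objects)
        if len(objset) != len(self.objects):
            raise ValueError("duplicate objects")
        for m, (d, c) in self.morphisms.items():
            if d not in objset or c not in objset:
                raise ValueError(f"morphism {m!r} has undeclared endpoint")
        for o in self.objects:
            i = self.identities.get(o)
            if i is None or self.morphisms.get(i) != (o, o):
                raise ValueError(f"bad identity for object {o!r}")
        ids = set(self.identities.values())
        # identity laws on every recorded composite
        for (f, g), fg in self.composition.items():
            df, cf = self.morphisms[f]
            dg, cg = self.morphisms[g]
            if cf != dg:
                raise ValueError(f"composite recorded for non-composable ({f!r},{g!r})")
            if self.morphisms[fg] != (df, cg):
                raise ValueError(f"composite of ({f!r},{g!r}) has wrong endpoints")
        for m, (d, c) in self.morphisms.items():
            if self.composition.get((self.identities[d], m), m) != m:
                raise ValueError(f"left identity law fails at {m!r}")
            if self.composition.get((m, self.identities[c]), m) != m:
                raise ValueError(f"right identity law fails at {m!r}")
        if self.strict:
            # totality on non-identity composable pairs (identity composites
            # are implicit via the identity laws)
            for f, (df, cf) in self.morphisms.items():
                if f in ids:
                    continue
                for g, (dg, cg) in self.morphisms.items():
                    if g in ids or cf != dg:
                        continue
                    if (f, g) not in self.composition:
                        raise ValueError(
                            f"composition undefined on composable ({f!r},{g!r})"
                        )
            for f, (df, cf) in self.morphisms.items():
                for g, (dg, cg) in self.morphisms.items():
                    if cf != dg:
                        continue
                    for h, (dh, ch) in self.morphisms.items():
                        if cg != dh:
                            continue
                        left = self.compose2(self.compose2(f, g), h)
                        right = self.compose2(f, self.compose2(g, h))
                        if left != right:
                            raise ValueError(
                                f"associativity fails at ({f!r},{g!r},{h!r})"
                            )

    def dom(self, m: Hashable) -> Hashable:
        return self.morphisms[m][0]

    def cod(self, m: Hashable) -> Hashable:
        return self.morphisms[m][1]

    def is_identity(self, m: Hashable) -> bool:
        o = self.morphisms[m][0]
        return self.identities.get(o) == m

    def compose2(self, f: Hashable, g: Hashable) -> Hashable:
        """Composite ``g o f`` for ``f`` then ``g`` (diagram order)."""
        if self.is_identity(f):
            return g
        if self.is_identity(g):
            return f
        return self.composition[(f, g)]


Simplex = Tuple[Hashable, ...]


@dataclass(frozen=True)
class TruncatedSimplicialSet:
    """A nerve truncated at dimension ``k``.

    ``simplices[0]`` lists objects; ``simplices[n]`` lists composable chains
    of n morphism ids.  Face and degeneracy operators act on stored chains.
    """

    category: FiniteCategory
    k: int
    simplices: Tuple[Tuple[Simplex, ...], ...]

    def face(self, n: int, simplex: Simplex, i: int) -> Simplex:
        """``d_i``: drop the first morphism (i=0), the last (i=n), or compose
        the adjacent pair at an inner index."""
        if not 0 <= i <= n or n < 1:
            raise IndexError("face index out of range")
        c = self.category
        if n == 1:
            return (c.cod(simplex[0]),) if i == 0 else (c.dom(simplex[0]),)
        if i == 0:
            return simplex[1:]
        if i == n:
            return simplex[:-1]
        composite = c.compose2(simplex[i - 1], simplex[i])
        return simplex[: i - 1] + (composite,) + simplex[i + 1:]

    def degeneracy(self, n: int, simplex: Simplex, j: int) -> Simplex:
        """``s_j``: insert the identity of the j-th object of the chain."""
        if not 0 <= j <= n:
            raise IndexError("degeneracy index out of range")
        c = self.category
        if n == 0:
            return (c.identities[simplex[0]],)
        if j == 0:
            obj = c.dom(simplex[0])
        else:
            obj = c.cod(simplex[j - 1])
        return simplex[:j] + (c.identities[obj],) + simplex[j:]

    def nondegenerate_counts(self) -> Tuple[int, ...]:
        out = [len(self.simplices[0])]
        for n in range(1, self.k + 1):
            out.append(
                sum(
                    1
                    for s in self.simplices[n]
                    if not is_degenerate(self.category, s)
                )
            )
        return tuple(out)


def is_degenerate(c: FiniteCategory, simplex: Simplex) -> bool:
    """A chain is degenerate iff some component morphism is an identity
    (0-simplices are never degenerate)."""
    return any(m in c.morphisms and c.is_identity(m) for m in simplex)


def nerve(
    c: FiniteCategory, k: int, cap: int = DEFAULT_CHAIN_CAP
) -> TruncatedSimplicialSet:
    """Composable-chain simplices of ``c`` up to dimension ``k``."""
    if k < 0:
        raise ValueError("dimension bound must be >= 0")
    if not c.strict and k > 1:
        raise ValueError("1-truncated presentation: nerve only to k=1")
    levels: List[Tuple[Simplex, ...]] = [tuple((o,) for o in c.objects)]
    if k >= 1:
        morphs = tuple(sorted(c.morphisms, key=repr))
        levels.append(tuple((m,) for m in morphs))
        by_dom: Dict[Hashable, List[Hashable]] = {}
        for m in morphs:
            by_dom.setdefault(c.dom(m), []).append(m)
        for n in range(2, k + 1):
            nxt = []
            for chain in levels[n - 1]:
                tail_cod = c.cod(chain[-1])
                for m in by_dom.get(tail_cod, ()):
                    nxt.append(chain + (m,))
                    if len(nxt) > cap:
                        raise ValueError(
                            f"chain count at dimension {n} exceeds cap {cap}"
                        )
            levels.append(tuple(nxt))
    return TruncatedSimplicialSet(category=c, k=k, simplices=tuple(levels))


def pi0(c: FiniteCategory) -> List[FrozenSet[Hashable]]:
    """Path components: zig-zag connectivity classes of objects under the
    morphism relation (direction ignored)."""
    parent = {o: o for o in c.objects}

    def find(o):
        root = o
        while parent[root] != root:
            root = parent[root]
        while parent[o] != root:
            parent[o], o = root, parent[o]
        return root

    for d, cod in c.morphisms.values():
        ra, rb = find(d), find(cod)
        if ra != rb:
            parent[ra] = rb
    comps: Dict[Hashable, set] = {}
    for o in c.objects:
        comps.setdefault(find(o), set()).add(o)
    return sorted((frozenset(v) for v in comps.values()),
                  key=lambda s: sorted(map(repr, s)))


@dataclass(frozen=True)
class SetValuedFunctor:
    """A functor ``C -> Set`` given by finite value sets and per-morphism
    mappings."""

    value_sets: Mapping[Hashable, Tuple[Hashable, ...]]
    maps: Mapping[Hashable, Mapping[Hashable, Hashable]]

    def validate(self, c: FiniteCategory) -> None:
        for o in c.objects:
            if o not in self.value_sets:
                raise ValueError(f"no value set for object {o!r}")
        for m, (d, cod) in c.morphisms.items():
            mp = self.maps.get(m)
            if mp is None:
                raise ValueError(f"no map for morphism {m!r}")
            if set(mp) != set(self.value_sets[d]):
                raise ValueError(f"map of {m!r} not defined on whole domain")
            if not set(mp.values()) <= set(self.value_sets[cod]):
                raise ValueError(f"map of {m!r} leaves codomain value set")
        for o, i in c.identities.items():
            for x in self.value_sets[o]:
                if self.maps[i][x] != x:
                    raise ValueError(f"identity of {o!r} not mapped to identity")
        for (f, g), fg in c.composition.items():
            d = c.dom(f)
            for x in self.value_sets[d]:
                if self.maps[g][self.maps[f][x]] != self.maps[fg][x]:
                    raise ValueError(
                        f"functoriality fails at ({f!r},{g!r}) on {x!r}"
                    )


def category_of_elements(
    c: FiniteCategory, delta: SetValuedFunctor
) -> FiniteCategory:
    """The category whose objects are pairs (object, element) and whose
    morphisms are ``(f, x): (dom f, x) -> (cod f, delta(f)(x))``."""
    delta.validate(c)
    objects = tuple(
        (o, x) for o in c.objects for x in delta.value_sets[o]
    )
    morphisms = {
        (m, x): ((c.dom(m), x), (c.cod(m), delta.maps[m][x]))
        for m in c.morphisms
        for x in delta.value_sets[c.dom(m)]
    }
    identities = {(o, x): (c.identities[o], x) for o, x in objects}
    composition = {}
    for (f, g), fg in c.composition.items():
        for x in delta.value_sets[c.dom(f)]:
            composition[((f, x), (g, delta.maps[f][x]))] = (fg, x)
    return FiniteCategory(
        objects=objects,
        morphisms=morphisms,
        identities=identities,
        composition=composition,
        strict=c.strict,
    )


def compare_invariants(
    c1: FiniteCategory, c0: FiniteCategory, k: int
) -> Dict[str, object]:
    """Compare classifying-space invariants up to dimension ``k``.

    A difference in pi_0 count, component-size multiset, or per-dimension
    nondegenerate simplex counts certifies non-isomorphism of the
    classifying spaces ("distinguishable"); equality certifies nothing
    beyond level k ("indistinguishable-at-level-k").
    """

    def invariants(c: FiniteCategory):
        comps = pi0(c)
        counts = nerve(c, k).nondegenerate_counts()
        return {
            "pi0": len(comps),
            "component_sizes": tuple(sorted(len(x) for x in comps)),
            "nondegenerate_counts": counts,
        }

    inv1, inv0 = invariants(c1), invariants(c0)
    differing = sorted(key for key in inv1 if inv1[key] != inv0[key])
    return {
        "verdict": "distinguishable" if differing else
                   f"indistinguishable-at-level-{k}",
        "differing": differing,
        "invariants": (inv1, inv0),
    }


# ---------------------------------------------------------------------------
# constructors
# ---------------------------------------------------------------------------


def poset_category(m: int) -> FiniteCategory:
    """The poset ``[m] = {0 <= 1 <= ... <= m}`` as a category: one morphism
    ``i -> j`` per ``i <= j``.  Its nerve has C(m+1, n+1) nondegenerate
    n-simplices."""
    objects = tuple(range(m + 1))
    morphisms = {(i, j): (i, j) for i in objects for j in objects if i <= j}
    identities = {i: (i, i) for i in objects}
    composition = {
        ((i, j), (j, k)): (i, k)
        for i in objects
        for j in objects
        for k in objects
        if i <= j <= k
    }
    return FiniteCategory(objects, morphisms, identities, composition)


def discrete_category(labels: Sequence[Hashable]) -> FiniteCategory:
    """Only identity morphisms: the classifying space is a discrete set."""
    objects = tuple(labels)
    morphisms = {("id", o): (o, o) for o in objects}
    identities = {o: ("id", o) for o in objects}
    return FiniteCategory(objects, morphisms, identities, {})


def category_from_graph(
    vertices: Sequence[Hashable], edges: Sequence[Tuple[Hashable, Hashable]]
) -> FiniteCategory:
    """A 1-truncated presentation of the free groupoid-like category on an
    undirected graph: identities plus one generator per edge.  Only pi_0 and
    the 1-skeleton are meaningful (``strict=False``)."""
    objects = tuple(vertices)
    morphisms: Dict[Hashable, Tuple[Hashable, Hashable]] = {
        ("id", o): (o, o) for o in objects
    }
    identities = {o: ("id", o) for o in objects}
    for idx, (a, b) in enumerate(edges):
        morphisms[("gen", idx)] = (a, b)
    return FiniteCategory(objects, morphisms, identities, {}, strict=False)
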