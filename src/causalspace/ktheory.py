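"""The pi_0-level algebra of the class space: commutative monoids of path
components and their Grothendieck group completion.

Tensoring causal models (disjoint union of variable sets) makes the set of
Markov equivalence classes a free commutative monoid on one generator per
class, with the empty model as unit.  Its group completion -- the universal
abelian group receiving it -- is then free abelian of the same rank, the
degree-zero K-group of the class space.  For general finite commutative
monoids the completion is computed from the pair construction: pairs
``(a, b)`` (formal differences) modulo ``(a, b) ~ (c, d)`` iff
``a + d + e = c + b + e`` for some ``e``, reduced to invariant factors.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import prod
from typing import Dict, Hashable, Mapping, Optional, Tuple

from .class_space import ClassPartition, canonical_representative

__all__ = [
    "CommutativeMonoidPresentation",
    "AbelianGroupDescription",
    "monoid_from_classes",
    "group_completion",
]


@dataclass(frozen=True)
class CommutativeMonoidPresentation:
    """Either a free commutative monoid on labeled generators, or a finite
    one given by an element list, unit, and Cayley table."""

    free_generators: Optional[Tuple[Hashable, ...]] = None
    elements: Optional[Tuple[Hashable, ...]] = None
    unit: Optional[Hashable] = None
    table: Optional[Mapping[Tuple[Hashable, Hashable], Hashable]] = None

    @classmethod
    def free(cls, generators) -> "CommutativeMonoidPresentation":
        return cls(free_generators=tuple(generators))

    @classmethod
    def finite(cls, elements, unit, table) -> "CommutativeMonoidPresentation":
        m = cls(elements=tuple(elements), unit=unit, table=dict(table))
        m._validate_finite()
        return m

    @property
    def is_free(self) -> bool:
        return self.free_generators is not None

    def add(self, a: Hashable, b: Hashable) -> Hashable:
        return self.table[(a, b)]

    def _validate_finite(self) -> None:
        els = set(self.elements)
        if self.unit not in els:
            raise ValueError("unit not among elements")
        for a in self.elements:
            for b in self.elements:
                c = self.table.get((a, b))
                if c not in els:
                    raise ValueError(f"table not closed at ({a!r}, {b!r})")
                if self.table[(b, a)] != c:
                    raise ValueError(f"not commutative at ({a!r}, {b!r})")
            if self.table[(self.unit, a)] != a:
                raise ValueError(f"unit law fails at {a!r}")
        for a in self.elements:
            for b in self.elements:
                for c in self.elements:
                    if self.table[(self.table[(a, b)], c)] != self.table[
                        (a, self.table[(b, c)])
                    ]:
                        raise ValueError(
                            f"associativity fails at ({a!r},{b!r},{c!r})"
                        )


@dataclass(frozen=True)
class AbelianGroupDescription:
    """A finitely generated abelian group: free rank plus torsion invariant
    factors (each dividing the next); small finite cases also carry their
    explicit element table."""

    free_rank: int
    invariant_factors: Tuple[int, ...]
    elements: Optional[Tuple[Hashable, ...]] = None
    table: Optional[Mapping[Tuple[Hashable, Hashable], Hashable]] = None
    unit: Optional[Hashable] = None

    def __post_init__(self) -> None:
        for a, b in zip(self.invariant_factors, self.invariant_factors[1:]):
            if b % a != 0:
                raise ValueError("invariant factors must form a divisor chain")

    @property
    def torsion_order(self) -> int:
        return prod(self.invariant_factors) if self.invariant_factors else 1

    @property
    def is_trivial(self) -> bool:
        return self.free_rank == 0 and self.torsion_order == 1


def monoid_from_classes(partition: ClassPartition) -> CommutativeMonoidPresentation:
    """The free commutative monoid on one generator per equivalence class
    (tensor of models = disjoint union; unit = the empty model).  Generators
    are named by the class's canonical representative edge set."""
    gens = []
    for members in partition.classes.values():
        rep = canonical_representative(members)
        gens.append("|".join(f"{a}->{b}" for a, b in rep.sorted_edges()) or "()")
    return CommutativeMonoidPresentation.free(tuple(sorted(gens)))


def _element_order(table, unit, g) -> int:
    order, acc = 1, g
    while acc != unit:
        acc = table[(acc, g)]
        order += 1
    return order


def _cyclic_subgroup(table, unit, g):
    sub = [unit]
    acc = g
    while acc != unit:
        sub.append(acc)
        acc = table[(acc, g)]
    return sub


def _invariant_factors(elements, unit, table) -> Tuple[int, ...]:
    """Invariant factors of a finite abelian group given by its table.

    Structure-theorem peeling: a cyclic subgroup generated by an element of
    maximal order is a direct summand, so the largest factor is that order
    and the rest are the factors of the quotient.
    """
    if len(elements) == 1:
        return ()
    orders = {g: _element_order(table, unit, g) for g in elements}
    gmax = max(elements, key=lambda g: (orders[g], repr(g)))
    dmax = orders[gmax]
    sub = set(_cyclic_subgroup(table, unit, gmax))
    # quotient group on cosets
    coset_of: Dict[Hashable, frozenset] = {}
    for g in elements:
        if g in coset_of:
            continue
        coset = frozenset(table[(g, s)] for s in sub)
        for h in coset:
            coset_of[h] = coset
    cosets = sorted(set(coset_of.values()), key=lambda c: sorted(map(repr, c)))
    qtable = {
        (c1, c2): coset_of[table[(next(iter(c1)), next(iter(c2)))]]
        for c1 in cosets
        for c2 in cosets
    }
    rest = _invariant_factors(cosets, coset_of[unit], qtable)
    return tuple(rest) + (dmax,)


def group_completion(m: CommutativeMonoidPresentation) -> AbelianGroupDescription:
    """The Grothendieck group completion of ``m``.

    Free case: free abelian of the same rank.  Finite case: the brute-force
    pair quotient ``(a, b) ~ (c, d) iff exists e with a+d+e = c+b+e``,
    returned with its explicit group table and invariant factors.
    """
    if m.is_free:
        return AbelianGroupDescription(
            free_rank=len(m.free_generators), invariant_factors=()
        )
    els = m.elements
    add = m.add
    pairs = [(a, b) for a in els for b in els]

    def related(p, q):
        a, b = p
        c, d = q
        return any(
            add(add(a, d), e) == add(add(c, b), e) for e in els
        )

    class_of: Dict[Tuple[Hashable, Hashable], frozenset] = {}
    classes = []
    for p in pairs:
        if p in class_of:
            continue
        cls = frozenset(q for q in pairs if related(p, q))
        classes.append(cls)
        for q in cls:
            class_of[q] = cls
    classes = sorted(classes, key=lambda c: sorted(map(repr, c)))
    unit_cls = class_of[(m.unit, m.unit)]
    table = {}
    for c1 in classes:
        a, b = next(iter(c1))
        for c2 in classes:
            c, d = next(iter(c2))
            table[(c1, c2)] = class_of[(add(a, c), add(b, d))]
    factors = _invariant_factors(classes, unit_cls, table)
    return AbelianGroupDescription(
        free_rank=0,
        invariant_factors=factors,
        elements=tuple(classes),
        table=table,
        unit=unit_cls,
    )
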