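"""Nerve combinatorics: simplicial identities, path components, categories
of elements, and invariant comparison."""

from math import comb

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from causalspace import (
    FiniteCategory,
    SetValuedFunctor,
    category_of_elements,
    compare_invariants,
    enumerate_dags,
    is_degenerate,
    nerve,
    partition_by_equivalence,
    pi0,
    reversal_graph,
)
from causalspace.nerve import (
    category_from_graph,
    discrete_category,
    poset_category,
)


def test_poset_2_nerve_counts():
    ts = nerve(poset_category(2), 2)
    assert [len(level) for level in ts.simplices] == [3, 6, 10]
    assert ts.nondegenerate_counts() == (3, 3, 1)


def test_poset_nondegenerate_counts_are_binomial():
    for m in range(5):
        ts = nerve(poset_category(m), min(m, 3))
        for n, count in enumerate(ts.nondegenerate_counts()):
            assert count == comb(m + 1, n + 1)


def test_discrete_category_nerve_has_only_identities():
    c = discrete_category("abc")
    ts = nerve(c, 2)
    assert all(c.is_identity(s[0]) for s in ts.simplices[1])
    assert ts.nondegenerate_counts() == (3, 0, 0)


def test_one_object_category_single_simplex_per_level():
    c = poset_category(0)
    ts = nerve(c, 3)
    for n in range(4):
        assert len(ts.simplices[n]) == 1
        if n >= 1:
            assert is_degenerate(c, ts.simplices[n][0])


def test_is_degenerate_examples():
    c = poset_category(1)
    assert is_degenerate(c, (c.identities[0],))
    assert not is_degenerate(c, ((0, 1),))
    ts = nerve(c, 2)
    for s in ts.simplices[1]:
        assert is_degenerate(c, ts.degeneracy(1, s, 0))


def _random_poset_category(seed: int) -> FiniteCategory:
    """A random finite preorder (reachability of a random DAG), always a
    valid strict category."""
    import random

    rnd = random.Random(seed)
    n = rnd.randint(1, 5)
    objects = list(range(n))
    reach = {o: {o} for o in objects}
    for i in objects:
        for j in objects[i + 1:]:
            if rnd.random() < 0.5:
                reach[i].add(j)
    # transitive closure
    for k in objects:
        for i in objects:
            if k in reach[i]:
                reach[i] |= reach[k]
    morphisms = {(i, j): (i, j) for i in objects for j in reach[i]}
    identities = {i: (i, i) for i in objects}
    composition = {
        ((i, j), (j, k)): (i, k)
        for i in objects
        for j in reach[i]
        for k in reach[j]
    }
    return FiniteCategory(tuple(objects), morphisms, identities, composition)


@settings(max_examples=40, derandomize=True)
@given(st.integers(0, 100_000))
def test_simplicial_identities_on_random_categories(seed):
    """The face/degeneracy operators of the nerve satisfy the simplicial
    identities on every stored simplex."""
    c = _random_poset_category(seed)
    k = 3
    ts = nerve(c, k, cap=200_000)
    for n in range(2, k + 1):
        for s in ts.simplices[n]:
            for j in range(n + 1):
                for i in range(j):
                    # d_i d_j = d_{j-1} d_i for i < j
                    assert ts.face(n - 1, ts.face(n, s, j), i) == ts.face(
                        n - 1, ts.face(n, s, i), j - 1
                    )
    for n in range(1, k):
        for s in ts.simplices[n]:
            for j in range(n + 1):
                up = ts.degeneracy(n, s, j)
                # d_j s_j = id = d_{j+1} s_j
                assert ts.face(n + 1, up, j) == s
                assert ts.face(n + 1, up, j + 1) == s


@settings(max_examples=40, derandomize=True)
@given(st.integers(0, 100_000))
def test_pi0_matches_one_skeleton_components(seed):
    """|pi0| equals the number of connected components of the nerve's
    1-skeleton."""
    c = _random_poset_category(seed)
    parent = {o: o for o in c.objects}

    def find(o):
        while parent[o] != o:
            o = parent[o]
        return o

    ts = nerve(c, 1)
    for (m,) in ts.simplices[1]:
        a, b = c.dom(m), c.cod(m)
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
    skeleton_comps = len({find(o) for o in c.objects})
    assert len(pi0(c)) == skeleton_comps


def test_pi0_examples():
    assert len(pi0(discrete_category("abc"))) == 3
    assert len(pi0(poset_category(2))) == 1
    two_arrows = category_from_graph(["a", "b", "c", "d"], [("a", "b"), ("c", "d")])
    assert len(pi0(two_arrows)) == 2


def test_category_of_elements_examples():
    p1 = poset_category(1)
    singleton = SetValuedFunctor(
        value_sets={0: ("*",), 1: ("*",)},
        maps={(0, 0): {"*": "*"}, (1, 1): {"*": "*"}, (0, 1): {"*": "*"}},
    )
    ce = category_of_elements(p1, singleton)
    assert len(ce.objects) == len(p1.objects)
    two_to_one = SetValuedFunctor(
        value_sets={0: ("a", "b"), 1: ("x",)},
        maps={
            (0, 0): {"a": "a", "b": "b"},
            (1, 1): {"x": "x"},
            (0, 1): {"a": "x", "b": "x"},
        },
    )
    ce2 = category_of_elements(p1, two_to_one)
    assert len(ce2.objects) == 3
    assert len(pi0(ce2)) == 1
    empty_at_one = SetValuedFunctor(
        value_sets={0: ("a",), 1: ()},
        maps={(0, 0): {"a": "a"}, (1, 1): {}},
    )
    with pytest.raises(ValueError):
        # (0,1) must map "a" somewhere, but the codomain set is empty
        category_of_elements(p1, empty_at_one)


def test_category_of_elements_rejects_non_functorial_delta():
    p1 = poset_category(1)
    broken = SetValuedFunctor(
        value_sets={0: ("a",), 1: ("x",)},
        maps={(0, 0): {"a": "a"}, (1, 1): {"x": "x"}},  # (0,1) missing
    )
    with pytest.raises(ValueError):
        category_of_elements(p1, broken)


def test_compare_invariants_verdicts():
    p2 = poset_category(2)
    assert compare_invariants(p2, p2, 2)["verdict"] == "indistinguishable-at-level-2"
    res = compare_invariants(p2, discrete_category("abc"), 2)
    assert res["verdict"] == "distinguishable"
    assert "nondegenerate_counts" in res["differing"]
    # deleting a morphism from the chain is detectable at the chain level
    chain = poset_category(2)
    cut_morphisms = {m: dc for m, dc in chain.morphisms.items() if m != (0, 2)}
    cut = FiniteCategory(
        chain.objects,
        cut_morphisms,
        chain.identities,
        {k: v for k, v in chain.composition.items()
         if k[0] != (0, 2) and k[1] != (0, 2) and v != (0, 2)},
        strict=False,
    )
    assert compare_invariants(chain, cut, 1)["verdict"] == "distinguishable"


def test_reversal_graph_category_pi0_matches_classes(partition3):
    """The 1-truncated category on the covered-reversal graph has one path
    component per Markov equivalence class."""
    graph = reversal_graph(partition3)
    cat = category_from_graph(
        graph.vertices, [tuple(pair) for pair in graph.edges]
    )
    assert len(pi0(cat)) == len(partition3.classes) == 11
    with pytest.raises(ValueError):
        nerve(cat, 2)  # truncated presentation refuses higher dimensions


def test_strict_validation_catches_broken_composition():
    # a single arrow needs no composition table (identities are implicit)
    FiniteCategory(
        objects=(0, 1),
        morphisms={"f": (0, 1), "id0": (0, 0), "id1": (1, 1)},
        identities={0: "id0", 1: "id1"},
        composition={},
        strict=True,
    )
    # but a genuinely missing non-identity composite is rejected
    with pytest.raises(ValueError):
        FiniteCategory(
            objects=(0, 1, 2),
            morphisms={
                "f": (0, 1), "g": (1, 2),
                "id0": (0, 0), "id1": (1, 1), "id2": (2, 2),
            },
            identities={0: "id0", 1: "id1", 2: "id2"},
            composition={},
            strict=True,
        )
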