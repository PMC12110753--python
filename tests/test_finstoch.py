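"""String-diagram semantics: composition, comonoid laws, network functors,
covered-edge invariance, and SCM interventions."""

import numpy as np
import pytest

from causalspace import (
    BayesNetFunctor,
    Dag,
    FinSpace,
    StochMorphism,
    check_comonoid_laws,
    check_natural_transformation,
    compose,
    do,
    generators,
    is_deterministic,
    joint,
    marginalize,
    mc_sequence,
    potential_outcome,
    reverse_covered_edge,
    scm_evaluate,
    tensor,
)
from causalspace.finstoch import (
    copy_map,
    delete_map,
    identity,
    random_stochastic,
    scm_to_bayes_net,
    swap_map,
)
from causalspace.synthdata import fixtures


@pytest.fixture
def ab_functor():
    """Worked example: P(A=1)=0.3, P(B=1|A=0)=0.2, P(B=1|A=1)=0.9."""
    A, B = FinSpace("A", 2), FinSpace("B", 2)
    return BayesNetFunctor(
        dag=Dag("AB", [("A", "B")]),
        spaces={"A": A, "B": B},
        cpts={
            "A": StochMorphism((), (A,), [[0.7, 0.3]]),
            "B": StochMorphism((A,), (B,), [[0.8, 0.2], [0.1, 0.9]]),
        },
    )


def test_morphism_validation():
    X = FinSpace("X", 2)
    with pytest.raises(ValueError):
        StochMorphism((X,), (X,), [[0.5, 0.6], [0.5, 0.5]])
    with pytest.raises(ValueError):
        StochMorphism((X,), (X,), [[1.5, -0.5], [0.5, 0.5]])
    with pytest.raises(ValueError):
        FinSpace("X", 0)


def test_compose_identity_and_elementwise_oracle():
    X = FinSpace("X", 3)
    rng = np.random.default_rng(0)
    f = random_stochastic((X,), (X,), rng)
    g = random_stochastic((X,), (X,), rng)
    assert compose(f, identity((X,))).allclose(f)
    prod = compose(f, g)
    for a in range(3):
        for c in range(3):
            manual = sum(f.matrix[a, b] * g.matrix[b, c] for b in range(3))
            assert prod.matrix[a, c] == pytest.approx(manual, abs=1e-12)
    # composing a state with delete normalizes to the scalar 1
    psi = random_stochastic((), (X,), rng)
    assert np.allclose(compose(psi, delete_map(X)).matrix, [[1.0]])


def test_tensor_index_oracle():
    X = FinSpace("X", 2)
    rng = np.random.default_rng(1)
    f = random_stochastic((X,), (X,), rng)
    g = random_stochastic((X,), (X,), rng)
    t = tensor(f, g)
    for i in range(2):
        for j in range(2):
            for k in range(2):
                for ell in range(2):
                    assert t.matrix[i * 2 + j, k * 2 + ell] == pytest.approx(
                        f.matrix[i, k] * g.matrix[j, ell], abs=1e-12
                    )
    unit = identity(())
    assert np.allclose(tensor(unit, unit).matrix, [[1.0]])
    # tensor with identity then delete the second factor recovers f
    fi = tensor(f, identity((X,)))
    proj = np.kron(np.eye(2), np.ones((2, 1)))
    recovered = fi.matrix @ proj
    # rows of fi are indexed by (dom f, X); delete averages nothing out of f
    for i in range(2):
        for j in range(2):
            assert recovered[i * 2 + j] == pytest.approx(f.matrix[i], abs=1e-12)


def test_generators_shapes_and_values():
    one = FinSpace("I", 1)
    cp1, dl1, _ = generators(one)
    assert np.allclose(cp1.matrix, [[1.0]])
    assert np.allclose(dl1.matrix, [[1.0]])
    X = FinSpace("X", 2)
    cp, _, sw = generators(X)
    assert np.allclose(cp.matrix, [[1, 0, 0, 0], [0, 0, 0, 1]])
    assert (sw.matrix @ sw.matrix == np.eye(4)).all()


def test_comonoid_laws_pass_and_corrupted_copy_fails():
    for size in range(1, 5):
        report = check_comonoid_laws(FinSpace("X", size), seed=3)
        assert all(ok for ok, _ in report.values())
        assert max(dev for _, dev in report.values()) < 1e-12
    # negative control: send outcome 1 to (0, 1) instead of (1, 1); the
    # right counit and cocommutativity both break
    X = FinSpace("X", 2)
    bad = np.array([[1.0, 0, 0, 0], [0, 1.0, 0, 0]])
    idn = np.eye(2)
    counit_right_dev = np.max(
        np.abs(bad @ np.kron(idn, delete_map(X).matrix) - idn)
    )
    cocomm_dev = np.max(np.abs(bad @ swap_map(X, X).matrix - bad))
    assert counit_right_dev > 1e-6 and cocomm_dev > 1e-6


def test_determinism_examples():
    X = FinSpace("X", 2)
    assert is_deterministic(identity((X,)))
    flip = StochMorphism((X,), (X,), [[0, 1], [1, 0]])
    assert is_deterministic(flip)
    assert not is_deterministic(
        StochMorphism((X,), (X,), [[0.5, 0.5], [0.5, 0.5]])
    )


def test_joint_worked_example(ab_functor):
    j = joint(ab_functor)
    assert j.matrix[0] == pytest.approx([0.56, 0.14, 0.03, 0.27], abs=1e-12)
    assert j.matrix.sum() == pytest.approx(1.0, abs=1e-12)


def test_joint_independent_coins_uniform():
    A, B = FinSpace("A", 2), FinSpace("B", 2)
    bn = BayesNetFunctor(
        dag=Dag("AB"),
        spaces={"A": A, "B": B},
        cpts={
            "A": StochMorphism((), (A,), [[0.5, 0.5]]),
            "B": StochMorphism((), (B,), [[0.5, 0.5]]),
        },
    )
    assert joint(bn).matrix[0] == pytest.approx([0.25] * 4, abs=1e-12)
    assert marginalize(joint(bn), {"A"}).matrix[0] == pytest.approx([0.5, 0.5])


def test_marginalize_against_summation_oracle(ab_functor):
    j = joint(ab_functor)
    grid = j.matrix[0].reshape(2, 2)
    assert marginalize(j, {"B"}).matrix[0] == pytest.approx(
        grid.sum(axis=0), abs=1e-12
    )
    assert marginalize(j, {"A"}).matrix[0] == pytest.approx(
        grid.sum(axis=1), abs=1e-12
    )
    assert np.allclose(marginalize(j, set()).matrix, [[1.0]])
    with pytest.raises(KeyError):
        marginalize(j, {"Z"})


def test_joint_conditional_consistency(ab_functor):
    """Conditioning the joint on the parent recovers each CPT row."""
    j = joint(ab_functor).matrix[0].reshape(2, 2)
    for a in range(2):
        pa = j[a].sum()
        assert j[a] / pa == pytest.approx(
            ab_functor.cpts["B"].matrix[a], abs=1e-12
        )


def test_reverse_covered_edge_preserves_joint(ab_functor):
    rev = reverse_covered_edge(ab_functor, ("A", "B"))
    assert rev.dag.edges == frozenset({("B", "A")})
    assert np.allclose(
        joint(rev).matrix, joint(ab_functor).matrix, atol=1e-9
    )


def test_reverse_covered_edge_chain_and_refusal():
    rng = np.random.default_rng(9)
    spaces = {v: FinSpace(v, 2) for v in "ABC"}
    dag = Dag("ABC", [("A", "B"), ("B", "C")])
    bn = BayesNetFunctor(
        dag=dag,
        spaces=spaces,
        cpts={
            "A": random_stochastic((), (spaces["A"],), rng),
            "B": random_stochastic((spaces["A"],), (spaces["B"],), rng),
            "C": random_stochastic((spaces["B"],), (spaces["C"],), rng),
        },
    )
    rev = reverse_covered_edge(bn, ("A", "B"))
    assert np.allclose(joint(rev).matrix, joint(bn).matrix, atol=1e-9)
    with pytest.raises(ValueError, match="not covered"):
        reverse_covered_edge(bn, ("B", "C"))


def test_reverse_covered_edge_zero_mass_parent_row():
    """A parent value of probability zero leaves an undefined conditional;
    the uniform fill still reproduces the joint."""
    A, B = FinSpace("A", 2), FinSpace("B", 2)
    bn = BayesNetFunctor(
        dag=Dag("AB", [("A", "B")]),
        spaces={"A": A, "B": B},
        cpts={
            "A": StochMorphism((), (A,), [[1.0, 0.0]]),
            "B": StochMorphism((A,), (B,), [[0.25, 0.75], [1.0, 0.0]]),
        },
    )
    rev = reverse_covered_edge(bn, ("A", "B"))
    assert np.allclose(joint(rev).matrix, joint(bn).matrix, atol=1e-12)


def test_full_reversal_sequences_preserve_joint_stepwise(dags3):
    """Replaying every certificate between equivalent seeded 3-node functors
    preserves the joint at every intermediate step."""
    rng = np.random.default_rng(21)
    chain = Dag("ABC", [("A", "B"), ("B", "C")])
    spaces = {v: FinSpace(v, 2) for v in "ABC"}

    def functor_on(dag):
        cpts = {}
        for v in dag.nodes:
            parents = tuple(spaces[p] for p in sorted(dag.parents(v)))
            cpts[v] = random_stochastic(parents, (spaces[v],), rng)
        return BayesNetFunctor(dag=dag, spaces=spaces, cpts=cpts)

    from causalspace import class_members

    members = sorted(class_members(chain), key=lambda d: d.sorted_edges())
    for g in members:
        bn = functor_on(g)
        reference = joint(bn).matrix
        for h in members:
            cert = mc_sequence(g, h)
            current = bn
            for edit in cert.edits:
                assert edit.kind == "reverse"
                current = reverse_covered_edge(current, edit.edge)
                assert np.allclose(joint(current).matrix, reference, atol=1e-9)
            assert current.dag.edges == h.edges


def test_natural_transformation_identity_and_negative_cases(ab_functor):
    A, B = ab_functor.spaces["A"], ab_functor.spaces["B"]
    ident = {"A": identity((A,)), "B": identity((B,))}
    assert check_natural_transformation(ab_functor, ab_functor, ident)
    # intervention-deleted variant: same objects, edge removed
    cut = BayesNetFunctor(
        dag=Dag("AB"),
        spaces=dict(ab_functor.spaces),
        cpts={
            "A": ab_functor.cpts["A"],
            "B": StochMorphism((), (B,), [[0.5, 0.5]]),
        },
    )
    assert not check_natural_transformation(ab_functor, cut, ident)
    rng = np.random.default_rng(4)
    scrambled = {
        "A": random_stochastic((A,), (A,), rng),
        "B": random_stochastic((B,), (B,), rng),
    }
    assert not check_natural_transformation(ab_functor, ab_functor, scrambled)
    with pytest.raises(KeyError):
        check_natural_transformation(ab_functor, ab_functor, {"A": ident["A"]})


# -- SCM layer ---------------------------------------------------------------


def test_scm_xor_hand_computations():
    s = fixtures()["xor_scm"]
    assert scm_evaluate(s, {"U": 1, "U2": 0}) == {"X": 0, "Y": 1}
    # idempotence
    assert scm_evaluate(s, {"U": 1, "U2": 0}) == scm_evaluate(
        s, {"U": 1, "U2": 0}
    )
    sub = do(s, {"X": 1})
    assert scm_evaluate(sub, {"U": 1, "U2": 0}) == {"X": 1, "Y": 0}
    assert potential_outcome(s, {"X": 1}, {"U": 1, "U2": 0}, "Y") == 0
    # intervening on the target returns the assigned constant
    assert potential_outcome(s, {"Y": 1}, {"U": 0, "U2": 0}, "Y") == 1
    # consistency: when X already equals x, Y_x(u) is the observed Y
    obs = scm_evaluate(s, {"U": 0, "U2": 1})
    assert potential_outcome(s, {"X": obs["X"]}, {"U": 0, "U2": 1}, "Y") == obs["Y"]


def test_do_refuses_exogenous_and_empty_do_is_identity():
    s = fixtures()["xor_scm"]
    with pytest.raises(ValueError):
        do(s, {"U": 1})
    same = do(s, {})
    for u in ({"U": 0, "U2": 0}, {"U": 1, "U2": 1}):
        assert scm_evaluate(same, u) == scm_evaluate(s, u)


def test_scm_mechanisms_are_deterministic_and_induce_a_functor():
    for name in ("xor_scm", "pollution_scm"):
        s = fixtures()[name]
        for _, mech in s.mechanisms.values():
            assert is_deterministic(mech)
        bn = scm_to_bayes_net(s)
        assert joint(bn).matrix.sum() == pytest.approx(1.0, abs=1e-9)


def test_swap_is_permutation_between_mixed_sizes():
    X, Y = FinSpace("X", 2), FinSpace("Y", 3)
    sw = swap_map(X, Y)
    back = swap_map(Y, X)
    assert (sw.matrix @ back.matrix == np.eye(6)).all()


def test_copy_then_marginal_recovers_state():
    X = FinSpace("X", 3)
    rng = np.random.default_rng(2)
    psi = random_stochastic((), (X,), rng)
    copied = compose(psi, copy_map(X))
    dropped = copied.matrix @ np.kron(np.eye(3), np.ones((3, 1)))
    assert dropped == pytest.approx(psi.matrix, abs=1e-12)
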