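"""Finite stochastic string-diagram semantics of Bayesian networks and SCMs.

The category FinStoch has finite sets as objects and row-stochastic matrices
as morphisms; composition is matrix multiplication in diagram order and the
monoidal product is the Kronecker product.  Every object carries a
commutative comonoid: a copy map ``X -> X (x) X`` (the diagonal) and a delete
map ``X -> I`` (the all-ones column), with delete natural (equivalently, all
morphisms are row-stochastic) while copy is not -- the hallmark of a Markov
category.  A Bayesian network on a DAG G is the same data as a functor from
G's syntactic category into FinStoch: one conditional probability table per
node, from the tensor of its parents' spaces to its own.  Reversing a
covered edge of G induces a semantics-preserving rewrite of the functor
(Bayes' rule on the local family), the semantic face of Markov equivalence.

Structural causal models live in the Cartesian (deterministic) fragment:
exogenous variables carry distributions, endogenous variables carry 0/1
mechanism matrices, and ``do`` interventions replace mechanisms by constants.

Conventions: matrix rows index inputs and columns index outputs, so the
composite ``f ; g`` is the product ``F @ G``; tensor outcome order is
mixed-radix with the last factor fastest (matching ``np.kron``); CPT parent
order is the canonical sorted label order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import product as iproduct
from typing import Dict, Iterable, Mapping, Optional, Sequence, Tuple

import numpy as np

from .dag import Dag, covered_edges

__all__ = [
    "ATOL",
    "FinSpace",
    "StochMorphism",
    "BayesNetFunctor",
    "Scm",
    "compose",
    "tensor",
    "identity",
    "copy_map",
    "delete_map",
    "swap_map",
    "generators",
    "random_stochastic",
    "check_comonoid_laws",
    "is_deterministic",
    "joint",
    "marginalize",
    "reverse_covered_edge",
    "check_natural_transformation",
    "scm_evaluate",
    "do",
    "potential_outcome",
    "scm_to_bayes_net",
]

#: numeric tolerance for all law and equality checks
ATOL = 1e-9


@dataclass(frozen=True)
class FinSpace:
    """A finite outcome space; the monoidal unit I is any space of size 1."""

    label: str
    size: int

    def __post_init__(self) -> None:
        if self.size < 1:
            raise ValueError("space size must be >= 1")


def _total(factors: Tuple[FinSpace, ...]) -> int:
    return int(math.prod(f.size for f in factors))


class StochMorphism:
    """A row-stochastic matrix with recorded domain/codomain factorizations.

    ``dom`` and ``cod`` are tuples of :class:`FinSpace`; the empty tuple is
    the monoidal unit I.  Row/column indices enumerate factor outcomes in
    mixed radix, last factor fastest.
    """

    __slots__ = ("dom", "cod", "matrix")

    def __init__(
        self,
        dom: Sequence[FinSpace],
        cod: Sequence[FinSpace],
        matrix,
    ):
        dom = tuple(dom)
        cod = tuple(cod)
        m = np.asarray(matrix, dtype=float)
        if m.ndim != 2 or m.shape != (_total(dom), _total(cod)):
            raise ValueError(
                f"matrix shape {m.shape} does not match factors "
                f"({_total(dom)}, {_total(cod)})"
            )
        if m.size and m.min() < -ATOL:
            raise ValueError("negative probability entry")
        rows = m.sum(axis=1)
        if m.size and np.max(np.abs(rows - 1.0)) > ATOL:
            raise ValueError("rows must sum to 1")
        self.dom = dom
        self.cod = cod
        self.matrix = m
        self.matrix.setflags(write=False)

    @property
    def dom_size(self) -> int:
        return _total(self.dom)

    @property
    def cod_size(self) -> int:
        return _total(self.cod)

    def allclose(self, other: "StochMorphism", atol: float = ATOL) -> bool:
        return self.matrix.shape == other.matrix.shape and bool(
            np.allclose(self.matrix, other.matrix, atol=atol, rtol=0.0)
        )

    def __repr__(self) -> str:
        d = "x".join(f"{s.label}:{s.size}" for s in self.dom) or "I"
        c = "x".join(f"{s.label}:{s.size}" for s in self.cod) or "I"
        return f"StochMorphism({d} -> {c})"


def compose(f: StochMorphism, g: StochMorphism) -> StochMorphism:
    """Diagram-order composite ``f ; g`` (matrix product)."""
    if f.cod_size != g.dom_size:
        raise ValueError(
            f"codomain size {f.cod_size} != domain size {g.dom_size}"
        )
    return StochMorphism(f.dom, g.cod, f.matrix @ g.matrix)


def tensor(f: StochMorphism, g: StochMorphism) -> StochMorphism:
    """Monoidal product (Kronecker product with factor bookkeeping)."""
    return StochMorphism(
        f.dom + g.dom, f.cod + g.cod, np.kron(f.matrix, g.matrix)
    )


def identity(factors: Sequence[FinSpace]) -> StochMorphism:
    factors = tuple(factors)
    return StochMorphism(factors, factors, np.eye(_total(factors)))


def copy_map(x: FinSpace) -> StochMorphism:
    """The diagonal ``X -> X (x) X``: outcome i maps to (i, i)."""
    n = x.size
    m = np.zeros((n, n * n))
    for i in range(n):
        m[i, i * n + i] = 1.0
    return StochMorphism((x,), (x, x), m)


def delete_map(x: FinSpace) -> StochMorphism:
    """The terminal map ``X -> I`` (all-ones column)."""
    return StochMorphism((x,), (), np.ones((x.size, 1)))


def swap_map(x: FinSpace, y: FinSpace) -> StochMorphism:
    """The braiding ``X (x) Y -> Y (x) X`` permutation."""
    m = np.zeros((x.size * y.size, y.size * x.size))
    for i in range(x.size):
        for j in range(y.size):
            m[i * y.size + j, j * x.size + i] = 1.0
    return StochMorphism((x, y), (y, x), m)


def generators(
    x: FinSpace, y: Optional[FinSpace] = None
) -> Tuple[StochMorphism, StochMorphism, StochMorphism]:
    """The comonoid generators ``(copy, delete, swap)`` for ``x`` (swap over
    ``x (x) y``, defaulting to ``y = x``)."""
    return copy_map(x), delete_map(x), swap_map(x, y if y is not None else x)


def random_stochastic(
    dom: Sequence[FinSpace], cod: Sequence[FinSpace], rng: np.random.Generator
) -> StochMorphism:
    """A Dirichlet(1)-row random morphism (for law and property checks)."""
    dom, cod = tuple(dom), tuple(cod)
    m = rng.dirichlet(np.ones(_total(cod)), size=_total(dom))
    return StochMorphism(dom, cod, m)


def check_comonoid_laws(
    x: FinSpace, seed: int = 0, n_random: int = 20
) -> Dict[str, Tuple[bool, float]]:
    """Verify the comonoid equations for ``x``'s generators.

    Checks coassociativity, both counit identities, cocommutativity, the
    tensor-compatibility construction ``(1 (x) swap (x) 1) o (copy (x) copy)``
    against the product space's copy, and naturality of delete for
    ``n_random`` seeded random morphisms out of ``x``.  Returns per-law
    ``(passed, max deviation)`` entries.
    """
    n = x.size
    cp, dl, _ = generators(x)
    idn = identity((x,))
    report: Dict[str, Tuple[bool, float]] = {}

    def record(name: str, a: np.ndarray, b: np.ndarray) -> None:
        dev = float(np.max(np.abs(a - b))) if a.size else 0.0
        report[name] = (dev <= ATOL, dev)

    record(
        "coassociativity",
        cp.matrix @ np.kron(cp.matrix, np.eye(n)),
        cp.matrix @ np.kron(np.eye(n), cp.matrix),
    )
    record("counit_left", cp.matrix @ np.kron(dl.matrix, np.eye(n)), idn.matrix)
    record("counit_right", cp.matrix @ np.kron(np.eye(n), dl.matrix), idn.matrix)
    record("cocommutativity", cp.matrix @ swap_map(x, x).matrix, cp.matrix)

    # tensor compatibility: copy on X (x) Y equals (copy_X (x) copy_Y)
    # followed by the middle swap, for a second space Y.
    y = FinSpace(x.label + "'", max(2, min(n, 3)))
    cx, cy = copy_map(x), copy_map(y)
    mid = np.kron(
        np.kron(np.eye(x.size), swap_map(x, y).matrix), np.eye(y.size)
    )
    xy = FinSpace(f"{x.label}*{y.label}", x.size * y.size)
    record(
        "tensor_compatibility",
        np.kron(cx.matrix, cy.matrix) @ mid,
        copy_map(xy).matrix,
    )

    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_random):
        cod = FinSpace("r", int(rng.integers(1, 5)))
        f = random_stochastic((x,), (cod,), rng)
        lhs = f.matrix @ delete_map(cod).matrix
        worst = max(worst, float(np.max(np.abs(lhs - dl.matrix))))
    report["del_naturality"] = (worst <= ATOL, worst)
    return report


def is_deterministic(f: StochMorphism, atol: float = ATOL) -> bool:
    """True iff ``f`` admits uniform copying:
    ``f ; copy_cod = copy_dom ; (f (x) f)``."""
    cod_space = FinSpace("c", f.cod_size)
    dom_space = FinSpace("d", f.dom_size)
    lhs = f.matrix @ copy_map(cod_space).matrix
    rhs = copy_map(dom_space).matrix @ np.kron(f.matrix, f.matrix)
    return bool(np.allclose(lhs, rhs, atol=atol, rtol=0.0))


# ---------------------------------------------------------------------------
# Bayesian-network functors
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BayesNetFunctor:
    """A DAG together with one CPT per node: the concrete form of a functor
    from the DAG's syntactic category into FinStoch.

    ``cpts[v]`` maps the tensor of ``v``'s parents' spaces (in canonical
    sorted label order; the unit I when parentless) to ``v``'s space.
    """

    dag: Dag
    spaces: Mapping[str, FinSpace]
    cpts: Mapping[str, StochMorphism]

    def __post_init__(self) -> None:
        for v in self.dag.nodes:
            if v not in self.spaces:
                raise ValueError(f"no space for node {v!r}")
            if v not in self.cpts:
                raise ValueError(f"no CPT for node {v!r}")
            expected_dom = tuple(
                self.spaces[p] for p in sorted(self.dag.parents(v))
            )
            cpt = self.cpts[v]
            if tuple(s.size for s in cpt.dom) != tuple(
                s.size for s in expected_dom
            ):
                raise ValueError(
                    f"CPT domain of {v!r} does not match parent spaces"
                )
            if cpt.cod_size != self.spaces[v].size:
                raise ValueError(f"CPT codomain of {v!r} has wrong size")

    def node_sizes(self) -> Tuple[int, ...]:
        return tuple(self.spaces[v].size for v in self.dag.nodes)


def _row_of(values: Mapping[str, int], labels: Sequence[str],
            sizes: Mapping[str, int]) -> int:
    idx = 0
    for lbl in labels:
        idx = idx * sizes[lbl] + values[lbl]
    return idx


def joint(bn: BayesNetFunctor) -> StochMorphism:
    """The joint state ``I -> (x)_v X_v`` (node order = sorted labels):
    each outcome tuple gets the product of its CPT entries."""
    nodes = bn.dag.nodes
    sizes = {v: bn.spaces[v].size for v in nodes}
    parent_lists = {v: sorted(bn.dag.parents(v)) for v in nodes}
    shape = tuple(sizes[v] for v in nodes)
    out = np.zeros(shape)
    for outcome in np.ndindex(*shape):
        values = dict(zip(nodes, outcome))
        p = 1.0
        for v in nodes:
            row = _row_of(values, parent_lists[v], sizes)
            p *= bn.cpts[v].matrix[row, values[v]]
            if p == 0.0:
                break
        out[outcome] = p
    return StochMorphism(
        (), tuple(bn.spaces[v] for v in nodes), out.reshape(1, -1)
    )


def marginalize(state: StochMorphism, keep: Iterable[str]) -> StochMorphism:
    """Marginal of a state ``I -> X_1 (x) ... (x) X_k`` onto the factors
    whose labels are in ``keep``: composition with identities and deletes."""
    if state.dom != ():
        raise ValueError("marginalize expects a state (domain I)")
    keep = set(keep)
    labels = {f.label for f in state.cod}
    unknown = keep - labels
    if unknown:
        raise KeyError(f"unknown factors {sorted(unknown)}")
    proj = np.eye(1)
    kept = []
    for f in state.cod:
        if f.label in keep:
            proj = np.kron(proj, np.eye(f.size))
            kept.append(f)
        else:
            proj = np.kron(proj, np.ones((f.size, 1)))
    return StochMorphism((), tuple(kept), state.matrix @ proj)


def reverse_covered_edge(
    bn: BayesNetFunctor, edge: Tuple[str, str]
) -> BayesNetFunctor:
    """The functor on the covered-edge-reversed DAG with the same joint.

    For a covered edge ``X -> Y`` with common parents P, the local family
    joint ``J(x, y | p) = P(x | p) P(y | p, x)`` is re-factored by Bayes'
    rule into ``P(y | p)`` and ``P(x | p, y)``.  Zero-mass conditionals are
    filled with the uniform row (any choice leaves the joint unchanged).
    Raises on a non-covered edge.
    """
    x, y = edge
    if edge not in covered_edges(bn.dag):
        raise ValueError(f"edge ({x!r}, {y!r}) is not covered")
    sizes = {v: bn.spaces[v].size for v in bn.dag.nodes}
    common = sorted(bn.dag.parents(x))
    sx, sy = sizes[x], sizes[y]
    old_x_parents = common  # == sorted(Pa(x))
    old_y_parents = sorted(set(common) | {x})
    new_y_parents = common
    new_x_parents = sorted(set(common) | {y})

    shape_p = tuple(sizes[c] for c in common)
    new_y = np.zeros((int(math.prod(shape_p)) or 1, sy))
    new_x = np.zeros(((int(math.prod(shape_p)) or 1) * sy, sx))
    for pvals in np.ndindex(*shape_p) if shape_p else [()]:
        assign = dict(zip(common, pvals))
        jxy = np.zeros((sx, sy))
        for xv in range(sx):
            assign[x] = xv
            px = bn.cpts[x].matrix[_row_of(assign, old_x_parents, sizes), xv]
            row_y = bn.cpts[y].matrix[_row_of(assign, old_y_parents, sizes)]
            jxy[xv] = px * row_y
        del assign[x]
        py = jxy.sum(axis=0)
        prow = _row_of(assign, common, sizes)
        new_y[prow] = py
        for yv in range(sy):
            assign[y] = yv
            xrow = _row_of(assign, new_x_parents, sizes)
            if py[yv] > 0:
                new_x[xrow] = jxy[:, yv] / py[yv]
            else:
                new_x[xrow] = np.full(sx, 1.0 / sx)
            del assign[y]
    new_dag = bn.dag.with_reversed_edge(x, y)
    cpts = dict(bn.cpts)
    cpts[y] = StochMorphism(
        tuple(bn.spaces[c] for c in new_y_parents), (bn.spaces[y],), new_y
    )
    cpts[x] = StochMorphism(
        tuple(bn.spaces[c] for c in new_x_parents), (bn.spaces[x],), new_x
    )
    return BayesNetFunctor(dag=new_dag, spaces=dict(bn.spaces), cpts=cpts)


def check_natural_transformation(
    f1: BayesNetFunctor,
    f2: BayesNetFunctor,
    components: Mapping[str, StochMorphism],
) -> bool:
    """Pointwise naturality check between two network functors.

    ``components`` assigns each node label a FinStoch morphism; the square
    for node v's mechanism commutes when
    ``F(cpt_v) ; alpha_v  =  (tensor of parent components) ; G(cpt_v)``.
    Returns False at the first failing or shape-incompatible square; raises
    ``KeyError`` on a missing component.
    """
    if set(f1.dag.nodes) != set(f2.dag.nodes):
        raise ValueError("functors have different object sets")
    for v in f1.dag.nodes:
        if v not in components:
            raise KeyError(f"missing component for {v!r}")
    for v in f1.dag.nodes:
        p1 = sorted(f1.dag.parents(v))
        p2 = sorted(f2.dag.parents(v))
        if p1 != p2:
            return False
        alpha_dom = np.eye(1)
        for p in p1:
            alpha_dom = np.kron(alpha_dom, components[p].matrix)
        lhs = f1.cpts[v].matrix @ components[v].matrix
        rhs = alpha_dom @ f2.cpts[v].matrix
        if lhs.shape != rhs.shape or not np.allclose(
            lhs, rhs, atol=ATOL, rtol=0.0
        ):
            return False
    return True


# ---------------------------------------------------------------------------
# Structural causal models
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Scm:
    """A structural causal model: exogenous distributions plus deterministic
    endogenous mechanisms.

    ``mechanisms[v]`` is ``(args, f)`` where ``args`` is the ordered argument
    list (labels in U or V minus v) and ``f`` a 0/1 morphism from the tensor
    of the argument spaces (in that order) to v's space.  The induced
    dependency graph must be acyclic.
    """

    spaces: Mapping[str, FinSpace]
    exogenous: Mapping[str, StochMorphism]
    mechanisms: Mapping[str, Tuple[Tuple[str, ...], StochMorphism]]
    dag: Dag = field(init=False)

    def __post_init__(self) -> None:
        overlap = set(self.exogenous) & set(self.mechanisms)
        if overlap:
            raise ValueError(f"labels both exogenous and endogenous: {overlap}")
        for u, st in self.exogenous.items():
            if st.dom != () or st.cod_size != self.spaces[u].size:
                raise ValueError(f"exogenous state for {u!r} has wrong shape")
        edges = []
        for v, (args, f) in self.mechanisms.items():
            if v in args:
                raise ValueError(f"mechanism of {v!r} refers to itself")
            for a in args:
                if a not in self.spaces:
                    raise ValueError(f"unknown argument {a!r}")
                edges.append((a, v))
            if tuple(s.size for s in f.dom) != tuple(
                self.spaces[a].size for a in args
            ):
                raise ValueError(f"mechanism domain of {v!r} mismatches args")
            if f.cod_size != self.spaces[v].size:
                raise ValueError(f"mechanism codomain of {v!r} has wrong size")
            m = f.matrix
            if not np.allclose(m * (1 - m), 0.0, atol=ATOL) or not np.allclose(
                m.sum(axis=1), 1.0, atol=ATOL
            ):
                raise ValueError(f"mechanism of {v!r} is not deterministic")
        # acyclicity of the induced dependency graph
        object.__setattr__(
            self, "dag", Dag(set(self.spaces), set(edges))
        )


def scm_evaluate(s: Scm, u: Mapping[str, int]) -> Dict[str, int]:
    """The unique solution of the structural equations at exogenous outcome
    ``u``: evaluation in topological order."""
    missing = set(s.exogenous) - set(u)
    if missing:
        raise ValueError(f"missing exogenous values for {sorted(missing)}")
    values: Dict[str, int] = {k: int(u[k]) for k in s.exogenous}
    sizes = {k: sp.size for k, sp in s.spaces.items()}
    for k, val in values.items():
        if not 0 <= val < sizes[k]:
            raise ValueError(f"value {val} out of range for {k!r}")
    for v in s.dag.topological_order():
        if v in values:
            continue
        args, f = s.mechanisms[v]
        row = 0
        for a in args:
            row = row * sizes[a] + values[a]
        values[v] = int(np.argmax(f.matrix[row]))
    return {v: values[v] for v in s.mechanisms}


def do(s: Scm, assignment: Mapping[str, int]) -> Scm:
    """The submodel with the mechanisms of the assigned variables replaced by
    constants; exogenous variables are non-manipulable."""
    bad = set(assignment) & set(s.exogenous)
    if bad:
        raise ValueError(f"cannot intervene on exogenous {sorted(bad)}")
    unknown = set(assignment) - set(s.mechanisms)
    if unknown:
        raise KeyError(f"unknown endogenous {sorted(unknown)}")
    mechanisms = dict(s.mechanisms)
    for v, val in assignment.items():
        size = s.spaces[v].size
        if not 0 <= int(val) < size:
            raise ValueError(f"value {val} out of range for {v!r}")
        const = np.zeros((1, size))
        const[0, int(val)] = 1.0
        mechanisms[v] = ((), StochMorphism((), (s.spaces[v],), const))
    return Scm(spaces=dict(s.spaces), exogenous=dict(s.exogenous),
               mechanisms=mechanisms)


def potential_outcome(
    s: Scm, assignment: Mapping[str, int], u: Mapping[str, int], target: str
) -> int:
    """``Y_x(u)``: the solution for ``target`` in the ``do(assignment)``
    submodel at exogenous outcome ``u``."""
    return scm_evaluate(do(s, assignment), u)[target]


def scm_to_bayes_net(s: Scm) -> BayesNetFunctor:
    """The network functor over U and V induced by an SCM: exogenous nodes
    carry their state distributions, endogenous nodes their mechanisms
    (re-indexed to canonical sorted parent order)."""
    sizes = {k: sp.size for k, sp in s.spaces.items()}
    cpts: Dict[str, StochMorphism] = {}
    for uvar, st in s.exogenous.items():
        cpts[uvar] = StochMorphism((), (s.spaces[uvar],), st.matrix)
    for v, (args, f) in s.mechanisms.items():
        sorted_args = tuple(sorted(args))
        shape = tuple(sizes[a] for a in sorted_args)
        m = np.zeros((int(math.prod(shape)) or 1, sizes[v]))
        for vals in np.ndindex(*shape) if shape else [()]:
            assign = dict(zip(sorted_args, vals))
            row_sorted = _row_of(assign, sorted_args, sizes)
            row_orig = 0
            for a in args:
                row_orig = row_orig * sizes[a] + assign[a]
            m[row_sorted] = f.matrix[row_orig]
        cpts[v] = StochMorphism(
            tuple(s.spaces[a] for a in sorted_args), (s.spaces[v],), m
        )
    return BayesNetFunctor(dag=s.dag, spaces=dict(s.spaces), cpts=cpts)
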