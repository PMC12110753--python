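"""Greedy Equivalence Search over Markov equivalence classes with a
decomposable BIC score.

The BIC of a discrete DAG model is the maximized multinomial log-likelihood
penalized by ``0.5 * ln(N)`` per free parameter, summed over nodes:

    S(G, D) = sum_i [ ll(X_i | Pa_i) - 0.5 ln(N) (r_i - 1) prod_j r_j ]

where ``r_i`` is the arity of node i and the product runs over its parents.
The score is the same for every DAG in an equivalence class (score
equivalence), so the search moves class-to-class: starting from the empty
graph it repeatedly jumps to the best-scoring class reachable by adding one
edge to any member DAG (forward phase), then by deleting one edge (backward
phase), stopping when no move improves the score.  With enough data from a
DAG-perfect distribution the generating class attains the strictly largest
score, and the search returns it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np

from .dag import Dag, EquivClassSignature, signature
from .class_space import canonical_representative, class_members

__all__ = [
    "DiscreteDataset",
    "ScoredClass",
    "local_score",
    "score_dag",
    "ges_run",
    "IMPROVEMENT_TOL",
]

#: minimum score gain (natural-log units) counted as an improvement
IMPROVEMENT_TOL = 1e-9


class DiscreteDataset:
    """A rectangular table of category codes, one column per variable.

    Parameters
    ----------
    variables:
        Ordered label sequence.
    rows:
        Array-like of shape ``(N, len(variables))`` of non-negative ints.
    arities:
        Optional per-variable category counts; inferred as ``max + 1``
        (at least 1) when omitted.
    """

    __slots__ = ("variables", "arities", "data")

    def __init__(
        self,
        variables: Sequence[str],
        rows,
        arities: Optional[Sequence[int]] = None,
    ):
        self.variables = tuple(str(v) for v in variables)
        if len(set(self.variables)) != len(self.variables):
            raise ValueError("duplicate variable labels")
        data = np.asarray(rows, dtype=np.int64)
        if data.ndim != 2 or data.shape[1] != len(self.variables):
            raise ValueError("rows must be N x len(variables)")
        if data.size and data.min() < 0:
            raise ValueError("negative category code")
        if arities is None:
            arities = [
                int(data[:, j].max()) + 1 if len(data) else 1
                for j in range(data.shape[1])
            ]
        arities = tuple(int(a) for a in arities)
        for j, a in enumerate(arities):
            if a < 1:
                raise ValueError("arity must be >= 1")
            if len(data) and data[:, j].max() >= a:
                raise ValueError(
                    f"value {int(data[:, j].max())} exceeds arity {a} in "
                    f"column {self.variables[j]!r}"
                )
        self.arities = arities
        self.data = data

    @property
    def n_rows(self) -> int:
        return self.data.shape[0]

    def column(self, label: str) -> np.ndarray:
        return self.data[:, self.variables.index(label)]

    def arity(self, label: str) -> int:
        return self.arities[self.variables.index(label)]


@dataclass(frozen=True)
class ScoredClass:
    """An equivalence class with its canonical representative and BIC score."""

    signature: EquivClassSignature
    representative: Dag
    score: float

    def __post_init__(self) -> None:
        if signature(self.representative) != self.signature:
            raise ValueError("representative does not match signature")


def local_score(
    data: DiscreteDataset, child: str, parents: Sequence[str]
) -> float:
    """BIC contribution of ``child`` given ``parents``.

    Maximized multinomial log-likelihood from the contingency counts minus
    ``0.5 ln(N) (r_child - 1) prod r_parent``; the convention ``0 ln 0 = 0``
    applies (empty cells contribute nothing).
    """
    parents = tuple(sorted(str(p) for p in parents))
    if child in parents:
        raise ValueError("child cannot be its own parent")
    n = data.n_rows
    if n == 0:
        raise ValueError("empty dataset")
    r_child = data.arity(child)
    child_col = data.column(child)
    q = 1
    for p in parents:
        q *= data.arity(p)
    if parents:
        pa_index = np.zeros(n, dtype=np.int64)
        for p in parents:
            pa_index = pa_index * data.arity(p) + data.column(p)
    else:
        pa_index = np.zeros(n, dtype=np.int64)
    counts = np.bincount(
        pa_index * r_child + child_col, minlength=q * r_child
    ).reshape(q, r_child)
    row_tot = counts.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        ll_terms = counts * (np.log(counts) - np.log(row_tot))
    ll = float(np.nansum(np.where(counts > 0, ll_terms, 0.0)))
    penalty = 0.5 * math.log(n) * (r_child - 1) * q
    return ll - penalty


def score_dag(data: DiscreteDataset, g: Dag) -> float:
    """Decomposable BIC of ``g``: sum of per-node local scores."""
    if set(g.nodes) != set(data.variables):
        raise ValueError("graph nodes and dataset variables differ")
    return sum(local_score(data, v, sorted(g.parents(v))) for v in g.nodes)


def _scored(data: DiscreteDataset, members) -> ScoredClass:
    rep = canonical_representative(members)
    return ScoredClass(
        signature=signature(rep), representative=rep,
        score=score_dag(data, rep),
    )


def _neighbor_classes(current_members, forward: bool):
    """Signatures reachable by one edge addition (forward) or deletion
    (backward) applied to any member DAG; returns canonical representatives.
    """
    reached: Dict[EquivClassSignature, Dag] = {}
    for g in current_members:
        if forward:
            moves = []
            for x in g.nodes:
                for y in g.nodes:
                    if x != y and not g.adjacent(x, y):
                        moves.append((x, y))
            for x, y in moves:
                try:
                    nxt = g.with_edge(x, y)
                except ValueError:  # cycle
                    continue
                sig = signature(nxt)
                if sig not in reached:
                    reached[sig] = nxt
        else:
            for x, y in g.edges:
                nxt = g.without_edge(x, y)
                sig = signature(nxt)
                if sig not in reached:
                    reached[sig] = nxt
    return reached


def _phase(data: DiscreteDataset, current: ScoredClass, forward: bool) -> ScoredClass:
    while True:
        members = class_members(current.representative)
        best = None
        for sig, some_member in _neighbor_classes(members, forward).items():
            cand = _scored(data, class_members(some_member))
            if best is None:
                best = cand
            else:
                if cand.score > best.score + IMPROVEMENT_TOL or (
                    abs(cand.score - best.score) <= IMPROVEMENT_TOL
                    and cand.representative.sorted_edges()
                    < best.representative.sorted_edges()
                ):
                    best = cand
        if best is None or best.score <= current.score + IMPROVEMENT_TOL:
            return current
        current = best


def ges_run(data: DiscreteDataset) -> ScoredClass:
    """Two-phase greedy search over equivalence classes.

    Starts at the empty graph's class; the forward phase repeatedly moves to
    the best class reachable by a single edge addition while the score
    improves, then the backward phase does the same with single deletions.
    Deterministic given the data (ties broken by lexicographically smallest
    canonical edge set).
    """
    if len(data.variables) < 2:
        raise ValueError("need at least two variables")
    if data.n_rows < 1:
        raise ValueError("empty dataset")
    empty = Dag(sorted(data.variables))
    current = _scored(data, frozenset([empty]))
    current = _phase(data, current, forward=True)
    current = _phase(data, current, forward=False)
    return current
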