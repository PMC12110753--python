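"""Transformational sequences between DAGs ordered by independence-map
inclusion.

Given DAGs ``G <= H`` (every independence of H holds in G), there is a
sequence of covered-edge reversals and edge additions carrying G to H such
that after every edit the intermediate graph is a DAG and still satisfies
``<= H``, and whose length is at most ``r + 2m`` where r counts edges of H
oppositely oriented in G and m counts edges of H absent from G in either
orientation.  This module constructs such sequences and verifies them
mechanically: the certificate replay, not the construction heuristic, is the
correctness authority.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

from .dag import Dag, covered_edges, is_independence_map

__all__ = [
    "Edit",
    "TransformCertificate",
    "NotIndependenceMapError",
    "edit_counts",
    "mc_sequence",
    "apply_edit",
    "verify_certificate",
]


class NotIndependenceMapError(ValueError):
    """Raised when the target is not an independence map of the source."""


@dataclass(frozen=True)
class Edit:
    """A single edge edit: ``reverse``/``add``/``delete`` of ``edge``."""

    kind: str
    edge: Tuple[str, str]

    def __post_init__(self) -> None:
        if self.kind not in ("reverse", "add", "delete"):
            raise ValueError(f"unknown edit kind {self.kind!r}")


@dataclass(frozen=True)
class TransformCertificate:
    """An ordered edit sequence with its claimed accounting.

    ``r``/``m`` are the opposite-orientation and missing-edge counts of the
    (source, target) pair; ``intermediate_ok`` records that every replay
    prefix was a DAG and an independence-map predecessor of the target.
    """

    edits: Tuple[Edit, ...]
    r: int
    m: int
    intermediate_ok: bool

    @property
    def length(self) -> int:
        return len(self.edits)


def edit_counts(g: Dag, h: Dag) -> Tuple[int, int]:
    """``(r, m)``: edges of ``h`` oppositely oriented in ``g``, and edges of
    ``h`` absent from ``g`` in either orientation."""
    if g.nodes != h.nodes:
        raise ValueError("node sets differ")
    r = sum(1 for x, y in h.edges if (y, x) in g.edges)
    m = sum(
        1
        for x, y in h.edges
        if (x, y) not in g.edges and (y, x) not in g.edges
    )
    return r, m


def apply_edit(g: Dag, edit: Edit) -> Dag:
    """Apply one edit, validating its applicability."""
    a, b = edit.edge
    if edit.kind == "reverse":
        return g.with_reversed_edge(a, b)
    if edit.kind == "add":
        if g.adjacent(a, b):
            raise ValueError(f"cannot add ({a!r}, {b!r}): pair already adjacent")
        return g.with_edge(a, b)
    return g.without_edge(a, b)


def _candidate_edits(current: Dag, h: Dag) -> list[Edit]:
    """Moves toward ``h``, in preference order.

    1. reverse a covered edge whose opposite orientation is in h;
    2. add a missing edge of h in h's orientation;
    3. add a missing edge of h in the reversed orientation (to be reversed
       later once it becomes covered);
    4. reverse any other covered edge (within-class rearrangement).
    Ties broken lexicographically on the edge.
    """
    cov = sorted(covered_edges(current))
    reversals = [
        Edit("reverse", (x, y)) for x, y in cov if (y, x) in h.edges
    ]
    adds_fwd = []
    adds_rev = []
    for x, y in sorted(h.edges):
        if not current.adjacent(x, y):
            adds_fwd.append(Edit("add", (x, y)))
            adds_rev.append(Edit("add", (y, x)))
    rearrange = [
        Edit("reverse", (x, y)) for x, y in cov if (y, x) not in h.edges
    ]
    return reversals + adds_fwd + adds_rev + rearrange


def _search(g: Dag, h: Dag, bound: int) -> Optional[Tuple[Edit, ...]]:
    """Depth-limited DFS over valid edits, preferring progress moves.

    A state is pruned when its admissible lower bound (one edit per opposite
    edge plus one per missing edge) exceeds the remaining budget, or when it
    was already reached at least as cheaply.
    """
    h_indep = None  # lazily bound below to avoid recompute in the closure
    from .dag import independence_statements

    h_indep = independence_statements(h)
    best_depth: dict[frozenset, int] = {}

    def rec(current: Dag, used: int, acc: list[Edit]) -> Optional[Tuple[Edit, ...]]:
        if current.edges == h.edges:
            return tuple(acc)
        r_cur, m_cur = edit_counts(current, h)
        if used + r_cur + m_cur > bound:
            return None
        key = current.edges
        prev = best_depth.get(key)
        if prev is not None and prev <= used:
            return None
        best_depth[key] = used
        for edit in _candidate_edits(current, h):
            try:
                nxt = apply_edit(current, edit)
            except ValueError:
                continue
            if not independence_statements(nxt) >= h_indep:
                continue
            acc.append(edit)
            found = rec(nxt, used + 1, acc)
            if found is not None:
                return found
            acc.pop()
        return None

    return rec(g, 0, [])


def mc_sequence(g: Dag, h: Dag) -> TransformCertificate:
    """A verified covered-reversal/addition sequence from ``g`` to ``h``.

    Requires ``g <= h`` (``h`` an independence map of ``g``).  The returned
    certificate has length at most ``r + 2m`` and passes
    :func:`verify_certificate`.
    """
    if g.nodes != h.nodes:
        raise ValueError("node sets differ")
    if not is_independence_map(g, h):
        raise NotIndependenceMapError("not an independence map: target does "
                                      "not dominate source")
    r, m = edit_counts(g, h)
    bound = r + 2 * m
    edits = _search(g, h, bound)
    if edits is None:  # theorem guarantees existence; reaching here is a bug
        raise RuntimeError("no transformation sequence found within r+2m")
    ok, reason = verify_certificate(
        g, h, TransformCertificate(edits=edits, r=r, m=m, intermediate_ok=True),
        explain=True,
    )
    if not ok:
        raise RuntimeError(f"constructed certificate failed verification: {reason}")
    return TransformCertificate(edits=edits, r=r, m=m, intermediate_ok=True)


def verify_certificate(
    g: Dag, h: Dag, cert: TransformCertificate, explain: bool = False
):
    """Replay ``cert`` and check the three transformational properties plus
    the length bound.

    Returns ``bool``, or ``(bool, reason)`` when ``explain`` is true.
    Properties checked: every reversal targets an edge covered at application
    time; after every edit the intermediate is a DAG with ``<= h``; the final
    graph equals ``h``; the length is at most ``r + 2m``.
    """

    def verdict(ok: bool, reason: str):
        return (ok, reason) if explain else ok

    r, m = edit_counts(g, h)
    if cert.length > r + 2 * m:
        return verdict(False, "length bound")
    current = g
    for edit in cert.edits:
        if edit.kind == "reverse" and edit.edge not in covered_edges(current):
            return verdict(False, "reversal not covered")
        try:
            current = apply_edit(current, edit)
        except ValueError:
            return verdict(False, "edit not applicable")
        if not is_independence_map(current, h):
            return verdict(False, "intermediate not dominated by target")
    if current.edges != h.edges:
        return verdict(False, "final graph differs from target")
    return verdict(True, "ok")
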