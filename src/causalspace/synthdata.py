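"""Synthetic data generators: conjunctive Bayesian network (CBN) tumor
genotypes and ancestral samples from discrete Bayesian networks.

Cancer genomes accumulate irreversible mutations, so the mutated-gene set of
a tumor is closed under the ancestor relation of a generating partial order:
a gene can mutate only after all of its poset predecessors have (a
noisy-AND / conjunctive model).  ``cbn_generate`` emulates the resulting
binary tumor x gene matrices.  ``bn_sample`` draws IID ancestral samples
from an arbitrary discrete network functor, the input regime in which
score-based search is consistent.  All generators take a mandatory seed and
use a single private PRNG stream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping

import numpy as np

from .dag import Dag
from .finstoch import (
    BayesNetFunctor,
    FinSpace,
    Scm,
    StochMorphism,
)
from .ges import DiscreteDataset

__all__ = [
    "CbnConfig",
    "cbn_generate",
    "bn_sample",
    "chain_functor",
    "fixtures",
    "PATHWAY_LABELS",
]

#: regulatory-pathway names used as node labels for the 12-node fixture
#: (labels only; the edge structure is synthetic)
PATHWAY_LABELS = (
    "Apoptosis",
    "DNA damage control",
    "G1/S phase transition",
    "Hedgehog signaling",
    "Homophilic cell adhesion",
    "Integrin signaling",
    "c-Jun N-terminal kinase",
    "KRAS signaling",
    "Regulation of invasion",
    "Small GTPase-dependent",
    "TGF-beta signaling",
    "Wnt/Notch signaling",
)


@dataclass(frozen=True)
class CbnConfig:
    """Configuration of a conjunctive Bayesian network generator.

    ``poset`` orders the genes; ``theta`` gives each gene's conditional
    mutation probability once all of its parents have mutated (genes absent
    from the mapping use ``default_theta``).
    """

    poset: Dag
    theta: Mapping[str, float] = field(default_factory=dict)
    n_samples: int = 5000
    seed: int = 0
    default_theta: float = 0.8

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        for gene, t in self.theta.items():
            if gene not in self.poset.nodes:
                raise ValueError(f"theta for unknown gene {gene!r}")
            if not 0.0 <= t <= 1.0:
                raise ValueError(f"theta[{gene!r}] outside [0, 1]")
        if not 0.0 <= self.default_theta <= 1.0:
            raise ValueError("default_theta outside [0, 1]")

    def theta_of(self, gene: str) -> float:
        return float(self.theta.get(gene, self.default_theta))


def cbn_generate(cfg: CbnConfig) -> DiscreteDataset:
    """Binary tumor x gene matrix from the conjunctive model.

    Per sample, genes are visited in topological order; gene i mutates with
    probability ``theta_i`` if every parent has mutated, and never otherwise.
    Every row's mutated set is therefore ancestor-closed.  Deterministic
    given the seed.
    """
    rng = np.random.default_rng(cfg.seed)
    order = cfg.poset.topological_order()
    genes = cfg.poset.nodes
    col = {g: i for i, g in enumerate(genes)}
    rows = np.zeros((cfg.n_samples, len(genes)), dtype=np.int64)
    draws = rng.random((cfg.n_samples, len(order)))
    for j, g in enumerate(order):
        parent_cols = [col[p] for p in cfg.poset.parents(g)]
        eligible = (
            rows[:, parent_cols].all(axis=1)
            if parent_cols
            else np.ones(cfg.n_samples, dtype=bool)
        )
        rows[:, col[g]] = (eligible & (draws[:, j] < cfg.theta_of(g))).astype(
            np.int64
        )
    return DiscreteDataset(genes, rows, arities=[2] * len(genes))


def bn_sample(bn: BayesNetFunctor, n: int, seed: int) -> DiscreteDataset:
    """``n`` IID ancestral samples from a network functor.

    Nodes are sampled in topological order from their CPT row given the
    already-sampled parents; the empirical joint converges to the exact
    joint of the functor.  Deterministic given the seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    nodes = bn.dag.nodes
    col = {v: i for i, v in enumerate(nodes)}
    sizes = {v: bn.spaces[v].size for v in nodes}
    rows = np.zeros((n, len(nodes)), dtype=np.int64)
    for v in bn.dag.topological_order():
        parents = sorted(bn.dag.parents(v))
        cpt = bn.cpts[v].matrix
        if parents:
            row_idx = np.zeros(n, dtype=np.int64)
            for p in parents:
                row_idx = row_idx * sizes[p] + rows[:, col[p]]
        else:
            row_idx = np.zeros(n, dtype=np.int64)
        u = rng.random(n)
        cdf = np.cumsum(cpt, axis=1)
        rows[:, col[v]] = (u[:, None] >= cdf[row_idx][:, :-1]).sum(axis=1)
    return DiscreteDataset(
        nodes, rows, arities=[sizes[v] for v in nodes]
    )


def chain_functor(
    labels=("A", "B", "C"), flip: float = 0.2, root_p1: float = 0.5
) -> BayesNetFunctor:
    """A binary Markov chain ``labels[0] -> labels[1] -> ...`` where each
    child copies its parent with probability ``1 - flip``.  The benchmark
    generator for score-consistency experiments."""
    labels = tuple(labels)
    spaces = {v: FinSpace(v, 2) for v in labels}
    edges = list(zip(labels, labels[1:]))
    dag = Dag(labels, edges)
    cpts: Dict[str, StochMorphism] = {}
    for i, v in enumerate(labels):
        if i == 0:
            cpts[v] = StochMorphism(
                (), (spaces[v],), [[1 - root_p1, root_p1]]
            )
        else:
            p = labels[i - 1]
            cpts[v] = StochMorphism(
                (spaces[p],),
                (spaces[v],),
                [[1 - flip, flip], [flip, 1 - flip]],
            )
    return BayesNetFunctor(dag=dag, spaces=spaces, cpts=cpts)


def _xor_scm() -> Scm:
    """Two-equation SCM: X := U2, Y := X xor U (all binary)."""
    b = lambda name: FinSpace(name, 2)  # noqa: E731
    spaces = {"U": b("U"), "U2": b("U2"), "X": b("X"), "Y": b("Y")}
    half = StochMorphism((), (b("U"),), [[0.5, 0.5]])
    copy_mech = StochMorphism((spaces["U2"],), (spaces["X"],),
                              [[1, 0], [0, 1]])
    xor_rows = np.zeros((4, 2))
    for x in range(2):
        for u in range(2):
            xor_rows[x * 2 + u, x ^ u] = 1.0
    xor_mech = StochMorphism((spaces["X"], spaces["U"]), (spaces["Y"],),
                             xor_rows)
    return Scm(
        spaces=spaces,
        exogenous={"U": half, "U2": StochMorphism((), (b("U2"),), [[0.5, 0.5]])},
        mechanisms={"X": (("U2",), copy_mech), "Y": (("X", "U"), xor_mech)},
    )


def _pollution_scm() -> Scm:
    """A pollution SCM skeleton: three exogenous drivers (overpopulation,
    lockdown, farming practices) feeding deterministic traffic, agriculture
    and pollution mechanisms.  Mechanisms are synthetic boolean rules."""
    def b(name):
        return FinSpace(name, 2)

    names_u = ["Overpopulation", "CovidLockdown", "FarmingPractices"]
    spaces = {n: b(n) for n in names_u}
    spaces.update({n: b(n) for n in ["Traffic", "Agriculture", "Pollution"]})

    def state(p1):
        return StochMorphism((), (FinSpace("s", 2),), [[1 - p1, p1]])

    def boolean(args, fn):
        rows = np.zeros((2 ** len(args), 2))
        for vals in np.ndindex(*(2,) * len(args)):
            idx = 0
            for v in vals:
                idx = idx * 2 + v
            rows[idx, int(fn(*vals))] = 1.0
        return StochMorphism(
            tuple(spaces[a] for a in args), (FinSpace("o", 2),), rows
        )

    mechanisms = {
        # traffic is heavy when population pressure is high and no lockdown
        "Traffic": (("Overpopulation", "CovidLockdown"),
                    boolean(("Overpopulation", "CovidLockdown"),
                            lambda o, c: o and not c)),
        # agricultural burning persists unless both lockdown and reform
        "Agriculture": (("CovidLockdown", "FarmingPractices"),
                        boolean(("CovidLockdown", "FarmingPractices"),
                                lambda c, f: f and not c)),
        "Pollution": (("Traffic", "Agriculture"),
                      boolean(("Traffic", "Agriculture"),
                              lambda t, a: t or a)),
    }
    exogenous = {
        "Overpopulation": state(0.7),
        "CovidLockdown": state(0.3),
        "FarmingPractices": state(0.5),
    }
    return Scm(spaces=spaces, exogenous=exogenous, mechanisms=mechanisms)


def fixtures() -> Dict[str, object]:
    """Named worked-example structures.

    * ``three_gene_path`` -- the KRAS -> TGFBR2 -> PPP1R3A mutation path
      whose orientations form a 3-member equivalence class plus a collider;
    * ``pathway_dag`` -- a 12-node DAG labeled by regulatory pathways
      (synthetic edge structure);
    * ``pollution_scm`` / ``xor_scm`` -- deterministic-mechanism SCMs.
    """
    three = Dag(
        ["KRAS", "TGFBR2", "PPP1R3A"],
        [("KRAS", "TGFBR2"), ("TGFBR2", "PPP1R3A")],
    )
    # synthetic pathway ordering: signaling cascades feed damage response,
    # adhesion/invasion modules downstream
    p = PATHWAY_LABELS
    pathway_edges = [
        (p[7], p[2]),   # KRAS signaling -> G1/S phase transition
        (p[7], p[10]),  # KRAS signaling -> TGF-beta signaling
        (p[10], p[0]),  # TGF-beta -> apoptosis
        (p[2], p[1]),   # G1/S -> DNA damage control
        (p[3], p[11]),  # Hedgehog -> Wnt/Notch
        (p[11], p[2]),  # Wnt/Notch -> G1/S
        (p[4], p[8]),   # adhesion -> invasion
        (p[5], p[8]),   # integrin -> invasion
        (p[9], p[5]),   # small GTPase -> integrin
        (p[6], p[0]),   # JNK -> apoptosis
        (p[1], p[0]),   # DNA damage control -> apoptosis
    ]
    pathway = Dag(p, pathway_edges)
    return {
        "three_gene_path": three,
        "pathway_dag": pathway,
        "pollution_scm": _pollution_scm(),
        "xor_scm": _xor_scm(),
    }
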