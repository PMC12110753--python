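# causalspace

Tools for working with **Markov equivalence classes of causal DAGs**: the
combinatorics of covered-edge reversals, score-based search over classes,
the string-diagram (FinStoch) semantics of Bayesian networks and structural
causal models, and the class space's homotopy-flavoured invariants (nerves,
path components, group completion).

It is written for researchers in network inference and systems biology who
study *what is identifiable from observational data*: two DAGs that share a
skeleton and v-structures encode exactly the same conditional
independences, so discovery algorithms can only ever pin down the class,
and the interesting structure lives in how classes are connected and
counted.  The running biological example is the partial ordering of gene
mutations in cancer (e.g. the KRAS → TGFBR2 → PPP1R3A path), where
irreversible mutations make conjunctive (noisy-AND) models natural.

## What is inside

| module | contents |
| --- | --- |
| `causalspace.dag` | `Dag`, covered edges (`Pa(Y) = Pa(X) ∪ {X}`), skeleton/v-structure signatures, d-separation (moralized ancestral graph), independence maps `G ≤ H` |
| `causalspace.transform` | sequences of covered-edge reversals and additions carrying `G` to `H` with at most `r + 2m` edits, plus a mechanical certificate verifier |
| `causalspace.class_space` | exhaustive DAG enumeration (≤ 5 nodes), class partitioning, the covered-reversal graph and its path components |
| `causalspace.ges` | decomposable BIC `S(G,D) = Σ_i [ll(X_i∣Pa_i) − ½ ln N · (r_i−1)·Π_j r_j]` and two-phase greedy equivalence search |
| `causalspace.finstoch` | row-stochastic morphisms, copy/delete/swap comonoid generators and their laws, Bayesian-network functors, joint/marginals, semantics-preserving covered-edge reversal (Bayes' rule), naturality checks, SCMs with `do` and potential outcomes |
| `causalspace.nerve` | finite categories, truncated nerves with face/degeneracy operators, π₀, categories of elements, invariant-based comparison of classifying spaces |
| `causalspace.ktheory` | free class monoids and Grothendieck group completion (pair quotient + invariant factors) |
| `causalspace.synthdata` | conjunctive Bayesian network genotype generator, ancestral sampling, worked fixtures |
| `causalspace.io` / `causalspace.cli` | TSV/CSV/JSON formats and the `causalspace` umbrella command |

## Worked example

```python
from causalspace import (Dag, class_members, covered_edges, mc_sequence,
                         partition_by_equivalence, enumerate_dags)

chain = Dag(["KRAS", "TGFBR2", "PPP1R3A"],
            [("KRAS", "TGFBR2"), ("TGFBR2", "PPP1R3A")])
print(sorted(covered_edges(chain)))
# [('KRAS', 'TGFBR2')]

print(len(class_members(chain)))
# 3        <- the three orientations of the path without a collider

part = partition_by_equivalence(enumerate_dags("ABC"))
print(part.universe_size, len(part.classes))
# 25 11    <- 25 labeled DAGs on three nodes fall into 11 classes

full = Dag("ABC", [("A", "B"), ("B", "C"), ("A", "C")])
cert = mc_sequence(Dag("ABC", [("A", "B"), ("B", "C")]), full)
print([(e.kind, e.edge) for e in cert.edits], cert.length, cert.r, cert.m)
# [('add', ('A', 'C'))] 1 0 1
```

The first two numbers say that the only reversible (covered) edge of the
mutation chain is the root edge, and that exactly three orientations of the
path are observationally indistinguishable — the collider `KRAS → TGFBR2 ←
PPP1R3A` forms its own class.  The last line exhibits the transformation
sequence from the chain to its supergraph: one edge addition, within the
`r + 2m = 2` budget, with every intermediate step independently verified.

On the semantic side, reversing a covered edge of a concrete network
preserves its joint distribution:

```python
from causalspace import (BayesNetFunctor, FinSpace, StochMorphism, joint,
                         reverse_covered_edge)
A, B = FinSpace("A", 2), FinSpace("B", 2)
bn = BayesNetFunctor(
    dag=Dag("AB", [("A", "B")]), spaces={"A": A, "B": B},
    cpts={"A": StochMorphism((), (A,), [[0.7, 0.3]]),
          "B": StochMorphism((A,), (B,), [[0.8, 0.2], [0.1, 0.9]])})
print(joint(bn).matrix[0])
# [0.56 0.14 0.03 0.27]
print(joint(reverse_covered_edge(bn, ("A", "B"))).matrix[0])
# [0.56 0.14 0.03 0.27]
```

The command line mirrors the library, e.g.:

```
causalspace enumerate-classes --n 3 --out classes.json
causalspace transform --from chain.tsv --to full.tsv --out cert.json
causalspace ges --data data.csv --out result.json
causalspace check-laws --size 4
```

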