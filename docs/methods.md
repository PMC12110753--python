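# Methods

## The objects

A causal DAG `G = (V, E)` represents the family of distributions that
factorize as `p(v) = Π_i p(v_i | pa_i)`.  Its testable content is the set of
conditional independences implied by d-separation, which we compute by
reachability over the moralized ancestral subgraph: restrict to ancestors of
`{x, y} ∪ z`, connect co-parents, forget orientation, delete `z`, and test
connectivity.  This formulation is deterministic, needs no path
enumeration, and is cross-checked in the test suite against networkx's
independent d-separation routine on every 3-node DAG and a slice of the
4-node ones.

Two DAGs are **Markov equivalent** iff they share a skeleton and
v-structures; the pair `(skeleton, v-structures)` is the canonical class
key (`EquivClassSignature`).  An edge `X → Y` is **covered** when
`Pa(Y) = Pa(X) ∪ {X}`; covered-edge reversal is exactly the move that stays
inside a class, and the class is the closure of any member under such
reversals.  `H` is an **independence map** of `G` (written `G ≤ H`) when
every independence of `H` holds in `G`; we check this over singleton pairs
and all conditioning subsets, which suffices because d-separation satisfies
the graphoid composition/decomposition properties — the exhaustive
≤ 4-node cross-check (mutual domination ⇔ equivalence) is part of the
acceptance suite.

## Transformation sequences

For `G ≤ H`, a sequence of covered-edge reversals and edge additions
carries `G` to `H` with every intermediate graph a DAG still dominated by
`H`, using at most `r + 2m` edits (`r` = edges of `H` oppositely oriented
in `G`, `m` = edges of `H` absent from `G`).  The constructor is a
preference-ordered depth-limited search: reverse a covered edge whose
opposite orientation is in `H`; else add a missing `H`-edge in `H`'s
orientation; else add it reversed (to be reversed again once covered); else
rearrange within the class.  States are pruned by the admissible lower
bound `used + r_cur + m_cur > r + 2m` and a best-depth table.  Correctness
does **not** rest on the search heuristic: every produced sequence is
replayed by `verify_certificate`, which independently checks coveredness at
application time, the DAG property and domination after every prefix, final
equality, and the length bound.  The suite runs this exhaustively over all
41,501 ordered 4-node pairs with `G ≤ H` and additionally brackets the
3-node lengths between a BFS shortest-sequence oracle and `r + 2m`.

## Class space and enumeration

Labeled DAGs are enumerated by assigning each unordered node pair one of
three states (absent / forward / backward) and filtering cyclic
orientations; the cap is five nodes (29,281 DAGs), the range where
exhaustive verification stays in seconds.  Counts are validated against the
alternating labeled-DAG recurrence
`a(n) = Σ_k (−1)^(k+1) C(n,k) 2^(k(n−k)) a(n−k)` rather than asserted.
The covered-reversal graph has the member DAGs as vertices and one edge per
single covered reversal; its path components (union-find) coincide
class-for-class with the signature partition — the combinatorial form of
the statement that the reversal groupoid's π₀ enumerates equivalence
classes.  The class representative is the member with lexicographically
smallest edge list.

## Scoring and search

The BIC local score of node `X` with parents `P` on `N` rows is the
maximized multinomial log-likelihood of the `(P, X)` contingency table
minus `½ ln N · (arity(X) − 1) · Π_{p∈P} arity(p)`, with `0·ln 0 = 0`.  It
is decomposable and score-equivalent across a class (verified exhaustively
to 1e-9 on three nodes), so the search scores one canonical representative
per class.  Greedy equivalence search starts at the empty class, moves in a
forward phase to the best class reachable by adding one edge to any class
member, then in a backward phase with single deletions, stopping when no
move gains more than 1e-9 in log units; ties break on the
lexicographically smallest representative.  Neighbor generation through
explicit class members (covered-reversal closure) replaces CPDAG operator
machinery; it is exact and entirely adequate at the node counts this
package targets.  The consistency benchmark uses a three-variable binary
chain with flip probability 0.2 and a fair root — an interior, clearly
identifiable regime — at 20,000 samples: over 20 replicates the generating
class must be the strict score argmax among all 11 classes in ≥ 95% and the
search must return it in ≥ 18.

## String-diagram semantics

FinStoch is modeled concretely: a morphism is a row-stochastic matrix with
recorded domain/codomain factor spaces, composition is the matrix product
in diagram order, and the monoidal product is the Kronecker product
(mixed-radix outcome order, last factor fastest — `np.kron`'s convention).
With rows as inputs, naturality of delete (`f ; del = del`) is literally
row-stochasticity, which is the type invariant.  Each space carries copy
(the diagonal), delete (all-ones column), and swap; the law checker
verifies coassociativity, both counits, cocommutativity, compatibility of
copy with the tensor (`(copy ⊗ copy) ; (1 ⊗ swap ⊗ 1)` against the product
space's copy), and delete-naturality on seeded random morphisms, reporting
per-law maximal deviations (observed at machine epsilon, far below the
1e-9 working tolerance).  A morphism is deterministic iff it commutes with
copy; this is the uniform-copying criterion and holds exactly for 0/1
matrices.

A Bayesian network on `G` is stored as one CPT per node (domain = tensor of
the parents' spaces in sorted label order), the concrete form of a functor
from `G`'s syntactic category into FinStoch.  The joint is the product of
CPT entries over outcome tuples; marginals compose the joint with
identities and deletes.  Reversing a covered edge `X → Y` re-factors the
local family by Bayes' rule over the common parents; a zero-mass parent
configuration leaves the new conditional row undefined and is filled with
the uniform distribution, which provably leaves the joint unchanged.  The
acceptance suite replays every within-class transformation certificate
through this semantic reversal and requires the joint to be preserved to
1e-9 at every intermediate step.  Pointwise naturality between two network
functors is checked square-by-square (`F(f) ; α_cod = α_dom ; G(f)`); the
full end-calculus description of the natural-transformation set is out of
scope.

Structural causal models are the Cartesian fragment: exogenous variables
carry state distributions, endogenous variables carry deterministic (0/1)
mechanisms with an explicit argument order, and the induced dependency
graph must be acyclic.  Evaluation solves the equations in topological
order; `do(X = x)` replaces mechanisms by constants (exogenous variables
are non-manipulable and refused); the potential outcome `Y_x(u)` is the
submodel's solution projected to `Y`.

## Nerve, π₀, and invariants

A finite category is stored explicitly (objects, morphisms, identities,
composition table).  Strict categories validate identity laws,
associativity, and totality of composition on non-identity composable
pairs; a 1-truncated *graph presentation* (identities plus generator
arrows, no composites) is also supported for structures consumed only
through π₀ and the 1-skeleton — notably the covered-reversal graph — and
its nerve is deliberately refused above dimension 1.  The nerve's
n-simplices are composable chains of n morphisms; `d_0`/`d_n` drop an end,
inner faces compose adjacent arrows, degeneracies insert identities, and a
simplex is degenerate iff it contains an identity.  Truncation defaults to
k = 3 with a 10⁵ chain cap.  `compare_invariants` computes π₀ count,
component-size multiset, and per-dimension nondegenerate simplex counts; a
difference certifies that the classifying spaces are not isomorphic, while
equality is reported only as "indistinguishable at level k" — deciding
isomorphism is out of scope.  Reference points used as oracles: the nerve
of the poset `[m]` has `C(m+1, n+1)` nondegenerate n-simplices, and |π₀|
equals the 1-skeleton's component count.

## Class monoid and group completion

With disjoint union of variable sets as the tensor (the concrete choice
for combining models), the Markov classes generate a free commutative
monoid with the empty model as unit.  Its Grothendieck group completion is
free abelian of the same rank — the degree-zero K-group of the class
space, recomputed for three and four nodes (ranks 11 and 185).  For finite
commutative monoids the completion is computed literally from the pair
construction, `(a, b) ~ (c, d)` iff `a + d + e = c + b + e` for some `e`,
and the resulting group table is reduced to invariant factors by structure-
theorem peeling (a maximal-order element generates a cyclic direct summand;
recurse on the quotient).  The universal property is tested exhaustively
against all homomorphisms into small cyclic groups, and the classical
collapses (absorbing/idempotent elements map to the identity) are asserted
on constructed families.  Only the π₀-level completion is built; the full
pair-category with its morphism classes is not materialized.

## Synthetic data

`cbn_generate` emulates binary tumor × gene matrices from a conjunctive
(noisy-AND) model: traversing the gene poset in topological order, a gene
mutates with probability θ once all its parents have, and never before, so
every genotype is ancestor-closed — the structural signature of
irreversible mutation accumulation.  θ defaults to 0.8 per gene (an
interior value giving clearly skewed but non-degenerate frequencies); the
per-gene conditional-probability form is the standard conjunctive
parameterization.  The generator reproduces the *structure* of such data
(binary matrix, ancestor-closure, skewed frequencies), not any published
cohort's values, and CBN distributions contain context-specific
determinism, so tests assert skeleton containment rather than exact class
recovery on CBN data.  `bn_sample` draws IID ancestral samples from an
arbitrary functor and is validated against the exact joint at 3σ
multinomial bounds.  Every generator takes a mandatory seed and uses a
single private PRNG stream; no global random state is touched.

## Numerical conventions and problem sizes

All law and equality checks use absolute tolerance 1e-9 (deviations are
reported and in practice sit at ~1e-16); the GES improvement threshold is
1e-9 in log units; enumeration is capped at five nodes and the nerve at
10⁵ chains per level (both configurable).  The default test suite and the
acceptance script run the exhaustive 4-node transformation check (41,501
pairs), 20 × 20,000-sample scoring replicates, and 5,000-sample generator
checks; these sizes were chosen as the smallest at which the exhaustive
statements are non-trivial and the stochastic ones stable.

## Known limitations

- No CPDAG/essential-graph machinery, no Meek orientation rules, no
  constraint-based discovery, and no latent-confounder models (MAGs/PAGs).
- Exhaustive guarantees are desk-scale by design (≤ 5 nodes); nothing here
  addresses the scalability of discovery on thousands of variables.
- The synthetic generators do not model measurement noise, missing data,
  back-mutation, or inter-tumor heterogeneity; passing tests certify the
  combinatorial and semantic machinery, not fidelity to any real cohort.
- Geometric realizations are represented only through combinatorial
  invariants; no topological spaces, higher homotopy groups, or simplicial
  homotopies between maps are constructed.
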