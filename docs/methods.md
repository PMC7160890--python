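# Methods

## Model and objective

Input: k unrooted gene trees on subsets of a leaf set L of size n, each
possibly multifurcating, plus an optional unrooted constraint tree T̄ on a
subset of L, also possibly multifurcating.  Output: an unrooted tree on L
maximizing the quartet score, the summed count of induced four-leaf
topologies shared with the gene trees, restricted (when T̄ is given) to
trees *compatible* with T̄ — trees whose restriction to T̄'s leaves
resolves T̄.  Maximizing shared quartets is the standard summary-method
criterion that is statistically consistent under the multi-species
coalescent when gene-tree discordance is caused by incomplete lineage
sorting.

A quartet a gene tree leaves unresolved (spanning a polytomy), or whose
leaves a gene tree lacks, contributes nothing; this is the usual
shared-quartet semantics for incomplete, partially resolved inputs.

## Dynamic program

Fix an arbitrary leaf o (the lexicographically smallest label shared by all
inputs, else the smallest label).  A *cluster* is a subset A ⊂ L′ = L∖{o};
rooting any candidate tree at o identifies its internal nodes with clusters.
The recursion

    S(A) = max over (A′, A∖A′), both in X, of S(A′) + S(A∖A′) + w(A′|A∖A′|L∖A)

with S({x}) = 0 finds the best tree assembled from the cluster set X.  The
tripartition weight w counts, over gene trees, resolved quartets with two
leaves paired inside one part and one leaf in each of the other two parts.
Summed over the internal nodes of any binary tree rooted at o these weights
equal exactly **twice** the quartet score (each displayed quartet is counted
at the two nodes flanking its internal edge), so the DP carries integer
doubled values and halves them only when reporting.  The implementation:

* quartet topologies are read from six leaf-pair LCA depths per quartet
  (constant-time LCA after an Euler-tour/sparse-table preprocessing); the
  unique maximal pairing-depth sum identifies the topology, a tie means
  unresolved.  Aggregated topology counts back both weights and scores;
  weight evaluation is brute-force over part combinations, which is adequate
  at the package's desk scale (n ≲ 25) and is deliberately simple rather
  than the optimized production weight calculation of large-scale tools.
* clusters are bit masks; the split enumeration is canonical (A′ contains
  A's lowest bit) to halve work; memoization is bottom-up in cluster size,
  so recursion depth is never an issue.
* ties in the max are broken toward the split whose smaller side is
  lexicographically least, making runs deterministic.
* with X = 2^L′ (`exact_solve`, capped at 10 taxa by default) the DP is
  provably optimal; the test suite checks it against exhaustive topology
  enumeration.
* a reachable cluster with no decomposition inside X raises an error naming
  the cluster — by construction (P1, below) this cannot happen for built
  search spaces.

## RF-minimizing completion with multifurcations

`comp(T_b, T_r)` adds to a backbone T_b the leaves present only in a
reference T_r, may resolve backbone polytomies with reference bipartitions,
and never disturbs the backbone otherwise: the output restricted to the
backbone's leaves is a resolution of T_b.  Both trees are rooted at a shared
leaf (the smallest, for determinism).  Stages:

1. **Backbone expansion.**  In a post-order pass over the reference, every
   reference bipartition compatible with the backbone is added by grouping
   the children of the corresponding backbone polytomy; incompatible
   resolutions are skipped.  A binary backbone passes through unchanged.
2. **Grafting.**  In a pre-order pass over the reference, each *fully
   missing* subtree (no leaves in the current backbone) is inserted when its
   parent is visited, at the anchor s_b = LCA in the backbone of its sister
   nodes' present leaves.  Two cases decide the local shape: if the sister
   leaves equal the anchor's clade exactly, a new node above the anchor
   reproduces the reference branch (Case 1); otherwise any new node would
   create a branch foreign to the reference, so the subtree becomes an extra
   child of the anchor — a polytomy (Case 2).  Multiple fully-missing
   children of one reference polytomy are inserted as a single group at the
   same position.  With fewer than two shared leaves on a side the insertion
   degenerates to grafting at the root edge, preserving the reference's own
   splits.

`brf_plus` is the binary-output baseline (always Case 1's shape);
`brf_star` is the polytomy-aware variant.  The star output is a contraction
of the plus output; it preserves the plus output's false-negative count and
adds no false positives beyond the backbone's own disagreement with the
restricted reference — hence it attains the minimum RF distance to the
reference among all trees compatible with the backbone.  The test suite
verifies this equivalence exhaustively at 5–6 leaves against an oracle that
enumerates *every* tree (any resolution) on the union leaf set, and on
seeded samples at 7 leaves; at 10 leaves, where enumeration is infeasible,
the structural sub-properties (contraction, FN preservation, FP invariance,
backbone preservation) are audited instead.

## Building the search space

With a constraint T̄, X must satisfy **P1** (every cluster lies in a
complete binary tree within X — otherwise the DP may dead-end) and **P2**
(every cluster compatible with T̄ — then any DP output is compatible with
T̄).  Filtering a conventional X by P2 can break P1, so X is instead built
from trees that are constraint-compatible *by construction*:

1. replace each gene tree t by comp(T̄, t) — the constraint completed and
   resolved by the gene tree (gene trees sharing no leaf with T̄ are used
   as-is, with a log warning);
2. complete the results onto L reference-free: the guide is the greedy
   consensus of the already-complete trees resolved with the quartet
   similarity matrix, or an average-linkage tree built from the matrix if no
   complete tree exists;
3. build greedy consensus trees of the completed trees at thresholds
   {0.0, 0.2, 0.5} (configurable; a plain greedy, a light-majority and a
   majority consensus — the thresholds are not critical, they diversify the
   pool);
4. replace each consensus c by comp(T̄, c), again backbone-first;
5. resolve every remaining polytomy agglomeratively with the similarity
   matrix — one deterministic resolution plus seeded noise-perturbed
   variants (`rounds`, default 2) — and pool all clusters of these complete
   binary *witness* trees, plus all singletons and L′.

Because X is exactly a union of witness-tree cluster sets, P1 holds with the
witnesses as certificates, and every witness descends from a
constraint-compatible tree by leaf addition and refinement only, so P2 holds
too.  `verify_p1`/`verify_p2` re-check both properties independently after
every build; the suite runs them on 200 random instances.  Increasing
`rounds` with a fixed seed only appends witnesses, so X grows monotonically.

The **quartet similarity matrix** entry (i, j) is the fraction of resolved
gene-tree quartets containing both taxa in which they are paired together;
pairs never co-occurring in a resolved quartet are imputed with row means
and logged; the diagonal is set maximal.  When a gene tree's quartet count
exceeds a budget (default 10⁵) a seeded random sample of 4-subsets is
scored instead — at the package's scales the full enumeration is always
used.  The polytomy-resolution step replaces the sampling heuristics of
large-scale implementations with this deterministic-plus-jitter
agglomeration; it is a documented simplification, adequate because only the
*role* of the step (supplying P1-safe resolutions) matters here.  No hard
cap is placed on |X|; a soft warning is logged above a configurable budget.

## Synthetic data

`simulate(SimulationConfig)` emulates a coalescent study without external
simulators.  A species tree on n taxa is drawn by sequential random edge
attachment.  Each gene tree applies Poisson(λ) random NNI moves to the
species tree, where λ is calibrated by bisection (30 pilot trees per probe,
seeded) so the mean normalized RF between species and gene trees matches the
requested `discordance`; a second Poisson pass of `error` expected NNI moves
emulates gene-tree estimation error.  Defaults (n=20, k=50) mirror a
published factorial design at one-tenth scale; the directional experiments
use discordance 0.69 — the analogue of the hardest published ILS level —
and error 8, giving gene trees roughly 75–80% RF from the species tree.

What the generator does *not* reproduce: coalescent branch lengths, locus
length/rate variation, clade-correlated missingness (a simple random-clade
pruning mode is provided instead), and the long-tailed error structure of
real gene-tree estimation.  Passing tests therefore demonstrate the
*algorithms'* contracts and the direction of constraint effects, not
field-realistic error magnitudes.  NNI-perturbation discordance is also
"averageable": with 50 genes the unconstrained search is already near
perfect at n=20, so constraint-induced accuracy gains mostly appear as ties
rather than strict improvements; the harness tests the direction (never
worse) accordingly.  A proper coalescent generator (e.g. msprime) can be
plugged in behind the same (species tree, gene trees) contract.

`derive_constraint` prunes `count` random leaves, collapses `count` random
internal branches, or prunes random clades (sizes capped by the remaining
quota, single leaves as fallback — our reading of clade-structured leaf
removal, which the source designs leave unparameterized).

## Numerical and design choices

* Newick I/O: parsing via dendropy; numeric internal-node labels are read as
  branch supports in [0, 1]; branch lengths are ignored (the package is
  topological).  Writing emits supports as internal labels.
* All comparisons of unrooted trees are split-set based; restriction
  suppresses degree-2 nodes; trees with fewer than 4 shared leaves cannot be
  RF-compared (error).
* Normalized RF divides by the total number of *internal* branches in the
  two (restricted) trees — consistent with a denominator of 396 for a pair
  of binary 201-taxon trees.
* Compatibility of one split with a tree is tested pairwise against the
  tree's splits after restriction; this is exact because one extra split
  that is pairwise compatible with a pairwise-compatible split system embeds
  jointly.
* The LCA index is an Euler tour with a sparse table — any structure with
  constant-time queries after near-linear preprocessing satisfies the
  contract; completion internals use simple parent-walk LCAs, since
  correctness, not asymptotics, is the goal at desk scale.
* Child order is canonicalized (smallest descendant label first) wherever
  determinism matters; all randomness flows from explicit integer seeds
  through numpy Generators, and child seeds are derived arithmetically so
  components are independently reproducible.

## Limitations

* Weight computation and quartet enumeration are O(n⁴)-ish per tree; the
  package targets tens of taxa, not thousands.  The optimized weight
  calculation, |X| size caps, multi-individual mapping, branch-length and
  branch-support estimation of production tools are all out of scope.
* `brf_plus`/`brf_star` require a binary reference; `comp` handles the
  general case.  Optimality of the completed tree's RF is proven (and
  tested) for binary backbones; with multifurcating backbones the expansion
  step makes the completion exact in all sampled instances, but no formal
  guarantee is claimed.
* The restricted search space is heuristic: the DP optimum over X can fall
  below the true constrained optimum (and conversely a constrained X can
  occasionally contain a better tree than an unconstrained heuristic X).
  The suite measures exactness only where the powerset is feasible.
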