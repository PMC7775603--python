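# Methods

This note documents the models, conventions and numerical choices behind
`pcmphylo`, in the order data flows through the package.

## The character model

A language is a string over {`+`, `-`, `0`, `?`} of fixed length P.  The
model treats `-` as a default (the state assumed absent positive evidence)
and `+` as a marked value acquired from evidence; `0` marks a parameter made
irrelevant or predictable by the values of other parameters, and `?` marks a
parameter that was simply not observed.  `0` and `?` behave identically in
every comparison (both are excluded) but are counted separately in
summaries, because they arise for different reasons: `0` is *deducible*
information while `?` is *missing* information.  The NEXUS export cannot
preserve this distinction (both become the missing symbol `?`); the CSV
round-trip can.

Dependency validation is optional by design: when no parameter definitions
are supplied, the matrix's null pattern is taken as authoritative.  When
definitions with conditions are supplied, a cell is flagged if it is null
while its condition holds, or informative while the condition fails;
`?` cells assert nothing.  Conditions are conjunctions or disjunctions of
(parameter, required value) terms over an acyclic reference graph; a term
whose referenced parameter is itself null or unknown counts as unmet.

## Distances

For a pair of languages, only positions informative in both enter the
comparison (`overlap`).  Normalized Hamming divides the differences by the
full overlap; Jaccard removes the `-/-` matches from the denominator
(`jaccard_support`).  The Jaccard denominator can be empty even when the
overlap is not — two languages agreeing only on defaults — in which case the
distance is *undefined*.  The default policy is to abort naming the pair
(such pairs do not occur in well-sampled real data, where even the weakest
pair retains double-digit support, but sparse synthetic matrices can produce
them); a `flag` policy records NaN for tools that tolerate missing
distances.  Bootstrap replicates with undefined pairs are discarded and
counted rather than propagated.

Distances are kept at full float precision internally; file outputs round to
3 decimal places, percentages to the nearest integer, matching how such
results are conventionally reported.

The helper `cross_family_mean` averages over the cross pairs of two taxon
groups.  When a "between-family distance" is quoted for pooled sets, an
alternative reading averages *all* pairs in the pooled set including
within-family ones; the package computes cross pairs only, which is the
reading consistent with quantifying between-group divergence.

## UPGMA

Average-linkage agglomeration: at each step merge the two clusters at
minimal distance d, placing the new node at height d/2; the distance from
the merged cluster to any other is the size-weighted mean of the member
distances, equivalent to the plain mean over all member pairs.  Output trees
are therefore exactly ultrametric (tip depths equal to machine precision),
encoding the clock assumption.  Tie-breaking is deterministic: among
equally close pairs, merge the pair whose sorted pair of cluster
representatives (each cluster represented by its lexicographically smallest
leaf label) is smallest.  This makes results reproducible across platforms
and taxon input orders; any other fixed rule would serve equally.

On an exactly ultrametric input matrix UPGMA provably reconstructs the
generating tree and its heights; the test suite asserts this against
randomly generated ultrametric metrics, and asserts agreement with both a
brute-force re-implementation and scipy's average-linkage on general random
matrices.

## Bootstrap supports

The character bootstrap resamples all P parameter columns with replacement,
recomputes the distance matrix and UPGMA tree, and scores each clade of the
reference (full-data) tree by the percentage of retained replicates
containing it.  Supports are reported on the reference topology by default;
a majority-rule consensus builder is available separately (clades above 50%
frequency are mutually compatible, hence assemble uniquely).  Replicates
discarded for undefined distances are logged and excluded from the
denominator.  The replicate count and the variant of the procedure are the
standard ones; supports are descriptive and are not compared against any
published values, whose exact bootstrap settings are not reproducible.

## PCoA

Classical metric scaling: square the distances, double-center with the
projector J = I − 11ᵀ/n, eigendecompose the symmetric form, and scale
eigenvectors by the square roots of their eigenvalues.  Axes are ordered by
descending eigenvalue; variance fractions are computed over the positive
eigenvalues only, with negative eigenvalues (non-Euclidean input — common
for Jaccard matrices) reported but excluded.  The positivity threshold is
relative (1e-10 of the leading eigenvalue) so that numerically zero
eigenvalues of degenerate configurations are not retained.  For genuinely
Euclidean inputs the embedding reproduces the distances to < 1e-6 and all
eigenvalues are ≥ −1e-9; both are asserted in tests, along with agreement
with scikit-bio's independent implementation.

## Heatmap tables

The leaf ordering is induced by the UPGMA merge tree, rotated so the
subtree containing the lexicographically smallest label comes first at every
node — deterministic and permutation-invariant.  Off-diagonal values are
split at their median into a cool half (≤ median) and a warm half
(> median); ties at the median are assigned cool, making the cool interval
closed above.  Each half is cut into equal-width shade bins (5 per half by
default).  The package emits the reordered matrix and the bin-label table as
CSV; rendering is left to the user's plotting tool of choice.

## Quartet tree-likeness

For each 4-subset the three pairing sums m₁ ≥ m₂ ≥ m₃ of its six distances
are formed.  The Δ-score is (m₁−m₂)/(m₁−m₃), zero exactly when the
four-point condition holds, one at maximal conflict; the fully degenerate
case m₁ = m₃ is scored 0 (it carries no conflicting signal).  The Q-residual
is (m₁−m₂)² computed after rescaling the matrix to mean off-diagonal
distance 1, which makes it invariant to global rescaling.  Per-taxon scores
are arithmetic means over the C(n−1, 3) quartets containing the taxon;
matrix-level summaries (median, mean, SD) are taken across taxa.  Quartets
are enumerated in fixed-size chunks with vectorized arithmetic and
accumulated in streaming fashion — all C(69, 4) ≈ 8.6×10⁵ quartets take
well under a second — with no quartet list held in memory.

Caveat: Q-residuals are elsewhere often computed from a NeighborNet split
network rather than directly from distances; the distance-quartet form used
here is self-consistent (zero on additive metrics, scale-invariant) but not
numerically interchangeable with network-derived values, so Q-residuals
should be compared only within analyses run by this package.

## Clade scoring

A ground-truth group is recovered iff some node's leaf set equals the group
exactly — no partial credit, by design, since graded clade similarity would
blur the question being asked (is this established group a clade here?).
The packaged table contains the 24 established Eurasian groups used as
ground truth for the original 69-language sample; "Altaic" is contested and
excluded by default (leaving 23).  Robinson–Foulds distances are symmetric
differences of non-trivial unrooted bipartitions, normalized by the total
bipartition count of the two trees.

## The simulator

The generator emulates the assumed structure of real parameter data, not any
particular dataset:

- **Tree**: pure-birth (Yule) process run until the target tip count, all
  tips contemporaneous, rescaled by default to unit root-to-tip height so
  that substitution rates read as expected events per total depth.
- **Characters**: independent two-state CTMCs along branches, gains
  (`-`→`+`) at rate λ₊ and losses at rate λ₋, simulated by exponential
  waiting times (exact event-level simulation), which yields a complete
  event log with branch and time stamps.
- **Implications**: a configurable fraction of parameters receives a
  single-controller condition "parameter j requires an earlier parameter to
  be `+`"; conditions reference only earlier indices, so the graph is acyclic
  by construction and controller trajectories are fully known when their
  dependents are simulated.  Where the condition fails the state is null;
  a parameter re-entering definedness restarts at the default `-`.  Chains
  of implications arise naturally because a controller may itself be
  dependent.
- **Borrowing**: applied at the leaves after vertical evolution — a sampled
  subset of the donor's informative parameters is copied to the recipient
  and the recipient's implicational layer is re-evaluated in topological
  order.  A branch-time borrowing variant is deliberately out of scope.

Defaults (69 taxa, 94 parameters, λ₊ = 0.6, λ₋ = 0.3, root `+` probability
0.15, dependency fraction 0.65) were fixed once so that the generated
matrices reproduce the gross statistics reported for the real 69×94 study
matrix — roughly 45% null cells, one fifth of cells `+`, and a mean
informative overlap near 40 characters per pair — with a gain-biased rate
asymmetry (stationary `+` share 2/3) reflecting that marked values such as
grammaticalized definiteness are observed to be acquired far more often than
dropped.  The simulator makes no attempt to reproduce finer structure of
real data: no rate variation across parameters or branches, no areal
geometry behind borrowing, no correlated gains, no observation error
(`?` cells).  Passing recovery tests therefore show that the pipeline is
correct and consistent under its own assumptions, not that real syntactic
data satisfy them.

Determinism: one generator seeded from `SimulationConfig.seed` drives the
whole run in fixed order; identical configs give byte-identical matrices,
trees and event logs.  In replicated experiments each replicate's seed is
derived from (base seed, replicate index).

### Recovery calibration

A pilot of the recovery experiment (20 taxa, unit-height trees, λ₊ = 0.6,
λ₋ = 0.3, no dependencies, no borrowing, 50 replicates) gives mean
normalized RF ≈ 0.45 at 25 characters, ≈ 0.23 at 100, ≈ 0.16 at 200 and
≈ 0.12 at 400 — the expected monotone improvement as characters accumulate,
asserted (as a trend, not as exact values) in the acceptance suite.  The
trend configuration disables the implicational layer so that small character
counts cannot produce pairs with empty Jaccard support, which would
otherwise drop replicates unevenly across the compared settings.

## Problem sizes in the test suite

The suite favours exhaustive verification at small n: brute-force
average-linkage and per-quartet loops up to 7–9 taxa, exact enumeration of
all 27 column resamples for a 3-character bootstrap, binomial-CI checks of
the CTMC stationary distribution at 3000 characters on a deep two-taxon
tree, and 50-replicate recovery runs at 20 taxa.  These sizes give tight
oracles while keeping the default `pytest` run in the tens of seconds.
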