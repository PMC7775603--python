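# pcmphylo

Distance-based phylogenetics for binary syntactic-parameter matrices — an
implementation of the analysis chain behind the Parametric Comparison Method
(PCM), in which languages are compared not by word etymologies but by strings
of formal syntactic parameter values.

## The problem

Each language is described by a vector of binary syntactic parameters.  A
cell takes one of four states:

| state | meaning |
|-------|---------|
| `+`   | the marked value, set from positive evidence |
| `-`   | the default value |
| `0`   | *null*: the parameter is irrelevant/predictable given other parameters (implicational structure) |
| `?`   | not observed |

Null cells carry no independent information, so every pairwise comparison is
restricted to the positions where *both* languages are informative.  Writing
N<sub>XY</sub> for the number of positions where language A has value X and
language B has value Y, the two distances supported are

- normalized Hamming:  (N₋₊ + N₊₋) / (N₊₊ + N₋₊ + N₊₋ + N₋₋)
- Jaccard:  (N₋₊ + N₊₋) / (N₋₊ + N₊₋ + N₊₊)

The Jaccard form drops the `-/-` matches from the denominator, on the view
that two languages sharing a *default* is weak evidence of common descent
compared to sharing a marked value; consequently Jaccard ≥ Hamming on every
pair, with equality exactly when the pair shares no `-/-` match.

From the distance matrix the package builds:

- **UPGMA trees** — average-linkage agglomeration, merge at height d/2,
  producing a rooted ultrametric (clock-like) tree, with character-bootstrap
  clade supports (parameter columns resampled with replacement);
- **PCoA** — classical metric scaling by Gower double-centering
  B = −½·J·D⁽²⁾·J and eigendecomposition; variance fractions over the
  positive eigenvalues;
- **heatmap tables** — the matrix reordered by the UPGMA merge tree, with
  cells binned into cool/warm shades split at the median off-diagonal
  distance (plot-ready CSV, no figures);
- **tree-likeness scores** — per-taxon quartet Δ-scores
  ((m₁−m₂)/(m₁−m₃) over the three pairing sums m₁ ≥ m₂ ≥ m₃ of each
  quartet) and Q-residuals ((m₁−m₂)² on mean-1-scaled distances); low
  scores mean a sharp vertical (tree-like) signal;
- **clade-recovery scores** — exact-membership comparison of the tree
  against ground-truth groups (the packaged table ships the 24
  etymologically established Eurasian groups, the contested "Altaic"
  excludable);
- **NEXUS export** — `+`→1, `-`→0, null/unknown→`?` (missing), for external
  character-based tools.

A full simulator closes the loop: Yule (pure-birth) clock trees, binary
characters evolving under an asymmetric two-state CTMC (gains more frequent
than losses), an implicational layer that renders dependent parameters null
whenever their controlling parameter lacks the required value, and
post-evolution horizontal borrowing between designated leaf pairs — so every
stage is testable with no external data.

## Worked example

Simulate a dataset, analyse it, and compare the reconstruction with the
truth:

```bash
$ pcmphylo simulate --n-taxa 12 --n-params 120 --seed 7
simulated 12 taxa x 120 parameters (736 null cells, 328 plus cells)
matrix: simulated_matrix.csv  tree: simulated_tree.nwk  events: simulated_events.csv

$ pcmphylo summary simulated_matrix.csv --out out
```

`out/summary.csv` then contains (excerpt): 1440 cells of which 736 null and
328 `+`; mean 27 `+` per language; mean pairwise informative overlap 51
(range 44–59).  The same steps from Python, continuing to trees and scores:

```python
import pcmphylo as p

m    = p.read_matrix("simulated_matrix.csv")
D    = p.distance_matrix(m, "jaccard")     # errors on pairs with no support
tree = p.upgma(D)                          # rooted ultrametric dendropy.Tree
true = p.newick_read("simulated_tree.nwk")

count, nrf = p.robinson_foulds(true, tree)
print(count, round(nrf, 3))                # 10 0.556
print(round(100 * p.pcoa(D).variance_fractions[0]))   # 36  (% on axis 1)
print(round(p.taxon_scores(D).delta_median, 3))       # 0.262

boot = p.bootstrap_support(m, n_reps=200, seed=7)
print(boot.support_table().head(2).to_string(index=False))
#                               clade  size  support_pct
# T01;T02;T03;T04;T05;T06;T07;T08;T12     9         23.5
#                 T01;T02;T03;T04;T05     5         93.0
```

Twelve taxa resolved from ~50 usable characters per pair is a hard setting:
the normalized Robinson–Foulds distance of 0.556 to the true tree and the
mixed bootstrap supports show exactly the signal-vs-characters trade-off the
method faces; the replicated experiment (`pcmphylo recover`) quantifies how
recovery improves as characters are added.

On a real matrix, `pcmphylo all config.yaml` runs every stage (summary,
dist, tree, boot, pcoa, heatmap, delta, gold, nexus) and writes a manifest
plus CSV/Newick/PHYLIP/NEXUS outputs; `pcmphylo gold matrix.csv` alone
scores the UPGMA tree against the packaged ground-truth groups.

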