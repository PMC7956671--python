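# Methods

This note records the model, the defaults and the numerical choices made
where the design was genuinely open.  It states no empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## The forest distance

The unsupervised problem is converted into a supervised one: the n real
rows are stacked over n synthetic rows drawn column-wise, i.i.d. with
replacement, from the real columns' empirical marginals.  Every marginal
is preserved exactly in distribution; every cross-column dependence is
destroyed.  A forest separating real from synthetic rows therefore splits
only where the real data carry joint structure.  Proximity is the
co-terminal fraction over trees, computed for all 2n rows and then
restricted to the real block as d = 1 − s.  One augmentation is a
Monte-Carlo draw, so dissimilarities and importances are element-wise
means over `n_forests` independent augmentation+forest repetitions
(default 20); the variance of a distance entry shrinks roughly like
1/n_forests (property-tested).

Two structural facts about this construction, found during development
and load-bearing for interpretation:

* **Root nodes are univariately null.**  Because the synthetic block
  preserves every marginal, no single feature separates real from
  synthetic at the root.  A conditional-inference tree that stops when no
  candidate is individually significant would therefore terminate at the
  root in about 95% of trees and the distance would degenerate.  Forests
  hence grow CIF trees *without* the significance stop by default
  (`cif_early_stop=False`), splitting on the smallest-p candidate until
  the node-size limit — the convention of reference conditional-forest
  implementations, which set the stopping criterion to zero inside
  ensembles.  The significance stop remains available for single trees.
* **Augmented rows are not exchangeable.**  The synthetic block is a
  bootstrap of the real block, so permutation p-values on the augmented
  task are conservative (increasingly with cardinality).  Engine-level
  calibration claims (cardinality bias, test calibration) are therefore
  assessed in the supervised setting, where exchangeability holds.

## Split regimes

* **RF** — maximum Gini impurity decrease over mtry candidates.
  Nominal features are split by level subsets found with the
  order-levels-by-class-fraction scan, which is exact for a binary class
  label under Gini (the label here is always binary); an enumeration
  oracle in the tests confirms exactness.
* **RRF** — the gain of a feature the current tree has not yet split on
  is multiplied by λ ∈ (0, 1] (default 0.8, per-tree scope to preserve
  inter-tree diversity).  λ = 1 reproduces RF bit-for-bit (tested).
* **CIF** — per candidate, a Monte-Carlo permutation test of
  independence between feature and label: |centered class-1 group sum|
  for ordered features, Pearson chi-square on the level × label table for
  nominal ones; B = 199 permutations by default (B is a resolution knob,
  not a model parameter).  The conservative p-value
  (1 + #{perm ≥ obs})/(1 + B) drives the significance/stopping decision;
  candidate *ranking* uses the mid-p variant (half the tie atom), because
  the full tie mass systematically handicaps features with discrete
  statistics and would re-introduce a cardinality bias through the
  ranking.  Bonferroni adjustment over the mtry candidates; all ties
  break to the lowest feature index for determinism.

Common defaults: `n_trees=100` (conditional-forest convention),
`mtry=ceil(sqrt(p))`, `min_node_size=5`, unlimited depth, subsample
0.632·N without replacement.  The study that motivated this package did
not publish its forest parameters; these are standard reconstructions.

## Variable importance

For each tree, accuracy is measured on its out-of-bag rows (the
permutation-importance convention; the source framework reports OOB error
elsewhere, and in-bag accuracy would reward overfit splits).
Unconditional: permute the whole column.  Conditional: permute within
strata of each other feature in turn — category levels for categorical
conditioners, the tree's own split thresholds (quartile bins if the tree
never split on the conditioner) for numeric ones — and average the drops
over conditioners (arithmetic mean; the combination rule is unstated in
the source, the mean is symmetric and variance-reducing).  Features never
split on have importance exactly 0.  Raw importances are reported
unscaled; scaled importances are clipped at 0 and divided by the maximum.

## Consensus clustering

Ward linkage is applied to the raw forest dissimilarities (no embedding,
no squaring) via scipy; heights are monotone for Ward and violations
would be recorded, not hidden.  Consensus: `n_resamples=250` subsets of
80% of items, each Ward-clustered and cut at every k in 2..10; consensus
matrix = co-assignment / co-sampling per pair; k maximises the delta-area
criterion, where the area under the consensus CDF is computed exactly as
1 − mean(consensus).  Final labels: Ward on 1 − consensus cut at the
chosen k, label ids assigned in dendrogram leaf order.  A pair never
co-sampled raises with guidance rather than producing a silent NaN.

## Evaluation metrics

ARI and Calinski–Harabasz delegate to scikit-learn behind the module
surface (independent pair-counting and scatter-matrix oracles live in the
tests); cluster purity, feature purity and Baker's Gamma are implemented
here.  Feature purity is the size-weighted modal-level fraction per
cluster, averaged over categorical features (numeric features belong to
CHI; the published definition of this metric was not available, this is
the reconstruction).  Baker's Gamma is the Goodman–Kruskal gamma between
the paired first-merge steps of all leaf pairs, computed exactly via a
contingency table with 2-D prefix sums (O(n²)); zero within-cluster
scatter in CHI returns +inf rather than raising.

## Simulation designs (the stated world of the benches)

* **Cardinality** — n = 200; eight predictors of cardinality
  2, 2, 4, 8, 16, 32 plus two continuous; two balanced latent classes.
  Each informative feature is a latent N(±effect_size/2, 1) discretised
  at equal-probability standard-normal bins into its cardinality
  (continuous features keep the latent value); `effect_size=1` latent SD.
  All features are informative by default: with the class label withheld
  and only one informative feature, the real columns are mutually
  independent and the synthetic augmentation is distributionally
  *identical* to the real data — no clustering method could beat the
  random baseline.  Noise features (effect 0) are exactly uniform over
  their levels.  `effect_size=0` everywhere gives the global null used by
  the cardinality-bias test.
* **Correlation** — n = 200, p = 12 standard Gaussians, X1..X4 pairwise
  correlated at ρ = 0.9; latent response y = Xβ + ε, ε ~ N(0, 1),
  β = (5, 5, 2, 0, −5, −5, −2, 0, 0, 0, 0, 0); class label by median
  dichotomisation.  X4 has zero coefficient but rides the correlated
  block; X5..X7 have large coefficients but no correlation — the
  configuration separating conditional from unconditional importance.
* **Planted clusters** — a positive control: 4 continuous features
  shifted by 3 SD and 4 binary features flipped at rate 0.1 between two
  balanced groups.  The separation is deliberately large enough that the
  groups are essentially Bayes-separable, so a failed recovery indicates
  a pipeline defect, not intrinsic ambiguity.

What a green bench establishes: that the pipeline recovers planted joint
structure of both numeric and categorical type, at the effect sizes
stated above, under the generators' idealisations (independent rows, no
missingness, balanced classes, exactly Gaussian/uniform marginals).  Real
cohort tables violate all four idealisations; nothing here validates
behaviour under informative missingness or batch structure.

## Runtime scaling

`scripts/acceptance.py` keeps the full Monte-Carlo structure (25
repetitions per target, 20 forests averaged per repetition, 250 consensus
resamples) and scales only per-forest resolution: 40 trees per forest and
B = 63 CIF permutations.  The pytest acceptance suite reduces repetition
counts further (6 and 4 repetitions for the two stochastic reproduction
tests, stated in their docstrings) with tolerance bands widened by the
predeclared Monte-Carlo standard error of the reduced counts.

## Known limitations

* Missing data are refused, not imputed (`drop_incomplete()` is the only
  supported route), matching the complete-case convention of the source
  analyses.
* The conditional-importance stratification for numeric conditioners is
  tree-local; importances from shallow trees can be noisy.
* Ward on a forest distance is a pragmatic convention: the distance is
  not Euclidean and the Ward objective is applied to it as-is.
* Monte-Carlo CIF p-values put selection on a 1/(B+1) grid; residual ties
  break deterministically to the lowest feature index, a visible (if
  tiny) asymmetry at small B.
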