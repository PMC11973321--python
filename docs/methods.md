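# Methods

## Problem and pipeline

`crcpod` re-implements, as a tested library, a cross-cohort gut-microbiome
analysis workflow for colorectal-cancer (CRC) risk assessment in ostensibly
healthy people (unaffected relatives of CRC patients, cohabitants, staff).
The input is species-level relative-abundance tables (MetaPhlAn-style
merged TSV, percent scale) plus per-sample metadata. The stages are:

1. **Normalization** — percent → proportion; for feature comparison, a
   pseudo-count of 1e-05 (proportion scale) followed by log10.
2. **Alpha diversity** — Shannon (nats), Simpson complement, observed
   taxa, Gini; group comparison by Student's t or Wilcoxon rank-sum.
3. **Ordination** — Bray-Curtis, Jensen-Shannon, Pearson and Spearman
   distances; classical PCoA with per-axis variance explained.
4. **Differential abundance** — per-cohort two-tailed Wilcoxon rank-sum
   screen at unadjusted α = 0.05.
5. **Biomarker overlap** — taxa significant in the screening cohorts,
   intersected with the taxa detected in the target cohorts.
6. **POD model** — a random forest over panel taxa; the POD (probability
   of disease) index of a sample is the fraction of trees voting "case".
7. **Evaluation** — ROC/AUC of POD against labels, pairwise group POD
   comparisons, and the contingency-table statistics used for participant
   characteristics (Fisher exact, t, chi-square, ANOVA, proportions).

## Statistical conventions

- **Wilcoxon rank-sum**: exact enumeration when min(n) ≤ 10 and the pooled
  sample is tie-free, else normal approximation with tie correction and no
  continuity correction. Degenerate input (both groups constant and equal)
  returns p = 1. Because the log transform is strictly monotone, screen
  p-values are identical on raw and transformed proportions (asserted in
  tests); the transform matters only for parametric displays.
- **Fisher exact (two-sided)**: point-probability rule — the sum of
  hypergeometric probabilities of all margin-fixed tables whose point
  probability is ≤ the observed one (relative slack 1 + 1e-7), summed in
  exact rational arithmetic. This is the convention that reproduces the
  printed demographic-table p-values. A zero margin gives p = 1.
- **Alpha diversity**: Shannon uses natural log; Simpson is the complement
  1 − Σp² so larger = more diverse; Gini is computed over the full taxon
  vector of the table, structural zeros included, making values comparable
  across samples of one aligned table. Both t and Wilcoxon comparisons are
  offered because methods text and figure captions in this literature use
  them interchangeably; they can disagree on small skewed samples, and the
  package does not arbitrate.
- **Distances**: Jensen-Shannon uses log base 2 and the square root, so it
  is a metric bounded by 1 and equals 1 on disjoint supports. Correlation
  distances (1 − r) are computed across taxa within each sample pair;
  Spearman uses midranks for ties; a constant profile makes correlation
  undefined and is an error naming the offending sample.
- **PCoA**: Gower double-centering of −D²/2, symmetric eigendecomposition.
  Negative eigenvalues (possible for non-Euclidean dissimilarities) are
  reported but excluded from the variance-explained denominator. Axis
  signs are fixed by forcing the largest-magnitude coordinate positive, so
  embeddings are deterministic. For Euclidean input the embedding
  reproduces the input distances to 1e-8 (tested).
- **AUC**: trapezoidal area under the ROC curve, which equals the
  Mann-Whitney probability P(case > control) + ½P(tie) exactly (tested to
  1e-12 against brute-force pair counting).

## The POD forest

Each of T trees (default T = 500, the conventional forest size; tests use
100–200 to keep runtimes in seconds) is grown on an n-out-of-n bootstrap,
choosing at every node the best Gini-impurity split among ⌊√p⌋ randomly
drawn panel taxa, grown to purity (min leaf 1). Out-of-bag (OOB) samples
give the internal error estimate and the mean-decrease-accuracy (MDA)
importance: per tree, each used taxon's values are permuted among that
tree's OOB samples and the accuracy drop is averaged over trees. A taxon
used by no split has importance exactly 0. Leaf-class ties vote control —
the conservative risk call.

Two deliberate choices:

- **POD is the vote fraction** in [0, 1], not the literal case/control
  vote odds ratio (unbounded, undefined at unanimity); the odds form is
  emitted alongside as `vote_odds`.
- **Split thresholds sit at observed feature values** (rule `x <= t`),
  not midpoints. Trees then consume only order statistics, so the grown
  structure *and every prediction* are exactly invariant under any
  strictly monotone per-taxon transform applied identically at train and
  score time (tested bit-for-bit). The trade-off is that an unseen value
  falling in the open gap above a threshold routes to the right child,
  where a midpoint rule would split the gap; on separable data this makes
  boundary behaviour slightly more "case-leaning" for gap values.

Training is deterministic given (data, panel, T, seed): identical seeds
give bit-identical serialized models and scores. Models serialize to JSON
(node arrays, thresholds, counts, OOB indices) and reload exactly.

One model is trained per training cohort (rather than pooling), mirroring
multi-cohort designs where per-cohort models are compared on a common test
cohort; inter-cohort heterogeneity then shows up as the spread of AUCs.

## Biomarker overlap semantics

The panel is the **union** of per-cohort significant taxa intersected with
the taxa detected in the target cohorts (`overlap_mode="union"`, default).
The union reading fits a design where each cohort's markers are expected
to be nested within one combined panel; a strict 9-way intersection is
available via `overlap_mode="intersection"`. No FDR correction is applied
by default, matching the unadjusted α = 0.05 screening convention; the
cross-cohort requirement is the de-facto multiplicity control.

## Synthetic data: what it emulates, what it does not

The generator produces the structure the analysis assumes: per-taxon
log-normal baselines (log-mean SD 1.0 across taxa), within-taxon
log-normal sample noise (SD 1.0 — abundances spanning ~2 orders of
magnitude, typical of species-level profiles), a multiplicative
case/control shift (default fold 4) on `n_diff` planted taxa (half
enriched, half depleted, as disease panels usually mix pathobionts and
depleted commensals), a per-(cohort, taxon) batch multiplier
exp(N(0, 0.5)) shared within a cohort (inter-study heterogeneity of the
scale that makes per-cohort model AUCs vary), closure to 100%, and a
binary diet covariate linked logistically to the standardized total
abundance of 10 designated taxa. All randomness flows from one seed
through spawned substreams (one shared stream for the taxon namespace,
baseline and planted set; one per cohort), so outputs are bit-identical
per seed.

Not emulated: phylogenetic correlation between taxa, zero-inflation beyond
what closure and log-normal tails produce, read-depth variation,
longitudinal structure, and realistic effect-size distributions (the
defaults are chosen for testability — passing recovery tests shows the
machinery is correct, not that real cohorts carry signal this strong).

## Numerical and degenerate-input conventions

- Percent-sum validation is off by default (profiler output often carries
  unclassified mass or sub-rank subsets); strict mode enforces
  |sum − 100| ≤ 1.0 per sample.
- Zero-variance groups: t/ANOVA return 1 for equal means, 0 otherwise;
  rank tests return 1 when the pooled sample is constant.
- Cohort alignment uses the lexicographic union of taxa with explicit
  zero fill, conserving each sample's abundance mass.
- Biomarker selection ties break by (importance desc, taxon id asc).
- p-value display uses 3 decimals with a "<0.001" floor; full precision is
  retained internally.

## Problem sizes

Tests and the acceptance script use two-cohort simulations of 200 taxa ×
100/100 samples (10 seeds) for recovery and chance-level checks, 10,000
aggregated null taxon-tests for Wilcoxon type-I calibration, and 1,000
replicates for ANOVA type-I — sizes chosen so the full suite completes in
about a minute while keeping Monte-Carlo error well inside the asserted
bands.

## Known limitations

- The forest is pure Python/NumPy; it trains ~10³ trees/s on hundred-sample
  panels but is not built for thousands of features.
- Correlation distances are undefined for constant profiles (an error, not
  a silent drop).
- The covariate model asserts association, not causation; it is a device
  for testing the correlation screen.
- Printed per-cohort AUCs from real external cohorts and real-data marker
  counts are not reproduction targets: they require the original
  metagenome data.
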