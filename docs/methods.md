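# Methods

## Problem and model

The package identifies genes specific to one labeled group in bulk
expression data by combining evidence across all pairwise comparisons
against the other groups, rather than a single one-vs-rest contrast.
One-vs-rest averages the "rest" — when the target shares a similar
sibling group, markers separating the target from dissimilar groups
dominate and markers distinguishing it from the sibling are lost.
Scoring each comparison separately and combining ranks weights every
comparison equally regardless of group size.

### Differential expression stage

Counts input: genes are filtered by a counts-per-million rule (CPM above
the CPM-equivalent of `min_count` = 10 at the median library size in at
least *k* samples, *k* = smallest group size, and total count ≥ 15);
library scaling factors come from the trimmed mean of M-values (TMM):
per sample, gene-wise log2 ratios (M) to a reference sample are trimmed
by ranks (30 % on M, 5 % on the average abundance A), averaged with
inverse-asymptotic-variance weights, and the factors normalized to unit
geometric mean.  The reference is the sample whose 75th CPM percentile
is closest to the mean.  Log2-CPM (offset 0.5) then gets per-observation
precision weights: gene-wise OLS residual SDs define a mean–variance
lowess trend (sqrt SD vs mean log2 count, span 0.5); weights are the
inverse fourth power of the trend interpolated at each fitted
log2-count.  Log-expression input skips all of this and is filtered by
user thresholds (mean log-expression ≥ 1.0, above a floor of 1.0 in at
least *k* samples).

Per gene, a weighted least-squares fit on a group-means design (batch as
fixed-effect dummies, reference batch omitted; confounded batch/group is
rejected as rank deficiency) gives the contrast estimate (logFC), and
residual variances are shrunken toward an empirical-Bayes prior.  The
prior is fitted by matching moments of the log variances to a scaled
F sampling model (prior df via a Newton inversion of the trigamma
function); for the log-expression route the prior scale follows a
lowess trend in mean expression (limma-trend-style).  The reference
implementation of this moderation family fits the trended prior with a
different smoother; rankings agree to Spearman > 0.9999 and p-values to
~0.001 in log10 on the count route.  With `lfc_threshold` = 0 the test
is the two-sided moderated t; with a positive threshold the null is
|true logFC| ≤ threshold and the p-value adds both shifted-null tails
(p = P(T ≥ (|β̂|−τ)/se) + P(T ≥ (|β̂|+τ)/se)), which reduces exactly to
the moderated t at τ = 0.  BH adjustment is applied within each
comparison, because ranks are later taken per comparison.

### Rank-product permutation score

Within each comparison the surviving common gene universe (intersection
of the n−1 filtered tables) is ranked by the chosen statistic (p-value
default; |logFC| descending when ranking by fold change; ties averaged).
RP_g = Σ ln rank_{g,i}.  The null is built by K independent shuffles of
each comparison's rank vector (a random bijection genes→ranks per
comparison); score_g is the fraction of shuffles with rp strictly below
RP_g.  K defaults to 1000 — resolution 10⁻³ against the 0.05 selection
threshold; the strict-inequality estimator can return exact zeros, and a
(hits+1)/(K+1) smoothed variant is available.  Selection keeps
score < 0.05 and, by default, only genes with positive logFC toward the
target in every comparison (a signature should mark the target, not its
absence; a two-sided flag exists).  `keep_top`/`keep_group` force the
top-N genes of named comparisons into the selection — the escape hatch
for closely related sibling groups whose comparison would otherwise be
overwhelmed in the product.

Monte-Carlo nulls are drawn per gene, so sampled scores are monotone in
RP only up to noise; exhaustive enumeration (used automatically in tests
and available as `exhaustive_score`) is exactly monotone.

### Pool constraining and aggregation

Marker pools merge any number of GMT collections into one union list
with per-gene source provenance (machine-queryable, idempotent under
re-merging).  The selection is intersected with the pool when one is
given.  Across datasets: union (best per-dataset score orders the
result), intersect, or Robust Rank Aggregation over each dataset's
score-ordered list — per gene with sorted normalized ranks r(1)…r(m)
over m lists, score = min_k P(Binomial(m, r(k)) ≥ k), Bonferroni ×m,
capped at 1; genes absent from a list carry rank 1.  RRA rewards
consistent *ordering* against an uncorrelated-lists null, so it needs
long ranked lists to gain power; with a couple of short signatures union
is the right tool (and the default).

### Background (SNR) refinement

To compare a signal dataset with a separately normalized background
dataset, each sample is reduced to within-sample relative expression:
fit N(μ_s, σ_s²) to the sample's log-expression by MLE (mean and
divide-by-n SD) and map each gene to Φ((x−μ_s)/σ_s).  The transform is
invariant to per-sample affine maps of log-expression, which is the
mechanism making the two datasets comparable — any global shift or
rescaling of a sample is absorbed into (μ_s, σ_s).  Counts are converted
to log2-CPM (offset 0.5) first, matching the DE route's scale.  Per gene
a normal fit across the signal samples' percentiles gives the median
x̂_S = μ_S (the median of a normal is its mean, so the SNR equals a
Cohen's-d-style (mean_S − mean_B)/SD_B on the percentile matrix — an
identity the tests verify to machine precision); likewise x̂_B, σ_B for
background, and snr = (x̂_S − x̂_B)/σ_B.  Genes with snr below the cutoff
(default 1, i.e. the signal median must sit one background-SD above the
background median) are removed, except pool genes (protected as
externally vetted) and genes absent from the background (unassessable,
kept with a warning).  σ_B = 0 is resolved by the sign of x̂_S − x̂_B.

## Synthetic data

The generator draws negative-binomial counts (variance m + φm², φ =
dispersion, default 0.1) with log-normal base means (log2 mean 5, SD 2,
floored at 1), plants disjoint per-group marker sets multiplied by
2^lfc in their group, adds per-sample library-depth variation (log2 SD
0.25) and optional shared batch factors, and can emit replicate datasets
under a shared truth and matched background datasets in which a chosen
fraction of the target markers are ubiquitously high (16×, at least the
95th percentile of base means) and the rest low.  It emulates sorted
bulk populations with clean labels; it does not emulate cell-type
mixtures within samples, correlated gene modules, outlier samples, or
annotation errors — passing tests show the statistical machinery is
correct under the stated model, not that signatures from messy real
cohorts will reach the same recall.

## Numerical and design choices

- Scale routing is explicit (`raw_counts` vs `log_expression`); raw
  counts must be non-negative integers.
- Gene-ID joins are exact string matches; an opt-in flag uppercases IDs
  on read (silent case folding creates false joins across species
  conventions).
- Rank ties are averaged (deterministic; fractional ranks enter RP
  through the log).
- The permutation estimator follows the strict-inequality form; zero
  scores are therefore possible at finite K.
- Default problem sizes in tests and the verification script (≤2000
  genes, K ≤ 1000, 5-seed grids) keep every check desk-scale; they are
  the sizes at which the planted-truth properties are sharp.
- End-to-end runs are deterministic: one seed drives the generator and
  the permutation null, and repeated runs produce byte-identical
  signature files.

## Known limitations

- No random-effects or duplicate-correlation modeling; batch is a fixed
  effect only, and a batch perfectly confounded with group is an error
  rather than a warning.
- No count-model GLM route (quasi-likelihood); counts always go through
  the precision-weighting path.
- The permutation null treats comparisons as independent, but observed
  ranks share the target samples: null genes whose target samples drift
  high by chance are favorably ranked in *all* comparisons at once,
  while the shuffled null carries no such correlation.  At small group
  sizes this admits a tail of correlated false positives that the score
  threshold alone does not remove — constraining to a curated pool
  and/or background SNR refinement is the intended mitigation.
- RRA aggregation has little power on short lists (see above).
- The SNR stage assumes within-sample log-expression is roughly
  Gaussian; heavy zero inflation (deep scRNA-seq sparsity) distorts the
  percentile fit.
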