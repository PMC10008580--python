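# Methods

## The problem and the model

ICU electronic health records yield, per admission, an irregular multivariate
time series: each attribute (a vital sign or lab value) is measured at its own
times, most attributes are missing for most admissions, and observation counts
per admission are heavy-tailed.  The package learns a fixed-size representation
of one admission's entire stay — static data included — by training a sequence
autoencoder to reconstruct all of an admission's time series from a single
bottleneck vector, and then treats that bottleneck as the feature space for
patient-subgroup discovery.

**Input representation.**  Per admission, rows are the sorted union of the
admission's own observation times (no fixed-step resampling), and columns are
dynamic attributes | static attributes | temporal features.  Dynamic values
are linearly interpolated in time between an attribute's own observations,
held constant beyond its observed range, and set to the training-split median
when the admission never measured the attribute.  Static columns (normalized
age, raw 0/1 sex index) repeat at every row.  Each dynamic attribute and age
are normalized independently by a quantile transform fitted on the training
split only (empirical quantiles followed by the standard-normal percent-point
function); the transform is monotone, robust to outliers, clamps outside the
fitted range, and is invertible up to local quantile spacing.

**Temporal features.**  Time is minutes since admission start.  Each row
carries the flat normalized minutes plus 64 sinusoidal positional encodings,
column 2i = sin(t / B^(2i/64)) and column 2i+1 = cos(t / B^(2i/64)) with base
B = 10000 — 65 temporal columns in total.  Since the encoding of t + d is a
fixed rotation of the encoding of t, a recurrent model can reason about
relative as well as absolute time; the position is physical elapsed time, not
the row index, because rows are irregularly spaced.

**Architecture.**  A GRU block is a bidirectional pair of GRU layers whose
per-step outputs are summed and layer-normalized, with dropout on the
non-recurrent (input) connections and an ELU candidate activation (gates stay
sigmoid).  The encoder runs a GRU block over the full input, averages the
valid (non-padded) time steps, and projects linearly to the bottleneck
(default 46 dimensions; odd sizes are rounded up to keep the feature space
even-dimensional).  The decoder repeats the bottleneck along time, re-appends
the input's temporal columns — without them it could not know *when* to place
reconstructed values — runs a second GRU block with separate weights, and
applies a per-step linear layer producing the dynamic + static reconstruction.
Temporal columns are never reconstruction targets.

**Training.**  Adam (lr 0.00075), Huber loss (delta 1.0) over mask-valid rows
of the dynamic + static columns, global gradient-norm clipping at 1,
mini-batches of 4 admissions padded to the longest admission in the batch,
Gaussian noise (sigma 0.0573) added to the dynamic input columns only (never
to targets or temporal columns), dropout 0.267, early stopping on validation
loss with patience 8 and restoration of the best-validation weights.  The
90/10 train/validation split is seeded-random; batches are reshuffled each
epoch from the run seed.  The network and its backpropagation are implemented
directly in numpy; the analytic gradients are pinned by a central-difference
test at relative error below 1e-5.

## Clustering and robustness

k-medoids with k-medoids++ seeding runs on Euclidean distances in the feature
space.  Candidates over several k and seeds are screened twice.  *Triviality*:
a clustering with a single non-empty cluster, or whose largest cluster holds
strictly more than 90% of points, is discarded.  *Robustness*: the same
procedure is re-run on 10 subsamples of 70% of the points drawn without
replacement; for each similarity metric h in {normalized mutual information,
Rand index, pairwise Jaccard} the lower bound rob_h is the 10th percentile of
sim_h(full labels restricted to the subsample, bootstrap labels), and the
threshold thresh_h is the 90th percentile of sim_h(full labels, uniform
shuffle of them), recomputed per clustering because it depends on the
cluster-size profile.  A clustering is robust iff rob_h > thresh_h (strict)
for all three metrics.  Mutual information is normalized so that bootstrap
similarities and shuffle thresholds share a [0, 1] scale; percentiles use
linear interpolation between order statistics.  Surviving clusterings are all
reported: they complement rather than compete.

## Code enrichment

Maximal frequent itemsets of diagnosis (or procedure) codes are mined once on
the whole population (depth-first tidset search; default minimum support
0.05), then every itemset is tested in every cluster against its complement
with a two-sided Fisher exact test on the 2x2 contingency table.  Direction
comes from the support comparison; relative enrichment is s_c / s_comp − 1 in
percent (undefined and flagged when the complement support is zero).
Significance is Bonferroni-controlled per clustering at alpha = 0.01 divided
by n_t = n_is · n_c.  A built-in ICD-9 chapter table (001–139 infectious, …,
460–519 respiratory, …, V and E code chapters) supports category-distribution
summaries that count every diagnosis occurrence without per-admission
de-duplication.

## Synthetic cohorts

Real critical-care data is credentialed, so the package ships a seeded
generator whose defaults emulate the statistical shape of such data: the
per-admission total observation count is lognormal(mu = 6.045, sigma = 1.0)
(median ≈ 422, IQR ≈ 215–828); per-attribute observation times form a
homogeneous Poisson process over a lognormal stay; attribute support slopes
from 1.0 down to 0.55; ages are uniform on [22, 90] and sex is Bernoulli(0.44).
Latent subgroups drive three things: (a) temporal signatures — each subgroup
adds, to a designated subset of attributes, a deterministic mean curve of
absolute time (level shift, linear trend, Gaussian bump, or sinusoid, rotated
over subgroup × attribute so no two subgroups share a curve on an attribute)
scaled by `signature_amplitude` on top of unit-variance noise; (b) code
enrichment — subgroup-linked codes appear `enrichment_multiplier` times the
baseline probability; (c) mortality — a logistic model with per-subgroup
log-odds shifts.  The generator makes no attempt at realistic physiology,
units, or a real attribute catalogue; what passing tests show is that the
pipeline recovers planted structure of the stated kind and strength, not that
it recovers clinical phenotypes from real records.

## Problem sizes used in tests and the acceptance script

Full-scale training (75 attributes, hundreds of grid rows, GRU 158,
bottleneck 46) is hours of compute; the shipped end-to-end checks instead use
a reduced study configuration chosen once: 300 admissions, 5 dynamic
attributes (3 signature-carrying), observation counts lognormal(3.7, 0.35)
(median ≈ 40), shorter stays, signature amplitude 3.0 — strong enough that
subgroup separation is a property of the method rather than of a lucky
clustering initialization — and a reduced model (GRU 32, bottleneck 8,
≤ 30 epochs).  Reduced runs use learning rate 0.003: a model this small does
not approach convergence within the epoch budget at the full-scale rate of
0.00075.  The bottleneck-capacity sweep uses an even smaller setting
(120 admissions, GRU 16, 10 epochs) since it compares three bottleneck sizes
across three seeds.

## Numerical choices and edge cases

* Quantile maps clamp out-of-range values to the fitted extremes
  (outlier-robustness is the motive for the transform); sex passes through
  untransformed because a quantile map of a binary column is degenerate; the
  flat time column reuses the same quantile mechanism, fitted on pooled
  training observation times.
* Duplicate (attribute, time) observations keep the last value read, with a
  warning.
* Masked (padded) rows are invisible everywhere by construction: GRU layers
  carry their hidden state through masked steps, the encoder mean pools only
  valid rows, and the loss and metrics exclude them — appending padding
  changes nothing beyond floating-point noise.
* MAPE is computed on the original measurement scale via the inverse quantile
  map, excluding targets with absolute value below 0.1, because relative
  error in a zero-mean normalized space is ill-defined.  Median MSE is
  computed in normalized space, per (admission, attribute) series.
* The error-vs-mortality summary keeps the bottom 99% of admissions by error
  and uses equal-width bins over the kept range.
* k-medoids breaks medoid-update ties by the lowest index; the Jaccard pair
  index of two all-singleton partitions is defined as 1.

## Known limitations

* The generator's subgroups are balanced and independent of age/sex; real
  cohorts confound demographics with phenotype.
* The reduced model's reconstruction error is not comparable in magnitude to
  a full-scale run; only directions and recovery rates transfer.
* No ICD-10 support, no hierarchy-aware code testing beyond top-level
  chapters, and no automatic selection of the number of clusters.
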