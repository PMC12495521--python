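# Methods

This note records the models, parameter choices, numerical conventions and
known limitations of the package. It is the place where genuinely open
design choices are argued; the README gives the user-facing overview.

## Hexagonal tessellation

Pointy-top hexagons in axial coordinates; with side *s* (centre-to-vertex)
the centres sit at x = s√3(q + r/2), y = (3/2)s·r. Points map to tiles by
cube rounding of fractional axial coordinates, i.e. nearest-centre
assignment, so the grid partitions the plane and cell counts are conserved
exactly. Defaults: *s* = 262.5 µm (per-tile area (3√3/2)s² ≈ 1.790 × 10⁵
µm²) and a 50-cell validity floor; both are exposed in `PipelineConfig`.

Orientation and registration conventions are not scientifically forced:
any fixed convention yields a valid tessellation. We fix pointy-top
orientation and anchor the grid origin at each case's bounding-box minimum
so reruns are deterministic; translation-invariance tests bound the
sensitivity (translating the point set by a lattice vector permutes tile
indices but preserves the multiset of per-tile counts). Edge tiles
straddling the bounding box are kept and left to the 50-cell filter —
no tissue-mask geometry is applied, since the upstream DIA export is
assumed to contain tumor cells only.

## Binning and the co-occurrence matrix

Tile positivity percentages are ranked into `n_bins` = 10 equal intervals
with a closed first interval: bin 1 = [0, 10], bin k = (10(k−1), 10k].
A 10⁻⁹ tolerance keeps floating-point representations of exact bin edges
(e.g. a ratio printing as 30.000000000000004) in the closed-edge bin.

Adjacency is the six axial neighbors at unit distance. Each unordered pair
of adjacent *valid* tiles increments both symmetric cells of the count
matrix (equal-bin pairs add 2 to the diagonal), and pairs touching an
invalid tile are dropped entirely rather than bridged — the literal
reading of excluding under-sampled hexagons. With zero or one valid tile,
or no adjacent valid pair, the matrix is empty: entropy is reported as 0
with a `degenerate` flag, consistent with minimal-heterogeneity scoring of
very small tumors.

## Entropy base

Entropy uses log₂ and is therefore bounded by log₂(100) ≈ 6.644 bits for a
10-bin matrix. The natural-log alternative caps at ln(100) ≈ 4.605, below
entropy values this metric is reported to reach in practice (up to ~5.1),
so base 2 is the only consistent choice; the base is locked in
`PipelineConfig` and recorded in run manifests.

## Ashman's D

A two-component Gaussian mixture is fitted to the valid-tile percentages
by EM (scikit-learn, 5 seeded restarts, `reg_covar = 1e-4` as a variance
floor against component collapse); D = |μ₁−μ₂|/√((σ₁²+σ₂²)/2). Constant
inputs return D = 0; fewer than two valid tiles yield NaN with a flag.

## Synthetic cohort generator

The generator is the package's stand-in for patient data and defines the
study conditions for every statistical experiment:

* **Geometry and density.** 50 000 cells uniform on a 10 × 10 mm region
  (≈ 560 tiles of ~90 cells each, comfortably above the 50-cell filter).
* **Positivity field.** p(x, y) = logistic(logit(b) + a·Z(x, y)), where Z
  is an i.i.d. standard-normal lattice with 1500 µm spacing, bilinearly
  interpolated and pointwise-normalized to unit variance. b is the
  case's base (median local) positivity; a is the heterogeneity
  amplitude. The per-case base is drawn logit-normally around 0.15 with
  logit-sd 1.0, giving a cohort Ki67% interquartile range of roughly
  10–30% — the order observed in ER+/HER2− cohorts; the amplitude is
  drawn uniformly from [0, 2.5], spreading cohort entropies over
  0–5.7 bits. Amplitude 0 reduces the field to a constant b.
* **Second platform.** Identical coordinates with each label flipped
  independently with probability 0.02, emulating classification
  disagreement between DIA platforms. No segmentation differences are
  modeled.
* **Survival.** Nodal status ~ Bernoulli(0.41); linear predictor
  η = ln(2.3)·node + ln(2.6)·I(entropy > cohort median); event times
  exponential with rate 4.6 × 10⁻⁴·e^η per month, independent exponential
  dropout at 5 × 10⁻⁴ per month, administrative censoring at 120 months,
  times rounded to 0.1 month (creating the ties Efron handling expects).
  The baseline rate was set analytically so the 10-year event fraction is
  ≈ 13%, matching a low-event surgical cohort. Entropy is dichotomized at
  the cohort *median* here — not the optimized cutoff — so the generator
  stays independent of the cutoff finder it is later used to test. Grade
  (21% G3) and visual Ki67% (lognormal, median 20%) are drawn
  independently of survival.
* **Determinism.** All draws flow from one `SeedSequence` through five
  named substreams (field, cells, replicate, clinical, survival, in that
  order); a cohort is bit-identical under a fixed seed.

What the generator does **not** emulate: nuclei shapes or staining
intensity, segmentation errors beyond label flips, tissue masks or
non-convex tumor outlines, grade/Ki67 prognostic effects, and any
dependence structure between Ki67 level and outcome beyond the planted
entropy effect. Passing tests therefore demonstrate the pipeline's
statistical machinery under controlled conditions, not clinical validity
on real cohorts.

A property worth knowing: because one positivity field drives both the
cell labels and (through tiles) the entropy, a case's global Ki67% and its
entropy are positively rank-correlated across synthetic cases (~0.9 at the
defaults) — low-positivity cases are compressed into the bottom bins and
score low entropy, as real low-Ki67 tumors do. Consequently an
optimized-cutoff Ki67% model captures much of a hazard planted on
entropy, and with ~34 events per cohort the likelihood-ratio ordering of
the entropy model over the Ki67% model reproduces in only ~60–75% of
seeds. The mean LRs do order correctly (≈13.5 vs ≈12.2 at n = 254 over 25
seeds).

A mean-preserving intercept calibration (solving for c with
E[logistic(c + aZ)] = b) was evaluated to decouple Ki67% level from
amplitude and rejected: at low base it skews tiles into the bottom bin as
amplitude grows, making mean entropy non-monotone in amplitude and
breaking the amplitude-ladder property the generator is designed to have.

## Sampling simulation

Halves and quadrants split at the bounding-box midpoint (geometric, not
cell-count median), with boundary cells going to the lower/left part so
the parts partition the cell multiset exactly. Biopsies are vertical
strips 1.2 mm wide and at most 12 mm tall, centred on the cell-mass
y-centroid, with a uniformly random x-centre redrawn (≤ 20 times) until
the strip holds at least `min_cells` cells; two strips per case are drawn
independently and may overlap. Region metrics re-anchor the grid to each
region's own bounding box: a real biopsy would be tiled on its own, and
entropy must not depend on the discarded remainder's origin.

A known behavior at the default field scale: a 1.2 mm strip spans few
1500-µm field patches, so biopsy entropy is an intrinsically noisy
estimate of section entropy. The full-vs-biopsy Spearman correlation
across 50 cases is typically 0.85–0.94 but can fall to ~0.76 for
unfavorable seeds, while halves (≥ 0.94) and quadrants (≥ 0.89) are
stable — the ordering one expects as subsample area shrinks.

## Agreement statistics

ICC(3,1) is the two-way mixed-effects, single-rater consistency form
computed from mean squares, with the standard F-based confidence interval;
it is invariant to a fixed shift between raters and is reported regardless
of non-normality (interpret with care, as is conventional for large
reproducibility studies). Lin's CCC uses population (1/n) moments — the
original estimator; sample-moment variants disagree already on the 3-pair
worked example — with a percentile bootstrap CI (1000 pairs-resamples by
default; percentile rather than BCa since nothing finer is warranted).
Bland-Altman reports mean difference, ±1.96·sd limits (sample sd), and the
slope of differences on pair means. The Wilcoxon signed-rank test drops
zero differences and uses the exact null for n ≤ 25 without rank ties, the
tie-corrected normal approximation otherwise. Normality is tested by
Kolmogorov-Smirnov with the Lilliefors correction, since the normal
parameters are estimated from the sample. No multiple-comparison
adjustment is applied to the pairwise region comparisons.

## Survival modeling

Cox models are fitted by lifelines (Efron tie handling, Newton-Raphson
tightened to 10⁻⁹ so small-sample fits agree with a grid-search
partial-likelihood oracle to < 10⁻⁴). Model-level statistics are the
likelihood-ratio test against the null model and Harrell's C (risk ties
count ½).

Cutoff optimization scans every distinct observed marker value as a
threshold (dichotomy at value > threshold), keeps thresholds leaving both
groups ≥ 10% of subjects, and minimizes the log-rank p (ties resolve to
the smaller threshold). The scan uses a vectorized two-group log-rank
statistic validated against lifelines. Because the threshold is selected
to minimize p, the resulting log-rank and univariate-Cox p-values are
anti-conservative — this selection effect is intrinsic to
optimized-cutoff analyses. The model suite therefore evaluates models on
a seeded 75/25 train/test split, stratified by event status: cutoffs and
coefficients come from the training split only, and the held-out C-index
is the honest performance figure (repeated-split averaging is available
via `n_splits`). Covariate sets are pre-specified (nodal status, grade
G1–2 vs G3, one dichotomized marker) and fitted by plain partial
likelihood; no variable-selection or boosting machinery is used, since
every model of interest contains exactly the forced covariates.
Inestimable models are flagged and skipped rather than aborting the suite.

## Numerical conventions

* Quartiles and medians use linear interpolation between order statistics
  (NumPy default).
* Administrative censoring truncates times at 120 months and clears the
  event flag; the operation is idempotent.
* CSV is the interchange format throughout (UTF-8, header row); grade is
  encoded for modeling as the binary G1–2 vs G3 contrast.
* Coordinates are stored in µm with a per-case bounding-box-minimum
  origin; pixel-unit inputs are converted via a configurable
  microns-per-pixel factor.

## Problem sizes used in tests

Unit tests run on scaled cohorts (20 cases, 8 000 cells on 4 × 4 mm — the
same cell density as the defaults) so the full suite stays fast; the
statistical acceptance checks use the default-size conditions they make
claims about (n = 254 cohorts for platform agreement and model
comparison, 50 cases for sampling robustness, 100/50 seed replicates for
coverage and cutoff recovery).

## Known limitations

* The generator's field is stationary and isotropic with a single length
  scale; real tumors mix scales and anisotropy.
* Platform differences are label flips only; real DIA platforms also
  disagree on segmentation, and hence on the cell set itself.
* Grade and visual Ki67% carry no planted prognostic signal, so models
  including them estimate null effects for those covariates.
* The entropy–Ki67% coupling noted above means synthetic experiments
  understate the *incremental* value of entropy relative to what a cohort
  with independent Ki67% variation would show.
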