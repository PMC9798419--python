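# Methods

## The selection procedure

The pipeline identifies blood miRNAs that are temporally stable in
healthy subjects and recurrently dysregulated across cancer types.

**Normalization.** Every dataset (the healthy time course and each
cancer study) is normalized independently with median-of-ratios size
factors: for sample *j*, the factor is the median over reference
features of count<sub>ij</sub> / geomean<sub>i</sub>, where
geomean<sub>i</sub> is feature *i*'s geometric mean across samples and
the reference set is the features with strictly positive counts in all
samples. The median is taken in log space, so an even number of
reference features uses the geometric midpoint of the two central
ratios. Note that absolute normalized levels are defined only up to a
common constant (rescaling one library by *c* shifts every normalized
value by *c*<sup>1/n</sup>); all downstream quantities are ratios and
are invariant to this. Datasets are *not* co-normalized: each cancer
contrast is case vs its own controls, and the healthy windows are built
within the healthy cohort alone, so no cross-dataset scale is ever
compared. Features with mean normalized count below 20 are discarded
(per dataset); in the healthy cohort a feature must clear 20 within
*every* time-point group to count as "expressed at all time points".

**Stability score.** Per miRNA, the time-point log2 fold-change vector
is X<sub>t</sub> = log2((mean over samples at t + pc)/(mean over all
samples + pc)), one entry per time point (subjects averaged; a
per-sample variant is available via `per_sample=True`). Variability is
MAD(X) = b·median(|X − median(X)|) with b = 1.4826, the Gaussian
consistency factor. Stability is MAD **strictly** below 0.2; the healthy
reference window is median(X) ± 3·MAD. Even-length medians use the
midpoint of the two central order statistics, so every score is
bit-reproducible.

**Rhythmicity screen.** A single-component cosinor
y = M + A·cos(2π(t−φ)/τ) is fitted by linear least squares
(y = M + β·cos + γ·sin; A = √(β²+γ²), φ = atan2(γ, β)·τ/2π), with the
zero-amplitude F-test of β = γ = 0 (df 2, n−3). The default fit uses
period τ = 24 h on the time points at ≤ 72 h only: the later samples
(days 7/30/60) are single observations weeks apart, from which a
24-hour rhythm is unidentifiable; `cosinor_max_time_h = inf` fits the
full series.

**Temporal clustering.** Profiles are grouped by deterministic
agglomerative clustering (Euclidean distance on X, Ward linkage, tree
cut at k = 5). Ward was chosen after average linkage proved to chain on
realistic profile clouds (one giant cluster plus singletons; adjusted
Rand ≈ 0.04 against planted pattern kinds vs ≈ 0.47 for Ward). The
cluster with the lowest mean MAD is reported as the stable cluster.
Because the generator randomizes rhythm phases and periods, the
generative classes are heterogeneous in profile space and perfect
agreement with them is not attainable by any shape-based clustering —
the clustering is descriptive, not part of the selection rule.

**Differential expression.** Per cancer dataset: log2FC =
log2((mean<sub>case</sub>+pc)/(mean<sub>control</sub>+pc)) on normalized
counts, p-values from Welch's unequal-variance t-test on log2(value+pc),
BH step-up adjustment across the dataset's features. This deliberately
simple engine preserves the two quantities the selection rule consumes —
log2FC and adjusted p — without the NB-GLM machinery (dispersion
shrinkage, Wald tests) of a full RNA-seq DE package. Like any
median-of-ratios workflow it shares the composition caveat: if a large
fraction of features shift in the same direction, size factors absorb
part of the effect (≈0.26 log2 units when 20% of features carry a +2
effect; negligible at the ~5% DE fraction of the default scenario).
Features with both groups constant get p = 1.

**Panel selection.** Candidates are the stable miRNAs. In each dataset
where a candidate passed the expression filter, it is an *outlier* when
its log2FC lies strictly outside the healthy window (borders count as
inside) **and** its adjusted p is below 0.05. The outlier fraction is
n_outlier over datasets-present (a `denominator="all"` mode divides by
all datasets instead; in worked-example mode, with printed fold changes
but no p-values, the significance gate is skipped and the denominator is
all datasets). Selection requires the fraction to be **strictly greater**
than 0.8 — 9/11 ≈ 81.8% passes, 8/11 ≈ 72.7% fails. Ranking is by mean
window distance (0 inside; otherwise the gap to the nearer border)
across datasets where present.

**Evaluation.** Per dataset and marker: AUC via the Mann–Whitney
identity on log2 normalized counts (ties counted ½), orientation
max(a, 1−a) applied per marker per dataset (the same miRNA can go up in
one cancer and down in another), operating point by Youden's J, p-value
from the tie-corrected normal approximation to U, percentile bootstrap
CI (1000 stratified replicates, seeded). The panel score is a
ridge-penalized logistic regression (λ = 10⁻³) on standardized
log2 values, evaluated by stratified 5-fold cross-validation; the ridge
keeps separable fits finite. PCA variance fractions come from the SVD of
the column-centered matrix.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `pseudocount` | 1.0 | added to means before every log2 ratio; with the mean ≥ 20 filter it perturbs values by < 5% |
| `min_mean_count` | 20 | low-expression filter on normalized means |
| `mad_b` | 1.4826 | MAD consistency constant (SD under normality) |
| `window_k` | 3 | window half-width in MADs |
| `mad_cutoff` | 0.2 | strict stability threshold (log2 units) |
| `min_outlier_fraction` | 0.8 | strict recurrence threshold for the panel |
| `fdr_alpha` | 0.05 | BH-adjusted significance gate |
| `n_clusters` | 5 | temporal profile clusters |
| `cosinor_period_h` | 24 | rhythm screen period |
| `cosinor_max_time_h` | 72 | last time point used by the rhythm fit |

## The synthetic-data generator

`generate_scenario` emulates the study conditions end to end: a healthy
cohort of 10 subjects × 9 time points (0, 3, 6, 24, 48, 72, 168, 720,
1440 h) and 11 cancer case/control datasets of 20 + 20 samples, over 200
miRNAs. Counts are negative-binomial with variance μ + α·μ² and
per-sample library factors 2^N(0, 0.25²); baselines are log-uniform on
[100, 1000] normalized counts and the default dispersion is α = 0.05
(α = 0.5 for the "noisy" class). Temporal patterns are assigned 40%
flat, 20% cosine, 15% drift, 15% spike, 10% noisy — proportions chosen
once as a plausible mix of the oscillation classes seen in healthy
blood, configurable via `default_pattern_specs`.

Two generator choices are identifiability-driven and worth stating:

- **Rhythm periods.** Seven of the nine sampling times are ≡ 0 (mod
  24 h), so a circadian cosine is aliased to a near-constant on this
  grid — its MAD is ~0 at every phase — and several other
  grid-commensurate periods (36, 48, 72, 120 h) have phases that are
  equally invisible. Cosine patterns therefore draw periods uniformly
  from 90–110 h (noiseless MAD ≥ 0.31 × amplitude at every phase) and
  amplitudes from 0.5–1.5 log2 units, so the "rhythmic" class is
  actually rejectable by the MAD screen. Grid-aliased 24 h rhythms are
  exactly what the cosinor screen on the dense 0–72 h points exists to
  catch, and the rhythm-detection test plants them explicitly.
- **Cancer effects.** Panel members (drawn from the flat class) receive
  an effect in *every* dataset with magnitude uniform in 1.5–2.5 log2
  units and independent random sign. The minimum magnitude must clear
  `window_k · mad_cutoff + 0.3` = 0.9 — the widest window a stable miRNA
  can carry, plus margin — or the scenario is rejected as
  unidentifiable.

What the generator does **not** model: batch effects, GC/length bias,
subject-level autocorrelation (every sample is an independent NB draw),
compositional closure of sequencing, or realistic cross-miRNA
correlation. Passing the recovery tests therefore shows the selection
machinery is correct under its stated noise model, not that the panel
would replicate on real cohorts.

## Numerical conventions and degenerate inputs

- Medians (MAD, windows, size factors): midpoint convention; size-factor
  medians in log space (geometric midpoint), matching the reference
  normalization implementation.
- Borders of the threshold window count as inside (conservative tie
  rule); `window_distance` is continuous and zero exactly on the closed
  window.
- A perfect cosinor fit (residual SS ~ 0) reports p = 0 when the
  harmonic explains variance and p = 1 for a constant series.
- Constant matrices: PCA warns and returns zero fractions; DE on
  identical constant groups returns log2FC = 0, p = 1.
- An empty median-of-ratios reference set (no feature positive in all
  samples) is an error advising filtering, not a silent fallback.
- Determinism: every stochastic step (simulation, CV folds, bootstrap)
  derives from one configured seed; two runs with the same config and
  inputs produce byte-identical output tables.

## Problem sizes

The recovery suite averages 20 scenario replicates (200 miRNAs, 90
healthy samples, 11 × 40 cancer samples) plus 5 null replicates; one
replicate runs in under a second, chosen so the whole suite iterates
comfortably on a laptop. `scripts/acceptance.py` uses the same sizes.

## Known limitations

- The MAD's breakdown point means single-time-point excursions (the
  "spike" class) and slow drifts can pass the stability screen; they are
  null in the cancer contrasts, so they inflate the candidate list but
  not the panel.
- The DE stand-in assumes approximate log-normality of normalized
  counts within groups; at very low counts the Welch test loses power
  relative to an NB likelihood test.
- The healthy cohort the design emulates is all-male; nothing in the
  machinery addresses sex-specific expression.
- CV AUC of the combiner is optimistic when the same dataset was used
  for selection (selection-induced bias); the evaluation here
  quantifies separation, not prospective performance.
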