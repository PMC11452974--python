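# Methods

This note documents the models, defaults and numerical choices behind
`itsakit`, and what the simulation-based validation does and does not
demonstrate.

## Experiment model

An iTSA experiment compares soluble protein abundance after a brief
single-temperature heat challenge between vehicle- and drug-treated
aliquots of the same lysate, quantified together in one TMT 10-plex
(channels 126–128C control, 129N–131 treated; 53 °C / 3 min challenge
carried as metadata). Ligand binding stabilizes a target, so the
target's treated channels carry systematically higher intensity; all
other proteins share a common expectation across conditions.

## Synthetic data generator

The generator draws, per protein, a log-normal base abundance
(ln-mean 13.8 ≈ 10⁶ intensity units, ln-sd 1.5 — the typical 4–5 decade
dynamic range of a deep TMT experiment) and produces each measurement
as base × shift × loading × noise:

- **shift**: fixed linear fold change ≥ 1 on treated channels of spiked
  targets (default 1.6, 50 targets out of 3000 — a strong but not
  extreme stabilization, similar to what single-temperature screens
  report for good binders); 1 everywhere else.
- **loading**: one multiplicative factor per channel, log-normal with
  sd 0.1, shared by all proteins — the pipetting/labeling-yield
  imbalance that total-abundance normalization exists to remove.
- **noise**: multiplicative log-normal with CV 10 % (σ_ln = √ln(1+CV²),
  mean exactly 1), the standard reporter-ion error model; on the log2
  scale this gives per-measurement sd σ = log₂e·√ln(1.01) ≈ 0.144.
- **missingness**: left-censored; the per-cell missing probability is
  2·r·logistic(−z) where z is the log-intensity z-score and r the
  nominal rate (default 0.02), so the average rate is r but low-
  abundance proteins are preferentially affected, as in real MS data.
- **QC metadata**: 5 % of rows draw a Sum PEP Score below the filter
  threshold (uniform on [0,5); the rest 5 + Exp(30)); unique-peptide
  counts are 1 + Poisson(7), so the unique-peptide gate is exercised
  only by explicitly constructed tables.

Randomness derives from one seed via named substreams (one per protein,
one for plex-level draws), so enlarging the panel leaves earlier rows
bit-identical. Which proteins are targets is drawn from the plex-level
stream and therefore resamples if the panel size changes.

The generator does **not** model peptide-level aggregation, isotopic
impurity, co-isolation interference, or protein-specific melting
behaviour at the challenge temperature. Passing calibration tests on
this model therefore demonstrates correctness of the statistics under
idealized TMT noise, not robustness to ratio compression or
interference in real data.

## Filters and normalization

Filters run before any normalization, in the order PEP → unique →
missing, all thresholds inclusive (≥). Abundances of exactly 0 are
treated as missing at ingest, since the log-scale stages require
positivity and a zero reporter intensity is a failed measurement.

- **Total abundance**: each channel scaled so every channel sum equals
  the mean of the input channel sums (this conserves the grand total).
- **IRS**: for multi-plex designs, each protein's within-plex geometric
  mean is rescaled to the across-plex geometric mean of those means;
  with no dedicated bridge channels in the assay design, the
  all-channel geometric mean serves as the per-plex reference. A single
  plex — the package's default study design — makes this stage the
  identity.
- **TMM**: edgeR-convention defaults — reference channel by
  upper-quartile closeness to the mean upper quartile (ties to the
  lowest index), M = log₂(channel/ref) and A = ½log₂(channel·ref) per
  protein, symmetric 30 % M-trim and 5 % A-trim (survivors are the
  intersection), precision weights 1/(1/x + 1/ref) (the large-library
  limit of the asymptotic-variance weights; library-size terms are
  moot after the total-abundance stage equalizes sums), factor =
  2^(weighted mean M), factors rescaled to geometric mean 1, applied
  by division.

Every stage is a per-channel positive scaling, so within-channel
protein rank order is preserved exactly; within-protein cross-channel
ranks are not, in general.

## Target calling

FC is the geometric-mean ratio 2^Δ(mean log₂) — the same scale as the
t-test, so the FC gate and the significance gate measure the same
effect. The test is the classic pooled-variance two-sided Student's t
on log₂ intensities; a zero-variance protein with equal means gets
t = 0, p = 1. No multiple-testing correction is applied at the calling
stage: the calling rule is the raw p < 0.05 joint with FC > cutoff, and
the FC gate is what controls the false-discovery proportion (at 5 v 5,
CV 10 %, a null protein needs a > 4σ fluctuation of mean log₂FC to pass
FC > 1.3 jointly with p < 0.05, so the null call rate is ≈ 2·10⁻⁵).

The variance–coverage cutoff is the empirical ⌈0.88·n⌉-th order
statistic of the FC sample — no interpolation or rounding by default; a
`round_to` option (e.g. 0.1) reproduces conventional one-decimal
reporting. Coverage 0.88 is the package default. On the default
synthetic panel the 88 % point falls near FC 1.08 because the simulated
null FC spread (σ ≈ 0.09 on log₂) is tighter than real lysate data;
the calling examples therefore use the explicit 1.3 cutoff, and the
data-driven mode is exercised separately.

Only stabilization is called (FC above the cutoff); destabilized
proteins are reported with their statistics but never flagged, matching
the premise that binding raises thermal stability.

**Calibration.** The analytic recall bound for spiked targets combines
the noncentral-t power of the pooled test (ncp = log₂(shift)/(σ√(2/5)),
df 8) with the probability of passing the FC gate
(Φ((log₂shift − log₂1.3)/(σ√(2/5)))) via the Bonferroni lower bound
power_t + p_FC − 1 ≈ 0.9995 at shift 1.6. Acceptance compares observed
recall against this bound minus three binomial standard errors of the
finite target count. Recall is computed among targets that survive the
quality filters: the bound speaks to the statistical calling stage, and
left-censoring losses upstream of it are a property of the missingness
model, not of the test.

## Enrichment and interrogation

One-sided (greater) Fisher exact p-values come from the hypergeometric
survival function on the 2×2 table (k, n−k; K−k, N−n−K+k), BH-corrected
across tested sets. The default background is the quality-filtered
protein list of the experiment rather than the whole annotation — the
detectable proteome is the correct universe for a detection-based
assay — and is overridable. Gene symbols are upper-cased everywhere on
ingest because the public disease databases mix case conventions.

## Pooled deconvolution

Pools are consecutive blocks of the input panel order (deterministic
and auditable; the nine-ingredient fixture order reproduces the
canonical three groups). Readout errors in simulation are independent
Bernoulli flips per assay (fpr on true negatives, fnr on true
positives) — the simplest defensible model for a binary
stabilized/not-stabilized call. The decoder assigns (m, t) when m's
pool is round-1-positive for t and m is round-2-positive for t;
multiple supported molecules for one target are reported as an
ambiguity, never auto-resolved; a round-1-positive target with no
supported molecule is unresolved. With no noise and one binder per
target the decode is exact by construction (a pool is positive iff it
holds the binder; the binder alone re-screens positive), which the
randomized tests confirm; with false-negative rate f, a true edge
survives both rounds with probability (1−f)². Assay economy:
#pools + the number of molecules advanced to round 2.

## Melt curves

The melting model is the descending 3-parameter logistic with lower
plateau; since measured CETSA curves are normalized to the 37 °C point,
the fitted model is f(T)/f(T_min), which makes noiseless recovery exact
rather than biased by the normalization. Fitting is bounded
least-squares (Tm within the temperature range, slope ∈ (0, 50],
plateau ∈ [0, 1)) with a deterministic multi-start over Tm at base-2
van-der-Corput points of the range — nested start sets, so adding
restarts can only improve the best residual. Curves with dynamic range
below 0.2 (empirical or fitted) are flagged non-melters with no Tm
rather than returning a meaningless midpoint. ΔTm = Tm(treated) −
Tm(control); non-melter inputs raise an error directing qualitative
review.

## Problem sizes

The default validation sizes — 3000 proteins × 10 channels, 20 seeded
replicates for calibration, 50 randomized decoder panels up to 200
molecules, 200 noisy screens, 60-seed melt-curve Monte Carlo — were
chosen to put three binomial standard errors well below the margins
being tested while keeping the full suite and the acceptance script in
the minutes range on a single core.

## Known limitations

- Single-temperature calling cannot distinguish stabilization from
  expression change; the synthetic model has no expression confounder.
- TMM trim fractions and the IRS reference convention are package
  decisions where the assay protocol names only the methods.
- The variance–coverage construction (coverage of the FC distribution,
  cumulative log₂FC variance) is this package's operationalization of
  the thresholding device; published variants differ in detail.
- The Bernoulli pool-assay model ignores concentration dilution in
  pools and target-specific effect sizes. An end-to-end alternative —
  running `generate_itsa_experiment` + `run_target_pipeline` per assay
  unit and reading the target's flag as the readout — composes directly
  from the library but is not wired into the screen simulators.
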