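# Methods

This note documents the models, parameter choices and numerical conventions
behind `cortidyn`, and what the synthetic-data experiments do and do not
establish about real data.

## Synthetic cortisol profiles

Each profile is a sum of Bateman-type pulses, `A·(e^{−ke·Δt} − e^{−ka·Δt})`
for time-since-dose Δt ≥ 0, evaluated on the trial's 8-point grid
(0, 25 min, 2, 4, 8, 12, 16, 24 h).  TID doses at 0, 4 and 8 h; OD is a
single dose split into a fast pulse and a slow-release pulse
(`sustained_fraction` 0.6 at absorption rate 0.5/h), which reproduces the
qualitative dual-release shape: rapid morning rise, single peak, monotone
decline.

Defaults (units per field docstrings): absorption 2.0/h, elimination
0.35/h, slow-release absorption 0.5/h.  Dose scales (OD 2646.04, TID 932.46
nmol/L) are calibrated so the regimen-mean grid-trapezoid AUC_0-24h equals
the trial's reported means, 3851 (OD) vs 4698 (TID) nmol/L·h — an ~18%
exposure gap.  Patient heterogeneity is log-normal: a shared amplitude
multiplier per patient (geometric CV 0.2, matching the reported ~22%
between-patient CV of AUC) and per-patient rate multipliers (CV 0.08).
Assay noise is additive Gaussian (SD 15 nmol/L) truncated at zero.  The
trial does not publish inter-individual pharmacokinetic variability, so
these magnitudes are free, realistic choices rather than estimates.

The synthetic AUTO values (~0.47 OD vs ~0.14 TID) preserve the reported
*ordering* (OD smoother) but sit below the 0.7–0.95 range seen in patients:
an 8-point series anchored at a zero pre-dose baseline has less serial
memory than a real day-curve.  Only directions and relative spreads of
AUTO, never its absolute level, are used downstream.

## Exposure and variability metrics

AUC uses the trapezoidal rule; window endpoints off the grid (4 h→10 h
window on a grid with no 10 h sample) are linearly interpolated — the
minimal assumption that makes the reported window set computable.  Window
additivity holds to 1e-9 relative tolerance by construction.

AUTO is the standard biased sample ACF at lag 1, computed on the raw,
unevenly spaced series in sampling order.  The series is *not* resampled by
default (the statistic is "value at T vs value at T+1"); an optional
`resample_hourly` flag interpolates to an hourly grid first for users who
want interval-aware smoothing.  A constant series raises an explicit
zero-variance error rather than returning NaN.  AUC scales linearly under
concentration rescaling while AUTO is invariant — the two axes are
deliberately non-redundant.

## Synthetic metabolome

For each feature, log-abundance = intercept + βa·z(AUC) + βt·z(AUTO) +
Normal(0, noise_sd) per sample, exponentiated to a log-normal abundance.
Betas are zeroed by class (AUC-only / AUTO-only / both / none) and alternate
in sign across planted features so planted effects do not shift whole-sample
distributions.  Defaults: |β| = 0.8, noise_sd = 0.5, per-platform class
counts mirroring the trial's platform table (126 GC-MS serum, 209 targeted
LC-MS serum, 1938 untargeted LC-MS serum, 143 targeted LC-MS urine, with
correlated/overlap proportions as reported).  Serum platforms emit one
sample per patient × period × timepoint (8 per period, 288 samples for 18
patients); urine one 24-h sample per patient × period.  All serum samples of
a period share that period's single AUC/AUTO value.

Intercepts are Normal(5, 3) on the log scale so baseline abundances span
several decades, as mass-spectrometric intensities do; this matters for
quantile normalisation (below).  Missingness is left-censored: each
feature's lowest values (a Binomial(n, missing_rate) count, default rate
0.02) fall below its detection limit.  That is the mechanism the standard
min-positive/5 imputation assumes; missing-completely-at-random entries
would turn imputation into large spurious outliers.

Identified features (GC-MS, targeted LC-MS) carry ids from the packaged
synthetic pathway library: AUC-only and AUTO-only features are seeded into
designated pathways (arginine-like and bile-acid-like for serum;
ascorbate-like and taurine-like for urine), and ~35% of the remaining
features receive other library ids (`hmdb_coverage`) — a minority, as in
real annotation — so mapped hit lists retain contrast against the library
universe.  Untargeted features get mass@retention-time labels, id level 2,
and no database id; they are associated but barred from pathway analysis.

What the generator does *not* emulate: real metabolite dynamics within a
day (per-timepoint values vary only by noise around a period-level mean),
technical batch/run-order effects, correlated metabolite modules, or
realistic annotation error.  Passing recovery tests therefore validate the
pipeline's statistical machinery, not its behaviour under those additional
real-data complications.

## Preprocessing chain

Per platform, in order: (1) missing/zero entries replaced by the feature's
minimum positive value / 5 (features with no positive values dropped and
logged); (2) relative-standard-deviation filter — default removes the
lowest-RSD 10% of features (`keep_fraction` 0.9), a threshold mode is also
available; (3) quantile normalisation of samples onto the mean sorted-value
vector, ties receiving the mean of the tied reference positions; (4) natural
log, then per-feature autoscaling to mean 0 / sample SD 1 (ddof 1).  The
state machine raw → filtered → normalized → scaled prevents out-of-order
application; every drop carries a reason code; the chain is deterministic.

**Quantile-normalisation caveat.**  QN assumes distributional differences
between samples are technical.  When a large fraction of features shift
strongly with the same covariate, a feature's rank displacement is inherited
by its neighbours, so *null features acquire real covariate dependence*.
Under the default planted design (~43% of features carrying |β| = 0.8), the
planted-null significance rate at the 89% HDI roughly doubles relative to
its nominal ~11% (`analysis/07_qn_signal_transfer.py` quantifies this, and
the platform count tables of a full run show the inflated overlap).  QN is
kept in the default chain for fidelity to standard practice, and is
switchable (`quantile=False`); validation experiments that measure the
association stage against planted truth disable it.

## Association model

Each autoscaled metabolite y is modelled as y = α + βa·z(AUC) + βt·z(AUTO) +
ε, ε ~ N(0, σ²), fitted by exact conjugate normal–inverse-gamma sampling:
slope priors Normal(0, 2.5²·σ²) on z-scored predictors (numerically the
weakly-informative default of Bayesian GLM toolchains once the response is
autoscaled, σ ≈ 1), intercept prior scale 10, vague InvGamma(0.01, 0.01) on
σ².  Exact draws (default 4000, seeded per feature × predictor via spawn
keys) replace MCMC: identical model family, no convergence tuning.

Significance: the 89% HDI of the slope — the shortest contiguous interval
containing ⌈0.89·n⌉ sorted draws — excludes 0.  Classification: significant
for both predictors → *overlap*; for one → *unique_AUC* / *unique_AUTO*;
neither → *none*.  No multiplicity correction is applied across metabolites,
matching the source analysis.

**Joint fit as default.**  AUC and AUTO co-vary with the regimen
(r ≈ −0.3 to −0.4 across patient × periods), and serum predictors repeat 8×
per period.  In separate univariate per-timepoint fits, the chance
cluster-level correlation between predictors (SD ≈ 1/√35 across 36
patient × periods) is scaled by β while the model's iid standard error
shrinks with all 288 samples, so a metabolite driven by one predictor is
flagged for the other roughly half the time — the unique/overlap partition
collapses.  The two-predictor model makes "uniquely correlated" a partial
effect and restores calibration; the univariate mode remains available
(`joint=False`).  Whether the source analysis fitted the predictors jointly
or separately is not documented; the joint reading is this package's choice.

**Calibration ceiling.**  Even a perfectly calibrated 89% interval excludes
a true-zero slope ~11% of the time, so a planted single-predictor feature
lands in *overlap* at ≥11% and expected unique recovery is ~89%, slightly
less under the right-skewed AUC distribution (high-leverage patients).
Observed over five seeds on trial-shaped cohorts: ~91% for AUC-only, ~88%
for AUTO-only, with planted-null significance rates ~12% per predictor.

## Pathway analysis

Hit lists are the requested class's features with id level ≤ 1 and a
database id in the library universe, deduplicated across platforms; serum
and urine are analysed separately.  Fewer than three mapped metabolites is a
refusal, not an empty result.  Enrichment is the exact hypergeometric
upper tail P(X ≥ hits) with the full library universe as reference (a
detected-only universe is a flag).  Impact is the hit members' share of
total relative betweenness centrality in the pathway graph — betweenness
normalised by (n−1)(n−2)/2, zero for graphs under 3 nodes — treating edges
as undirected, since GMT+SIF fixtures do not carry reliable directions;
edgeless pathways get impact 0 and are excluded from significance by the
impact > 0 rule.  FDR is Benjamini–Hochberg across the pathways tested in
one run.  The packaged 12-pathway library is synthetic (invented ids, named
after the kinds of pathways this analysis surfaces) and exists so the
machinery is testable without redistributing curated pathway content.

## Crossover statistics

Within-patient OD−TID differences feed three tests, all two-sided at .05,
zeros dropped and counted: Wilcoxon signed-rank with an exact tie-safe
sign-flip null (dynamic programming over doubled midranks) up to n = 25 and
a tie-corrected normal approximation beyond; an exact binomial sign test;
and a difference-of-means permutation test between sequence groups, exactly
enumerated when the number of splits is ≤ 20,000 and otherwise seeded
Monte-Carlo with the observed split counted.  Two-sided p-values double the
smaller tail, capped at 1.

## Problem sizes and numerical conventions

Validation experiments use 18-patient cohorts with the trial-shaped platform
layout over five seeds (≈2400 features, ≈4800 fits per seed) — large enough
for sub-percent recovery standard errors while a full five-seed sweep runs
in well under a minute per stage on one core.  Direction-of-effect checks
use 50–200 patients.  Posterior draws default to 4000; HDI comparisons with
quantile oracles average endpoints over independent 10⁴-draw sets because a
single sample HDI has endpoint noise of the same order as the tolerance.
RSD keep-fraction counts use floor with a 1e-9 epsilon so 10% of 10 is 1;
RSD ties break by feature order (stable sort) for determinism.  All outputs
avoid timestamps so a rerun from the same config is byte-identical.

## Known limitations

- The synthetic cohort cannot reproduce the trial's actual metabolite or
  pathway p-values; those depend on the deposited raw data and the curated
  pathway library version.  The pipeline reproduces the *arithmetic* of the
  published summary tables and the *recoverability* of planted structure.
- No within-patient random effect is modelled in the association stage (the
  source analysis describes a plain GLM); with per-timepoint serum samples
  this understates uncertainty for cluster-constant predictors.
- Carry-over effects between crossover periods are not modelled.
- The lag-1 autocorrelation ignores interval lengths on the uneven grid by
  default; the hourly-resampling mode is provided but changes the statistic.
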