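# Methods

This note documents the models, estimators and design choices behind
`hrvalid`, in the spirit of a statistical package's methods appendix.  It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Protocol and transient-state segmentation

A protocol is an ordered, contiguous list of phases `(name, duration_s,
load)` with strictly positive durations; timestamps are integer seconds
from protocol start (0-based; ISO-8601 input is converted and sub-second
stamps floored).  The default protocol is sit 180 s, stand 180 s, walk
4 km/h 240 s, walk 6 km/h 240 s, walk 6 km/h + 5 % incline 240 s, stand
120 s (1200 s total), with phase-change times {180, 360, 600, 840, 1080} s.

Transition onsets are the protocol phase-change times, applied identically
to all subjects — segmentation is by design protocol-driven, never detected
from the HR signal, so device lag cannot shift the windows.  Each window
spans `[onset − pre_span, onset + post_span]`, default 10 s before to 60 s
after (70 s long).  Decisions:

* **Closed bounds on both ends.**  Keeps the 10 s pre-window samples and
  the last in-window second for every reporting cadence.  The steady
  label is the complement, so labels always partition the timeline.
* **Overlap tie-break.**  Windows can only overlap for unusually large
  spans (default gaps are ≥ 110 s); a timestamp in two windows goes to the
  earlier onset, with a warning.
* Windows are clipped to the protocol span; a single-phase protocol has no
  transitions.

## Synthetic cohort generator

The generator exists so the statistical machinery can be exercised against
known ground truth.  It emulates the *statistical structure* the analysis
assumes — not physiology or any vendor's firmware.

**Reference trajectory** (1 Hz "truth" per subject):

* First-order response `dHR/dt = (target(load) − HR)/τ`, discretised
  exactly at 1 s steps.  τ defaults to ~35 s (drawn per subject from
  N(35, 8²) clipped to [15, 60] s), producing the familiar rise/plateau
  morphology at each load step and an exponential recovery at the stop.
* An orthostatic pulse `A·exp(−(t−t₁)/τₒ)` fired at the sit→stand onset
  (the first boundary where load steps up from the protocol minimum),
  A ~ N(12, 4²) bpm clipped at 0, τₒ ≈ 20 s — the sharp standing peak that
  wrist devices tend to miss.
* Stationary AR(1) heart-rate variability with coefficient φ = 0.8 and
  stationary SD ~2.5 bpm.  AR(1) rather than white noise is deliberate:
  it makes per-second and 10 s-averaged errors genuinely different, which
  the resolution comparison needs.

Subject steady-state targets are nondecreasing in load by construction:
resting HR ~ N(70, 8²) truncated to [50, 95] bpm, plus nonnegative
per-load increments (means 8, 27, 20, 15 bpm for stand, walk 4, walk 6,
incline).  These magnitudes are ordinary for healthy adults walking at
4–6 km/h.

**Device observation model.**  At each scheduled report time `t` the
device emits the mean of the truth over `(t − lag, t]`, plus a constant
bias, plus Gaussian noise whose SD is `noise_sd_motion` inside transition
windows and `noise_sd_steady` elsewhere (the motion-artifact analogue);
samples are dropped independently with probability `dropout_p` and during
burst dropouts (Poisson bursts with exponential lengths); readings are
optionally rounded to integer bpm.  Schedules: fixed-interval (anchored at
t = 0, so a 1 s schedule with zero error reproduces the reference
exactly), once-a-minute, or jittered with inter-report gaps from a shifted
log-normal (σ = 0.9) calibrated to a (min, mean) pair and clipped to
(min, max) — matching reporting cadences described only by their range and
average.  Six stylised named profiles span a 1 s chest strap, 1–3 s and
1 s wrist trackers, two irregular ~10 s reporters and a 60 s reporter.

**Reproducibility.**  All randomness flows from one root seed through
per-(subject, device) derived streams (`SeedSequence` spawn keys; device
keys hash the device id), so adding a device or subject never perturbs
other series, and CSV export is byte-identical for identical seeds.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: waveform-level PPG/ECG artefacts, skin-tone or
placement covariates, vendor smoothing algorithms (the trailing-mean lag
is a stylised stand-in), circadian drift, and non-Gaussian error tails.
Conclusions about *devices* require real recordings; the synthetic cohort
validates the *pipeline*.

## Pairing

The reference grid always drives pairing; the device never defines it.

* **Per-second**: pairs at timestamps present (to 1 s) in both streams, no
  averaging.
* **Trailing window** (default 10 s): for each reference timestamp `t`,
  the device value is the mean of device samples in `(t − w, t]`.
  Half-open on the left so a sample at exactly `t − w` is not counted by
  two consecutive reference ticks.  `w = 1` s reduces exactly to
  per-second pairing.
* **Synchronized windows** (default 60 s): both streams averaged over
  `[kw, (k+1)w)` bins anchored at protocol t = 0 (the anchor is a
  convention; t = 0 is reproducible and subject-independent).

A pair is emitted only when both sides have data (pairwise deletion);
outliers are retained; nothing is interpolated or imputed.  State labels
attach at the reference timestamp for the two fine resolutions; 60 s
pairs carry no state, because a 60 s average cannot resolve a 70 s
transition — the pipeline refuses transition analyses at that resolution.
Missingness is the complement of paired over expected points, where
expected counts reference timestamps (or reference-occupied bins) across
the subjects with a valid recording for that device.

## Estimators

**Accuracy.**  MAE and MAPE are computed per participant (MAPE denominator
is the reference value of each pair — the device-vs-truth convention) and
summarised as median and IQR across participants, each subject weighted
equally regardless of pair count.  Quantiles use linear interpolation (the
common default; configurable).

**Random-intercept REML engine.**  Both mixed-model statistics reduce to
the model `y = Xβ + u_group + e` with a single random intercept.  The
variance ratio λ = σ_u²/σ_e² is profiled out: for fixed λ the GLS
estimates and residual variance are closed-form via per-group sums, and
the REML criterion is minimised over log λ on [−30, 30] by bounded scalar
search (xatol 1e−10).  This is exact, O(n) per evaluation, and fast
enough to sit inside a 1000-resample bootstrap.  A boundary fit
(σ_u² = 0) is detected by comparing against the λ → 0 criterion and
reported; the model then collapses to OLS.  The engine is cross-checked
against statsmodels `MixedLM` in the test suite.

**Bland–Altman via mixed model.**  Differences d = device − reference are
modelled with subject random intercepts; bias = μ̂ with a Wald test of
μ = 0, and LoA = μ̂ ± 1.96·√(σ̂_u² + σ̂_e²) (the standard 95 % multiplier).
At the σ_u² = 0 boundary this reduces, with a warning, to ordinary
pooled-SD limits.  All-identical differences degenerate to bias = c,
LoA = [c, c].

**Repeated-measures CCC.**  The stacked (reference, device) values are
modelled with a method fixed effect and a random intercept for every
measurement occasion (the subject × timestamp pair, nested in subject):

    rmCCC = σ_a² / (σ_a² + σ_e² + d²/2)

where σ_a² is the occasion variance — everything both methods track
together, between- *plus* within-subject — σ_e² the method-disagreement
residual, and d the fixed method difference.  Placing the intercept at the
occasion level is essential: with a subject-level intercept only, the
protocol-driven within-subject HR swing (~20× the between-subject
variance here) would be charged to σ_e² and a near-perfect device would
score near 0.  With one pair per subject the model reduces exactly to
Lin's closed-form CCC (asserted to 1e−6 in tests); device ≡ reference
gives 1; a growing constant shift drives the estimate to 0.  Because
variances are nonnegative, the estimator truncates at 0 for discordant
data rather than going negative.  Confidence intervals are percentile
bootstrap over subjects (default 1000 resamples, seeded) — that is where
the repeated-measures clustering enters the uncertainty.

**Repeated-measures Spearman.**  Ranks are computed on the pooled sample
per variable; the point estimate is the Pearson correlation of
subject-centred ranks (the common-slope ANCOVA estimate, equal to the
rmcorr estimator and cross-checked against `pingouin.rm_corr` in tests);
CIs by the same subject bootstrap with ranks recomputed per resample.
Within-subject-constant variables are an error.

**Wilcoxon signed-rank.**  Two-sided, paired by subject; pairs missing a
value on either side are dropped, zero differences are dropped (classic
convention; counts logged).  Exact null distribution for n ≤ 25 without
ties among absolute differences (verified against full 2ⁿ enumeration for
n ≤ 12), otherwise the tie-corrected normal approximation with continuity
correction; the switch point is configurable.  Pairwise device matrices
are symmetric with unit diagonal; cells with fewer than five usable
subjects are flagged untestable (NaN, never significant); the Bonferroni
divisor counts *all* unordered pairs so the adjusted α does not depend on
data loss: α/21 = 0.0024 at seven devices, α/15 = 0.0033 at six.

**Thresholds.**  Median MAPE ≤ 10 % or median MAE ≤ 5 bpm (boundary
inclusive) for acceptability; correlation bands weak (cc ≤ 0.5), moderate
(0.5 < cc < 0.7), strong (cc ≥ 0.7); concordance acceptability at 0.80.

## Pipeline conventions

Devices whose pair count at a resolution falls below `min_pair_ratio`
(default 0.25) × the median pair count across devices are excluded from
that resolution's statistics, with an audit log entry — this reproduces
the standard practice of dropping a once-a-minute reporter from
second-level statistics rather than comparing it on a handful of pairs.
Any device stream can serve as the reference (e.g. validating wrist
devices per-second against a 1 s chest strap).  Numerical outputs (CSV
tables, JSON manifest) are the determinism contract — identical config and
seed give identical manifests; figures (Bland–Altman scatters, notched
condition boxplots) are best-effort artifacts.

## Problem sizes and simulation designs

The replicate suites use 24-subject cohorts over the 1200 s protocol
(28 800 reference seconds per cohort).  Bland–Altman recovery injects
μ = 2 bpm, σ_u = 1, σ_e = 3 over 50 replicates of 24 subjects × 100 pairs;
the averaging-window and transient-degradation contrasts use 50-seed
suites in the tests (20 in the acceptance script); the condition-test null
uses a *flat* trajectory (all phase targets at resting HR, no orthostatic
pulse) with equal noise in both states, so the steady/transition labels
are exchangeable and the null truly holds — with the standard rising
trajectory, the MAPE denominator differs systematically between
conditions and the "null" would not be one.  The device-comparison null
uses two devices with identical error models on the same cohort.

## Known limitations

* The corruption model is a stylised stand-in for proprietary device
  processing; parameter profiles are illustrative, not vendor claims.
* The rmCCC estimator is one defensible variance-components reading of
  "repeated-measures concordance"; other estimators (e.g. U-statistic or
  GEE-based) can differ slightly on unbalanced data.
* LoA assume Gaussian between/within components; heavy-tailed device
  error widens true coverage relative to the nominal 95 %.
* No lag correction is applied before pairing (by design — the paired
  comparison evaluates the device as reported), so devices with long
  internal smoothing show inflated transient error at fine resolutions.
* R-R-interval (ms) error metrics are out of scope.
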