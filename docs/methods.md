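# Methods

`agiwear` implements a momentary-assessment analysis of wrist-wearable
physiology in a dementia-ward setting: nurse-submitted agitation surveys
anchor 6-minute windows over multi-modal sensor streams, each modality is
quality-controlled and summarized by a handful of interpretable statistics,
and the association between each statistic and momentary agitation is
estimated with logistic mixed models.  Because clinical ward data of this
kind cannot be shared, the package pairs the analysis with a synthetic
cohort generator that plants a known autonomic-activation signature, so
every stage of the pipeline can be verified end to end against ground
truth.

## Windows and data model

All sensor data are uniformly sampled single- or tri-channel series with
explicit NaN missingness (`SensorStream`); timestamps are seconds since
local midnight of day 1, since only local clock time enters the analysis.
For each survey a 6-minute window centered on the submission time is
extracted per modality.  Windows are half-open, `[t-180 s, t+180 s)`, so a
boundary sample is never counted twice; the bound convention is a package
choice (either convention is defensible) and is fixed here once.  A window
always carries its full nominal slot count (`duration x rate`); slots
outside the recording span count as missing, which makes "proportion
missing" well defined for quality control.

## Per-modality quality control

* **Acceleration (32 Hz, tri-axial).**  Per-sample magnitude
  `sqrt(x^2+y^2+z^2)` in g.  No quality gate is applied beyond dropping
  fully empty windows; the magnitude SD doubles as the movement confounder
  for the heart-rate models.
* **Heart rate (0.5 Hz, derived upstream from PPG; missing samples marked
  NaN).**  Interior gaps shorter than 10 s are filled with a centered
  rolling 10 s median over valid neighbors; remaining interior gaps are
  filled by cubic-spline interpolation through the valid samples.  Gaps
  touching a window edge have no surrounding data on one side and stay
  missing — extrapolation is never performed.  A window is dropped when at
  least 50% of its slots are missing *before* imputation ("the number of
  values that would need imputing"), which keeps the verdict monotone in
  missingness.
* **Skin temperature (1 Hz).**  A sample is valid when present and inside
  the closed physiological range 20–40 °C; the window is dropped when the
  valid fraction is <= 50%.  Features are computed on the valid samples
  only.
* **Electrodermal activity** — see below.

All thresholds live in `QcRuleSet` and are exposed in the pipeline
configuration.

## EDA branch

At the device rate (256 Hz) the signal is Savitzky–Golay filtered and
decimated to 8 Hz.  The filter parameters (order 2, 1 s window = 257
samples) are a package choice: the window is long enough to span several
ADC quantization steps yet shorter than an SCR rise time (~1 s), so
quantization staircase noise is suppressed without blunting responses.
Downsampling takes every 32nd filtered sample.

Signal quality is scored by a documented rule-based heuristic over 5 s
segments — a segment is unclean if it contains missing samples, values
outside 0.05–60 µS, sample-to-sample slopes above 10 µS/s, or is flat
(range < 0.001 µS, a detached-electrode signature).  The quality indicator
is the clean-segment fraction and windows below 0.5 are removed.  This
replaces a pretrained artifact classifier that cannot be redistributed;
the 0.5 decision threshold is retained, but numeric agreement with any
particular learned model is not claimed.  Unclean segments of kept windows
are repaired by cubic interpolation from flanking clean data (edge
segments are held at the nearest clean value).

The cleaned 8 Hz signal is decomposed as

    eda(t) = tonic(t) + (h * driver)(t),    driver >= 0,

with a unit-peak Bateman kernel `h(t) = exp(-t/tau_d) - exp(-t/tau_r)`
(defaults tau_r = 0.75 s, tau_d = 2.0 s, truncated at 20 s, configurable).
The tonic level is first estimated by a monotone (PCHIP) curve through
10 s-bin minima (inter-impulse troughs); the driver is then found by
nonnegative least squares on the residual with a small ridge (1e-6) for
conditioning, and the tonic is refitted on the SCR-free signal, for two
rounds.  The NNLS subproblem is solved by accelerated projected gradient
(FISTA) over the convolution operator, initialized with the kernel's exact
discrete inverse filter (a difference of two geometric decays has an O(n)
second-difference inverse), and finished by an exact active-set solve
restricted to the detected impulse support, whose Gram matrix is a kernel
autocorrelation lookup.  Driver entries below 1 µS/1000 are zeroed to keep
the impulse train sparse.  Solver non-convergence is never silent: it
raises by default and is recorded per window in the pipeline audit trail.
On noiseless traces generated with the same kernel the reconstruction RMSE
is below 0.01 µS and planted impulse timings/amplitudes are recovered
within ±0.5 s / ±10% (verified in the test suite).

## Features and standardization

Each kept window contributes min, max, median, mean and sample SD (n−1) of
its series — acceleration magnitude, heart rate, cleaned EDA, EDA tonic,
EDA phasic, and skin temperature — plus an OLS slope (°C/min) for skin
temperature only, capturing drift in this slow signal.  Every feature is
then centered and scaled within patient (all kept windows pooled), so a
coefficient reads as log-odds per within-patient SD; a patient with zero
variance or a single window contributes no usable value for that feature.
Patients with fewer than two kept surveys in a modality are excluded from
that modality's models only.

## Surveys and outcomes

Surveys carry four observer-rated agitation items (vocalization, motor,
aggression, resistance to care; 0–4 each) plus a sedation–agitation
rating that is carried through but not modeled.  Duplicates — a survey
within 5 minutes of the previously retained one — are removed by a
sequential per-patient scan keeping the earlier record.  Outcomes are
binary: overall agitation iff the item total exceeds 0, motor/verbal
agitation iff the corresponding item exceeds 0 (aggression and resistance
feed the overall outcome only).  Each survey is assigned a clock block
(1: 8–12 h, 2: 12–16 h, 3: 16–20 h, 4: 20–8 h wrap-around) used as a
categorical fixed effect for the diurnal (sundowning) pattern.

## Mixed models

For each feature and each outcome a separate model is fitted:

    y_ij | u_i ~ Bernoulli(logit^-1(b0 + b1 z_ij + time-block terms
                                    [+ confounder] + u_i)),
    u_i ~ N(0, sigma_u^2)

with a patient random intercept and no random slopes.  Confounders are
modality-specific: mean ambient temperature over the same window for EDA
and skin-temperature features, acceleration-magnitude SD for heart-rate
features, none for acceleration features.  Continuous confounders are
standardized within patient for comparability (configurable).  Time blocks
are treatment-coded against block 1.

The marginal likelihood integrates the random intercept per patient.  The
package maximizes a higher-order Laplace approximation: the usual
mode/curvature term plus the fourth- and sixth-order series corrections
(functions of the third- to sixth derivatives of the integrand's log at
the conditional mode).  With the small clusters this design produces, the
corrections tighten agreement with 25-node adaptive Gauss–Hermite
quadrature from ~1e-1 to ~1e-4 median (the quadrature implementation is
retained purely as an independent test oracle).  Optimization is L-BFGS-B
over (beta, sigma_u) with sigma_u bounded at zero, restarts from
sigma_u ∈ {0.5, 0.1, 1}; at sigma_u = 0 the objective reduces exactly to
plain logistic regression.  Standard errors come from the inverse observed
information (central finite-difference Hessian at the optimum; sigma_u is
profiled out of the block when it sits on the boundary), p-values from
Wald tests, uncorrected for multiple testing by design (an exploratory
screen).  Complete separation is detected via |beta| > 10 on standardized
predictors and flagged rather than reported as a valid Wald result;
optimizer non-convergence is flagged likewise.

Calibration, verified in the test suite at 25 patients x 20 surveys:
type-I error of the feature's Wald test within [0.03, 0.08] at alpha 0.05
(500 null replicates); planted beta = 0.5 recovered within [0.4, 0.6] and
sigma_u = 1 within [0.8, 1.2] on average (200 replicates).

## Synthetic cohort generator

The generator emulates the study design, not any patient's data:

* **Design.**  30 patients x 7 days (defaults); nine pseudorandom survey
  prompts/day in 08:45–20:45 with pairwise gaps >= 50 min (exact rejection
  sampling in vectorized batches), plus spontaneous surveys fired at
  episode midpoints with probability 0.15 — chosen so the overall agitated
  fraction lands near one quarter, a typical figure for ward cohorts with
  severe behavioral symptoms; the prompted/spontaneous mix is otherwise
  unconstrained and exposed in the config.
* **Episodes.**  Piecewise-constant-rate Poisson over the four clock
  blocks — base rate 1.1/h times sundowning multipliers (0.5, 1, 1.5, 2) —
  the simplest process yielding a monotone increase of agitation across
  the day.  Durations are lognormal with median 6 min (sigma_log 0.5),
  matching the motivating choice of the 6-min window; overlaps are thinned
  keeping the earlier episode.  Types are motor/verbal/both (0.45 / 0.25 /
  0.25, 5% untyped residual discarded).
* **Signals.**  Streams cover the daily wear period 08:00–21:00 (every
  possible survey window lies inside it), one stream per
  patient/modality/day so uniform sampling holds within each stream.
  Baselines: ACC magnitude ≈ 1 g with slow posture drift and white
  activity noise; HR 72 bpm with diurnal drift and AR(1) variability; EDA
  = smooth tonic (2 µS baseline) plus a Poisson SCR train (2/min) drawn
  with the same Bateman kernel the decomposition assumes, so recovery
  tests have an exact forward model (a config flag perturbs the kernel
  taus by 30% for robustness checks); ST near 32.5 °C coupled negatively
  to ambient-temperature deviation from 22 °C.  At the device EDA rate the
  signal is quantized to 1/128 µS steps so the filtering stage has real
  work to do; the 8 Hz switch emits the post-filter signal directly.
* **Planted effects.**  During episodes: tonic +1 µS, SCR rate +4/min,
  HR +10 bpm, ST −1.5 °C, ACC-magnitude SD +0.15 g, with smoothed onsets.
  Motor-type episodes scale movement/HR deltas by 1.5; verbal-type scale
  EDA deltas by 1.5 and movement by 0.25.  These magnitudes are strong,
  clean autonomic-activation responses: the generator is a verification
  harness, and passing its tests shows the pipeline recovers a signature
  that is genuinely present — not that effects of this size exist in real
  patients.
* **Missingness.**  HR samples go missing in bursts (alternating-renewal
  mask, 15% stationary fraction, 20 s mean burst); each survey has a 10%
  nonwear probability that blanks all wearable modalities in its window
  (the ambient sensor is wall-mounted and unaffected).
* **Determinism.**  Every patient-day draws from its own seed substream
  derived statelessly from the master seed, so identical configs produce
  identical cohorts.  High-rate ACC activity noise is drawn per survey
  window from a dedicated substream: the streaming analysis mode
  materializes ACC only inside the windows it consumes, yet produces
  sample-identical window contents to the full streams written to disk
  (asserted in the tests).

## What the generator does not emulate

Real wearable data have posture- and pressure-dependent EDA artifacts,
PPG-derived HR error correlated with motion, device clock drift, and
agitation episodes whose physiology varies across patients and episodes.
None of these are modeled.  Passing the end-to-end tests therefore
demonstrates internal correctness of the pipeline (windowing, QC rules,
decomposition, model fitting and inference are mutually consistent and
recover planted truth), not clinical validity on ward data.

## Problem sizes and numerical choices

The end-to-end checks run 20 replicate cohorts of 30 patients x 7 days
with the 8 Hz EDA path; statistical calibration uses 500 null and 200
effect replicates at 25 patients x 20 surveys.  Tolerances: EDA
reconstruction RMSE < 0.01 µS on noiseless traces; Laplace vs quadrature
agreement 1e-2 over random small instances; sigma_u -> 0 limit equal to
plain logistic regression within 1e-4; within-patient standardization
identities at 1e-12.  Ties and degenerate inputs: windows with fewer than
two finite samples raise; zero-variance features become missing; the
duplicate-survey rule keeps the earlier record; the visualization subset
orders patients by kept-survey count then id.

## Known limitations

* The EDA quality heuristic is a transparent stand-in with the same
  decision threshold as learned artifact classifiers, not a reimplementation
  of one; absolute keep rates will differ on real data.
* The tonic/phasic split is identifiable only up to the smoothness
  assumption on the tonic; the coarse-grid refit (10 s bins) can absorb
  very slow phasic activity.
* Laplace-based sigma_u estimates are mildly biased downward in very
  sparse designs; the recovery tests bound this at the study's design
  sizes.
* Wald p-values are reported unadjusted, by design; consumers screening
  many features should apply their own error control.
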