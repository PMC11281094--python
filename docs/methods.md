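# Methods

This note documents the models, estimators and numerical choices behind
`sixmwt`, what the synthetic-data generator does and does not emulate, and
the known limitations.

## Signal model and preprocessing

A 50 Hz ankle accelerometer measures gravity plus gait acceleration on
three axes (x mediolateral, y vertical, z anteroposterior).  Gravity is
taken to be the output of a causal second-order Butterworth low-pass with
cutoff f_c = 0.2 Hz (bilinear design at normalized cutoff 2·f_c/f_s; unit
DC gain, −3 dB at f_c), and gait acceleration is the residual, so the two
components always reconstruct the input exactly.  The recursion is run
with its internal state initialized to the steady state of the first
second's mean — exact for constant input, and insensitive to the noise of
any single sample.  The first 1 s of each recording is excluded from
analysis as filter warm-up.

Gait acceleration is smoothed per axis by a Kalman filter with
constant-acceleration state (position, velocity, acceleration),
transition F = [[1, dt, dt²/2], [0, 1, dt], [0, 0, 1]], dt = 1/f_s, and
acceleration as the only observation.  The noise magnitudes are not part
of the published design, so they are set as: process-noise intensity
q = 1e-2 (m/s²)² shaping covariance q·G·Gᵀ with G = (dt²/2, dt, 1)ᵀ, and
measurement variance r estimated from the data as var(first difference)/2
(the first difference of a noise-dominated signal has twice the noise
variance).  Both are configurable.  At these defaults the smoother behaves
like a light exponential smoother of acceleration (≈ 50 ms lag at 2 Hz),
enough to suppress sample noise without displacing step peaks.  Kalman
positions and velocities are diagnostic only: distance is *never*
integrated from acceleration; it comes from the lane geometry.

## Turn segmentation

U-turns at the lane ends show up as bursts of mediolateral energy.  The
detector is deliberately scale-free:

- remove a slow x baseline with an 8 s moving **median** (a moving mean
  smears the 2 s turn burst across the window; the median ignores it).
  Within half a window of the trace edges the median is clamped to the
  nearest fully-covered window, since shrunken/padded windows are
  dominated by whatever touches the edge;
- compute a 1 s moving RMS (edge-aware normalization) and threshold it at
  median + 2·MAD over the whole trace;
- reject runs whose peak is below median + 8·MAD: with a turn contrast of
  ≥ 3× the straight-walk RMS the genuine turns sit ≈ 30 MADs above the
  floor, while noise excursions rarely exceed ≈ 5;
- refine each surviving run to the contiguous region around its peak that
  stays above threshold + 0.15·(peak − threshold), floored at 0.30·peak.
  The refinement undoes the ± half-window inflation of a plain threshold
  crossing; anchoring at the peak makes it immune to isolated spikes; the
  floor keeps the level meaningful when the noise floor (hence the MAD) is
  ~0;
- runs shorter than 0.8 s are dropped, runs separated by less than 3 s of
  "straight walk" are merged (no lane can be walked in under 3 s).

Straight walks are the complement; segments tile the trace with
alternating labels, and a trailing straight walk not followed by a turn is
the final partial lane.  On simulated walks at default noise the detected
turn boundaries are within ≈ 0.2 s of truth.  Two structural caveats: the
adaptive threshold presumes straight walking dominates the recording (true
of any real 6MWT — a trace that is all turn-level activity yields a single
straight-walk segment); and a trailing turn cut short by the 6-minute
clock is only partially observed, so its detectability and boundary
accuracy degrade with how little of it was recorded.

## Gait parameters

Within each complete straight walk:

- **cadence** is the frequency of the largest spectral magnitude of the
  mean-removed, Hann-tapered vertical gait acceleration, zero-padded to a
  grid of ≤ 0.02 Hz, searched in the 0.5–4 Hz band.  One ankle sensor
  registers both feet's impacts, so this is step (not stride) frequency,
  ≈ 2 step/s in healthy elderly walkers;
- **steps** are peaks of the vertical signal band-passed around the
  spectral cadence ([0.55, 1.6]·SC): the narrow band isolates the step
  fundamental, whose peak count equals the impact count, where a fixed
  wide band would keep enough second harmonic (up to ~0.9× the
  fundamental for sharp impacts) to create secondary maxima.  Peaks must
  be ≥ 0.5/SC apart with prominence ≥ 1 MAD of the filtered segment;
- **stride length** is lane length / step count (20 m default), **gait
  velocity** is SL·SC from the per-test means over complete lanes, and
  **distance** is 6MWD = lane·p + SL·q.  A complete lane with no
  detectable steps is excluded from the SL/SC means but still counts in p
  (the lane was walked).  The final partial lane contributes its q steps
  to the distance only.

## Energy expenditure

BMR comes from the gender-specific Harris–Benedict equations [kcal/day],
the walking MET from the linear model MET = 0.832·GV − 0.016·W − 0.196·G +
1.034 (G = 1 male, 2 female), evaluated verbatim — it is not floored at
1.0, so very slow walkers can score below resting level.  The walking
energy is (BMR/24)·MET·duration with duration 0.1 h for a six-minute test,
reported in kcal/h convention.  A known inconsistency is documented here
rather than patched: applying these equations to the source cohort's
published group-mean anthropometrics yields 6MWEE values several-fold
smaller than that cohort's tabulated 6MWEE (≈ 5.5 vs ≈ 21.5 kcal/h for the
non-frail group); the cohort-level energy computation is not
reconstructible from the printed equations under any unit reading we
found.  Consequently the published WMS sigmoid (centered at 18.388, where
the energy term dominates the index) is calibrated for the tabulated
energy scale, and pipeline-computed 6MWEE values will score low on it.
The synthetic cohort generator therefore draws 6MWEE from the tabulated
distributions directly, and refitting (a, b) is recommended whenever the
index is built from pipeline-computed energies.

## Frailty scoring and the range map

The five-item phenotype scores weak handgrip (< 26 kg men, < 18 kg women),
slow five-meter walking speed (< 1.0 m/s) and three questionnaire items;
n ≥ 3 is frail, 1–2 pre-frail, 0 non-frail.  The (SL, SC) plane is cut at
0.6 m/step and 2.0 step/s — the rounded published cutoffs, not re-derived
ones — with Range I requiring both parameters strictly above cutoff and
Range III both at-or-below (the published inequality conventions; II and
IV inherit accordingly).  ROC cutoffs maximize Youden's J, with ties
broken toward the score median; AUC is trapezoidal and equals the
pair-counting statistic.  Group comparisons screen each group with
Shapiro–Wilk (skipped below n = 3) and use Student's t-test for normal
pairs and one-way ANOVA otherwise, with Cohen's d pooled by n−1 weights.

## The WMS index and scale

SL, SC and 6MWEE co-vary strongly along one axis.  The default refit
(`fit_wms_line`) mean-normalizes the three parameters, takes the first
principal axis of the centered cloud (total least squares), orients it so
stronger walkers score higher, and re-expresses the projection as a linear
form in the raw parameters; the reported r is the square root of the
variance fraction carried by the axis.  Because the published description
also mentions multiple regression, an OLS variant is available behind
`method="ols"`, which requires an explicit response (e.g. 6MWD) since no
response is named in the source.  Neither estimator claims to reproduce
the published coefficients — the original 60-subject data are not
distributed.

The sigmoid S(WMS) = 1/(1+exp(−a(WMS−b))) is fitted by nonlinear least
squares against binary labels 1{6MWD ≥ 400 m} with a > 0, initialized at
a₀ = 4/IQR(WMS), b₀ = median(WMS), tolerances 1e-10.  The scale is WMS1
(S < 0.01), WMS2 (0.01 ≤ S < 0.50), WMS3 (0.50 ≤ S ≤ 0.95), WMS4
(S > 0.95); the published strict ">" of the top boundary fixes the
inclusivity of 0.95 (level 3), and the symmetric convention is applied at
0.01 (level 2).

## Synthetic data

`simulate_6mwt` generates the measurement model the pipeline assumes:
constant gravity along a configurable orientation; one raised-cosine
impulse (0.15 s wide, 3 m/s², Gaussian optional) per step on the vertical
axis at the set cadence; a small forward oscillation; U-turns every
round(lane/stride) steps as a half-sine mediolateral swing (amplitude
max(1.5, 3·noise) m/s²) with step rate reduced 20% and a half-step
deceleration margin before straight walking resumes; white Gaussian
sensor noise (0.3 m/s² default) on all axes; and a 1 s standing lead-in
matching the pipeline's warm-up crop.  Ground truth carries step times,
segment boundaries, per-lane step counts and the implied SL/SC/GV/6MWD.
Fixed seed gives byte-identical output.

`simulate_cohort` draws (SL, SC, 6MWEE, 6MWD) per group from Gaussians
whose defaults are the published frail / pre-frail / non-frail means and
SDs (group sizes apportioned 8:23:29), with a configurable common
correlation (0.4 default), and frailty items drawn consistently with each
group's category.

What the generator does *not* emulate — and therefore what passing
recovery tests do not show about real data: biomechanical step-shape
variability (every impact is the same pulse), cadence drift and rest
pauses within a test, sensor drift and axis misalignment, double-support
asymmetries between left and right ankles, and any dependence of turn
style on frailty.  Recovery results on synthetic walks are a correctness
check of the estimator chain, not a clinical validation.

## Problem sizes and numerical conventions

The recovery suites use 100 simulated tests of 120 s (full 360 s tests are
exercised end-to-end separately) — at these sizes the whole test suite
runs in well under a minute per suite.  Sampling-based assertions pin
their generators to fixed seeds.  Times are seconds from test start;
intervals are half-open [start, end); sample indexing is 0-based.  Two
ankle traces for one subject are analyzed independently and reported per
sensor; no cross-sensor fusion is attempted because none is defined by the
method.

## Known limitations

- Stride length is a per-lane mean (lane / step count); no per-step
  lengths, gait symmetry, stance/swing phases or variability metrics.
- The segmentation detector needs a clear mediolateral turn contrast; a
  walker who pivots without leaning (or a sensor worn off-axis) degrades
  turn detection, and with it p, q and 6MWD.
- The published WMS coefficients, cutoffs and AUCs cannot be reproduced
  without the original cohort; the package verifies internal consistency
  of the published constants and recovery of refit parameters on
  synthetic cohorts instead.
- The energy-scale mismatch described above means absolute WMS levels from
  pipeline-computed energies are conservative (shifted toward WMS1) under
  the published sigmoid.
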