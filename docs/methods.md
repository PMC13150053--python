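# Methods

## Signal model of the synthetic cohort

Each simulated trial carries two latent durations whose sum is the
reaction time, exactly: a premotor interval (stimulus onset to LRP
onset) and a motor interval (LRP onset to button press).  Subject-level
means are driven by standardized age through the path coefficients of
the dual-mediator model; age is uniform on 14–19 years (z-scored within
sample, reproducing an age SD near 1.7), sex is Bernoulli(0.686 female)
and affects RT only.

Because RT is the exact component sum, the direct age path and the sex
path cannot act "outside" the two intervals; their standardized
contributions, scaled by the cohort RT SD implied by the component SDs
(√(42² + 38²) ≈ 56.7 ms), are carried on the motor interval.  This is a
structural property of exact fractionation, not an implementation
convenience: any variance in RT must live in one of its parts.

Trial-to-trial variability is ex-Gaussian with defaults σ = 40 ms
(split evenly between the two intervals) and τ = 50 ms assigned to the
premotor interval, where sequential-sampling accounts place RT skew.
The exponential component is centered so subject means are preserved.
Trials slower than the 1000-ms response window become omission errors;
button errors occur at rate 0.12 (the task's observed average error
rate).

The rendered EEG (500 Hz; C3, C4, two mastoids, VEOG, HEOG) contains:

* a lateralized linear ramp on the hemisphere contralateral to the
  responding hand, onset exactly at the trial's premotor duration,
  peaking (−3 µV) at the response and decaying over 200 ms — the double
  subtraction therefore yields a positive LRP of ~6 µV peak;
* a common-mode 10 Hz background (4 µV) and a bilateral stimulus-evoked
  bump (5 µV), identical on C3 and C4, which cancel exactly in the LRP;
* channel-independent band-limited (≤30 Hz) Gaussian noise, default
  4 µV RMS.  This parameter is the *lateralized* residual: scalp EEG is
  strongly spatially correlated, so the independent part of C3 vs C4 is
  much smaller than the per-channel background (which the common-mode
  terms supply);
* blink (150 µV, 0.08/s) and saccade templates on VEOG/HEOG with
  propagation 0.08 / 0.02 into the scalp channels.

What the generator does **not** emulate: volume conduction through a
head model, 1/f spectral shape beyond band-limiting, eye-movement
physics, or non-stationary artifacts.  Passing tests therefore show that
the pipeline recovers the latent structure the model encodes, not that
it is robust to every property of real recordings.

Artifact injection constructs minimal offenders for the four rejection
rules — a 120 µV smooth bump (absolute amplitude), a ±93 µV swing inside
100 ms (peak-to-peak), an 80 µV adjacent-sample jump (voltage step,
40 µV/ms at 500 Hz), and a 150-ms flatline — each placed in a distinct
trial's post-stimulus window.

## Preprocessing

Fixed order: re-reference to averaged mastoids → 0.1–30 Hz second-order
Butterworth applied forward–backward (zero phase; the bidirectional pass
doubles the effective roll-off) → 60 Hz IIR notch (quality factor 30,
narrow enough to spare the 30 Hz band edge) → removal of error trials →
segmentation (stimulus-locked −200..600 ms, baseline −200..0; response-
locked −1000..200 ms, baseline −1000..−800) → regression-based ocular
correction → baseline correction → artifact rejection.  Baseline
correction follows ocular correction because correction changes offsets.

Milliseconds convert to samples by rounding half away from zero and
windows are half-open [start, end), so the 800-ms stimulus window is
exactly 400 samples at 500 Hz.

Ocular correction estimates VEOG/HEOG propagation on residuals after
subtracting the per-condition event-related average from every channel
(preventing stimulus-locked activity from leaking into the factors),
then subtracts propagation × raw EOG from the raw EEG.  Zero-variance
EOG yields zero factors with a warning.

Rejection flags a trial when any criterion fires on any scanned channel
(default: all EEG channels, excluding EOG and mastoid/reference
channels, which would otherwise trip the low-activity rule on quiet
recordings): |x| > 100 µV; moving-100-ms peak-to-peak > 175 µV;
adjacent-sample step > 30 µV/ms; moving-100-ms range < 0.5 µV.  Windows
advance one sample at a time.

## Onset scoring

Peaks are the positive extrema in 200–500 ms (stimulus-locked) and
−200–100 ms (response-locked), ties to the earliest sample.  Onset is
the SSE-minimizing breakpoint of the flat-then-rising two-segment model
over the interval from the baseline start to the peak, searched at every
sample (no subsample interpolation), earliest breakpoint on ties.
Response-locked latency is reported as a positive duration before the
button press.  An all-constant waveform has no defined onset and returns
a flagged estimate.

Two properties of this estimator matter for interpretation:

* **Latency jitter biases onsets early.**  The average of ramps with
  jittered onsets rises from the *earliest* onsets; under symmetric
  jitter the fitted rise's extrapolation still crosses the baseline near
  the mean, but skewed (ex-Gaussian) jitter moves the breakpoint toward
  the mode of the onset distribution — with the default τ = 50 ms this
  is roughly −40 ms on the stimulus-locked side.  The shift is nearly
  uniform across subjects, so between-subject correlations with truth
  survive (~0.8), while absolute S-LRP means sit below the mean premotor
  duration.  Response-locked onsets are unaffected (motor jitter is
  symmetric).
* **Noise biases breakpoints slightly early.**  An early breakpoint
  costs less SSE than a late one on a noisy rise; at the default noise
  and 300 trials the measured stimulus-locked bias is about −6 ms
  (response-locked ≈ 0), with subject-level correlation to truth ≈ 0.88
  (0.91 response-locked) over 200 subjects.

## Behavioral cleaning

Per subject, in one pass: drop error trials; drop RT < 100 ms; drop
RT ≥ mean + 3 SD where mean/SD come from the trials surviving the first
two steps (upper tail only, no re-iteration — iterating would be a
different estimator).  Zero spread makes the fence vacuous and removes
nothing.  Accuracy uses all administered trials as denominator.  The
chance-performance exclusion threshold is the exact binomial tail:
min{k : P(Bin(n, ½) ≥ k) ≤ α}/n, which at n = 300, α = .01 is 171/300 =
57%.  Cohort-level vectors are winsorized two-sided at 3 sample SDs
(single-pass fences), replacing each outlier with the most extreme
non-outlying value on its own side.

## Cohort inference

Pearson correlations are tested with t = r√((n−2)/(1−r²)).  Two
correlations sharing a variable are compared with the
Meng–Rosenthal–Rubin z for overlapping correlations (an independent-
samples Fisher z is available; the dependent form is the default).
Commonality analysis decomposes the two-predictor regression R² into
unique and common parts from the three hierarchical regressions; a
negative common component is a legitimate suppression artifact and is
reported as such.  The trial-level linear mixed model (statsmodels
MixedLM) fits age × compatibility × sex with random intercepts and
compatibility slopes by participant; compatibility is coded ±0.5, sex
centered, age standardized; accuracy is modeled linearly on trial
correctness, mirroring the reporting convention of the analysis this
package implements.  Variance explained is summarized Nakagawa-style
(marginal = fixed effects; conditional = fixed + random).

## Path model and power

All five observed variables are z-scored (which also mean-centers the
mediators), so coefficients are the standardized solution.  The model is
recursive, hence estimated by equation-wise OLS — identical point
estimates to an ML SEM optimizer for this structure, fully auditable and
deterministic; a statsmodels OLS route cross-checks the estimates in the
tests.  Indirect-effect inference uses the delta method,
SE(ab) = √(a²SE_b² + b²SE_a²).  Under the joint null a = b = 0 this test
is strongly conservative (the product z concentrates near zero); its
size approaches the nominal α only when one path is clearly nonzero —
both regimes are asserted in the tests.

Global fit is evaluated against the 5-variable covariance with the
sex→mediator paths fixed at zero (15 observed moments, 13 free
parameters, df = 2): χ² = (n−1)·F_ML, RMSEA (0 by convention at df = 0),
SRMR over the unique standardized residuals, and CFI/TLI against the
independence baseline.

Monte Carlo power draws cohorts from the multivariate normal implied by
the standardized parameterization (residual variances solved so every
variable has unit variance; a parameterization that over-explains RT
variance is rejected as a configuration error), refits per replicate,
and counts significant delta-method z tests.  The sex covariate is
included by default (standardized path 0.221) and can be toggled.  At
the study parameterization (a_S = −0.09/0.41, a_R = 0.02/0.23,
b_S = 0.41, b_R = 0.23, c = −0.08, ψ-corr = −0.12, n = 194, 5000
replications) the package computes ~85% power through the premotor path
and ~12% through the motor path; `scripts/acceptance.py` reproduces
these numbers from a seed.

## Problem sizes and numerical choices

The test suite exercises the full EEG chain at 200 subjects × 300 trials
for the recovery property and smaller cohorts elsewhere; power checks
use 400–2000 replicates and the acceptance script 5000.  Randomness
flows from a single root seed through named `SeedSequence` substreams
per stage, so trial tables are independent of whether EEG is rendered,
and reruns are bit-identical.  Ties in peak picking and breakpoint
search resolve to the earliest sample; filters validate band edges
against Nyquist; BrainVision data are float32, so round-trips are exact
to quantization (< 10⁻³ µV at scalp amplitudes).

## Known limitations

* Single-subject onset scoring inherits the jitter and noise biases
  described above; no jackknife or fractional-area alternatives are
  provided.
* The generator's rejection rate is ~0% unless artifacts are injected:
  rendered blinks propagate at 0.08 and stay under the 100 µV rule, so
  the empirical 4.1% rejection rate of real recordings is not emulated
  by default.
* The accuracy mixed model is linear, not logistic, by design (matching
  the reporting convention being implemented).
* Commonality analysis is implemented for the two-predictor case only.
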