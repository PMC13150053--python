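# lrpfrac

Fractionation of choice reaction time into premotor and motor intervals
using the lateralized readiness potential (LRP), with the full inference
chain that sits on top of it: cohort simulation with known ground truth,
ERP preprocessing, single-subject onset scoring, behavioral cleaning,
commonality analysis, a dual-mediator path model, and Monte Carlo power.

## The problem

In a two-choice task, reaction time (RT) bundles together stimulus
evaluation, response selection, and motor execution.  The LRP — the
double-subtraction difference of motor-cortex activity over C3 and C4 —
isolates hand-specific response activation, and its onset splits every
subject's RT into two interpretable pieces:

* **S-LRP latency**: stimulus onset → LRP onset.  Premotor processing
  (stimulus evaluation + response selection).
* **R-LRP latency**: LRP onset → button press.  Motor processing.

With the double subtraction

```
LRP = (C3 − C4)_left-hand − (C3 − C4)_right-hand
```

contralateral motor negativity yields a positive-going LRP, so peaks are
maxima.  Onset is scored per subject by segmented regression: the
waveform from the baseline to the peak is modeled as a flat pre-onset
level followed by a straight rise, continuous at the breakpoint τ; the
τ minimizing the least-squares error is the onset (the pre-onset slope
is fixed at zero, leaving τ as the single structural degree of freedom).

Downstream, the package asks the developmental question this design
supports: in an adolescent cohort (ages 14–19), does age reach RT through
the premotor or the motor interval?  The dual-mediator path model

```
S = a_S·age + e_S
R = a_R·age + e_R          cov(e_S, e_R) = ψ
RT = c·age + b_S·S + b_R·R + β_sex·sex + e_RT
```

is recursive, so maximum-likelihood point estimates coincide with
equation-by-equation OLS.  Indirect effects are the products a·b with
delta-method standard errors; the total effect is exactly
c + a_S·b_S + a_R·b_R.  Power for each indirect effect is estimated by
Monte Carlo: draw cohorts from the model-implied multivariate normal,
refit, and count significant delta-method z statistics.

## Worked example

One command simulates a small cohort, renders and preprocesses its EEG,
scores latencies, and fits the full chain:

```bash
lrpfrac run-all --out demo/ --seed 7 --subjects 20 --trials 100 --power-reps 1000
```

which prints (among other artifacts written to `demo/`):

```
{
  "mean_rt_ms": 367.0253973273615,
  "s_lrp_ms": 150.7,
  "r_lrp_ms": 181.8
}
{
  "power_s": 0.149,
  "power_r": 0.025,
  ...
}
```

The first block is the retained cohort's mean RT and mean scored S-/R-LRP
latencies in ms; the second is the Monte Carlo power of the two indirect
effects **at the demo's own size** (n = 20), which is naturally low.  At
this small scale the single-subject onsets are noisy and the skewed
trial-latency jitter shifts stimulus-locked onsets early (see
`docs/methods.md`); the recovery tests in `tests/test_lrp.py` show the
scorer tracking ground truth at the full study scale (200 subjects × 300
trials).

Every stage is also exposed individually (`simulate`, `preprocess`,
`score`, `behavior`, `mediate`, `power`) and as library functions, e.g.:

```python
from lrpfrac import PathParams, monte_carlo_power
res = monte_carlo_power(PathParams(), n=194, n_reps=5000, seed=1)
print(res.power_s, res.power_r)   # 0.850 0.115
```

## Layout

```
src/lrpfrac/
  synthetic.py    cohort generator: latent premotor/motor durations, EEG
                  rendering, artifact injection
  io.py           BrainVision (.vhdr/.vmrk/.eeg) writer/reader, HDF5 epochs
  preprocess.py   re-reference, 0.1–30 Hz zero-phase Butterworth, 60 Hz
                  notch, segmentation, Gratton-style ocular correction,
                  four-rule artifact rejection
  lrp.py          double subtraction, peak picking, segmented-regression
                  onset scoring
  behavior.py     RT trimming, summaries, binomial chance exclusion,
                  winsorization
  stats.py        Pearson matrix, dependent-correlation z, commonality
                  decomposition, trial-level mixed model
  mediation.py    path model, fit indices, Monte Carlo power
  pipeline.py     orchestration; cli.py: `lrpfrac` subcommands
```
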