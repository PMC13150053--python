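"""Double subtraction, peak picking, and segmented-regression onsets."""

import numpy as np
import pytest

from conftest import make_epochs
from lrpfrac.lrp import (
    LRPWaveform,
    ScoreConfig,
    derive_lrp,
    estimate_onset,
    find_peak,
    score_subject,
)

FS = 500.0


def _wave(amplitude, t0=-200.0):
    n = len(amplitude)
    return LRPWaveform(
        lock="stimulus",
        time_ms=t0 + np.arange(n) * 1000.0 / FS,
        amplitude_uv=np.asarray(amplitude, float),
        n_left_trials=10,
        n_right_trials=10,
    )


# ---------------------------------------------------------------------------
# derive_lrp


def test_constructed_hand_difference():
    n = 400
    data = np.zeros((4, 2, n))
    hands = ["left", "left", "right", "right"]
    data[:2, 0] = 2.0  # C3 - C4 = +2 on left-hand trials
    data[2:, 0] = -2.0  # C3 - C4 = -2 on right-hand trials
    ep = make_epochs(data, hands=hands)
    wave = derive_lrp(ep)
    np.testing.assert_allclose(wave.amplitude_uv, 4.0)


def test_common_mode_cancellation(rng):
    n = 400
    data = rng.normal(size=(6, 2, n))
    hands = ["left", "right"] * 3
    ep = make_epochs(data.copy(), hands=hands)
    base = derive_lrp(ep)
    common = rng.normal(size=n)
    data[:, 0] += common
    data[:, 1] += common
    ep2 = make_epochs(data, hands=hands)
    np.testing.assert_allclose(
        derive_lrp(ep2).amplitude_uv, base.amplitude_uv, atol=1e-10
    )


def test_hand_swap_antisymmetry(rng):
    data = rng.normal(size=(6, 2, 400))
    hands = ["left", "right", "left", "right", "left", "right"]
    swapped = ["right", "left", "right", "left", "right", "left"]
    w1 = derive_lrp(make_epochs(data, hands=hands))
    w2 = derive_lrp(make_epochs(data, hands=swapped))
    np.testing.assert_allclose(w2.amplitude_uv, -w1.amplitude_uv, atol=1e-12)


def test_missing_hand_raises(rng):
    ep = make_epochs(rng.normal(size=(3, 2, 400)), hands=["left"] * 3)
    with pytest.raises(ValueError, match="both hands"):
        derive_lrp(ep)


# ---------------------------------------------------------------------------
# find_peak


def test_peak_unique_maximum():
    amp = np.zeros(400)
    amp[270] = 3.0  # t = -200 + 270*2 = 340 ms
    peak_ms, peak_uv = find_peak(_wave(amp), (200, 500))
    assert (peak_ms, peak_uv) == (340.0, 3.0)


def test_peak_tie_goes_to_earliest():
    amp = np.zeros(400)
    amp[250] = amp[300] = 2.0  # 300 ms and 400 ms
    peak_ms, _ = find_peak(_wave(amp), (200, 500))
    assert peak_ms == 300.0


def test_peak_monotone_waveform_hits_window_end():
    amp = np.linspace(0, 1, 400)
    peak_ms, _ = find_peak(_wave(amp), (200, 500))
    assert peak_ms == 500.0


def test_peak_empty_window_raises():
    with pytest.raises(ValueError, match="window"):
        find_peak(_wave(np.zeros(400)), (900, 1000))


# ---------------------------------------------------------------------------
# estimate_onset


def _ramp_wave(onset_ms=100.0, slope=0.05, t0=-200.0, n=400):
    w = _wave(np.zeros(n), t0=t0)
    t = w.time_ms
    w.amplitude_uv = np.where(t < onset_ms, 0.0, slope * (t - onset_ms))
    return w


def test_noise_free_breakpoint_recovered_within_one_sample():
    w = _ramp_wave(onset_ms=100.0)
    est = estimate_onset(w, (-200.0, 340.0))
    assert abs(est.onset_ms - 100.0) <= 2.0
    assert not est.degenerate


def test_shift_equivariance():
    e1 = estimate_onset(_ramp_wave(onset_ms=100.0), (-200.0, 340.0))
    e2 = estimate_onset(_ramp_wave(onset_ms=150.0), (-200.0, 390.0))
    assert abs((e2.onset_ms - e1.onset_ms) - 50.0) <= 2.0


def test_vertical_scale_invariance():
    w = _ramp_wave(onset_ms=120.0)
    w10 = _wave(10.0 * w.amplitude_uv)
    e1 = estimate_onset(w, (-200.0, 340.0))
    e2 = estimate_onset(w10, (-200.0, 340.0))
    assert e1.onset_ms == e2.onset_ms


def _brute_force_onset(times, y):
    """Independent oracle: exhaustive SSE scan with a full design-matrix
    least-squares fit per candidate breakpoint."""
    best_sse, best_tau = np.inf, None
    for k in range(1, len(times) - 1):
        X = np.column_stack(
            [np.ones_like(times), np.maximum(times - times[k], 0.0)]
        )
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        sse = float(np.sum((y - X @ beta) ** 2))
        if sse < best_sse:
            best_sse, best_tau = sse, times[k]
    return best_tau, best_sse


@pytest.mark.parametrize("seed", range(8))
def test_onset_matches_exhaustive_sse_oracle(seed):
    rng = np.random.default_rng(seed)
    n = 150
    w = _ramp_wave(onset_ms=rng.uniform(0, 200), slope=rng.uniform(0.02, 0.1), n=n)
    w.amplitude_uv = w.amplitude_uv + rng.normal(0, 0.5, size=n)
    interval = (-200.0, float(w.time_ms[-1]))
    est = estimate_onset(w, interval)
    tau, sse = _brute_force_onset(w.time_ms, w.amplitude_uv)
    assert est.onset_ms == tau
    assert est.sse == pytest.approx(sse, rel=1e-9)


def test_flat_waveform_flagged_degenerate():
    est = estimate_onset(_wave(np.full(400, 1.5)), (-200.0, 340.0))
    assert est.degenerate


def test_interval_too_short_raises():
    with pytest.raises(ValueError, match="at least 4"):
        estimate_onset(_wave(np.zeros(400)), (-200.0, -196.0))


# ---------------------------------------------------------------------------
# subject scoring on rendered ground truth


def _pipeline_scores(cc, n_subjects):
    from lrpfrac.pipeline import PipelineConfig, preprocess_subject
    from lrpfrac.synthetic import render_eeg, simulate_cohort, subject_eeg_rng

    subjects, trials = simulate_cohort(cc)
    cfg = PipelineConfig(cohort=cc)
    s_lat, r_lat = [], []
    for sid in range(n_subjects):
        rec = render_eeg(
            trials[trials.subject_id == sid], subjects.iloc[sid], cc,
            subject_eeg_rng(cc, sid),
        )
        s_ep, r_ep, _ = preprocess_subject(rec, trials[trials.subject_id == sid], cfg)
        score = score_subject(s_ep, r_ep)
        s_lat.append(score.s_latency_ms)
        r_lat.append(score.r_latency_ms)
    return subjects, np.array(s_lat), np.array(r_lat)


def test_noise_free_subject_recovers_component_durations():
    from lrpfrac.synthetic import CohortConfig, TrialNoise

    cc = CohortConfig(
        n_subjects=1,
        n_trials=60,
        premotor_mean_ms=190.0,
        motor_mean_ms=150.0,
        premotor_sd_ms=0.0,
        motor_sd_ms=0.0,
        trial_noise=TrialNoise(0.0, 0.0, 0.0),
        compat_effect_ms=0.0,
        eeg_noise_sd=0.0,
        blink_rate_hz=0.0,
        saccade_rate_hz=0.0,
        error_rate=0.0,
        path_params=__import__("lrpfrac").PathParams(c_direct=0.0, beta_sex=0.0),
        seed=2,
    )
    subjects, s_lat, r_lat = _pipeline_scores(cc, 1)
    assert abs(s_lat[0] - subjects.iloc[0]["premotor_mean_ms"]) <= 2.0
    assert abs(r_lat[0] - subjects.iloc[0]["motor_mean_ms"]) <= 2.0


def test_latency_recovery_across_cohort():
    """EEG-noise robustness of the onset scorer at the default noise level:
    200 subjects, trial latency jitter held at zero so the target of the
    estimate is the subject's mean premotor/motor duration.  The scorer
    tracks truth (r > 0.8) with a small early bias on the stimulus-locked
    side (noisy breakpoints slip early more cheaply than late)."""
    from lrpfrac.synthetic import CohortConfig, TrialNoise

    cc = CohortConfig(
        n_subjects=200,
        n_trials=300,
        trial_noise=TrialNoise(0.0, 0.0, 0.0),
        seed=0,
    )
    subjects, s_lat, r_lat = _pipeline_scores(cc, 200)
    pm = subjects["premotor_mean_ms"].to_numpy()
    mt = subjects["motor_mean_ms"].to_numpy()
    assert abs(np.mean(s_lat - pm)) < 10.0
    assert abs(np.mean(r_lat - mt)) < 5.0
    assert np.corrcoef(s_lat, pm)[0, 1] > 0.8
    assert np.corrcoef(r_lat, mt)[0, 1] > 0.8


def test_trial_imbalance_does_not_bias_lrp(rng):
    """60/40 left/right split under symmetric noise leaves the mean LRP
    within 2 SEs of the balanced version."""
    n_samp = 400
    signal = np.zeros(n_samp)
    signal[150:] = 2.0

    def build(n_left, n_right, rng):
        n = n_left + n_right
        data = rng.normal(0, 3.0, size=(n, 2, n_samp))
        hands = ["left"] * n_left + ["right"] * n_right
        for i in range(n):
            if hands[i] == "left":
                data[i, 1] -= signal  # contralateral C4 negativity
            else:
                data[i, 0] -= signal
        return derive_lrp(make_epochs(data, hands=hands)).amplitude_uv

    reps = 30
    bal = np.array([build(50, 50, np.random.default_rng(s)) for s in range(reps)])
    imb = np.array(
        [build(60, 40, np.random.default_rng(1000 + s)) for s in range(reps)]
    )
    diff = imb.mean(axis=0).mean() - bal.mean(axis=0).mean()
    se = np.sqrt(bal.mean(axis=1).var(ddof=1) / reps + imb.mean(axis=1).var(ddof=1) / reps)
    assert abs(diff) < 2 * se + 1e-12


def test_r_latency_sign_convention():
    """Response-locked onsets are reported as positive durations before the
    button press."""
    n = 600  # [-1000, 200] at 500 Hz
    t0 = -1000.0
    w = _wave(np.zeros(n), t0=t0)
    t = w.time_ms
    onset = -150.0
    w.amplitude_uv = np.where(t < onset, 0.0, 0.05 * (t - onset))
    peak_ms, _ = find_peak(w, (-200, 100))
    est = estimate_onset(w, (-1000.0, peak_ms))
    assert -est.onset_ms == pytest.approx(150.0, abs=2.0)
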