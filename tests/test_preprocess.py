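"""Reduction-chain operations against closed-form and constructed oracles."""

import numpy as np
import pytest
from scipy import signal as spsig

from conftest import make_epochs
from lrpfrac.io import EEGRecording, Marker
from lrpfrac.preprocess import (
    RejectionCriteria,
    baseline_correct,
    bandpass_filter,
    notch_filter,
    ocular_correct,
    reject_artifacts,
    rereference,
    segment,
)

FS = 500.0


def _rec(data, labels=("C3", "C4", "M1", "M2"), markers=()):
    return EEGRecording(list(labels), FS, np.asarray(data, float), list(markers))


# ---------------------------------------------------------------------------
# re-referencing


def test_rereference_shifts_by_mastoid_mean():
    n = 100
    data = np.vstack([np.zeros(n), np.ones(n), np.full(n, 2.0), np.full(n, 4.0)])
    out = rereference(_rec(data))
    np.testing.assert_allclose(out.channel("C3"), -3.0)
    np.testing.assert_allclose(out.channel("C4"), 1.0 - 3.0)
    # reference channels retained unmodified
    np.testing.assert_allclose(out.channel("M1"), 2.0)


def test_rereference_zero_mastoids_is_identity(rng):
    data = np.vstack([rng.normal(size=(2, 200)), np.zeros((2, 200))])
    out = rereference(_rec(data))
    np.testing.assert_allclose(out.data, data)


def test_rereference_preserves_c3_c4_difference(rng):
    data = rng.normal(size=(4, 300))
    data[1] = data[0]  # C4 == C3
    out = rereference(_rec(data))
    np.testing.assert_allclose(out.channel("C3"), out.channel("C4"))


def test_rereference_missing_mastoid_named():
    with pytest.raises(KeyError, match="M2"):
        rereference(_rec(np.zeros((2, 10)), labels=("C3", "M1")))


# ---------------------------------------------------------------------------
# filters


def _sine(freq, n=10000, fs=FS):
    t = np.arange(n) / fs
    return np.sin(2 * np.pi * freq * t)


def test_bandpass_removes_dc():
    data = np.full((1, 10000), 50.0)
    out = bandpass_filter(_rec(data, labels=("C3",)))
    settled = out.data[0, 2000:-2000]
    assert np.mean(np.abs(settled)) < 0.05 * 50.0


def test_bandpass_passes_10hz_without_delay():
    # long signal: the 0.1 Hz high-pass edge has a ~10 s transient
    x = _sine(10.0, n=100_000)
    out = bandpass_filter(_rec(x[None, :], labels=("C3",)))
    y = out.data[0, 30_000:-30_000]
    ref = x[30_000:-30_000]
    assert np.max(np.abs(y)) == pytest.approx(1.0, abs=0.05)
    # zero-phase: cross-correlation peaks within one sample of zero lag
    lags = spsig.correlation_lags(len(y), len(ref))
    xc = spsig.correlate(y, ref)
    assert abs(lags[np.argmax(xc)]) <= 1


def test_bandpass_attenuation_matches_frequency_response():
    """Forward-backward filtering realizes |H(f)|^2; the 60/10 Hz amplitude
    ratio must match the brute-force transfer-function magnitude."""
    sos = spsig.butter(2, [0.1, 30.0], btype="bandpass", fs=FS, output="sos")
    w, h = spsig.sosfreqz(sos, worN=[10.0, 60.0], fs=FS)
    expected_ratio = (np.abs(h[1]) / np.abs(h[0])) ** 2  # two passes
    out10 = bandpass_filter(_rec(_sine(10.0, n=100_000)[None, :], labels=("C3",)))
    out60 = bandpass_filter(_rec(_sine(60.0, n=100_000)[None, :], labels=("C3",)))
    a10 = np.max(np.abs(out10.data[0, 30_000:-30_000]))
    a60 = np.max(np.abs(out60.data[0, 30_000:-30_000]))
    assert a60 / a10 == pytest.approx(expected_ratio, rel=0.05)


def test_bandpass_invalid_edges():
    with pytest.raises(ValueError):
        bandpass_filter(_rec(np.zeros((1, 100)), labels=("C3",)), 30.0, 0.1)
    with pytest.raises(ValueError):
        bandpass_filter(_rec(np.zeros((1, 100)), labels=("C3",)), 0.1, 300.0)


def test_notch_attenuates_60hz_spares_10hz():
    out60 = notch_filter(_rec(_sine(60.0)[None, :], labels=("C3",)))
    out10 = notch_filter(_rec(_sine(10.0)[None, :], labels=("C3",)))
    rms = lambda x: np.sqrt(np.mean(x[2000:-2000] ** 2))
    assert rms(out60.data[0]) < 0.10 * rms(_sine(60.0)[None, :][0])
    assert rms(out10.data[0]) == pytest.approx(rms(_sine(10.0)[None, :][0]), rel=0.05)
    zero = notch_filter(_rec(np.zeros((1, 5000)), labels=("C3",)))
    np.testing.assert_allclose(zero.data, 0.0)
    with pytest.raises(ValueError):
        notch_filter(_rec(np.zeros((1, 100)), labels=("C3",)), freq_hz=400.0)


# ---------------------------------------------------------------------------
# segmentation and baselines


def _trial_table(n, correct=True):
    import pandas as pd

    return pd.DataFrame(
        {
            "trial_index": np.arange(n),
            "hand": ["left"] * n,
            "compatibility": ["compatible"] * n,
            "correct": [correct] * n,
            "rt_ms": [300.0] * n,
        }
    )


def test_segment_window_sample_arithmetic():
    rec = _rec(np.zeros((4, 5000)), markers=[Marker(1000, "stimulus", 0)])
    ep = segment(rec, _trial_table(1), "stimulus", (-200, 600), (-200, 0))
    assert ep.data.shape == (1, 4, 400)  # 800 ms at 500 Hz
    assert ep.times_ms[0] == pytest.approx(-200.0)
    # marker at 1000, window start -200 ms -> sample 900: mark it and check
    rec.data[0, 900] = 7.0
    ep = segment(rec, _trial_table(1), "stimulus", (-200, 600), (-200, 0))
    assert ep.data[0, 0, 0] == 7.0


def test_segment_all_incorrect_warns_and_returns_empty():
    rec = _rec(np.zeros((4, 5000)), markers=[Marker(1000, "stimulus", 0)])
    with pytest.warns(UserWarning, match="no correct trials"):
        ep = segment(rec, _trial_table(1, correct=False), "stimulus")
    assert ep.n_trials == 0


def test_segment_drops_edge_epochs_with_warning():
    rec = _rec(np.zeros((4, 500)), markers=[Marker(50, "stimulus", 0)])
    with pytest.warns(UserWarning, match="edges"):
        ep = segment(rec, _trial_table(1), "stimulus")
    assert ep.n_trials == 0 and ep.n_dropped_edges == 1


def test_segment_without_requested_markers_raises():
    rec = _rec(np.zeros((4, 500)), markers=[Marker(50, "stimulus", 0)])
    with pytest.raises(ValueError, match="response"):
        segment(rec, _trial_table(1), "response")


def test_baseline_correct_constant_ramp_idempotent(rng):
    const = make_epochs(np.full((2, 2, 400), 7.0))
    np.testing.assert_allclose(baseline_correct(const).data, 0.0)

    ramp = make_epochs(np.tile(np.linspace(0, 10, 400), (1, 2, 1)))
    base_mean = ramp.data[0, 0, :100].mean()
    corrected = baseline_correct(ramp)
    np.testing.assert_allclose(corrected.data, ramp.data - base_mean)
    # idempotence
    np.testing.assert_allclose(baseline_correct(corrected).data, corrected.data)

    with pytest.raises(ValueError, match="baseline"):
        baseline_correct(ramp, (-500.0, -300.0))


# ---------------------------------------------------------------------------
# ocular correction


def test_ocular_correction_recovers_known_mixing(rng):
    n_trials, n_samp = 40, 400
    signal = rng.normal(size=(n_trials, 1, n_samp))
    veog = rng.normal(0, 50, size=(n_trials, n_samp))
    data = np.zeros((n_trials, 3, n_samp))
    data[:, 0] = signal[:, 0] + 0.5 * veog
    data[:, 1] = veog
    data[:, 2] = 0.0
    ep = make_epochs(data, channel_labels=["C3", "VEOG", "HEOG"])
    corrected, factors = ocular_correct(ep)
    assert factors["C3"]["veog"] == pytest.approx(0.5, abs=0.01)
    assert np.max(np.abs(corrected.data[:, 0] - signal[:, 0])) < 0.1


def test_ocular_correction_zero_eog_is_identity(rng):
    data = rng.normal(size=(5, 3, 400))
    data[:, 1:] = 0.0
    ep = make_epochs(data, channel_labels=["C3", "VEOG", "HEOG"])
    with pytest.warns(UserWarning, match="zero-variance"):
        corrected, factors = ocular_correct(ep)
    np.testing.assert_allclose(corrected.data, data)


def test_erp_subtraction_prevents_signal_leakage(rng):
    """With a large event-related average present, estimating propagation on
    average-subtracted residuals must beat the naive raw-data regression."""
    n_trials, n_samp = 60, 400
    true_prop = 0.3
    erp = 20.0 * np.sin(np.linspace(0, np.pi, n_samp))
    eog_erp = 30.0 * np.hanning(n_samp)  # blink-locked component shared by all trials
    naive_errs, corrected_errs = [], []
    for _ in range(5):
        veog = eog_erp + rng.normal(0, 10, size=(n_trials, n_samp))
        eeg = erp + true_prop * veog + rng.normal(0, 2, size=(n_trials, n_samp))
        data = np.stack([eeg, veog, np.zeros_like(veog)], axis=1)
        ep = make_epochs(data, channel_labels=["C3", "VEOG", "HEOG"])
        _, factors = ocular_correct(ep, condition_cols=())
        corrected_errs.append(abs(factors["C3"]["veog"] - true_prop))
        naive = np.polyfit(veog.ravel(), eeg.ravel(), 1)[0]
        naive_errs.append(abs(naive - true_prop))
    assert np.mean(corrected_errs) < np.mean(naive_errs)


def test_ocular_missing_channel_raises(rng):
    ep = make_epochs(rng.normal(size=(3, 2, 400)))
    with pytest.raises(KeyError, match="VEOG"):
        ocular_correct(ep)


# ---------------------------------------------------------------------------
# artifact rejection


def _clean_epochs(n_trials=5, n_samp=400, amp=5.0):
    """Ongoing 10 Hz activity: passes every criterion."""
    t = np.arange(n_samp) / FS
    x = amp * np.sin(2 * np.pi * 10 * t)
    data = np.tile(x, (n_trials, 2, 1))
    return make_epochs(data)


def test_clean_epochs_not_flagged():
    _, report = reject_artifacts(_clean_epochs())
    assert not report.per_trial["flagged"].any()


def test_absolute_amplitude_threshold_plus_one():
    ep = _clean_epochs()
    ep.data[2, 0, 200] = 101.0
    kept, report = reject_artifacts(ep)
    row = report.per_trial.iloc[2]
    assert row["flagged"] and row["criterion"] == "abs_amp"
    assert kept.n_trials == 4


def test_peak_to_peak_moving_window():
    ep = _clean_epochs()
    # ramp 0 -> 176 µV spanning 40 ms (20 samples): inside one 100-ms window
    ep.data[1, 0, 100:120] += np.linspace(0, 88, 20)  # 4.6 µV/ms, sub-step
    ep.data[1, 0, 120:140] += 88 + np.linspace(0, 88, 20)
    ep.data[1, 0, 140:] += 176
    ep.data[1, 0] -= 88  # keep |x| under the absolute criterion
    _, report = reject_artifacts(ep)
    assert report.per_trial.iloc[1]["criterion"] == "p2p"


def test_voltage_step_unit_conversion():
    """30 µV/ms at 500 Hz is 60 µV per sample: a 31 µV jump must NOT fire,
    an 80 µV jump must."""
    ep = _clean_epochs()
    ep.data[0, 0, 200:210] += 31.0  # 15.5 µV/ms
    _, report = reject_artifacts(ep)
    assert not report.per_trial.iloc[0]["flagged"]

    ep = _clean_epochs()
    ep.data[0, 0, 200:210] += 80.0  # 40 µV/ms
    _, report = reject_artifacts(ep)
    assert report.per_trial.iloc[0]["criterion"] == "step"


def test_flatline_criterion():
    ep = _clean_epochs()
    ep.data[3, 0, :] = 0.2  # constant: range 0 over every window
    _, report = reject_artifacts(ep)
    assert report.per_trial.iloc[3]["criterion"] == "low_activity"


def test_rejection_is_monotone(rng):
    """Adding an offender to one retained trial never changes other flags."""
    ep = _clean_epochs(n_trials=8)
    _, before = reject_artifacts(ep)
    ep2 = ep.copy()
    ep2.data[5, 0, 150] = 150.0
    _, after = reject_artifacts(ep2)
    others = before.per_trial.index != 5
    assert (
        before.per_trial.loc[others, "flagged"].tolist()
        == after.per_trial.loc[others, "flagged"].tolist()
    )
    assert after.per_trial.iloc[5]["flagged"]


def test_injected_offenders_are_exactly_the_flagged_trials():
    """End-to-end: k constructed offenders on a clean recording are flagged,
    and nothing else is."""
    from lrpfrac.io import Marker  # noqa: F401  (markers used via synthetic)
    from lrpfrac.synthetic import (
        ArtifactSpec,
        CohortConfig,
        TrialNoise,
        inject_artifacts,
        render_eeg,
        simulate_cohort,
        subject_eeg_rng,
    )

    cc = CohortConfig(
        n_subjects=1,
        n_trials=40,
        eeg_noise_sd=0.0,
        blink_rate_hz=0.0,
        saccade_rate_hz=0.0,
        error_rate=0.0,
        seed=21,
    )
    subjects, trials = simulate_cohort(cc)
    rec = render_eeg(trials, subjects.iloc[0], cc, subject_eeg_rng(cc, 0))
    specs = [
        ArtifactSpec("abs_amp", 2),
        ArtifactSpec("p2p", 2),
        ArtifactSpec("step", 2),
        ArtifactSpec("low_activity", 10),
    ]
    dirty, tally = inject_artifacts(rec, specs, 99)
    rec2 = rereference(dirty)
    ep = segment(rec2, trials, "stimulus")
    _, report = reject_artifacts(ep)
    flagged = set(report.per_trial.loc[report.per_trial["flagged"], "trial_index"])
    assert flagged == set(tally["trial_index"])
    n_flat = (
        report.per_trial["criterion"] == "low_activity"
    ).sum()
    assert n_flat >= 10


def test_custom_criteria_and_short_epoch_error(rng):
    ep = make_epochs(rng.normal(size=(2, 2, 20)))
    with pytest.raises(ValueError, match="shorter"):
        reject_artifacts(ep)
    loose = RejectionCriteria(abs_uv=1e6, p2p_uv=1e6, step_uv_per_ms=1e6, flat_uv=0.0)
    _, report = reject_artifacts(_clean_epochs(), loose)
    assert not report.per_trial["flagged"].any()
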