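"""ERP reduction chain: re-reference, filter, segment, correct, reject.

The chain mirrors standard lab practice for LRP studies: offline
re-reference to averaged mastoids, a second-order zero-phase Butterworth
band-pass (0.1-30 Hz) plus a 60 Hz notch, stimulus- and response-locked
segmentation of correct trials, regression-based ocular correction, and
a four-rule artifact screen (absolute amplitude, moving-window
peak-to-peak, per-millisecond voltage step, and low-activity/flatline).

Millisecond-to-sample conversion rounds half away from zero and windows
are half-open [start, end), so the 800-ms stimulus window is exactly 400
samples at 500 Hz.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal as spsig
from scipy.ndimage import maximum_filter1d, minimum_filter1d

from .io import EEGRecording

EOG_LABELS = {"VEOG", "HEOG"}
REFERENCE_LABELS = {"M1", "M2", "TP9", "TP10", "A1", "A2"}

STIM_WINDOW_MS = (-200.0, 600.0)
STIM_BASELINE_MS = (-200.0, 0.0)
RESP_WINDOW_MS = (-1000.0, 200.0)
RESP_BASELINE_MS = (-1000.0, -800.0)


def ms_to_samples(ms: float, fs: float) -> int:
    """Round half away from zero, in samples."""
    x = ms * fs / 1000.0
    return int(np.sign(x) * np.floor(abs(x) + 0.5))


@dataclass
class EpochSet:
    """Trials x channels x samples, locked to stimulus or response."""

    lock: str  # "stimulus" | "response"
    window_ms: tuple[float, float]
    baseline_ms: tuple[float, float]
    data: np.ndarray
    channel_labels: list[str]
    sampling_rate: float
    trial_meta: pd.DataFrame  # trial_index, hand, compatibility, correct, rt_ms
    n_dropped_edges: int = 0

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise ValueError("epoch data must be trials x channels x samples")
        if self.data.shape[1] != len(self.channel_labels):
            raise ValueError("channel axis does not match channel labels")
        if len(self.trial_meta) != self.data.shape[0]:
            raise ValueError("trial metadata does not match trial axis")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def times_ms(self) -> np.ndarray:
        start = ms_to_samples(self.window_ms[0], self.sampling_rate)
        n = self.data.shape[2]
        return (np.arange(n) + start) * 1000.0 / self.sampling_rate

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in epoch set") from None

    def copy(self) -> "EpochSet":
        return replace(
            self,
            data=self.data.copy(),
            channel_labels=list(self.channel_labels),
            trial_meta=self.trial_meta.copy(),
        )


# ---------------------------------------------------------------------------
# continuous-data operations


def rereference(
    recording: EEGRecording, reference_labels: tuple[str, str] = ("M1", "M2")
) -> EEGRecording:
    """Subtract the mean of the two mastoid channels from every other
    channel; the reference channels themselves are retained unmodified."""
    for lab in reference_labels:
        if lab not in recording.channel_labels:
            raise KeyError(f"reference channel {lab!r} missing from recording")
    out = recording.copy()
    ref = np.mean(
        [recording.channel(lab) for lab in reference_labels], axis=0
    )
    for i, lab in enumerate(out.channel_labels):
        if lab not in reference_labels:
            out.data[i] -= ref
    return out


def bandpass_filter(
    recording: EEGRecording,
    low_hz: float = 0.1,
    high_hz: float = 30.0,
    order: int = 2,
) -> EEGRecording:
    """Zero-phase (forward-backward) Butterworth band-pass.

    The design order is applied bidirectionally, doubling the effective
    roll-off, which is the dominant convention in commercial ERP software.
    """
    nyq = recording.sampling_rate / 2.0
    if not (0 < low_hz < high_hz < nyq):
        raise ValueError(
            f"band edges ({low_hz}, {high_hz}) must satisfy 0 < low < high < "
            f"Nyquist ({nyq})"
        )
    sos = spsig.butter(
        order, [low_hz, high_hz], btype="bandpass", fs=recording.sampling_rate,
        output="sos",
    )
    out = recording.copy()
    out.data = spsig.sosfiltfilt(sos, out.data, axis=1)
    return out


def notch_filter(
    recording: EEGRecording, freq_hz: float = 60.0, quality: float = 30.0
) -> EEGRecording:
    """Zero-phase IIR notch (quality factor 30: narrow enough to spare the
    30 Hz band-pass edge)."""
    nyq = recording.sampling_rate / 2.0
    if not 0 < freq_hz < nyq:
        raise ValueError(f"notch frequency {freq_hz} must lie in (0, {nyq})")
    b, a = spsig.iirnotch(freq_hz, quality, fs=recording.sampling_rate)
    out = recording.copy()
    out.data = spsig.filtfilt(b, a, out.data, axis=1)
    return out


# ---------------------------------------------------------------------------
# segmentation


def segment(
    recording: EEGRecording,
    trial_table: pd.DataFrame,
    lock: str,
    window_ms: tuple[float, float] | None = None,
    baseline_ms: tuple[float, float] | None = None,
) -> EpochSet:
    """Cut one epoch per correct trial around the requested lock event.

    Incorrect-response trials are excluded before segmentation.  Epochs
    that would overlap the recording edges are dropped with a warning.
    """
    if lock not in ("stimulus", "response"):
        raise ValueError("lock must be 'stimulus' or 'response'")
    if window_ms is None:
        window_ms = STIM_WINDOW_MS if lock == "stimulus" else RESP_WINDOW_MS
    if baseline_ms is None:
        baseline_ms = STIM_BASELINE_MS if lock == "stimulus" else RESP_BASELINE_MS

    correct_col = "correct" if "correct" in trial_table else "is_error"
    meta = trial_table.copy()
    if correct_col == "is_error":
        meta["correct"] = ~meta["is_error"].astype(bool)
    correct = meta[meta["correct"].astype(bool)]

    wanted = set(correct["trial_index"].astype(int))
    if lock == "stimulus":
        events = {m.trial_index: m.sample for m in recording.markers if m.kind == "stimulus"}
    else:
        events = {
            m.trial_index: m.sample
            for m in recording.markers
            if m.kind.startswith("response")
        }
    if not events:
        raise ValueError(f"recording has no {lock} markers")

    fs = recording.sampling_rate
    off0 = ms_to_samples(window_ms[0], fs)
    off1 = ms_to_samples(window_ms[1], fs)
    n_samp = off1 - off0

    epochs, rows, dropped = [], [], 0
    for row in correct.sort_values("trial_index").itertuples():
        trial = int(row.trial_index)
        if trial not in wanted or trial not in events:
            continue
        start = events[trial] + off0
        stop = start + n_samp
        if start < 0 or stop > recording.n_samples:
            dropped += 1
            continue
        epochs.append(recording.data[:, start:stop])
        rows.append(
            {
                "trial_index": trial,
                "hand": getattr(row, "hand", None),
                "compatibility": getattr(row, "compatibility", None),
                "correct": True,
                "rt_ms": getattr(row, "rt_ms", np.nan),
            }
        )
    if dropped:
        warnings.warn(f"{dropped} epochs overlapped the recording edges and were dropped")
    if not epochs:
        warnings.warn("no correct trials to segment; returning empty epoch set")
        data = np.empty((0, len(recording.channel_labels), n_samp))
    else:
        data = np.stack(epochs)
    return EpochSet(
        lock=lock,
        window_ms=tuple(window_ms),
        baseline_ms=tuple(baseline_ms),
        data=data,
        channel_labels=list(recording.channel_labels),
        sampling_rate=fs,
        trial_meta=pd.DataFrame(
            rows, columns=["trial_index", "hand", "compatibility", "correct", "rt_ms"]
        ),
        n_dropped_edges=dropped,
    )


def _baseline_slice(epochs: EpochSet, baseline_ms: tuple[float, float]) -> slice:
    fs = epochs.sampling_rate
    w0 = ms_to_samples(epochs.window_ms[0], fs)
    b0 = ms_to_samples(baseline_ms[0], fs) - w0
    b1 = ms_to_samples(baseline_ms[1], fs) - w0
    if b0 < 0 or b1 > epochs.data.shape[2] or b1 <= b0:
        raise ValueError(
            f"baseline {baseline_ms} lies outside the epoch window {epochs.window_ms}"
        )
    return slice(b0, b1)


def baseline_correct(
    epochs: EpochSet, baseline_ms: tuple[float, float] | None = None
) -> EpochSet:
    """Subtract the per-trial, per-channel mean over the baseline samples."""
    if baseline_ms is None:
        baseline_ms = epochs.baseline_ms
    sl = _baseline_slice(epochs, baseline_ms)
    out = epochs.copy()
    out.data = out.data - out.data[:, :, sl].mean(axis=2, keepdims=True)
    out.baseline_ms = tuple(baseline_ms)
    return out


# ---------------------------------------------------------------------------
# ocular correction (regression method)


def ocular_correct(
    epochs: EpochSet,
    veog_label: str = "VEOG",
    heog_label: str = "HEOG",
    condition_cols: tuple[str, ...] = ("hand",),
) -> tuple[EpochSet, dict[str, dict[str, float]]]:
    """Regression-based ocular correction.

    Propagation of eye activity into each EEG channel is estimated on
    event-related-average-subtracted residuals (so stimulus-locked brain
    activity does not leak into the factors), then ``propagation x raw
    EOG`` is subtracted from the raw EEG.  Returns the corrected epochs
    and the estimated factors per channel.
    """
    for lab in (veog_label, heog_label):
        if lab not in epochs.channel_labels:
            raise KeyError(f"EOG channel {lab!r} missing from epoch set")
    if epochs.n_trials == 0:
        return epochs.copy(), {}

    iv = epochs.channel_index(veog_label)
    ih = epochs.channel_index(heog_label)

    # step 1: remove the per-condition event-related average from every
    # channel (EEG and EOG alike) before estimating propagation
    resid = epochs.data.copy()
    meta = epochs.trial_meta.reset_index(drop=True)
    cols = [c for c in condition_cols if c in meta.columns]
    groups = meta.groupby(cols).indices if cols else {"all": np.arange(len(meta))}
    for idx in groups.values():
        idx = np.asarray(idx)
        resid[idx] -= resid[idx].mean(axis=0, keepdims=True)

    v = resid[:, iv, :].ravel()
    h = resid[:, ih, :].ravel()
    var_v, var_h = v.var(), h.var()
    factors: dict[str, dict[str, float]] = {}
    out = epochs.copy()
    eeg_idx = [
        i
        for i, lab in enumerate(epochs.channel_labels)
        if lab not in (veog_label, heog_label)
    ]
    if var_v == 0 and var_h == 0:
        warnings.warn("zero-variance EOG; propagation factors set to 0")
        for i in eeg_idx:
            factors[epochs.channel_labels[i]] = {"veog": 0.0, "heog": 0.0}
        return out, factors

    X = np.column_stack([v, h])
    keep = [j for j, s in enumerate((var_v, var_h)) if s > 0]
    if len(keep) < 2:
        warnings.warn("zero-variance EOG channel; its factor set to 0")
    Xk = X[:, keep]
    xtx_inv = np.linalg.pinv(Xk.T @ Xk)
    for i in eeg_idx:
        y = resid[:, i, :].ravel()
        beta = np.zeros(2)
        beta[keep] = xtx_inv @ (Xk.T @ y)
        lab = epochs.channel_labels[i]
        factors[lab] = {"veog": float(beta[0]), "heog": float(beta[1])}
        out.data[:, i, :] -= (
            beta[0] * epochs.data[:, iv, :] + beta[1] * epochs.data[:, ih, :]
        )
    return out, factors


# ---------------------------------------------------------------------------
# artifact rejection


@dataclass(frozen=True)
class RejectionCriteria:
    abs_uv: float = 100.0  # |x| > 100 µV at any time point
    p2p_uv: float = 175.0  # peak-to-peak > 175 µV in a moving 100 ms
    step_uv_per_ms: float = 30.0  # adjacent-sample step > 30 µV/ms
    flat_uv: float = 0.5  # range < 0.5 µV over a moving 100 ms
    window_ms: float = 100.0


@dataclass
class RejectionReport:
    per_trial: pd.DataFrame  # trial_index, flagged, criterion, channel
    fraction_rejected: float


def reject_artifacts(
    epochs: EpochSet,
    criteria: RejectionCriteria | None = None,
    channels: list[str] | None = None,
) -> tuple[EpochSet, RejectionReport]:
    """Flag and remove trials violating any of the four criteria.

    A trial is flagged if any criterion fires on any scanned channel; by
    default all EEG channels are scanned (EOG and mastoid/reference
    channels are skipped).  Moving windows advance one sample at a time.
    """
    if criteria is None:
        criteria = RejectionCriteria()
    if channels is None:
        channels = [
            lab
            for lab in epochs.channel_labels
            if lab not in EOG_LABELS and lab not in REFERENCE_LABELS
        ]
    fs = epochs.sampling_rate
    win = int(round(criteria.window_ms * fs / 1000.0))
    n_samp = epochs.data.shape[2]
    if n_samp < win:
        raise ValueError("epochs shorter than the moving-window length")
    uv_per_ms = fs / 1000.0

    rows = []
    for t in range(epochs.n_trials):
        fired, fired_ch = "none", None
        for lab in channels:
            x = epochs.data[t, epochs.channel_index(lab)]
            if np.any(np.abs(x) > criteria.abs_uv):
                fired, fired_ch = "abs_amp", lab
                break
            # moving-window range via running max/min filters
            rng_w = (
                maximum_filter1d(x, win, mode="nearest")
                - minimum_filter1d(x, win, mode="nearest")
            )
            # restrict to windows fully inside the epoch
            half_lo = (win - 1) // 2
            half_hi = win - 1 - half_lo
            inner = rng_w[half_lo : n_samp - half_hi]
            if np.any(inner > criteria.p2p_uv):
                fired, fired_ch = "p2p", lab
                break
            step = np.abs(np.diff(x)) * uv_per_ms
            if np.any(step > criteria.step_uv_per_ms):
                fired, fired_ch = "step", lab
                break
            if np.any(inner < criteria.flat_uv):
                fired, fired_ch = "low_activity", lab
                break
        rows.append(
            {
                "trial_index": int(epochs.trial_meta.iloc[t]["trial_index"]),
                "flagged": fired != "none",
                "criterion": fired,
                "channel": fired_ch,
            }
        )
    report_df = pd.DataFrame(rows, columns=["trial_index", "flagged", "criterion", "channel"])
    keep = ~report_df["flagged"].to_numpy(bool)
    out = epochs.copy()
    out.data = out.data[keep]
    out.trial_meta = out.trial_meta.iloc[keep].reset_index(drop=True)
    frac = float((~keep).mean()) if len(keep) else 0.0
    return out, RejectionReport(per_trial=report_df, fraction_rejected=frac)
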