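"""LRP derivation and latency scoring.

The lateralized readiness potential is computed by double subtraction:

    LRP = mean over left-hand trials of (C3 - C4)
        - mean over right-hand trials of (C3 - C4)

Activity common to both hands cancels exactly.  With this equation,
contralateral motor negativity yields a POSITIVE-going LRP (left-hand
trials give a positive C3-C4 difference, right-hand trials a negative
one), so peaks are maxima; many LRP papers average the two hand
differences instead and plot the opposite polarity.

Onset latency uses the single-subject segmented-regression method: the
waveform between the search start and the peak is modeled as a flat
pre-onset level followed by a straight rise, continuous at the
breakpoint; the breakpoint minimizing the least-squares error is the
onset.  The pre-onset slope is fixed at zero, so the breakpoint is the
only structural degree of freedom.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .preprocess import EpochSet


@dataclass
class LRPWaveform:
    lock: str
    time_ms: np.ndarray
    amplitude_uv: np.ndarray
    n_left_trials: int
    n_right_trials: int


@dataclass
class LatencyEstimate:
    onset_ms: float
    peak_ms: float
    peak_uv: float
    search_interval_ms: tuple[float, float]
    sse: float
    level_uv: float
    slope_uv_per_ms: float
    degenerate: bool = False


def derive_lrp(
    epochs: EpochSet, channel_left: str = "C3", channel_right: str = "C4"
) -> LRPWaveform:
    """Double-subtraction LRP from correct, retained trials."""
    i3 = epochs.channel_index(channel_left)
    i4 = epochs.channel_index(channel_right)
    meta = epochs.trial_meta.reset_index(drop=True)
    correct = meta["correct"].astype(bool).to_numpy()
    left = (meta["hand"] == "left").to_numpy() & correct
    right = (meta["hand"] == "right").to_numpy() & correct
    if not left.any() or not right.any():
        raise ValueError(
            f"need retained correct trials for both hands "
            f"(left={int(left.sum())}, right={int(right.sum())})"
        )
    diff = epochs.data[:, i3, :] - epochs.data[:, i4, :]
    lrp = diff[left].mean(axis=0) - diff[right].mean(axis=0)
    return LRPWaveform(
        lock=epochs.lock,
        time_ms=epochs.times_ms,
        amplitude_uv=lrp,
        n_left_trials=int(left.sum()),
        n_right_trials=int(right.sum()),
    )


def find_peak(
    waveform: LRPWaveform,
    window_ms: tuple[float, float],
    polarity: str = "positive",
) -> tuple[float, float]:
    """Extremum of the configured polarity in the closed window; ties go
    to the earliest time point."""
    t = waveform.time_ms
    mask = (t >= window_ms[0]) & (t <= window_ms[1])
    if not mask.any():
        raise ValueError(f"peak window {window_ms} contains no samples")
    seg = waveform.amplitude_uv[mask]
    idx = int(np.argmax(seg) if polarity == "positive" else np.argmin(seg))
    times = t[mask]
    return float(times[idx]), float(seg[idx])


def estimate_onset(
    waveform: LRPWaveform, interval_ms: tuple[float, float]
) -> LatencyEstimate:
    """Segmented-regression onset: grid search over breakpoints.

    ``interval_ms`` spans from the search start to the identified peak.
    For each candidate breakpoint tau (every sample strictly inside the
    interval) the model  y(t) = c for t <= tau,  y(t) = c + s (t - tau)
    for t > tau  is fit by least squares; the tau with the smallest SSE
    wins, earliest tau on ties.  An all-constant waveform has no defined
    onset and is returned flagged.
    """
    t = waveform.time_ms
    mask = (t >= interval_ms[0]) & (t <= interval_ms[1])
    tt = t[mask]
    y = waveform.amplitude_uv[mask]
    if tt.size < 4:
        raise ValueError(
            f"interval {interval_ms} holds {tt.size} samples; need at least 4"
        )
    peak_ms, peak_uv = float(tt[-1]), float(y[-1])

    if np.ptp(y) == 0:
        return LatencyEstimate(
            onset_ms=float(tt[0]),
            peak_ms=peak_ms,
            peak_uv=peak_uv,
            search_interval_ms=(float(tt[0]), peak_ms),
            sse=0.0,
            level_uv=float(y[0]),
            slope_uv_per_ms=0.0,
            degenerate=True,
        )

    best = (math.inf, 0, 0.0, 0.0)  # sse, tau index, c, s
    for k in range(1, tt.size - 1):
        ramp = np.maximum(tt - tt[k], 0.0)
        # two-parameter LS: y ~ c + s * ramp
        n = tt.size
        sr, srr = ramp.sum(), float(ramp @ ramp)
        sy, sry = y.sum(), float(ramp @ y)
        det = n * srr - sr * sr
        if det <= 0:
            continue
        c = (srr * sy - sr * sry) / det
        s = (n * sry - sr * sy) / det
        resid = y - c - s * ramp
        sse = float(resid @ resid)
        if sse < best[0]:  # strict: earliest tau wins ties
            best = (sse, k, c, s)
    sse, k, c, s = best
    return LatencyEstimate(
        onset_ms=float(tt[k]),
        peak_ms=peak_ms,
        peak_uv=peak_uv,
        search_interval_ms=(float(tt[0]), peak_ms),
        sse=sse,
        level_uv=c,
        slope_uv_per_ms=s,
    )


@dataclass(frozen=True)
class ScoreConfig:
    s_peak_window_ms: tuple[float, float] = (200.0, 500.0)
    r_peak_window_ms: tuple[float, float] = (-200.0, 100.0)
    s_search_start_ms: float = -200.0  # baseline start
    r_search_start_ms: float = -1000.0
    polarity: str = "positive"


@dataclass
class SubjectScore:
    s_latency_ms: float
    r_latency_ms: float
    s_peak_uv: float
    r_peak_uv: float
    n_s_trials: int
    n_r_trials: int
    s_degenerate: bool = False
    r_degenerate: bool = False


def score_subject(
    s_epochs: EpochSet, r_epochs: EpochSet, config: ScoreConfig | None = None
) -> SubjectScore:
    """Premotor (S-LRP) and motor (R-LRP) latencies for one subject.

    S-LRP latency is the onset of the stimulus-locked LRP (ms after
    stimulus); R-LRP latency is the negated onset of the response-locked
    LRP, reported as a positive duration before the button press.
    """
    if config is None:
        config = ScoreConfig()

    s_wave = derive_lrp(s_epochs)
    s_peak_ms, s_peak_uv = find_peak(s_wave, config.s_peak_window_ms, config.polarity)
    s_est = estimate_onset(s_wave, (config.s_search_start_ms, s_peak_ms))

    r_wave = derive_lrp(r_epochs)
    r_peak_ms, r_peak_uv = find_peak(r_wave, config.r_peak_window_ms, config.polarity)
    r_est = estimate_onset(r_wave, (config.r_search_start_ms, r_peak_ms))

    return SubjectScore(
        s_latency_ms=s_est.onset_ms,
        r_latency_ms=-r_est.onset_ms,
        s_peak_uv=s_peak_uv,
        r_peak_uv=r_peak_uv,
        n_s_trials=s_wave.n_left_trials + s_wave.n_right_trials,
        n_r_trials=r_wave.n_left_trials + r_wave.n_right_trials,
        s_degenerate=s_est.degenerate,
        r_degenerate=r_est.degenerate,
    )
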