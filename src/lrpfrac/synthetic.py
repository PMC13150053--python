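"""Synthetic flanker-task EEG cohort with known ground truth.

Every downstream stage of the pipeline is exercised against data whose
latent structure is known exactly: each trial's reaction time is the sum
of a premotor duration (stimulus evaluation + response selection, ending
at LRP onset) and a motor duration (LRP onset to button press).  Age is
sampled uniformly over the adolescent range and drives the subject-level
premotor and motor means through the standardized a-paths of the
dual-mediator model; the rendered EEG carries a lateralized C3/C4 ramp
whose onset is exactly the trial's premotor duration, so the preprocessing
and onset-scoring stages can be validated against truth.

The generator renders blinks, horizontal eye movements, band-limited
background noise, and can inject the four classes of artifact the
rejection stage screens for (absolute amplitude, peak-to-peak, voltage
step, flatline).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import signal as spsig

from .io import EEGRecording, Marker
from .mediation import ConfigurationError, PathParams

CHANNELS = ["C3", "C4", "M1", "M2", "VEOG", "HEOG"]
MASTOIDS = ("M1", "M2")
ITI_MS = (1080, 1100, 1130)  # inter-trial intervals used by the task
RESPONSE_WINDOW_MS = 1000  # responses recorded only within 1 s of stimulus
STIMULUS_DURATION_MS = 250  # marker property only; no visual modeling


@dataclass(frozen=True)
class TrialNoise:
    """Ex-Gaussian trial-to-trial RT variability, in ms.

    The Gaussian part is split evenly between the premotor and motor
    intervals; the exponential (right-skew) part is assigned to the
    premotor interval, where decision-stage models place RT skew.  The
    exponential component is centered (tau subtracted) so the subject
    means are preserved.
    """

    mu: float = 0.0
    sigma: float = 40.0
    tau: float = 50.0


@dataclass(frozen=True)
class CohortConfig:
    n_subjects: int = 194
    age_range: tuple[float, float] = (14.0, 19.0)
    n_trials: int = 300
    sampling_rate: float = 500.0
    path_params: PathParams = field(default_factory=PathParams)
    premotor_mean_ms: float = 191.0
    premotor_sd_ms: float = 42.0
    motor_mean_ms: float = 152.0
    motor_sd_ms: float = 38.0
    trial_noise: TrialNoise = field(default_factory=TrialNoise)
    compat_effect_ms: float = 36.5  # incompatible minus compatible, premotor
    eeg_noise_sd: float = 4.0  # µV, channel-independent (lateralized) residual
    lrp_amplitude: float = 3.0  # µV, per-hemisphere ramp amplitude
    alpha_amplitude: float = 4.0  # µV, common-mode 10 Hz background
    evoked_amplitude: float = 5.0  # µV, bilateral stimulus-evoked bump
    blink_rate_hz: float = 0.08
    blink_amplitude_uv: float = 150.0
    saccade_rate_hz: float = 0.05
    saccade_amplitude_uv: float = 40.0
    veog_propagation: float = 0.08
    heog_propagation: float = 0.02
    error_rate: float = 0.12
    female_proportion: float = 0.686
    seed: int = 0

    def validate(self) -> None:
        if self.n_trials <= 0:
            raise ConfigurationError("n_trials must be positive")
        if self.sampling_rate <= 0:
            raise ConfigurationError("sampling_rate must be positive")
        if not 0 <= self.error_rate <= 1:
            raise ConfigurationError("error_rate must be in [0, 1]")
        if self.age_range[0] >= self.age_range[1]:
            raise ConfigurationError("age_range must be an increasing interval")
        self.path_params.validate()


def simulate_subjects(config: CohortConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw per-subject ground truth: age, sex, latent component means.

    Age is uniform on ``age_range`` and z-scored within the sample; the
    standardized age score drives the premotor mean via a_S and the motor
    mean via a_R, with mediator residuals correlated ``rho_med``.  The
    direct age path and the sex path act on RT outside the LRP-onset
    mechanism; because synthetic RT is exactly premotor + motor, their
    contribution (scaled by the implied cohort RT SD) is carried on the
    motor interval.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    p = config.path_params
    n = config.n_subjects

    age = rng.uniform(*config.age_range, size=n)
    sd_age = np.std(age, ddof=1) if n > 1 else 0.0
    z_age = (age - age.mean()) / sd_age if sd_age > 0 else np.zeros(n)
    sex = (rng.random(n) < config.female_proportion).astype(int)  # 1 = female
    sex_c = sex - sex.mean()

    resid_cov = np.array([[1.0, p.rho_med], [p.rho_med, 1.0]])
    resid = rng.multivariate_normal([0.0, 0.0], resid_cov, size=n)
    m_s = p.a_s * z_age + math.sqrt(1 - p.a_s**2) * resid[:, 0]
    m_r = p.a_r * z_age + math.sqrt(1 - p.a_r**2) * resid[:, 1]

    premotor = config.premotor_mean_ms + config.premotor_sd_ms * m_s
    motor = config.motor_mean_ms + config.motor_sd_ms * m_r
    rt_scale = math.hypot(config.premotor_sd_ms, config.motor_sd_ms)
    motor = motor + rt_scale * (p.c_direct * z_age + p.beta_sex * sex_c)

    premotor = np.maximum(premotor, 60.0)
    motor = np.maximum(motor, 40.0)

    return pd.DataFrame(
        {
            "subject_id": np.arange(n),
            "age": age,
            "z_age": z_age,
            "sex": sex,
            "premotor_mean_ms": premotor,
            "motor_mean_ms": motor,
        }
    )


def simulate_trials(
    subject: pd.Series, config: CohortConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Draw the trial table for one subject.

    Hands and flanker compatibilities are equiprobable; per-trial premotor
    and motor durations are drawn around the subject means with the
    configured ex-Gaussian noise, so the RT identity rt = premotor + motor
    holds exactly.  Errors (wrong button) are flagged at ``error_rate``;
    responses slower than the 1000-ms response window are recorded as
    omission errors.
    """
    if subject["premotor_mean_ms"] <= 0 or subject["motor_mean_ms"] <= 0:
        raise ConfigurationError("subject latent means must be positive")
    n = config.n_trials
    tn = config.trial_noise
    hand = np.where(rng.random(n) < 0.5, "left", "right")
    compat = np.where(rng.random(n) < 0.5, "compatible", "incompatible")

    compat_shift = np.where(compat == "incompatible", 0.5, -0.5) * config.compat_effect_ms
    premotor = (
        subject["premotor_mean_ms"]
        + compat_shift
        + tn.mu
        + rng.normal(0.0, tn.sigma / math.sqrt(2), size=n)
        + (rng.exponential(tn.tau, size=n) - tn.tau if tn.tau > 0 else 0.0)
    )
    motor = subject["motor_mean_ms"] + rng.normal(0.0, tn.sigma / math.sqrt(2), size=n)
    premotor = np.maximum(premotor, 20.0)
    motor = np.maximum(motor, 10.0)
    rt = premotor + motor

    is_error = rng.random(n) < config.error_rate
    is_error |= rt > RESPONSE_WINDOW_MS  # omission: no response within window

    return pd.DataFrame(
        {
            "subject_id": int(subject["subject_id"]),
            "trial_index": np.arange(n),
            "hand": hand,
            "compatibility": compat,
            "premotor_ms": premotor,
            "motor_ms": motor,
            "rt_ms": rt,
            "is_error": is_error,
        }
    )


def _band_limited_noise(
    rng: np.random.Generator, n: int, fs: float, sd: float, high_hz: float = 30.0
) -> np.ndarray:
    white = rng.standard_normal(n)
    sos = spsig.butter(4, high_hz, btype="low", fs=fs, output="sos")
    shaped = spsig.sosfiltfilt(sos, white)
    s = shaped.std()
    return shaped * (sd / s) if s > 0 else shaped


def _event_train(
    rng: np.random.Generator, n: int, fs: float, rate_hz: float, template: np.ndarray
) -> np.ndarray:
    out = np.zeros(n)
    n_events = rng.poisson(rate_hz * n / fs)
    if n_events == 0:
        return out
    starts = rng.integers(0, max(n - template.size, 1), size=n_events)
    for s in starts:
        seg = out[s : s + template.size]
        seg += template[: seg.size]
    return out


def render_eeg(
    trials: pd.DataFrame,
    subject: pd.Series,
    config: CohortConfig,
    rng: np.random.Generator,
) -> EEGRecording:
    """Render a continuous recording for one subject's trial table.

    For each correct trial a lateralized ramp starts ``premotor_ms`` after
    the stimulus marker on the hemisphere contralateral to the responding
    hand (negative-going), peaks at the response marker, and decays over
    200 ms; the double subtraction therefore yields a positive LRP with
    onset equal to the premotor duration.  A bilateral stimulus-evoked
    bump and a common-mode 10 Hz background are added identically to C3
    and C4 (they cancel in the LRP); mastoids carry low-level noise;
    VEOG/HEOG carry blink and saccade templates that propagate into the
    scalp channels with the configured factors.
    """
    fs = config.sampling_rate
    if fs < 100:
        raise ConfigurationError(
            f"sampling rate {fs} Hz is too low to place LRP onsets reliably"
        )
    spms = fs / 1000.0  # samples per ms
    n_trials = len(trials)
    itis = rng.choice(ITI_MS, size=n_trials)
    stim_ms = np.empty(n_trials)
    t = 2000.0  # pre-roll so the first response-locked window fits
    for i in range(n_trials):
        stim_ms[i] = t
        t += STIMULUS_DURATION_MS + RESPONSE_WINDOW_MS + itis[i]
    total_ms = t + 2000.0
    n_samples = int(round(total_ms * spms))

    data = np.zeros((len(CHANNELS), n_samples))
    ch = {label: data[i] for i, label in enumerate(CHANNELS)}
    time_s = np.arange(n_samples) / fs

    # common-mode background: 10 Hz with random phase, identical on C3/C4
    alpha = config.alpha_amplitude * np.sin(
        2 * np.pi * 10.0 * time_s + rng.uniform(0, 2 * np.pi)
    )
    ch["C3"] += alpha
    ch["C4"] += alpha

    # bilateral stimulus-evoked bump (common mode, cancels in the LRP)
    if config.evoked_amplitude:
        bump_len = int(round(300 * spms))
        bt = np.arange(bump_len) / spms  # ms
        bump = config.evoked_amplitude * np.exp(-0.5 * ((bt - 150.0) / 50.0) ** 2)
        for s0 in stim_ms:
            i0 = int(round(s0 * spms))
            seg = slice(i0, i0 + bump_len)
            ch["C3"][seg] += bump[: ch["C3"][seg].size]
            ch["C4"][seg] += bump[: ch["C4"][seg].size]

    markers: list[Marker] = []
    decay_ms = 200.0
    for row in trials.itertuples():
        stim_sample = int(round(stim_ms[row.trial_index] * spms))
        markers.append(Marker(stim_sample, "stimulus", row.trial_index))
        rt = float(row.rt_ms)
        if rt > RESPONSE_WINDOW_MS:
            continue  # omission: no response marker
        pressed = row.hand
        if row.is_error:
            pressed = "left" if row.hand == "right" else "right"
        resp_sample = int(round((stim_ms[row.trial_index] + rt) * spms))
        markers.append(Marker(resp_sample, f"response_{pressed}", row.trial_index))

        if row.is_error or config.lrp_amplitude == 0:
            continue
        onset_sample = int(round((stim_ms[row.trial_index] + row.premotor_ms) * spms))
        rise = np.linspace(0.0, -config.lrp_amplitude, max(resp_sample - onset_sample, 1) + 1)
        n_decay = int(round(decay_ms * spms))
        fall = np.linspace(-config.lrp_amplitude, 0.0, n_decay + 1)[1:]
        ramp = np.concatenate([rise, fall])
        target = ch["C4"] if row.hand == "left" else ch["C3"]  # contralateral
        seg = target[onset_sample : onset_sample + ramp.size]
        seg += ramp[: seg.size]

    # ocular channels and their propagation into the scalp
    blink_len = int(round(400 * spms))
    blink = config.blink_amplitude_uv * np.hanning(blink_len)
    veog = _event_train(rng, n_samples, fs, config.blink_rate_hz, blink)
    sacc_len = int(round(300 * spms))
    saccade = config.saccade_amplitude_uv * np.concatenate(
        [np.linspace(0, 1, sacc_len // 4), np.ones(sacc_len // 2),
         np.linspace(1, 0, sacc_len - sacc_len // 4 - sacc_len // 2)]
    )
    heog = _event_train(rng, n_samples, fs, config.saccade_rate_hz, saccade)
    ch["VEOG"] += veog
    ch["HEOG"] += heog
    for lab in ("C3", "C4"):
        ch[lab] += config.veog_propagation * veog + config.heog_propagation * heog

    if config.eeg_noise_sd > 0:
        for lab in ("C3", "C4"):
            ch[lab] += _band_limited_noise(rng, n_samples, fs, config.eeg_noise_sd)
        for lab in MASTOIDS:
            ch[lab] += _band_limited_noise(rng, n_samples, fs, 0.5 * config.eeg_noise_sd)
        ch["VEOG"] += _band_limited_noise(rng, n_samples, fs, config.eeg_noise_sd)
        ch["HEOG"] += _band_limited_noise(rng, n_samples, fs, config.eeg_noise_sd)

    return EEGRecording(
        channel_labels=list(CHANNELS), sampling_rate=fs, data=data, markers=markers
    )


# ---------------------------------------------------------------------------
# artifact injection

ARTIFACT_KINDS = ("abs_amp", "p2p", "step", "low_activity")


@dataclass(frozen=True)
class ArtifactSpec:
    kind: str
    count: int
    channel: str = "C3"

    def __post_init__(self) -> None:
        if self.kind not in ARTIFACT_KINDS:
            raise ValueError(f"unknown artifact kind {self.kind!r}")


def inject_artifacts(
    recording: EEGRecording,
    specs: list[ArtifactSpec],
    seed: int | np.random.Generator = 0,
) -> tuple[EEGRecording, pd.DataFrame]:
    """Insert constructed offenders of each artifact class into trials.

    Each offender is placed inside the post-stimulus window of a distinct
    randomly chosen trial and is designed to fire exactly its own
    rejection criterion: a smooth 120 µV bump (absolute amplitude), a
    bipolar ±90 µV swing inside 100 ms (peak-to-peak), an 80 µV jump
    between adjacent samples (voltage step), and a 150-ms flatline
    (low activity).  Returns the modified recording and a tally of
    (trial_index, kind, channel).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = recording.copy()
    fs = out.sampling_rate
    spms = fs / 1000.0
    stim = {m.trial_index: m.sample for m in out.markers if m.kind == "stimulus"}
    available = sorted(stim)
    total = sum(s.count for s in specs)
    if total > len(available):
        raise ValueError(
            f"{total} artifacts requested but only {len(available)} trials available"
        )
    chosen = rng.permutation(available)[:total]
    tally = []
    k = 0
    for spec in specs:
        sig = out.data[out.channel_index(spec.channel)]
        for _ in range(spec.count):
            trial = int(chosen[k]); k += 1
            # place within the stimulus-locked epoch, after baseline
            start = stim[trial] + int(round(100 * spms))
            if spec.kind == "abs_amp":
                n = int(round(120 * spms))
                sig[start : start + n] += 120.0 * np.hanning(n)
            elif spec.kind == "p2p":
                # +-93 µV swing: range 186 clears 175 even if the ongoing
                # background partially cancels it, while |x| stays near 100
                n = int(round(90 * spms))
                sig[start : start + n] += 93.0 * np.sin(
                    2 * np.pi * np.arange(n) / n
                )
            elif spec.kind == "step":
                n = int(round(10 * spms))
                sig[start : start + n] += 80.0
            elif spec.kind == "low_activity":
                n = int(round(150 * spms))
                sig[start : start + n] = sig[start]
            tally.append({"trial_index": trial, "kind": spec.kind,
                          "channel": spec.channel})
    return out, pd.DataFrame(tally, columns=["trial_index", "kind", "channel"])


def simulate_cohort(
    config: CohortConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Subjects table plus the concatenated trial tables (no EEG).

    Deterministic under ``config.seed``; EEG rendering draws from
    per-subject child streams so trial tables do not depend on whether
    recordings are rendered.
    """
    root = np.random.SeedSequence(config.seed)
    subj_seed, trial_seed = root.spawn(2)
    subjects = simulate_subjects(config, np.random.default_rng(subj_seed))
    trial_streams = trial_seed.spawn(config.n_subjects)
    tables = [
        simulate_trials(subjects.iloc[i], config, np.random.default_rng(trial_streams[i]))
        for i in range(config.n_subjects)
    ]
    return subjects, pd.concat(tables, ignore_index=True)


def subject_eeg_rng(config: CohortConfig, subject_id: int) -> np.random.Generator:
    """Named substream for one subject's EEG rendering."""
    root = np.random.SeedSequence(config.seed)
    _, _, eeg_seed = root.spawn(3)
    return np.random.default_rng(eeg_seed.spawn(config.n_subjects)[subject_id])


def config_to_dict(config: CohortConfig) -> dict:
    d = asdict(config)
    d["age_range"] = list(config.age_range)
    return d
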