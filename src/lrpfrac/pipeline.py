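"""End-to-end orchestration: simulate -> preprocess -> score -> behavior
-> stats -> mediation -> power.

All randomness flows from one root seed through named substreams per
stage, so a rerun with the same config is bit-identical for the
deterministic stages.  Every stage writes plain-text artifacts (TSV /
JSON) into the output directory, stamped with a hash of the config.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior, lrp, mediation, preprocess, stats, synthetic
from .io import read_brainvision, write_brainvision

log = logging.getLogger("lrpfrac")


@dataclass(frozen=True)
class PipelineConfig:
    cohort: synthetic.CohortConfig = field(default_factory=synthetic.CohortConfig)
    criteria: preprocess.RejectionCriteria = field(
        default_factory=preprocess.RejectionCriteria
    )
    score: lrp.ScoreConfig = field(default_factory=lrp.ScoreConfig)
    fast_cutoff_ms: float = 100.0
    sd_cutoff: float = 3.0
    chance_alpha: float = 0.01
    winsor_sd: float = 3.0
    power_reps: int = 1000
    power_alpha: float = 0.05
    run_lme: bool = False
    write_raw: bool = True  # round-trip each recording through BrainVision
    min_trials_per_hand: int = 20

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cohort"]["age_range"] = list(self.cohort.age_range)
        return d

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]


class StageError(RuntimeError):
    def __init__(self, stage: str, context: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed ({context}): {cause}")
        self.stage, self.context = stage, context


def preprocess_subject(
    recording, trial_table: pd.DataFrame, config: PipelineConfig
) -> tuple[preprocess.EpochSet, preprocess.EpochSet, dict]:
    """The fixed reduction chain for one subject.

    Re-reference -> band-pass -> notch -> segment (correct trials only,
    stimulus- and response-locked) -> ocular correction -> baseline
    correction -> artifact rejection.
    """
    rec = preprocess.rereference(recording)
    rec = preprocess.bandpass_filter(rec)
    rec = preprocess.notch_filter(rec)
    report = {}
    epochs = {}
    for lock in ("stimulus", "response"):
        ep = preprocess.segment(rec, trial_table, lock)
        ep, factors = preprocess.ocular_correct(ep)
        ep = preprocess.baseline_correct(ep)
        ep, rej = preprocess.reject_artifacts(ep, config.criteria)
        epochs[lock] = ep
        report[lock] = {
            "fraction_rejected": rej.fraction_rejected,
            "n_retained": ep.n_trials,
            "ocular_factors": factors.get("C3", {}),
        }
    return epochs["stimulus"], epochs["response"], report


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Run every stage on a synthetic cohort; returns the result summary.

    Artifacts written: trials.tsv, subjects.tsv, scores.tsv, cohort.tsv,
    correlations.tsv, commonality.tsv, model.json, power.json,
    report.json (and per-subject BrainVision triplets under raw/ when
    ``write_raw``).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cc = config.cohort

    log.info("simulating cohort: %d subjects x %d trials", cc.n_subjects, cc.n_trials)
    subjects, trials = synthetic.simulate_cohort(cc)
    trials_out = trials.rename(columns={"is_error": "correct"}).copy()
    trials_out["correct"] = ~trials["is_error"]
    trials_out.to_csv(out / "trials.tsv", sep="\t", index=False)
    subjects.to_csv(out / "subjects.tsv", sep="\t", index=False)

    raw_dir = out / "raw"
    if config.write_raw:
        raw_dir.mkdir(exist_ok=True)

    scores, prep_reports = [], {}
    for sid in subjects["subject_id"]:
        sid = int(sid)
        subj = subjects.loc[subjects["subject_id"] == sid].iloc[0]
        ttable = trials[trials["subject_id"] == sid]
        try:
            rec = synthetic.render_eeg(
                ttable, subj, cc, synthetic.subject_eeg_rng(cc, sid)
            )
            if config.write_raw:
                vhdr = write_brainvision(rec, raw_dir / f"sub-{sid:03d}")
                rec = read_brainvision(vhdr)
            s_ep, r_ep, rep = preprocess_subject(rec, ttable, config)
            prep_reports[sid] = rep
            counts = s_ep.trial_meta["hand"].value_counts()
            if len(counts) < 2 or counts.min() < config.min_trials_per_hand:
                log.warning(
                    "subject %d has fewer than %d retained trials for a hand",
                    sid, config.min_trials_per_hand,
                )
            score = lrp.score_subject(s_ep, r_ep, config.score)
        except Exception as exc:  # noqa: BLE001 - halt with subject context
            raise StageError("preprocess/score", f"subject {sid}", exc) from exc
        scores.append(
            {
                "subject_id": sid,
                "s_lrp_ms": score.s_latency_ms,
                "r_lrp_ms": score.r_latency_ms,
                "s_peak_uv": score.s_peak_uv,
                "r_peak_uv": score.r_peak_uv,
                "n_s_trials": score.n_s_trials,
                "n_r_trials": score.n_r_trials,
            }
        )
    scores_df = pd.DataFrame(scores)
    scores_df.to_csv(out / "scores.tsv", sep="\t", index=False)

    # behavioral summaries and exclusions
    summaries = [
        behavior.summarize_subject(
            trials[trials["subject_id"] == int(sid)],
            config.fast_cutoff_ms,
            config.sd_cutoff,
        )
        for sid in subjects["subject_id"]
    ]
    threshold = behavior.binomial_chance_threshold(
        cc.n_trials, alpha=config.chance_alpha
    )
    summary_df = behavior.exclude_subjects(summaries, threshold)

    cohort = (
        subjects[["subject_id", "age", "sex"]]
        .merge(summary_df[["subject_id", "mean_rt_ms", "accuracy", "excluded"]],
               on="subject_id")
        .merge(scores_df[["subject_id", "s_lrp_ms", "r_lrp_ms"]], on="subject_id")
    )
    cohort = cohort[~cohort["excluded"]].drop(columns="excluded").reset_index(drop=True)
    for col in ("mean_rt_ms", "s_lrp_ms", "r_lrp_ms"):
        cohort[col] = behavior.winsorize_cohort(cohort[col], config.winsor_sd)
    cohort.to_csv(out / "cohort.tsv", sep="\t", index=False)

    corr, pvals = stats.pearson_matrix(
        cohort, ["age", "sex", "mean_rt_ms", "accuracy", "s_lrp_ms", "r_lrp_ms"]
    )
    corr.to_csv(out / "correlations.tsv", sep="\t")

    common_rt = stats.commonality_two_predictor(
        cohort["mean_rt_ms"], cohort["s_lrp_ms"], cohort["r_lrp_ms"]
    )
    common_age = stats.commonality_two_predictor(
        cohort["age"], cohort["s_lrp_ms"], cohort["r_lrp_ms"]
    )
    pd.DataFrame(
        [{"model": "rt", **common_rt.to_dict()}, {"model": "age", **common_age.to_dict()}]
    ).to_csv(out / "commonality.tsv", sep="\t", index=False)

    lme_summary = None
    if config.run_lme:
        lme_trials = trials.merge(subjects[["subject_id", "age", "sex"]], on="subject_id")
        lme_trials = lme_trials[~lme_trials["is_error"]]
        lme = stats.fit_trial_lme(lme_trials)
        lme.fixed_effects.to_csv(out / "lme_rt.tsv", sep="\t", index=False)
        lme_summary = {
            "marginal_r2": lme.marginal_r2,
            "conditional_r2": lme.conditional_r2,
            "converged": lme.converged,
        }

    model = mediation.fit_path_model(cohort)
    (out / "model.json").write_text(json.dumps(model.to_dict(), indent=2))

    fitted = mediation.PathParams(
        a_s=model.params["a_s"].est,
        a_r=model.params["a_r"].est,
        b_s=model.params["b_s"].est,
        b_r=model.params["b_r"].est,
        c_direct=model.params["c_direct"].est,
        rho_med=model.psi_corr,
        beta_sex=model.params["beta_sex"].est,
    )
    power_seed = int(np.random.SeedSequence(cc.seed).generate_state(1)[0] % (2**31))
    try:
        power = mediation.monte_carlo_power(
            fitted,
            n=len(cohort),
            n_reps=config.power_reps,
            alpha=config.power_alpha,
            seed=power_seed,
        ).to_dict()
    except mediation.ConfigurationError as exc:
        # tiny demo cohorts can yield fitted paths that over-explain the
        # unit RT variance; report the reason instead of a power estimate
        log.warning("power simulation skipped: %s", exc)
        power = {"error": str(exc), "n": len(cohort)}
    (out / "power.json").write_text(json.dumps(power, indent=2))

    report = {
        "config_hash": config.digest(),
        "seed": cc.seed,
        "n_subjects": int(len(subjects)),
        "n_retained_subjects": int(len(cohort)),
        "chance_threshold": threshold,
        "mean_rejection_fraction": float(
            np.mean(
                [r["stimulus"]["fraction_rejected"] for r in prep_reports.values()]
            )
        )
        if prep_reports
        else float("nan"),
        "cohort_means": {
            "mean_rt_ms": float(cohort["mean_rt_ms"].mean()),
            "s_lrp_ms": float(cohort["s_lrp_ms"].mean()),
            "r_lrp_ms": float(cohort["r_lrp_ms"].mean()),
        },
        "model": model.to_dict(),
        "power": power,
        "lme": lme_summary,
    }
    (out / "report.json").write_text(json.dumps(report, indent=2))
    return report
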