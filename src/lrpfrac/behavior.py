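"""Behavioral cleaning: RT trimming, subject summaries, exclusions.

Cleaning order per subject: (1) drop error trials, (2) drop RT < 100 ms,
(3) drop RT >= mean + 3 SD where mean/SD are computed once on the trials
surviving steps 1-2 (upper tail only, no re-iteration).  When the
surviving RTs have zero spread the 3-SD fence is vacuous and nothing is
removed.  Accuracy is computed against all administered trials.  Cohort
vectors (mean RT, latencies) are winsorized two-sided at 3 SD, replacing
each outlier with the most extreme non-outlying value on its own side.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class CleaningReport:
    n_total: int
    n_errors: int
    n_fast: int
    n_slow: int
    n_retained: int

    def to_dict(self) -> dict:
        return self.__dict__.copy()


def clean_rts(
    table: pd.DataFrame,
    fast_cutoff_ms: float = 100.0,
    sd_cutoff: float = 3.0,
) -> tuple[pd.DataFrame, CleaningReport]:
    """Single-subject trial cleaning; returns the retained trials and a
    per-rule removal tally."""
    n_total = len(table)
    correct_mask = _correct_mask(table)
    correct = table[correct_mask]
    n_errors = n_total - len(correct)

    fast = correct["rt_ms"] < fast_cutoff_ms
    survivors = correct[~fast]
    n_fast = int(fast.sum())

    if len(survivors) > 1:
        mean = survivors["rt_ms"].mean()
        sd = survivors["rt_ms"].std(ddof=1)
        slow = (survivors["rt_ms"] >= mean + sd_cutoff * sd) if sd > 0 else pd.Series(
            False, index=survivors.index
        )
    else:
        slow = pd.Series(False, index=survivors.index)
    retained = survivors[~slow]
    return retained, CleaningReport(
        n_total=n_total,
        n_errors=n_errors,
        n_fast=n_fast,
        n_slow=int(slow.sum()),
        n_retained=len(retained),
    )


def _correct_mask(table: pd.DataFrame) -> pd.Series:
    if "correct" in table:
        return table["correct"].astype(bool)
    if "is_error" in table:
        return ~table["is_error"].astype(bool)
    raise KeyError("trial table needs a 'correct' or 'is_error' column")


@dataclass
class SubjectSummary:
    subject_id: int
    mean_rt_ms: float
    accuracy: float
    n_retained: int
    excluded: bool = False
    reason: str = ""


def summarize_subject(
    table: pd.DataFrame,
    fast_cutoff_ms: float = 100.0,
    sd_cutoff: float = 3.0,
) -> SubjectSummary:
    """Mean RT over cleaned correct trials; accuracy over all administered
    trials (the pre-cleaning denominator)."""
    subject_id = int(table["subject_id"].iloc[0]) if "subject_id" in table and len(table) else -1
    n_admin = len(table)
    accuracy = float(_correct_mask(table).mean()) if n_admin else float("nan")
    retained, _ = clean_rts(table, fast_cutoff_ms, sd_cutoff)
    if len(retained) == 0:
        return SubjectSummary(
            subject_id=subject_id,
            mean_rt_ms=float("nan"),
            accuracy=accuracy,
            n_retained=0,
            excluded=True,
            reason="no_trials",
        )
    return SubjectSummary(
        subject_id=subject_id,
        mean_rt_ms=float(retained["rt_ms"].mean()),
        accuracy=accuracy,
        n_retained=len(retained),
    )


def binomial_chance_threshold(
    n_trials: int, p_chance: float = 0.5, alpha: float = 0.01
) -> float:
    """Minimal accuracy proportion beating chance at ``alpha``.

    Returns k*/n with k* = min{k : P(X >= k) <= alpha}, X ~ Bin(n, p),
    from the exact binomial tail.
    """
    if n_trials <= 0:
        raise ValueError("n_trials must be positive")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    k = np.arange(n_trials + 1)
    # P(X >= k) = sf(k - 1)
    tail = sps.binom.sf(k - 1, n_trials, p_chance)
    passing = k[tail <= alpha]
    if passing.size == 0:
        return float("inf")  # no attainable accuracy beats chance at this alpha
    return float(passing[0]) / n_trials


def exclude_subjects(
    summaries: list[SubjectSummary] | pd.DataFrame, threshold: float
) -> pd.DataFrame:
    """Flag subjects whose accuracy falls below the chance criterion; the
    threshold itself is the minimal passing accuracy."""
    if isinstance(summaries, pd.DataFrame):
        df = summaries.copy()
    else:
        df = pd.DataFrame([s.__dict__ for s in summaries])
    below = df["accuracy"] < threshold
    df.loc[below, "excluded"] = True
    df.loc[below, "reason"] = df.loc[below, "reason"].where(
        df.loc[below, "reason"].astype(bool), "below_chance"
    )
    return df


def winsorize_cohort(values: np.ndarray | pd.Series, k_sd: float = 3.0) -> np.ndarray:
    """Two-sided winsorization at ``k_sd`` sample SDs.

    Fences use the mean/SD of the original vector (single pass).  Each
    outlying value (|v - mean| >= k_sd * SD) is replaced by the most
    extreme value on the same side that is not itself outlying.  Length
    and order are preserved; zero-SD input is returned unchanged.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("winsorization needs at least 3 values")
    mean, sd = x.mean(), x.std(ddof=1)
    if sd == 0:
        return x.copy()
    lo, hi = mean - k_sd * sd, mean + k_sd * sd
    inside = (x > lo) & (x < hi)
    out = x.copy()
    if not inside.any():
        return out
    repl_hi = x[inside].max()
    repl_lo = x[inside].min()
    out[x >= hi] = repl_hi
    out[x <= lo] = repl_lo
    return out
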