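"""Cohort-level descriptive inference.

Pearson correlations with t-based tests, the Meng-Rosenthal-Rubin
comparison of two dependent (overlapping) correlations, a two-predictor
commonality decomposition of regression R^2, and the trial-level linear
mixed model (random intercepts and compatibility slopes by participant).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats as sps


def pearson_matrix(
    cohort: pd.DataFrame, columns: list[str] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson r and two-sided p-values.

    p comes from t = r sqrt((n-2)/(1-r^2)) on n-2 df.  Zero-variance
    columns yield NaN and a warning.
    """
    if columns is None:
        columns = [c for c in cohort.columns if np.issubdtype(cohort[c].dtype, np.number)]
    n = len(cohort)
    if n < 3:
        raise ValueError("need at least 3 rows for correlation tests")
    k = len(columns)
    r = pd.DataFrame(np.eye(k), index=columns, columns=columns)
    p = pd.DataFrame(np.zeros((k, k)), index=columns, columns=columns)
    for i, a in enumerate(columns):
        for j in range(i + 1, k):
            b = columns[j]
            x, y = cohort[a].to_numpy(float), cohort[b].to_numpy(float)
            if np.std(x) == 0 or np.std(y) == 0:
                warnings.warn(f"zero-variance column in pair ({a}, {b}); r undefined")
                rij, pij = np.nan, np.nan
            else:
                rij = float(np.corrcoef(x, y)[0, 1])
                if abs(rij) >= 1.0:
                    pij = 0.0
                else:
                    t = rij * math.sqrt((n - 2) / (1 - rij**2))
                    pij = float(2 * sps.t.sf(abs(t), n - 2))
            r.iloc[i, j] = r.iloc[j, i] = rij
            p.iloc[i, j] = p.iloc[j, i] = pij
    return r, p


def compare_dependent_correlations(
    r_jk: float, r_jh: float, r_kh: float, n: int, method: str = "dependent"
) -> tuple[float, float]:
    """Compare two correlations sharing variable j.

    ``dependent`` (default) is the Meng-Rosenthal-Rubin z for overlapping
    correlations:

        z = (z_jk - z_jh) * sqrt((n - 3) / (2 (1 - r_kh) h)),
        h = (1 - f rbar^2) / (1 - rbar^2),
        f = min(1, (1 - r_kh) / (2 (1 - rbar^2))),
        rbar^2 = (r_jk^2 + r_jh^2) / 2.

    ``independent`` applies the two-sample Fisher z ignoring the overlap.
    Returns (z, two-sided p).
    """
    for r in (r_jk, r_jh, r_kh):
        if abs(r) >= 1:
            raise ValueError("correlations must satisfy |r| < 1")
    if n <= 3:
        raise ValueError("need n > 3")
    z_jk, z_jh = np.arctanh(r_jk), np.arctanh(r_jh)
    if method == "independent":
        se = math.sqrt(2.0 / (n - 3))
        z = (z_jk - z_jh) / se
    elif method == "dependent":
        rbar2 = (r_jk**2 + r_jh**2) / 2.0
        f = min(1.0, (1.0 - r_kh) / (2.0 * (1.0 - rbar2)))
        h = (1.0 - f * rbar2) / (1.0 - rbar2)
        z = (z_jk - z_jh) * math.sqrt((n - 3) / (2.0 * (1.0 - r_kh) * h))
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(z), float(2 * sps.norm.sf(abs(z)))


@dataclass
class CommonalityResult:
    unique_1: float
    unique_2: float
    common: float
    total: float

    @property
    def pct_of_total(self) -> dict[str, float]:
        if self.total == 0:
            return {"unique_1": np.nan, "unique_2": np.nan, "common": np.nan}
        return {
            "unique_1": 100.0 * self.unique_1 / self.total,
            "unique_2": 100.0 * self.unique_2 / self.total,
            "common": 100.0 * self.common / self.total,
        }

    def to_dict(self) -> dict:
        d = {
            "unique_1": self.unique_1,
            "unique_2": self.unique_2,
            "common": self.common,
            "total": self.total,
        }
        d.update({f"pct_{k}": v for k, v in self.pct_of_total.items()})
        return d


def _r2(y: np.ndarray, X: np.ndarray) -> float:
    model = sm.OLS(y, sm.add_constant(X)).fit()
    return float(model.rsquared)


def commonality_two_predictor(
    y: np.ndarray, x1: np.ndarray, x2: np.ndarray
) -> CommonalityResult:
    """Decompose R^2(y ~ x1 + x2) into unique and common parts.

        unique_1 = R^2(full) - R^2(y ~ x2)
        unique_2 = R^2(full) - R^2(y ~ x1)
        common   = R^2(y ~ x1) + R^2(y ~ x2) - R^2(full)

    The components sum to the full-model R^2 by construction.  A negative
    common component is legitimate (a suppression artifact), not an error.
    """
    y = np.asarray(y, float)
    x1 = np.asarray(x1, float)
    x2 = np.asarray(x2, float)
    if y.size <= 3:
        raise ValueError("need n > 3")
    r12 = np.corrcoef(x1, x2)[0, 1]
    if abs(r12) > 1 - 1e-12:
        raise ValueError("predictors are collinear")
    r2_full = _r2(y, np.column_stack([x1, x2]))
    r2_1 = _r2(y, x1[:, None])
    r2_2 = _r2(y, x2[:, None])
    return CommonalityResult(
        unique_1=r2_full - r2_2,
        unique_2=r2_full - r2_1,
        common=r2_1 + r2_2 - r2_full,
        total=r2_full,
    )


# ---------------------------------------------------------------------------
# trial-level mixed model


@dataclass
class LMEResult:
    fixed_effects: pd.DataFrame  # term, beta, se, t, p
    marginal_r2: float
    conditional_r2: float
    converged: bool
    random_variances: dict[str, float]


def fit_trial_lme(
    trials: pd.DataFrame,
    outcome: str = "rt_ms",
    group_col: str = "subject_id",
) -> LMEResult:
    """Fixed effects of age x compatibility x sex with random intercepts
    and compatibility slopes by participant.

    Expects columns ``age`` (years), ``sex`` (0 male / 1 female),
    ``compatibility`` ('compatible'/'incompatible') and the outcome.
    Inside the model age is standardized, compatibility is coded +0.5
    (compatible) / -0.5 (incompatible), and sex is centered.  Variance
    explained is summarized by marginal (fixed effects only) and
    conditional (fixed + random) R^2.
    """
    df = trials.copy()
    df["age_z"] = (df["age"] - df["age"].mean()) / df["age"].std(ddof=1)
    df["compat"] = np.where(df["compatibility"] == "compatible", 0.5, -0.5)
    df["sex_c"] = df["sex"] - df["sex"].mean()
    df["_y"] = df[outcome].astype(float)
    df = df.dropna(subset=["_y"])

    model = smf.mixedlm(
        "_y ~ age_z * compat * sex_c",
        data=df,
        groups=df[group_col],
        re_formula="~compat",
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = model.fit(reml=True, method="lbfgs")
    converged = bool(getattr(fit, "converged", True))

    terms = []
    for name in fit.fe_params.index:
        terms.append(
            {
                "term": name,
                "beta": float(fit.fe_params[name]),
                "se": float(fit.bse_fe[name]),
                "t": float(fit.tvalues[name]),
                "p": float(fit.pvalues[name]),
            }
        )
    fixed = pd.DataFrame(terms)

    # Nakagawa-style variance decomposition
    X = fit.model.exog
    var_fixed = float(np.var(X @ fit.fe_params.to_numpy()))
    cov_re = fit.cov_re.to_numpy()
    z_mean = np.array([1.0, float(df["compat"].mean())])
    z_var = np.array([0.0, float(df["compat"].var())])
    var_random = float(z_mean @ cov_re @ z_mean + np.sum(np.diag(cov_re) * z_var))
    var_resid = float(fit.scale)
    denom = var_fixed + var_random + var_resid
    return LMEResult(
        fixed_effects=fixed,
        marginal_r2=var_fixed / denom,
        conditional_r2=(var_fixed + var_random) / denom,
        converged=converged,
        random_variances={
            "intercept": float(cov_re[0, 0]),
            "compat_slope": float(cov_re[1, 1]),
            "residual": var_resid,
        },
    )
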