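"""Dual-mediator path model: age -> {S-LRP, R-LRP} -> RT, sex covariate.

The model is recursive (no feedback loops), so the maximum-likelihood
point estimates coincide with equation-by-equation OLS:

    S  = a_S * age + e_S
    R  = a_R * age + e_R          cov(e_S, e_R) = psi (free)
    RT = c * age + b_S * S + b_R * R + g * sex + e_RT

Indirect effects are the a*b products with delta-method standard errors,
SE(ab) = sqrt(a^2 SE_b^2 + b^2 SE_a^2), and the total effect of age on RT
is the exact sum c + a_S b_S + a_R b_R.  Global fit is evaluated against
the 5-variable observed covariance (age, sex, S, R, RT) with the
sex->mediator paths fixed to zero, which leaves 2 degrees of freedom.

Monte Carlo power draws cohorts from the multivariate normal implied by a
standardized parameterization, refits the model per replicate, and counts
significant delta-method z statistics for each indirect effect.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

VARIABLES = ("age", "sex", "s_lrp", "r_lrp", "rt")


class ConfigurationError(ValueError):
    """Raised when a path parameterization implies an invalid covariance."""


@dataclass(frozen=True)
class PathParams:
    """Standardized coefficients of the dual-mediator model.

    Defaults are the fitted standardized solution of the adolescent
    flanker cohort this package models: the a-paths are backed out of the
    printed indirect effects (ab / b), the b-paths, direct path, residual
    mediator correlation and sex path are the printed standardized
    estimates.
    """

    a_s: float = -0.09 / 0.41  # age -> S-LRP latency
    a_r: float = 0.02 / 0.23  # age -> R-LRP latency
    b_s: float = 0.41  # S-LRP latency -> RT
    b_r: float = 0.23  # R-LRP latency -> RT
    c_direct: float = -0.08  # age -> RT, direct
    rho_med: float = -0.12  # residual correlation of the two mediators
    beta_sex: float = 0.221  # sex -> RT
    r_age_sex: float = 0.0  # exogenous correlation

    def validate(self) -> None:
        for name in ("a_s", "a_r"):
            if abs(getattr(self, name)) >= 1:
                raise ConfigurationError(
                    f"|{name}| >= 1 leaves no residual mediator variance"
                )
        if abs(self.rho_med) >= 1:
            raise ConfigurationError("|rho_med| must be < 1")
        if abs(self.r_age_sex) >= 1:
            raise ConfigurationError("|r_age_sex| must be < 1")


def implied_covariance(params: PathParams) -> np.ndarray:
    """Model-implied covariance of (age, sex, S, R, RT), all unit variance.

    Residual variances are solved so every observed variable is
    standardized; a parameterization whose RT paths already explain more
    than the unit variance is rejected.
    """
    params.validate()
    p = params
    var_es = 1.0 - p.a_s**2
    var_er = 1.0 - p.a_r**2
    psi = p.rho_med * math.sqrt(var_es * var_er)

    cov = np.eye(5)
    idx = {v: i for i, v in enumerate(VARIABLES)}

    def put(u: str, v: str, value: float) -> None:
        cov[idx[u], idx[v]] = cov[idx[v], idx[u]] = value

    put("age", "sex", p.r_age_sex)
    put("age", "s_lrp", p.a_s)
    put("age", "r_lrp", p.a_r)
    put("sex", "s_lrp", p.a_s * p.r_age_sex)
    put("sex", "r_lrp", p.a_r * p.r_age_sex)
    cov_sr = p.a_s * p.a_r + psi
    put("s_lrp", "r_lrp", cov_sr)

    c, bs, br, g = p.c_direct, p.b_s, p.b_r, p.beta_sex
    cov_age_rt = c + bs * p.a_s + br * p.a_r + g * p.r_age_sex
    cov_sex_rt = g + (c + bs * p.a_s + br * p.a_r) * p.r_age_sex
    cov_s_rt = c * p.a_s + bs + br * cov_sr + g * p.a_s * p.r_age_sex
    cov_r_rt = c * p.a_r + bs * cov_sr + br + g * p.a_r * p.r_age_sex
    put("age", "rt", cov_age_rt)
    put("sex", "rt", cov_sex_rt)
    put("s_lrp", "rt", cov_s_rt)
    put("r_lrp", "rt", cov_r_rt)

    explained = (
        c * cov_age_rt + g * cov_sex_rt + bs * cov_s_rt + br * cov_r_rt
    )
    if explained >= 1.0:
        raise ConfigurationError(
            f"paths explain {explained:.3f} of unit RT variance; "
            "residual variance would be non-positive"
        )
    try:
        np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:
        raise ConfigurationError("implied covariance is not positive definite") from exc
    return cov


# ---------------------------------------------------------------------------
# estimation


@dataclass
class Effect:
    est: float
    se: float
    z: float
    p: float


@dataclass
class PathModelResult:
    params: dict[str, Effect]
    indirect_s: Effect
    indirect_r: Effect
    total: Effect
    psi_corr: float
    n: int
    chi2: float = math.nan
    df: int = 0
    rmsea: float = math.nan
    srmr: float = math.nan
    cfi: float = math.nan
    tli: float = math.nan
    standardized: bool = True
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {
            name: {"est": e.est, "se": e.se, "z": e.z, "p": e.p}
            for name, e in self.params.items()
        }
        for name, e in (
            ("indirect_s", self.indirect_s),
            ("indirect_r", self.indirect_r),
            ("total", self.total),
        ):
            out[name] = {"est": e.est, "se": e.se, "z": e.z, "p": e.p}
        out["psi_corr"] = self.psi_corr
        out["fit"] = {
            "chi2": self.chi2,
            "df": self.df,
            "rmsea": self.rmsea,
            "srmr": self.srmr,
            "cfi": self.cfi,
            "tli": self.tli,
        }
        out["n"] = self.n
        return out


def _ols(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """OLS with intercept-free design already assembled; returns
    (coefficients, standard errors, residuals)."""
    n, k = X.shape
    xtx = X.T @ X
    try:
        xtx_inv = np.linalg.inv(xtx)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError("singular design matrix") from exc
    beta = xtx_inv @ (X.T @ y)
    resid = y - X @ beta
    dof = n - k
    if dof <= 0:
        raise ValueError("not enough observations for the design")
    sigma2 = float(resid @ resid) / dof
    se = np.sqrt(np.diag(xtx_inv) * sigma2)
    return beta, se, resid


def _two_sided_p(z: float) -> float:
    return float(2.0 * sps.norm.sf(abs(z)))


def _effect(est: float, se: float) -> Effect:
    z = est / se if se > 0 else math.inf * np.sign(est) if est else 0.0
    return Effect(est=float(est), se=float(se), z=float(z), p=_two_sided_p(z))


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = np.std(x, ddof=1)
    if sd == 0:
        raise ValueError("zero-variance column cannot be standardized")
    return (x - np.mean(x)) / sd


def fit_path_model(
    cohort,
    *,
    standardize: bool = True,
    age_col: str = "age",
    sex_col: str = "sex",
    s_col: str = "s_lrp_ms",
    r_col: str = "r_lrp_ms",
    rt_col: str = "mean_rt_ms",
    compute_fit: bool = True,
) -> PathModelResult:
    """Fit the dual-mediator path model on a cohort table.

    ``cohort`` is a DataFrame-like with one row per subject.  With
    ``standardize`` every variable is z-scored, so coefficients are the
    standardized solution; mediator centering is implied by z-scoring.
    """
    cols = [cohort[c] for c in (age_col, sex_col, s_col, r_col, rt_col)]
    arrs = [np.asarray(c, dtype=float) for c in cols]
    if any(np.isnan(a).any() for a in arrs):
        raise ValueError("cohort table contains missing values in modeled columns")
    if standardize:
        arrs = [_zscore(a) for a in arrs]
    else:  # mediators and age centered, matching the reporting convention
        arrs = [a - a.mean() for a in arrs]
    age, sex, s, r, rt = arrs
    n = age.size
    return _fit_arrays(age, sex, s, r, rt, n, compute_fit=compute_fit,
                       standardized=standardize)


def _fit_arrays(
    age, sex, s, r, rt, n, *, compute_fit: bool, standardized: bool
) -> PathModelResult:
    ones = np.ones(n)
    X_a = np.column_stack([ones, age])
    beta_s, se_s, resid_s = _ols(X_a, s)
    beta_r, se_r, resid_r = _ols(X_a, r)
    X_y = np.column_stack([ones, age, s, r, sex])
    beta_y, se_y, _ = _ols(X_y, rt)

    a_s, a_r = _effect(beta_s[1], se_s[1]), _effect(beta_r[1], se_r[1])
    c_eff = _effect(beta_y[1], se_y[1])
    b_s, b_r = _effect(beta_y[2], se_y[2]), _effect(beta_y[3], se_y[3])
    g_eff = _effect(beta_y[4], se_y[4])

    sd_prod = float(np.std(resid_s, ddof=1) * np.std(resid_r, ddof=1))
    psi_cov = float(resid_s @ resid_r) / (n - 1)
    psi_corr = psi_cov / sd_prod if sd_prod > 0 else 0.0

    ind_s = _product_effect(a_s, b_s)
    ind_r = _product_effect(a_r, b_r)
    total_est = c_eff.est + ind_s.est + ind_r.est
    # delta-method SE treating the mediator regressions and the outcome
    # regression as independent estimation stages
    total_var = (
        c_eff.se**2
        + b_s.est**2 * a_s.se**2
        + a_s.est**2 * b_s.se**2
        + b_r.est**2 * a_r.se**2
        + a_r.est**2 * b_r.se**2
    )
    total = _effect(total_est, math.sqrt(total_var))

    result = PathModelResult(
        params={
            "a_s": a_s,
            "a_r": a_r,
            "b_s": b_s,
            "b_r": b_r,
            "c_direct": c_eff,
            "beta_sex": g_eff,
        },
        indirect_s=ind_s,
        indirect_r=ind_r,
        total=total,
        psi_corr=psi_corr,
        n=n,
        standardized=standardized,
    )

    if compute_fit:
        data = np.column_stack([age, sex, s, r, rt])
        sample_cov = np.cov(data, rowvar=False, ddof=1)
        implied = _implied_from_fit(
            sample_cov, beta_s, beta_r, beta_y, resid_s, resid_r, rt, X_y, n
        )
        df = 2  # sex->S and sex->R omitted from 15 observed moments
        fit = fit_indices(sample_cov, implied, df=df, n=n)
        result.chi2, result.rmsea, result.srmr = fit["chi2"], fit["rmsea"], fit["srmr"]
        result.cfi, result.tli, result.df = fit["cfi"], fit["tli"], df
    return result


def _product_effect(a: Effect, b: Effect) -> Effect:
    se = math.sqrt(a.est**2 * b.se**2 + b.est**2 * a.se**2)
    return _effect(a.est * b.est, se)


def _implied_from_fit(sample_cov, beta_s, beta_r, beta_y, resid_s, resid_r, rt, X_y, n):
    """Model-implied covariance with the exogenous block (age, sex) free."""
    v_age, v_sex = sample_cov[0, 0], sample_cov[1, 1]
    c_as = sample_cov[0, 1]
    a_s, a_r = beta_s[1], beta_r[1]
    c, bs, br, g = beta_y[1], beta_y[2], beta_y[3], beta_y[4]
    var_es = float(resid_s @ resid_s) / (n - 1)
    var_er = float(resid_r @ resid_r) / (n - 1)
    psi = float(resid_s @ resid_r) / (n - 1)
    resid_y = rt - X_y @ beta_y
    var_ey = float(resid_y @ resid_y) / (n - 1)

    cov = np.empty((5, 5))
    cov[0, 0], cov[1, 1], cov[0, 1] = v_age, v_sex, c_as
    cov[1, 0] = c_as
    cov_age_s, cov_age_r = a_s * v_age, a_r * v_age
    cov_sex_s, cov_sex_r = a_s * c_as, a_r * c_as  # sex paths omitted
    var_s = a_s**2 * v_age + var_es
    var_r = a_r**2 * v_age + var_er
    cov_sr = a_s * a_r * v_age + psi
    cov[0, 2] = cov[2, 0] = cov_age_s
    cov[0, 3] = cov[3, 0] = cov_age_r
    cov[1, 2] = cov[2, 1] = cov_sex_s
    cov[1, 3] = cov[3, 1] = cov_sex_r
    cov[2, 2], cov[3, 3] = var_s, var_r
    cov[2, 3] = cov[3, 2] = cov_sr

    cov_age_rt = c * v_age + bs * cov_age_s + br * cov_age_r + g * c_as
    cov_sex_rt = c * c_as + bs * cov_sex_s + br * cov_sex_r + g * v_sex
    cov_s_rt = c * cov_age_s + bs * var_s + br * cov_sr + g * cov_sex_s
    cov_r_rt = c * cov_age_r + bs * cov_sr + br * var_r + g * cov_sex_r
    var_rt = (
        c * cov_age_rt + bs * cov_s_rt + br * cov_r_rt + g * cov_sex_rt + var_ey
    )
    cov[0, 4] = cov[4, 0] = cov_age_rt
    cov[1, 4] = cov[4, 1] = cov_sex_rt
    cov[2, 4] = cov[4, 2] = cov_s_rt
    cov[3, 4] = cov[4, 3] = cov_r_rt
    cov[4, 4] = var_rt
    return cov


# ---------------------------------------------------------------------------
# fit indices


def fit_indices(
    sample_cov: np.ndarray,
    implied_cov: np.ndarray,
    df: int,
    n: int,
    baseline_cov: np.ndarray | None = None,
) -> dict[str, float]:
    """Normal-theory ML discrepancy and the standard absolute/relative
    fit indices.

    chi2 = (n-1) * F_ML with F_ML = ln|Sigma| - ln|S| + tr(S Sigma^-1) - p;
    RMSEA = sqrt(max(chi2 - df, 0) / (df (n-1))) (0 by convention at df=0);
    SRMR is the RMS of the standardized moment residuals; CFI/TLI are
    computed against the independence baseline (diagonal of S).
    """
    S = np.asarray(sample_cov, dtype=float)
    sigma = np.asarray(implied_cov, dtype=float)
    p = S.shape[0]
    if S.shape != sigma.shape or S.shape[0] != S.shape[1]:
        raise ValueError("covariance matrices must be square and conformable")
    for name, m in (("sample", S), ("implied", sigma)):
        if np.any(np.linalg.eigvalsh(m) <= 0):
            raise ValueError(f"{name} covariance is not positive definite")

    def f_ml(sig: np.ndarray) -> float:
        sign, logdet_sig = np.linalg.slogdet(sig)
        _, logdet_s = np.linalg.slogdet(S)
        return float(logdet_sig - logdet_s + np.trace(S @ np.linalg.inv(sig)) - p)

    chi2 = max((n - 1) * f_ml(sigma), 0.0)
    rmsea = math.sqrt(max(chi2 - df, 0.0) / (df * (n - 1))) if df > 0 else 0.0

    d = np.sqrt(np.diag(S))
    std_resid = (S - sigma) / np.outer(d, d)
    iu = np.triu_indices(p)
    srmr = math.sqrt(float(np.mean(std_resid[iu] ** 2)))

    if baseline_cov is None:
        baseline_cov = np.diag(np.diag(S))
    chi2_b = max((n - 1) * f_ml(baseline_cov), 0.0)
    df_b = p * (p - 1) // 2
    denom = max(chi2_b - df_b, chi2 - df, 0.0)
    cfi = 1.0 - max(chi2 - df, 0.0) / denom if denom > 0 else 1.0
    if df > 0 and df_b > 0 and chi2_b / df_b > 1:
        tli = (chi2_b / df_b - chi2 / df) / (chi2_b / df_b - 1)
    else:
        tli = 1.0
    return {
        "chi2": chi2,
        "df": df,
        "rmsea": rmsea,
        "srmr": srmr,
        "cfi": cfi,
        "tli": tli,
        "chi2_baseline": chi2_b,
        "df_baseline": df_b,
    }


# ---------------------------------------------------------------------------
# Monte Carlo power


@dataclass
class PowerResult:
    power_s: float
    power_r: float
    n_reps: int
    n: int
    alpha: float
    seed: int
    convergence_failures: int = 0

    def to_dict(self) -> dict:
        return {
            "power_s": self.power_s,
            "power_r": self.power_r,
            "n_reps": self.n_reps,
            "n": self.n,
            "alpha": self.alpha,
            "seed": self.seed,
            "convergence_failures": self.convergence_failures,
        }


def monte_carlo_power(
    params: PathParams,
    n: int = 194,
    n_reps: int = 5000,
    alpha: float = 0.05,
    seed: int = 0,
    include_sex: bool = True,
) -> PowerResult:
    """Power to detect each indirect effect at sample size ``n``.

    Each replicate draws ``n`` observations from the multivariate normal
    implied by the standardized path model, refits the model, and tests
    both indirect effects with the delta-method z at ``alpha``
    (two-sided).  Power is the fraction of converged replicates with a
    significant z.  Deterministic under ``seed``.
    """
    if not include_sex:
        params = PathParams(**{**params.__dict__, "beta_sex": 0.0, "r_age_sex": 0.0})
    cov = implied_covariance(params)
    chol = np.linalg.cholesky(cov)
    rng = np.random.default_rng(seed)
    z_crit = sps.norm.ppf(1 - alpha / 2)

    hits_s = hits_r = failures = 0
    for _ in range(n_reps):
        data = rng.standard_normal((n, 5)) @ chol.T
        try:
            cols = [_zscore(data[:, j]) for j in range(5)]
            res = _fit_arrays(*cols, n, compute_fit=False, standardized=True)
        except (np.linalg.LinAlgError, ValueError):
            failures += 1
            continue
        if abs(res.indirect_s.z) > z_crit:
            hits_s += 1
        if abs(res.indirect_r.z) > z_crit:
            hits_r += 1
    done = n_reps - failures
    if done == 0:
        raise RuntimeError("all power replicates failed to converge")
    return PowerResult(
        power_s=hits_s / done,
        power_r=hits_r / done,
        n_reps=n_reps,
        n=n,
        alpha=alpha,
        seed=seed,
        convergence_failures=failures,
    )
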