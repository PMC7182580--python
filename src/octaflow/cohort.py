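"""Cohort statistics: group comparisons and variance-components models.

This layer reproduces the statistical toolkit of a two-group (disease vs
control) ophthalmic cohort in which some subjects contribute both eyes:

* mean arterial pressure, MAP = (1/3) systolic + (2/3) diastolic,
  averaged over repeated cuff readings;
* distributional checks (Shapiro-Wilk normality, folded F equality of
  variances) gating the unpaired t-tests used for subject-level
  covariates, and Fisher's exact test for categorical ones;
* power of a correlation test via the Fisher z transform;
* variance-components linear mixed models with a random subject
  intercept to account for intra-subject eye correlation, used both for
  continuous associations (e.g. morphology vs blood flow per 100 uL/min)
  and for adjusted group differences with the control group as the
  reference level.  All tests are two-sided at alpha = 0.05.

Mixed-model inference uses Wald t statistics on the REML fit with
Satterthwaite degrees of freedom.  With most subjects contributing a
single eye, the information for an eye-level covariate comes largely
from between-subject contrasts, which simple df-counting conventions
(between-within, containment) misjudge badly in one direction or the
other; the Satterthwaite approximation tracks the actual curvature of
the restricted likelihood and keeps small-sample CI coverage near
nominal.  The exact df convention differs across software; differences
show up only in the last digits of p-values at this n.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLM

from octaflow.errors import SingularDesignError

__all__ = [
    "SubjectRecord",
    "EyeRecord",
    "ModelFit",
    "GroupComparison",
    "mean_arterial_pressure",
    "check_assumptions",
    "ttest_from_summary",
    "fisher_exact_2x2",
    "power_correlation",
    "fit_association_model",
    "fit_group_model",
    "records_to_frame",
]

ALPHA = 0.05


def mean_arterial_pressure(readings: Sequence[tuple[float, float]]) -> float:
    """MAP in mmHg from (systolic, diastolic) readings.

    Each reading contributes (1/3) systolic + (2/3) diastolic; the
    per-reading values are averaged (clinically, three cuff readings).

    Raises
    ------
    ValueError
        If no readings are given or any reading has ``dbp >= sbp`` or a
        non-positive pressure.
    """
    if not readings:
        raise ValueError("need at least one blood-pressure reading")
    maps = []
    for sbp, dbp in readings:
        if not dbp > 0:
            raise ValueError("diastolic pressure must be positive")
        if not sbp > dbp:
            raise ValueError(
                f"systolic ({sbp}) must exceed diastolic ({dbp}) pressure"
            )
        maps.append(sbp / 3.0 + 2.0 * dbp / 3.0)
    return float(np.mean(maps))


@dataclass
class SubjectRecord:
    """One study subject with group label and clinical covariates.

    ``map`` is always derived from ``bp_readings``; it is not an input.
    """

    subject_id: str
    group: str
    age: float
    sex: str
    race: str
    bp_readings: list[tuple[float, float]]
    haematocrit: float
    map: float = field(init=False)

    def __post_init__(self) -> None:
        if self.group not in ("SCR", "NC"):
            raise ValueError("group must be SCR or NC")
        if not 0 < self.haematocrit < 100:
            raise ValueError("haematocrit must be a percentage in (0, 100)")
        self.map = mean_arterial_pressure(self.bp_readings)


@dataclass
class EyeRecord:
    """Per-eye metrics; missing metrics are None (excluded listwise)."""

    subject_id: str
    laterality: str
    vti: float | None = None
    vd: float | None = None
    ssv: float | None = None
    slv: float | None = None
    trbf_ul_min: float | None = None

    def __post_init__(self) -> None:
        if self.laterality not in ("OD", "OS"):
            raise ValueError("laterality must be OD or OS")
        if self.trbf_ul_min is not None and self.trbf_ul_min < 0:
            raise ValueError("TRBF cannot be negative")


@dataclass(frozen=True)
class ModelFit:
    """One fixed effect from a variance-components mixed model."""

    beta: float
    ci_low: float
    ci_high: float
    p_value: float
    var_subject: float
    var_residual: float
    se: float = float("nan")
    df: float = float("nan")

    def __post_init__(self) -> None:
        if not self.ci_low <= self.beta <= self.ci_high:
            raise ValueError("beta must lie inside its confidence interval")
        if self.var_subject < 0 or self.var_residual < 0:
            raise ValueError("variance components cannot be negative")


@dataclass(frozen=True)
class GroupComparison:
    """Adjusted group difference (NC reference) with raw group summaries."""

    mean_scr: float
    sd_scr: float
    mean_nc: float
    sd_nc: float
    beta: float
    ci_low: float
    ci_high: float
    p_value: float


def check_assumptions(a: Sequence[float], b: Sequence[float]) -> dict:
    """Shapiro-Wilk normality per sample plus the folded F variance test.

    The folded F statistic is ``s_max^2 / s_min^2`` with the larger
    sample variance in the numerator and a two-sided p-value from the F
    distribution.  Flags are evaluated at alpha = 0.05 (a *passing*
    check is a non-significant test).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each sample needs n >= 3")
    sw_a = stats.shapiro(a)
    sw_b = stats.shapiro(b)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va >= vb:
        f, dfn, dfd = va / vb, len(a) - 1, len(b) - 1
    else:
        f, dfn, dfd = vb / va, len(b) - 1, len(a) - 1
    p_f = min(1.0, 2.0 * stats.f.sf(f, dfn, dfd))
    return {
        "shapiro_w": (float(sw_a.statistic), float(sw_b.statistic)),
        "shapiro_p": (float(sw_a.pvalue), float(sw_b.pvalue)),
        "folded_f": float(f),
        "folded_f_df": (dfn, dfd),
        "folded_f_p": float(p_f),
        "normal": (sw_a.pvalue > ALPHA, sw_b.pvalue > ALPHA),
        "equal_variance": p_f > ALPHA,
    }


def ttest_from_summary(
    m1: float, s1: float, n1: int, m2: float, s2: float, n2: int
) -> dict:
    """Two-sided pooled-variance unpaired t-test from summary statistics."""
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if s1 <= 0 or s2 <= 0:
        raise ValueError("standard deviations must be positive")
    res = stats.ttest_ind_from_stats(m1, s1, n1, m2, s2, n2, equal_var=True)
    return {"t": float(res.statistic), "df": n1 + n2 - 2, "p": float(res.pvalue)}


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher's exact p for the table [[a, b], [c, d]].

    Sums hypergeometric probabilities of all tables with the observed
    margins that are no more probable than the observed table.
    """
    for x in (a, b, c, d):
        if not (isinstance(x, (int, np.integer)) and x >= 0):
            raise ValueError("cell counts must be non-negative integers")
    if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
        raise ValueError("all table margins must be positive")
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def power_correlation(n: int, r: float, alpha: float = ALPHA) -> float:
    """Power of a two-sided test for a Pearson correlation.

    Uses the Fisher z transform: atanh(r_hat) is approximately normal
    with mean atanh(r) and SD 1/sqrt(n - 3), so

        power = Phi(sqrt(n-3) atanh(r) - z_{1-a/2})
              + Phi(-sqrt(n-3) atanh(r) - z_{1-a/2}).

    At r = 0 the power equals alpha (the type-I error rate).
    """
    if n <= 3:
        raise ValueError("n must exceed 3")
    if not 0 <= r < 1:
        raise ValueError("r must lie in [0, 1)")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    z_crit = stats.norm.ppf(1 - alpha / 2)
    shift = np.sqrt(n - 3) * np.arctanh(r)
    return float(stats.norm.cdf(shift - z_crit) + stats.norm.cdf(-shift - z_crit))


# ---------------------------------------------------------------------------
# mixed models


def records_to_frame(
    subjects: Sequence[SubjectRecord], eyes: Sequence[EyeRecord]
) -> pd.DataFrame:
    """Join eye metrics to subject covariates, one row per eye."""
    subj = {s.subject_id: s for s in subjects}
    rows = []
    for e in eyes:
        s = subj[e.subject_id]
        rows.append(
            {
                "subject_id": e.subject_id,
                "laterality": e.laterality,
                "group": s.group,
                "age": s.age,
                "sex": s.sex,
                "race": s.race,
                "map": s.map,
                "haematocrit": s.haematocrit,
                "vti": e.vti,
                "vd": e.vd,
                "ssv": e.ssv,
                "slv": e.slv,
                "trbf": e.trbf_ul_min,
            }
        )
    return pd.DataFrame(rows)


def _encode(df: pd.DataFrame, col: str) -> np.ndarray:
    if col == "laterality":
        return (df[col] == "OS").to_numpy(float)  # OD is reference
    if col == "group":
        return (df[col] == "SCR").to_numpy(float)  # NC is reference
    return df[col].to_numpy(float)


def _check_rank(exog: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(exog)
    if rank < exog.shape[1]:
        from scipy.linalg import qr

        _, _, piv = qr(exog, pivoting=True)
        bad = sorted(names[j] for j in piv[rank:])
        raise SingularDesignError(
            f"singular design: collinear column(s) {', '.join(bad)}"
        )


def _subject_blocks(
    exog: np.ndarray, endog: np.ndarray, groups: np.ndarray
) -> list[tuple[np.ndarray, np.ndarray]]:
    return [
        (exog[groups == g], endog[groups == g]) for g in np.unique(groups)
    ]


def _beta_cov(theta: tuple[float, float], blocks, p: int) -> np.ndarray:
    """GLS covariance of the fixed effects at variance components theta.

    For a random-intercept model each subject block has
    ``V_i = sigma_e^2 I + sigma_u^2 J`` whose inverse is available in
    closed form (Sherman-Morrison).
    """
    var_u, var_e = theta
    info = np.zeros((p, p))
    for x_i, y_i in blocks:
        n_i = len(y_i)
        v_inv = (
            np.eye(n_i) - (var_u / (var_e + n_i * var_u)) * np.ones((n_i, n_i))
        ) / var_e
        info += x_i.T @ v_inv @ x_i
    return np.linalg.inv(info)


def _reml_loglike(theta: tuple[float, float], blocks, p: int) -> float:
    var_u, var_e = max(theta[0], 0.0), theta[1]
    if var_e <= 0:
        return -np.inf
    logdet = 0.0
    quad_parts = []
    info = np.zeros((p, p))
    score = np.zeros(p)
    for x_i, y_i in blocks:
        n_i = len(y_i)
        v_inv = (
            np.eye(n_i) - (var_u / (var_e + n_i * var_u)) * np.ones((n_i, n_i))
        ) / var_e
        logdet += np.linalg.slogdet(
            var_e * np.eye(n_i) + var_u * np.ones((n_i, n_i))
        )[1]
        info += x_i.T @ v_inv @ x_i
        score += x_i.T @ v_inv @ y_i
        quad_parts.append((x_i, y_i, v_inv))
    beta = np.linalg.solve(info, score)
    quad = sum(
        (y_i - x_i @ beta) @ v_inv @ (y_i - x_i @ beta)
        for x_i, y_i, v_inv in quad_parts
    )
    return -0.5 * (logdet + np.linalg.slogdet(info)[1] + quad)


def _satterthwaite_df(
    theta: tuple[float, float], blocks, p: int, j: int, fallback: float
) -> float:
    """Satterthwaite df for fixed effect ``j``: 2 g^2 / (grad' A grad).

    ``g`` is the Wald variance of the effect as a function of the
    variance components and ``A`` the inverse curvature of the REML
    log-likelihood; both derivatives are taken numerically.
    """
    var_u, var_e = max(theta[0], 0.0), theta[1]
    h = max(var_u, var_e) * 1e-5 + 1e-12

    def g(t):
        return _beta_cov((max(t[0], 0.0), t[1]), blocks, p)[j, j]

    try:
        grad = np.array(
            [
                (g((var_u + h, var_e)) - g((max(var_u - h, 0.0), var_e)))
                / (h + min(var_u, h)),
                (g((var_u, var_e + h)) - g((var_u, var_e - h))) / (2 * h),
            ]
        )
        hess = np.zeros((2, 2))
        t0 = np.array([var_u, var_e])
        for a in range(2):
            for b in range(2):
                ea = np.eye(2)[a] * h
                eb = np.eye(2)[b] * h
                hess[a, b] = (
                    _reml_loglike(t0 + ea + eb, blocks, p)
                    - _reml_loglike(t0 + ea - eb, blocks, p)
                    - _reml_loglike(t0 - ea + eb, blocks, p)
                    + _reml_loglike(t0 - ea - eb, blocks, p)
                ) / (4 * h * h)
        denom = grad @ np.linalg.inv(-hess) @ grad
        if not np.isfinite(denom) or denom <= 0:
            return fallback
        df = 2.0 * g((var_u, var_e)) ** 2 / denom
    except np.linalg.LinAlgError:
        return fallback
    if not np.isfinite(df):
        return fallback
    n_obs = sum(len(y_i) for _, y_i in blocks)
    return float(np.clip(df, 1.0, n_obs - p))


def _fit_mixed(
    df: pd.DataFrame, outcome: str, terms: list[str], focus: str
) -> tuple[float, float, float, float, float, float, float]:
    """REML random-intercept fit; Wald t inference on the focus term."""
    cols = [outcome, "subject_id"] + [
        t for t in terms if t in df.columns or t in ("laterality", "group")
    ]
    data = df.dropna(subset=[c for c in cols if c in df.columns]).reset_index(
        drop=True
    )
    if data["subject_id"].nunique() < 2:
        raise ValueError("need eyes from at least 2 subjects")
    endog = data[outcome].to_numpy(float)
    design_cols = [np.ones(len(data))] + [_encode(data, t) for t in terms]
    exog = np.column_stack(design_cols)
    _check_rank(exog, ["intercept"] + terms)
    # center and scale covariates for numerical stability; the focus
    # coefficient and its SE are mapped back to the original scale
    scales = np.ones(exog.shape[1])
    exog_std = exog.copy()
    for j in range(1, exog.shape[1]):
        mu, sd = exog[:, j].mean(), exog[:, j].std()
        if sd > 0:
            exog_std[:, j] = (exog[:, j] - mu) / sd
            scales[j] = sd
    groups = data["subject_id"].to_numpy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # boundary variance fits warn
        model = MixedLM(endog, exog_std, groups=groups)
        try:
            first = model.fit(reml=True)
        except np.linalg.LinAlgError:
            # gradient-based search can fail on near-singular profiles
            first = None
        # gradient-free refinement pass; resolves boundary fits (zero
        # subject variance) that the default optimizer leaves short of
        # the REML optimum
        result = model.fit(
            reml=True,
            start_params=first.params if first is not None else None,
            method="powell",
            maxiter=2000,
        )
    idx = 1 + terms.index(focus)
    beta = float(result.fe_params[idx]) / scales[idx]
    var_subject = max(float(np.asarray(result.cov_re)[0, 0]), 0.0)
    var_residual = float(result.scale)
    blocks = _subject_blocks(exog_std, endog, groups)
    n_obs, p_fixed = exog_std.shape
    # Wald SE from the closed-form GLS covariance at the REML estimates
    # (statsmodels' own covariance can fail near the variance boundary)
    cov_fe = _beta_cov((var_subject, var_residual), blocks, p_fixed)
    se = float(np.sqrt(cov_fe[idx, idx])) / scales[idx]
    dof = _satterthwaite_df(
        (var_subject, var_residual),
        blocks,
        p_fixed,
        idx,
        fallback=float(n_obs - p_fixed),
    )
    t_crit = stats.t.ppf(1 - ALPHA / 2, dof)
    p = float(2 * stats.t.sf(abs(beta) / se, dof)) if se > 0 else float("nan")
    return beta, se, beta - t_crit * se, beta + t_crit * se, p, var_subject, var_residual, dof


def fit_association_model(
    data: pd.DataFrame,
    outcome: str,
    predictor: str = "trbf",
    covariates: Sequence[str] = ("map", "laterality"),
    predictor_scale: float = 100.0,
) -> ModelFit:
    """Association between an eye-level outcome and TRBF, mixed model.

    Fits ``outcome ~ predictor/scale + covariates`` with a random
    subject intercept by REML; the returned ``beta`` is the change in
    the outcome per ``predictor_scale`` units of the predictor (default
    100 uL/min of TRBF), with a two-sided Wald 95% CI and p-value.

    Raises
    ------
    SingularDesignError
        If the fixed-effects design is rank deficient (the error names
        the collinear columns).
    """
    scaled = f"{predictor}_scaled"
    df = data.copy()
    df[scaled] = df[predictor] / predictor_scale
    terms = [scaled] + list(covariates)
    beta, se, lo, hi, p, v_s, v_r, dof = _fit_mixed(df, outcome, terms, scaled)
    return ModelFit(
        beta=beta, ci_low=lo, ci_high=hi, p_value=p,
        var_subject=v_s, var_residual=v_r, se=se, df=dof,
    )


def fit_group_model(
    data: pd.DataFrame,
    outcome: str,
    covariates: Sequence[str] = ("map", "laterality"),
) -> GroupComparison:
    """Adjusted SCR-vs-NC difference in an eye-level outcome.

    Disease group enters as a fixed effect with NC as the reference
    level, alongside the covariates and a random subject intercept; the
    raw per-group mean and SD of the outcome are reported next to the
    adjusted effect.
    """
    terms = ["group"] + list(covariates)
    beta, se, lo, hi, p, *_ = _fit_mixed(data, outcome, terms, "group")
    scr = data.loc[data["group"] == "SCR", outcome].dropna()
    nc = data.loc[data["group"] == "NC", outcome].dropna()
    return GroupComparison(
        mean_scr=float(scr.mean()),
        sd_scr=float(scr.std(ddof=1)),
        mean_nc=float(nc.mean()),
        sd_nc=float(nc.std(ddof=1)),
        beta=beta,
        ci_low=lo,
        ci_high=hi,
        p_value=p,
    )
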