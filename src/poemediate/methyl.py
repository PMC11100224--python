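"""Longitudinal methylation summarization.

Repeated M-value measurements per subject are reduced to a single
subject-level value per CpG by fitting, per CpG, a linear mixed model

    m_value ~ age_c + platform + sex  +  (1 | subject)

by restricted maximum likelihood (REML), where ``age_c`` is mean-centered
age so the intercept is interpretable as the subject mean over follow-up at
the reference platform (450K) and sex (female).  The returned summary is
the estimated fixed intercept plus the subject's best linear unbiased
predictor (BLUP) of the random intercept — the model's posterior mean of
the subject's methylation level — which is then used as the mediator in the
downstream regression models.

For the default random-intercept model the REML profile likelihood is
one-dimensional in the variance ratio τ²/σ² and is maximized directly with
per-subject rank-one updates, which scales to populations of tens of
thousands of subjects; statsmodels MixedLM gives the identical fit and is
used for the optional random-age-slope variant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

__all__ = [
    "mvalue_from_beta",
    "beta_from_mvalue",
    "RandomInterceptFit",
    "fit_random_intercept_reml",
    "summarize_subject_methylation",
]


def mvalue_from_beta(beta):
    """M-value transform, log2(beta / (1 - beta)).

    ``beta`` is the methylated fraction in (0, 1); values at or outside the
    open interval are rejected (callers wanting clipping must pre-clip with
    an explicit epsilon).  Accepts scalars or arrays.
    """
    b = np.asarray(beta, dtype=float)
    if np.any(~np.isfinite(b)) or np.any(b <= 0.0) or np.any(b >= 1.0):
        raise ValueError("beta values must lie strictly in (0, 1)")
    out = np.log2(b / (1.0 - b))
    return float(out) if np.isscalar(beta) else out


def beta_from_mvalue(m):
    """Inverse M-value transform, 2^m / (2^m + 1)."""
    m = np.asarray(m, dtype=float)
    out = 1.0 / (1.0 + np.exp2(-m))
    return float(out) if out.ndim == 0 else out


@dataclass
class RandomInterceptFit:
    """REML fit of y = X fixed + (1 | group) + error."""

    fe_params: np.ndarray
    fe_names: list[str]
    tau2: float
    sigma2: float
    blups: np.ndarray  # one per group, in group-code order
    group_labels: np.ndarray
    reml_loglike: float
    singular: bool  # between-subject variance estimated at (near) zero


def _reml_neg2ll(log_rho: float, y, X, codes, n_groups) -> float:
    rho = np.exp(log_rho)
    beta, r, logdet_sig, xtvx = _profile_beta(rho, y, X, codes, n_groups)
    n, p = X.shape
    sigma2 = r / (n - p)
    sign, logdet_x = np.linalg.slogdet(xtvx)
    # -2 * REML log-likelihood up to an additive constant
    return (n - p) * np.log(sigma2) + logdet_sig + logdet_x


def _profile_beta(rho: float, y, X, codes, n_groups):
    """GLS quantities for V = sigma2 * (I + rho * Z Z') via per-group downdates."""
    n_i = np.bincount(codes, minlength=n_groups).astype(float)
    c_i = rho / (1.0 + rho * n_i)  # shrinkage factor per group
    sum_y = np.bincount(codes, weights=y, minlength=n_groups)
    sum_X = np.vstack(
        [np.bincount(codes, weights=X[:, j], minlength=n_groups) for j in range(X.shape[1])]
    ).T  # n_groups x p
    xtvx = X.T @ X - (sum_X * c_i[:, None]).T @ sum_X
    xtvy = X.T @ y - (sum_X * c_i[:, None]).T @ sum_y
    ytvy = y @ y - c_i @ (sum_y**2)
    beta = np.linalg.solve(xtvx, xtvy)
    r = float(ytvy - beta @ xtvy)
    logdet_sig = float(np.sum(np.log1p(rho * n_i)))
    return beta, r, logdet_sig, xtvx


def fit_random_intercept_reml(
    y: np.ndarray, X: np.ndarray, groups: np.ndarray, fe_names: list[str] | None = None
) -> RandomInterceptFit:
    """Fit a random-intercept linear mixed model by REML.

    Profiles the fixed effects and residual variance out of the restricted
    likelihood, leaving a one-dimensional maximization over the variance
    ratio rho = tau2/sigma2 solved with bounded scalar optimization.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    labels, codes = np.unique(np.asarray(groups), return_inverse=True)
    n_groups = len(labels)
    n, p = X.shape
    if n_groups < 2:
        raise ValueError("need at least 2 subjects to fit a mixed model")
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("fixed-effect design is rank deficient")

    res = minimize_scalar(
        _reml_neg2ll,
        bounds=(-14.0, 14.0),
        args=(y, X, codes, n_groups),
        method="bounded",
        options={"xatol": 1e-10},
    )
    rho = float(np.exp(res.x))
    singular = rho < 1e-6
    if singular:
        rho = 0.0
    beta, r, _, _ = _profile_beta(rho, y, X, codes, n_groups)
    sigma2 = r / (n - p)
    tau2 = rho * sigma2

    resid = y - X @ beta
    n_i = np.bincount(codes, minlength=n_groups).astype(float)
    sum_r = np.bincount(codes, weights=resid, minlength=n_groups)
    blups = (rho / (1.0 + rho * n_i)) * sum_r  # tau2 * 1' V_i^{-1} resid_i
    return RandomInterceptFit(
        fe_params=beta,
        fe_names=fe_names or [f"x{j}" for j in range(p)],
        tau2=float(tau2),
        sigma2=float(sigma2),
        blups=blups,
        group_labels=labels,
        reml_loglike=-0.5 * float(res.fun),
        singular=singular,
    )


def _design_for_cpg(df: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    cols = [np.ones(len(df))]
    names = ["intercept"]
    age_c = df["age_years"].to_numpy(dtype=float)
    age_c = age_c - age_c.mean()
    if age_c.std() > 0:
        cols.append(age_c)
        names.append("age_c")
    epic = (df["platform"].to_numpy() == "EPIC").astype(float)
    if 0.0 < epic.mean() < 1.0:
        cols.append(epic)
        names.append("platform_epic")
    if "sex" in df.columns:
        male = (df["sex"].to_numpy() == "male").astype(float)
        if 0.0 < male.mean() < 1.0:
            cols.append(male)
            names.append("sex_male")
    return np.column_stack(cols), names


def summarize_subject_methylation(
    methylation: pd.DataFrame,
    phenotype: pd.DataFrame | None = None,
    random_slope: bool = False,
) -> pd.DataFrame:
    """One methylation summary per (subject, CpG) from the mixed model.

    Parameters
    ----------
    methylation : long-format frame with columns subject_id, cpg_id,
        age_years, platform, m_value.
    phenotype : optional frame providing ``sex`` per subject_id (joined in
        as a fixed effect when it varies).
    random_slope : if True, additionally fit a random age slope per subject
        (via statsmodels MixedLM); the summary remains the intercept BLUP.

    Returns
    -------
    DataFrame with columns subject_id, cpg_id, summary_m, n_visits, where
    summary_m = fixed intercept + subject BLUP (covariates at reference,
    age at its mean).

    A CpG whose M-values have zero total variance raises; a fit whose
    between-subject variance collapses to zero warns and falls back to the
    fixed-effect prediction (BLUPs are zero in that limit).
    """
    required = {"subject_id", "cpg_id", "age_years", "platform", "m_value"}
    missing = required - set(methylation.columns)
    if missing:
        raise ValueError(f"methylation table missing columns: {sorted(missing)}")
    df = methylation
    if phenotype is not None and "sex" in phenotype.columns:
        df = df.merge(phenotype[["subject_id", "sex"]], on="subject_id", how="left")

    out = []
    for cpg, sub in df.groupby("cpg_id", sort=True):
        y = sub["m_value"].to_numpy(dtype=float)
        if not np.all(np.isfinite(y)):
            raise ValueError(f"non-finite m_value for CpG {cpg}")
        if np.var(y) == 0.0:
            raise ValueError(f"CpG {cpg} has zero total variance")
        X, names = _design_for_cpg(sub)
        groups = sub["subject_id"].to_numpy()
        if random_slope:
            fit = _fit_random_slope(y, X, names, sub)
        else:
            fit = fit_random_intercept_reml(y, X, groups, fe_names=names)
        if fit.singular:
            warnings.warn(
                f"CpG {cpg}: between-subject variance estimated at zero; "
                "summaries fall back to fixed-effect predictions",
                stacklevel=2,
            )
        intercept = fit.fe_params[fit.fe_names.index("intercept")]
        summary = intercept + fit.blups
        n_visits = pd.Series(groups).value_counts()
        out.append(
            pd.DataFrame(
                {
                    "subject_id": fit.group_labels,
                    "cpg_id": cpg,
                    "summary_m": summary,
                    "n_visits": n_visits.reindex(fit.group_labels).to_numpy(dtype=int),
                }
            )
        )
    return pd.concat(out, ignore_index=True)


def _fit_random_slope(y, X, names, sub) -> RandomInterceptFit:
    """Random intercept + random age slope via statsmodels MixedLM."""
    import statsmodels.api as sm

    groups = sub["subject_id"].to_numpy()
    age_c = sub["age_years"].to_numpy(dtype=float)
    age_c = age_c - age_c.mean()
    exog_re = np.column_stack([np.ones(len(sub)), age_c])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(y, X, groups=groups, exog_re=exog_re)
        res = model.fit(reml=True)
    labels = np.array(sorted(pd.unique(groups), key=str))
    re = res.random_effects
    blups = np.array([re[g].iloc[0] for g in labels])
    tau2 = float(np.asarray(res.cov_re)[0, 0])
    return RandomInterceptFit(
        fe_params=np.asarray(res.fe_params),
        fe_names=names,
        tau2=tau2,
        sigma2=float(res.scale),
        blups=blups,
        group_labels=labels,
        reml_loglike=float(res.llf),
        singular=tau2 < 1e-8,
    )
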