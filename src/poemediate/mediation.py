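"""Counterfactual mediation of family-history effects through methylation.

Two regression models are fit on the nested case-control sample:

* **Mediator model** — weighted linear regression of the subject-level
  methylation summary M on the family-history dummies (mother,
  father-or-sibling; "none" is reference) and the high-risk HLA-DR3/4
  genotype, with survey-style case-control weights (cases weighted by
  pi/q, controls by (1-pi)/(1-q)) and a heteroskedasticity-robust sandwich
  covariance:

      M = beta0 + beta1m*FHm + beta1f*FHf + beta2*HLA + eps,  eps ~ (0, sigma2)

* **Outcome model** — unweighted maximum-likelihood logistic regression of
  case status on family history, methylation, their interaction, and HLA:

      logit P(Y=1) = theta0 + theta1m*FHm + theta1f*FHf + theta2*M
                     + theta3m*FHm*M + theta3f*FHf*M + theta4*HLA

  Odds ratios from case-control data are sampling-consistent for all terms
  except the intercept, and theta0 does not enter the effect formulas, so
  no outcome weighting is needed.

The two fits are combined in the counterfactual framework for a rare
binary outcome with a continuous mediator and exposure-mediator
interaction.  For an exposure contrast a=1 vs a*=0 at covariate level c:

    log PNIE = (theta2 + theta3*a*) * beta_a * (a - a*)  =  theta2 * beta_a
    log TNDE = [theta1 + theta3*(beta0 + beta_a*a + beta2*c + theta2*sigma2)]
               * (a - a*)  +  0.5 * theta3**2 * sigma2 * (a**2 - a***2)
    log TE   = log PNIE + log TNDE

(pure natural indirect effect, total natural direct effect; both on the
odds-ratio scale under the rare-outcome approximation).  A Monte-Carlo
counterfactual oracle that averages outcome probabilities over draws of
the mediator provides an independent check of the closed forms.

Confidence intervals come either from the multivariate delta method over
the block-diagonal covariance of (beta, sigma2, theta), or from a
stratified nonparametric bootstrap that refits both models per resample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

__all__ = [
    "CaseControlWeights",
    "compute_cc_weights",
    "MediatorFit",
    "OutcomeFit",
    "MediationEffects",
    "fit_mediator_model",
    "fit_outcome_model",
    "closed_form_effects",
    "decompose_effects",
    "delta_ci",
    "bootstrap_ci",
    "mc_counterfactual_oracle",
    "total_effect",
    "predicted_methylation_by_group",
    "run_mediation",
]

CONTRASTS = ("mother", "father_or_sib")

_MED_NAMES = ["intercept", "fh_mother", "fh_father_or_sib", "hla_dr34"]
_OUT_NAMES = [
    "intercept",
    "fh_mother",
    "fh_father_or_sib",
    "m",
    "fh_mother:m",
    "fh_father_or_sib:m",
    "hla_dr34",
]


@dataclass(frozen=True)
class CaseControlWeights:
    """Inverse-sampling weights for a balanced nested case-control design."""

    pi: float
    q: float
    w_case: float
    w_control: float

    def __post_init__(self):
        if not (0.0 < self.pi < 1.0 and 0.0 < self.q < 1.0):
            raise ValueError("pi and q must lie strictly in (0, 1)")
        ident = self.w_case * self.q + self.w_control * (1.0 - self.q)
        if abs(ident - 1.0) > 1e-12:
            raise ValueError("weights do not satisfy w_case*q + w_control*(1-q) = 1")


def compute_cc_weights(pi: float, q: float) -> CaseControlWeights:
    """Case weight pi/q, control weight (1-pi)/(1-q).

    With pi = 0.06 and a balanced sample (q = 0.5) this down-weights cases
    to 0.12 and up-weights controls to 1.88.
    """
    if not (0.0 < pi < 1.0):
        raise ValueError(f"pi must be in (0, 1), got {pi}")
    if not (0.0 < q < 1.0):
        raise ValueError(f"q must be in (0, 1), got {q}")
    return CaseControlWeights(pi=pi, q=q, w_case=pi / q, w_control=(1.0 - pi) / (1.0 - q))


@dataclass
class MediatorFit:
    beta: pd.Series  # indexed by _MED_NAMES
    robust_cov: pd.DataFrame
    sigma2: float
    conf_int: pd.DataFrame  # columns lower, upper
    pvalues: pd.Series
    nobs: int
    sum_weights: float

    @property
    def df_weighted(self) -> float:
        return self.sum_weights - len(self.beta)


@dataclass
class OutcomeFit:
    theta: pd.Series  # indexed by _OUT_NAMES
    cov: pd.DataFrame
    pvalues: pd.Series
    interaction_p: pd.Series  # Wald p for the two interaction terms
    nobs: int

    def significant_interactions(self, alpha: float = 0.1) -> pd.Series:
        """Interaction flags at the conventional p < 0.1 screening level."""
        return self.interaction_p < alpha


@dataclass
class MediationEffects:
    contrast: str
    c: float
    pnie_or: float
    tnde_or: float
    te_or: float
    log_se: dict = field(default_factory=dict)
    ci: dict = field(default_factory=dict)  # effect -> (lower, upper)
    ci_method: str | None = None


def _merge_design(summaries: pd.DataFrame, phenotype: pd.DataFrame) -> pd.DataFrame:
    df = summaries.merge(phenotype, on="subject_id", how="inner")
    if df["subject_id"].duplicated().any():
        raise ValueError("multiple summaries per subject; summarize one CpG at a time")
    df = df.dropna(subset=["summary_m", "fh_category", "hla_dr34", "case"])
    df["fh_mother"] = (df["fh_category"] == "mother").astype(float)
    df["fh_father_or_sib"] = (df["fh_category"] == "father_or_sib").astype(float)
    return df.reset_index(drop=True)


def _check_aliased(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        _, R = np.linalg.qr(X)
        diag = np.abs(np.diag(R))
        bad = [names[j] for j in np.where(diag < 1e-8 * diag.max())[0]]
        raise ValueError(f"design matrix is collinear; aliased columns: {bad or names}")


def fit_mediator_model(
    summaries: pd.DataFrame,
    phenotype: pd.DataFrame,
    weights: CaseControlWeights,
    cov_type: str = "HC0",
) -> MediatorFit:
    """Weighted linear regression of the methylation summary on exposure.

    Uses statsmodels WLS with case-control weights; the requested
    heteroskedasticity-robust covariance on the weighted model is exactly
    the survey sandwich (weights enter the meat squared).  The residual
    variance sigma2 = sum(w * e^2) / (sum(w) - p) feeds the direct-effect
    closed form.
    """
    import statsmodels.api as sm

    df = _merge_design(summaries, phenotype)
    if df["fh_category"].nunique() < 2:
        raise ValueError("exposure must have at least 2 observed levels")
    y = df["summary_m"].to_numpy(dtype=float)
    X = df[["fh_mother", "fh_father_or_sib", "hla_dr34"]].to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(df)), X])
    _check_aliased(X, _MED_NAMES)
    w = np.where(df["case"].to_numpy() == 1, weights.w_case, weights.w_control)
    res = sm.WLS(y, X, weights=w).fit(cov_type=cov_type)
    resid = y - X @ res.params
    sigma2 = float(np.sum(w * resid**2) / (w.sum() - X.shape[1]))
    ci = res.conf_int()
    return MediatorFit(
        beta=pd.Series(res.params, index=_MED_NAMES),
        robust_cov=pd.DataFrame(res.cov_params(), index=_MED_NAMES, columns=_MED_NAMES),
        sigma2=sigma2,
        conf_int=pd.DataFrame(ci, index=_MED_NAMES, columns=["lower", "upper"]),
        pvalues=pd.Series(res.pvalues, index=_MED_NAMES),
        nobs=len(df),
        sum_weights=float(w.sum()),
    )


def fit_outcome_model(summaries: pd.DataFrame, phenotype: pd.DataFrame) -> OutcomeFit:
    """Logistic outcome model with exposure-methylation interaction."""
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import PerfectSeparationError

    df = _merge_design(summaries, phenotype)
    y = df["case"].to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("outcome must have both cases and controls")
    m = df["summary_m"].to_numpy(dtype=float)
    X = np.column_stack(
        [
            np.ones(len(df)),
            df["fh_mother"],
            df["fh_father_or_sib"],
            m,
            df["fh_mother"] * m,
            df["fh_father_or_sib"] * m,
            df["hla_dr34"],
        ]
    )
    _check_aliased(X, _OUT_NAMES)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", category=RuntimeWarning)
            res = sm.Logit(y, X).fit(disp=0, maxiter=100)
    except PerfectSeparationError as e:
        raise ValueError(f"outcome model: perfect separation ({e})") from e
    if not res.mle_retvals.get("converged", False):
        raise RuntimeError("outcome model did not converge within 100 iterations")
    pvals = pd.Series(res.pvalues, index=_OUT_NAMES)
    return OutcomeFit(
        theta=pd.Series(res.params, index=_OUT_NAMES),
        cov=pd.DataFrame(res.cov_params(), index=_OUT_NAMES, columns=_OUT_NAMES),
        pvalues=pvals,
        interaction_p=pvals[["fh_mother:m", "fh_father_or_sib:m"]],
        nobs=len(df),
    )


def closed_form_effects(
    beta0: float,
    beta_a: float,
    beta2c: float,
    sigma2: float,
    theta1: float,
    theta2: float,
    theta3: float,
    a: float = 1.0,
    a_star: float = 0.0,
) -> tuple[float, float, float]:
    """(PNIE, TNDE, TE) odds ratios from model coefficients.

    ``beta2c`` is the mediator-model covariate contribution beta2 * c at
    the conditioning level c.
    """
    log_pnie = (theta2 + theta3 * a_star) * beta_a * (a - a_star)
    log_tnde = (theta1 + theta3 * (beta0 + beta_a * a + beta2c + theta2 * sigma2)) * (
        a - a_star
    ) + 0.5 * theta3**2 * sigma2 * (a**2 - a_star**2)
    return float(np.exp(log_pnie)), float(np.exp(log_tnde)), float(np.exp(log_pnie + log_tnde))


def _contrast_coefs(med: MediatorFit, out: OutcomeFit, contrast: str):
    if contrast not in CONTRASTS:
        raise ValueError(f"contrast must be one of {CONTRASTS}, got {contrast!r}")
    fh = f"fh_{contrast}"
    for name, obj in ((fh, med.beta), (fh, out.theta), (f"{fh}:m", out.theta)):
        if name not in obj.index:
            raise ValueError(f"required coefficient {name!r} missing from fit")
    return fh


def decompose_effects(
    med: MediatorFit, out: OutcomeFit, contrast: str = "mother", c: float = 0.0
) -> MediationEffects:
    """Combine the two fitted models into PNIE/TNDE/TE odds ratios.

    The other exposure dummy is held at 0 (contrasts are each level vs the
    "none" reference), and effects are conditioned on HLA level ``c``
    (reference 0 by default).
    """
    fh = _contrast_coefs(med, out, contrast)
    pnie, tnde, te = closed_form_effects(
        beta0=med.beta["intercept"],
        beta_a=med.beta[fh],
        beta2c=med.beta["hla_dr34"] * c,
        sigma2=med.sigma2,
        theta1=out.theta[fh],
        theta2=out.theta["m"],
        theta3=out.theta[f"{fh}:m"],
    )
    return MediationEffects(contrast=contrast, c=c, pnie_or=pnie, tnde_or=tnde, te_or=te)


def _delta_gradients(med: MediatorFit, out: OutcomeFit, contrast: str, c: float):
    """Gradients of (log PNIE, log TNDE) wrt the stacked (beta, sigma2, theta)."""
    fh = f"fh_{contrast}"
    beta0 = med.beta["intercept"]
    beta_a = med.beta[fh]
    beta2 = med.beta["hla_dr34"]
    s2 = med.sigma2
    th1 = out.theta[fh]
    th2 = out.theta["m"]
    th3 = out.theta[f"{fh}:m"]

    k = len(_MED_NAMES) + 1 + len(_OUT_NAMES)
    i_beta = {n: j for j, n in enumerate(_MED_NAMES)}
    i_s2 = len(_MED_NAMES)
    i_th = {n: len(_MED_NAMES) + 1 + j for j, n in enumerate(_OUT_NAMES)}

    g_pnie = np.zeros(k)
    g_pnie[i_beta[fh]] = th2
    g_pnie[i_th["m"]] = beta_a

    g_tnde = np.zeros(k)
    g_tnde[i_beta["intercept"]] = th3
    g_tnde[i_beta[fh]] = th3
    g_tnde[i_beta["hla_dr34"]] = th3 * c
    g_tnde[i_s2] = th3 * th2 + 0.5 * th3**2
    g_tnde[i_th[fh]] = 1.0
    g_tnde[i_th["m"]] = th3 * s2
    g_tnde[i_th[f"{fh}:m"]] = beta0 + beta_a + beta2 * c + th2 * s2 + th3 * s2
    return g_pnie, g_tnde


def delta_ci(
    med: MediatorFit,
    out: OutcomeFit,
    contrast: str = "mother",
    c: float = 0.0,
    alpha: float = 0.05,
) -> MediationEffects:
    """Delta-method confidence intervals for PNIE, TNDE, and TE.

    The mediator and outcome fits are treated as independent blocks; the
    sampling variance of sigma2 uses the normal-theory approximation
    2*sigma2^2 / (sum(w) - p).
    """
    _contrast_coefs(med, out, contrast)
    eff = decompose_effects(med, out, contrast=contrast, c=c)
    g_pnie, g_tnde = _delta_gradients(med, out, contrast, c)
    if not (np.all(np.isfinite(g_pnie)) and np.all(np.isfinite(g_tnde))):
        raise ValueError("non-finite gradient in delta method")
    var_s2 = 2.0 * med.sigma2**2 / med.df_weighted
    cov = np.zeros((len(g_pnie), len(g_pnie)))
    p = len(_MED_NAMES)
    cov[:p, :p] = med.robust_cov.to_numpy()
    cov[p, p] = var_s2
    cov[p + 1 :, p + 1 :] = out.cov.to_numpy()

    z = norm.ppf(1.0 - alpha / 2.0)
    log_effects = {
        "pnie": (np.log(eff.pnie_or), g_pnie),
        "tnde": (np.log(eff.tnde_or), g_tnde),
        "te": (np.log(eff.te_or), g_pnie + g_tnde),
    }
    for name, (log_est, grad) in log_effects.items():
        se = float(np.sqrt(grad @ cov @ grad))
        eff.log_se[name] = se
        eff.ci[name] = (float(np.exp(log_est - z * se)), float(np.exp(log_est + z * se)))
    eff.ci_method = "delta"
    return eff


def mc_counterfactual_oracle(
    med_params: tuple[float, float, float, float],
    out_params: tuple[float, float, float, float, float],
    c: float = 0.0,
    n_mc: int = 1_000_000,
    seed: int = 0,
    a: float = 1.0,
    a_star: float = 0.0,
    scale: str = "rr",
) -> tuple[float, float]:
    """Monte-Carlo counterfactual oracle for (PNIE, TNDE).

    Draws the mediator under each exposure level from the mediator model
    with Normal(0, sigma2) errors (common random numbers across levels)
    and averages outcome probabilities to form the counterfactual risks
    P(Y(a*, M(a*))), P(Y(a*, M(a))), and P(Y(a, M(a))).  Returns

        PNIE = P(Y(a*, M(a))) / P(Y(a*, M(a*)))
        TNDE = P(Y(a, M(a)))  / P(Y(a*, M(a)))

    as risk ratios (``scale="rr"``, default) or with each probability
    converted to odds first (``scale="or"``; the closed forms are odds
    ratios, so this removes the OR-vs-RR component of the rare-outcome
    approximation error).  Under a rare outcome both scales approximate
    the closed forms, and PNIE x TNDE equals the total effect.

    Parameters are the raw model coefficients for a single contrast:
    ``med_params = (beta0, beta_a, beta2, sigma2)`` and
    ``out_params = (theta0, theta1, theta2, theta3, theta4)``; ``c`` is
    the covariate (HLA) level conditioned on.
    """
    if n_mc < 1e5:
        raise ValueError("n_mc must be at least 1e5 for a stable oracle")
    beta0, beta_a, beta2, sigma2 = (float(v) for v in med_params)
    th0, th1, th2, th3, th4 = (float(v) for v in out_params)
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    rng = np.random.default_rng(seed)
    eps = rng.normal(0.0, np.sqrt(sigma2), size=int(n_mc))
    m_astar = beta0 + beta_a * a_star + beta2 * c + eps
    m_a = m_astar + beta_a * (a - a_star)

    def risk(expo, m):
        return float(np.mean(expit(th0 + th1 * expo + (th2 + th3 * expo) * m + th4 * c)))

    p_astar_mastar = risk(a_star, m_astar)
    p_astar_ma = risk(a_star, m_a)
    p_a_ma = risk(a, m_a)
    if scale == "or":
        p_astar_mastar, p_astar_ma, p_a_ma = (
            p / (1.0 - p) for p in (p_astar_mastar, p_astar_ma, p_a_ma)
        )
    elif scale != "rr":
        raise ValueError(f"scale must be 'rr' or 'or', got {scale!r}")
    return p_astar_ma / p_astar_mastar, p_a_ma / p_astar_ma


# ---------------------------------------------------------------------------
# Fast refit kernels for the bootstrap (numerically identical to the
# statsmodels fits; verified by unit test).
# ---------------------------------------------------------------------------


def _wls_refit(y, X, w):
    sw = np.sqrt(w)
    beta, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
    resid = y - X @ beta
    sigma2 = float(np.sum(w * resid**2) / (w.sum() - X.shape[1]))
    return beta, sigma2


def _logit_newton(y, X, start, max_iter=60, tol=1e-9):
    beta = start.copy()
    for _ in range(max_iter):
        eta = X @ beta
        mu = expit(eta)
        wdiag = mu * (1.0 - mu)
        grad = X.T @ (y - mu)
        hess = (X * wdiag[:, None]).T @ X
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            return None
        beta = beta + step
        if not np.all(np.isfinite(beta)):
            return None
        if np.max(np.abs(step)) < tol:
            return beta
    return None


def bootstrap_ci(
    summaries: pd.DataFrame,
    phenotype: pd.DataFrame,
    weights: CaseControlWeights,
    contrast: str = "mother",
    c: float = 0.0,
    n_boot: int = 2000,
    seed: int = 0,
    alpha: float = 0.05,
) -> MediationEffects:
    """Stratified nonparametric bootstrap percentile intervals.

    Subjects are resampled with replacement within the case and control
    strata (preserving the design's case fraction q); both models are
    refit per replicate and the closed-form effects recomputed.  More than
    10% replicate fit failures aborts.
    """
    if n_boot < 200:
        raise ValueError("n_boot must be at least 200")
    med = fit_mediator_model(summaries, phenotype, weights)
    out = fit_outcome_model(summaries, phenotype)
    eff = decompose_effects(med, out, contrast=contrast, c=c)
    fh = f"fh_{contrast}"
    j_beta_a = _MED_NAMES.index(fh)
    j_th1 = _OUT_NAMES.index(fh)
    j_th2 = _OUT_NAMES.index("m")
    j_th3 = _OUT_NAMES.index(f"{fh}:m")

    df = _merge_design(summaries, phenotype)
    y_m = df["summary_m"].to_numpy(dtype=float)
    y_o = df["case"].to_numpy(dtype=float)
    m = y_m
    X_m = np.column_stack(
        [np.ones(len(df)), df["fh_mother"], df["fh_father_or_sib"], df["hla_dr34"]]
    )
    X_o = np.column_stack(
        [
            np.ones(len(df)),
            df["fh_mother"],
            df["fh_father_or_sib"],
            m,
            df["fh_mother"] * m,
            df["fh_father_or_sib"] * m,
            df["hla_dr34"],
        ]
    )
    w = np.where(y_o == 1, weights.w_case, weights.w_control)
    idx_case = np.where(y_o == 1)[0]
    idx_ctrl = np.where(y_o == 0)[0]
    start = out.theta.to_numpy()

    rng = np.random.default_rng(seed)
    logs = {"pnie": [], "tnde": [], "te": []}
    failures = 0
    for _ in range(n_boot):
        idx = np.concatenate(
            [
                rng.choice(idx_case, size=len(idx_case), replace=True),
                rng.choice(idx_ctrl, size=len(idx_ctrl), replace=True),
            ]
        )
        Xm_b, Xo_b = X_m[idx], X_o[idx]
        if np.linalg.matrix_rank(Xm_b) < Xm_b.shape[1]:
            failures += 1
            continue
        beta_b, s2_b = _wls_refit(y_m[idx], Xm_b, w[idx])
        theta_b = _logit_newton(y_o[idx], Xo_b, start)
        if theta_b is None or s2_b <= 0:
            failures += 1
            continue
        pnie, tnde, te = closed_form_effects(
            beta0=beta_b[0],
            beta_a=beta_b[j_beta_a],
            beta2c=beta_b[3] * c,
            sigma2=s2_b,
            theta1=theta_b[j_th1],
            theta2=theta_b[j_th2],
            theta3=theta_b[j_th3],
        )
        logs["pnie"].append(np.log(pnie))
        logs["tnde"].append(np.log(tnde))
        logs["te"].append(np.log(te))
    if failures > 0.1 * n_boot:
        raise RuntimeError(
            f"bootstrap: {failures}/{n_boot} replicate fits failed (> 10%)"
        )
    lo, hi = 100 * alpha / 2.0, 100 * (1.0 - alpha / 2.0)
    for name in logs:
        vals = np.asarray(logs[name])
        eff.ci[name] = (
            float(np.exp(np.percentile(vals, lo))),
            float(np.exp(np.percentile(vals, hi))),
        )
        eff.log_se[name] = float(np.std(vals, ddof=1))
    eff.ci_method = "bootstrap"
    return eff


def total_effect(phenotype: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Total-effect odds ratios of family history on T1D, adjusted for HLA.

    Multivariable logistic regression of case status on the two exposure
    dummies and HLA-DR3/4; returns OR and CI per exposure category.
    """
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import PerfectSeparationError

    df = phenotype.dropna(subset=["case", "fh_category", "hla_dr34"]).copy()
    df["fh_mother"] = (df["fh_category"] == "mother").astype(float)
    df["fh_father_or_sib"] = (df["fh_category"] == "father_or_sib").astype(float)
    names = ["intercept", "fh_mother", "fh_father_or_sib", "hla_dr34"]
    X = np.column_stack(
        [np.ones(len(df)), df["fh_mother"], df["fh_father_or_sib"], df["hla_dr34"]]
    )
    _check_aliased(X, names)
    try:
        res = sm.Logit(df["case"].to_numpy(dtype=float), X).fit(disp=0, maxiter=100)
    except PerfectSeparationError as e:
        raise ValueError(f"total effect model: perfect separation ({e})") from e
    ci = res.conf_int(alpha=alpha)
    rows = []
    for term in ("fh_mother", "fh_father_or_sib"):
        j = names.index(term)
        rows.append(
            {
                "contrast": term.removeprefix("fh_"),
                "or": float(np.exp(res.params[j])),
                "lower": float(np.exp(ci[j, 0])),
                "upper": float(np.exp(ci[j, 1])),
                "p_value": float(res.pvalues[j]),
            }
        )
    return pd.DataFrame(rows)


def predicted_methylation_by_group(
    summaries: pd.DataFrame, phenotype: pd.DataFrame
) -> pd.DataFrame:
    """Fitted methylation means by family history x case status.

    Rearranges the outcome model as a linear regression of the methylation
    summary on the family-history-by-case interaction plus HLA, and returns
    the six fitted cell means at the HLA reference level — the standard way
    to visualize an exposure-mediator interaction.
    """
    import statsmodels.api as sm

    df = _merge_design(summaries, phenotype)
    cells = df.groupby(["fh_category", "case"]).size()
    for fh in ("mother", "father_or_sib", "none"):
        for case in (0, 1):
            if (fh, case) not in cells.index:
                raise ValueError(f"empty cell: fh_category={fh!r}, case={case}")
    case = df["case"].to_numpy(dtype=float)
    X = np.column_stack(
        [
            np.ones(len(df)),
            df["fh_mother"],
            df["fh_father_or_sib"],
            case,
            df["fh_mother"] * case,
            df["fh_father_or_sib"] * case,
            df["hla_dr34"],
        ]
    )
    res = sm.OLS(df["summary_m"].to_numpy(dtype=float), X).fit()
    b = res.params
    rows = []
    for fh, (im, iff) in (("mother", (1, 0)), ("father_or_sib", (0, 1)), ("none", (0, 0))):
        for cs in (0, 1):
            mean = b[0] + b[1] * im + b[2] * iff + b[3] * cs + b[4] * im * cs + b[5] * iff * cs
            rows.append({"fh_category": fh, "case": cs, "predicted_m": float(mean)})
    return pd.DataFrame(rows)


def run_mediation(
    summaries: pd.DataFrame,
    phenotype: pd.DataFrame,
    pi: float,
    q: float | None = None,
    c: float = 0.0,
    ci_method: str = "delta",
    n_boot: int = 2000,
    seed: int = 0,
) -> dict:
    """Fit both models and decompose effects for both exposure contrasts.

    ``q`` defaults to the observed case fraction.  Returns a dict with the
    fits, weights, and a MediationEffects per contrast.
    """
    merged = _merge_design(summaries, phenotype)
    if q is None:
        q = float(merged["case"].mean())
    weights = compute_cc_weights(pi, q)
    med = fit_mediator_model(summaries, phenotype, weights)
    out = fit_outcome_model(summaries, phenotype)
    effects = {}
    for contrast in CONTRASTS:
        if ci_method == "delta":
            effects[contrast] = delta_ci(med, out, contrast=contrast, c=c)
        elif ci_method == "bootstrap":
            effects[contrast] = bootstrap_ci(
                summaries, phenotype, weights, contrast=contrast, c=c,
                n_boot=n_boot, seed=seed,
            )
        else:
            raise ValueError(f"unknown ci_method {ci_method!r}")
    return {"weights": weights, "mediator_fit": med, "outcome_fit": out, "effects": effects}
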