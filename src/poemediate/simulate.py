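"""Synthetic nested case-control cohort generator.

Emulates a prospective T1D cohort in which a three-level family-history
exposure (affected mother / affected father or sibling / no first-degree
relative) shifts blood DNA methylation (M-values) at candidate CpGs, and in
which T1D risk depends on family history, methylation, and their
interaction, plus the high-risk HLA-DR3/4 genotype.  The generator produces

* a source population with a target marginal T1D incidence (default 6%),
* longitudinal per-visit M-values (random subject intercept + visit noise,
  with an additive platform offset for EPIC vs 450K arrays),
* a frequency-matched nested case-control subsample, and
* optionally, single-visit log2 gene expression linked linearly to
  methylation (for eQTM analyses).

All ground-truth parameters are carried along so that downstream estimators
can be tested for parameter recovery against closed-form truths.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

__all__ = [
    "FH_LEVELS",
    "SimulationParams",
    "PopulationDataset",
    "simulate_population",
    "sample_case_control",
    "simulate_expression",
    "true_effects",
    "write_dataset",
]

#: Family-history exposure levels, in dummy-coding order.  "none" is the
#: reference level throughout.
FH_LEVELS = ("mother", "father_or_sib", "none")

_PHENOTYPE_COLS = [
    "subject_id",
    "case",
    "fh_category",
    "hla_dr34",
    "sex",
    "nhw",
    "age_dx_or_censor",
]


@dataclass(frozen=True)
class SimulationParams:
    """Ground-truth parameters of the synthetic cohort.

    Coefficient vectors use the dummy coding (mother, father_or_sib) with
    "none" as reference, matching the analysis models:

    * ``beta_true`` — mediator model on the M-value scale:
      (intercept β0, mother β1m, father/sib β1f, HLA β2).
    * ``theta_true`` — outcome logistic model on the log-odds scale:
      (intercept θ0, mother θ1m, father/sib θ1f, methylation θ2,
      mother×methylation θ3m, father/sib×methylation θ3f, HLA θ4).
      θ0 may be ``None``, in which case it is calibrated by bisection so
      the realized population prevalence matches ``incidence_pi``.

    ``tau2_true`` is the between-subject variance of the latent methylation
    level (the residual variance the mediator model sees), while
    ``sigma2_true`` is the within-subject visit-to-visit noise variance.

    Default effect sizes mirror the motivating study: a maternal methylation
    shift of 0.46 M-value units, an outcome interaction that flips the sign
    of the methylation-T1D slope in the affected-mother group, and a true
    maternal pure natural indirect effect (odds ratio) of 2.0.
    """

    n_population: int = 20_000
    incidence_pi: float = 0.06
    exposure_probs: tuple[float, float, float] = (0.18, 0.36, 0.46)
    beta_true: tuple[float, float, float, float] = (0.0, 0.46, 0.05, 0.10)
    sigma2_true: float = 0.1
    theta_true: tuple[float | None, float, float, float, float, float, float] = (
        None,
        1.96,
        1.21,
        1.5069,
        -2.2,
        0.0,
        1.0,
    )
    tau2_true: float = 0.5
    visit_ages: tuple[float, ...] = (0.75, 1.25, 2.0, 4.0, 7.0)
    platform_effect: float = 0.2
    hla_prob_by_exposure: tuple[float, float, float] = (0.30, 0.30, 0.20)
    eqtm_slopes: dict[str, float] | None = None
    expr_noise_sd: float = 0.5
    cpg_id: str = "cgSIM0000001"
    n_null_cpgs: int = 0
    seed: int = 0

    def validate(self) -> None:
        probs = np.asarray(self.exposure_probs, dtype=float)
        if probs.shape != (3,):
            raise ValueError("exposure_probs must have exactly 3 entries")
        if np.any(probs < 0) or np.any(probs > 1):
            raise ValueError("exposure_probs must lie in [0, 1]")
        if abs(probs.sum() - 1.0) > 1e-12:
            raise ValueError(f"exposure_probs must sum to 1, got {probs.sum()!r}")
        if not 0.0 < self.incidence_pi < 1.0:
            raise ValueError("incidence_pi must be in (0, 1)")
        if self.sigma2_true <= 0:
            raise ValueError("sigma2_true must be > 0")
        if self.tau2_true < 0:
            raise ValueError("tau2_true must be >= 0")
        if self.expr_noise_sd < 0:
            raise ValueError("expr_noise_sd must be >= 0")
        ages = np.asarray(self.visit_ages, dtype=float)
        if len(ages) == 0 or np.any(ages <= 0) or np.any(np.diff(ages) <= 0):
            raise ValueError("visit_ages must be strictly increasing and > 0")
        if len(self.beta_true) != 4:
            raise ValueError("beta_true must have 4 entries (β0, β1m, β1f, β2)")
        if len(self.theta_true) != 7:
            raise ValueError("theta_true must have 7 entries (θ0..θ4)")
        hla = np.asarray(self.hla_prob_by_exposure, dtype=float)
        if hla.shape != (3,) or np.any(hla < 0) or np.any(hla > 1):
            raise ValueError("hla_prob_by_exposure must be 3 probabilities")

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        return json.dumps(d, indent=2, sort_keys=True)


@dataclass
class PopulationDataset:
    """A simulated population or case-control subsample.

    Attributes
    ----------
    subjects : DataFrame
        One row per subject: phenotype schema columns plus the ground-truth
        ``latent_m`` (subject-level latent methylation mean of the causal
        CpG), which writers exclude.
    methylation : DataFrame
        Long format: subject_id, cpg_id, age_years, platform, m_value.
    expression : DataFrame or None
        genes x subjects log2 expression matrix (gene_id index).
    expression_obs : DataFrame or None
        Per-subject single-visit methylation and covariates used to
        generate expression (subject_id, m_value, age_years, sex).
    truth : SimulationParams
        Echo of the generating parameters (unmodified).
    meta : dict
        Realized quantities: calibrated θ0, realized prevalence, and for
        case-control subsamples the case sampling fraction ``q`` and
        population incidence ``pi``.
    """

    subjects: pd.DataFrame
    methylation: pd.DataFrame
    expression: pd.DataFrame | None = None
    expression_obs: pd.DataFrame | None = None
    truth: SimulationParams | None = None
    meta: dict = field(default_factory=dict)


def _calibrate_intercept(eta_partial: np.ndarray, pi: float, max_iter: int = 100) -> float:
    """Solve mean(expit(theta0 + eta_partial)) = pi for theta0 by bisection."""
    lo, hi = -60.0, 60.0

    def prev(t0: float) -> float:
        return float(np.mean(expit(t0 + eta_partial)))

    if not (prev(lo) <= pi <= prev(hi)):
        raise RuntimeError("intercept calibration: target prevalence not bracketed")
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        if prev(mid) < pi:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-12:
            break
    else:
        raise RuntimeError("intercept calibration did not converge in 100 bisection steps")
    return 0.5 * (lo + hi)


def simulate_population(params: SimulationParams) -> PopulationDataset:
    """Draw a source population with longitudinal methylation and outcomes.

    The subject-level latent methylation mean is
    ``β0 + β1·exposure + β2·HLA + b_i`` with ``b_i ~ N(0, tau2_true)``;
    per-visit M-values add the platform offset and ``N(0, sigma2_true)``
    visit noise.  The binary outcome is drawn from the logistic outcome
    model evaluated at the latent mean, with θ0 calibrated (if ``None``)
    so the realized prevalence matches ``incidence_pi``.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    n = params.n_population

    fh_code = rng.choice(3, size=n, p=np.asarray(params.exposure_probs, dtype=float))
    is_mother = (fh_code == 0).astype(float)
    is_fathersib = (fh_code == 1).astype(float)
    hla_p = np.asarray(params.hla_prob_by_exposure, dtype=float)[fh_code]
    hla = (rng.random(n) < hla_p).astype(int)
    sex = np.where(rng.random(n) < 0.5, "male", "female")
    nhw = (rng.random(n) < 0.88).astype(int)

    b0, b1m, b1f, b2 = params.beta_true
    latent_mu = b0 + b1m * is_mother + b1f * is_fathersib + b2 * hla
    latent = latent_mu + rng.normal(0.0, math.sqrt(params.tau2_true), size=n)

    t0, t1m, t1f, t2, t3m, t3f, t4 = params.theta_true
    with np.errstate(invalid="ignore"):  # finiteness checked just below
        eta_partial = (
            t1m * is_mother
            + t1f * is_fathersib
            + t2 * latent
            + t3m * is_mother * latent
            + t3f * is_fathersib * latent
            + t4 * hla
        )
    if not np.all(np.isfinite(eta_partial)):
        raise RuntimeError(
            "non-finite outcome linear predictor; check theta_true="
            f"{params.theta_true} and beta_true={params.beta_true}"
        )
    theta0 = float(t0) if t0 is not None else _calibrate_intercept(eta_partial, params.incidence_pi)
    p_case = expit(theta0 + eta_partial)
    case = (rng.random(n) < p_case).astype(int)

    # Diagnosis age for cases, censoring/follow-up age for controls; both
    # drawn from a common distribution so controls are eligible matches in
    # every whole-year age stratum.
    age_dx = np.clip(rng.normal(9.7, 4.6, size=n), 1.0, 20.0)
    age_censor = np.clip(rng.normal(9.7, 4.6, size=n), 1.0, 20.0)
    age_dx_or_censor = np.where(case == 1, age_dx, age_censor)

    subjects = pd.DataFrame(
        {
            "subject_id": [f"S{i:06d}" for i in range(n)],
            "case": case,
            "fh_category": np.array(FH_LEVELS)[fh_code],
            "hla_dr34": hla,
            "sex": sex,
            "nhw": nhw,
            "age_dx_or_censor": np.round(age_dx_or_censor, 3),
            "latent_m": latent,
        }
    )

    n_visits = len(params.visit_ages)
    sub_rep = np.repeat(subjects["subject_id"].to_numpy(), n_visits)
    ages = np.tile(np.asarray(params.visit_ages, dtype=float), n)
    frames = []
    cpg_specs = [(params.cpg_id, latent)]
    for k in range(params.n_null_cpgs):
        null_latent = b0 + rng.normal(0.0, math.sqrt(params.tau2_true), size=n)
        cpg_specs.append((f"cgNULL{k + 1:07d}", null_latent))
    for cpg_id, lat in cpg_specs:
        epic = rng.random(n * n_visits) < 0.5
        m = (
            np.repeat(lat, n_visits)
            + params.platform_effect * epic
            + rng.normal(0.0, math.sqrt(params.sigma2_true), size=n * n_visits)
        )
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": sub_rep,
                    "cpg_id": cpg_id,
                    "age_years": ages,
                    "platform": np.where(epic, "EPIC", "450K"),
                    "m_value": m,
                }
            )
        )
    methylation = pd.concat(frames, ignore_index=True)

    return PopulationDataset(
        subjects=subjects,
        methylation=methylation,
        truth=params,
        meta={
            "theta0": theta0,
            "realized_prevalence": float(case.mean()),
        },
    )


def _stratum_key(df: pd.DataFrame, match_vars: tuple[str, ...]) -> pd.Series:
    parts = []
    for v in match_vars:
        if v == "age":
            parts.append(np.floor(df["age_dx_or_censor"]).astype(int).astype(str))
        elif v in df.columns:
            parts.append(df[v].astype(str))
        else:
            raise ValueError(f"unknown matching variable {v!r}")
    if not parts:
        return pd.Series("all", index=df.index)
    out = parts[0]
    for p in parts[1:]:
        out = out + "|" + p
    return out


def sample_case_control(
    pop: PopulationDataset,
    n_cases: int,
    n_controls: int,
    match_vars: tuple[str, ...] = ("age",),
    seed: int = 0,
) -> PopulationDataset:
    """Draw a nested case-control sample with frequency-matched controls.

    Cases are sampled at random; controls are allocated across the strata
    defined by ``match_vars`` (age is binned by whole years) in proportion
    to the case stratum distribution (largest-remainder rounding), so the
    marginal matching-variable distributions agree.  Records the case
    sampling fraction ``q = n_cases / (n_cases + n_controls)`` used by the
    downstream case-control weights.
    """
    if n_cases <= 0 or n_controls <= 0:
        raise ValueError("n_cases and n_controls must be positive")
    subj = pop.subjects
    cases = subj[subj["case"] == 1]
    controls = subj[subj["case"] == 0]
    if len(cases) < n_cases:
        raise ValueError(f"population has only {len(cases)} cases; {n_cases} requested")
    if len(controls) < n_controls:
        raise ValueError(
            f"population has only {len(controls)} controls; {n_controls} requested"
        )
    rng = np.random.default_rng(seed)
    sel_cases = cases.sample(n=n_cases, random_state=rng)

    case_strata = _stratum_key(sel_cases, match_vars)
    control_strata = _stratum_key(controls, match_vars)
    props = case_strata.value_counts(normalize=True).sort_index()
    raw = props * n_controls
    alloc = np.floor(raw).astype(int)
    remainder = n_controls - int(alloc.sum())
    if remainder > 0:
        order = (raw - alloc).sort_values(ascending=False).index
        for s in order[:remainder]:
            alloc[s] += 1

    picked = []
    for stratum, k in alloc.items():
        if k == 0:
            continue
        eligible = controls[control_strata == stratum]
        if len(eligible) < k:
            raise ValueError(
                f"insufficient controls in matching stratum {stratum!r}: "
                f"need {k}, have {len(eligible)}"
            )
        picked.append(eligible.sample(n=int(k), random_state=rng))
    sel_controls = pd.concat(picked) if picked else controls.iloc[:0]

    sel = pd.concat([sel_cases, sel_controls]).sort_index().reset_index(drop=True)
    ids = set(sel["subject_id"])
    meth = pop.methylation[pop.methylation["subject_id"].isin(ids)].reset_index(drop=True)
    expr = None
    if pop.expression is not None:
        keep = [c for c in pop.expression.columns if c in ids]
        expr = pop.expression[keep]
    meta = dict(pop.meta)
    meta["q"] = n_cases / (n_cases + n_controls)
    meta["pi"] = pop.truth.incidence_pi if pop.truth is not None else None
    return PopulationDataset(
        subjects=sel,
        methylation=meth,
        expression=expr,
        expression_obs=pop.expression_obs,
        truth=pop.truth,
        meta=meta,
    )


def simulate_expression(
    pop: PopulationDataset,
    params: SimulationParams,
    intercept: float = 5.0,
    age_effect: float = 0.05,
    sex_effect: float = 0.10,
) -> PopulationDataset:
    """Attach single-visit log2 expression linked linearly to methylation.

    One post-seroconversion visit per subject: a fresh single-visit M-value
    of the causal CpG is drawn, and per gene g,
    ``log2_expr = intercept + eqtm_slopes[g]·M + age_effect·age +
    sex_effect·I(male) + N(0, expr_noise_sd)``.
    """
    if pop.methylation is None or len(pop.methylation) == 0:
        raise ValueError("population has no methylation data")
    if not params.eqtm_slopes:
        raise ValueError("params.eqtm_slopes must be a non-empty mapping gene -> slope")
    rng = np.random.default_rng([params.seed, 977])
    subj = pop.subjects
    n = len(subj)
    age = max(params.visit_ages) + rng.uniform(0.0, 2.0, size=n)
    m_visit = subj["latent_m"].to_numpy() + rng.normal(
        0.0, math.sqrt(params.sigma2_true), size=n
    )
    male = (subj["sex"].to_numpy() == "male").astype(float)
    rows = {}
    for gene, slope in params.eqtm_slopes.items():
        rows[gene] = (
            intercept
            + slope * m_visit
            + age_effect * age
            + sex_effect * male
            + rng.normal(0.0, params.expr_noise_sd, size=n)
        )
    expr = pd.DataFrame(rows, index=subj["subject_id"]).T
    expr.index.name = "gene_id"
    obs = pd.DataFrame(
        {
            "subject_id": subj["subject_id"].to_numpy(),
            "m_value": m_visit,
            "age_years": age,
            "sex": subj["sex"].to_numpy(),
        }
    )
    return PopulationDataset(
        subjects=subj,
        methylation=pop.methylation,
        expression=expr,
        expression_obs=obs,
        truth=pop.truth,
        meta=dict(pop.meta),
    )


def true_effects(
    params: SimulationParams, contrast: str = "mother", c: float = 0.0
) -> tuple[float, float, float]:
    """Closed-form true (PNIE, TNDE, TE) odds ratios implied by the truth.

    Because the outcome is generated from the subject latent mean, the
    mediator-model residual variance the analysis sees is ``tau2_true``;
    that is the σ² entering the direct-effect formula.
    """
    from .mediation import closed_form_effects

    b0, b1m, b1f, b2 = params.beta_true
    _, t1m, t1f, t2, t3m, t3f, _ = params.theta_true
    if contrast == "mother":
        beta_a, t1, t3 = b1m, t1m, t3m
    elif contrast == "father_or_sib":
        beta_a, t1, t3 = b1f, t1f, t3f
    else:
        raise ValueError(f"unknown contrast {contrast!r}")
    return closed_form_effects(
        beta0=b0, beta_a=beta_a, beta2c=b2 * c, sigma2=params.tau2_true,
        theta1=t1, theta2=t2, theta3=t3,
    )


def write_dataset(dataset: PopulationDataset, outdir: str | Path) -> dict[str, Path]:
    """Write phenotype/methylation/expression TSVs and a truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    pheno = dataset.subjects[_PHENOTYPE_COLS]
    paths["phenotype"] = outdir / "phenotype.tsv"
    pheno.to_csv(paths["phenotype"], sep="\t", index=False)
    paths["methylation"] = outdir / "methylation.tsv"
    dataset.methylation.to_csv(paths["methylation"], sep="\t", index=False)
    if dataset.expression is not None:
        paths["expression"] = outdir / "expression.tsv"
        dataset.expression.to_csv(paths["expression"], sep="\t")
    if dataset.expression_obs is not None:
        paths["expression_obs"] = outdir / "expression_obs.tsv"
        dataset.expression_obs.to_csv(paths["expression_obs"], sep="\t", index=False)
    if dataset.truth is not None:
        paths["truth"] = outdir / "truth.json"
        payload = json.loads(dataset.truth.to_json())
        payload["_meta"] = dataset.meta
        paths["truth"].write_text(json.dumps(payload, indent=2, sort_keys=True))
    return paths
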