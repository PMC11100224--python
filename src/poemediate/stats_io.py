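"""Cohort descriptive statistics, file I/O, and pipeline orchestration.

Implements the descriptive case-control comparison table (counts, column
percentages, and uncorrected Pearson chi-square tests), readers and writers
for the phenotype / methylation / expression / annotation TSV schemas, and
``run_pipeline``, which wires the full analysis end to end:

    summarize -> weighted mediator model -> interaction outcome model ->
    counterfactual decomposition -> E-values -> (optional) eQTM

emitting one TSV per report table plus a JSON run manifest.
"""

from __future__ import annotations

import json
import logging
import sys
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency, fisher_exact

from . import mediation, methyl, sensitivity, simulate
from .eqtm import eqtm_scan

__all__ = [
    "pearson_chisq",
    "table1",
    "format_p",
    "read_phenotype",
    "read_methylation",
    "read_expression",
    "run_pipeline",
]

logger = logging.getLogger("poemediate")
if not logger.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    logger.addHandler(_h)
    logger.setLevel(logging.INFO)


def pearson_chisq(table) -> tuple[float, int, float]:
    """Pearson chi-square test of independence, without continuity correction.

    ``table`` is an r x c array of nonnegative counts.  Returns
    (statistic, degrees of freedom, p-value).  Zero row or column margins
    are rejected (expected counts would be undefined).
    """
    counts = np.asarray(table, dtype=float)
    if counts.ndim != 2 or np.any(counts < 0):
        raise ValueError("table must be a 2-D array of nonnegative counts")
    if counts.sum() <= 0:
        raise ValueError("table total must be positive")
    if np.any(counts.sum(axis=0) == 0) or np.any(counts.sum(axis=1) == 0):
        raise ValueError("table has a zero margin")
    stat, p, dof, _ = chi2_contingency(counts, correction=False)
    return float(stat), int(dof), float(p)


def format_p(p: float) -> str:
    """Display convention: 3 decimals above 0.001, scientific below."""
    return f"{p:.3f}" if p >= 0.001 else f"{p:.1E}"


def _cat_block(df: pd.DataFrame, col: str, label: str, levels, test: str) -> list[dict]:
    counts = pd.crosstab(df[col], df["case"]).reindex(levels, fill_value=0)
    counts = counts.reindex(columns=[1, 0], fill_value=0)
    if test == "fisher" and counts.shape == (2, 2):
        _, p = fisher_exact(counts.to_numpy())
    else:
        _, _, p = pearson_chisq(counts.to_numpy())
    n_case, n_ctrl = counts[1].sum(), counts[0].sum()
    rows = []
    for i, lev in enumerate(levels):
        rows.append(
            {
                "characteristic": label,
                "level": str(lev),
                "case_n": int(counts.loc[lev, 1]),
                "case_pct": 100.0 * counts.loc[lev, 1] / n_case if n_case else np.nan,
                "control_n": int(counts.loc[lev, 0]),
                "control_pct": 100.0 * counts.loc[lev, 0] / n_ctrl if n_ctrl else np.nan,
                "p_value": p if i == 0 else np.nan,
            }
        )
    return rows


def table1(phenotype: pd.DataFrame, test: str = "pearson") -> pd.DataFrame:
    """Descriptive characteristics of cases vs frequency-matched controls.

    Categorical rows carry counts, column percentages, and an uncorrected
    Pearson chi-square p-value (Fisher's exact available via
    ``test="fisher"`` for 2x2 blocks); the diagnosis-age row reports mean
    (SD) among cases only, with no test.
    """
    df = phenotype.copy()
    known = {"mother", "father_or_sib", "none"}
    bad = set(df["fh_category"].unique()) - known
    if bad:
        raise ValueError(f"unknown fh_category level(s): {sorted(bad)}")
    rows: list[dict] = []
    if df["case"].nunique() == 2:
        rows += _cat_block(
            df, "fh_category", "Family history of T1D",
            ["father_or_sib", "mother", "none"], test,
        )
        for col, label in (
            ("hla_dr34", "High risk HLA-DR3/4 genotype"),
            ("sex", "Male"),
            ("nhw", "Non-Hispanic White"),
        ):
            if df[col].nunique() < 2:
                logger.info("table1: skipping constant column %s", col)
                continue
            levels = sorted(df[col].unique(), reverse=True)
            block = _cat_block(df, col, label, levels, test)
            if col == "sex":
                block = [r for r in block if r["level"] == "male"]
                if block:
                    block[0]["p_value"] = _cat_block(df, col, label, levels, test)[0]["p_value"]
            else:
                block = [r for r in block if r["level"] == "1"]
                if block:
                    block[0]["p_value"] = _cat_block(df, col, label, levels, test)[0]["p_value"]
            rows += block
    cases = df[df["case"] == 1]
    if len(cases):
        rows.append(
            {
                "characteristic": "Age at T1D diagnosis (yrs)",
                "level": "mean (SD), cases",
                "case_n": len(cases),
                "case_pct": np.nan,
                "control_n": 0,
                "control_pct": np.nan,
                "p_value": np.nan,
                "mean": float(cases["age_dx_or_censor"].mean()),
                "sd": float(cases["age_dx_or_censor"].std(ddof=1)),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    return pd.read_csv(path, sep=sep)


def read_phenotype(path: str | Path) -> pd.DataFrame:
    df = _read_table(path)
    required = {"subject_id", "case", "fh_category", "hla_dr34", "sex", "nhw"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"phenotype table missing columns: {sorted(missing)}")
    return df


def read_methylation(path: str | Path) -> pd.DataFrame:
    df = _read_table(path)
    required = {"subject_id", "cpg_id", "age_years", "platform", "m_value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"methylation table missing columns: {sorted(missing)}")
    return df


def read_expression(path: str | Path) -> pd.DataFrame:
    return _read_table(path).set_index("gene_id")


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------


def _simulated_inputs(config: dict, seed: int):
    sim_cfg = dict(config.get("simulate", {}))
    n_cases = sim_cfg.pop("n_cases", 87)
    n_controls = sim_cfg.pop("n_controls", 87)
    with_expression = sim_cfg.pop("with_expression", False)
    sim_cfg.setdefault("seed", seed)
    if with_expression and not sim_cfg.get("eqtm_slopes"):
        sim_cfg["eqtm_slopes"] = {"GENE_POS": 0.8, "GENE_NEG": -0.6, "GENE_NULL": 0.0}
    params = simulate.SimulationParams(**sim_cfg)
    pop = simulate.simulate_population(params)
    if with_expression:
        pop = simulate.simulate_expression(pop, params)
    sample = simulate.sample_case_control(
        pop, n_cases=n_cases, n_controls=n_controls, seed=seed + 1
    )
    annotations = None
    if with_expression:
        # Synthetic genomic coordinates: probe at 1 Mb, gene TSSs inside the
        # cis window so every simulated gene is eligible.
        cpgs = sorted(sample.methylation["cpg_id"].unique())
        cpg_ann = pd.DataFrame(
            {
                "cpg_id": cpgs,
                "pos": [1_000_000 + 1000 * i for i in range(len(cpgs))],
                "dmr_id": "DMR_SIM1",
            }
        )
        gene_ids = list(params.eqtm_slopes)
        gene_ann = pd.DataFrame(
            {
                "gene_id": gene_ids,
                "symbol": gene_ids,
                "start": [1_200_000 + 50_000 * i for i in range(len(gene_ids))],
                "end": [1_210_000 + 50_000 * i for i in range(len(gene_ids))],
                "strand": ["+" if i % 2 == 0 else "-" for i in range(len(gene_ids))],
                "biotype": "protein_coding",
            }
        )
        annotations = {"cpg": cpg_ann, "gene": gene_ann}
    return sample, annotations


def _load_inputs(config: dict):
    inp = config["inputs"]
    phenotype = read_phenotype(inp["phenotype"])
    methylation = read_methylation(inp["methylation"])
    sample = simulate.PopulationDataset(subjects=phenotype, methylation=methylation)
    annotations = None
    if "expression" in inp:
        sample.expression = read_expression(inp["expression"])
        sample.expression_obs = _read_table(inp["expression_obs"])
        annotations = {
            "cpg": _read_table(inp["cpg_annotation"]),
            "gene": _read_table(inp["gene_annotation"]),
        }
    return sample, annotations


def run_pipeline(config: dict, out_dir: str | Path) -> dict:
    """Run the full mediation analysis and write report tables.

    ``config`` names either input files (``inputs``) or a simulation
    scenario (``simulate``), plus analysis settings: ``pi`` (population
    incidence), ``ci_method`` ("delta" or "bootstrap"), ``n_boot``,
    ``covariate_level`` ("reference" or "mean"), ``cpgs`` (subset of CpG
    ids), and ``seed``.

    Writes table1.tsv, total_effects.tsv, mediator_model.tsv,
    mediation_effects.tsv, predicted_methylation.tsv, eqtm.tsv (when
    expression inputs are configured) and manifest.json under ``out_dir``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    pi = float(config.get("pi", 0.06))
    ci_method = config.get("ci_method", "delta")
    n_boot = int(config.get("n_boot", 2000))

    stage = "load"
    try:
        if "inputs" in config:
            sample, annotations = _load_inputs(config)
        else:
            sample, annotations = _simulated_inputs(config, seed)
        phenotype = sample.subjects
        logger.info(
            "loaded %d subjects (%d cases), %d methylation rows",
            len(phenotype), int(phenotype["case"].sum()), len(sample.methylation),
        )

        stage = "table1"
        t1 = table1(phenotype)
        t1.to_csv(out_dir / "table1.tsv", sep="\t", index=False)

        stage = "total_effect"
        te = mediation.total_effect(phenotype)
        te.to_csv(out_dir / "total_effects.tsv", sep="\t", index=False)

        stage = "summarize"
        available = set(sample.methylation["cpg_id"].unique())
        cpgs = config.get("cpgs") or sorted(available)
        unknown = [c for c in cpgs if c not in available]
        if unknown:
            raise ValueError(f"unknown CpG id(s): {unknown}")
        summaries = methyl.summarize_subject_methylation(
            sample.methylation[sample.methylation["cpg_id"].isin(cpgs)], phenotype
        )

        med_rows, eff_rows, pred_frames = [], [], []
        for cpg in cpgs:
            stage = f"mediate:{cpg}"
            s = summaries[summaries["cpg_id"] == cpg]
            merged = s.merge(phenotype, on="subject_id")
            c = (
                float(merged["hla_dr34"].mean())
                if config.get("covariate_level") == "mean"
                else 0.0
            )
            res = mediation.run_mediation(
                s, phenotype, pi=pi, c=c, ci_method=ci_method, n_boot=n_boot, seed=seed
            )
            med, out = res["mediator_fit"], res["outcome_fit"]
            row = {"cpg_id": cpg, "sigma2": med.sigma2}
            for short, term in (("mother", "fh_mother"), ("father_or_sib", "fh_father_or_sib")):
                row[f"{short}_estimate"] = round(med.beta[term], 2)
                row[f"{short}_lower"] = round(med.conf_int.loc[term, "lower"], 2)
                row[f"{short}_upper"] = round(med.conf_int.loc[term, "upper"], 2)
                row[f"{short}_p"] = med.pvalues[term]
            med_rows.append(row)
            for contrast, eff in res["effects"].items():
                eff_rows.append(
                    {
                        "cpg_id": cpg,
                        "contrast": contrast,
                        "pnie_or": round(eff.pnie_or, 2),
                        "pnie_lower": round(eff.ci["pnie"][0], 2),
                        "pnie_upper": round(eff.ci["pnie"][1], 2),
                        "tnde_or": round(eff.tnde_or, 2),
                        "tnde_lower": round(eff.ci["tnde"][0], 2),
                        "tnde_upper": round(eff.ci["tnde"][1], 2),
                        "te_or": round(eff.te_or, 2),
                        "interaction_p": out.interaction_p[f"fh_{contrast}:m"],
                        "pnie_evalue": sensitivity.mediational_evalue(
                            eff.pnie_or
                        ).evalue_point,
                        "tnde_evalue": sensitivity.mediational_evalue(
                            eff.tnde_or
                        ).evalue_point,
                        "ci_method": eff.ci_method,
                    }
                )
            pred = mediation.predicted_methylation_by_group(s, phenotype)
            pred.insert(0, "cpg_id", cpg)
            pred_frames.append(pred)

        pd.DataFrame(med_rows).to_csv(out_dir / "mediator_model.tsv", sep="\t", index=False)
        pd.DataFrame(eff_rows).to_csv(
            out_dir / "mediation_effects.tsv", sep="\t", index=False
        )
        pd.concat(pred_frames, ignore_index=True).to_csv(
            out_dir / "predicted_methylation.tsv", sep="\t", index=False
        )

        eqtm_df = None
        if sample.expression is not None and annotations is not None:
            stage = "eqtm"
            obs = sample.expression_obs.merge(
                phenotype[["subject_id", "sex"]], on="subject_id", how="left",
                suffixes=("", "_pheno"),
            )
            if "sex" not in obs.columns and "sex_pheno" in obs.columns:
                obs["sex"] = obs["sex_pheno"]
            obs = obs[obs["subject_id"].isin(phenotype["subject_id"])]
            obs = obs.assign(cpg_id=annotations["cpg"]["cpg_id"].iloc[0])
            eqtm_df = eqtm_scan(
                sample.expression, obs, annotations["cpg"], annotations["gene"]
            )
            eqtm_df.to_csv(out_dir / "eqtm.tsv", sep="\t", index=False)
    except Exception as e:
        logger.error("pipeline failed at stage %s: %s", stage, e)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {e}") from e

    manifest = {
        "seed": seed,
        "pi": pi,
        "ci_method": ci_method,
        "n_subjects": int(len(phenotype)),
        "n_cases": int(phenotype["case"].sum()),
        "cpgs": list(cpgs),
        "outputs": sorted(p.name for p in out_dir.glob("*.tsv")),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    logger.info("pipeline complete; outputs in %s", out_dir)
    return {
        "table1": t1,
        "total_effects": te,
        "mediator_model": pd.DataFrame(med_rows),
        "mediation_effects": pd.DataFrame(eff_rows),
        "eqtm": eqtm_df,
        "manifest": manifest,
    }
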