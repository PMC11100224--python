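"""Expression quantitative trait methylation (eQTM) analysis.

Tests whether methylation at single CpGs, or the first principal component
of the CpGs within a differentially methylated region (DMR), is associated
with log2 expression of nearby genes.  "Nearby" means the gene's
transcription start site lies within a +/- 1 Mb closed window of the probe
position (or the DMR midpoint for regional analyses).  Effects are reported
as the fold change in expression per one standard deviation increase in
methylation M-value — 2^slope from an age- and sex-adjusted ordinary least
squares fit on standardized methylation — so values below 1 encode negative
association.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["EQTMResult", "add_tss", "cis_pairs", "dmr_pc1", "fit_eqtm", "eqtm_scan"]


@dataclass(frozen=True)
class EQTMResult:
    predictor_id: str
    gene_id: str
    fold_change: float
    p_value: float
    n: int
    slope: float
    slope_se: float


def add_tss(genes: pd.DataFrame) -> pd.DataFrame:
    """Derive the transcription start site: start on +, end on - strand.

    ``strand`` may be encoded as "+"/"-" or 1/-1.
    """
    g = genes.copy()
    if (g["start"] > g["end"]).any():
        raise ValueError("gene annotation has start > end")
    strand = g["strand"].astype(str)
    plus = strand.isin({"+", "1"})
    minus = strand.isin({"-", "-1", "−1"})
    if not (plus | minus).all():
        bad = sorted(strand[~(plus | minus)].unique())
        raise ValueError(f"unrecognized strand values: {bad}")
    g["tss"] = np.where(plus, g["start"], g["end"])
    return g


def cis_pairs(
    predictor_pos: int, genes: pd.DataFrame, window: int = 1_000_000
) -> pd.DataFrame:
    """Genes whose TSS lies within the closed window around the predictor.

    ``predictor_pos`` is the 1-based probe position, or the DMR midpoint
    (floor of the mean of the span endpoints) for regional predictors.
    """
    if window < 0:
        raise ValueError("window must be nonnegative")
    g = genes if "tss" in genes.columns else add_tss(genes)
    keep = (g["tss"] - int(predictor_pos)).abs() <= window
    return g[keep].reset_index(drop=True)


def dmr_midpoint(start: int, end: int) -> int:
    """Midpoint of a DMR span, rounded down."""
    return (int(start) + int(end)) // 2


def dmr_pc1(methyl_matrix: pd.DataFrame) -> pd.Series:
    """First principal component of the CpGs in one DMR, per subject.

    Columns (CpGs) are centered and scaled to unit variance before the
    decomposition.  The score sign is anchored so scores correlate
    non-negatively with the per-subject mean of the scaled methylation,
    making the PC1 direction reproducible across runs and subsets.
    """
    X = methyl_matrix.to_numpy(dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 1:
        raise ValueError("need at least 2 subjects and 1 CpG")
    if np.any(~np.isfinite(X)):
        raise ValueError("missing or non-finite methylation values; complete cases only")
    sd = X.std(axis=0, ddof=1)
    zero = np.where(sd == 0.0)[0]
    if len(zero):
        names = [str(methyl_matrix.columns[j]) for j in zero]
        raise ValueError(f"zero-variance CpG column(s): {names}")
    Z = (X - X.mean(axis=0)) / sd
    _, _, vt = np.linalg.svd(Z, full_matrices=False)
    scores = Z @ vt[0]
    anchor = Z.mean(axis=1)
    if float(scores @ anchor) < 0:
        scores = -scores
    return pd.Series(scores, index=methyl_matrix.index, name="pc1")


def fit_eqtm(
    expression: np.ndarray | pd.Series,
    methylation: np.ndarray | pd.Series,
    age: np.ndarray | pd.Series,
    sex: np.ndarray | pd.Series,
    predictor_id: str = "",
    gene_id: str = "",
) -> EQTMResult:
    """OLS of log2 expression on standardized methylation, adjusting age and sex.

    Methylation is standardized to unit sample SD across the included
    subjects, so 2^slope is the expression fold change per 1 SD increase in
    methylation.  ``sex`` may be "male"/"female" labels or 0/1.
    """
    import statsmodels.api as sm

    e = np.asarray(expression, dtype=float)
    m = np.asarray(methylation, dtype=float)
    a = np.asarray(age, dtype=float)
    s = np.asarray(sex)
    if s.dtype.kind in "OUS":
        s = (s == "male").astype(float)
    s = s.astype(float)
    ok = np.isfinite(e) & np.isfinite(m) & np.isfinite(a) & np.isfinite(s)
    e, m, a, s = e[ok], m[ok], a[ok], s[ok]
    n = len(e)
    if n < 10:
        raise ValueError(f"need at least 10 complete observations, have {n}")
    sd = m.std(ddof=1)
    if sd == 0.0:
        raise ValueError("methylation has zero variance")
    z = (m - m.mean()) / sd
    X = np.column_stack([np.ones(n), z, a, s])
    keep = [0, 1] + [j for j in (2, 3) if X[:, j].std() > 0]
    res = sm.OLS(e, X[:, keep]).fit()
    slope = float(res.params[1])
    return EQTMResult(
        predictor_id=predictor_id,
        gene_id=gene_id,
        fold_change=float(2.0**slope),
        p_value=float(res.pvalues[1]),
        n=n,
        slope=slope,
        slope_se=float(res.bse[1]),
    )


def eqtm_scan(
    expression: pd.DataFrame,
    methylation_obs: pd.DataFrame,
    cpg_annotation: pd.DataFrame,
    gene_annotation: pd.DataFrame,
    window: int = 1_000_000,
    include_dmr_pc1: bool = True,
) -> pd.DataFrame:
    """Cis eQTM scan over single CpGs and per-DMR PC1 predictors.

    Parameters
    ----------
    expression : genes x subjects log2 matrix (gene_id index).
    methylation_obs : long frame subject_id, cpg_id, m_value plus
        age_years and sex (single-visit values).
    cpg_annotation : cpg_id, pos, dmr_id (dmr_id may be empty/NaN for
        probes analysed singly only).
    gene_annotation : gene_id, symbol, start, end, strand, biotype.
    """
    genes = add_tss(gene_annotation)
    wide = methylation_obs.pivot_table(
        index="subject_id", columns="cpg_id", values="m_value"
    )
    covars = methylation_obs.drop_duplicates("subject_id").set_index("subject_id")
    subjects = [s for s in wide.index if s in expression.columns]
    wide = wide.loc[subjects]
    covars = covars.loc[subjects]
    expr = expression[subjects]

    predictors: list[tuple[str, int, pd.Series]] = []
    for _, row in cpg_annotation.iterrows():
        cpg = row["cpg_id"]
        if cpg in wide.columns:
            predictors.append((cpg, int(row["pos"]), wide[cpg]))
    if include_dmr_pc1 and "dmr_id" in cpg_annotation.columns:
        ann = cpg_annotation.dropna(subset=["dmr_id"])
        for dmr, grp in ann.groupby("dmr_id"):
            cpgs = [c for c in grp["cpg_id"] if c in wide.columns]
            if not cpgs:
                continue
            mid = dmr_midpoint(grp["pos"].min(), grp["pos"].max())
            predictors.append((f"DMR_PC1:{dmr}", mid, dmr_pc1(wide[cpgs])))

    rows = []
    for pred_id, pos, values in predictors:
        for _, g in cis_pairs(pos, genes, window=window).iterrows():
            if g["gene_id"] not in expr.index:
                continue
            r = fit_eqtm(
                expr.loc[g["gene_id"], values.index],
                values,
                covars.loc[values.index, "age_years"],
                covars.loc[values.index, "sex"],
                predictor_id=pred_id,
                gene_id=g["gene_id"],
            )
            rows.append(
                {
                    "predictor_id": pred_id,
                    "pos": pos,
                    "gene_id": g["gene_id"],
                    "symbol": g.get("symbol", g["gene_id"]),
                    "start": g["start"],
                    "end": g["end"],
                    "strand": g["strand"],
                    "biotype": g.get("biotype", ""),
                    "fold_change": r.fold_change,
                    "p_value": r.p_value,
                    "n": r.n,
                }
            )
    return pd.DataFrame(rows)
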