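"""Protein-group aggregation, per-study covariate-adjusted effects,
random-effects meta-analysis and the nine-sector RNA-protein concordance
classification.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "StudyEffect",
    "MetaResult",
    "aggregate_protein_groups",
    "study_effect",
    "meta_re",
    "percent_change",
    "forest_table",
    "nine_sector",
]


@dataclass
class StudyEffect:
    study_id: str
    gene: str
    y: float  # log2 effect of the HF indicator
    se: float
    n_hf: int
    n_ctrl: int
    shapiro_p: float = np.nan
    scale_location_slope: float = np.nan

    def __post_init__(self) -> None:
        if not self.se > 0:
            raise ValueError("standard error must be positive")


@dataclass
class MetaResult:
    gene: str
    k: int
    mu: float
    se: float
    ci_low: float
    ci_high: float
    z: float
    pvalue: float
    Q: float
    tau2: float
    I2: float  # percent


def aggregate_protein_groups(
    intensities: pd.DataFrame,
    group_to_gene: pd.Series,
    input_scale: str = "linear",
) -> pd.DataFrame:
    """Sum protein-group intensities per gene on the linear scale, then log2.

    ``intensities``: protein groups x samples.  ``input_scale`` may be
    'linear' or 'log2' (log2 tables are linearized before summing).
    Returns gene x sample log2 intensities.
    """
    x = intensities.astype(float)
    if input_scale == "log2":
        x = 2.0**x
    elif input_scale != "linear":
        raise ValueError("input_scale must be 'linear' or 'log2'")
    genes = group_to_gene.reindex(x.index)
    if genes.isna().any():
        missing = list(x.index[genes.isna()])[:5]
        raise ValueError(f"protein groups without gene mapping, e.g. {missing}")
    summed = x.groupby(genes).sum()
    with np.errstate(divide="ignore"):
        return np.log2(summed)


def study_effect(
    gene_table: pd.DataFrame,
    covariates: pd.DataFrame,
    study_id: str = "",
    hf_col: str = "HF",
    adjust: tuple[str, ...] = ("age", "sex"),
) -> list[StudyEffect]:
    """OLS of log2 intensity on HF status adjusting for covariates, per gene.

    ``gene_table``: genes x samples (log2).  ``covariates``: samples x
    columns including ``hf_col`` (0/1) and the adjustment columns.  Constant
    (collinear) covariates are dropped with a warning.  Residual diagnostics
    (Shapiro-Wilk p, scale-location slope) are reported, never gating.
    """
    cov = covariates.loc[gene_table.columns]
    cols = [hf_col]
    for c in adjust:
        if cov[c].nunique() < 2:
            warnings.warn(f"study {study_id}: covariate {c} is constant; dropped")
        else:
            cols.append(c)
    X = np.column_stack(
        [np.ones(len(cov))] + [cov[c].to_numpy(dtype=float) for c in cols]
    )
    n, p = X.shape
    if n <= p:
        raise ValueError(f"study {study_id}: too few samples for the model")
    xtx_inv = np.linalg.inv(X.T @ X)
    hat = xtx_inv @ X.T
    n_hf = int((cov[hf_col] == 1).sum())
    out = []
    for gene, row in gene_table.iterrows():
        y = row.to_numpy(dtype=float)
        beta = hat @ y
        resid = y - X @ beta
        sigma2 = float(resid @ resid) / (n - p)
        se = float(np.sqrt(sigma2 * xtx_inv[1, 1]))
        if se == 0:
            se = np.finfo(float).tiny
        fitted = X @ beta
        try:
            sh_p = float(stats.shapiro(resid).pvalue) if 3 <= n <= 5000 else np.nan
        except ValueError:
            sh_p = np.nan
        sl_slope = _scale_location_slope(fitted, resid)
        out.append(
            StudyEffect(
                study_id=study_id,
                gene=str(gene),
                y=float(beta[1]),
                se=se,
                n_hf=n_hf,
                n_ctrl=n - n_hf,
                shapiro_p=sh_p,
                scale_location_slope=sl_slope,
            )
        )
    return out


def _scale_location_slope(fitted: np.ndarray, resid: np.ndarray) -> float:
    s = np.sqrt(np.abs(resid))
    if np.ptp(fitted) == 0:
        return np.nan
    slope = np.polyfit(fitted, s, 1)[0]
    return float(slope)


def meta_re(effects: list[StudyEffect]) -> MetaResult:
    """DerSimonian-Laird inverse-variance random-effects pooling."""
    if len(effects) < 2:
        raise ValueError("meta-analysis requires >= 2 studies")
    genes = {e.gene for e in effects}
    if len(genes) != 1:
        raise ValueError(f"effects span multiple genes: {sorted(genes)}")
    y = np.array([e.y for e in effects])
    v = np.array([e.se**2 for e in effects])
    k = len(y)
    w = 1.0 / v
    y_fixed = np.sum(w * y) / np.sum(w)
    Q = float(np.sum(w * (y - y_fixed) ** 2))
    denom = np.sum(w) - np.sum(w**2) / np.sum(w)
    tau2 = max(0.0, (Q - (k - 1)) / denom) if denom > 0 else 0.0
    ws = 1.0 / (v + tau2)
    mu = float(np.sum(ws * y) / np.sum(ws))
    se = float(np.sum(ws) ** -0.5)
    I2 = max(0.0, (Q - (k - 1)) / Q) * 100.0 if Q > 0 else 0.0
    z = mu / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    return MetaResult(
        gene=next(iter(genes)),
        k=k,
        mu=mu,
        se=se,
        ci_low=mu - 1.96 * se,
        ci_high=mu + 1.96 * se,
        z=float(z),
        pvalue=p,
        Q=Q,
        tau2=float(tau2),
        I2=float(I2),
    )


def percent_change(log2fc: float) -> float:
    """Convert a log2 fold change to percent change: (2**b - 1) * 100."""
    return (2.0 ** float(log2fc) - 1.0) * 100.0


def forest_table(meta: MetaResult, effects: list[StudyEffect]) -> pd.DataFrame:
    """Study rows plus a pooled row, each with y, se and a 95% CI."""
    rows = []
    for e in effects:
        rows.append(
            {
                "row": e.study_id,
                "kind": "study",
                "y": e.y,
                "se": e.se,
                "ci_low": e.y - 1.96 * e.se,
                "ci_high": e.y + 1.96 * e.se,
                "n_hf": e.n_hf,
                "n_ctrl": e.n_ctrl,
            }
        )
    rows.append(
        {
            "row": "pooled",
            "kind": "pooled",
            "y": meta.mu,
            "se": meta.se,
            "ci_low": meta.ci_low,
            "ci_high": meta.ci_high,
            "n_hf": sum(e.n_hf for e in effects),
            "n_ctrl": sum(e.n_ctrl for e in effects),
        }
    )
    return pd.DataFrame(rows)


_SECTOR = {
    # (protein_state, rna_state) -> sector, rows protein (up, NS, down),
    # columns rna (down, NS, up), row-major 1..9
    ("up", "down"): 1,
    ("up", "NS"): 2,
    ("up", "up"): 3,
    ("NS", "down"): 4,
    ("NS", "NS"): 5,
    ("NS", "up"): 6,
    ("down", "down"): 7,
    ("down", "NS"): 8,
    ("down", "up"): 9,
}


def _axis_state(lfc: float, significant: bool) -> str:
    if not significant or not np.isfinite(lfc):
        return "NS"
    return "up" if lfc > 0 else "down" if lfc < 0 else "NS"


def nine_sector(
    rna: pd.DataFrame,
    protein: pd.DataFrame,
) -> tuple[pd.DataFrame, dict]:
    """Classify genes into the 3x3 RNA/protein regulation grid.

    Both inputs are indexed by gene with columns ``log2FoldChange`` and
    ``significant``; the join is inner.  Returns the per-gene sector table
    and a summary with sector counts and the concordance fraction
    (sectors 3 and 7 over all joined genes).
    """
    genes = rna.index.intersection(protein.index)
    rows = []
    for gene in genes:
        r_state = _axis_state(
            float(rna.loc[gene, "log2FoldChange"]), bool(rna.loc[gene, "significant"])
        )
        p_state = _axis_state(
            float(protein.loc[gene, "log2FoldChange"]),
            bool(protein.loc[gene, "significant"]),
        )
        rows.append(
            {
                "gene": gene,
                "rna_log2fc": float(rna.loc[gene, "log2FoldChange"]),
                "rna_state": r_state,
                "protein_log2fc": float(protein.loc[gene, "log2FoldChange"]),
                "protein_state": p_state,
                "sector": _SECTOR[(p_state, r_state)],
            }
        )
    table = pd.DataFrame(rows).set_index("gene") if rows else pd.DataFrame(
        columns=["rna_log2fc", "rna_state", "protein_log2fc", "protein_state", "sector"]
    )
    counts = {s: int((table["sector"] == s).sum()) for s in range(1, 10)} if len(
        table
    ) else {s: 0 for s in range(1, 10)}
    n = len(table)
    concordant = counts[3] + counts[7]
    summary = {
        "n_genes": n,
        "sector_counts": counts,
        "n_concordant": concordant,
        "concordance_fraction": concordant / n if n else np.nan,
    }
    return table, summary
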