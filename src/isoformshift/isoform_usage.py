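"""Per-gene isoform proportions, Dirichlet-multinomial differential usage and
opposing-direction isoform-switch detection.

A single precision theta, shared between the null and alternative models,
is profiled against the alternative; the usage test is a likelihood-ratio
test with (G-1)(K-1) degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .diffexpr import bh_adjust

__all__ = [
    "UsageResult",
    "SwitchCall",
    "dm_loglik",
    "fit_dm",
    "proportions",
    "detect_opposing",
    "usage_table",
]

_LOG_THETA_LO = np.log(1e-2)
_LOG_THETA_HI = np.log(1e6)


@dataclass
class UsageResult:
    gene_id: str
    K: int
    pi_by_group: dict[str, np.ndarray]
    pi_null: np.ndarray
    theta: float
    lr: float
    df: int
    pvalue: float


@dataclass
class SwitchCall:
    gene_id: str
    up: tuple[str, ...]
    down: tuple[str, ...]

    @property
    def opposing(self) -> bool:
        return bool(self.up) and bool(self.down)


def dm_loglik(y: np.ndarray, pi: np.ndarray, theta: float) -> float:
    """Dirichlet-multinomial log-likelihood (without the multinomial
    normalizing constant, which cancels in likelihood ratios).

    ``y`` is samples x K counts; ``pi`` a probability vector; ``theta`` the
    precision.  K = 1 is degenerate and returns 0.
    """
    y = np.atleast_2d(np.asarray(y, dtype=float))
    pi = np.asarray(pi, dtype=float)
    if pi.ndim != 1 or y.shape[1] != pi.size:
        raise ValueError("pi must be a vector of length K matching y columns")
    if y.shape[1] == 1:
        return 0.0
    n = y.sum(axis=1)
    a = theta * pi
    # guard zero-probability components with zero counts
    keep = a > 0
    if not keep.all() and (y[:, ~keep] > 0).any():
        return -np.inf
    term = special.gammaln(y[:, keep] + a[keep]) - special.gammaln(a[keep])
    return float(
        np.sum(special.gammaln(theta) - special.gammaln(n + theta))
        + term.sum()
    )


def _pi_mle(y: np.ndarray, theta: float, tol: float = 1e-10, max_iter: int = 200) -> np.ndarray:
    """MLE of the mean vector at fixed precision (fixed-point iteration)."""
    y = np.atleast_2d(np.asarray(y, dtype=float))
    tot = y.sum(axis=0)
    pi = tot / tot.sum()
    pi = np.maximum(pi, 1e-12)
    pi /= pi.sum()
    n = y.sum(axis=1)
    for _ in range(max_iter):
        a = theta * pi
        num = (special.digamma(y + a[None, :]) - special.digamma(a[None, :])).sum(axis=0)
        new = pi * np.maximum(num, 1e-300)
        ssum = new.sum()
        if ssum <= 0:
            return pi
        new = new / ssum
        if np.max(np.abs(new - pi)) < tol:
            return new
        pi = new
    return pi


def fit_dm(
    y: np.ndarray | pd.DataFrame,
    groups: np.ndarray | pd.Series,
    gene_id: str = "",
) -> UsageResult:
    """Dirichlet-multinomial usage LRT for one gene.

    ``y``: samples x K isoform counts.  A single precision theta, shared by
    the null and alternative models, is profiled on log-theta in
    [ln 1e-2, ln 1e6] against the alternative (group-wise proportions);
    pooled and group-wise proportions are then estimated at that theta and
    compared by LR against chi-square with (G-1)(K-1) df.
    """
    if isinstance(y, pd.DataFrame):
        iso_ids = list(y.columns)
        y = y.to_numpy(dtype=float)
    else:
        y = np.atleast_2d(np.asarray(y, dtype=float))
        iso_ids = list(range(y.shape[1]))
    g = np.asarray(groups)
    if y.shape[0] != g.size:
        raise ValueError("groups length must match number of samples")
    expressed = y.sum(axis=0) > 0
    if expressed.sum() < y.shape[1]:
        y = y[:, expressed]
    K = y.shape[1]
    levels = sorted(pd.unique(g).tolist())
    G = len(levels)
    if K < 2:
        raise ValueError(f"gene {gene_id or '?'}: fewer than 2 expressed isoforms")
    for lv in levels:
        if (y[g == lv].sum(axis=1) > 0).sum() < 2:
            raise ValueError(
                f"gene {gene_id or '?'}: group {lv} has <2 samples with counts"
            )

    y_by_group = {lv: y[g == lv] for lv in levels}

    def neg_profile(log_theta: float) -> float:
        # theta profiled under the alternative (group-wise proportions) so a
        # real usage shift is not mistaken for overdispersion
        th = np.exp(log_theta)
        return -sum(
            dm_loglik(yg, _pi_mle(yg, th), th) for yg in y_by_group.values()
        )

    res = optimize.minimize_scalar(
        neg_profile, bounds=(_LOG_THETA_LO, _LOG_THETA_HI), method="bounded",
        options={"xatol": 1e-6},
    )
    theta = float(np.exp(res.x))
    pi_null = _pi_mle(y, theta)
    ll_null = dm_loglik(y, pi_null, theta)
    ll_alt = 0.0
    pi_by_group: dict[str, np.ndarray] = {}
    for lv in levels:
        yg = y[g == lv]
        pig = _pi_mle(yg, theta)
        pi_by_group[str(lv)] = pig
        ll_alt += dm_loglik(yg, pig, theta)
    lr = max(0.0, 2.0 * (ll_alt - ll_null))
    df = (G - 1) * (K - 1)
    p = float(stats.chi2.sf(lr, df)) if df > 0 else 1.0
    if G == 1:
        lr, p = 0.0, 1.0
    return UsageResult(gene_id, K, pi_by_group, pi_null, theta, lr, df, p)


def usage_table(
    counts: pd.DataFrame,
    gene_map: pd.Series,
    groups: np.ndarray | pd.Series,
    min_gene_count: int = 10,
) -> pd.DataFrame:
    """Run fit_dm per gene over a transcript x sample count matrix.

    Genes must have total count >= ``min_gene_count`` in at least half the
    samples and >= 2 expressed isoforms; others are reported as filtered.
    """
    g = np.asarray(groups)
    rows = []
    for gene, tids in gene_map.groupby(gene_map).groups.items():
        sub = counts.loc[tids]
        tot = sub.sum(axis=0).to_numpy()
        if (tot >= min_gene_count).sum() < len(tot) / 2.0:
            rows.append({"gene_id": gene, "K": sub.shape[0], "status": "low_count"})
            continue
        if (sub.sum(axis=1) > 0).sum() < 2:
            rows.append({"gene_id": gene, "K": sub.shape[0], "status": "degenerate"})
            continue
        try:
            r = fit_dm(sub.T, g, gene_id=str(gene))
        except ValueError:
            rows.append({"gene_id": gene, "K": sub.shape[0], "status": "degenerate"})
            continue
        rows.append(
            {
                "gene_id": gene,
                "K": r.K,
                "status": "tested",
                "theta": r.theta,
                "lr": r.lr,
                "df": r.df,
                "pvalue": r.pvalue,
            }
        )
    out = pd.DataFrame(rows).set_index("gene_id")
    tested = out["status"] == "tested"
    out["padj"] = np.nan
    out.loc[tested, "padj"] = bh_adjust(out.loc[tested, "pvalue"].to_numpy())
    return out


def proportions(
    counts: pd.DataFrame, groups: np.ndarray | pd.Series
) -> pd.DataFrame:
    """Per-group isoform proportions (group total counts, normalized)."""
    g = np.asarray(groups)
    out = {}
    for lv in pd.unique(g):
        tot = counts.loc[:, g == lv].sum(axis=1)
        s = tot.sum()
        out[str(lv)] = tot / s if s > 0 else tot * np.nan
    return pd.DataFrame(out)


def detect_opposing(
    de: pd.DataFrame,
    gene_map: pd.Series,
    alpha_star: float | None = None,
    use_padj: bool = False,
    padj_threshold: float = 0.05,
) -> pd.DataFrame:
    """Per gene, label isoforms UP/DOWN/NO from transcript-level DE and flag
    genes with significant isoform changes in opposing directions.

    Significance: raw p <= alpha_star (default) or padj <= threshold.
    """
    if use_padj:
        sig = de["padj"] <= padj_threshold
    else:
        if alpha_star is None:
            raise ValueError("alpha_star required unless use_padj=True")
        sig = de["pvalue"] <= alpha_star
    sig = sig.fillna(False)
    direction = np.where(
        ~sig, "NO", np.where(de["log2FoldChange"] > 0, "UP", "DOWN")
    )
    tab = pd.DataFrame(
        {"gene_id": gene_map.reindex(de.index), "direction": direction},
        index=de.index,
    )
    rows = []
    for gene, grp in tab.groupby("gene_id"):
        up = tuple(sorted(grp.index[grp["direction"] == "UP"]))
        down = tuple(sorted(grp.index[grp["direction"] == "DOWN"]))
        rows.append(
            {
                "gene_id": gene,
                "n_up": len(up),
                "n_down": len(down),
                "up": ",".join(up),
                "down": ",".join(down),
                "opposing": bool(up) and bool(down),
            }
        )
    return pd.DataFrame(rows).set_index("gene_id")
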