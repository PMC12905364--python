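"""Negative-binomial Wald differential expression with permutation-calibrated
significance, plus TPM quantification and rank-based group comparison.

The GLM is NB with log link and ``variance = mu + alpha * mu**2``; fits are
vectorized across features (all features share the design matrix), so the
permutation loop re-fits the whole matrix per shuffle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CountMatrix",
    "PermutationCalibration",
    "size_factors",
    "estimate_dispersions",
    "nb_wald",
    "permutation_cutoff",
    "tpm",
    "group_compare_tpm",
    "bh_adjust",
    "design_matrix",
]


@dataclass
class CountMatrix:
    """Feature x sample integer counts with lengths and sample metadata."""

    counts: pd.DataFrame  # features x samples, non-negative integers
    lengths: pd.Series  # feature lengths in bp
    metadata: pd.DataFrame  # indexed by sample; columns condition, age, sex

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if not self.counts.columns.equals(self.metadata.index):
            raise ValueError("count columns and metadata rows must match")
        if not self.lengths.index.equals(self.counts.index):
            raise ValueError("lengths index must match count rows")
        if (self.lengths <= 0).any():
            raise ValueError("feature lengths must be positive")

    @property
    def features(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns


@dataclass
class PermutationCalibration:
    B: int
    min_p: np.ndarray  # per-permutation minimum raw p
    alpha_star: float
    seed: int
    rule: str = "minp"


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up; NaNs pass through and do not count."""
    p = np.asarray(p, dtype=float)
    out = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    m = ok.sum()
    if m == 0:
        return out
    ps = p[ok]
    order = np.argsort(ps)
    ranked = ps[order] * m / (np.arange(m) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(ranked, 1.0)
    out[ok] = adj
    return out


def size_factors(counts: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors, normalized to geometric mean 1."""
    k = np.asarray(counts, dtype=float)
    with np.errstate(divide="ignore"):
        logk = np.log(k)
    all_pos = np.isfinite(logk).all(axis=1)
    if not all_pos.any():
        warnings.warn(
            "no feature with all-positive counts; falling back to total-count ratios"
        )
        totals = k.sum(axis=0)
        s = totals / np.exp(np.mean(np.log(totals)))
        return s
    geomean = np.exp(logk[all_pos].mean(axis=1))
    raw = np.median(k[all_pos] / geomean[:, None], axis=0)
    return raw / np.exp(np.mean(np.log(raw)))  # geometric mean 1


def estimate_dispersions(
    counts: pd.DataFrame | np.ndarray,
    s: np.ndarray,
    alpha_floor: float = 1e-8,
) -> np.ndarray:
    """Per-feature dispersion: method-of-moments blended with a 1/mu trend.

    alpha_hat_i = max(floor, (var_i - mu_i)/mu_i^2) on normalized counts;
    trend a0 + a1/mu fit by least squares; final estimate is the geometric
    mean of the raw estimate and the trend value.
    """
    k = np.asarray(counts, dtype=float) / np.asarray(s)[None, :]
    mu = k.mean(axis=1)
    v = k.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = (v - mu) / mu**2
    raw = np.where(np.isfinite(raw), raw, alpha_floor)
    raw = np.maximum(raw, alpha_floor)
    usable = mu > 0
    if usable.sum() >= 2:
        X = np.column_stack([np.ones(usable.sum()), 1.0 / mu[usable]])
        coef, *_ = np.linalg.lstsq(X, raw[usable], rcond=None)
        a0, a1 = coef
    else:
        a0, a1 = raw.mean(), 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        trend = a0 + a1 / mu
    trend = np.where((mu > 0) & (trend > 0), trend, raw)
    trend = np.maximum(trend, alpha_floor)
    final = np.exp(0.5 * np.log(raw) + 0.5 * np.log(trend))
    return np.maximum(final, alpha_floor)


def design_matrix(
    metadata: pd.DataFrame,
    condition: str = "condition",
    reference: str = "CTRL",
    contrast_groups: tuple[str, ...] | None = None,
    covariates: tuple[str, ...] = (),
) -> tuple[np.ndarray, list[str]]:
    """Intercept + one indicator per non-reference group + optional covariates.

    If ``contrast_groups`` is given, the indicator is 1 for samples in any of
    those groups (pooled contrast, e.g. HF = DCM + ICM vs CTRL).
    """
    cond = metadata[condition].astype(str)
    cols = [np.ones(len(metadata))]
    names = ["intercept"]
    if contrast_groups is not None:
        cols.append(cond.isin(contrast_groups).to_numpy(dtype=float))
        names.append("+".join(contrast_groups))
    else:
        for g in sorted(set(cond) - {reference}):
            cols.append((cond == g).to_numpy(dtype=float))
            names.append(g)
    for c in covariates:
        x = metadata[c].to_numpy(dtype=float)
        sd = x.std()
        cols.append((x - x.mean()) / (sd if sd > 0 else 1.0))
        names.append(c)
    return np.column_stack(cols), names


def _irls_nb(
    k: np.ndarray,
    X: np.ndarray,
    offset: np.ndarray,
    alpha: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized IRLS for NB log-link GLM across features.

    Returns (beta [m, p], cov diag SE of beta [m, p], converged [m]).
    """
    m, n = k.shape
    p = X.shape[1]
    # initial beta from OLS on log pseudo-counts
    z0 = np.log((k + 0.5)) - offset[None, :]
    beta, *_ = np.linalg.lstsq(X, z0.T, rcond=None)
    beta = beta.T  # (m, p)
    alpha = np.asarray(alpha, dtype=float)[:, None]
    converged = np.zeros(m, dtype=bool)
    active = np.ones(m, dtype=bool)
    xtwx = np.empty((m, p, p))
    for _ in range(max_iter):
        idx = np.where(active)[0]
        if idx.size == 0:
            break
        eta = beta[idx] @ X.T + offset[None, :]
        eta = np.clip(eta, -30, 30)
        mu = np.exp(eta)
        W = mu / (1.0 + alpha[idx] * mu)  # IRLS weights for log link
        z = eta - offset[None, :] + (k[idx] - mu) / mu
        # X^T W X and X^T W z per feature
        WX = W[:, :, None] * X[None, :, :]
        A = np.einsum("fnp,nq->fpq", WX, X)
        b = np.einsum("fnp,fn->fp", WX, z)
        # ridge jitter for numerical safety
        A += np.eye(p)[None, :, :] * 1e-10
        new_beta = np.linalg.solve(A, b[..., None])[..., 0]
        delta = np.max(np.abs(new_beta - beta[idx]), axis=1)
        beta[idx] = new_beta
        xtwx[idx] = A
        done = delta < tol
        converged[idx[done]] = True
        active[idx[done]] = False
    # SE from observed information at convergence
    try:
        cov = np.linalg.inv(xtwx)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(xtwx)
    d = np.einsum("fpp->fp", cov)
    se = np.sqrt(np.maximum(d, 0.0))
    return beta, se, converged


def nb_wald(
    counts: pd.DataFrame | np.ndarray,
    s: np.ndarray,
    alpha: np.ndarray,
    design: np.ndarray,
    contrast: int,
    feature_ids: pd.Index | None = None,
) -> pd.DataFrame:
    """Per-feature NB Wald test for one design coefficient.

    Returns a table with baseMean, log2FoldChange, lfcSE, stat, pvalue, padj
    and a converged flag.  All-zero and non-convergent features get NaN p and
    are excluded from the BH denominator.
    """
    k = np.asarray(counts, dtype=float)
    if feature_ids is None:
        feature_ids = (
            counts.index if isinstance(counts, pd.DataFrame) else pd.RangeIndex(len(k))
        )
    X = np.asarray(design, dtype=float)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    offset = np.log(np.asarray(s, dtype=float))
    nonzero = k.sum(axis=1) > 0
    m = k.shape[0]
    beta = np.full((m, X.shape[1]), np.nan)
    se = np.full((m, X.shape[1]), np.nan)
    conv = np.zeros(m, dtype=bool)
    if nonzero.any():
        b, e, c = _irls_nb(k[nonzero], X, offset, np.asarray(alpha)[nonzero])
        beta[nonzero], se[nonzero], conv[nonzero] = b, e, c
    base_mean = (k / np.exp(offset)[None, :]).mean(axis=1)
    bc = beta[:, contrast]
    sec = se[:, contrast]
    with np.errstate(invalid="ignore", divide="ignore"):
        W = bc / sec
    p = 2.0 * stats.norm.sf(np.abs(W))
    p[~conv | ~nonzero | ~np.isfinite(W)] = np.nan
    return pd.DataFrame(
        {
            "baseMean": base_mean,
            "log2FoldChange": bc / np.log(2),
            "lfcSE": sec / np.log(2),
            "stat": W,
            "pvalue": p,
            "padj": bh_adjust(p),
            "converged": conv,
        },
        index=feature_ids,
    )


def permutation_cutoff(
    counts: pd.DataFrame | np.ndarray,
    s: np.ndarray,
    alpha: np.ndarray,
    metadata: pd.DataFrame,
    contrast_spec: dict,
    B: int = 100,
    seed: int = 0,
    rule: str = "minp",
    target: float = 0.05,
) -> PermutationCalibration:
    """Derive a significance cutoff from permuted condition labels.

    For each permutation the condition column is shuffled across samples
    (covariates stay attached to their samples), the Wald test is re-run and
    the minimum raw p recorded.  ``rule='minp'`` sets alpha* to the empirical
    ``target`` (default 5th) percentile of the minima; ``rule='efp'`` sets
    alpha* to the largest threshold with on average <= 1 permuted p below it.
    """
    if rule == "minp" and B < 20:
        raise ValueError(
            "B < 20 gives an unstable 5th percentile; increase B or use rule='efp'"
        )
    rng = np.random.default_rng(seed)
    meta = metadata.copy()
    min_p = np.empty(B)
    all_p: list[np.ndarray] = []
    for b in range(B):
        perm = rng.permutation(len(meta))
        meta["condition"] = metadata["condition"].to_numpy()[perm]
        X, names = design_matrix(meta, **contrast_spec)
        res = nb_wald(counts, s, alpha, X, contrast=1)
        pv = res["pvalue"].to_numpy()
        pv = pv[np.isfinite(pv)]
        min_p[b] = pv.min() if pv.size else 1.0
        if rule == "efp":
            all_p.append(pv)
    if rule == "minp":
        alpha_star = float(np.quantile(min_p, target))
    elif rule == "efp":
        pooled = np.sort(np.concatenate(all_p))
        # largest t with (#permuted p <= t)/B <= 1
        if len(pooled) >= B:
            alpha_star = float(pooled[B - 1])
        else:
            alpha_star = 1.0
    else:
        raise ValueError(f"unknown rule {rule!r}")
    alpha_star = min(max(alpha_star, np.finfo(float).tiny), 1.0 - 1e-12)
    return PermutationCalibration(B=B, min_p=min_p, alpha_star=alpha_star, seed=seed, rule=rule)


def flag_significant(result: pd.DataFrame, calibration: PermutationCalibration) -> pd.DataFrame:
    """Add a boolean ``significant`` column: raw p <= alpha*."""
    out = result.copy()
    out["significant"] = out["pvalue"] <= calibration.alpha_star
    return out


def tpm(counts: pd.DataFrame | np.ndarray, lengths: np.ndarray) -> pd.DataFrame:
    """Transcripts-per-million: length-normalized, column sums of 1e6."""
    k = np.asarray(counts, dtype=float)
    L = np.asarray(lengths, dtype=float)
    rate = k / L[:, None]
    denom = rate.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = rate / denom[None, :] * 1e6
    t = np.where(denom[None, :] > 0, t, 0.0)
    if isinstance(counts, pd.DataFrame):
        return pd.DataFrame(t, index=counts.index, columns=counts.columns)
    return pd.DataFrame(t)


def group_compare_tpm(
    tpm_table: pd.DataFrame, groups: np.ndarray | pd.Series
) -> pd.DataFrame:
    """Per-feature two-sided Mann-Whitney U between two groups, BH-adjusted.

    Exact null for group sizes <= 8 without ties; tie-corrected normal
    approximation otherwise.
    """
    g = np.asarray(groups)
    labels = pd.unique(g)
    if len(labels) != 2:
        raise ValueError("group_compare_tpm requires exactly two groups")
    a = tpm_table.loc[:, g == labels[0]].to_numpy()
    b = tpm_table.loc[:, g == labels[1]].to_numpy()
    n1, n2 = a.shape[1], b.shape[1]
    pvals = np.empty(len(tpm_table))
    stats_u = np.empty(len(tpm_table))
    for i in range(len(tpm_table)):
        x, y = a[i], b[i]
        if np.all(x == x[0]) and np.all(y == y[0]) and x[0] == y[0]:
            stats_u[i], pvals[i] = n1 * n2 / 2.0, 1.0
            continue
        has_ties = len(np.unique(np.concatenate([x, y]))) < n1 + n2
        method = "exact" if (n1 <= 8 and n2 <= 8 and not has_ties) else "asymptotic"
        r = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
        stats_u[i], pvals[i] = r.statistic, min(r.pvalue, 1.0)
    return pd.DataFrame(
        {"U": stats_u, "pvalue": pvals, "padj": bh_adjust(pvals)},
        index=tpm_table.index,
    )
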