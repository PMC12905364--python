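import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import optimize, special, stats

from isoformshift.diffexpr import (
    CountMatrix,
    bh_adjust,
    design_matrix,
    estimate_dispersions,
    flag_significant,
    group_compare_tpm,
    nb_wald,
    permutation_cutoff,
    size_factors,
    tpm,
)
from isoformshift.synthetic_data import CohortDesign, EffectSpec, simulate_counts


def _null_matrix(rng, m=200, alpha=0.2, n1=6, n2=6, mean=100.0):
    n = n1 + n2
    k = rng.negative_binomial(1 / alpha, 1 / (1 + alpha * mean), size=(m, n))
    design = np.column_stack([np.ones(n), np.repeat([0.0, 1.0], [n1, n2])])
    return k.astype(float), design


# ---------------------------------------------------------------------------
# BH


def _bh_brute(p):
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    for rank_pos, i in enumerate(order):
        candidates = [
            p[j] * m / (list(order).index(j) + 1) for j in order[rank_pos:]
        ]
        adj[i] = min(1.0, min(candidates))
    return adj


def test_bh_matches_brute_force(rng):
    for _ in range(10):
        p = rng.uniform(size=15)
        assert np.allclose(bh_adjust(p), _bh_brute(p))


def test_bh_padj_geq_p(rng):
    p = rng.uniform(size=100)
    assert (bh_adjust(p) >= p - 1e-12).all()


def test_bh_nan_passthrough():
    p = np.array([0.01, np.nan, 0.5])
    adj = bh_adjust(p)
    assert np.isnan(adj[1]) and np.isfinite(adj[0])


# ---------------------------------------------------------------------------
# size factors


def test_size_factors_identical_columns():
    k = np.tile(np.array([[10.0], [20.0], [5.0]]), (1, 4))
    assert np.allclose(size_factors(k), 1.0)


def test_size_factors_doubled_column():
    rng = np.random.default_rng(0)
    base = rng.poisson(100, size=(50, 4)).astype(float) + 1
    k = base.copy()
    k[:, 2] *= 2
    s = size_factors(k)
    assert np.allclose(s[2] / s[0], 2.0, rtol=0.05)


def test_size_factors_match_brute_force(rng):
    k = rng.negative_binomial(5, 0.05, size=(100, 6)).astype(float) + 1
    s = size_factors(k)
    # independent median-of-ratios
    geo = np.exp(np.mean(np.log(k), axis=1))
    ratios = k / geo[:, None]
    raw = np.median(ratios, axis=0)
    expect = raw / np.exp(np.mean(np.log(raw)))
    assert np.allclose(s, expect)


def test_size_factors_fallback_warning():
    k = np.array([[0.0, 5.0], [3.0, 0.0]])
    with pytest.warns(UserWarning, match="total-count"):
        size_factors(k)


# ---------------------------------------------------------------------------
# dispersion


def test_dispersions_poisson_near_floor(rng):
    k = rng.poisson(200, size=(500, 200)).astype(float)
    alpha = estimate_dispersions(k, np.ones(200))
    assert np.median(alpha) < 0.01


def test_dispersion_recovery_alpha_02():
    design = CohortDesign(seed=5)
    feats = [f"F{i}" for i in range(2000)]
    cm = simulate_counts(
        feats, design, EffectSpec(dispersion={f: 0.2 for f in feats}), seed=7
    )
    s = size_factors(cm.counts)
    alpha = estimate_dispersions(cm.counts, s)
    assert 0.15 <= np.median(alpha) <= 0.25


def test_dispersion_trend_intercept(rng):
    # constant-mean NB features: the trend intercept approximates alpha
    alpha_true = 0.15
    mean = 500.0
    k = rng.negative_binomial(
        1 / alpha_true, 1 / (1 + alpha_true * mean), size=(3000, 60)
    ).astype(float)
    alpha = estimate_dispersions(k, np.ones(60))
    assert abs(np.median(alpha) - alpha_true) < 0.05


# ---------------------------------------------------------------------------
# Wald test


def test_nb_wald_null_type_one(rng):
    k, X = _null_matrix(rng, m=2000, n1=10, n2=10)
    res = nb_wald(k, np.ones(20), np.full(2000, 0.2), X, contrast=1)
    pv = res["pvalue"].dropna()
    assert 0.03 <= (pv < 0.05).mean() <= 0.07


def test_nb_wald_lfc_consistency(rng):
    n = 200
    k = np.concatenate(
        [rng.poisson(100, size=(1, n)), rng.poisson(400, size=(1, n))], axis=1
    )
    X = np.column_stack([np.ones(2 * n), np.repeat([0.0, 1.0], n)])
    res = nb_wald(k, np.ones(2 * n), np.array([1e-8]), X, contrast=1)
    assert abs(res["log2FoldChange"].iloc[0] - 2.0) < 0.1


def test_nb_wald_matches_grid_mle_oracle(rng):
    # independent oracle: profile the NB log-likelihood by direct optimization
    alpha = 0.1
    k = rng.negative_binomial(1 / alpha, 1 / (1 + alpha * 100), size=(1, 12)).astype(
        float
    )
    k[0, 6:] = rng.negative_binomial(1 / alpha, 1 / (1 + alpha * 300), size=6)
    X = np.column_stack([np.ones(12), np.repeat([0.0, 1.0], 6)])
    res = nb_wald(k, np.ones(12), np.array([alpha]), X, contrast=1)

    def negll(beta):
        mu = np.exp(X @ beta)
        r = 1 / alpha
        return -np.sum(
            special.gammaln(k[0] + r)
            - special.gammaln(r)
            - special.gammaln(k[0] + 1)
            + r * np.log(r / (r + mu))
            + k[0] * np.log(mu / (r + mu))
        )

    opt = optimize.minimize(negll, x0=[4.0, 0.5], method="Nelder-Mead",
                            options={"xatol": 1e-10, "fatol": 1e-12})
    assert abs(res["log2FoldChange"].iloc[0] * np.log(2) - opt.x[1]) < 1e-4


def test_nb_wald_all_zero_feature_excluded(rng):
    k, X = _null_matrix(rng, m=5)
    k[2] = 0
    res = nb_wald(k, np.ones(12), np.full(5, 0.2), X, contrast=1)
    assert np.isnan(res["pvalue"].iloc[2])
    # BH computed over the 4 testable features only
    finite = res["pvalue"].dropna()
    assert np.allclose(
        res["padj"].dropna().to_numpy(), bh_adjust(finite.to_numpy())
    )


def test_nb_wald_rank_deficient_design_raises(rng):
    k, _ = _null_matrix(rng, m=3)
    X = np.ones((12, 2))
    with pytest.raises(ValueError, match="rank"):
        nb_wald(k, np.ones(12), np.full(3, 0.2), X, contrast=1)


def test_nb_wald_invariant_to_within_group_relabeling(rng):
    k, X = _null_matrix(rng, m=50)
    res1 = nb_wald(k, np.ones(12), np.full(50, 0.2), X, contrast=1)
    perm = np.concatenate([np.random.default_rng(1).permutation(6), 6 + np.random.default_rng(2).permutation(6)])
    res2 = nb_wald(k[:, perm], np.ones(12), np.full(50, 0.2), X, contrast=1)
    assert np.allclose(
        res1["log2FoldChange"], res2["log2FoldChange"], atol=1e-6
    )


def test_nb_wald_sample_scaling_absorbed_by_size_factor(rng):
    k, X = _null_matrix(rng, m=100, mean=200.0)
    res1 = nb_wald(k, size_factors(k), np.full(100, 0.2), X, contrast=1)
    k2 = k.copy()
    k2[:, 0] *= 3
    s2 = size_factors(k2)
    assert np.allclose(s2[0] / size_factors(k)[0] / (s2[1] / size_factors(k)[1]), 3.0, rtol=0.02)
    res2 = nb_wald(k2, s2, np.full(100, 0.2), X, contrast=1)
    # NB weights make this invariance approximate (exact only as alpha -> 0)
    assert np.allclose(
        res1["log2FoldChange"], res2["log2FoldChange"], atol=2e-2
    )


# ---------------------------------------------------------------------------
# permutation calibration


def test_permutation_cutoff_deterministic(rng):
    design = CohortDesign(n_ctrl=5, n_dcm=4, n_icm=4, seed=3)
    cm = simulate_counts([f"F{i}" for i in range(100)], design, seed=9)
    s = size_factors(cm.counts)
    alpha = estimate_dispersions(cm.counts, s)
    spec = {"contrast_groups": ("DCM", "ICM")}
    c1 = permutation_cutoff(cm.counts, s, alpha, cm.metadata, spec, B=25, seed=42)
    c2 = permutation_cutoff(cm.counts, s, alpha, cm.metadata, spec, B=25, seed=42)
    assert c1.alpha_star == c2.alpha_star
    assert np.array_equal(c1.min_p, c2.min_p)


def test_permutation_cutoff_small_b_error(rng):
    design = CohortDesign(n_ctrl=3, n_dcm=3, n_icm=3, seed=3)
    cm = simulate_counts([f"F{i}" for i in range(20)], design, seed=9)
    s = size_factors(cm.counts)
    alpha = estimate_dispersions(cm.counts, s)
    with pytest.raises(ValueError, match="efp"):
        permutation_cutoff(
            cm.counts, s, alpha, cm.metadata,
            {"contrast_groups": ("DCM", "ICM")}, B=5, seed=1,
        )


def test_flag_significant_uses_raw_p(rng):
    design = CohortDesign(n_ctrl=5, n_dcm=4, n_icm=4, seed=3)
    cm = simulate_counts([f"F{i}" for i in range(50)], design, seed=9)
    s = size_factors(cm.counts)
    alpha = estimate_dispersions(cm.counts, s)
    X, _ = design_matrix(cm.metadata, contrast_groups=("DCM", "ICM"))
    res = nb_wald(cm.counts, s, alpha, X, contrast=1)
    calib = permutation_cutoff(
        cm.counts, s, alpha, cm.metadata,
        {"contrast_groups": ("DCM", "ICM")}, B=20, seed=1,
    )
    out = flag_significant(res, calib)
    assert out["significant"].equals(out["pvalue"] <= calib.alpha_star)


# ---------------------------------------------------------------------------
# TPM and Mann-Whitney


def test_tpm_single_feature():
    t = tpm(np.array([[5.0, 7.0]]), np.array([100.0]))
    assert np.allclose(t.to_numpy(), 1e6)


def test_tpm_length_normalization():
    t = tpm(np.array([[10.0], [10.0]]), np.array([1000.0, 2000.0]))
    assert np.isclose(t.iloc[0, 0] / t.iloc[1, 0], 2.0)


def test_tpm_column_sums(rng):
    k = rng.poisson(50, size=(30, 8)).astype(float)
    lengths = rng.integers(200, 5000, size=30).astype(float)
    t = tpm(k, lengths)
    assert np.allclose(t.sum(axis=0), 1e6, atol=1e-6)


def test_mwu_identical_groups_p1():
    tab = pd.DataFrame([[3.0] * 6], columns=list("abcdef"))
    res = group_compare_tpm(tab, np.array(["x", "x", "x", "y", "y", "y"]))
    assert res["pvalue"].iloc[0] == 1.0


def test_mwu_exact_p_point1():
    # enumerate all C(6,3)=20 assignments: only the observed split and its
    # mirror are as extreme, p = 2/20
    tab = pd.DataFrame([[1.0, 2.0, 3.0, 4.0, 5.0, 6.0]], columns=list("abcdef"))
    res = group_compare_tpm(tab, np.array(["x", "x", "x", "y", "y", "y"]))
    assert np.isclose(res["pvalue"].iloc[0], 0.1)


def test_mwu_power_monotone_in_shift(rng):
    shifts = [0.0, 2.0, 5.0]
    rates = []
    for shift in shifts:
        rej = 0
        for _ in range(60):
            a = rng.normal(10, 1, size=10)
            b = rng.normal(10 + shift, 1, size=10)
            tab = pd.DataFrame([np.concatenate([a, b])])
            res = group_compare_tpm(tab, np.repeat(["x", "y"], 10))
            rej += res["pvalue"].iloc[0] < 0.05
        rates.append(rej / 60)
    assert rates[0] < rates[1] <= rates[2]


# ---------------------------------------------------------------------------
# CountMatrix contract


def test_count_matrix_validation():
    counts = pd.DataFrame([[1, 2]], index=["f"], columns=["s1", "s2"])
    meta = pd.DataFrame({"condition": ["CTRL", "DCM"]}, index=["s1", "s2"])
    lengths = pd.Series([100], index=["f"])
    CountMatrix(counts, lengths, meta)
    with pytest.raises(ValueError):
        CountMatrix(-counts, lengths, meta)
    with pytest.raises(ValueError):
        CountMatrix(counts, pd.Series([0], index=["f"]), meta)


@settings(max_examples=30, deadline=None)
@given(st.lists(st.floats(0.001, 0.999), min_size=1, max_size=30))
def test_bh_idempotent_on_sorted_property(ps):
    p = np.array(ps)
    adj = bh_adjust(p)
    assert ((adj >= p - 1e-12) & (adj <= 1.0)).all()
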