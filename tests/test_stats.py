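"""Comparative statistics: oracles, identities, and permutation calibration."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from pprd import stats as st


# ----------------------------------------------------------------- G-test

def test_g_test_worked_example():
    """Derepressed TEs (32/265) vs derepressed genes (38/8442)."""
    r = st.g_test_2x2(32, 233, 38, 8404)
    assert r.value == pytest.approx(132.96, abs=0.005)
    assert r.df == 1
    assert r.pvalue == pytest.approx(9.23e-31, rel=0.01)


def test_g_test_independence_is_zero():
    assert st.g_test_2x2(10, 10, 10, 10).value == pytest.approx(0.0)


def test_g_test_matches_direct_formula_and_scipy():
    a, b, c, d = 10, 10, 5, 15
    obs = np.array([[a, b], [c, d]], float)
    exp = np.outer(obs.sum(1), obs.sum(0)) / obs.sum()
    oracle = 2 * (obs * np.log(obs / exp)).sum()
    r = st.g_test_2x2(a, b, c, d)
    assert r.value == pytest.approx(oracle, rel=1e-12)
    g2, _, _, _ = sps.chi2_contingency(obs, correction=False,
                                       lambda_="log-likelihood")
    assert r.value == pytest.approx(g2, rel=1e-12)


def test_g_test_zero_margin_rejected():
    with pytest.raises(ValueError):
        st.g_test_2x2(0, 0, 5, 5)


# ------------------------------------------------------------- chi-square

def test_chi_square_proportional_rows_zero():
    assert st.chi_square_rxc([[10, 20], [5, 10]]).value == pytest.approx(0.0)


def test_chi_square_2x2_equals_squared_z():
    r = st.chi_square_rxc([[12, 28], [22, 18]])
    z = st.two_proportion_z(12, 40, 22, 40)
    assert r.value == pytest.approx(z.value ** 2, rel=1e-10)


def test_chi_square_matches_direct_formula(rng):
    obs = rng.integers(1, 40, size=(3, 2)).astype(float)
    exp = np.outer(obs.sum(1), obs.sum(0)) / obs.sum()
    oracle = ((obs - exp) ** 2 / exp).sum()
    r = st.chi_square_rxc(obs)
    assert r.value == pytest.approx(oracle, rel=1e-12)
    assert r.df == 2


# ---------------------------------------------------------------- Wilcoxon

def test_wilcoxon_identical_samples():
    assert st.wilcoxon_rank_sum([1, 2, 3], [1, 2, 3]).pvalue > 0.99


def test_wilcoxon_complete_separation_floor():
    x, y = [1, 2, 3, 4], [10, 11, 12, 13]
    r = st.wilcoxon_rank_sum(x, y, alternative="less")
    assert r.pvalue == pytest.approx(1 / 70)  # 1 / C(8,4)


def test_wilcoxon_exact_matches_enumeration():
    x, y = [1.0, 5.0, 2.5, 7.0], [3.0, 8.0, 6.0, 9.0]
    pooled = np.array(x + y)
    obs_w = sps.rankdata(pooled)[:4].sum()
    count = 0
    total = 0
    ranks = sps.rankdata(pooled)
    mean_w = ranks.sum() / 2
    for combo in itertools.combinations(range(8), 4):
        w = ranks[list(combo)].sum()
        total += 1
        if abs(w - mean_w) >= abs(obs_w - mean_w) - 1e-12:
            count += 1
    r = st.wilcoxon_rank_sum(x, y)
    assert r.extras["method"] == "exact"
    assert r.pvalue == pytest.approx(count / total)
    assert r.value == pytest.approx(obs_w)


def test_wilcoxon_ties_use_normal_approximation():
    x = [1, 1, 2, 2, 3]
    y = [2, 2, 3, 3, 4]
    assert st.wilcoxon_rank_sum(x, y).extras["method"] == "asymptotic"


# ------------------------------------------------------------------ t-test

def test_t_zero_under_equality():
    assert st.two_sample_t([1, 2, 3], [3, 2, 1]).value == pytest.approx(0.0)


def test_t_pooled_df_accounting():
    x = np.arange(40, dtype=float)
    y = np.arange(33, dtype=float) + 0.5
    assert st.two_sample_t(x, y).df == 71


def test_t_matches_textbook_formula(rng):
    x = rng.normal(0, 1, 9)
    y = rng.normal(0.5, 1, 7)
    nx, ny = len(x), len(y)
    sp2 = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
    oracle = (x.mean() - y.mean()) / np.sqrt(sp2 * (1 / nx + 1 / ny))
    assert st.two_sample_t(x, y).value == pytest.approx(oracle, rel=1e-12)


def test_t_zero_variance_rejected():
    with pytest.raises(ValueError):
        st.two_sample_t([1.0, 1.0], [1.0, 1.0])


# ----------------------------------------------------------------- Pearson

def test_pearson_perfect_lines():
    x = np.arange(10.0)
    assert st.pearson(x, 2 * x + 1).value == pytest.approx(1.0)
    assert st.pearson(x, -x).value == pytest.approx(-1.0)


def test_pearson_matches_covariance_formula(rng):
    x = rng.normal(size=20)
    y = rng.normal(size=20)
    oracle = np.cov(x, y)[0, 1] / (x.std(ddof=1) * y.std(ddof=1))
    assert st.pearson(x, y).value == pytest.approx(oracle, abs=1e-12)


def test_correlations_affine_invariant(rng):
    x = rng.normal(size=15)
    y = rng.normal(size=15)
    assert st.pearson(3 * x + 5, -0.5 * y + 2).value == pytest.approx(
        -st.pearson(x, y).value, rel=1e-10
    )


# ------------------------------------------------------ partial correlation

def residual_regression_pcorr(X: pd.DataFrame, i, j):
    """Regress i and j on all other columns; correlate the residuals."""
    others = [c for c in X.columns if c not in (i, j)]
    Z = np.column_stack([np.ones(len(X)), X[others].to_numpy()])
    ri = X[i].to_numpy() - Z @ np.linalg.lstsq(Z, X[i].to_numpy(), rcond=None)[0]
    rj = X[j].to_numpy() - Z @ np.linalg.lstsq(Z, X[j].to_numpy(), rcond=None)[0]
    return np.corrcoef(ri, rj)[0, 1]


def test_partial_identity_correlation_gives_zero():
    rng = np.random.default_rng(5)
    # whiten so the empirical correlation matrix is exactly the identity
    raw = rng.normal(size=(50, 3))
    c = (raw - raw.mean(0)) / raw.std(0)
    corr = np.corrcoef(c, rowvar=False)
    X = pd.DataFrame(c @ np.linalg.inv(np.linalg.cholesky(corr)).T,
                     columns=list("abc"))
    pc = st.partial_correlation(X)
    off = pc.to_numpy()[~np.eye(3, dtype=bool)]
    assert np.abs(off).max() < 1e-10


def test_partial_vanishes_when_r_xy_equals_product():
    rng = np.random.default_rng(6)
    z = rng.normal(size=500)
    x = 0.8 * z + 0.6 * rng.normal(size=500)
    y = 0.5 * z + np.sqrt(1 - 0.25) * rng.normal(size=500)
    X = pd.DataFrame({"x": x, "y": y, "z": z})
    pc = st.partial_correlation(X)
    oracle = residual_regression_pcorr(X, "x", "y")
    assert pc.loc["x", "y"] == pytest.approx(oracle, abs=1e-10)


def test_partial_matches_residual_oracle_random(rng):
    for _ in range(20):
        X = pd.DataFrame(rng.normal(size=(30, 4)), columns=list("abcd"))
        pc = st.partial_correlation(X)
        for i, j in itertools.combinations("abcd", 2):
            assert pc.loc[i, j] == pytest.approx(
                residual_regression_pcorr(X, i, j), abs=1e-10
            )


def test_partial_matches_pingouin():
    pg = pytest.importorskip("pingouin")
    rng = np.random.default_rng(8)
    X = pd.DataFrame(rng.normal(size=(40, 4)), columns=list("abcd"))
    assert np.allclose(st.partial_correlation(X).to_numpy(),
                       X.pcorr().to_numpy(), atol=1e-10)


def test_partial_requires_nonsingular():
    X = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [2.0, 4, 6, 8],
                      "c": [0.0, 1, 0, 1]})
    with pytest.raises(ValueError, match="singular"):
        st.partial_correlation(X)


# -------------------------------------------------------- permutation test

def test_permutation_deterministic_under_seed():
    rng = np.random.default_rng(9)
    X = pd.DataFrame(rng.normal(size=(30, 4)), columns=list("abcd"))
    r1 = st.permutation_partial_test(X, [("a", "b")], n_perm=100, seed=3)
    r2 = st.permutation_partial_test(X, [("a", "b")], n_perm=100, seed=3)
    pd.testing.assert_frame_equal(r1, r2)


def test_permutation_null_calibration():
    """Independent columns: ~5% of focal pairs flagged over replicates."""
    flags = 0
    n_rep = 100
    for rep in range(n_rep):
        rng = np.random.default_rng(1000 + rep)
        X = pd.DataFrame(rng.normal(size=(40, 4)), columns=list("abcd"))
        out = st.permutation_partial_test(X, [("a", "b")], n_perm=199,
                                          seed=rep)
        flags += int(out["significant"].iloc[0])
    rate = flags / n_rep
    assert rate <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / n_rep)


def test_permutation_power_on_planted_dependence():
    """Planted conditional dependence is flagged in nearly all replicates."""
    hits = 0
    n_rep = 20
    for rep in range(n_rep):
        rng = np.random.default_rng(2000 + rep)
        z = rng.normal(size=60)
        common = rng.normal(size=60)
        x = 0.5 * z + 0.75 * common + 0.4 * rng.normal(size=60)
        y = 0.5 * z + 0.75 * common + 0.4 * rng.normal(size=60)
        X = pd.DataFrame({"x": x, "y": y, "z": z,
                          "w": rng.normal(size=60)})
        out = st.permutation_partial_test(X, [("x", "y")], n_perm=199, seed=rep)
        hits += int(out["significant"].iloc[0])
    assert hits >= 0.95 * n_rep


# -------------------------------------------------- derepression by category

def test_category_equal_proportions_z_near_zero():
    cats = pd.Series(["a"] * 50 + ["b"] * 50)
    flags = pd.Series([True] * 10 + [False] * 40 + [True] * 10 + [False] * 40)
    res = st.derepression_by_category(cats, flags)
    for z in res["pairwise_z"].values():
        assert abs(z.value) < 1e-9


def test_category_extreme_contrast_max_z():
    cats = pd.Series(["a"] * 20 + ["b"] * 20 + ["c"] * 20)
    flags = pd.Series([True] * 20 + [False] * 20 + [True] * 10 + [False] * 10)
    res = st.derepression_by_category(cats, flags)
    zs = {k: abs(v.value) for k, v in res["pairwise_z"].items()}
    assert max(zs, key=zs.get) == ("a", "b")


def test_category_chi_square_null_calibration():
    """Random flags at a fixed rate: chi-square p roughly uniform."""
    rng = np.random.default_rng(12)
    pvals = []
    for _ in range(200):
        cats = pd.Series(rng.choice(["a", "b", "c"], size=120))
        flags = pd.Series(rng.random(120) < 0.12)
        res = st.derepression_by_category(cats, flags)
        if res["chi_square"] is not None:
            pvals.append(res["chi_square"].pvalue)
    ks = sps.kstest(pvals, "uniform").statistic
    assert ks < 0.12  # chi-square approximation at moderate counts


def test_g_and_chi_square_converge_on_scaled_tables():
    base = np.array([[12, 20], [30, 38]], float)
    rel = []
    for scale in (1, 10, 100):
        tab = base * scale
        g = st.g_test_2x2(*tab.ravel()).value
        x2 = st.chi_square_rxc(tab).value
        rel.append(abs(g - x2) / x2)
    assert rel[2] < rel[0]
    assert rel[2] < 0.01
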