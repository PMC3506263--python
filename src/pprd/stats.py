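"""Comparative statistics: G-test, chi-square, Wilcoxon, pooled t, Pearson,
partial correlations, and the permutation-calibrated partial-correlation test.

The G-test is the plain likelihood-ratio statistic 2 sum O ln(O/E) with no
Williams or continuity correction.  Partial correlations come from the
normalized inverse of the correlation matrix.  The permutation null for
partial correlations shuffles the rows of every column except a fixed
reference column independently, which preserves each variable's marginal
distribution while destroying all dependence; a focal observed value is
significant when it exceeds the 95th percentile of its permuted
distribution.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .types import StatResult, digest_inputs


def g_test_2x2(a: float, b: float, c: float, d: float) -> StatResult:
    """Likelihood-ratio (G) test of independence on a 2x2 count table.

    G = 2 sum O ln(O/E) with independence-expected E; df = 1; no Williams
    or continuity correction; p from the chi-square upper tail.
    """
    obs = np.array([[a, b], [c, d]], dtype=float)
    if (obs < 0).any():
        raise ValueError("counts must be non-negative")
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        raise ValueError("all margins must be positive")
    exp = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / obs.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(obs > 0, obs * np.log(obs / exp), 0.0)
    g = 2.0 * terms.sum()
    p = float(stats.chi2.sf(g, 1))
    return StatResult("G", float(g), df=1, pvalue=p, n=int(obs.sum()),
                      inputs_digest=digest_inputs(obs))


def chi_square_rxc(table) -> StatResult:
    """Pearson chi-square of independence on an RxC count table."""
    obs = np.asarray(table, dtype=float)
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        raise ValueError("all margins must be positive")
    x2, p, df, _ = stats.chi2_contingency(obs, correction=False)
    return StatResult("X2", float(x2), df=float(df), pvalue=float(p),
                      n=int(obs.sum()), inputs_digest=digest_inputs(obs))


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float],
                      alternative: str = "two-sided") -> StatResult:
    """Wilcoxon rank-sum (Mann-Whitney) with midranks for ties.

    Exact p when the smaller sample has n <= 8 and there are no ties;
    normal approximation with tie correction otherwise.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if (min(len(x), len(y)) <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative=alternative, method=method)
    # report the rank-sum of x (W) alongside the U statistic
    w = float(res.statistic + len(x) * (len(x) + 1) / 2)
    return StatResult("W", w, pvalue=float(res.pvalue), n=len(x) + len(y),
                      extras={"U": float(res.statistic), "method": method},
                      inputs_digest=digest_inputs(x, y))


def two_sample_t(x: Sequence[float], y: Sequence[float]) -> StatResult:
    """Pooled-variance two-sample t test with df = nx + ny - 2."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) + len(y) < 3:
        raise ValueError("need nx + ny >= 3")
    if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0 and x.mean() == y.mean():
        raise ValueError("zero pooled variance")
    res = stats.ttest_ind(x, y, equal_var=True)
    return StatResult("t", float(res.statistic), df=float(len(x) + len(y) - 2),
                      pvalue=float(res.pvalue), n=len(x) + len(y),
                      inputs_digest=digest_inputs(x, y))


def pearson(x: Sequence[float], y: Sequence[float]) -> StatResult:
    """Pearson correlation with t-based p-value."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 3:
        raise ValueError("need n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance input")
    r, p = stats.pearsonr(x, y)
    return StatResult("r", float(r), df=float(len(x) - 2), pvalue=float(p),
                      n=len(x), inputs_digest=digest_inputs(x, y))


def partial_correlation(X) -> pd.DataFrame:
    """Matrix of partial correlations, each pair controlling all other columns.

    Computed as the negated, normalized inverse of the correlation matrix
    (precision-matrix identity).  Raises on a singular correlation matrix.
    """
    X = pd.DataFrame(X)
    if X.shape[1] < 3:
        raise ValueError("need >= 3 variables")
    if X.isna().any().any():
        raise ValueError("rows must be complete (no missing values)")
    corr = np.corrcoef(X.to_numpy(float), rowvar=False)
    det = np.linalg.det(corr)
    if abs(det) < 1e-12:
        raise ValueError("singular correlation matrix")
    prec = np.linalg.inv(corr)
    d = np.sqrt(np.diag(prec))
    pcorr = -prec / np.outer(d, d)
    np.fill_diagonal(pcorr, 1.0)
    return pd.DataFrame(pcorr, index=X.columns, columns=X.columns)


def permutation_partial_test(
    X,
    focal_pairs: Sequence[tuple],
    n_perm: int = 10_000,
    seed: int = 0,
    reference: Optional[str] = None,
    quantile: float = 0.95,
) -> pd.DataFrame:
    """Permutation calibration of partial correlations.

    Each permutation independently shuffles the row order of every column
    except the fixed ``reference`` column (default: first column), then
    recomputes the partial-correlation matrix.  An observed focal value is
    flagged significant when it exceeds the ``quantile`` (default 95th
    percentile) of its permuted distribution.  Fully reproducible under
    ``seed``.
    """
    X = pd.DataFrame(X)
    if reference is None:
        reference = X.columns[0]
    rng = np.random.default_rng(int(seed) % (2**31))
    observed = partial_correlation(X)
    perm_vals = {pair: np.empty(n_perm) for pair in focal_pairs}
    data = X.to_numpy(float)
    cols = list(X.columns)
    ref_idx = cols.index(reference)
    work = data.copy()
    n = len(X)
    for k in range(n_perm):
        for j in range(work.shape[1]):
            if j == ref_idx:
                work[:, j] = data[:, j]
            else:
                work[:, j] = data[rng.permutation(n), j]
        corr = np.corrcoef(work, rowvar=False)
        prec = np.linalg.inv(corr)
        d = np.sqrt(np.diag(prec))
        pc = -prec / np.outer(d, d)
        for (u, v) in focal_pairs:
            perm_vals[(u, v)][k] = pc[cols.index(u), cols.index(v)]
    rows = []
    for (u, v) in focal_pairs:
        thr = float(np.quantile(perm_vals[(u, v)], quantile))
        obs = float(observed.loc[u, v])
        rows.append({"var1": u, "var2": v, "observed": obs,
                     "threshold_95": thr, "significant": obs > thr})
    return pd.DataFrame(rows)


def two_proportion_z(x1: int, n1: int, x2: int, n2: int) -> StatResult:
    """Two-proportion score z test (pooled variance under the null)."""
    if min(n1, n2) == 0:
        raise ValueError("empty sample")
    p1, p2 = x1 / n1, x2 / n2
    pooled = (x1 + x2) / (n1 + n2)
    se = np.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    if se == 0:
        z = 0.0
    else:
        z = (p1 - p2) / se
    p = float(2 * stats.norm.sf(abs(z)))
    return StatResult("z", float(z), df=float(n1 + n2 - 2), pvalue=p, n=n1 + n2,
                      inputs_digest=digest_inputs([x1, n1, x2, n2]))


def derepression_by_category(
    categories: pd.Series, derepressed: pd.Series
) -> dict:
    """Does derepression incidence differ across piRNA-abundance categories?

    Returns per-category proportions, the overall Rx2 chi-square, and
    pairwise two-proportion z tests.  Empty categories are excluded with
    a warning field.
    """
    categories = pd.Series(categories)
    flags = pd.Series(derepressed).reindex(categories.index)
    if flags.isna().any():
        raise ValueError("every family needs a category and a flag")
    flags = flags.astype(bool)
    grp = pd.DataFrame({"category": categories, "flag": flags}).groupby("category")[
        "flag"
    ].agg(n_derepressed="sum", n_total="count")
    excluded = [str(c) for c in grp.index[grp["n_total"] == 0]]
    grp = grp[grp["n_total"] > 0]
    proportions = (grp["n_derepressed"] / grp["n_total"]).rename(
        "proportion_derepressed"
    )
    tab = np.column_stack(
        [grp["n_derepressed"], grp["n_total"] - grp["n_derepressed"]]
    )
    overall = chi_square_rxc(tab) if len(grp) >= 2 and tab.sum(axis=0).min() > 0 else None
    pairwise = {}
    cats = list(grp.index)
    for i in range(len(cats)):
        for j in range(i + 1, len(cats)):
            ci, cj = cats[i], cats[j]
            pairwise[(str(ci), str(cj))] = two_proportion_z(
                int(grp.loc[ci, "n_derepressed"]), int(grp.loc[ci, "n_total"]),
                int(grp.loc[cj, "n_derepressed"]), int(grp.loc[cj, "n_total"]),
            )
    return {"proportions": proportions, "chi_square": overall,
            "pairwise_z": pairwise, "excluded_categories": excluded}
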