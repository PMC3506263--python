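"""TE and gene mRNA quantification and the dual-parent derepression call.

A family is called derepressed when its normalized transcript abundance
in the hybrid is at least 2-fold above BOTH parents and the per-parent
count test survives BH correction at q < alpha; underexpression is the
symmetric call.  A fold-only variant (no significance gate) is emitted
alongside.  Normalization is count x 1e9 / (library size x consensus
length), i.e. the per-kilobase-per-million convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .profile import family_weights
from .types import Strand, StrandedHit

PSEUDOCOUNT = 0.5


def quantify(hits: Iterable[StrandedHit]) -> pd.Series:
    """Weighted read counts per family (fractional tie policy)."""
    df = family_weights(hits)
    if df.empty:
        return pd.Series(dtype=float, name="count")
    return df["weight"].rename("count")


def normalize(counts: pd.Series, library_size: float, lengths: pd.Series) -> pd.Series:
    """count x 1e9 / (library_size x length)  (RPKM-style)."""
    if library_size <= 0:
        raise ValueError("library_size must be positive")
    lengths = lengths.reindex(counts.index)
    if (lengths <= 0).any() or lengths.isna().any():
        raise ValueError("all feature lengths must be positive")
    return counts * 1e9 / (library_size * lengths)


def size_factors(counts: pd.DataFrame, scale_to_totals: bool = True) -> dict[str, float]:
    """Median-of-ratios effective library sizes (robust to composition bias).

    Total-count normalization is biased when a block of features changes
    in one direction (e.g. many derepressed TE families inflating the
    hybrid library); the median ratio against the per-row geometric mean
    reference is the standard robust estimator.  Factors are rescaled to
    the mean column total so RPM-style values keep a familiar scale.
    """
    log = np.log(counts.where(counts > 0))
    ref = log.mean(axis=1)
    ok = np.isfinite(ref)
    sf = {c: float(np.exp(np.median(log.loc[ok, c] - ref[ok]))) for c in counts}
    if scale_to_totals:
        mean_total = float(counts.sum(axis=0).mean())
        sf = {c: v * mean_total for c, v in sf.items()}
    return sf


def _binomial_pvalues(x: np.ndarray, y: np.ndarray, n_x: float, n_y: float) -> np.ndarray:
    """Two-library conditional binomial test per row.

    Conditional on the row total t = x + y, x ~ Binomial(t, n_x/(n_x+n_y))
    under the null of equal underlying concentration; two-sided p.
    """
    p0 = n_x / (n_x + n_y)
    out = np.ones(len(x))
    for i, (xi, ti) in enumerate(zip(np.rint(x).astype(int),
                                     np.rint(x + y).astype(int))):
        if ti > 0:
            out[i] = stats.binomtest(int(xi), int(ti), p0).pvalue
    return out


def _nb_pvalues(x: np.ndarray, y: np.ndarray, n_x: float, n_y: float,
                alpha_disp: float) -> np.ndarray:
    """Single-dispersion negative-binomial two-sided test per row.

    Tests the observed count ``x`` against NB(mu, alpha) with mu the
    rate pooled from both libraries scaled to library x, doubling the
    smaller tail.
    """
    mu = (x + y) / (n_x + n_y) * n_x
    mu = np.maximum(mu, 1e-8)
    r = 1.0 / max(alpha_disp, 1e-8)
    p = r / (r + mu)
    xi = np.rint(x).astype(int)
    lower = stats.nbinom.cdf(xi, r, p)
    upper = stats.nbinom.sf(xi - 1, r, p)
    return np.clip(2 * np.minimum(lower, upper), 0, 1)


def estimate_dispersion(counts: pd.DataFrame) -> float:
    """Method-of-moments common dispersion from the two parental columns."""
    a = counts.iloc[:, 0].to_numpy(float)
    b = counts.iloc[:, 1].to_numpy(float)
    m = (a + b) / 2
    v = (a - m) ** 2 + (b - m) ** 2  # 1-df variance estimate per row
    ok = m > 0
    excess = v[ok] - m[ok]
    disp = np.sum(excess) / np.sum(m[ok] ** 2)
    return float(max(disp, 0.0))


@dataclass
class CallerConfig:
    fold: float = 2.0
    alpha: float = 0.05
    strict_greater: bool = False  # exclusive |log2FC| > 1 instead of >= 1
    test: str = "binomial"  # or "nb"
    min_count: float = 1.0  # min raw count in every library to keep a row


def call_status(
    counts: pd.DataFrame,
    library_sizes: dict[str, float],
    lengths: Optional[pd.Series] = None,
    hybrid: str = "hybrid",
    parents: tuple[str, str] = ("parentA", "parentB"),
    config: Optional[CallerConfig] = None,
) -> pd.DataFrame:
    """Dual-parent derepression caller.

    ``counts``: rows = families/genes, columns include the hybrid and both
    parent libraries (raw weighted counts).  Returns an expression table
    with normalized abundances, per-parent log2 fold changes (pseudocount
    0.5 on raw counts), BH q-values per comparison, the
    significance-gated ``status`` and the ``status_fold_only`` variant.
    """
    cfg = config or CallerConfig()
    pa, pb = parents
    keep = (counts[[hybrid, pa, pb]] >= cfg.min_count).all(axis=1)
    tab = counts.loc[keep, [hybrid, pa, pb]].astype(float).copy()

    out = pd.DataFrame(index=tab.index)
    for col in (hybrid, pa, pb):
        out[f"count_{col}"] = tab[col]
        if lengths is not None:
            out[f"norm_{col}"] = normalize(tab[col], library_sizes[col], lengths)
    disp = None
    for parent, tag in ((pa, "A"), (pb, "B")):
        n_h, n_p = library_sizes[hybrid], library_sizes[parent]
        rate_h = (tab[hybrid] + PSEUDOCOUNT) / n_h
        rate_p = (tab[parent] + PSEUDOCOUNT) / n_p
        out[f"log2fc_vs_{tag}"] = np.log2(rate_h / rate_p)
        x = tab[hybrid].to_numpy(float)
        y = tab[parent].to_numpy(float)
        if cfg.test == "binomial":
            pvals = _binomial_pvalues(x, y, n_h, n_p)
        elif cfg.test == "nb":
            if disp is None:
                disp = estimate_dispersion(tab[[pa, pb]])
            pvals = _nb_pvalues(x, y, n_h, n_p, disp)
        else:
            raise ValueError(f"unknown test {cfg.test!r}")
        out[f"p_vs_{tag}"] = pvals
        out[f"q_vs_{tag}"] = multipletests(pvals, method="fdr_bh")[1] if len(pvals) else pvals

    if cfg.strict_greater:
        up = (out["log2fc_vs_A"] > 1) & (out["log2fc_vs_B"] > 1)
        down = (out["log2fc_vs_A"] < -1) & (out["log2fc_vs_B"] < -1)
    else:
        up = (out["log2fc_vs_A"] >= 1) & (out["log2fc_vs_B"] >= 1)
        down = (out["log2fc_vs_A"] <= -1) & (out["log2fc_vs_B"] <= -1)
    sig = (out["q_vs_A"] < cfg.alpha) & (out["q_vs_B"] < cfg.alpha)

    out["status_fold_only"] = np.select([up, down], ["derepressed", "underexpressed"],
                                        default="unchanged")
    out["status"] = np.select([up & sig, down & sig],
                              ["derepressed", "underexpressed"], default="unchanged")
    return out


# ---------------------------------------------------------------------------
# species-of-origin partition


@dataclass
class OriginPartition:
    """Per-family read counts unique to genome A, genome B, or shared."""

    table: pd.DataFrame  # index family; columns a_only, b_only, shared
    read_classes: pd.Series  # read_id -> {A_only, B_only, shared, unmapped}


def origin_partition(
    reads: Iterable[tuple[str, str]],
    index_a,
    index_b,
    insertions_a=None,
    insertions_b=None,
) -> OriginPartition:
    """Classify reads by zero-mismatch presence in each parental genome.

    A read is A-only when it places somewhere in genome A (either strand,
    zero mismatches) but nowhere in genome B; symmetric for B; shared when
    it places in both.  Family attribution uses the TE insertion the
    read's placement overlaps (first placement wins; reads outside any
    annotated insertion count under family ``*intergenic*``).
    """
    from .io import assign_reads

    reads = list(reads)
    res_a = assign_reads(reads, index_a)
    res_b = assign_reads(reads, index_b)
    placed_a: dict[str, list] = {}
    for h in res_a.hits:
        placed_a.setdefault(h.read_id, []).append(h)
    placed_b: dict[str, list] = {}
    for h in res_b.hits:
        placed_b.setdefault(h.read_id, []).append(h)

    def _family(hit_list, insertions):
        if insertions is None:
            return "*intergenic*"
        h = hit_list[0]
        for ins in insertions:
            if ins.contig == h.target and ins.start <= h.start and h.end <= ins.end:
                return ins.family
        return "*intergenic*"

    classes = {}
    rows: dict[str, dict] = {}
    # reads may collapse to one representative id; map every input id via sequence
    rep_of: dict[str, str] = {}
    first_for_seq: dict[str, str] = {}
    for rid, seq in reads:
        seq = seq.upper()
        rep_of[rid] = first_for_seq.setdefault(seq, rid)
    for rid, _seq in reads:
        rep = rep_of[rid]
        in_a, in_b = rep in placed_a, rep in placed_b
        if in_a and in_b:
            cls, fam = "shared", _family(placed_a[rep], insertions_a)
        elif in_a:
            cls, fam = "A_only", _family(placed_a[rep], insertions_a)
        elif in_b:
            cls, fam = "B_only", _family(placed_b[rep], insertions_b)
        else:
            cls, fam = "unmapped", None
        classes[rid] = cls
        if fam is not None:
            rec = rows.setdefault(fam, {"a_only": 0, "b_only": 0, "shared": 0})
            rec[{"A_only": "a_only", "B_only": "b_only", "shared": "shared"}[cls]] += 1
    table = (
        pd.DataFrame.from_dict(rows, orient="index")
        .rename_axis("family")
        .sort_index()
        if rows
        else pd.DataFrame(columns=["a_only", "b_only", "shared"])
    )
    return OriginPartition(table, pd.Series(classes, name="origin_class"))


def per_origin_fold_change(
    hybrid_partition: pd.DataFrame,
    parent_a_partition: pd.DataFrame,
    parent_b_partition: pd.DataFrame,
    library_sizes: dict[str, float],
) -> pd.DataFrame:
    """Per-family log2 fold change of hybrid vs parent for each genome of origin.

    A-only hybrid reads are compared against the A-only reads of parent A
    (per-million normalized, pseudocount 0.5); symmetric for B.  Families
    with zero origin-specific parent reads are flagged.
    """
    universe = hybrid_partition.index.union(parent_a_partition.index).union(
        parent_b_partition.index
    )
    out = pd.DataFrame(index=universe)
    for tag, col, parent_part, parent_lib in (
        ("A", "a_only", parent_a_partition, "parentA"),
        ("B", "b_only", parent_b_partition, "parentB"),
    ):
        h = hybrid_partition.reindex(universe).fillna(0).get(col, 0)
        p = parent_part.reindex(universe).fillna(0).get(col, 0)
        rate_h = (h + PSEUDOCOUNT) / library_sizes["hybrid"]
        rate_p = (p + PSEUDOCOUNT) / library_sizes[parent_lib]
        out[f"log2fc_{tag}_origin"] = np.log2(rate_h / rate_p)
        out[f"flag_no_parent_{tag}_reads"] = p == 0
    return out
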