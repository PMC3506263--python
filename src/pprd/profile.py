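"""Small-RNA size-class partitioning and per-family piRNA abundance.

Reads of length >= 23 nt are counted as the piRNA class; 18-22 nt reads
are the miRNA/endo-siRNA background.  Per-family tallies follow the
fractional tie policy: a read placed equally well on k distinct families
contributes ``copies / k`` weight to each.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .types import (
    PIRNA_MAX_LEN,
    PIRNA_MIN_LEN,
    SMALLRNA_MAX_LEN,
    SMALLRNA_MIN_LEN,
    Interval,
    Strand,
    StrandedHit,
)


@dataclass
class SizeDistribution:
    """Length histogram of a small-RNA library with its piRNA share."""

    library_id: str
    counts: pd.Series  # index = length
    fractions: pd.Series
    pirna_share: float  # fraction of reads with length >= 23 nt

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"count": self.counts, "fraction": self.fractions}
        ).rename_axis("length")


def size_distribution(
    lengths: Sequence[int],
    weights: Optional[Sequence[float]] = None,
    length_range: tuple[int, int] = (SMALLRNA_MIN_LEN, SMALLRNA_MAX_LEN),
    library_id: str = "",
    pirna_min_len: int = PIRNA_MIN_LEN,
) -> SizeDistribution:
    """Histogram of read lengths over ``length_range`` (inclusive).

    Reads outside the range are excluded; an empty in-range library is an
    error.  ``weights`` defaults to 1 per read (pass collapsed copy
    counts to weight by abundance).
    """
    lo, hi = length_range
    lengths = np.asarray(lengths, dtype=int)
    w = np.ones(len(lengths)) if weights is None else np.asarray(weights, dtype=float)
    mask = (lengths >= lo) & (lengths <= hi)
    lengths, w = lengths[mask], w[mask]
    if w.sum() <= 0:
        raise ValueError(f"no reads in range [{lo}, {hi}]")
    idx = pd.RangeIndex(lo, hi + 1, name="length")
    counts = pd.Series(0.0, index=idx)
    for length, weight in zip(lengths, w):
        counts[length] += weight
    fractions = counts / counts.sum()
    pirna_share = float(fractions[fractions.index >= pirna_min_len].sum())
    return SizeDistribution(library_id, counts, fractions, pirna_share)


def _per_read_family_hits(hits: Iterable[StrandedHit]):
    """Group hits by collapsed read, then by target family."""
    by_read: dict[str, dict[str, list[StrandedHit]]] = defaultdict(lambda: defaultdict(list))
    for h in hits:
        by_read[h.read_id][h.target].append(h)
    return by_read


def family_weights(
    hits: Iterable[StrandedHit],
    min_len: Optional[int] = None,
    max_len: Optional[int] = None,
    unique_only: bool = False,
) -> pd.DataFrame:
    """Per-family sense/antisense weights under the fractional tie policy.

    Returns a DataFrame indexed by family with columns ``weight``,
    ``sense_weight``, ``antisense_weight``.  With ``unique_only`` a read
    is counted only if it maps to a single location in the database.
    """
    acc: dict[str, np.ndarray] = defaultdict(lambda: np.zeros(2))  # [sense, anti]
    for read_hits in _per_read_family_hits(hits).values():
        some = next(iter(read_hits.values()))[0]
        if min_len is not None and some.length < min_len:
            continue
        if max_len is not None and some.length > max_len:
            continue
        if unique_only and some.n_locations > 1:
            continue
        k = len(read_hits)
        for fam, placements in read_hits.items():
            share = some.copies / k
            n_anti = sum(1 for p in placements if p.strand is Strand.ANTISENSE)
            frac_anti = n_anti / len(placements)
            acc[fam] += share * np.array([1 - frac_anti, frac_anti])
    if not acc:
        return pd.DataFrame(columns=["weight", "sense_weight", "antisense_weight"])
    df = pd.DataFrame(
        {fam: {"sense_weight": v[0], "antisense_weight": v[1]} for fam, v in acc.items()}
    ).T.rename_axis("family")
    df["weight"] = df["sense_weight"] + df["antisense_weight"]
    return df[["weight", "sense_weight", "antisense_weight"]].sort_index()


def family_abundance(
    hits: Iterable[StrandedHit],
    library_size: float,
    library_id: str = "",
    min_len: int = PIRNA_MIN_LEN,
    max_len: int = PIRNA_MAX_LEN,
    unique_only: bool = False,
) -> pd.DataFrame:
    """Per-family piRNA abundance: weighted counts, RPM, antisense fraction.

    Only reads in the [min_len, max_len] window (default the 23-29 nt
    piRNA class) are counted; RPM = weight x 1e6 / library_size.
    """
    if library_size <= 0:
        raise ValueError("library_size must be positive")
    df = family_weights(hits, min_len=min_len, max_len=max_len, unique_only=unique_only)
    df = df.copy()
    df["library_id"] = library_id
    df["rpm"] = df["weight"] * 1e6 / library_size
    with np.errstate(invalid="ignore", divide="ignore"):
        df["antisense_fraction"] = np.where(
            df["weight"] > 0, df["antisense_weight"] / df["weight"], np.nan
        )
    return df


def antisense_fraction(hits: Iterable[StrandedHit], family: str,
                       min_len: int = PIRNA_MIN_LEN,
                       max_len: int = PIRNA_MAX_LEN) -> Optional[float]:
    """Antisense weight share for one family; None when no reads (not 0)."""
    df = family_weights(hits, min_len=min_len, max_len=max_len)
    if family not in df.index or df.loc[family, "weight"] <= 0:
        return None
    return float(df.loc[family, "antisense_weight"] / df.loc[family, "weight"])


def differential_abundance(
    rpm_a: pd.Series,
    rpm_b: pd.Series,
    fold: float = 2.0,
    library_size_a: float = 1e6,
    library_size_b: float = 1e6,
) -> pd.Series:
    """Classify families as A_biased / B_biased / nondifferential.

    A family is A-biased iff RPM_A >= fold x RPM_B (inclusive), and
    symmetrically for B.  Zero RPM values are replaced by a pseudo-RPM
    floor of ``0.5 / library_size x 1e6`` for ratio formation only; the
    input tables are never modified.
    """
    universe = rpm_a.index.union(rpm_b.index)
    a = rpm_a.reindex(universe, fill_value=0.0).astype(float)
    b = rpm_b.reindex(universe, fill_value=0.0).astype(float)
    floor_a = 0.5 / library_size_a * 1e6
    floor_b = 0.5 / library_size_b * 1e6
    a_eff = a.where(a > 0, floor_a)
    b_eff = b.where(b > 0, floor_b)
    out = pd.Series("nondifferential", index=universe, name="category")
    out[a_eff >= fold * b_eff] = "A_biased"
    out[b_eff >= fold * a_eff] = "B_biased"
    return out


def cluster_unique_read_ids(
    genome_hits: Iterable[StrandedHit], clusters: Sequence[Interval]
) -> set[str]:
    """Reads mapping uniquely (n_locations == 1) inside a cluster interval.

    Used by the optional filter that removes cluster-unique piRNAs before
    family tallies.  Membership is decided by the 5' coordinate.
    """
    out = set()
    for h in genome_hits:
        if h.n_locations != 1:
            continue
        if any(cl.contains(h.target, h.five_prime) for cl in clusters):
            out.add(h.read_id)
    return out


def exclude_reads(hits: Iterable[StrandedHit], read_ids: set[str]) -> list[StrandedHit]:
    return [h for h in hits if h.read_id not in read_ids]
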