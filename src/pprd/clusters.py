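"""piRNA-cluster activity under three mapping schemes and inheritance classes.

Schemes (per cluster x library):
  unique   — only reads with a single genomic placement count, full copies;
  weighted — every read counts copies / n_locations per in-cluster placement;
  all      — every read with >=1 in-cluster placement counts full copies.

The hybrid's expected cluster frequency is the interspecific average of
the two parental frequencies; relative expression = hybrid frequency /
expectation, with inheritance called overexpressed at >= 2, underexpressed
at <= 0.5, additive otherwise (both boundaries inclusive).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd

from .types import Interval, StrandedHit

SCHEMES = ("unique", "weighted", "all")
OVER_BOUND = 2.0
UNDER_BOUND = 0.5


def cluster_tally(
    hits: Iterable[StrandedHit],
    clusters: Sequence[Interval],
    scheme: str = "unique",
) -> pd.Series:
    """Raw per-cluster tallies of genome-placed reads under one scheme.

    Cluster membership is decided by the placement's 5' coordinate lying
    in the half-open interval.  Raises on intervals naming a contig absent
    from the hits' target universe only if hits exist for other contigs.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"scheme must be one of {SCHEMES}")
    hits = list(hits)
    contigs = {h.target for h in hits}
    for cl in clusters:
        if contigs and cl.contig not in contigs:
            raise ValueError(f"cluster {cl.name!r} on unknown contig {cl.contig!r}")
    tallies = pd.Series(0.0, index=pd.Index([c.name for c in clusters], name="cluster"))
    by_read: dict[str, list[StrandedHit]] = {}
    for h in hits:
        by_read.setdefault(h.read_id, []).append(h)
    for placements in by_read.values():
        rep = placements[0]
        if scheme == "unique" and rep.n_locations != 1:
            continue
        for cl in clusters:
            in_cluster = [p for p in placements if cl.contains(p.target, p.five_prime)]
            if not in_cluster:
                continue
            if scheme == "weighted":
                tallies[cl.name] += rep.copies * len(in_cluster) / rep.n_locations
            else:  # unique (n_locations==1) or all: full copies once per cluster
                tallies[cl.name] += rep.copies
    return tallies


def cluster_frequencies(tallies: pd.Series, total_mappable: float) -> pd.Series:
    """Tally / total mappable piRNA-class reads in the library."""
    if total_mappable <= 0:
        raise ValueError("total_mappable must be positive")
    return tallies / total_mappable


@dataclass
class ClusterActivityRecord:
    cluster: str
    scheme: str
    freq_parent_a: float
    freq_parent_b: float
    freq_hybrid: float
    expectation: float
    relative_expression: Optional[float]
    inheritance: str  # overexpressed / underexpressed / additive / undefined


def inheritance_class(
    freq_parent_a: float,
    freq_parent_b: float,
    freq_hybrid: float,
    cluster: str = "",
    scheme: str = "",
) -> ClusterActivityRecord:
    """Classify hybrid cluster activity against the additive expectation."""
    expectation = (freq_parent_a + freq_parent_b) / 2.0
    if expectation == 0:
        return ClusterActivityRecord(cluster, scheme, freq_parent_a, freq_parent_b,
                                     freq_hybrid, 0.0, None, "undefined")
    relative = freq_hybrid / expectation
    if relative >= OVER_BOUND:
        label = "overexpressed"
    elif relative <= UNDER_BOUND:
        label = "underexpressed"
    else:
        label = "additive"
    return ClusterActivityRecord(cluster, scheme, freq_parent_a, freq_parent_b,
                                 freq_hybrid, expectation, relative, label)


def single_parent_expectation(parent_freq: float) -> tuple[float, bool]:
    """Additive expectation when the other parent contributes zero.

    The unassembled/unamplifiable parent is assumed silent, so the hybrid
    expectation is 50% of the measurable parent's level.  Returns
    (expectation, flagged) where flagged marks a zero input.
    """
    return parent_freq / 2.0, parent_freq == 0


def cluster_activity_table(
    freq_a: pd.Series,
    freq_b: pd.Series,
    freq_h: pd.Series,
    scheme: str = "unique",
) -> pd.DataFrame:
    """Inheritance classification for every cluster under one scheme."""
    idx = freq_a.index
    rows = []
    for cl in idx:
        rec = inheritance_class(float(freq_a[cl]), float(freq_b.get(cl, 0.0)),
                                float(freq_h.get(cl, 0.0)), cluster=str(cl),
                                scheme=scheme)
        rows.append(vars(rec))
    return pd.DataFrame(rows).set_index("cluster")
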