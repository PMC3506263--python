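"""The ping-pong fraction: the probability that a randomly sampled piRNA
of a TE family has a complementary partner whose 5' end is offset by 10 bp.

On the single plus-strand axis used throughout (antisense 5' = highest
covered plus-strand coordinate) a sense read with 5' end at p and an
antisense read with 5' end at p + 9 overlap by exactly 10 nt, the
geometry left by Aub/Ago3-mediated slicing.  A read participates iff at
least one opposite-strand read completes that geometry; the fraction is
the participating share of the family's read weight.

Weighting is by collapsed read copies (abundance) by default; reads
placed on several families contribute fully to each family's statistic
(no fractional split inside the pair search), diverging deliberately
from the fractional tie policy of the family abundance tallies.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Optional

import pandas as pd

from .types import PIRNA_MAX_LEN, PIRNA_MIN_LEN, Strand, StrandedHit

#: reporting filter defaults: >50 reads and fraction >0.1 in >=1 library
MIN_READS = 50
MIN_FRACTION = 0.1
PING_PONG_OFFSET = 10


@dataclass
class PingPongResult:
    family: str
    library_id: str
    fraction: Optional[float]  # None when the family has no reads in window
    total_weight: float
    participating_weight: float = 0.0

    @property
    def passes_filter(self) -> bool:
        return (
            self.fraction is not None
            and self.total_weight > MIN_READS
            and self.fraction > MIN_FRACTION
        )


def _family_reads(hits: Iterable[StrandedHit], min_len: int, max_len: int,
                  by_distinct: bool):
    """One entry per collapsed read: (weight, strand-> set of 5' coords)."""
    per_read: dict[str, dict] = {}
    for h in hits:
        if not (min_len <= h.length <= max_len):
            continue
        rec = per_read.setdefault(
            h.read_id,
            {"weight": 1.0 if by_distinct else float(h.copies),
             Strand.SENSE: set(), Strand.ANTISENSE: set()},
        )
        rec[h.strand].add(h.five_prime)
    return per_read


def pingpong_fraction(
    hits: Iterable[StrandedHit],
    family: Optional[str] = None,
    library_id: str = "",
    min_len: int = PIRNA_MIN_LEN,
    max_len: int = PIRNA_MAX_LEN,
    offset: int = PING_PONG_OFFSET,
    by_distinct: bool = False,
) -> PingPongResult:
    """Ping-pong fraction for the reads of one family (one consensus axis).

    ``hits`` must all target the same consensus; pass ``family`` for
    labelling.  Returns fraction None when no reads fall in the length
    window.
    """
    hits = list(hits)
    if family is None:
        family = hits[0].target if hits else ""
    per_read = _family_reads(hits, min_len, max_len, by_distinct)
    if not per_read:
        return PingPongResult(family, library_id, None, 0.0)
    sense5: set[int] = set()
    anti5: set[int] = set()
    for rec in per_read.values():
        sense5 |= rec[Strand.SENSE]
        anti5 |= rec[Strand.ANTISENSE]
    total = participating = 0.0
    for rec in per_read.values():
        total += rec["weight"]
        partnered = any(p + offset - 1 in anti5 for p in rec[Strand.SENSE]) or any(
            a - offset + 1 in sense5 for a in rec[Strand.ANTISENSE]
        )
        if partnered:
            participating += rec["weight"]
    return PingPongResult(family, library_id, participating / total, total, participating)


def pingpong_table(
    results: Iterable[PingPongResult],
    min_reads: float = MIN_READS,
    min_fraction: float = MIN_FRACTION,
) -> pd.DataFrame:
    """Family x library table retaining families that pass the reporting
    filter (>min_reads reads AND fraction >min_fraction) in >=1 library;
    all libraries' values are emitted for retained families."""
    rows = [
        {
            "family": r.family,
            "library": r.library_id,
            "fraction": r.fraction,
            "weight": r.total_weight,
            "passes_filter": (
                r.fraction is not None
                and r.total_weight > min_reads
                and r.fraction > min_fraction
            ),
        }
        for r in results
    ]
    df = pd.DataFrame(rows, columns=["family", "library", "fraction", "weight",
                                     "passes_filter"])
    if df.empty:
        return df
    keep = df.groupby("family")["passes_filter"].any()
    return df[df["family"].map(keep)].reset_index(drop=True)


def overlap_spectrum(
    hits: Iterable[StrandedHit],
    max_overlap: int = 25,
    min_len: int = PIRNA_MIN_LEN,
    max_len: int = PIRNA_MAX_LEN,
    by_distinct: bool = False,
) -> pd.Series:
    """Participating read weight per 5'-5' overlap length 1..max_overlap.

    Diagnostic generalisation of the 10-nt rule: entry ``o`` is the total
    weight of reads having >=1 opposite-strand partner whose 5' ends
    overlap by exactly ``o`` nt.  Empty (all-zero) when either strand is
    absent.
    """
    per_read = _family_reads(hits, min_len, max_len, by_distinct)
    sense5: set[int] = set()
    anti5: set[int] = set()
    for rec in per_read.values():
        sense5 |= rec[Strand.SENSE]
        anti5 |= rec[Strand.ANTISENSE]
    spectrum = pd.Series(0.0, index=pd.RangeIndex(1, max_overlap + 1, name="overlap"))
    if not sense5 or not anti5:
        return spectrum
    for o in spectrum.index:
        w = 0.0
        for rec in per_read.values():
            partnered = any(p + o - 1 in anti5 for p in rec[Strand.SENSE]) or any(
                a - o + 1 in sense5 for a in rec[Strand.ANTISENSE]
            )
            if partnered:
                w += rec["weight"]
        spectrum[o] = w
    return spectrum


def pingpong_by_family(
    hits: Iterable[StrandedHit],
    library_id: str = "",
    min_len: int = PIRNA_MIN_LEN,
    max_len: int = PIRNA_MAX_LEN,
    offset: int = PING_PONG_OFFSET,
    by_distinct: bool = False,
) -> list[PingPongResult]:
    """Split a mixed hit list by target family and compute each fraction."""
    by_fam: dict[str, list[StrandedHit]] = defaultdict(list)
    for h in hits:
        by_fam[h.target].append(h)
    return [
        pingpong_fraction(fam_hits, family=fam, library_id=library_id,
                          min_len=min_len, max_len=max_len, offset=offset,
                          by_distinct=by_distinct)
        for fam, fam_hits in sorted(by_fam.items())
    ]
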