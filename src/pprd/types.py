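"""Core domain types shared across the pipeline.

Coordinates are 0-based, half-open everywhere. The 5' coordinate of an
antisense placement is the highest plus-strand position covered by the
read (the biological 5' end of a minus-strand read), so that the ping-pong
10-nt 5'-5' overlap rule is expressible on a single plus-strand axis.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

NUCLEOTIDES = frozenset("ACGTN")

#: inclusive piRNA length window (nt)
PIRNA_MIN_LEN = 23
PIRNA_MAX_LEN = 29

#: small-RNA library length range (nt)
SMALLRNA_MIN_LEN = 18
SMALLRNA_MAX_LEN = 30


class Strand(str, Enum):
    SENSE = "sense"
    ANTISENSE = "antisense"

    def flipped(self) -> "Strand":
        return Strand.ANTISENSE if self is Strand.SENSE else Strand.SENSE


class TEClass(str, Enum):
    LTR = "LTR"
    NON_LTR = "non_LTR"
    TIR = "TIR"


class Tissue(str, Enum):
    GERMLINE = "germline"
    SOMATIC = "somatic"
    INTERMEDIATE = "intermediate"
    UNKNOWN = "unknown"


class DependencyGroup(str, Enum):
    """Effector-protein dependency of a family's piRNA production.

    Group I: Piwi-dependent; group II: Piwi+Aub; group III: Aub/Ago3
    (ping-pong) dependent.
    """

    I = "I"
    II = "II"
    III = "III"
    UNKNOWN = "unknown"


class FullLengthPresence(str, Enum):
    BOTH_GENOMES = "both_genomes"
    MEL_ONLY = "mel_only"
    NEITHER = "neither"
    UNKNOWN = "unknown"


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


@dataclass(frozen=True)
class TEFamily:
    """A transposable-element family: consensus sequence plus metadata."""

    name: str
    consensus: str
    te_class: TEClass = TEClass.LTR
    tissue: Tissue = Tissue.UNKNOWN
    dependency_group: DependencyGroup = DependencyGroup.UNKNOWN
    ht_candidate: bool = False
    full_length_presence: FullLengthPresence = FullLengthPresence.UNKNOWN

    def __post_init__(self) -> None:
        if len(self.consensus) < 50:
            raise ValueError(
                f"consensus of {self.name!r} is {len(self.consensus)} nt; minimum is 50"
            )
        bad = set(self.consensus) - NUCLEOTIDES
        if bad:
            raise ValueError(
                f"consensus of {self.name!r} contains non-ACGTN characters: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.consensus)


@dataclass(frozen=True)
class Interval:
    """0-based half-open genomic interval."""

    contig: str
    start: int
    end: int
    name: Optional[str] = None
    strand: Optional[str] = None

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.contig}:{self.start}-{self.end} (need 0 <= start < end)"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, contig: str, pos: int) -> bool:
        return contig == self.contig and self.start <= pos < self.end


@dataclass(frozen=True)
class Insertion:
    """One TE copy placed in a genome."""

    family: str
    contig: str
    start: int
    end: int
    strand: str = "+"


@dataclass
class GenomeAnnotation:
    """A genome sequence with its TE-insertion and piRNA-cluster annotations."""

    genome_id: str
    sequences: dict[str, str]
    insertions: list[Insertion] = field(default_factory=list)
    clusters: list[Interval] = field(default_factory=list)

    def validate(self) -> None:
        ids = [c.name for c in self.clusters]
        if len(ids) != len(set(ids)):
            raise ValueError(f"duplicate cluster ids in genome {self.genome_id!r}")
        for ins in self.insertions:
            self._check_bounds(ins.contig, ins.start, ins.end)
        for cl in self.clusters:
            self._check_bounds(cl.contig, cl.start, cl.end)

    def _check_bounds(self, contig: str, start: int, end: int) -> None:
        if contig not in self.sequences:
            raise ValueError(f"unknown contig {contig!r} in genome {self.genome_id!r}")
        if not (0 <= start < end <= len(self.sequences[contig])):
            raise ValueError(
                f"interval {contig}:{start}-{end} outside contig bounds "
                f"in genome {self.genome_id!r}"
            )


@dataclass(frozen=True)
class StrandedHit:
    """One placement of a (collapsed) read on a consensus or genome target.

    ``five_prime`` is the plus-strand coordinate of the read's biological
    5' end; for antisense placements this is the highest covered position.
    ``n_locations`` counts all equally-good (best mismatch stratum)
    placements of the read across the whole target database, and is shared
    by every hit of the same read.  ``copies`` is the number of identical
    input reads collapsed into this record.
    """

    read_id: str
    target: str
    strand: Strand
    five_prime: int
    length: int
    n_locations: int = 1
    copies: int = 1
    mismatches: int = 0

    def __post_init__(self) -> None:
        if self.n_locations < 1:
            raise ValueError("n_locations must be >= 1")
        if self.copies < 1:
            raise ValueError("copies must be >= 1")

    @property
    def start(self) -> int:
        """Leftmost plus-strand coordinate covered by the read."""
        if self.strand is Strand.SENSE:
            return self.five_prime
        return self.five_prime - self.length + 1

    @property
    def end(self) -> int:
        return self.start + self.length


@dataclass
class StatResult:
    """A named test statistic with its provenance."""

    name: str
    value: float
    df: Optional[float] = None
    pvalue: Optional[float] = None
    n: Optional[int] = None
    extras: dict = field(default_factory=dict)
    inputs_digest: Optional[str] = None

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        parts = [f"{self.name}={self.value:.6g}"]
        if self.df is not None:
            parts.append(f"df={self.df:g}")
        if self.pvalue is not None:
            parts.append(f"p={self.pvalue:.4g}")
        return f"StatResult({', '.join(parts)})"


def digest_inputs(*arrays) -> str:
    """Stable short digest of the numeric inputs that produced a statistic."""
    h = hashlib.sha256()
    for a in arrays:
        import numpy as np

        h.update(np.asarray(a, dtype=float).tobytes())
    return h.hexdigest()[:16]


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]
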