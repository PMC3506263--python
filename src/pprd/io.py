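"""Readers, writers, and the mismatch-tolerant read-placement index.

File conventions: FASTA for references and consensus sequences, FASTQ
(optionally gzip-compressed) for reads, BED3+ for clusters and insertions,
TSV with a header row for all tabular side data.  BED is consumed natively
as 0-based half-open; FASTA coordinates are converted at the boundary.

Read placement is implemented in-package as an exact / <=k-mismatch
(Hamming) search over both strands of every target, returning all hits in
the best mismatch stratum, so that the mapper is self-contained and can be
verified against an exhaustive sliding-window oracle at desk scale.
"""

from __future__ import annotations

import gzip
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional

from Bio import SeqIO

from .types import (
    NUCLEOTIDES,
    FormatError,
    Insertion,
    Interval,
    Strand,
    StrandedHit,
    TEFamily,
    revcomp,
)


def _open_text(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into an ordered ``{identifier: sequence}`` map.

    Sequences are uppercased; duplicate identifiers and non-ACGTN
    characters are rejected with a :class:`FormatError` naming the record.
    """
    out: dict[str, str] = {}
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in out:
                raise FormatError(f"duplicate FASTA identifier {rec.id!r} in {path}")
            seq = str(rec.seq).upper()
            bad = set(seq) - NUCLEOTIDES
            if bad:
                raise FormatError(
                    f"record {rec.id!r} in {path} contains non-nucleotide "
                    f"characters: {sorted(bad)}"
                )
            out[rec.id] = seq
    return out


def write_fasta(path, sequences: dict[str, str]) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def read_fastq(path) -> Iterator[tuple[str, str]]:
    """Stream ``(read id, sequence)`` pairs from a FASTQ file.

    Qualities are ignored.  Gzip input is accepted transparently.  A
    truncated record raises :class:`FormatError` with the record index.
    """
    with _open_text(path) as fh:
        record_idx = 0
        while True:
            header = fh.readline()
            if not header:
                return
            lines = [header, fh.readline(), fh.readline(), fh.readline()]
            record_idx += 1
            if not lines[3] or not lines[1] or not lines[2]:
                raise FormatError(f"truncated FASTQ record {record_idx} in {path}")
            if not lines[0].startswith("@") or not lines[2].startswith("+"):
                raise FormatError(f"malformed FASTQ record {record_idx} in {path}")
            seq = lines[1].strip().upper()
            if len(seq) != len(lines[3].strip()):
                raise FormatError(
                    f"sequence/quality length mismatch at FASTQ record {record_idx} in {path}"
                )
            yield lines[0][1:].split()[0], seq


def write_fastq(path, reads: Iterable[tuple[str, str]]) -> None:
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


def read_bed(path) -> list[Interval]:
    """Read BED3+ intervals (0-based half-open). Overlaps are retained, never merged."""
    out = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise FormatError(f"{path}:{lineno}: BED needs >=3 columns")
            try:
                start, end = int(cols[1]), int(cols[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start >= end or start < 0:
                raise FormatError(
                    f"{path}:{lineno}: invalid interval {cols[0]}:{start}-{end}"
                )
            name = cols[3] if len(cols) > 3 else None
            strand = cols[5] if len(cols) > 5 else None
            out.append(Interval(cols[0], start, end, name=name, strand=strand))
    return out


def write_bed(path, intervals: Iterable[Interval]) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            cols = [iv.contig, str(iv.start), str(iv.end)]
            if iv.name is not None:
                cols.append(iv.name)
                if iv.strand is not None:
                    cols += ["0", iv.strand]
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# mismatch-tolerant placement index


@dataclass
class _Placement:
    target: str
    start: int
    strand: Strand
    mismatches: int


class SeedIndex:
    """Seed-and-verify Hamming-distance index over a set of target sequences.

    Supports exact and <=k-mismatch placement of a query on either strand
    of every target, returning only the best stratum (fewest mismatches,
    ties kept).  The pigeonhole principle guarantees completeness: a query
    with <=k mismatches must match one of k+1 disjoint seeds exactly.
    """

    def __init__(self, sequences: dict[str, str], max_mismatch: int = 0,
                 min_query_len: int = 18):
        if max_mismatch not in (0, 1, 2, 3):
            raise ValueError("max_mismatch must be in {0, 1, 2, 3}")
        self.max_mismatch = max_mismatch
        self.sequences = {k: v.upper() for k, v in sequences.items()}
        self.seed_len = max(4, min_query_len // (max_mismatch + 1))
        self._seeds: dict[str, list[tuple[str, int]]] = defaultdict(list)
        s = self.seed_len
        for name, seq in self.sequences.items():
            for i in range(len(seq) - s + 1):
                self._seeds[seq[i : i + s]].append((name, i))

    def search(self, query: str) -> list[_Placement]:
        """All best-stratum placements of ``query`` on either strand."""
        query = query.upper()
        if len(query) < self.seed_len:
            return []
        best: list[_Placement] = []
        best_mm = self.max_mismatch + 1
        for strand, q in ((Strand.SENSE, query), (Strand.ANTISENSE, revcomp(query))):
            for target, start, mm in self._scan(q):
                if mm < best_mm:
                    best_mm = mm
                    best = []
                if mm == best_mm:
                    best.append(_Placement(target, start, strand, mm))
        # de-duplicate placements found through multiple seeds
        seen = set()
        out = []
        for p in best:
            key = (p.target, p.start, p.strand)
            if key not in seen:
                seen.add(key)
                out.append(p)
        out.sort(key=lambda p: (p.target, p.start, p.strand.value))
        return out

    def _scan(self, q: str):
        s = self.seed_len
        k = self.max_mismatch
        offsets = [i * s for i in range(k + 1)]
        offsets = [o for o in offsets if o + s <= len(q)]
        candidates = set()
        for off in offsets:
            for target, pos in self._seeds.get(q[off : off + s], ()):
                candidates.add((target, pos - off))
        for target, start in candidates:
            seq = self.sequences[target]
            if start < 0 or start + len(q) > len(seq):
                continue
            mm = 0
            window = seq[start : start + len(q)]
            for a, b in zip(q, window):
                if a != b:
                    mm += 1
                    if mm > k:
                        break
            else:
                yield target, start, mm


def build_consensus_index(families: Iterable[TEFamily], max_mismatch: int = 0) -> SeedIndex:
    """Index the consensus sequences of a TE family library."""
    return SeedIndex({f.name: f.consensus for f in families}, max_mismatch=max_mismatch)


def build_genome_index(genome_sequences: dict[str, str], max_mismatch: int = 0) -> SeedIndex:
    return SeedIndex(genome_sequences, max_mismatch=max_mismatch)


@dataclass
class MappingResult:
    hits: list[StrandedHit]
    unmapped: Counter = field(default_factory=Counter)

    @property
    def unmapped_copies(self) -> int:
        return sum(self.unmapped.values())

    @property
    def total_copies(self) -> int:
        mapped = sum({h.read_id: h.copies for h in self.hits}.values())
        return mapped + self.unmapped_copies


def assign_reads(reads: Iterable[tuple[str, str]], index: SeedIndex) -> MappingResult:
    """Place reads on the index, collapsing identical sequences.

    Each surviving collapsed read carries all best-stratum placements; the
    shared ``n_locations`` is the total number of such placements across
    the database.  Unmapped sequences are routed to a counter keyed by
    sequence.
    """
    collapsed: dict[str, tuple[str, int]] = {}
    for rid, seq in reads:
        seq = seq.upper()
        if seq in collapsed:
            first, n = collapsed[seq]
            collapsed[seq] = (first, n + 1)
        else:
            collapsed[seq] = (rid, 1)

    hits: list[StrandedHit] = []
    unmapped: Counter = Counter()
    for seq, (rid, copies) in collapsed.items():
        placements = index.search(seq)
        if not placements:
            unmapped[seq] += copies
            continue
        n_loc = len(placements)
        for p in placements:
            five_prime = p.start if p.strand is Strand.SENSE else p.start + len(seq) - 1
            hits.append(
                StrandedHit(
                    read_id=rid,
                    target=p.target,
                    strand=p.strand,
                    five_prime=five_prime,
                    length=len(seq),
                    n_locations=n_loc,
                    copies=copies,
                    mismatches=p.mismatches,
                )
            )
    return MappingResult(hits=hits, unmapped=unmapped)


# ---------------------------------------------------------------------------
# tabular side data

FAMILY_TSV_COLUMNS = [
    "name", "te_class", "tissue", "dependency_group", "ht_candidate",
    "full_length_presence",
]


def write_family_table(path, families: Iterable[TEFamily]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(FAMILY_TSV_COLUMNS) + "\n")
        for f in families:
            fh.write(
                "\t".join(
                    [
                        f.name,
                        f.te_class.value,
                        f.tissue.value,
                        f.dependency_group.value,
                        str(int(f.ht_candidate)),
                        f.full_length_presence.value,
                    ]
                )
                + "\n"
            )


def read_family_table(path, consensus: dict[str, str]) -> list[TEFamily]:
    from .types import DependencyGroup, FullLengthPresence, TEClass, Tissue

    out = []
    with _open_text(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != FAMILY_TSV_COLUMNS:
            raise FormatError(f"unexpected family-table header in {path}")
        for line in fh:
            name, te_class, tissue, group, ht, flp = line.rstrip("\n").split("\t")
            if name not in consensus:
                raise FormatError(f"family {name!r} has no consensus sequence")
            out.append(
                TEFamily(
                    name=name,
                    consensus=consensus[name],
                    te_class=TEClass(te_class),
                    tissue=Tissue(tissue),
                    dependency_group=DependencyGroup(group),
                    ht_candidate=bool(int(ht)),
                    full_length_presence=FullLengthPresence(flp),
                )
            )
    return out


HIT_TSV_COLUMNS = [
    "read_id", "target", "strand", "five_prime", "length", "n_locations",
    "copies", "mismatches",
]


def write_hits(path, hits: Iterable[StrandedHit]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(HIT_TSV_COLUMNS) + "\n")
        for h in hits:
            fh.write(
                f"{h.read_id}\t{h.target}\t{h.strand.value}\t{h.five_prime}\t"
                f"{h.length}\t{h.n_locations}\t{h.copies}\t{h.mismatches}\n"
            )


def read_hits(path) -> list[StrandedHit]:
    out = []
    with _open_text(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != HIT_TSV_COLUMNS:
            raise FormatError(f"unexpected hit-table header in {path}")
        for line in fh:
            rid, target, strand, fp, length, nloc, copies, mm = line.rstrip("\n").split("\t")
            out.append(
                StrandedHit(
                    read_id=rid,
                    target=target,
                    strand=Strand(strand),
                    five_prime=int(fp),
                    length=int(length),
                    n_locations=int(nloc),
                    copies=int(copies),
                    mismatches=int(mm),
                )
            )
    return out
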