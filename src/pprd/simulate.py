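"""Synthetic data with known ground truth.

Generates the full input universe of the analysis: a TE-family consensus
library with metadata, two diverged parental genomes carrying shared and
species-specific insertions plus piRNA clusters, small-RNA libraries with
a planted ping-pong pairing probability, antisense fraction, and length
profile, and negative-binomial mRNA count tables with planted fold
changes.  Every output is fully determined by ``SimConfig.seed``.

Small-RNA reads of the piRNA class are drawn on the consensus axis: a
read is emitted together with an opposite-strand partner whose 5' ends
overlap by exactly 10 nt with the configured family probability, and is
otherwise placed so that it does NOT accidentally complete a 10-nt
overlap with an existing opposite-strand read.  This keeps the planted
pairing probability identifiable from the emitted reads (see
docs/methods.md for what this idealisation does and does not emulate).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .types import (
    DependencyGroup,
    FullLengthPresence,
    GenomeAnnotation,
    Insertion,
    Interval,
    Strand,
    TEClass,
    TEFamily,
    Tissue,
    revcomp,
)

_BASES = np.array(list("ACGT"))

# fixed per-purpose stream ids so adding a stage never shifts another's draws
_STREAMS = {
    "library": 1,
    "genomes": 2,
    "smallrna": 3,
    "mrna": 4,
    "genomic_reads": 5,
}


def _rng(seed: int, stream: str, extra: int = 0) -> np.random.Generator:
    return np.random.default_rng([int(seed) % (2**31), _STREAMS[stream], extra])


@dataclass
class LibraryParams:
    """Parameters of one simulated small-RNA library.

    ``antisense_fraction`` and ``pingpong_prob`` may be scalars or
    per-family dicts (family name -> value).
    """

    n_reads: int = 20_000
    pirna_fraction: float = 0.6
    pirna_len_mean: float = 26.0
    pirna_len_sd: float = 1.5
    bg_len_mean: float = 20.5
    bg_len_sd: float = 1.2
    antisense_fraction: float | dict = 0.8
    pingpong_prob: float | dict = 0.5
    cluster_fraction: float = 0.2
    cluster_weights: Optional[dict] = None

    def family_value(self, attr: str, family: str) -> float:
        v = getattr(self, attr)
        if isinstance(v, dict):
            return float(v[family])
        return float(v)


def mutant_like(params: LibraryParams, pirna_fraction: float = 0.2,
                pingpong_scale: float = 0.3,
                cluster_multipliers: Optional[dict] = None) -> LibraryParams:
    """Hybrid "mutant-like" regime: depleted piRNA share, collapsed
    ping-pong pairing, and perturbed cluster weights."""
    pi = params.pingpong_prob
    if isinstance(pi, dict):
        pi = {k: v * pingpong_scale for k, v in pi.items()}
    else:
        pi = pi * pingpong_scale
    cw = params.cluster_weights
    if cluster_multipliers is not None:
        cw = dict(cw or {})
        for cl, m in cluster_multipliers.items():
            cw[cl] = cw.get(cl, 1.0) * m
    return replace(params, pirna_fraction=pirna_fraction, pingpong_prob=pi,
                   cluster_weights=cw)


@dataclass
class MrnaParams:
    base_mean: float = 500.0
    dispersion: float = 0.01  # near-isogenic pooled-tissue libraries
    library_sizes: dict = field(
        default_factory=lambda: {"parentA": 1.0, "parentB": 1.0, "hybrid": 1.0}
    )
    n_null_genes: int = 200
    planted_log2fc: dict = field(default_factory=dict)  # family -> hybrid log2FC


@dataclass
class SimConfig:
    seed: int = 0
    n_families: int = 12
    consensus_length_range: tuple[int, int] = (1500, 3000)
    insertions_per_family: float = 2.0  # Poisson mean per genome (>=1 enforced)
    divergence: float = 0.02  # substitution prob per site per genome
    n_clusters: int = 5
    cluster_families: int = 3  # families contributing fragments per cluster
    cluster_fragment_range: tuple[int, int] = (300, 700)
    genome_spacer: int = 1500
    abundance_log2_range: tuple[float, float] = (0.0, 5.0)  # log-uniform family weights
    smallrna: dict = field(
        default_factory=lambda: {
            "parentA": LibraryParams(),
            "parentB": LibraryParams(),
            "hybrid": LibraryParams(),
        }
    )
    mrna: MrnaParams = field(default_factory=MrnaParams)
    hybrid_mutant_like: bool = True

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "SimConfig":
        raw = dict(raw)
        if "smallrna" in raw:
            raw["smallrna"] = {
                k: LibraryParams(**v) if isinstance(v, dict) else v
                for k, v in raw["smallrna"].items()
            }
        if "mrna" in raw and isinstance(raw["mrna"], dict):
            raw["mrna"] = MrnaParams(**raw["mrna"])
        for key in ("consensus_length_range", "cluster_fragment_range",
                    "abundance_log2_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        return json.loads(json.dumps(dataclasses.asdict(self), default=list))


# ---------------------------------------------------------------------------
# TE library


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def gen_te_library(config: SimConfig) -> tuple[list[TEFamily], pd.DataFrame]:
    """Random consensus library with metadata and log-uniform abundance weights.

    Returns the families and a per-family truth table (class, tissue,
    dependency group, HT candidacy, abundance weight).
    """
    rng = _rng(config.seed, "library")
    lo, hi = config.consensus_length_range
    families: list[TEFamily] = []
    rows = []
    presence_cycle = [
        FullLengthPresence.BOTH_GENOMES,
        FullLengthPresence.BOTH_GENOMES,
        FullLengthPresence.MEL_ONLY,
        FullLengthPresence.NEITHER,
    ]
    for i in range(config.n_families):
        length = int(rng.integers(lo, hi + 1))
        fam = TEFamily(
            name=f"TE{i + 1:03d}",
            consensus=_random_seq(rng, length),
            te_class=list(TEClass)[int(rng.integers(0, 3))],
            tissue=[Tissue.GERMLINE, Tissue.SOMATIC, Tissue.INTERMEDIATE][
                int(rng.integers(0, 3))
            ],
            dependency_group=[DependencyGroup.I, DependencyGroup.II,
                              DependencyGroup.III][int(rng.integers(0, 3))],
            ht_candidate=bool(rng.random() < 0.2),
            full_length_presence=presence_cycle[i % len(presence_cycle)],
        )
        families.append(fam)
        lo2, hi2 = config.abundance_log2_range
        rows.append(
            {
                "family": fam.name,
                "length": length,
                "te_class": fam.te_class.value,
                "tissue": fam.tissue.value,
                "dependency_group": fam.dependency_group.value,
                "ht_candidate": fam.ht_candidate,
                "full_length_presence": fam.full_length_presence.value,
                "abundance_weight": float(2.0 ** rng.uniform(lo2, hi2)),
            }
        )
    truth = pd.DataFrame(rows).set_index("family") if rows else pd.DataFrame(
        columns=["length", "abundance_weight"]
    )
    return families, truth


# ---------------------------------------------------------------------------
# parental genomes


@dataclass
class GenomePair:
    parent_a: GenomeAnnotation
    parent_b: GenomeAnnotation
    diagnostic_sites: pd.DataFrame  # family, copy, offset, base_a, base_b
    cluster_composition: dict  # cluster id -> list of (family, frag_len)


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> tuple[str, np.ndarray]:
    """Substitute each site independently with probability ``rate``."""
    if rate <= 0:
        return seq, np.array([], dtype=int)
    arr = np.array(list(seq))
    hit = np.where(rng.random(len(arr)) < rate)[0]
    for i in hit:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[int(rng.integers(0, 3))]
    return "".join(arr), hit


def gen_parental_genomes(config: SimConfig, families: Sequence[TEFamily]) -> GenomePair:
    """Two genomes with shared and species-specific TE copies plus clusters.

    Shared (orthologous) copies are mutated independently in each genome
    at the per-site divergence rate; when divergence > 0 every shared
    copy is guaranteed at least one diagnostic substitution
    distinguishing the genomes.  piRNA clusters — TE-dense intervals of
    fragmented antisense copies — are annotated on parent A only,
    mirroring the asymmetric assembly quality of real references.
    """
    rng = _rng(config.seed, "genomes")
    spacer = config.genome_spacer
    seq_a: list[str] = []
    seq_b: list[str] = []
    pos_a = pos_b = 0
    ins_a: list[Insertion] = []
    ins_b: list[Insertion] = []
    diag_rows = []

    def _pad(n: int):
        nonlocal pos_a, pos_b
        pad_a = _random_seq(rng, n)
        pad_b = _random_seq(rng, n)
        seq_a.append(pad_a)
        seq_b.append(pad_b)
        pos_a += n
        pos_b += n

    for fam in families:
        presence = fam.full_length_presence
        if presence is FullLengthPresence.NEITHER:
            continue
        n_copies = max(1, int(rng.poisson(config.insertions_per_family)))
        for copy_idx in range(n_copies):
            _pad(spacer)
            strand = "+" if rng.random() < 0.5 else "-"
            base = fam.consensus if strand == "+" else revcomp(fam.consensus)
            copy_a, sub_a = _mutate(base, config.divergence, rng)
            seq_a.append(copy_a)
            ins_a.append(Insertion(fam.name, "chr1", pos_a, pos_a + len(copy_a), strand))
            pos_a += len(copy_a)
            if presence is FullLengthPresence.BOTH_GENOMES:
                copy_b, sub_b = _mutate(base, config.divergence, rng)
                if config.divergence > 0 and copy_a == copy_b:
                    # force one diagnostic substitution
                    i = int(rng.integers(0, len(copy_b)))
                    arr = list(copy_b)
                    choices = [b for b in "ACGT" if b != arr[i]]
                    arr[i] = choices[int(rng.integers(0, 3))]
                    copy_b = "".join(arr)
                seq_b.append(copy_b)
                ins_b.append(
                    Insertion(fam.name, "chr1", pos_b, pos_b + len(copy_b), strand)
                )
                pos_b += len(copy_b)
                for off in np.union1d(sub_a, np.where(
                    np.frombuffer(copy_a.encode(), dtype="S1")
                    != np.frombuffer(copy_b.encode(), dtype="S1")
                )[0]):
                    if copy_a[off] != copy_b[off]:
                        diag_rows.append(
                            {
                                "family": fam.name,
                                "copy": copy_idx,
                                "offset": int(off),
                                "base_a": copy_a[off],
                                "base_b": copy_b[off],
                            }
                        )

    # piRNA clusters on parent A: concatenated antisense fragments
    clusters: list[Interval] = []
    composition: dict[str, list] = {}
    frag_lo, frag_hi = config.cluster_fragment_range
    eligible = [f for f in families
                if f.full_length_presence is not FullLengthPresence.NEITHER] or list(families)
    for ci in range(config.n_clusters):
        _pad(spacer)
        start = pos_a
        frags = []
        for _ in range(config.cluster_families):
            fam = eligible[int(rng.integers(0, len(eligible)))]
            flen = int(rng.integers(frag_lo, min(frag_hi, len(fam.consensus)) + 1))
            off = int(rng.integers(0, len(fam.consensus) - flen + 1))
            frag = revcomp(fam.consensus[off : off + flen])
            seq_a.append(frag)
            pos_a += flen
            frags.append((fam.name, flen))
        cid = f"cluster{ci + 1}"
        clusters.append(Interval("chr1", start, pos_a, name=cid))
        composition[cid] = frags
    _pad(spacer)

    genome_a = GenomeAnnotation("parentA", {"chr1": "".join(seq_a)}, ins_a, clusters)
    genome_b = GenomeAnnotation("parentB", {"chr1": "".join(seq_b)}, ins_b, [])
    genome_a.validate()
    genome_b.validate()
    diag = pd.DataFrame(diag_rows, columns=["family", "copy", "offset", "base_a", "base_b"])
    return GenomePair(genome_a, genome_b, diag, composition)


# ---------------------------------------------------------------------------
# small RNA libraries


def _trunc_lengths(rng, n, mean, sd, lo, hi) -> np.ndarray:
    """Integer lengths from a normal truncated (by resampling) to [lo, hi]."""
    out = np.rint(rng.normal(mean, sd, size=n)).astype(int)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = np.rint(rng.normal(mean, sd, size=int(bad.sum()))).astype(int)
        bad = (out < lo) | (out > hi)
    return out


@dataclass
class SmallRnaTruth:
    reads: pd.DataFrame  # per-read truth
    families: pd.DataFrame  # per-family planted parameters and realised counts
    resampled_partners: int = 0


def sim_small_rna_library(
    config: SimConfig,
    families: Sequence[TEFamily],
    library_id: str,
    params: Optional[LibraryParams] = None,
    family_weights: Optional[pd.Series] = None,
    genome_pair: Optional[GenomePair] = None,
    stream: int = 0,
) -> tuple[list[tuple[str, str]], SmallRnaTruth]:
    """One small-RNA library (18-30 nt) with planted ping-pong structure.

    piRNA-class reads (lengths truncated to [23, 29]) are allocated across
    families by abundance weight.  A binomially-drawn share of each
    family's reads is emitted as exact-10-nt 5'-5' overlap pairs; the rest
    are lone reads whose strand follows the configured antisense fraction
    and whose placement avoids completing a spurious pair.  Background
    reads (18-22 nt) are random sequence.  An optional cluster slice draws
    reads from parent-A piRNA cluster intervals.
    """
    params = params or config.smallrna[library_id]
    rng = _rng(config.seed, "smallrna", abs(hash(library_id)) % 10_000 + stream)
    fam_by_name = {f.name: f for f in families}
    if family_weights is None:
        family_weights = pd.Series(1.0, index=[f.name for f in families])
    family_weights = family_weights / family_weights.sum()

    n_pi = int(rng.binomial(params.n_reads, params.pirna_fraction))
    n_bg = params.n_reads - n_pi
    n_cluster = 0
    if genome_pair is not None and genome_pair.parent_a.clusters and params.cluster_fraction > 0:
        n_cluster = int(rng.binomial(n_pi, params.cluster_fraction))
    n_fam_reads = n_pi - n_cluster

    alloc = rng.multinomial(n_fam_reads, family_weights.to_numpy())
    reads: list[tuple[str, str]] = []
    truth_rows = []
    fam_rows = []
    resampled = 0
    counter = 0

    def _next_id() -> str:
        nonlocal counter
        counter += 1
        return f"{library_id}:{counter:07d}"

    for fam_name, n_f in zip(family_weights.index, alloc):
        if n_f == 0:
            continue
        fam = fam_by_name[fam_name]
        L = len(fam.consensus)
        pi = params.family_value("pingpong_prob", fam_name)
        af = params.family_value("antisense_fraction", fam_name)
        paired = int(rng.binomial(n_f, pi))
        n_pairs = paired // 2
        sense5: set[int] = set()
        anti5: set[int] = set()
        for p_idx in range(n_pairs):
            ls, la = _trunc_lengths(rng, 2, params.pirna_len_mean,
                                    params.pirna_len_sd, 23, 29)
            lo = max(0, int(la) - 10)
            hi = min(L - int(ls), L - 10)
            if hi < lo:  # both partners cannot fit at these lengths
                resampled += 1
                ls = la = 23
                lo, hi = max(0, la - 10), min(L - ls, L - 10)
            p = int(rng.integers(lo, hi + 1))
            pair_id = f"{library_id}:{fam_name}:pp{p_idx}"
            a5 = p + 9
            sense5.add(p)
            anti5.add(a5)
            rid_s, rid_a = _next_id(), _next_id()
            reads.append((rid_s, fam.consensus[p : p + int(ls)]))
            a_start = a5 - int(la) + 1
            reads.append((rid_a, revcomp(fam.consensus[a_start : a_start + int(la)])))
            truth_rows.append(dict(read_id=rid_s, family=fam_name, source="pingpong",
                                   strand="sense", length=int(ls), five_prime=p,
                                   pair_id=pair_id, cluster=None))
            truth_rows.append(dict(read_id=rid_a, family=fam_name, source="pingpong",
                                   strand="antisense", length=int(la), five_prime=a5,
                                   pair_id=pair_id, cluster=None))
        n_lone = n_f - 2 * n_pairs
        for _ in range(n_lone):
            length = int(_trunc_lengths(rng, 1, params.pirna_len_mean,
                                        params.pirna_len_sd, 23, 29)[0])
            anti = rng.random() < af
            for _attempt in range(50):
                if anti:
                    a5 = int(rng.integers(length - 1, L))
                    if (a5 - 9) not in sense5:
                        break
                else:
                    p = int(rng.integers(0, L - length + 1))
                    if (p + 9) not in anti5:
                        break
                resampled += 1
            rid = _next_id()
            if anti:
                start = a5 - length + 1
                reads.append((rid, revcomp(fam.consensus[start : start + length])))
                anti5.add(a5)
                truth_rows.append(dict(read_id=rid, family=fam_name, source="lone",
                                       strand="antisense", length=length,
                                       five_prime=a5, pair_id=None, cluster=None))
            else:
                reads.append((rid, fam.consensus[p : p + length]))
                sense5.add(p)
                truth_rows.append(dict(read_id=rid, family=fam_name, source="lone",
                                       strand="sense", length=length, five_prime=p,
                                       pair_id=None, cluster=None))
        fam_rows.append(
            dict(family=fam_name, n_reads=int(n_f), planted_pi=pi,
                 planted_antisense_fraction=af,
                 expected_antisense_fraction=(2 * n_pairs * 0.5 + (n_f - 2 * n_pairs) * af) / n_f,
                 paired_fraction=2 * n_pairs / n_f)
        )

    # cluster-derived piRNAs (parent-A genomic sequence)
    if n_cluster:
        clusters = genome_pair.parent_a.clusters
        chrom = genome_pair.parent_a.sequences["chr1"]
        weights = np.array(
            [
                (params.cluster_weights or {}).get(cl.name, 1.0) * len(cl)
                for cl in clusters
            ],
            dtype=float,
        )
        weights /= weights.sum()
        calloc = rng.multinomial(n_cluster, weights)
        for cl, n_c in zip(clusters, calloc):
            for _ in range(int(n_c)):
                length = int(_trunc_lengths(rng, 1, params.pirna_len_mean,
                                            params.pirna_len_sd, 23, 29)[0])
                start = int(rng.integers(cl.start, cl.end - length + 1))
                frag = chrom[start : start + length]
                minus = rng.random() < 0.5
                rid = _next_id()
                reads.append((rid, revcomp(frag) if minus else frag))
                fp = start + length - 1 if minus else start
                truth_rows.append(dict(read_id=rid, family=None, source="cluster",
                                       strand="antisense" if minus else "sense",
                                       length=length, five_prime=fp,
                                       pair_id=None, cluster=cl.name))

    # 18-22 nt background (miRNA/endo-siRNA-like, random sequence)
    bg_lengths = _trunc_lengths(rng, n_bg, params.bg_len_mean, params.bg_len_sd, 18, 22)
    for length in bg_lengths:
        rid = _next_id()
        reads.append((rid, _random_seq(rng, int(length))))
        truth_rows.append(dict(read_id=rid, family=None, source="background",
                               strand=None, length=int(length), five_prime=None,
                               pair_id=None, cluster=None))

    truth_reads = pd.DataFrame(
        truth_rows,
        columns=["read_id", "family", "source", "strand", "length", "five_prime",
                 "pair_id", "cluster"],
    )
    truth_fams = pd.DataFrame(
        fam_rows,
        columns=["family", "n_reads", "planted_pi", "planted_antisense_fraction",
                 "expected_antisense_fraction", "paired_fraction"],
    ).set_index("family") if fam_rows else pd.DataFrame()
    return reads, SmallRnaTruth(truth_reads, truth_fams, resampled)


def sim_genomic_reads(
    config: SimConfig,
    genome_pair: GenomePair,
    n_reads: int,
    length_range: tuple[int, int] = (23, 29),
    stream: int = 0,
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Error-free reads sampled from TE insertion copies of both genomes.

    Each read carries the per-copy substitutions of its genome of origin,
    so reads covering a diagnostic site are genome-unique at zero
    mismatches.  Used for species-of-origin partition studies.
    """
    rng = _rng(config.seed, "genomic_reads", stream)
    genomes = [genome_pair.parent_a, genome_pair.parent_b]
    pools = []
    for g in genomes:
        for ins in g.insertions:
            pools.append((g, ins))
    if not pools:
        raise ValueError("no insertions to sample from")
    weights = np.array([ins.end - ins.start for _, ins in pools], dtype=float)
    weights /= weights.sum()
    lo, hi = length_range
    reads, rows = [], []
    for i in range(n_reads):
        g, ins = pools[int(rng.choice(len(pools), p=weights))]
        length = int(rng.integers(lo, hi + 1))
        start = int(rng.integers(ins.start, ins.end - length + 1))
        seq = g.sequences[ins.contig][start : start + length]
        if rng.random() < 0.5:
            seq = revcomp(seq)
        rid = f"gread:{i:07d}"
        reads.append((rid, seq))
        rows.append(dict(read_id=rid, genome_of_origin=g.genome_id,
                         family=ins.family, contig=ins.contig, start=start,
                         length=length))
    return reads, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# mRNA counts


def sim_mrna_counts(
    config: SimConfig,
    families: Optional[Sequence[TEFamily]] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Negative-binomial count table for {parentA, parentB, hybrid}.

    Hybrid mean = (parent A mean + parent B mean) / 2 x 2**planted_log2fc.
    Dispersion 0 falls back to Poisson noise.  Rows are TE families plus
    ``n_null_genes`` protein-coding-gene-like null rows.
    """
    p = config.mrna
    rng = _rng(config.seed, "mrna")
    names = [f.name for f in families] if families else [
        f"TE{i + 1:03d}" for i in range(config.n_families)
    ]
    names = names + [f"gene{i + 1:04d}" for i in range(p.n_null_genes)]
    base = p.base_mean * 2.0 ** rng.uniform(-1.5, 1.5, size=len(names))
    l2fc = np.array([p.planted_log2fc.get(n, 0.0) for n in names])
    mean_a = base * 2.0 ** rng.normal(0, 0.05, size=len(names))
    mean_b = base * 2.0 ** rng.normal(0, 0.05, size=len(names))
    mean_h = 0.5 * (mean_a + mean_b) * 2.0 ** l2fc

    def _draw(mu: np.ndarray, size_factor: float) -> np.ndarray:
        mu = np.maximum(mu * size_factor, 1e-8)
        if p.dispersion <= 0:
            return rng.poisson(mu)
        r = 1.0 / p.dispersion
        return rng.negative_binomial(r, r / (r + mu))

    counts = pd.DataFrame(
        {
            "parentA": _draw(mean_a, p.library_sizes.get("parentA", 1.0)),
            "parentB": _draw(mean_b, p.library_sizes.get("parentB", 1.0)),
            "hybrid": _draw(mean_h, p.library_sizes.get("hybrid", 1.0)),
        },
        index=pd.Index(names, name="feature"),
    )
    truth = pd.DataFrame(
        {
            "mean_parentA": mean_a,
            "mean_parentB": mean_b,
            "mean_hybrid": mean_h,
            "planted_log2fc": l2fc,
            "derepressed": l2fc >= 1.0,
            "is_te": [n.startswith("TE") for n in names],
        },
        index=counts.index,
    )
    return counts, truth


# ---------------------------------------------------------------------------
# full simulation bundle


@dataclass
class SimOutput:
    families: list[TEFamily]
    family_truth: pd.DataFrame
    genome_pair: GenomePair
    smallrna_reads: dict  # library id -> list of (id, seq)
    smallrna_truth: dict  # library id -> SmallRnaTruth
    mrna_counts: pd.DataFrame
    mrna_truth: pd.DataFrame


def simulate_all(config: SimConfig) -> SimOutput:
    """Run every generator stage under one seed."""
    families, family_truth = gen_te_library(config)
    genome_pair = gen_parental_genomes(config, families)
    weights = family_truth["abundance_weight"] if len(family_truth) else None
    sr_reads, sr_truth = {}, {}
    for lib_id, params in config.smallrna.items():
        if lib_id == "hybrid" and config.hybrid_mutant_like:
            params = mutant_like(params)
        reads, truth = sim_small_rna_library(
            config, families, lib_id, params=params, family_weights=weights,
            genome_pair=genome_pair,
        )
        sr_reads[lib_id] = reads
        sr_truth[lib_id] = truth
    mrna_counts, mrna_truth = sim_mrna_counts(config, families)
    return SimOutput(families, family_truth, genome_pair, sr_reads, sr_truth,
                     mrna_counts, mrna_truth)


def write_simulation(out: SimOutput, outdir) -> dict:
    """Write FASTA/FASTQ/BED/TSV outputs plus truth.json; returns the path map."""
    from . import io as pio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    def _p(name: str) -> Path:
        paths[name] = str(outdir / name)
        return outdir / name

    pio.write_fasta(_p("te_consensus.fasta"), {f.name: f.consensus for f in out.families})
    pio.write_family_table(_p("te_metadata.tsv"), out.families)
    for tag, g in (("parentA", out.genome_pair.parent_a), ("parentB", out.genome_pair.parent_b)):
        pio.write_fasta(_p(f"genome_{tag}.fasta"), g.sequences)
        pio.write_bed(
            _p(f"insertions_{tag}.bed"),
            [Interval(i.contig, i.start, i.end, name=i.family, strand=i.strand)
             for i in g.insertions],
        )
    pio.write_bed(_p("clusters_parentA.bed"), out.genome_pair.parent_a.clusters)
    out.genome_pair.diagnostic_sites.to_csv(_p("diagnostic_sites.tsv"), sep="\t", index=False)
    for lib_id, reads in out.smallrna_reads.items():
        pio.write_fastq(_p(f"smallrna_{lib_id}.fastq"), reads)
        out.smallrna_truth[lib_id].reads.to_csv(
            _p(f"smallrna_{lib_id}.truth.tsv"), sep="\t", index=False
        )
    out.mrna_counts.to_csv(_p("mrna_counts.tsv"), sep="\t")
    truth = {
        "family_truth": out.family_truth.reset_index().to_dict(orient="list"),
        "mrna_truth": out.mrna_truth.reset_index().to_dict(orient="list"),
        "smallrna_family_truth": {
            lib: t.families.reset_index().to_dict(orient="list")
            for lib, t in out.smallrna_truth.items()
        },
        "cluster_composition": out.genome_pair.cluster_composition,
    }
    with open(_p("truth.json"), "w") as fh:
        json.dump(truth, fh, indent=1)
    return paths
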