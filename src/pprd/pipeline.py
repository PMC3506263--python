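"""End-to-end orchestration: simulate -> map -> profile -> ping-pong ->
expression -> clusters -> stats, with a manifest and a summary report.

Every stage writes a TSV under the output directory; the summary report
only collects numbers already present in stage outputs.  Re-running with
an identical config and seed reproduces byte-identical tabular outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from . import clusters as cl
from . import expression as ex
from . import pingpong as pp
from . import profile as pr
from . import stats as st
from .io import assign_reads, build_consensus_index, build_genome_index
from .simulate import SimConfig, simulate_all, write_simulation
from .types import PIRNA_MIN_LEN

log = logging.getLogger("pprd")


@dataclass
class RunManifest:
    config: dict
    seed: int
    version: str = __version__
    input_digests: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)
    stages: list = field(default_factory=list)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=1, default=str)


def _digest(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()[:16]


def run_all(config: SimConfig, outdir) -> tuple[Path, RunManifest]:
    """Run the whole pipeline on a fresh simulation; returns (outdir, manifest)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=config.to_dict(), seed=config.seed)
    t_all = time.time()

    def _stage(name):
        log.info("stage %s", name)
        manifest.stages.append({"stage": name, "t": round(time.time() - t_all, 2)})

    _stage("simulate")
    sim = simulate_all(config)
    sim_paths = write_simulation(sim, outdir / "sim")
    manifest.input_digests = {k: _digest(v) for k, v in sim_paths.items()}

    _stage("map")
    cons_index = build_consensus_index(sim.families, max_mismatch=0)
    genome_index = build_genome_index(sim.genome_pair.parent_a.sequences, max_mismatch=0)
    cons_hits = {}
    genome_hits = {}
    libsizes = {}
    for lib_id, reads in sim.smallrna_reads.items():
        cons_hits[lib_id] = assign_reads(reads, cons_index)
        genome_hits[lib_id] = assign_reads(reads, genome_index)
        libsizes[lib_id] = len(reads)

    _stage("profile")
    size_rows = []
    abundance_frames = []
    for lib_id, reads in sim.smallrna_reads.items():
        dist = pr.size_distribution([len(s) for _, s in reads], library_id=lib_id)
        size_rows.append(dist.to_frame().assign(library=lib_id))
        ab = pr.family_abundance(cons_hits[lib_id].hits, libsizes[lib_id],
                                 library_id=lib_id)
        abundance_frames.append(ab.assign(library=lib_id))
    size_table = pd.concat(size_rows)
    size_table.to_csv(outdir / "size_distribution.tsv", sep="\t")
    abundance = pd.concat(abundance_frames)
    abundance.to_csv(outdir / "family_abundance.tsv", sep="\t")
    pirna_share = {
        lib: pr.size_distribution([len(s) for _, s in reads], library_id=lib).pirna_share
        for lib, reads in sim.smallrna_reads.items()
    }

    diff = pr.differential_abundance(
        abundance[abundance["library"] == "parentA"]["rpm"],
        abundance[abundance["library"] == "parentB"]["rpm"],
        library_size_a=libsizes["parentA"],
        library_size_b=libsizes["parentB"],
    )
    diff.to_frame().to_csv(outdir / "differential_abundance.tsv", sep="\t")

    _stage("pingpong")
    pp_results = []
    for lib_id in sim.smallrna_reads:
        pp_results.extend(pp.pingpong_by_family(cons_hits[lib_id].hits, library_id=lib_id))
    pp_table = pp.pingpong_table(pp_results)
    pp_table.to_csv(outdir / "pingpong.tsv", sep="\t", index=False)

    _stage("expression")
    mrna_libsizes = ex.size_factors(sim.mrna_counts)
    lengths = pd.Series(
        {f.name: len(f) for f in sim.families}, name="length"
    ).reindex(sim.mrna_counts.index)
    # gene-like rows get a nominal 1 kb length for normalization
    lengths = lengths.fillna(1000.0)
    expr = ex.call_status(sim.mrna_counts, mrna_libsizes, lengths=lengths)
    expr.to_csv(outdir / "expression.tsv", sep="\t")

    _stage("clusters")
    clusters = sim.genome_pair.parent_a.clusters
    cluster_rows = []
    freq = {}
    for lib_id in sim.smallrna_reads:
        pirna_total = sum(
            1 for _, seq in sim.smallrna_reads[lib_id] if len(seq) >= PIRNA_MIN_LEN
        )
        for scheme in cl.SCHEMES:
            tallies = cl.cluster_tally(
                [h for h in genome_hits[lib_id].hits if h.length >= PIRNA_MIN_LEN],
                clusters, scheme=scheme,
            )
            freq[(lib_id, scheme)] = cl.cluster_frequencies(tallies, pirna_total)
    for scheme in cl.SCHEMES:
        tab = cl.cluster_activity_table(
            freq[("parentA", scheme)], freq[("parentB", scheme)],
            freq[("hybrid", scheme)], scheme=scheme,
        )
        cluster_rows.append(tab.assign(scheme=scheme))
    cluster_table = pd.concat(cluster_rows)
    cluster_table.to_csv(outdir / "cluster_activity.tsv", sep="\t")

    _stage("stats")
    te_rows = expr[expr.index.str.startswith("TE")]
    gene_rows = expr[~expr.index.str.startswith("TE")]
    stats_out: dict = {}
    te_dr = int((te_rows["status"] == "derepressed").sum())
    gene_dr = int((gene_rows["status"] == "derepressed").sum())
    if te_dr and len(gene_rows) and gene_dr < len(gene_rows) and te_dr < len(te_rows):
        g = st.g_test_2x2(te_dr, len(te_rows) - te_dr, gene_dr,
                          len(gene_rows) - gene_dr)
        stats_out["g_test_te_vs_gene"] = {"G": g.value, "df": g.df, "p": g.pvalue}
    te_families_with_cat = diff.index.intersection(te_rows.index)
    if len(te_families_with_cat) >= 3:
        cat = st.derepression_by_category(
            diff.loc[te_families_with_cat],
            te_rows.loc[te_families_with_cat, "status"] == "derepressed",
        )
        stats_out["derepression_by_category"] = {
            "proportions": cat["proportions"].to_dict(),
            "chi_square": (
                {"X2": cat["chi_square"].value, "df": cat["chi_square"].df,
                 "p": cat["chi_square"].pvalue}
                if cat["chi_square"] else None
            ),
        }

    summary = {
        "n_derepressed_te": te_dr,
        "n_te": int(len(te_rows)),
        "n_derepressed_genes": gene_dr,
        "n_genes": int(len(gene_rows)),
        "pirna_share": pirna_share,
        "pingpong_families_reported": sorted(pp_table["family"].unique().tolist()),
        "cluster_inheritance": {
            scheme: cl_tab["inheritance"].to_dict()
            for scheme, cl_tab in cluster_table.groupby("scheme")
        },
        "stats": stats_out,
    }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1)

    for name in ("size_distribution.tsv", "family_abundance.tsv",
                 "differential_abundance.tsv", "pingpong.tsv", "expression.tsv",
                 "cluster_activity.tsv", "summary.json"):
        manifest.outputs[name] = _digest(outdir / name)
    manifest.save(outdir / "manifest.json")
    _stage("done")
    return outdir, manifest
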