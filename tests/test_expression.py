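"""mRNA quantification, the dual-parent derepression caller, origin partition."""

import numpy as np
import pandas as pd
import pytest
from conftest import make_hit

from pprd import expression as ex
from pprd.io import build_genome_index
from pprd.simulate import SimConfig, sim_genomic_reads, sim_mrna_counts
from pprd.types import revcomp


# ------------------------------------------------------------ quantify/normalize

def test_quantify_unique_and_tied():
    hits = [make_hit(f"r{i}", target="F", five_prime=i) for i in range(100)]
    hits += [make_hit("t", target="F", n_locations=2),
             make_hit("t", target="G", n_locations=2)]
    counts = ex.quantify(hits)
    assert counts["F"] == pytest.approx(100.5)
    assert counts["G"] == pytest.approx(0.5)


def test_normalize_formula():
    counts = pd.Series({"F": 100.0})
    lengths = pd.Series({"F": 1000.0})
    assert ex.normalize(counts, 1e6, lengths)["F"] == pytest.approx(100.0)
    assert ex.normalize(counts, 2e6, lengths)["F"] == pytest.approx(50.0)
    assert ex.normalize(counts, 1e6, pd.Series({"F": 2000.0}))["F"] == pytest.approx(50.0)
    with pytest.raises(ValueError):
        ex.normalize(counts, 0, lengths)


# ------------------------------------------------------------------- caller

def _table(h, a, b, index=("x",)):
    return pd.DataFrame({"hybrid": h, "parentA": a, "parentB": b},
                        index=list(index))


EQ_SIZES = {"hybrid": 1.0, "parentA": 1.0, "parentB": 1.0}


def test_fold_rule_arithmetic():
    tab = _table([4000], [1000], [1500])
    out = ex.call_status(tab, EQ_SIZES)
    assert out.loc["x", "log2fc_vs_A"] == pytest.approx(2.0, abs=0.01)
    assert out.loc["x", "log2fc_vs_B"] == pytest.approx(np.log2(4000 / 1500), abs=0.01)
    assert out.loc["x", "status_fold_only"] == "derepressed"


def test_fold_fails_against_one_parent():
    tab = _table([3000], [2000], [2500])
    out = ex.call_status(tab, EQ_SIZES)
    assert out.loc["x", "status_fold_only"] == "unchanged"
    assert out.loc["x", "status"] == "unchanged"


def test_gate_only_removes_calls():
    cfg = SimConfig(seed=83, n_families=30)
    cfg.mrna.planted_log2fc = {f"TE{i + 1:03d}": 2.0 for i in range(5)}
    counts, _ = sim_mrna_counts(cfg)
    sizes = {c: float(counts[c].sum()) for c in counts}
    out = ex.call_status(counts, sizes)
    gated = set(out.index[out["status"] == "derepressed"])
    fold_only = set(out.index[out["status_fold_only"] == "derepressed"])
    assert gated <= fold_only


def test_monotonic_in_hybrid_count():
    base = _table([4000], [1000], [1000])
    out1 = ex.call_status(base, EQ_SIZES)
    out2 = ex.call_status(_table([8000], [1000], [1000]), EQ_SIZES)
    assert out1.loc["x", "status"] == "derepressed"
    assert out2.loc["x", "status"] == "derepressed"


def test_strict_greater_flag_boundary():
    # exact 2-fold with pseudocounts: (199.5+0.5) = 2 x (99.5+0.5)
    exact = _table([199.5], [99.5], [99.5])
    incl = ex.call_status(exact, EQ_SIZES)
    strict = ex.call_status(exact, EQ_SIZES,
                            config=ex.CallerConfig(strict_greater=True))
    assert incl.loc["x", "log2fc_vs_A"] == pytest.approx(1.0)
    assert incl.loc["x", "status_fold_only"] == "derepressed"
    assert strict.loc["x", "status_fold_only"] == "unchanged"


def test_planted_recovery_and_truth(small_config):
    cfg = SimConfig(seed=84, n_families=25)
    cfg.mrna.planted_log2fc = {f"TE{i + 1:03d}": 2.0 for i in range(5)}
    cfg.mrna.n_null_genes = 50
    counts, truth = sim_mrna_counts(cfg)
    sizes = {c: float(counts[c].sum()) for c in counts}
    out = ex.call_status(counts, sizes)
    called = set(out.index[out["status"] == "derepressed"])
    planted = set(truth.index[truth["derepressed"]])
    assert planted <= called


def test_null_calibration_poisson():
    """Conditional-binomial q-values: null positive rate within tolerance."""
    n_sig = 0
    n_rows = 0
    for seed in range(5):
        cfg = SimConfig(seed=100 + seed, n_families=10)
        cfg.mrna.dispersion = 0.0  # the test's exact regime
        cfg.mrna.n_null_genes = 100
        counts, _ = sim_mrna_counts(cfg)
        sizes = {c: float(counts[c].sum()) for c in counts}
        out = ex.call_status(counts, sizes)
        n_sig += int(((out["q_vs_A"] < 0.05) | (out["q_vs_B"] < 0.05)).sum())
        n_rows += len(out)
    assert n_sig / n_rows <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / n_rows)


def test_nb_test_option_runs_and_recovers():
    cfg = SimConfig(seed=85, n_families=10)
    cfg.mrna.planted_log2fc = {"TE001": 2.0}
    counts, _ = sim_mrna_counts(cfg)
    sizes = {c: float(counts[c].sum()) for c in counts}
    out = ex.call_status(counts, sizes, config=ex.CallerConfig(test="nb"))
    assert out.loc["TE001", "status"] == "derepressed"


# ---------------------------------------------------------- origin partition

@pytest.fixture(scope="module")
def origin_setup():
    cfg = SimConfig(seed=90, n_families=5, divergence=0.02, n_clusters=0)
    from pprd.simulate import gen_parental_genomes, gen_te_library

    fams, _ = gen_te_library(cfg)
    pair = gen_parental_genomes(cfg, fams)
    idx_a = build_genome_index(pair.parent_a.sequences)
    idx_b = build_genome_index(pair.parent_b.sequences)
    return cfg, pair, idx_a, idx_b


def test_diagnostic_read_is_genome_unique(origin_setup):
    cfg, pair, idx_a, idx_b = origin_setup
    site = pair.diagnostic_sites.iloc[0]
    ins = next(i for i in pair.parent_a.insertions if i.family == site.family)
    pos = ins.start + int(site.offset)
    seq = pair.parent_a.sequences["chr1"][pos - 10:pos + 15]
    part = ex.origin_partition([("r1", seq)], idx_a, idx_b,
                               pair.parent_a.insertions, pair.parent_b.insertions)
    assert part.read_classes["r1"] == "A_only"


def test_shared_read_classified_shared(origin_setup):
    cfg, pair, idx_a, idx_b = origin_setup
    # find a window of a shared insertion with no diagnostic site
    ins_a = pair.parent_a.insertions[0]
    diag = set(pair.diagnostic_sites.query("family == @ins_a.family and copy == 0")["offset"])
    for off in range(0, ins_a.end - ins_a.start - 25):
        if not any(off <= d < off + 25 for d in diag):
            seq = pair.parent_a.sequences["chr1"][ins_a.start + off:ins_a.start + off + 25]
            break
    part = ex.origin_partition([("r1", seq)], idx_a, idx_b,
                               pair.parent_a.insertions, pair.parent_b.insertions)
    assert part.read_classes["r1"] == "shared"


def test_simulated_reads_match_substring_oracle(origin_setup):
    """Zero-mismatch classification agrees with direct substring search."""
    cfg, pair, idx_a, idx_b = origin_setup
    reads, truth = sim_genomic_reads(cfg, pair, 400)
    part = ex.origin_partition(reads, idx_a, idx_b)
    ga = pair.parent_a.sequences["chr1"]
    gb = pair.parent_b.sequences["chr1"]
    for rid, seq in reads:
        in_a = seq in ga or revcomp(seq) in ga
        in_b = seq in gb or revcomp(seq) in gb
        expect = {(True, True): "shared", (True, False): "A_only",
                  (False, True): "B_only", (False, False): "unmapped"}[(in_a, in_b)]
        assert part.read_classes[rid] == expect


def test_per_origin_fold_change():
    hyb = pd.DataFrame({"a_only": [20], "b_only": [10], "shared": [5]}, index=["F"])
    pa = pd.DataFrame({"a_only": [5], "b_only": [0], "shared": [3]}, index=["F"])
    pb = pd.DataFrame({"a_only": [0], "b_only": [5], "shared": [3]}, index=["F"])
    sizes = {"hybrid": 1.0, "parentA": 1.0, "parentB": 1.0}
    out = ex.per_origin_fold_change(hyb, pa, pb, sizes)
    assert out.loc["F", "log2fc_A_origin"] == pytest.approx(np.log2(20.5 / 5.5))
    assert not out.loc["F", "flag_no_parent_A_reads"]
    assert not out.loc["F", "flag_no_parent_B_reads"]
    out2 = ex.per_origin_fold_change(hyb, pb.rename(columns={}), pa, sizes)
    assert out2.loc["F", "flag_no_parent_A_reads"]
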