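"""Generator sanity: divergence recovery, ts/tv bias, read error rates,
naive assembly, determinism."""

import math

import numpy as np
import pytest

from strainvar.seqio import QualSeq
from strainvar.simulate import (ErrorProfile, SimConfig, assemble_naive,
                                shred_to_reads, simulate_quartet_segments,
                                simulate_strains)


def _pairwise_diff(a: str, b: str) -> tuple[int, int]:
    mism = sum(x != y for x, y in zip(a, b))
    return mism, len(a)


def test_zero_branch_lengths_yield_identical_strains():
    cfg = SimConfig(n_genes=5, strain_tree="(A:0.0,B:0.0,C:0.0);",
                    recomb_rate=0.0, seed=3)
    sim = simulate_strains(cfg)
    for strain, genes in sim.strains.items():
        assert genes == sim.reference
    assert all(not v for v in sim.truth.snps.values())
    assert sim.truth.tracts == []


def test_degenerate_tree_rejected():
    with pytest.raises(ValueError):
        simulate_strains(SimConfig(n_genes=2, strain_tree=";"))


def test_divergence_matches_jukes_cantor_expectation():
    # branch 0.05 from the root: observed p should match the JC forward map
    cfg = SimConfig(n_genes=200, gene_len_dist=(300, 300, 300),
                    strain_tree="(X:0.05);", seed=5)
    sim = simulate_strains(cfg)
    mism = total = 0
    for gene, ref in sim.reference.items():
        m, n = _pairwise_diff(ref, sim.strains["X"][gene])
        mism, total = mism + m, total + n
    p_obs = mism / total
    p_exp = 0.75 * (1 - math.exp(-4 * 0.05 / 3))
    se = math.sqrt(p_exp * (1 - p_exp) / total)
    assert abs(p_obs - p_exp) < 3 * se


@pytest.mark.parametrize("branch", [0.02, 0.08, 0.15])
def test_truth_snp_density_recovers_branch_under_jc(branch):
    cfg = SimConfig(n_genes=150, gene_len_dist=(400, 400, 400),
                    strain_tree=f"(X:{branch});", seed=17)
    sim = simulate_strains(cfg)
    total = sum(len(s) for s in sim.reference.values())
    p_obs = len(sim.truth.snps["X"]) / total
    d_hat = -0.75 * math.log(1 - 4 * p_obs / 3)
    se_p = math.sqrt(p_obs * (1 - p_obs) / total)
    # delta method on the JC inverse map
    se_d = se_p / (1 - 4 * p_obs / 3)
    assert abs(d_hat - branch) < 3 * se_d


def test_tstv_ratio_recovered_within_binomial_error():
    # short branch keeps multiple hits per site negligible, so observed
    # SNP ts/tv reflects the per-event bias
    cfg = SimConfig(n_genes=100, gene_len_dist=(5000, 5000, 5000),
                    strain_tree="(X:0.01);", tstv_ratio=2.0, seed=9)
    sim = simulate_strains(cfg)
    ts_pairs = {frozenset("AG"), frozenset("CT")}
    ts = sum(frozenset((a, d)) in ts_pairs
             for _, _, a, d in sim.truth.snps["X"])
    n = len(sim.truth.snps["X"])
    assert n > 5000
    # each substitution is a transition w.p. 2/3 under kappa=2
    p_hat = ts / n
    se = math.sqrt((2 / 3) * (1 / 3) / n)
    assert abs(p_hat - 2 / 3) < 3 * se


def test_truth_snps_lie_within_their_genes(small_sim):
    lengths = small_sim.gene_lengths
    for rows in small_sim.truth.snps.values():
        for gene, pos, anc, der in rows:
            assert 1 <= pos <= lengths[gene]
            assert anc != der


def test_identical_seeds_are_byte_identical():
    a = simulate_strains(SimConfig(n_genes=10, recomb_rate=1.0, seed=21))
    b = simulate_strains(SimConfig(n_genes=10, recomb_rate=1.0, seed=21))
    assert a.reference == b.reference
    assert a.strains == b.strains
    assert a.truth.snps == b.truth.snps
    assert a.truth.tracts == b.truth.tracts


def test_recomb_tracts_recorded_and_in_bounds():
    cfg = SimConfig(n_genes=30, recomb_rate=3.0, seed=2)
    sim = simulate_strains(cfg)
    assert sim.truth.tracts, "expected at least one tract at rate 3"
    for donor, recip, gene, start, end in sim.truth.tracts:
        assert donor != recip
        assert 1 <= start < end <= sim.gene_lengths[gene]
    # recipients carry the donor-lineage haplotype over the tract; only a
    # second tract hitting the same region may overwrite it
    def touched(strain, gene, start, end, skip):
        return any((r2 == strain and g2 == gene and s2 <= end and e2 >= start
                    and (r2, g2, s2, e2) != skip)
                   for _, r2, g2, s2, e2 in sim.truth.tracts)

    # same seed without recombination reproduces the pre-tract lineages
    pre = simulate_strains(SimConfig(n_genes=30, recomb_rate=0.0, seed=2))
    verified = 0
    for donor, recip, gene, start, end in sim.truth.tracts:
        if touched(recip, gene, start, end, (recip, gene, start, end)):
            continue
        assert sim.strains[recip][gene][start - 1:end] == \
            pre.strains[donor][gene][start - 1:end]
        verified += 1
    assert verified >= 1


# ---- reads -----------------------------------------------------------------

def test_high_quality_reads_have_no_errors():
    cfg = SimConfig(n_genes=1, gene_len_dist=(5000, 5000, 5000),
                    strain_tree="(X:0.0);", coverage=30.0, read_len=500,
                    error_profile=ErrorProfile(kind="constant", q_peak=90),
                    seed=4)
    sim = simulate_strains(cfg)
    genome = sim.genome("X")
    reads = shred_to_reads(genome, cfg, seed=8)
    checked = 0
    for r in reads:
        src = genome[r.meta["replicon"]]
        truth = src[r.meta["start"]:r.meta["start"] + len(r)]
        assert r.seq == truth
        checked += len(r)
    assert checked > 1e5


def test_read_count_tracks_coverage():
    cfg = SimConfig(n_genes=1, gene_len_dist=(100, 100, 100),
                    strain_tree="(X:0.0);", coverage=1.0, read_len=1000, seed=4)
    genome = "A" * 1_000_000
    reads = shred_to_reads(genome, cfg, seed=12)
    expected = 1000
    assert abs(len(reads) - expected) < 4 * math.sqrt(expected)


def test_q20_error_rate_is_one_percent():
    cfg = SimConfig(n_genes=1, gene_len_dist=(100, 100, 100),
                    strain_tree="(X:0.0);", coverage=1.0, read_len=1000,
                    error_profile=ErrorProfile(kind="constant", q_peak=20),
                    seed=4)
    genome = {"chr": "ACGT" * 50_000}
    reads = shred_to_reads(genome, cfg, seed=13)
    errors = bases = 0
    for r in reads:
        truth = genome["chr"][r.meta["start"]:r.meta["start"] + len(r)]
        errors += sum(x != y for x, y in zip(r.seq, truth))
        bases += len(r)
    assert bases > 1e5
    p_hat = errors / bases
    se = math.sqrt(0.01 * 0.99 / bases)
    assert abs(p_hat - 0.01) < 4 * se


def test_coverage_zero_rejected():
    with pytest.raises(ValueError):
        SimConfig(coverage=0.0)


# ---- naive assembly --------------------------------------------------------

def _read(seq, start, q=40, rid="r"):
    return QualSeq(rid, seq, np.full(len(seq), q),
                   meta={"replicon": "chr", "start": start})


def test_assembly_merges_overlap():
    a = _read("A" * 500, 0, rid="r1")
    b = _read("A" * 500, 300, rid="r2")
    (contig,) = assemble_naive([a, b])
    assert len(contig) == 800


def test_assembly_disjoint_reads_pass_through():
    reads = [_read("ACGT" * 10, 0, rid="r1"), _read("ACGT" * 10, 100, rid="r2")]
    contigs = assemble_naive(reads)
    assert sorted(len(c) for c in contigs) == [40, 40]
    assert sorted(c.seq for c in contigs) == sorted(r.seq for r in reads)


def test_assembly_conflict_resolved_by_quality():
    lo = _read("AATA", 0, q=20, rid="lo")   # claims T at position 2
    hi = _read("GA", 2, q=50, rid="hi")     # claims G at position 2
    (contig,) = assemble_naive([lo, hi])
    assert contig.seq == "AAGA"
    assert contig.quals[2] == 50  # max of contributing qualities


def test_quartet_generator_tracts_copy_donor():
    segs, tracts = simulate_quartet_segments(3, tract_len=400, seed=6)
    assert len(tracts) == 3
    for (i, start, end), seg in zip(tracts, segs):
        a, c = seg.row("A"), seg.row("C")
        assert a[start - 1:end] == c[start - 1:end]
        assert end - start + 1 == 400
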