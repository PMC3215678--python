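"""Ortholog mapping: alignment gates, RBH injectivity, block filtering,
quartet and shared-segment assembly."""

import numpy as np
import pytest

from strainvar.orthomap import (OrthologAlignment, SegmentMatrix,
                                align_fragments, build_quartets,
                                filter_blocks, rbh_filter, shared_segments)
from strainvar.seqio import QualSeq, reverse_complement
from strainvar.simulate import GeneInfo


def _contig(seq, cid="c1", q=60):
    return QualSeq(cid, seq, np.full(len(seq), q))


def _rand_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def _mutated(rng, seq, frac):
    out = list(seq)
    idx = rng.choice(len(seq), size=int(frac * len(seq)), replace=False)
    for i in idx:
        out[i] = rng.choice([b for b in "ACGT" if b != seq[i]])
    return "".join(out)


def test_exact_match_gives_full_identity_and_coverage(rng):
    gene = _rand_seq(rng, 400)
    (aln,) = align_fragments([_contig(gene)], {"g1": gene})
    assert aln.identity == 100.0
    assert aln.coverage == 100.0
    assert (aln.r_start, aln.r_end) == (1, 400)
    assert aln.strand == "+"


def test_heavily_diverged_query_yields_no_candidate(rng):
    gene = _rand_seq(rng, 400)
    bad = _mutated(rng, gene, 0.30)
    assert align_fragments([_contig(bad)], {"g1": gene}) == []


def test_reverse_strand_hit_is_flagged(rng):
    gene = _rand_seq(rng, 400)
    (aln,) = align_fragments([_contig(reverse_complement(gene))], {"g1": gene})
    assert aln.strand == "-"
    assert aln.identity == 100.0


def test_simulated_divergence_reflected_in_identity(star_sim):
    sim = star_sim
    ref = sim.strains["A"]
    contigs = [QualSeq(f"B_{g}", s, np.full(len(s), 60))
               for g, s in sim.strains["B"].items()]
    alns = rbh_filter(align_fragments(contigs, ref))
    assert len(alns) > 40
    med = np.median([a.identity for a in alns])
    # two tips at 5%: ~10% divergence, minus multiple hits
    assert 89 < med < 93


def _fake(query, gene, identity=95.0, coverage=90.0, score=100.0,
          q_start=1, q_end=100):
    n = 100
    return OrthologAlignment(
        query_id=query, gene_id=gene, q_start=q_start, q_end=q_end,
        r_start=1, r_end=n, strand="+", qcols="A" * n, rcols="A" * n,
        qquals=np.full(n, 60), rpos=np.arange(1, n + 1),
        identity=identity, coverage=coverage, score=score)


def test_rbh_keeps_best_paralog_copy():
    cands = [_fake("c1", "geneA", identity=99.0, score=95.0),
             _fake("c1", "geneB", identity=90.0, score=80.0)]
    kept = rbh_filter(cands)
    assert [a.gene_id for a in kept] == ["geneA"]


def test_rbh_coverage_gate_is_strict():
    assert rbh_filter([_fake("c1", "g", coverage=59.9)]) == []
    assert rbh_filter([_fake("c1", "g", coverage=60.1)]) != []


def test_rbh_identity_gate():
    assert rbh_filter([_fake("c1", "g", identity=84.0)]) == []
    assert rbh_filter([_fake("c1", "g", identity=85.0)]) != []


def test_rbh_is_partial_injection(star_sim):
    sim = star_sim
    ref = sim.strains["A"]
    contigs = [QualSeq(f"B_{g}", s, np.full(len(s), 60))
               for g, s in sim.strains["B"].items()]
    kept = rbh_filter(align_fragments(contigs, ref))
    genes = [a.gene_id for a in kept]
    frags = [(a.query_id, a.q_start // 50) for a in kept]
    assert len(genes) == len(set(genes))
    assert len(frags) == len(set(frags))


def test_rbh_monotone_in_thresholds():
    cands = [_fake(f"c{i}", f"g{i}", identity=85 + i, coverage=61 + i)
             for i in range(10)]
    loose = {(a.query_id, a.gene_id) for a in rbh_filter(cands)}
    tight = {(a.query_id, a.gene_id)
             for a in rbh_filter(cands, min_identity=90, min_coverage=65)}
    assert tight <= loose


# ---- gap-block filtering ---------------------------------------------------

def test_filter_blocks_identity_on_gapfree():
    m = SegmentMatrix("s", ["a", "b"], ["ACGTACGTACGTACG", "ACGTACGTACGTACG"])
    assert filter_blocks(m).rows == m.rows


def test_filter_blocks_removes_gap_run_and_short_flanks():
    left = "ACGTA"              # 5 cols: flank < B, removed
    gap = "-" * 30
    right = "ACGTACGTACGT"      # 12 cols: kept
    a = left + gap + right
    b = left + "ACGT" * 7 + "AC" + right
    m = filter_blocks(SegmentMatrix("s", ["a", "b"], [a, b]))
    assert m.length == 12
    assert m.rows[0] == right


def test_filter_blocks_output_gap_free(rng):
    n = 400
    rows = []
    for _ in range(4):
        row = list(_rand_seq(rng, n))
        for i in rng.choice(n, size=20, replace=False):
            row[i] = "-"
        rows.append("".join(row))
    out = filter_blocks(SegmentMatrix("s", list("abcd"), rows))
    assert all("-" not in r for r in out.rows)


# ---- quartets & shared segments -------------------------------------------

def _aln_for(gene_id, seq, r_start=1, strain=""):
    n = len(seq)
    return OrthologAlignment(
        query_id=f"{strain}_{gene_id}", gene_id=gene_id,
        q_start=1, q_end=n, r_start=r_start, r_end=r_start + n - 1,
        strand="+", qcols=seq, rcols=seq, qquals=np.full(n, 60),
        rpos=np.arange(r_start, r_start + n), identity=99.0,
        coverage=99.0, score=float(n), strain=strain)


def test_quartet_requires_outgroup_presence(rng):
    gene = _rand_seq(rng, 300)
    genes = {"g1": gene}
    d = [_aln_for("g1", gene, strain="d")]
    b = [_aln_for("g1", gene, strain="b")]
    assert build_quartets(d, b, [], genes) == []
    quartets = build_quartets(d, b, [_aln_for("g1", gene, strain="o")], genes)
    assert len(quartets) == 1
    assert quartets[0].ids == ["draft", "ref_a", "ref_b", "outgroup"]
    assert quartets[0].length == 300


def test_quartet_minimum_length_enforced(rng):
    gene = _rand_seq(rng, 150)
    genes = {"g1": gene}
    mk = lambda s: [_aln_for("g1", gene, strain=s)]
    assert build_quartets(mk("d"), mk("b"), mk("o"), genes) == []


def test_shared_segments_drop_gene_missing_in_one_strain(rng):
    g1, g2 = _rand_seq(rng, 300), _rand_seq(rng, 300)
    genes = {"g1": g1, "g2": g2}
    order = [GeneInfo("g1", "chromosome", 1, 300),
             GeneInfo("g2", "chromosome", 301, 600)]
    alns = {
        "s1": [_aln_for("g1", g1, strain="s1"), _aln_for("g2", g2, strain="s1")],
        "s2": [_aln_for("g1", g1, strain="s2")],   # g2 missing
    }
    segs, concat, manifest = shared_segments(alns, genes, order)
    assert [m["gene"] for m in manifest] == ["g1"]
    assert concat.length == 300
    assert concat.length == sum(s.length for s in segs)


def test_shared_segments_concatenation_conserves_length_and_order(star_sim):
    sim = star_sim
    ref = sim.strains["A"]
    alns = {}
    for s in ["B", "C", "D"]:
        contigs = [QualSeq(f"{s}_{g}", seq, np.full(len(seq), 60))
                   for g, seq in sim.strains[s].items()]
        alns[s] = rbh_filter(align_fragments(contigs, ref, strain=s))
    segs, concat, manifest = shared_segments(alns, ref, sim.gene_order,
                                             ref_name="A")
    assert segs
    assert concat.length == sum(s.length for s in segs)
    starts = [m["global_start"] for m in manifest]
    assert starts == sorted(starts)
    chrom_done = False
    for m in manifest:
        if m["location"] == "plasmid":
            chrom_done = True
        elif chrom_done:
            pytest.fail("chromosome segment after plasmid segment")
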