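"""Detector statistics, permutation nulls, consensus rule, attribution
and event clustering."""

import numpy as np
import pytest

from strainvar.orthomap import SegmentMatrix
from strainvar.recomb import (DetectorResult, consensus_call,
                              event_matrix_cluster, geneconv_like,
                              informative_columns, maxchi_test, nss_test,
                              pair_attribution_summary, phi_test,
                              recombinant_fraction, site_incompatibility,
                              analyze_segment)
from strainvar.simulate import simulate_quartet_segments


def _mat(rows: dict[str, str]) -> SegmentMatrix:
    return SegmentMatrix("m", list(rows), list(rows.values()))


def _arr(cols: list[str]) -> np.ndarray:
    rows = ["".join(c[i] for c in cols) for i in range(len(cols[0]))]
    return np.array([np.frombuffer(r.encode(), dtype=np.uint8) for r in rows])


# ---- incompatibility primitive --------------------------------------------

def test_incompatibility_all_four_gametes():
    # joint states AA, AG, GA, GG: one extra mutation required
    arr = np.array([np.frombuffer(r.encode(), dtype=np.uint8)
                    for r in ["AA", "AG", "GA", "GG"]])
    assert site_incompatibility(arr, 0, 1) == 1


def test_incompatibility_compatible_sites():
    arr = np.array([np.frombuffer(r.encode(), dtype=np.uint8)
                    for r in ["AA", "AA", "GG", "GG"]])
    assert site_incompatibility(arr, 0, 1) == 0


def test_informative_columns_definition():
    # AABB is informative; AAAB (singleton) is not
    arr = np.array([np.frombuffer(r.encode(), dtype=np.uint8)
                    for r in ["AA", "AA", "GA", "GG"]])
    assert informative_columns(arr).tolist() == [0]


# ---- PHI -------------------------------------------------------------------

def _compatible_quartet():
    # two clean informative sites, same bipartition -> fully compatible
    return _mat({"a": "AAGAAAAGAA", "b": "AAGAAAAGAA",
                 "c": "AACAAAACAA", "d": "AACAAAACAA"})


def test_phi_compatible_sites_give_zero_statistic_p_one():
    res = phi_test(_compatible_quartet(), permutations=200, seed=1)
    assert res.statistic == 0.0
    assert res.p_value == 1.0


def test_phi_permutations_zero_gives_statistic_only():
    res = phi_test(_compatible_quartet(), permutations=0)
    assert res.statistic == 0.0
    assert res.p_value is None


def test_phi_not_evaluable_cases():
    res = phi_test(_mat({"a": "AAAA", "b": "AAAA", "c": "AAAA", "d": "AAAA"}))
    assert not res.evaluable
    res3 = phi_test(_mat({"a": "AG", "b": "AG", "c": "GA"}))
    assert not res3.evaluable  # <4 sequences


def test_phi_detects_implanted_tract():
    segs, _ = simulate_quartet_segments(8, tract_len=500, seed=21)
    hits = sum(phi_test(s, permutations=500, seed=i).p_value < 0.05
               for i, s in enumerate(segs))
    assert hits >= 6


# ---- MaxChi ----------------------------------------------------------------

def test_maxchi_closed_form_breakpoint():
    """Pair differing only right of the midpoint: 100 polymorphic
    columns, 20 mismatches all in the right 50."""
    rng = np.random.default_rng(5)
    n = 100
    s1 = ["A"] * n
    s2 = ["A"] * n
    diff_pos = sorted(rng.choice(np.arange(50, 100), size=20, replace=False))
    for p in diff_pos:
        s1[p] = "G"
    # make every column polymorphic via a divergent pair whose own
    # differences are uniformly interleaved (low chi-squared)
    s3 = [("C" if i % 2 else "T") for i in range(n)]
    s4 = ["C"] * n
    m = _mat({"s1": "".join(s1), "s2": "".join(s2),
              "s3": "".join(s3), "s4": "".join(s4)})
    res = maxchi_test(m, permutations=300, seed=2)
    # brute-force oracle over all breakpoints of the s1/s2 vector
    v = np.array([1.0 if p in diff_pos else 0.0 for p in range(n)])
    best = 0.0
    for k in range(1, n):
        b = v[:k].sum(); d = v[k:].sum()
        a = k - b; c = (n - k) - d
        denom = k * (n - k) * (n - v.sum()) * v.sum()
        chi = n * (a * d - b * c) ** 2 / denom
        best = max(best, chi)
    assert res.statistic == pytest.approx(best)
    assert res.pair == ("s1", "s2")
    # optimum split is just before the first mismatch; both flanks of the
    # mismatch-free region give the same table, argmax returns the first
    assert res.breakpoints[0] <= diff_pos[0] + 1
    assert res.statistic == pytest.approx(
        n * (50 * 20) ** 2 / (50 * 50 * 80 * 20))
    assert res.p_value < 0.05


def test_maxchi_interleaved_differences_not_significant():
    s1 = "".join("AG"[i % 2] for i in range(60))
    s2 = "A" * 60
    s3 = "".join("CT"[(i // 1) % 2] for i in range(60))
    m = _mat({"s1": s1, "s2": s2, "s3": s3})
    res = maxchi_test(m, permutations=300, seed=3)
    assert res.p_value > 0.2


def test_maxchi_identical_sequences_not_evaluable():
    res = maxchi_test(_mat({"a": "ACGT", "b": "ACGT"}))
    assert not res.evaluable


# ---- NSS -------------------------------------------------------------------

def test_nss_all_compatible_is_one_p_one():
    res = nss_test(_compatible_quartet(), permutations=200, seed=4)
    assert res.statistic == 1.0
    assert res.p_value == 1.0


def test_nss_two_blocks_elevate_statistic():
    # block 1: three AABB sites; block 2: three ABAB sites (incompatible
    # across blocks, compatible within)
    cols = ["AAGG"] * 3 + ["AGAG"] * 3
    rows = {"t1": "", "t2": "", "t3": "", "t4": ""}
    names = list(rows)
    for c in cols:
        for i, n in enumerate(names):
            rows[n] += c[i]
    m = _mat(rows)
    res = nss_test(m, permutations=400, seed=5)
    assert res.statistic == pytest.approx(4 / 5)
    # permutation mean is below the observed blocked arrangement
    assert res.p_value < 0.2


def test_nss_single_informative_site_not_evaluable():
    m = _mat({"a": "AG", "b": "AG", "c": "AA", "d": "AA"})
    assert not nss_test(m).evaluable


# ---- GENECONV-like ---------------------------------------------------------

def test_geneconv_identical_pair_not_evaluable():
    res = geneconv_like(_mat({"a": "ACGT", "b": "ACGT"}))
    assert not res.evaluable


def test_geneconv_finds_implanted_tract():
    segs, tracts = simulate_quartet_segments(6, tract_len=500, seed=31)
    found = 0
    for (i, start, end), seg in zip(tracts, segs):
        res = geneconv_like(seg, permutations=500, seed=i)
        if res.p_value < 0.05:
            lo, hi = res.fragment
            overlap = max(0, min(hi, end) - max(lo, start))
            if overlap > 0:
                found += 1
    assert found >= 5


def test_geneconv_pair_names_donor_recipient():
    segs, _ = simulate_quartet_segments(4, tract_len=600, seed=41)
    pairs = [geneconv_like(s, permutations=200, seed=9).pair for s in segs]
    assert ("A", "C") in pairs  # tract copied C -> A


# ---- consensus & summaries -------------------------------------------------

def _dr(name, p):
    return DetectorResult(name, statistic=1.0, p_value=p, permutations=100)


def test_consensus_one_significant_is_not_enough():
    rec = consensus_call([_dr("PHI", 0.01), _dr("MAXCHI", 0.20),
                          _dr("NSS", 0.60), _dr("GENECONV", 0.70)], "s")
    assert rec.verdict is False


def test_consensus_two_significant_suffice():
    rec = consensus_call([_dr("PHI", 0.01), _dr("MAXCHI", 0.04),
                          _dr("NSS", 0.60), _dr("GENECONV", 0.70)], "s")
    assert rec.verdict is True
    assert rec.supporting == ["MAXCHI", "PHI"]


def test_consensus_not_evaluable_detectors_excluded():
    ne = DetectorResult("PHI", evaluable=False)
    rec = consensus_call([ne, _dr("MAXCHI", 0.01), _dr("NSS", 0.01)], "s")
    assert rec.verdict is True
    rec2 = consensus_call([DetectorResult(d, evaluable=False)
                           for d in ("PHI", "MAXCHI", "NSS", "GENECONV")], "s")
    assert rec2.verdict is None


def test_recombinant_fraction_reporting():
    records = []
    for i in range(2781):
        verdict = i < 123
        sup = ["MAXCHI", "PHI"] if verdict else []
        records.append(
            __import__("strainvar.recomb", fromlist=["RecombinationRecord"])
            .RecombinationRecord(f"q{i}", {}, verdict, sup, [("a", "b")]))
    hits, tested, pct = recombinant_fraction(records)
    assert (hits, tested) == (123, 2781)
    assert pct == pytest.approx(4.42, abs=0.005)


def test_pair_attribution_sums_to_100():
    from strainvar.recomb import RecombinationRecord
    recs = [RecombinationRecord(f"s{i}", {}, True, ["PHI", "NSS"],
                                [("a", "b") if i % 3 else ("a", "c")])
            for i in range(9)]
    summ = pair_attribution_summary(recs)
    assert sum(summ.values()) == pytest.approx(100.0)
    assert summ[("a", "b")] == pytest.approx(100 * 6 / 9)
    assert pair_attribution_summary([]) == {}


def test_event_clustering_groups_sharing_strains():
    verdicts = {
        "s1": {f"g{i}": True for i in range(6)},
        "s2": {f"g{i}": True for i in range(6)},
        "s3": {f"g{i}": False for i in range(6)},
    }
    out = event_matrix_cluster(verdicts)
    assert out.matrix.shape == (6, 3)
    # s1 and s2 join first: they appear as a cherry in the newick
    assert "(s1:0,s2:0)" in out.newick.replace(" ", "")


def test_event_clustering_all_zero_matrix_flat():
    verdicts = {"s1": {"g1": False}, "s2": {"g1": False}, "s3": {"g1": False}}
    out = event_matrix_cluster(verdicts)
    assert out.matrix.sum() == 0
    assert out.newick.count("(") >= 1  # emitted, flat distances


def test_seeded_pvalues_reproducible_and_never_zero():
    segs, _ = simulate_quartet_segments(2, tract_len=500, seed=51)
    for seg in segs:
        r1 = analyze_segment(seg, permutations=300, seed=99)
        r2 = analyze_segment(seg, permutations=300, seed=99)
        for name in r1.detectors:
            p1 = r1.detectors[name].p_value
            p2 = r2.detectors[name].p_value
            assert p1 == p2
            if p1 is not None:
                assert p1 > 0.0
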