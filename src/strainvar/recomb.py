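"""Recombination detection on shared-segment matrices.

Four complementary detectors are run per segment, each with a seeded
permutation null and an add-one-corrected p-value p = (b + 1)/(n + 1):

* PHI  — mean refined incompatibility of parsimony-informative site
  pairs lying within a window of each other; recombination makes nearby
  sites *more* compatible than distant ones, so low observed values are
  significant (permutation tail: Φ_perm ≤ Φ_obs).
* MAXCHI — per sequence pair, the maximal 2×2 χ² of match/mismatch
  counts left vs right of a candidate breakpoint over polymorphic
  columns; also yields a breakpoint estimate and the maximising pair.
* NSS — mean compatibility of *adjacent* informative-site pairs;
  recombination blocks elevate it (tail: NSS_perm ≥ NSS_obs).
* GENECONV-like — the highest-scoring run of consecutive matches
  between any sequence pair over polymorphic columns (match +1,
  mismatch −(1−m)/m for pairwise mismatch rate m), flagging unusually
  long identical inner fragments; yields the fragment interval.

A segment is called recombinant only when at least ``quorum`` (default
2) detectors reject at α — the multi-method consensus rule.  Detectors
that cannot be evaluated (too little signal) never count toward the
quorum, and the quorum itself is not reduced.

Incompatibility between two sites is the minimum number of extra
mutations any tree must invoke, computed as the cycle rank E − V + C of
the bipartite state-intersection graph (vertices: observed states at
each site; edges: observed joint states).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .orthomap import SegmentMatrix

DNA_CODES = frozenset(b"ACGT")

DETECTORS = ("PHI", "MAXCHI", "NSS", "GENECONV")


@dataclass
class DetectorResult:
    detector: str
    statistic: float = float("nan")
    p_value: float | None = None
    permutations: int = 0
    breakpoints: list[int] = field(default_factory=list)
    fragment: tuple[int, int] | None = None     # 1-based columns (GENECONV)
    pair: tuple[str, str] | None = None
    evaluable: bool = True
    note: str = ""

    def __post_init__(self) -> None:
        if self.p_value is not None and not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")

    def significant(self, alpha: float) -> bool:
        return (self.evaluable and self.p_value is not None
                and self.p_value < alpha)


@dataclass
class RecombinationRecord:
    segment_id: str
    detectors: dict[str, DetectorResult]
    verdict: bool | None        # None = untested (no evaluable detector)
    supporting: list[str]
    attributed_pairs: list[tuple[str, str]]

    def __post_init__(self) -> None:
        if self.verdict and len(self.supporting) < 2:
            raise ValueError("positive verdict requires >=2 supporting detectors")


def _as_array(matrix: SegmentMatrix) -> np.ndarray:
    return np.array([np.frombuffer(r.encode(), dtype=np.uint8)
                     for r in matrix.rows])


def _called(arr: np.ndarray) -> np.ndarray:
    mask = np.zeros(arr.shape, dtype=bool)
    for b in DNA_CODES:
        mask |= arr == b
    return mask


def polymorphic_columns(arr: np.ndarray) -> np.ndarray:
    called = _called(arr)
    out = []
    for j in range(arr.shape[1]):
        vals = arr[called[:, j], j]
        if np.unique(vals).size >= 2:
            out.append(j)
    return np.asarray(out, dtype=np.int64)


def informative_columns(arr: np.ndarray) -> np.ndarray:
    """Parsimony-informative columns: ≥2 alleles each in ≥2 sequences."""
    called = _called(arr)
    out = []
    for j in range(arr.shape[1]):
        vals, counts = np.unique(arr[called[:, j], j], return_counts=True)
        if np.sum(counts >= 2) >= 2:
            out.append(j)
    return np.asarray(out, dtype=np.int64)


def site_incompatibility(arr: np.ndarray, i: int, j: int) -> int:
    """Minimum extra mutations required to fit sites i and j on one tree."""
    called = _called(arr)
    rows = called[:, i] & called[:, j]
    a, b = arr[rows, i], arr[rows, j]
    if a.size == 0:
        return 0
    pairs = {(x, y) for x, y in zip(a.tolist(), b.tolist())}
    sa = {x for x, _ in pairs}
    sb = {y for _, y in pairs}
    parent = {("a", x): ("a", x) for x in sa} | {("b", y): ("b", y) for y in sb}

    def find(u):
        while parent[u] != u:
            parent[u] = parent[parent[u]]
            u = parent[u]
        return u

    comps = len(parent)
    for x, y in pairs:
        ru, rv = find(("a", x)), find(("b", y))
        if ru != rv:
            parent[ru] = rv
            comps -= 1
    extra = len(pairs) - (len(sa) + len(sb)) + comps
    return max(int(extra), 0)


def _incompat_matrix(arr: np.ndarray, cols: np.ndarray) -> np.ndarray:
    k = cols.size
    m = np.zeros((k, k))
    for a in range(k):
        for b in range(a + 1, k):
            v = site_incompatibility(arr, int(cols[a]), int(cols[b]))
            m[a, b] = m[b, a] = v
    return m


def _pvalue(count_as_extreme: int, permutations: int) -> float:
    return (count_as_extreme + 1) / (permutations + 1)


def _perm_indices(rng: np.random.Generator, n_perm: int, m: int) -> np.ndarray:
    return rng.permuted(np.tile(np.arange(m), (n_perm, 1)), axis=1)


def phi_test(matrix: SegmentMatrix, window: int = 25,
             permutations: int = 1000, seed: int = 0) -> DetectorResult:
    """Pairwise homoplasy index restricted to nearby informative sites."""
    arr = _as_array(matrix)
    if arr.shape[0] < 4:
        return DetectorResult("PHI", evaluable=False, note="<4 sequences")
    cols = informative_columns(arr)
    if cols.size < 2:
        return DetectorResult("PHI", evaluable=False,
                              note="<2 informative sites")
    m = _incompat_matrix(arr, cols)
    ia, ja = np.triu_indices(cols.size, k=1)
    near = (cols[ja] - cols[ia]) <= window
    ia, ja = ia[near], ja[near]
    if ia.size == 0:
        return DetectorResult("PHI", evaluable=False,
                              note="no informative pairs within window")
    phi_obs = float(m[ia, ja].mean())
    if permutations <= 0:
        return DetectorResult("PHI", statistic=phi_obs)
    rng = np.random.default_rng(seed)
    perms = _perm_indices(rng, permutations, cols.size)
    vals = m[perms[:, ia], perms[:, ja]].mean(axis=1)
    p = _pvalue(int(np.sum(vals <= phi_obs + 1e-12)), permutations)
    return DetectorResult("PHI", statistic=phi_obs, p_value=p,
                          permutations=permutations)


def _pair_diff_vectors(arr: np.ndarray, cols: np.ndarray, ids: list[str]):
    """Per sequence pair: (pair ids, columns used, mismatch 0/1 vector)."""
    called = _called(arr)
    for r, s in combinations(range(arr.shape[0]), 2):
        use = called[r, cols] & called[s, cols]
        sub = cols[use]
        if sub.size == 0:
            continue
        v = (arr[r, sub] != arr[s, sub]).astype(np.float64)
        yield (ids[r], ids[s]), sub, v


def maxchi_test(matrix: SegmentMatrix, permutations: int = 1000,
                seed: int = 0) -> DetectorResult:
    """Maximum χ² breakpoint scan over all sequence pairs."""
    arr = _as_array(matrix)
    cols = polymorphic_columns(arr)
    if cols.size < 2:
        return DetectorResult("MAXCHI", evaluable=False,
                              note="<2 polymorphic columns")

    def chi_profile(cum: np.ndarray, m: int, d: float) -> np.ndarray:
        # margins are fixed: left size k, right m−k, matches m−d, mismatches d
        k = np.arange(1, m)
        length = cum[..., :-1] if cum.ndim > 1 else cum[:-1]
        a = k - length          # left matches
        b = length              # left mismatches
        dd = d - length         # right mismatches
        c = (m - k) - dd        # right matches
        denom = k * (m - k) * (m - d) * d
        with np.errstate(invalid="ignore", divide="ignore"):
            chi = m * (a * dd - b * c) ** 2 / denom
        return np.nan_to_num(chi)

    best = -1.0
    best_pair = None
    best_break = None
    pair_data = []
    for pair, sub, v in _pair_diff_vectors(arr, cols, matrix.ids):
        m = v.size
        d = float(v.sum())
        if m < 2 or d == 0 or d == m:
            continue
        pair_data.append((pair, sub, v))
        chi = chi_profile(np.cumsum(v), m, d)
        k_best = int(np.argmax(chi))
        if chi[k_best] > best:
            best = float(chi[k_best])
            best_pair = pair
            best_break = int(sub[k_best]) + 1   # boundary after this column
    if not pair_data:
        return DetectorResult("MAXCHI", evaluable=False,
                              note="no divergent sequence pair")
    if permutations <= 0:
        return DetectorResult("MAXCHI", statistic=best, pair=best_pair,
                              breakpoints=[best_break])
    rng = np.random.default_rng(seed)
    perm_max = np.zeros(permutations)
    for pair, sub, v in pair_data:
        m = v.size
        d = float(v.sum())
        perms = _perm_indices(rng, permutations, m)
        cums = np.cumsum(v[perms], axis=1)
        chi = chi_profile(cums, m, d).max(axis=1)
        perm_max = np.maximum(perm_max, chi)
    p = _pvalue(int(np.sum(perm_max >= best - 1e-12)), permutations)
    return DetectorResult("MAXCHI", statistic=best, p_value=p,
                          permutations=permutations, pair=best_pair,
                          breakpoints=[best_break])


def nss_test(matrix: SegmentMatrix, permutations: int = 1000,
             seed: int = 0) -> DetectorResult:
    """Neighbor similarity score: compatibility of adjacent informative sites."""
    arr = _as_array(matrix)
    cols = informative_columns(arr)
    if cols.size < 2:
        return DetectorResult("NSS", evaluable=False,
                              note="<2 informative sites")
    compat = (_incompat_matrix(arr, cols) == 0).astype(np.float64)
    idx = np.arange(cols.size)
    nss_obs = float(compat[idx[:-1], idx[1:]].mean())
    if permutations <= 0:
        return DetectorResult("NSS", statistic=nss_obs)
    rng = np.random.default_rng(seed)
    perms = _perm_indices(rng, permutations, cols.size)
    vals = compat[perms[:, :-1], perms[:, 1:]].mean(axis=1)
    p = _pvalue(int(np.sum(vals >= nss_obs - 1e-12)), permutations)
    return DetectorResult("NSS", statistic=nss_obs, p_value=p,
                          permutations=permutations)


def geneconv_like(matrix: SegmentMatrix, permutations: int = 1000,
                  seed: int = 0) -> DetectorResult:
    """Inner-fragment scan: longest high-identity run between any pair."""
    arr = _as_array(matrix)
    cols = polymorphic_columns(arr)
    if cols.size < 2:
        return DetectorResult("GENECONV", evaluable=False,
                              note="<2 polymorphic columns")
    pair_data = []
    best = -np.inf
    best_pair = None
    best_frag = None
    for pair, sub, v in _pair_diff_vectors(arr, cols, matrix.ids):
        d = float(v.sum())
        if d == 0 or v.size < 2:
            continue
        mismatch_rate = d / v.size
        penalty = (1 - mismatch_rate) / mismatch_rate
        scores = np.where(v > 0, -penalty, 1.0)
        pair_data.append((pair, sub, scores))
        # Kadane with interval tracking
        run = 0.0
        run_start = 0
        top = -np.inf
        frag = (0, 0)
        for j, sc in enumerate(scores):
            if run + sc < sc:
                run = sc
                run_start = j
            else:
                run += sc
            if run > top:
                top = run
                frag = (run_start, j)
        if top > best:
            best = float(top)
            best_pair = pair
            best_frag = (int(sub[frag[0]]) + 1, int(sub[frag[1]]) + 1)
    if not pair_data:
        return DetectorResult("GENECONV", evaluable=False,
                              note="no divergent sequence pair")
    if permutations <= 0:
        return DetectorResult("GENECONV", statistic=best, pair=best_pair,
                              fragment=best_frag)
    rng = np.random.default_rng(seed)
    perm_max = np.full(permutations, -np.inf)
    for pair, sub, scores in pair_data:
        perms = _perm_indices(rng, permutations, scores.size)
        shuffled = scores[perms]
        run = np.full(permutations, -np.inf)
        top = np.full(permutations, -np.inf)
        for j in range(scores.size):
            col = shuffled[:, j]
            run = np.where(run + col < col, col, run + col)
            top = np.maximum(top, run)
        perm_max = np.maximum(perm_max, top)
    p = _pvalue(int(np.sum(perm_max >= best - 1e-12)), permutations)
    return DetectorResult("GENECONV", statistic=best, p_value=p,
                          permutations=permutations, pair=best_pair,
                          fragment=best_frag)


def consensus_call(
    results: list[DetectorResult], segment_id: str = "",
    alpha: float = 0.05, quorum: int = 2,
) -> RecombinationRecord:
    """≥ ``quorum`` detectors at α ⇒ recombinant.

    Not-evaluable detectors never count toward (nor reduce) the quorum;
    a segment with zero evaluable detectors is marked untested
    (verdict ``None``).
    """
    by_name = {r.detector: r for r in results}
    evaluable = [r for r in results if r.evaluable]
    if not evaluable:
        return RecombinationRecord(segment_id, by_name, None, [], [])
    supporting = sorted(r.detector for r in results if r.significant(alpha))
    verdict = len(supporting) >= quorum
    pairs: list[tuple[str, str]] = []
    gc = by_name.get("GENECONV")
    mx = by_name.get("MAXCHI")
    if gc is not None and gc.significant(alpha) and gc.pair:
        pairs.append(gc.pair)
    elif mx is not None and mx.evaluable and mx.pair:
        pairs.append(mx.pair)
    return RecombinationRecord(segment_id, by_name, verdict, supporting, pairs)


def analyze_segment(
    matrix: SegmentMatrix, *, window: int = 25, permutations: int = 1000,
    alpha: float = 0.05, quorum: int = 2, seed: int = 0,
) -> RecombinationRecord:
    """Run all four detectors on one segment and apply the consensus rule."""
    results = [
        phi_test(matrix, window=window, permutations=permutations, seed=seed),
        maxchi_test(matrix, permutations=permutations, seed=seed + 1),
        nss_test(matrix, permutations=permutations, seed=seed + 2),
        geneconv_like(matrix, permutations=permutations, seed=seed + 3),
    ]
    return consensus_call(results, matrix.id, alpha=alpha, quorum=quorum)


def recombinant_fraction(records: list[RecombinationRecord]) -> tuple[int, int, float]:
    """(recombinant, tested, percent) over a group of segment records."""
    tested = [r for r in records if r.verdict is not None]
    hits = sum(1 for r in tested if r.verdict)
    pct = 100.0 * hits / len(tested) if tested else 0.0
    return hits, len(tested), pct


def pair_attribution_summary(
    records: list[RecombinationRecord], mode: str = "single",
) -> dict[tuple[str, str], float]:
    """Percent of recombinant segments attributed to each strain pair.

    ``single`` counts one pair per recombinant segment (percentages sum
    to 100); ``multiple`` counts every pair named by a significant
    detector, with the denominator still the recombinant segment count.
    """
    rec = [r for r in records if r.verdict]
    if not rec:
        return {}
    counts: dict[tuple[str, str], int] = {}
    for r in rec:
        pairs = r.attributed_pairs[:1] if mode == "single" else r.attributed_pairs
        for p in dict.fromkeys(pairs):
            key = tuple(sorted(p))
            counts[key] = counts.get(key, 0) + 1
    return {p: 100.0 * c / len(rec) for p, c in sorted(counts.items())}


@dataclass
class EventClustering:
    genes: list[str]
    strains: list[str]
    matrix: np.ndarray          # genes × strains, 1 = recombinant verdict
    newick: str
    linkage: np.ndarray | None


def event_matrix_cluster(
    verdicts: dict[str, dict[str, bool]],
) -> EventClustering:
    """Presence/absence matrix of recombination events, strains clustered.

    ``verdicts``: strain → gene → verdict.  Rows are genes tested in at
    least two strains; strains are average-linkage clustered on Jaccard
    distance between their event profiles.
    """
    strains = sorted(verdicts)
    gene_count: dict[str, int] = {}
    for s in strains:
        for g in verdicts[s]:
            gene_count[g] = gene_count.get(g, 0) + 1
    genes = sorted(g for g, n in gene_count.items() if n >= 2)
    mat = np.zeros((len(genes), len(strains)), dtype=np.int64)
    for j, s in enumerate(strains):
        for i, g in enumerate(genes):
            mat[i, j] = int(bool(verdicts[s].get(g, False)))

    if len(strains) < 2 or not genes:
        return EventClustering(genes, strains, mat,
                               "(" + ",".join(strains) + ");", None)
    with np.errstate(invalid="ignore"):
        dist = pdist(mat.T.astype(bool), metric="jaccard")
    dist = np.nan_to_num(dist)  # all-zero profiles: identical → distance 0
    link = hierarchy.linkage(dist, method="average")

    def to_newick(node) -> str:
        if node.is_leaf():
            return strains[node.id]
        left = to_newick(node.get_left())
        right = to_newick(node.get_right())
        return f"({left}:{node.dist / 2:.6g},{right}:{node.dist / 2:.6g})"

    tree = hierarchy.to_tree(link)
    return EventClustering(genes, strains, mat, to_newick(tree) + ";", link)
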