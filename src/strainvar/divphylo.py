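"""Diversity and phylogeny over shared segments.

Nucleotide diversity π is the mean per-site difference fraction over
all ingroup sequence pairs (the outgroup orients comparisons but never
enters π or S).  Sites with a gap or ambiguity in any ingroup row are
excluded from the denominator (complete deletion).  Transitions (A↔G,
C↔T) and transversions are counted directly over ingroup pairwise
differences.  Trees are neighbor-joining on Jukes-Cantor-corrected
distances; congruence of per-segment trees with the concatenation tree
is scored by Robinson-Foulds distance, with discordant segments
categorised by which designated "mobile" taxon explains the conflict.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

from .orthomap import SegmentMatrix

_TS_PAIRS = {frozenset("AG"), frozenset("CT")}
DNA = set("ACGT")


@dataclass
class DiversityRecord:
    segment_id: str
    pi: float
    s: int                     # segregating sites (ingroup)
    ts: int
    tv: int
    length: int                # complete-deletion column count
    recombinant: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.pi <= 0.75:
            raise ValueError("pi outside [0, 0.75]")
        if self.s > self.length:
            raise ValueError("more segregating sites than columns")

    @property
    def tstv(self) -> float | None:
        """ts/tv ratio; None (undefined) when no transversions occurred."""
        return self.ts / self.tv if self.tv else None


@dataclass
class TreeResult:
    newick: str
    method: str = "NJ"

    def tree(self) -> TreeNode:
        return TreeNode.read(io.StringIO(self.newick))


class SaturationError(ValueError):
    """A pairwise distance at or beyond the Jukes-Cantor ceiling."""


def diversity(matrix: SegmentMatrix, outgroup: str | None = None,
              recombinant: bool = False) -> DiversityRecord:
    """π, segregating sites and ts/tv counts for one segment's ingroup."""
    ids = [i for i in matrix.ids if i != outgroup]
    if len(ids) < 2:
        raise ValueError("diversity requires >=2 ingroup sequences")
    rows = np.array([np.frombuffer(matrix.row(i).encode(), dtype=np.uint8)
                     for i in ids])
    called = np.zeros(rows.shape, dtype=bool)
    for b in b"ACGT":
        called |= rows == b
    keep = called.all(axis=0)
    sub = rows[:, keep]
    n, length = sub.shape
    if length == 0:
        return DiversityRecord(matrix.id, 0.0, 0, 0, 0, 0, recombinant)
    s = int(np.sum([np.unique(sub[:, j]).size > 1 for j in range(length)]))
    diff_total = 0
    ts = tv = 0
    for a, b in combinations(range(n), 2):
        mism = sub[a] != sub[b]
        diff_total += int(mism.sum())
        for x, y in zip(sub[a, mism], sub[b, mism]):
            if frozenset((chr(x), chr(y))) in _TS_PAIRS:
                ts += 1
            else:
                tv += 1
    n_pairs = n * (n - 1) // 2
    pi = diff_total / (n_pairs * length)
    return DiversityRecord(matrix.id, float(pi), s, ts, tv, length, recombinant)


@dataclass
class DiversityContrast:
    mean_recomb: float
    mean_nonrecomb: float
    ci_recomb: tuple[float, float]
    ci_nonrecomb: tuple[float, float]
    t_statistic: float
    p_value: float
    df: float
    tstv_recomb: float
    tstv_nonrecomb: float
    n_recomb: int
    n_nonrecomb: int


def _mean_ci(x: np.ndarray) -> tuple[float, tuple[float, float]]:
    m = float(np.mean(x))
    if x.size < 2:
        return m, (m, m)
    half = stats.t.ppf(0.975, x.size - 1) * stats.sem(x)
    return m, (m - half, m + half)


def compare_recombinant_diversity(
    records: list[DiversityRecord],
) -> DiversityContrast | None:
    """Welch two-sample t-test of π between recombinant and
    non-recombinant segments; returns None (with a notice) if either
    group is empty."""
    rec = np.array([r.pi for r in records if r.recombinant])
    non = np.array([r.pi for r in records if not r.recombinant])
    if rec.size == 0 or non.size == 0:
        import warnings
        warnings.warn("one diversity group is empty; contrast skipped")
        return None
    t, p = stats.ttest_ind(rec, non, equal_var=False)
    # Welch-Satterthwaite degrees of freedom
    va, vb = rec.var(ddof=1) if rec.size > 1 else 0.0, \
        non.var(ddof=1) if non.size > 1 else 0.0
    num = (va / rec.size + vb / non.size) ** 2
    den = ((va / rec.size) ** 2 / max(rec.size - 1, 1)
           + (vb / non.size) ** 2 / max(non.size - 1, 1))
    df = num / den if den else float(rec.size + non.size - 2)

    def group_tstv(flag: bool) -> float:
        ts = sum(r.ts for r in records if r.recombinant == flag)
        tv = sum(r.tv for r in records if r.recombinant == flag)
        return ts / tv if tv else float("nan")

    mr, cir = _mean_ci(rec)
    mn, cin = _mean_ci(non)
    return DiversityContrast(
        mean_recomb=mr, mean_nonrecomb=mn, ci_recomb=cir, ci_nonrecomb=cin,
        t_statistic=float(t), p_value=float(p), df=float(df),
        tstv_recomb=group_tstv(True), tstv_nonrecomb=group_tstv(False),
        n_recomb=rec.size, n_nonrecomb=non.size,
    )


def jc_distance_matrix(matrix: SegmentMatrix) -> DistanceMatrix:
    """Pairwise Jukes-Cantor distances, pairwise deletion per pair."""
    n = len(matrix.ids)
    rows = np.array([np.frombuffer(r.encode(), dtype=np.uint8)
                     for r in matrix.rows])
    called = np.zeros(rows.shape, dtype=bool)
    for b in b"ACGT":
        called |= rows == b
    d = np.zeros((n, n))
    for a, b in combinations(range(n), 2):
        use = called[a] & called[b]
        if not use.any():
            raise ValueError(
                f"no comparable sites between {matrix.ids[a]} and {matrix.ids[b]}")
        p = float(np.mean(rows[a, use] != rows[b, use]))
        if p >= 0.75:
            raise SaturationError(
                f"saturated distance between {matrix.ids[a]} and "
                f"{matrix.ids[b]} (p = {p:.3f})")
        d[a, b] = d[b, a] = -0.75 * np.log(1 - 4.0 * p / 3.0)
    return DistanceMatrix(d, ids=list(matrix.ids))


def nj_tree(matrix: SegmentMatrix) -> TreeResult:
    """Neighbor-joining tree from JC-corrected distances.

    Negative branch lengths are set to zero with the difference moved
    to the adjacent branch (standard NJ post-processing).
    """
    if len(matrix.ids) < 4:
        raise ValueError("NJ tree requires >=4 sequences")
    tree = nj(jc_distance_matrix(matrix), neg_as_zero=True)
    return TreeResult(str(tree).strip())


def rf_distance(a: TreeNode, b: TreeNode) -> float:
    return a.compare_rfd(b)


@dataclass
class CongruenceEntry:
    segment_id: str
    rf: float | None
    category: str        # congruent | mobile:<taxon> | other | low_signal


def congruence_scan(
    segments: list[SegmentMatrix],
    consensus: TreeResult,
    mobile_taxa: list[str] | None = None,
    min_informative: int = 4,
) -> tuple[list[CongruenceEntry], dict[str, int]]:
    """Per-segment NJ trees vs the concatenation tree.

    Segments with fewer than ``min_informative`` parsimony-informative
    sites are flagged low-signal and excluded from the category counts;
    discordant segments where pruning a single designated mobile taxon
    restores congruence are attributed to that taxon.
    """
    from .recomb import informative_columns, _as_array

    cons = consensus.tree()
    mobile_taxa = mobile_taxa or []
    entries: list[CongruenceEntry] = []
    counts: dict[str, int] = {}
    for seg in segments:
        if informative_columns(_as_array(seg)).size < min_informative:
            entries.append(CongruenceEntry(seg.id, None, "low_signal"))
            continue
        try:
            seg_tree = nj_tree(seg).tree()
        except (SaturationError, ValueError):
            entries.append(CongruenceEntry(seg.id, None, "low_signal"))
            continue
        rf = rf_distance(seg_tree, cons)
        if rf == 0:
            cat = "congruent"
        else:
            cat = "other"
            for taxon in mobile_taxa:
                keep = [t for t in seg.ids if t != taxon]
                if len(keep) < 4:
                    continue
                pruned_seg = seg_tree.shear(keep)
                pruned_cons = cons.shear(keep)
                if rf_distance(pruned_seg, pruned_cons) == 0:
                    cat = f"mobile:{taxon}"
                    break
        entries.append(CongruenceEntry(seg.id, rf, cat))
        counts[cat] = counts.get(cat, 0) + 1
    return entries, counts
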