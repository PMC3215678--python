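"""Ortholog mapping: fragment↔ORF alignment, reciprocal-best-hit
filtering, and shared-segment (quartet / all-strain) matrix assembly.

The alignment stage is two-phase, mirroring classical draft-genome
comparative pipelines: an ungapped seed-and-extend scan keeps only
fragment/gene pairs above 80% similarity, and survivors are realigned
with an affine-gap local aligner (match +1, mismatch −2, gap open 3,
gap extend 2).  Orthology is then enforced per *fragment* (the aligned
piece of a contig, which may span several genes) by reciprocal best
hits with identity ≥ 85% and reference-gene coverage > 60%.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import Align

from .seqio import QualSeq, reverse_complement

DNA = set("ACGT")


@dataclass
class OrthologAlignment:
    """A filtered query-fragment ↔ reference-ORF pairwise alignment.

    Aligned columns are stored as parallel strings (``qcols``/``rcols``,
    '-' for gaps) with per-column query qualities (−1 at query gaps) and
    1-based reference positions (−1 at insertion columns).  Reference
    coordinates are on the reference forward strand; reverse-strand
    query hits are reverse-complemented before alignment and flagged.
    """

    query_id: str
    gene_id: str
    q_start: int          # 1-based inclusive, oriented query
    q_end: int
    r_start: int          # 1-based inclusive, reference forward strand
    r_end: int
    strand: str           # '+' or '-'
    qcols: str
    rcols: str
    qquals: np.ndarray
    rpos: np.ndarray
    identity: float       # percent, over aligned columns
    coverage: float       # percent of reference gene length
    score: float
    strain: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 <= self.identity <= 100:
            raise ValueError("identity outside [0, 100]")
        if not 0 < self.coverage <= 100:
            raise ValueError("coverage outside (0, 100]")

    @property
    def n_columns(self) -> int:
        return len(self.qcols)

    def ref_projection(self) -> dict[int, tuple[str, int]]:
        """Map reference position (1-based) → (query char, query Q).

        Insertion columns (query bases absent from the reference) are
        dropped; reference positions deleted in the query map to '-'.
        """
        out: dict[int, tuple[str, int]] = {}
        for qc, rp, qq in zip(self.qcols, self.rpos, self.qquals):
            if rp > 0:
                out[int(rp)] = (qc, int(qq))
        return out


@dataclass
class SegmentMatrix:
    """A gap-filtered multi-strain alignment of one shared segment."""

    id: str
    ids: list[str]
    rows: list[str]
    gene_id: str = ""
    location: str = "chromosome"

    def __post_init__(self) -> None:
        if len({len(r) for r in self.rows}) > 1:
            raise ValueError(f"segment {self.id!r}: unequal row lengths")
        if len(self.ids) != len(self.rows):
            raise ValueError(f"segment {self.id!r}: ids/rows length mismatch")

    @property
    def length(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, name: str) -> str:
        return self.rows[self.ids.index(name)]


def _make_aligner() -> Align.PairwiseAligner:
    # a stiff gap-open keeps clustered substitutions aligned as mismatch
    # runs instead of compensating insertion/deletion pairs; with cheap
    # gap opens a 1-base shift can outscore three adjacent mismatches
    # and silently move variant columns
    return Align.PairwiseAligner(
        mode="local", match_score=1, mismatch_score=-2,
        open_gap_score=-12, extend_gap_score=-2,
    )


def _columns(aln) -> tuple[str, str, np.ndarray]:
    """Aligned (ref_cols, query_cols, ref positions) from a Bio.Align alignment."""
    t_blocks, q_blocks = aln.aligned
    target, query = aln.target, aln.query
    rcols: list[str] = []
    qcols: list[str] = []
    rpos: list[int] = []
    prev_t = t_blocks[0][0]
    prev_q = q_blocks[0][0]
    for (ts, te), (qs, qe) in zip(t_blocks, q_blocks):
        for t in range(prev_t, ts):       # deletion in query
            rcols.append(target[t]); qcols.append("-"); rpos.append(t + 1)
        for q in range(prev_q, qs):       # insertion in query
            rcols.append("-"); qcols.append(query[q]); rpos.append(-1)
        for t, q in zip(range(ts, te), range(qs, qe)):
            rcols.append(target[t]); qcols.append(query[q]); rpos.append(t + 1)
        prev_t, prev_q = te, qe
    return "".join(rcols), "".join(qcols), np.asarray(rpos, dtype=np.int64)


def _kmer_index(genes: dict[str, str], k: int) -> dict[str, list[tuple[str, int]]]:
    index: dict[str, list[tuple[str, int]]] = {}
    for gid, seq in genes.items():
        for i in range(0, len(seq) - k + 1):
            index.setdefault(seq[i:i + k], []).append((gid, i))
    return index


def _ungapped_similarity(qseq: str, gene: str, diag: int) -> float:
    """Percent identity of the ungapped overlap at a fixed diagonal."""
    qs = max(0, -diag)
    rs = qs + diag
    n = min(len(qseq) - qs, len(gene) - rs)
    if n <= 0:
        return 0.0
    qa = np.frombuffer(qseq[qs:qs + n].encode(), dtype=np.uint8)
    ra = np.frombuffer(gene[rs:rs + n].encode(), dtype=np.uint8)
    return 100.0 * float(np.mean(qa == ra))


def align_fragments(
    contigs: list[QualSeq],
    ref_genes: dict[str, str],
    *,
    seed_similarity: float = 80.0,
    k: int = 14,
    stride: int = 4,
    strain: str = "",
) -> list[OrthologAlignment]:
    """Two-phase candidate search: ungapped seed scan then gapped realignment.

    Phase 1 anchors each contig/gene pair on its modal seed diagonal and
    requires ungapped similarity ≥ ``seed_similarity`` percent; phase 2
    realigns surviving pairs with the affine-gap local aligner.  Returns
    every candidate (RBH filtering is a separate step); an empty result
    is legitimate.
    """
    if not contigs or not ref_genes:
        raise ValueError("align_fragments requires nonempty contigs and genes")
    aligner = _make_aligner()
    index = _kmer_index(ref_genes, k)
    out: list[OrthologAlignment] = []
    for contig in contigs:
        for strand in "+-":
            qseq = contig.seq if strand == "+" else reverse_complement(contig.seq)
            quals = contig.quals if strand == "+" else contig.quals[::-1]
            diags: dict[str, dict[int, int]] = {}
            for i in range(0, len(qseq) - k + 1, stride):
                for gid, rp in index.get(qseq[i:i + k], ()):
                    d = diags.setdefault(gid, {})
                    d[rp - i] = d.get(rp - i, 0) + 1
            for gid, dcounts in diags.items():
                diag = max(dcounts, key=lambda d: (dcounts[d], -abs(d)))
                if _ungapped_similarity(qseq, ref_genes[gid], diag) < seed_similarity:
                    continue
                alns = aligner.align(ref_genes[gid], qseq)
                if len(alns) == 0:
                    continue
                aln = alns[0]
                rcols, qcols, rpos = _columns(aln)
                ncols = len(rcols)
                if ncols == 0:
                    continue
                matches = sum(a == b and a in DNA for a, b in zip(rcols, qcols))
                identity = 100.0 * matches / ncols
                t_blocks, q_blocks = aln.aligned
                r_start, r_end = t_blocks[0][0] + 1, t_blocks[-1][1]
                q_start, q_end = q_blocks[0][0] + 1, q_blocks[-1][1]
                coverage = 100.0 * (r_end - r_start + 1) / len(ref_genes[gid])
                qquals = np.full(ncols, -1, dtype=np.int64)
                qi = q_start - 1
                for ci, ch in enumerate(qcols):
                    if ch != "-":
                        qquals[ci] = quals[qi]
                        qi += 1
                out.append(OrthologAlignment(
                    query_id=contig.id, gene_id=gid,
                    q_start=q_start, q_end=q_end,
                    r_start=int(r_start), r_end=int(r_end), strand=strand,
                    qcols=qcols, rcols=rcols, qquals=qquals, rpos=rpos,
                    identity=identity, coverage=min(coverage, 100.0),
                    score=float(aln.score), strain=strain,
                ))
    return out


def _overlap_frac(a: OrthologAlignment, b: OrthologAlignment) -> float:
    lo = max(a.q_start, b.q_start)
    hi = min(a.q_end, b.q_end)
    if hi < lo:
        return 0.0
    return (hi - lo + 1) / min(a.q_end - a.q_start + 1, b.q_end - b.q_start + 1)


def rbh_filter(
    candidates: list[OrthologAlignment],
    *,
    min_identity: float = 85.0,
    min_coverage: float = 60.0,
    diff_score: float = 10.0,
) -> list[OrthologAlignment]:
    """Reciprocal-best-hit orthology filter.

    Candidates below the identity (≥85%) or coverage (>60%) gates are
    dropped.  Overlapping candidate alignments from the same contig
    (≥50% mutual query overlap — typically paralogous reference copies)
    compete as one *fragment*: only the best-scoring alignment survives,
    with ties broken by coverage then lexicographic gene id.  A fragment
    whose runner-up (to a different gene) scores within ``diff_score``
    percent of the best is flagged ambiguous but, being the reciprocal
    best, is retained.  Finally each reference gene keeps only its
    best-scoring fragment, making the output a partial injection.
    """
    survivors = [c for c in candidates
                 if c.identity >= min_identity and c.coverage > min_coverage]

    def rank(c: OrthologAlignment):
        return (-c.score, -c.coverage, c.gene_id, c.query_id, c.strand)

    # cluster per-contig candidates into fragments by query-interval overlap
    frag_best: list[OrthologAlignment] = []
    by_contig: dict[str, list[OrthologAlignment]] = {}
    for c in survivors:
        by_contig.setdefault(c.query_id, []).append(c)
    for contig in sorted(by_contig):
        group = sorted(by_contig[contig], key=rank)
        clusters: list[list[OrthologAlignment]] = []
        for c in group:
            for cl in clusters:
                if _overlap_frac(c, cl[0]) >= 0.5:
                    cl.append(c)
                    break
            else:
                clusters.append([c])
        for cl in clusters:
            best = cl[0]
            rivals = [c for c in cl[1:] if c.gene_id != best.gene_id]
            if rivals and rivals[0].score >= best.score * (1 - diff_score / 100.0):
                best.meta["ambiguous"] = True
            frag_best.append(best)

    # reciprocal direction: one fragment per reference gene
    by_gene: dict[str, list[OrthologAlignment]] = {}
    for c in frag_best:
        by_gene.setdefault(c.gene_id, []).append(c)
    out = [sorted(group, key=rank)[0] for _, group in sorted(by_gene.items())]
    out.sort(key=lambda c: (c.gene_id, c.query_id))
    return out


def filter_blocks(matrix: SegmentMatrix, min_block: int = 10) -> SegmentMatrix:
    """Remove gap-containing regions, keeping gap-free blocks ≥ ``min_block``.

    A column survives iff no row carries a gap there and it lies in a
    maximal run of such columns at least ``min_block`` long — a compact
    reimplementation of "strip large-gap regions" block filtering.  May
    return a zero-length matrix (caller drops the segment).
    """
    if not matrix.rows:
        return matrix
    arr = np.array([np.frombuffer(r.encode(), dtype=np.uint8) for r in matrix.rows])
    gap_free = ~np.any(arr == ord("-"), axis=0)
    keep = np.zeros_like(gap_free)
    n = gap_free.size
    i = 0
    while i < n:
        if gap_free[i]:
            j = i
            while j < n and gap_free[j]:
                j += 1
            if j - i >= min_block:
                keep[i:j] = True
            i = j
        else:
            i += 1
    rows = [bytes(r[keep]).decode() for r in arr]
    return SegmentMatrix(matrix.id, list(matrix.ids), rows,
                         matrix.gene_id, matrix.location)


def _project_rows(
    gene_seq: str,
    members: list[tuple[str, OrthologAlignment]],
) -> tuple[list[str], list[str], int, int] | None:
    """Project member alignments onto the shared reference interval."""
    start = max(a.r_start for _, a in members)
    end = min(a.r_end for _, a in members)
    if end < start:
        return None
    ids: list[str] = []
    rows: list[str] = []
    for name, aln in members:
        proj = aln.ref_projection()
        ids.append(name)
        rows.append("".join(proj.get(p, ("-", -1))[0] for p in range(start, end + 1)))
    return ids, rows, start, end


def build_quartets(
    draft_alns: list[OrthologAlignment],
    ref_b_alns: list[OrthologAlignment],
    outgroup_alns: list[OrthologAlignment],
    ref_genes: dict[str, str],
    *,
    names: tuple[str, str, str, str] = ("draft", "ref_a", "ref_b", "outgroup"),
    min_len: int = 200,
    min_block: int = 10,
    locations: dict[str, str] | None = None,
) -> list[SegmentMatrix]:
    """Four-row segment matrices for genes shared by draft, both
    references and the outgroup (all RBH-filtered against reference A).

    Rows are projected onto reference-A coordinates over the
    intersection of the three aligned intervals, gap-block filtered,
    and emitted only at ≥ ``min_len`` columns.
    """
    draft_name, ref_a_name, ref_b_name, out_name = names
    d_by = {a.gene_id: a for a in draft_alns}
    b_by = {a.gene_id: a for a in ref_b_alns}
    o_by = {a.gene_id: a for a in outgroup_alns}
    quartets: list[SegmentMatrix] = []
    for gene in sorted(set(d_by) & set(b_by) & set(o_by)):
        members = [(draft_name, d_by[gene]), (ref_b_name, b_by[gene]),
                   (out_name, o_by[gene])]
        proj = _project_rows(ref_genes[gene], members)
        if proj is None:
            continue
        ids, rows, start, end = proj
        ids = [ref_a_name] + ids
        rows = [ref_genes[gene][start - 1:end]] + rows
        order = [draft_name, ref_a_name, ref_b_name, out_name]
        perm = [ids.index(n) for n in order]
        mat = SegmentMatrix(
            f"{draft_name}|{gene}", order, [rows[i] for i in perm], gene,
            (locations or {}).get(gene, "chromosome"),
        )
        mat = filter_blocks(mat, min_block)
        if mat.length >= min_len:
            quartets.append(mat)
    return quartets


def shared_segments(
    alns_by_strain: dict[str, list[OrthologAlignment]],
    ref_genes: dict[str, str],
    gene_order: list,
    *,
    ref_name: str = "reference",
    min_len: int = 100,
    min_block: int = 10,
) -> tuple[list[SegmentMatrix], SegmentMatrix, list[dict]]:
    """Segments present in ALL strains, plus their concatenation.

    Concatenation follows the reference gene order (chromosome genes
    first, then plasmids), as in the study's profile construction.
    Returns (segments, concatenated matrix, manifest); the manifest maps
    each segment to its global coordinates and replicon class.
    """
    strains = sorted(alns_by_strain)
    by_gene: dict[str, dict[str, OrthologAlignment]] = {}
    for strain in strains:
        for a in alns_by_strain[strain]:
            by_gene.setdefault(a.gene_id, {})[strain] = a
    ordered = sorted(
        gene_order,
        key=lambda g: (0 if g.replicon == "chromosome" else 1, g.start, g.gene_id),
    )
    segments: list[SegmentMatrix] = []
    manifest: list[dict] = []
    offset = 0
    for info in ordered:
        members_map = by_gene.get(info.gene_id, {})
        if len(members_map) < len(strains):
            continue
        proj = _project_rows(ref_genes[info.gene_id],
                             [(s, members_map[s]) for s in strains])
        if proj is None:
            continue
        ids, rows, start, end = proj
        mat = SegmentMatrix(
            f"seg|{info.gene_id}", [ref_name] + ids,
            [ref_genes[info.gene_id][start - 1:end]] + rows,
            info.gene_id, info.replicon,
        )
        mat = filter_blocks(mat, min_block)
        if mat.length < min_len:
            continue
        segments.append(mat)
        manifest.append({
            "segment": mat.id, "gene": info.gene_id, "location": info.replicon,
            "length": mat.length, "global_start": offset + 1,
            "global_end": offset + mat.length,
        })
        offset += mat.length
    if segments:
        ids = segments[0].ids
        concat = SegmentMatrix(
            "concatenated", list(ids),
            ["".join(seg.row(name) for seg in segments) for name in ids],
        )
    else:
        concat = SegmentMatrix("concatenated", [], [])
    return segments, concat, manifest
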