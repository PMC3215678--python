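"""Synthetic strain-collection generator.

Emulates the study design that the rest of the pipeline analyses: a
"complete" reference gene set (ORFs on a chromosome plus a plasmid),
several strains diverged 2-10% from it along a known rooted tree with a
transition/transversion bias, donor→recipient homologous-recombination
tracts, and Sanger-like quality-annotated shotgun reads at ~1× coverage.
Every stochastic choice flows from a single integer seed, and a truth
table (per-strain SNPs vs the ancestral reference, plus implanted
tracts) is returned for parameter-recovery tests.

Model notes
-----------
* Substitutions: per branch of length ``t`` (expected substitutions per
  site) each site receives a Poisson(t) number of hits applied
  sequentially, so multiple hits can overwrite each other and the
  Jukes-Cantor correction of observed divergence recovers ``t``.
* Each hit is a transition with probability κ/(κ+1) (κ =
  ``tstv_ratio``), otherwise one of the two transversions uniformly, so
  the expected transition:transversion *count* ratio equals κ.
* Recombination tracts are copied from the donor's post-substitution
  sequence, so a tract carries the donor lineage's SNPs — the signal
  the quartet detectors are meant to find.
* Reads are substitution-only: per-base miscall probability 10^(−Q/10),
  miscalls uniform over the three alternatives, no indels.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
from skbio import TreeNode

from .seqio import QualSeq

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_INDEX = {b: i for i, b in enumerate("ACGT")}
# transition partner of A,C,G,T (indices into BASES)
_TRANSITION = np.array([2, 3, 0, 1])
# the two transversion partners of each base
_TRANSVERSIONS = np.array([[1, 3], [0, 2], [1, 3], [0, 2]])

#: 8 ingroup strains (two "complete", six "draft") plus one outgroup,
#: with 2-10% pairwise ingroup divergence — the default study layout.
DEFAULT_TREE = (
    "((((S3:0.02,S4:0.02):0.005,S5:0.022):0.012,"
    "((S6:0.016,S7:0.016):0.005,REFB:0.018):0.012):0.004,"
    "(REFA:0.03,S8:0.03):0.006,OUT:0.07);"
)


@dataclass
class ErrorProfile:
    """Position-dependent Phred curve for simulated Sanger reads.

    ``kind='sanger'``: quality ramps from ``q_start`` to ``q_peak`` over
    the first ``ramp`` bases, stays flat, then declines linearly to
    ``q_end`` over the final ``tail`` bases — the familiar trace shape.
    ``kind='constant'`` holds ``q_peak`` everywhere (used for clean-read
    experiments).
    """

    kind: str = "sanger"
    q_start: int = 20
    q_peak: int = 50
    q_end: int = 15
    ramp: int = 100
    tail: int = 300

    def phred(self, read_len: int) -> np.ndarray:
        pos = np.arange(read_len)
        if self.kind == "constant":
            return np.full(read_len, self.q_peak, dtype=np.int64)
        q = np.full(read_len, float(self.q_peak))
        up = pos < self.ramp
        q[up] = self.q_start + (self.q_peak - self.q_start) * pos[up] / max(self.ramp, 1)
        tail_start = max(read_len - self.tail, self.ramp)
        down = pos >= tail_start
        span = max(read_len - tail_start, 1)
        q[down] = np.minimum(
            q[down],
            self.q_peak + (self.q_end - self.q_peak) * (pos[down] - tail_start + 1) / span,
        )
        return np.maximum(np.rint(q), 0).astype(np.int64)


@dataclass
class SimConfig:
    """Parameters of one synthetic strain collection."""

    n_genes: int = 200
    gene_len_dist: tuple[int, int, int] = (200, 300, 1500)  # (min, median, max) bp
    strain_tree: str = DEFAULT_TREE
    tstv_ratio: float = 2.0
    recomb_rate: float = 0.0          # expected tracts per genome
    tract_len_dist: tuple[int, int] = (200, 1000)
    read_len: int = 1000
    coverage: float = 1.0
    error_profile: ErrorProfile = field(default_factory=ErrorProfile)
    plasmid_fraction: float = 0.1     # tail of the gene order placed on a plasmid
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        lo, med, hi = self.gene_len_dist
        if not (0 < lo <= med <= hi):
            raise ValueError("gene_len_dist must satisfy 0 < min <= median <= max")
        if self.tstv_ratio <= 0:
            raise ValueError("tstv_ratio must be positive")
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        if self.read_len <= 0:
            raise ValueError("read_len must be positive")
        if self.recomb_rate < 0:
            raise ValueError("recomb_rate must be non-negative")
        lo, hi = self.tract_len_dist
        if not 0 < lo <= hi:
            raise ValueError("tract_len_dist must satisfy 0 < min <= max")


@dataclass
class GeneInfo:
    gene_id: str
    replicon: str        # 'chromosome' or 'plasmid'
    start: int           # 1-based inclusive within replicon
    end: int
    strand: str = "+"


@dataclass
class TruthTable:
    """Ground truth of one simulation.

    ``snps``: per strain, list of (gene_id, position 1-based, ancestral
    base, derived base) relative to the ancestral reference.
    ``tracts``: (donor, recipient, gene_id, start, end) 1-based inclusive.
    """

    snps: dict[str, list[tuple[str, int, str, str]]]
    tracts: list[tuple[str, str, str, int, int]]

    def validate(self, gene_lengths: dict[str, int]) -> None:
        for strain, rows in self.snps.items():
            for gene, pos, anc, der in rows:
                if not 1 <= pos <= gene_lengths[gene]:
                    raise ValueError(f"truth SNP outside gene: {strain} {gene}:{pos}")
                if anc == der:
                    raise ValueError("truth SNP with identical alleles")
        for donor, recip, gene, start, end in self.tracts:
            if not start < end:
                raise ValueError(f"tract with start >= end: {gene}:{start}-{end}")


@dataclass
class SimResult:
    config: SimConfig
    reference: dict[str, str]                  # ancestral ORF set
    gene_order: list[GeneInfo]
    strains: dict[str, dict[str, str]]         # strain -> gene -> sequence
    truth: TruthTable
    tree: TreeNode

    @property
    def gene_lengths(self) -> dict[str, int]:
        return {g: len(s) for g, s in self.reference.items()}

    def genome(self, strain: str) -> dict[str, str]:
        """Concatenated replicon sequences of one strain (genes abut)."""
        parts: dict[str, list[str]] = {}
        genes = self.strains[strain] if strain in self.strains else self.reference
        for info in self.gene_order:
            parts.setdefault(info.replicon, []).append(genes[info.gene_id])
        return {rep: "".join(chunks) for rep, chunks in parts.items()}


def _draw_gene_lengths(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    lo, med, hi = cfg.gene_len_dist
    # two-piece uniform keeps the configured median exactly in expectation
    left = rng.integers(lo, med + 1, size=cfg.n_genes)
    right = rng.integers(med, hi + 1, size=cfg.n_genes)
    pick = rng.random(cfg.n_genes) < 0.5
    return np.where(pick, left, right)


def _mutate(seq: np.ndarray, t: float, kappa: float,
            rng: np.random.Generator) -> np.ndarray:
    """One branch of K2P-like evolution on a base-index array."""
    if t <= 0:
        return seq.copy()
    out = seq.copy()
    hits = rng.poisson(t, size=out.size)
    p_ts = kappa / (kappa + 1.0)
    for site in np.nonzero(hits)[0]:
        for _ in range(hits[site]):
            b = out[site]
            if rng.random() < p_ts:
                out[site] = _TRANSITION[b]
            else:
                out[site] = _TRANSVERSIONS[b][rng.integers(2)]
    return out


def simulate_strains(config: SimConfig) -> SimResult:
    """Generate the reference ORF set, diverged strains, and truth table.

    Deterministic under ``config.seed``.  Raises ``ValueError`` for a
    degenerate (zero-taxon) tree.
    """
    rng = np.random.default_rng(config.seed)
    tree = TreeNode.read(io.StringIO(config.strain_tree))
    leaves = [tip.name for tip in tree.tips()]
    if not leaves:
        raise ValueError("strain tree has no taxa")
    if len(set(leaves)) != len(leaves):
        raise ValueError("duplicate taxon names in strain tree")

    lengths = _draw_gene_lengths(config, rng)
    gene_ids = [f"g{i:05d}" for i in range(config.n_genes)]
    reference_idx = {g: rng.integers(0, 4, size=int(n)).astype(np.int64)
                     for g, n in zip(gene_ids, lengths)}

    # evolve each gene down the tree (pre-order, root holds the reference)
    strain_idx: dict[str, dict[str, np.ndarray]] = {name: {} for name in leaves}
    for gene in gene_ids:
        node_seq = {id(tree): reference_idx[gene]}
        for node in tree.preorder(include_self=False):
            t = node.length or 0.0
            child = _mutate(node_seq[id(node.parent)], t, config.tstv_ratio, rng)
            node_seq[id(node)] = child
            if node.is_tip():
                strain_idx[node.name][gene] = child

    # recombination tracts: donor lineage sequence copied over recipient
    ingroup = [name for name in leaves if name != "OUT"] or leaves
    tracts: list[tuple[str, str, str, int, int]] = []
    if config.recomb_rate > 0 and len(ingroup) >= 2:
        # donors are the post-substitution lineage sequences; freezing them
        # keeps every recorded tract equal to its donor's final flanking
        # haplotype even when several tracts touch the same gene
        donor_idx = {s: {g: v.copy() for g, v in genes.items()}
                     for s, genes in strain_idx.items()}
        for recipient in ingroup:
            for _ in range(rng.poisson(config.recomb_rate)):
                donor = ingroup[rng.integers(len(ingroup) - 1)]
                if donor == recipient:
                    donor = ingroup[-1]
                gene = gene_ids[rng.integers(len(gene_ids))]
                glen = reference_idx[gene].size
                lo, hi = config.tract_len_dist
                tlen = min(int(rng.integers(lo, hi + 1)), glen)
                if tlen < 2:
                    continue
                start = int(rng.integers(0, glen - tlen + 1))
                seg = donor_idx[donor][gene][start:start + tlen].copy()
                strain_idx[recipient][gene][start:start + tlen] = seg
                tracts.append((donor, recipient, gene, start + 1, start + tlen))

    def decode(idx: np.ndarray) -> str:
        return idx.astype(np.uint8).choose(BASES).tobytes().decode()

    reference = {g: decode(v) for g, v in reference_idx.items()}
    strains = {name: {g: decode(v) for g, v in genes.items()}
               for name, genes in strain_idx.items()}

    snps: dict[str, list[tuple[str, int, str, str]]] = {}
    for name in leaves:
        rows = []
        for gene in gene_ids:
            ref = reference_idx[gene]
            alt = strain_idx[name][gene]
            for pos in np.nonzero(ref != alt)[0]:
                rows.append((gene, int(pos) + 1, "ACGT"[ref[pos]], "ACGT"[alt[pos]]))
        snps[name] = rows

    n_plasmid = int(round(config.plasmid_fraction * config.n_genes))
    order: list[GeneInfo] = []
    offsets = {"chromosome": 0, "plasmid": 0}
    for i, gene in enumerate(gene_ids):
        rep = "plasmid" if i >= config.n_genes - n_plasmid else "chromosome"
        start = offsets[rep] + 1
        end = offsets[rep] + len(reference[gene])
        offsets[rep] = end
        order.append(GeneInfo(gene, rep, start, end))

    truth = TruthTable(snps=snps, tracts=tracts)
    truth.validate({g: len(s) for g, s in reference.items()})
    return SimResult(config, reference, order, strains, truth, tree)


def shred_to_reads(genome: dict[str, str] | str, config: SimConfig,
                   seed: int, prefix: str = "read") -> list[QualSeq]:
    """Shatter a genome into Sanger-like reads with Phred-driven miscalls.

    Read count is Poisson with mean coverage × genome_len / read_len;
    start positions are uniform.  Each base gets its position's Phred Q
    from the error profile and is miscalled with probability 10^(−Q/10).
    Reads carry their source replicon/strand/start in ``meta``.
    """
    if config.coverage <= 0:
        raise ValueError("coverage must be positive")
    if isinstance(genome, str):
        genome = {"genome": genome}
    rng = np.random.default_rng(seed)
    reads: list[QualSeq] = []
    n_total = 0
    for rep in sorted(genome):
        seq = genome[rep]
        if not seq:
            raise ValueError(f"empty replicon {rep!r}")
        glen = len(seq)
        n_reads = int(rng.poisson(config.coverage * glen / config.read_len))
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        idx = np.zeros(glen, dtype=np.int64)
        for b, i in _BASE_INDEX.items():
            idx[arr == ord(b)] = i
        for _ in range(n_reads):
            start = int(rng.integers(0, max(glen - config.read_len, 0) + 1))
            rlen = min(config.read_len, glen - start)
            quals = config.error_profile.phred(rlen)
            base_idx = idx[start:start + rlen].copy()
            err = rng.random(rlen) < 10.0 ** (-quals / 10.0)
            for site in np.nonzero(err)[0]:
                shift = 1 + rng.integers(3)
                base_idx[site] = (base_idx[site] + shift) % 4
            seq_out = base_idx.astype(np.uint8).choose(BASES).tobytes().decode()
            reads.append(QualSeq(
                f"{prefix}_{rep}_{n_total:06d}", seq_out, quals,
                meta={"replicon": rep, "start": start, "strand": "+"},
            ))
            n_total += 1
    return reads


def assemble_naive(reads: list[QualSeq]) -> list[QualSeq]:
    """Coordinate-based merge of overlapping reads into contigs.

    A simulation-only shortcut: reads are grouped by source replicon and
    merged by their true coordinates.  At a covered position the base of
    the highest-quality contributing read is retained and the position's
    quality is the maximum of contributing qualities.  Non-overlapping
    reads pass through as single-read contigs.
    """
    by_rep: dict[str, list[QualSeq]] = {}
    for r in reads:
        if "start" not in r.meta:
            raise ValueError(f"read {r.id!r} lacks source coordinates")
        by_rep.setdefault(r.meta.get("replicon", "genome"), []).append(r)

    contigs: list[QualSeq] = []
    n = 0
    for rep in sorted(by_rep):
        group = sorted(by_rep[rep], key=lambda r: (r.meta["start"], r.id))
        cluster: list[QualSeq] = []
        cluster_end = -1
        for read in group + [None]:  # sentinel flushes the final cluster
            if read is not None and (not cluster or read.meta["start"] <= cluster_end):
                cluster.append(read)
                cluster_end = max(cluster_end, read.meta["start"] + len(read))
                continue
            if cluster:
                start0 = cluster[0].meta["start"]
                length = cluster_end - start0
                seq = np.zeros(length, dtype=np.uint8)
                qual = np.full(length, -1, dtype=np.int64)
                for r in cluster:
                    off = r.meta["start"] - start0
                    rq = r.quals
                    rs = np.frombuffer(r.seq.encode(), dtype=np.uint8)
                    better = rq > qual[off:off + len(r)]
                    seq[off:off + len(r)][better] = rs[better]
                    qual[off:off + len(r)][better] = rq[better]
                contigs.append(QualSeq(
                    f"contig_{rep}_{n:05d}",
                    seq.tobytes().decode(),
                    qual,
                    meta={"replicon": rep, "start": start0, "n_reads": len(cluster)},
                ))
                n += 1
            if read is not None:
                cluster = [read]
                cluster_end = read.meta["start"] + len(read)
    return contigs


def simulate_quartet_segments(
    n_segments: int,
    *,
    length: int = 1000,
    divergence: float = 0.05,
    tstv_ratio: float = 2.0,
    tract_len: int = 0,
    donor: str = "internal",
    seed: int = 0,
):
    """Four-taxon segment alignments for detector calibration and power.

    Each segment evolves independently down the balanced quartet tree
    ((A,B),(C,D)) with tip branches of ``divergence`` expected
    substitutions/site and internal branches of half that, so A/B and
    C/D are sister pairs and the cross pairs are the divergent donors.
    With ``tract_len`` > 0, one donor tract of that length is implanted
    into A at a random position — a clean recombination signal of known
    location.  ``donor='internal'`` copies from quartet member C (an
    exchange within the sampled strains, the geometry the inner-fragment
    scan targets); ``donor='external'`` copies from an unsampled lineage
    diverged 3× further from the ancestor, the geometry that inflates a
    recombinant segment's nucleotide diversity.

    Returns (segment matrices, truth tracts) where each truth entry is
    (segment index, start, end) in 1-based alignment columns.
    """
    from .orthomap import SegmentMatrix

    if tract_len < 0 or tract_len > length:
        raise ValueError("tract_len outside [0, segment length]")
    if donor not in ("internal", "external"):
        raise ValueError("donor must be 'internal' or 'external'")
    rng = np.random.default_rng(seed)
    inner = divergence / 2.0
    segments = []
    tracts: list[tuple[int, int, int]] = []
    for i in range(n_segments):
        anc = rng.integers(0, 4, size=length).astype(np.int64)
        node_ab = _mutate(anc, inner, tstv_ratio, rng)
        node_cd = _mutate(anc, inner, tstv_ratio, rng)
        tips = {
            "A": _mutate(node_ab, divergence, tstv_ratio, rng),
            "B": _mutate(node_ab, divergence, tstv_ratio, rng),
            "C": _mutate(node_cd, divergence, tstv_ratio, rng),
            "D": _mutate(node_cd, divergence, tstv_ratio, rng),
        }
        if tract_len:
            start = int(rng.integers(0, length - tract_len + 1))
            if donor == "internal":
                src = tips["C"]
            else:
                src = _mutate(anc, 3.0 * divergence, tstv_ratio, rng)
            tips["A"][start:start + tract_len] = src[start:start + tract_len]
            tracts.append((i, start + 1, start + tract_len))
        rows = [tips[k].astype(np.uint8).choose(BASES).tobytes().decode()
                for k in "ABCD"]
        segments.append(SegmentMatrix(f"quartet{i:04d}", list("ABCD"), rows))
    return segments, tracts
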