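"""End-to-end pipeline: ortholog mapping → SNP calling → ANV →
profiles → recombination → diversity/phylogeny.

``run_pipeline`` consumes files (reference ORF FASTA + gene-order TSV,
per-strain contig FASTQs, outgroup ORF FASTA) and writes one report
per stage into the output directory: TSVs with '#'-prefixed header
lines, Newick trees, and a JSON summary.  ``write_sim_inputs`` bridges
the synthetic generator to the same file interface so the whole
analysis runs with no downloads.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import divphylo, divstats, orthomap, profiles, recomb, seqio, snpcall
from .simulate import GeneInfo, SimConfig, SimResult, assemble_naive, shred_to_reads


@dataclass
class PipelineConfig:
    """Paths and stage thresholds.

    Threshold defaults are the stringent settings of the study design:
    identity 85%, reference coverage 60%, differential score 10%,
    Phred ≥ Q45, posterior > 0.99, 250-nt profile windows, 25-nt PHI
    window, α 0.05 with a ≥2-detector quorum.
    """

    reference_fasta: str = ""
    gene_order_tsv: str = ""
    query_fastqs: dict[str, str] = field(default_factory=dict)
    outgroup_fasta: str = ""
    second_reference: str = ""
    out_dir: str = "strainvar_out"

    min_identity: float = 85.0
    min_coverage: float = 60.0
    diff_score: float = 10.0
    min_phred: int = 45
    min_posterior: float = 0.99
    theta: float = 0.01
    profile_window: int = 250
    phi_window: int = 25
    permutations: int = 1000
    alpha: float = 0.05
    quorum: int = 2
    min_segment_len: int = 200
    min_shared_len: int = 100
    tiebreak_strain: str = ""
    seed: int = 0

    def validate(self) -> None:
        for name, val, lo, hi in [
            ("min_identity", self.min_identity, 0, 100),
            ("min_coverage", self.min_coverage, 0, 100),
            ("diff_score", self.diff_score, 0, 100),
            ("min_posterior", self.min_posterior, 0, 1),
            ("alpha", self.alpha, 0, 1),
            ("theta", self.theta, 0, 1),
        ]:
            if not lo < val <= hi:
                raise ValueError(f"{name}={val} outside ({lo}, {hi}]")
        if not 1 <= self.quorum <= len(recomb.DETECTORS):
            raise ValueError(
                f"quorum={self.quorum} outside [1, {len(recomb.DETECTORS)}]")
        if self.min_phred < 0 or self.profile_window <= 0 or self.phi_window <= 0:
            raise ValueError("thresholds must be positive")

    def snp_thresholds(self) -> snpcall.SnpThresholds:
        return snpcall.SnpThresholds(
            min_phred=self.min_phred, min_posterior=self.min_posterior,
            theta=self.theta)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage and input."""


def read_gene_order(path: str | Path) -> list[GeneInfo]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            gene, rep, start, end, strand = line.rstrip("\n").split("\t")
            out.append(GeneInfo(gene, rep, int(start), int(end), strand))
    return out


def write_gene_order(order, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# gene_id\treplicon\tstart\tend\tstrand\n")
        for g in order:
            fh.write(f"{g.gene_id}\t{g.replicon}\t{g.start}\t{g.end}\t{g.strand}\n")


def write_sim_inputs(
    sim: SimResult, out_dir: str | Path, *,
    reference_strain: str = "REFA",
    complete_strains: tuple[str, ...] = ("REFB",),
    outgroup_strain: str = "OUT",
    shred: bool = True,
) -> PipelineConfig:
    """Materialise a simulation as pipeline input files.

    The designated reference strain provides the ORF FASTA and gene
    order; ``complete_strains`` contribute their full genes as Q60
    contigs; every other ingroup strain is shredded into reads and
    naively assembled into quality-annotated contigs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ref_genes = sim.strains[reference_strain]
    seqio.write_fasta(ref_genes, out / "reference.fasta")
    write_gene_order(sim.gene_order, out / "gene_order.tsv")
    seqio.write_fasta(sim.strains[outgroup_strain], out / "outgroup.fasta")

    queries: dict[str, str] = {}
    leaves = sorted(sim.strains)
    for i, strain in enumerate(leaves):
        if strain in (reference_strain, outgroup_strain):
            continue
        path = out / f"{strain}.contigs.fastq"
        if strain in complete_strains or not shred:
            contigs = []
            offset = {}
            for info in sim.gene_order:
                start = offset.get(info.replicon, 0)
                seq = sim.strains[strain][info.gene_id]
                contigs.append(seqio.QualSeq(
                    f"{strain}_{info.gene_id}", seq,
                    np.full(len(seq), 60, dtype=np.int64),
                    meta={"replicon": info.replicon, "start": start}))
                offset[info.replicon] = start + len(seq)
        else:
            reads = shred_to_reads(sim.genome(strain), sim.config,
                                   seed=sim.config.seed * 1009 + i + 1,
                                   prefix=strain)
            contigs = assemble_naive(reads)
        seqio.write_fastq(contigs, path)
        queries[strain] = str(path)

    return PipelineConfig(
        reference_fasta=str(out / "reference.fasta"),
        gene_order_tsv=str(out / "gene_order.tsv"),
        query_fastqs=queries,
        outgroup_fasta=str(out / "outgroup.fasta"),
        second_reference=(complete_strains[0] if complete_strains else ""),
        out_dir=str(out / "reports"),
        tiebreak_strain=(complete_strains[0] if complete_strains else ""),
        seed=sim.config.seed,
    )


def _write_tsv(path: Path, header: list[str], rows: list[list]) -> None:
    with open(path, "w") as fh:
        fh.write("# " + "\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(
                f"{x:.6g}" if isinstance(x, float) else str(x)
                for x in row) + "\n")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the summary dict (also written as JSON).

    The log records every threshold and the record count surviving each
    filter; any stage failure aborts with the stage name.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = [f"config: {json.dumps(asdict(config), sort_keys=True)}"]
    summary: dict = {"stages": {}}

    def fail(stage: str, exc: Exception):
        raise StageError(f"stage {stage!r} failed: {exc}") from exc

    # ---- stage 1: ortholog mapping -------------------------------------
    try:
        ref_genes = seqio.read_fasta(config.reference_fasta)
        gene_order = read_gene_order(config.gene_order_tsv)
        outgroup_genes = seqio.read_fasta(config.outgroup_fasta) \
            if config.outgroup_fasta else {}
        orthologs: dict[str, list[orthomap.OrthologAlignment]] = {}
        for strain in sorted(config.query_fastqs):
            contigs = seqio.read_fastq(config.query_fastqs[strain])
            cands = orthomap.align_fragments(contigs, ref_genes, strain=strain)
            kept = orthomap.rbh_filter(
                cands, min_identity=config.min_identity,
                min_coverage=config.min_coverage, diff_score=config.diff_score)
            orthologs[strain] = kept
            log.append(f"orthomap[{strain}]: {len(cands)} candidates -> "
                       f"{len(kept)} RBH orthologs")
        rows = [[a.strain, a.query_id, a.gene_id, a.q_start, a.q_end,
                 a.r_start, a.r_end, a.strand, a.identity, a.coverage, a.score]
                for s in sorted(orthologs) for a in orthologs[s]]
        _write_tsv(out / "orthologs.tsv",
                   ["strain", "query", "gene", "q_start", "q_end", "r_start",
                    "r_end", "strand", "identity", "coverage", "score"], rows)
        summary["stages"]["orthomap"] = {s: len(v) for s, v in orthologs.items()}
    except StageError:
        raise
    except Exception as exc:
        fail("orthomap", exc)

    # ---- stage 2: SNP calling ------------------------------------------
    try:
        th = config.snp_thresholds()
        frags_by_strain: dict[str, list[snpcall.FragmentVariation]] = {}
        snp_rows, frag_rows = [], []
        for strain in sorted(orthologs):
            frags, calls = snpcall.fragment_variation(orthologs[strain], th)
            frags_by_strain[strain] = frags
            snp_rows += [[c.strain, c.gene_id, c.position, c.ref_base,
                          c.alt_base, c.query_phred, c.site_phred,
                          c.posterior] for c in calls]
            frag_rows += [[f.strain, f.query_id, f.gene_id, f.length,
                           f.snp_count, f.percent] for f in frags]
            log.append(f"snpcall[{strain}]: {len(frags)} fragments, "
                       f"{sum(f.snp_count for f in frags)} accepted SNPs "
                       f"(Q>={th.min_phred}, P>{th.min_posterior})")
        _write_tsv(out / "snps.tsv",
                   ["strain", "gene", "pos", "ref", "alt", "q", "site_q",
                    "posterior"], snp_rows)
        _write_tsv(out / "fragments.tsv",
                   ["strain", "query", "gene", "length", "snps", "percent"],
                   frag_rows)
        summary["stages"]["snpcall"] = {
            s: snpcall.variation_summary(f) for s, f in frags_by_strain.items()}
    except Exception as exc:
        fail("snpcall", exc)

    # ---- stage 3: ANV ---------------------------------------------------
    try:
        populated = {s: f for s, f in frags_by_strain.items() if f}
        if len(populated) >= 2:
            report = divstats.anv(populated, reference="reference")
            rows = [[s, report.medians[s], report.intervals[s][0],
                     report.intervals[s][1],
                     "outlier" if s in report.outliers else ""]
                    for s in sorted(report.medians)]
            _write_tsv(out / "anv.tsv",
                       ["strain", "median_pct", "ci_low", "ci_high", "flag"],
                       rows)
            anv_json = {
                "reference": report.reference, "anv_percent": report.anv,
                "chi2": report.chi2, "df": report.df, "p": report.p_value,
                "averaged_interval": list(report.averaged_interval),
                "outliers": report.outliers,
            }
            (out / "anv.json").write_text(json.dumps(anv_json, indent=2,
                                                     sort_keys=True))
            summary["stages"]["anv"] = anv_json
            log.append(f"anv: {report.anv:.3f}% over {len(populated)} strains")
        else:
            summary["stages"]["anv"] = None
            log.append("anv: skipped (<2 strains with fragments)")
    except Exception as exc:
        fail("anv", exc)

    # ---- stage 4: shared segments & profiles ---------------------------
    try:
        segments, concat, manifest = orthomap.shared_segments(
            orthologs, ref_genes, gene_order, ref_name="reference",
            min_len=config.min_shared_len)
        _write_tsv(out / "segments.tsv",
                   ["segment", "gene", "location", "length", "global_start",
                    "global_end"],
                   [[m["segment"], m["gene"], m["location"], m["length"],
                     m["global_start"], m["global_end"]] for m in manifest])
        log.append(f"profiles: {len(segments)} shared segments, "
                   f"{concat.length} concatenated bp")
        if segments:
            tiebreak = config.tiebreak_strain or concat.ids[0]
            cons = profiles.consensus_sequence(concat, tiebreak)
            sites = profiles.classify_sites(concat, cons)
            poly = [s for s in sites if s.site_class != "monomorphic"]
            _write_tsv(out / "sites.tsv",
                       ["position", "class", "carriers", "consensus"],
                       [[s.position, s.site_class, ",".join(sorted(s.carriers)),
                         s.consensus] for s in poly])
            wins = profiles.window_counts(sites, concat.ids,
                                          window=config.profile_window)
            _write_tsv(out / "windows.tsv",
                       ["window", "start", "end", "singletons", "shared",
                        "polyallelic"],
                       [[w.index, w.start, w.end,
                         sum(w.singleton_by_strain.values()), w.shared_count,
                         w.polyallelic_count] for w in wins])
            patterns = profiles.shared_pattern_detection(sites)
            _write_tsv(out / "patterns.tsv",
                       ["pattern", "strains", "n_columns"],
                       [[p["pattern"], ",".join(p["strains"]), p["n_columns"]]
                        for p in patterns])
            summary["stages"]["profiles"] = {
                "segments": len(segments), "concatenated_bp": concat.length,
                "polymorphic": len(poly), "patterns": len(patterns)}
        else:
            summary["stages"]["profiles"] = {"segments": 0}
    except Exception as exc:
        fail("profiles", exc)

    # ---- stage 5: recombination ----------------------------------------
    try:
        records_by_strain: dict[str, list[recomb.RecombinationRecord]] = {}
        quartets_by_strain: dict[str, list[orthomap.SegmentMatrix]] = {}
        ref_b = config.second_reference
        if ref_b and ref_b in orthologs and outgroup_genes:
            out_alns = orthomap.rbh_filter(
                orthomap.align_fragments(
                    seqio.as_qualseqs(outgroup_genes), ref_genes,
                    strain="outgroup"),
                min_identity=config.min_identity, min_coverage=config.min_coverage,
                diff_score=config.diff_score)
            locations = {g.gene_id: g.replicon for g in gene_order}
            det_rows, cons_rows = [], []
            for strain in sorted(orthologs):
                if strain == ref_b:
                    continue
                quartets = orthomap.build_quartets(
                    orthologs[strain], orthologs[ref_b], out_alns, ref_genes,
                    names=(strain, "reference", ref_b, "outgroup"),
                    min_len=config.min_segment_len, locations=locations)
                quartets_by_strain[strain] = quartets
                records = []
                for qi, mat in enumerate(quartets):
                    rec = recomb.analyze_segment(
                        mat, window=config.phi_window,
                        permutations=config.permutations, alpha=config.alpha,
                        quorum=config.quorum,
                        seed=(config.seed * 1000003 + qi * 7 + 1) % 2**31)
                    records.append(rec)
                    for name, d in sorted(rec.detectors.items()):
                        det_rows.append([
                            strain, mat.id, name,
                            "" if np.isnan(d.statistic) else d.statistic,
                            "" if d.p_value is None else d.p_value,
                            int(d.evaluable), d.note])
                    cons_rows.append([
                        strain, mat.id,
                        {True: "recombinant", False: "clonal",
                         None: "untested"}[rec.verdict],
                        ",".join(rec.supporting),
                        ";".join("-".join(p) for p in rec.attributed_pairs)])
                records_by_strain[strain] = records
                hits, tested, pct = recomb.recombinant_fraction(records)
                log.append(f"recomb[{strain}]: {hits}/{tested} recombinant "
                           f"({pct:.2f}%)")
            _write_tsv(out / "recomb_detectors.tsv",
                       ["strain", "segment", "detector", "statistic", "p",
                        "evaluable", "note"], det_rows)
            _write_tsv(out / "recomb_consensus.tsv",
                       ["strain", "segment", "verdict", "supporting", "pairs"],
                       cons_rows)
            attr_rows = []
            for strain, records in sorted(records_by_strain.items()):
                for pair, pct in recomb.pair_attribution_summary(records).items():
                    attr_rows.append([strain, "-".join(pair), pct])
            _write_tsv(out / "pair_attribution.tsv",
                       ["strain", "pair", "percent"], attr_rows)
            verdicts = {
                s: {r.segment_id.split("|", 1)[1]: bool(r.verdict)
                    for r in records if r.verdict is not None}
                for s, records in records_by_strain.items()}
            clustering = recomb.event_matrix_cluster(verdicts)
            (out / "recomb_dendrogram.nwk").write_text(clustering.newick + "\n")
            summary["stages"]["recomb"] = {
                s: dict(zip(("recombinant", "tested", "percent"),
                            recomb.recombinant_fraction(r)))
                for s, r in records_by_strain.items()}
        else:
            summary["stages"]["recomb"] = None
            log.append("recomb: skipped (needs second reference and outgroup)")
    except Exception as exc:
        fail("recomb", exc)

    # ---- stage 6: diversity & phylogeny --------------------------------
    try:
        div_rows = []
        div_records = []
        for strain, quartets in sorted(quartets_by_strain.items()):
            rec_map = {r.segment_id: bool(r.verdict)
                       for r in records_by_strain[strain]
                       if r.verdict is not None}
            for mat in quartets:
                if mat.id not in rec_map:
                    continue
                d = divphylo.diversity(mat, outgroup="outgroup",
                                       recombinant=rec_map[mat.id])
                div_records.append(d)
                div_rows.append([strain, d.segment_id, d.pi, d.s, d.ts, d.tv,
                                 "" if d.tstv is None else d.tstv,
                                 int(d.recombinant)])
        _write_tsv(out / "diversity.tsv",
                   ["strain", "segment", "pi", "S", "ts", "tv", "tstv",
                    "recombinant"], div_rows)
        contrast = divphylo.compare_recombinant_diversity(div_records) \
            if div_records else None
        if contrast is not None:
            (out / "diversity_contrast.json").write_text(
                json.dumps(asdict(contrast), indent=2, sort_keys=True))
            summary["stages"]["diversity"] = asdict(contrast)
        else:
            summary["stages"]["diversity"] = None

        if segments and len(concat.ids) >= 4:
            tree = divphylo.nj_tree(concat)
            (out / "tree.nwk").write_text(tree.newick + "\n")
            entries, counts = divphylo.congruence_scan(segments, tree)
            _write_tsv(out / "congruence.tsv",
                       ["segment", "rf", "category"],
                       [[e.segment_id, "" if e.rf is None else e.rf,
                         e.category] for e in entries])
            summary["stages"]["phylogeny"] = {
                "tree": tree.newick, "congruence": counts}
            log.append(f"phylogeny: congruence categories {counts}")
        else:
            summary["stages"]["phylogeny"] = None
    except Exception as exc:
        fail("divphylo", exc)

    (out / "pipeline.log").write_text("\n".join(log) + "\n")
    (out / "summary.json").write_text(json.dumps(summary, indent=2,
                                                 sort_keys=True))
    return summary
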