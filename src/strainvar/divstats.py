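"""Average Nucleotide Variation (ANV) and the low-coverage robustness check.

ANV condenses a strain collection's divergence from a reference into a
single percentage: the arithmetic mean, across strains, of each
strain's median per-fragment SNP percentage.  Homogeneity of the
underlying per-strain SNP proportions is tested with a k-sample
chi-squared on pooled (SNP, non-SNP) counts, and each strain's median
gets a Wilson score interval whose effective sample size is the
strain's median fragment length — fragment medians, not base totals,
drive the interval width, matching the fragment-level definition of
the statistic.  A strain whose median falls outside the mean of the
per-strain intervals is flagged as an outlier.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .snpcall import FragmentVariation


@dataclass
class AnvReport:
    reference: str
    anv: float                                   # percent
    medians: dict[str, float]                    # strain → median SNP percent
    intervals: dict[str, tuple[float, float]]    # strain → Wilson CI (percent)
    averaged_interval: tuple[float, float]
    chi2: float
    df: int
    p_value: float
    outliers: list[str]

    def __post_init__(self) -> None:
        vals = list(self.medians.values())
        if vals and not (min(vals) - 1e-9 <= self.anv <= max(vals) + 1e-9):
            raise ValueError("ANV outside the range of strain medians")


@dataclass
class CoverageComparison:
    coverage_a: float
    coverage_b: float
    median_a: float
    median_b: float
    mannwhitney_u: float
    mannwhitney_p: float
    ks_d: float
    ks_p: float
    n_a: int = 0
    n_b: int = 0


def wilson_interval(p: float, n: float, z: float = 1.959964) -> tuple[float, float]:
    """Wilson score interval for a proportion ``p`` at effective size ``n``."""
    if n <= 0:
        return (0.0, 1.0)
    denom = 1.0 + z * z / n
    centre = (p + z * z / (2 * n)) / denom
    half = (z / denom) * math.sqrt(p * (1 - p) / n + z * z / (4 * n * n))
    return (max(0.0, centre - half), min(1.0, centre + half))


def anv(
    per_strain: dict[str, list[FragmentVariation]],
    reference: str = "reference",
) -> AnvReport:
    """Compute the ANV report for one reference comparison.

    Strains with zero fragments are excluded with a warning; at least
    two populated strains are required.
    """
    populated = {s: f for s, f in per_strain.items() if f}
    for s in sorted(set(per_strain) - set(populated)):
        warnings.warn(f"strain {s!r} has no fragments; excluded from ANV")
    if len(populated) < 2:
        raise ValueError("ANV requires at least two strains with fragments")

    medians: dict[str, float] = {}
    intervals: dict[str, tuple[float, float]] = {}
    counts = []
    for strain in sorted(populated):
        frags = populated[strain]
        pct = np.array([f.percent for f in frags])
        med = float(np.median(pct))
        medians[strain] = med
        n_eff = float(np.median([f.length for f in frags]))
        lo, hi = wilson_interval(med / 100.0, n_eff)
        intervals[strain] = (100.0 * lo, 100.0 * hi)
        counts.append((sum(f.snp_count for f in frags),
                       sum(f.length for f in frags)))

    table = np.array([[snp, max(total - snp, 0)] for snp, total in counts])
    if table[:, 0].sum() == 0 or table[:, 1].sum() == 0:
        chi2, p = 0.0, 1.0
    else:
        chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    df = len(populated) - 1

    avg_lo = float(np.mean([iv[0] for iv in intervals.values()]))
    avg_hi = float(np.mean([iv[1] for iv in intervals.values()]))
    outliers = [s for s, m in medians.items() if m < avg_lo or m > avg_hi]
    return AnvReport(
        reference=reference,
        anv=float(np.mean(list(medians.values()))),
        medians=medians, intervals=intervals,
        averaged_interval=(avg_lo, avg_hi),
        chi2=float(chi2), df=df, p_value=float(p),
        outliers=sorted(outliers),
    )


def compare_distributions(
    pct_a: np.ndarray, pct_b: np.ndarray,
    coverage_a: float, coverage_b: float,
) -> CoverageComparison:
    """Two-sample Mann-Whitney U and Kolmogorov-Smirnov comparison."""
    pct_a = np.asarray(pct_a, dtype=float)
    pct_b = np.asarray(pct_b, dtype=float)
    if np.array_equal(pct_a, pct_b):
        u, up = float(len(pct_a)) ** 2 / 2.0, 1.0
        d, dp = 0.0, 1.0
    else:
        u, up = stats.mannwhitneyu(pct_a, pct_b, alternative="two-sided")
        d, dp = stats.ks_2samp(pct_a, pct_b)
    return CoverageComparison(
        coverage_a=coverage_a, coverage_b=coverage_b,
        median_a=float(np.median(pct_a)), median_b=float(np.median(pct_b)),
        mannwhitney_u=float(u), mannwhitney_p=float(up),
        ks_d=float(d), ks_p=float(dp),
        n_a=len(pct_a), n_b=len(pct_b),
    )


def subsample_reads(reads: list, target_coverage: float,
                    available_coverage: float, seed: int) -> list:
    """Seeded without-replacement subsample to a target fold coverage."""
    if target_coverage > available_coverage + 1e-9:
        raise ValueError(
            f"target coverage {target_coverage} exceeds available "
            f"{available_coverage}")
    rng = np.random.default_rng(seed)
    n_keep = int(round(len(reads) * target_coverage / available_coverage))
    idx = rng.choice(len(reads), size=min(n_keep, len(reads)), replace=False)
    return [reads[i] for i in sorted(idx)]


def coverage_robustness(
    reads: list,
    ref_genes: dict[str, str],
    target_coverages: list[float],
    available_coverage: float,
    *,
    seed: int = 0,
    thresholds=None,
    strain: str = "",
) -> list[CoverageComparison]:
    """Does low coverage bias the SNP% distribution?

    Subsamples the read set to each target coverage, re-runs assembly,
    ortholog mapping and SNP calling, and compares each level's
    per-fragment SNP% distribution against the deepest level with
    Mann-Whitney and KS tests.
    """
    from .simulate import assemble_naive
    from .orthomap import align_fragments, rbh_filter
    from .snpcall import fragment_variation

    def snp_percents(read_subset) -> np.ndarray:
        contigs = assemble_naive(read_subset)
        if not contigs:
            return np.array([])
        cands = align_fragments(contigs, ref_genes, strain=strain)
        kept = rbh_filter(cands)
        frags, _ = fragment_variation(kept, thresholds)
        return np.array([f.percent for f in frags])

    levels = sorted(set(target_coverages))
    dists = {}
    for i, cov in enumerate(levels):
        subset = subsample_reads(reads, cov, available_coverage, seed + i)
        dists[cov] = snp_percents(subset)
    top = levels[-1]
    return [compare_distributions(dists[cov], dists[top], cov, top)
            for cov in levels[:-1]]
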