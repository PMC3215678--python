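"""Quality-aware Bayesian SNP calling on ortholog alignments.

Each mismatch column is scored with a two-sequence Bayesian model of
true polymorphism.  With per-base error ε = 10^(−Q/10) and miscalls
uniform over the three alternative bases, the likelihood of observing
bases (o₁, o₂) is marginalised over the 16 possible true-base pairs
under two hypotheses:

* identical truth (prior 1−θ): true bases equal, uniform over 4;
* polymorphic truth (prior θ): true bases differ, the derived base
  uniform over the 3 alternatives.

The posterior of polymorphism gates calls together with a minimum
per-site Phred support (the weaker of the two base qualities).  The
defaults — site Phred ≥ 45 and posterior > 0.99 — are the stringent
acceptance thresholds used throughout the analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .orthomap import OrthologAlignment

DNA = set("ACGT")


@dataclass
class SnpThresholds:
    min_phred: int = 45
    min_posterior: float = 0.99
    theta: float = 0.01      # prior probability that a site is polymorphic
    ref_phred: int = 60      # finished-reference per-base quality


@dataclass
class SnpCall:
    """One accepted polymorphic site."""

    strain: str
    gene_id: str
    position: int            # 1-based on the reference gene
    ref_base: str
    alt_base: str
    query_phred: int
    site_phred: int          # min of member qualities
    posterior: float

    def __post_init__(self) -> None:
        if self.ref_base == self.alt_base:
            raise ValueError("SNP with identical alleles")
        if not 0.0 <= self.posterior <= 1.0:
            raise ValueError("posterior outside [0, 1]")
        if self.site_phred < 0:
            raise ValueError("negative Phred")


@dataclass
class FragmentVariation:
    """Per-fragment SNP load: count / aligned length, as a percent."""

    strain: str
    query_id: str
    gene_id: str
    length: int              # aligned (both-base) columns
    snp_count: int

    def __post_init__(self) -> None:
        if self.snp_count > self.length:
            raise ValueError("more SNPs than aligned columns")

    @property
    def percent(self) -> float:
        return 100.0 * self.snp_count / self.length if self.length else 0.0


def site_posterior(base1: str, q1: float, base2: str, q2: float,
                   theta: float = 0.01) -> float:
    """Posterior probability that the true bases at a site differ.

    Symmetric in its two (base, Q) arguments.  Closed form: with
    f_i(b) = 1−ε_i if b = o_i else ε_i/3 and Σ_b f_i(b) = 1,

        L_same = ¼ Σ_b f₁(b) f₂(b)
        L_diff = (1 − 4·L_same) / 12

    and P_poly = θ·L_diff / (θ·L_diff + (1−θ)·L_same).
    """
    if not 0.0 < theta < 1.0:
        raise ValueError("theta must lie in (0, 1)")
    if q1 < 0 or q2 < 0:
        raise ValueError("Phred qualities must be non-negative")
    e1 = 10.0 ** (-q1 / 10.0)
    e2 = 10.0 ** (-q2 / 10.0)
    if base1 == base2:
        dot = (1 - e1) * (1 - e2) + e1 * e2 / 3.0
    else:
        dot = (1 - e1) * e2 / 3.0 + e1 * (1 - e2) / 3.0 + 2.0 * e1 * e2 / 9.0
    l_same = 0.25 * dot
    l_diff = (1.0 - 4.0 * l_same) / 12.0
    num = theta * l_diff
    return num / (num + (1.0 - theta) * l_same)


def call_snps(
    alignment: OrthologAlignment,
    thresholds: SnpThresholds | None = None,
) -> list[SnpCall]:
    """Accept mismatch columns passing the Phred and posterior gates.

    Gap columns are never called; columns with IUPAC ambiguity codes in
    either sequence are skipped (they still count toward the fragment's
    aligned length).
    """
    th = thresholds or SnpThresholds()
    calls: list[SnpCall] = []
    for qc, rc, rp, qq in zip(alignment.qcols, alignment.rcols,
                              alignment.rpos, alignment.qquals):
        if qc == "-" or rc == "-":
            continue
        if qc not in DNA or rc not in DNA:
            continue
        if qc == rc:
            continue
        site_phred = int(min(qq, th.ref_phred))
        if site_phred < th.min_phred:
            continue
        post = site_posterior(qc, qq, rc, th.ref_phred, th.theta)
        if post <= th.min_posterior:
            continue
        calls.append(SnpCall(
            strain=alignment.strain, gene_id=alignment.gene_id,
            position=int(rp), ref_base=rc, alt_base=qc,
            query_phred=int(qq), site_phred=site_phred, posterior=post,
        ))
    return calls


def aligned_length(alignment: OrthologAlignment) -> int:
    """Columns where both sequences carry a base (gap columns excluded)."""
    return sum(q != "-" and r != "-"
               for q, r in zip(alignment.qcols, alignment.rcols))


def fragment_variation(
    alignments: list[OrthologAlignment],
    thresholds: SnpThresholds | None = None,
) -> tuple[list[FragmentVariation], list[SnpCall]]:
    """SNP percentage per retained alignment, plus the raw calls."""
    frags: list[FragmentVariation] = []
    all_calls: list[SnpCall] = []
    for aln in alignments:
        calls = call_snps(aln, thresholds)
        all_calls.extend(calls)
        frags.append(FragmentVariation(
            strain=aln.strain, query_id=aln.query_id, gene_id=aln.gene_id,
            length=aligned_length(aln), snp_count=len(calls),
        ))
    return frags, all_calls


def variation_summary(frags: list[FragmentVariation]) -> dict[str, float]:
    """Median and quartiles of the per-fragment SNP percent distribution."""
    if not frags:
        return {"n": 0, "median": float("nan"),
                "q1": float("nan"), "q3": float("nan")}
    pct = np.array([f.percent for f in frags])
    q1, med, q3 = np.percentile(pct, [25, 50, 75])
    return {"n": len(frags), "median": float(med),
            "q1": float(q1), "q3": float(q3)}
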