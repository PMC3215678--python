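# Methods

This note documents the models, thresholds and numerical choices
behind `strainvar`, and what the synthetic-data experiments do and do
not demonstrate.

## Synthetic strain collections

`simulate.simulate_strains` evolves a random ancestral ORF set down a
user-supplied rooted tree (branch lengths in expected substitutions
per site). Per branch of length *t*, every site receives a Poisson(*t*)
number of substitution events applied sequentially, so multiple hits
can overwrite one another and the Jukes–Cantor correction of observed
divergence recovers *t* — a strict one-hit-per-site scheme would make
the JC estimator upward-biased. Each event is a transition with
probability κ/(κ+1) (κ = `tstv_ratio`, default 2), each transversion
with probability 1/(2(κ+1)); the configured κ is therefore the
*expected transition:transversion count ratio*, which is what the
direct-counting estimator downstream measures.

The default tree places 8 ingroup strains (two designated "complete",
six "draft") and one outgroup at 2–10% pairwise ingroup divergence —
two three-strain clusters, two long-branch strains, and an outgroup at
~10–14% — and is fully binary so that tree-recovery checks can demand
Robinson–Foulds distance exactly 0. Genes (default 200, lengths
drawn from a two-piece uniform with min/median/max 200/300/1500 bp)
abut on a chromosome plus a plasmid carrying the last 10% of the gene
order.

Recombination: each ingroup strain receives Poisson(`recomb_rate`)
tracts (default length uniform on 200–1000 bp), copied from the
*post-substitution, pre-recombination* sequence of a uniformly chosen
donor strain. Freezing the donor pool means every recorded tract
matches its donor's lineage haplotype even when several tracts touch
the same gene, which keeps the truth table exact; tracts therefore
carry the donor lineage's SNPs — precisely the mosaic signal the
quartet detectors target. `simulate_quartet_segments` additionally
provides per-segment quartets with one implanted tract, from either a
quartet member (`donor="internal"`, the geometry an inner-fragment
scan detects) or an unsampled lineage diverged 3× further
(`donor="external"`, the geometry that inflates a recombinant
segment's π).

Reads are substitution-only (no indels, matching the
substitution-only analysis downstream): length 1000, count
Poisson(coverage × genome/read length), per-base miscall probability
10^(−Q/10) with miscalls uniform over the three alternatives. The
Phred curve is a free modelling choice (no published per-position
profile is being reproduced): a trace-like ramp from Q20 to a Q50
plateau over the first 100 bases, declining to Q15 over the final 300;
a constant-Q profile is available for clean-read experiments. "Assembly"
is a simulation-only coordinate merge: overlapping reads from the same
replicon are fused, each position keeping the base and Phred of its
best-quality read. It produces contigs with realistic lengths and
quality mosaics but models no assembler behaviour (no misassembly, no
repeat collapse).

**What passing tests show — and not.** Parameter recovery, detector
calibration and congruence results on these simulations validate the
*statistical machinery* under an idealised error model: i.i.d.
miscalls, no indels, no chimeric contigs, uniform coverage, a single
true tree. They do not certify performance on real draft genomes,
where alignment error, repeats and assembly artefacts add structured
noise that this generator deliberately omits.

## Ortholog mapping

Candidate fragment↔ORF pairs come from a 14-mer index (query stride 4,
both strands); each contig/gene pair is anchored on its modal seed
diagonal and kept only if ungapped similarity there is ≥ 80%.
Survivors are realigned with an affine-gap local aligner: match +1,
mismatch −2, gap open 12, gap extend 2. The stiff gap-open is a
deliberate numerical choice: with a cheap gap-open (≈3), a
compensating insertion/deletion pair outscores three adjacent
mismatches, so clustered substitutions get rendered as spurious gap
pairs and variant columns silently move; gap open 12 makes a gap pair
worth more than an eight-mismatch run, which essentially never occurs
at ≤10% divergence. Identity is computed over aligned columns
(including gap columns); coverage is the aligned reference span over
the gene length.

Orthology is enforced per *fragment*: overlapping candidate alignments
from one contig (≥50% mutual query overlap, typically paralogous
reference copies) compete, and only the best by score (ties: coverage,
then lexicographic gene id) survives; each reference gene then keeps
its single best fragment. The result is a partial injection
fragment ↔ gene. A fragment whose cross-gene runner-up scores within
10% is flagged ambiguous but retained, being the reciprocal best.
Gates: identity ≥ 85%, reference coverage > 60%.

Multi-strain matrices (quartets, all-strain shared segments) are built
by projecting each member's alignment onto reference coordinates over
the intersection of aligned intervals (insertions relative to the
reference are dropped, deletions become gaps). Gap regions are removed
by a block filter: a column survives iff it is gap-free in every row
and lies in a maximal gap-free run of ≥ 10 columns; quartets must
retain ≥ 200 columns, shared segments ≥ 100 (shorter shared segments
are tolerated because the profile stage concatenates them, whereas
quartets are tested individually and need per-segment signal).

## SNP calling

The polymorphism posterior treats contig consensus and reference as
two observations of possibly-distinct true bases: identical truth with
prior 1−θ (true base uniform on 4), polymorphic truth with prior θ
(derived base uniform on the 3 alternatives). Marginalising the 16
true-base pairs gives the closed form in the README; the test suite
pins it to an explicit 16-term enumeration at 10⁻¹². Defaults:
θ = 0.01; finished references carry Q60 per base; site Phred is the
minimum of the two base qualities (weakest-evidence rule); calls
require site Phred ≥ 45 and posterior > 0.99. Near these defaults the
two gates agree (a Q45/Q60 mismatch has posterior ≈ 0.997, a Q40 one
≈ 0.98), so Q45 is the binding constraint for clean data and the
posterior gate takes over when both bases are uncertain. IUPAC
ambiguity columns are skipped but still count in the fragment length
(conservative: they dilute, never inflate, SNP%).

## ANV

ANV = mean over strains of the median per-fragment SNP percentage.
Design choices:

* The homogeneity test is a k×2 chi-squared on pooled (SNP, non-SNP)
  counts, df = k−1, no continuity correction (counts are large).
* Per-strain uncertainty is a Wilson score interval for
  p = median%/100 at effective n = the strain's *median fragment
  length*. This is an interpretation: the interval is meant to reflect
  the granularity of a typical fragment, not the pooled base count
  (which would shrink it absurdly). The averaged interval (mean of
  per-strain bounds) is the outlier criterion: a strain whose median
  falls outside it is flagged. Per-strain intervals are reported too.
* ANV is invariant to fragment order and to duplicating a strain's
  whole fragment set (medians are).

The low-coverage check subsamples reads without replacement to each
target coverage, re-runs assembly→mapping→calling, and compares
per-fragment SNP% distributions against the deepest level with
two-sample Mann–Whitney and Kolmogorov–Smirnov tests.

## Profiles

Consensus: per column, the plurality base over non-gap bases; when the
plurality is tied the designated tiebreak strain's base wins. The rule
is stated for the half-half case in the study design; extending *any*
plurality tie to the tiebreak strain's base (even when that base is
not among the tied ones) makes the function total with one rule.
Classification partitions every column: monomorphic; singleton
(exactly one strain off-consensus); polyallelic (≥3 alleles and ≥2
off-consensus strains); shared biallelic (the single non-consensus
allele carried by ≥2 strains). Windows are fixed 250 nt,
non-overlapping, last window short. Patterns are carrier sets backed
by ≥2 shared-biallelic columns, named A, B, … by decreasing column
count.

## Recombination detectors

All four detectors work on one segment matrix and share conventions:
polymorphic/informative columns computed over non-gap bases; seeded
permutation nulls; add-one p-values p = (b+1)/(n+1), never exactly 0;
default 1,000 permutations (desk scale; production scale is a flag
away); a detector with too little signal returns "not evaluable" and
never counts toward — nor reduces — the 2-of-4 consensus quorum.

Incompatibility of two sites is the minimum number of extra mutations
any tree must invoke, computed exactly as the cycle rank E − V + C of
the bipartite state-intersection graph. This generalises the
four-gamete test to multi-state sites.

* **PHI**: mean incompatibility over informative-site pairs ≤ 25
  columns apart; permutes site order; rejects when the observed value
  is in the *low* tail.
* **MaxChi**: per pair, the max over breakpoints of the 2×2 χ² of
  left/right × match/mismatch over polymorphic columns (margins are
  fixed per pair, so χ² = m(ad−bc)²/(k(m−k)(m−D)D)); statistic is the
  max over pairs; reports breakpoint and maximising pair. The argmax
  is the first column attaining the maximum (ties along a
  mismatch-free plateau are equivalent tables).
* **NSS**: mean compatibility of adjacent informative sites; rejects
  in the high tail (clustered compatibility = blocks).
* **GENECONV-like**: per pair, scores polymorphic columns +1 for match
  and −(1−m)/m for mismatch (m = the pair's mismatch rate, making the
  expected column score zero), and takes the best-scoring run
  (Kadane); the global best run over pairs is the inner fragment.
  Pairs with no mismatches over polymorphic columns are skipped.

Attribution: the pair named by a significant GENECONV-like result,
else MaxChi's maximising pair — a declared rule, since no published
per-pair attribution procedure exists to reproduce. Both
single-attribution (percentages sum to 100) and multiple-attribution
summaries are available. Event presence/absence profiles (genes tested
in ≥2 strains) are average-linkage clustered on Jaccard distance;
all-zero profiles get distance 0 (a flat join).

Calibration measured by the test suite at these defaults: per-detector
null rejection ≤ 8% at α = 0.05 over 200 clonal quartets, consensus
null rate ≤ 5% and below the mean single-detector rate. The consensus
is *not* guaranteed to sit below every single detector's rate — false
positives are correlated across detectors on the same segment — so
that stronger phrasing is deliberately not asserted. No
multiple-testing correction is applied across segments in the headline
counts (raw-count reporting); Benjamini–Hochberg-adjusted counts can
be derived from the per-segment TSV.

## Diversity and phylogeny

π is the mean per-site difference fraction over ingroup pairs under
complete deletion (columns with any ingroup gap/ambiguity excluded
from the denominator); the outgroup orients quartets but never enters
π, S or ts/tv. ts/tv is counted directly from pairwise differences
(A↔G, C↔T are transitions) rather than estimated by maximum
likelihood: at these divergences direct counts are exact,
oracle-checkable, and sufficient for a recombinant/non-recombinant
contrast; the ratio is reported as undefined when no transversions
occur. The contrast is Welch's t with Welch–Satterthwaite df and
t-based 95% CIs per group.

Trees: Jukes–Cantor distances (pairwise deletion per pair; p ≥ 0.75
raises a saturation error naming the pair), Saitou–Nei neighbor
joining with negative branch lengths clamped to zero and the
difference moved to the adjacent branch. ML/Bayesian reconstruction
and likelihood-based topology tests are out of scope; NJ plus
Robinson–Foulds congruence answers the operative question (does
recombination distort the tree?) at desk scale. Congruence scan:
segments with < 4 informative sites are flagged low-signal and
excluded from category counts; a discordant segment is attributed to a
designated "mobile" taxon when pruning that taxon alone restores
RF = 0.

## Pipeline and problem sizes

`run_pipeline` chains the stages on files, logs every threshold and
surviving-record count, writes '#'-headed TSVs, Newick trees and a
JSON summary, and fails loudly with the stage name. All permutation
seeds derive deterministically from the config seed, so identical
configurations produce byte-identical reports.

`scripts/acceptance.py` runs the study design at 120 genes, ~2×
coverage (the read-count arithmetic of ~13,000 × 1 kb reads against a
~6.5 Mb genome is ≈2×), 3 expected tracts per genome and 300
permutations — sizes chosen so the whole recomputation is a
few minutes of CPU while every stage still carries enough records to
be statistically meaningful. The test suite uses 200 quartets × 1,000
permutations for detector calibration and 20 replicates for the
1×-coverage proxy, the sizes at which those claims are stated.

## Known limitations

* The two-sequence posterior replaces a multi-read genotyper: it sees
  the contig consensus, not the read pileup, so read-level conflicts
  surface only through the merged base's Phred.
* Coordinate-based "assembly" cannot create misassemblies, so the
  pipeline's robustness to chimeric contigs is untested.
* The ANV confidence interval is one defensible reading of an
  under-specified procedure ("adjusted by the distribution of gene
  size medians"); alternatives (pooled-count intervals) would be
  materially narrower.
* Internal-donor recombination between sampled strains barely moves π
  (distances redistribute among pairs); only external-donor tracts
  reliably inflate it. The diversity contrast therefore speaks to
  imported divergence, not to within-sample shuffling.
* No indel simulation or calling; IUPAC ambiguity handling is
  conservative skipping.
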