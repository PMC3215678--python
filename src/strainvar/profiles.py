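"""SNP-profile machinery over concatenated shared segments.

Every column of the all-strain concatenation is compared to a
consensus and classified as monomorphic, a singleton (one strain
differs), shared biallelic (the single non-consensus allele is carried
by ≥2 strains) or polyallelic (≥3 alleles with ≥2 non-consensus
carriers).  Counts are reported in fixed non-overlapping windows
(250 nt by default), and shared-biallelic columns are grouped by their
carrier strain set into named patterns — the shared-segment SNP
profiles used to spot strains with common ancestry or exchanged DNA.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from .orthomap import SegmentMatrix

DNA = set("ACGT")


@dataclass
class SiteClass:
    position: int                 # 1-based concatenated coordinate
    site_class: str               # monomorphic|singleton|shared_biallelic|polyallelic
    consensus: str
    carriers: frozenset[str]      # strains carrying a non-consensus allele
    bases: dict[str, str]

    def __post_init__(self) -> None:
        if self.site_class == "singleton" and len(self.carriers) != 1:
            raise ValueError("singleton must name exactly one strain")


@dataclass
class WindowProfile:
    index: int
    start: int                    # 1-based inclusive
    end: int
    singleton_by_strain: dict[str, int]
    shared_count: int
    polyallelic_count: int

    @property
    def span(self) -> int:
        return self.end - self.start + 1


def consensus_sequence(matrix: SegmentMatrix, tiebreak: str) -> str:
    """Per-column plurality base; plurality ties resolve to the
    tiebreak strain's base.

    Gap characters neither vote nor can be consensus.  The half-half
    tie rule is generalised: whenever the plurality is tied, the
    designated strain's base wins (falling back to the alphabetically
    first tied base if that strain holds a gap there).  An all-gap
    column is an upstream filtering failure and raises.
    """
    if tiebreak not in matrix.ids:
        raise ValueError(f"tiebreak strain {tiebreak!r} not in matrix")
    tb_row = matrix.row(tiebreak)
    out = []
    for j in range(matrix.length):
        votes = Counter(r[j] for r in matrix.rows if r[j] in DNA)
        if not votes:
            raise ValueError(f"column {j + 1} is all gaps/ambiguity")
        top = max(votes.values())
        tied = sorted(b for b, c in votes.items() if c == top)
        if len(tied) == 1:
            out.append(tied[0])
        elif tb_row[j] in DNA:
            out.append(tb_row[j])
        else:
            out.append(tied[0])
    return "".join(out)


def classify_sites(matrix: SegmentMatrix, consensus: str) -> list[SiteClass]:
    """Assign exactly one class to every column (a partition)."""
    if len(consensus) != matrix.length:
        raise ValueError("consensus length mismatch")
    sites: list[SiteClass] = []
    for j in range(matrix.length):
        bases = {name: row[j] for name, row in zip(matrix.ids, matrix.rows)}
        called = {n: b for n, b in bases.items() if b in DNA}
        alleles = set(called.values())
        carriers = frozenset(n for n, b in called.items() if b != consensus[j])
        if len(alleles) <= 1:
            cls = "monomorphic"
        elif len(carriers) == 1:
            cls = "singleton"
        elif len(alleles) >= 3:
            cls = "polyallelic"
        else:
            cls = "shared_biallelic"
        sites.append(SiteClass(j + 1, cls, consensus[j], carriers, bases))
    return sites


def window_counts(sites: list[SiteClass], strains: list[str],
                  window: int = 250) -> list[WindowProfile]:
    """Non-overlapping fixed windows over the concatenation; the final
    window may be short."""
    if window <= 0:
        raise ValueError("window must be positive")
    if not sites:
        return []
    total = max(s.position for s in sites)
    profiles: list[WindowProfile] = []
    for w, start in enumerate(range(1, total + 1, window)):
        end = min(start + window - 1, total)
        profiles.append(WindowProfile(
            w, start, end, {s: 0 for s in strains}, 0, 0))
    for s in sites:
        prof = profiles[(s.position - 1) // window]
        if s.site_class == "singleton":
            (strain,) = s.carriers
            prof.singleton_by_strain[strain] = (
                prof.singleton_by_strain.get(strain, 0) + 1)
        elif s.site_class == "shared_biallelic":
            prof.shared_count += 1
        elif s.site_class == "polyallelic":
            prof.polyallelic_count += 1
    return profiles


def shared_pattern_detection(
    sites: list[SiteClass], min_columns: int = 2,
) -> list[dict]:
    """Group shared-biallelic columns by carrier strain set.

    Carrier sets backed by ≥ ``min_columns`` columns become named
    patterns (A, B, ... by decreasing column count) — the repeated SNP
    patterns that mark strain subsets sharing branches or exchanged
    tracts.
    """
    groups: dict[frozenset[str], list[int]] = {}
    for s in sites:
        if s.site_class == "shared_biallelic":
            groups.setdefault(s.carriers, []).append(s.position)
    ranked = sorted(
        ((carriers, pos) for carriers, pos in groups.items()
         if len(pos) >= min_columns),
        key=lambda kv: (-len(kv[1]), sorted(kv[0])),
    )
    out = []
    for i, (carriers, positions) in enumerate(ranked):
        name = chr(ord("A") + i) if i < 26 else f"P{i}"
        out.append({"pattern": name, "strains": sorted(carriers),
                    "n_columns": len(positions), "positions": sorted(positions)})
    return out
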