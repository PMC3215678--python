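"""Sequence/quality containers and file formats.

FASTQ records use Sanger Phred+33 encoding throughout.  FASTA and FASTQ
parsing is delegated to Biopython; this module adds the validation the
pipeline relies on (sequence/quality length agreement, IUPAC alphabet)
and a small quality-annotated sequence container shared by all stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

IUPAC_NT = set("ACGTRYSWKMBDHVN")

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN-", "TGCAYRSWMKVHDBN-")


class FormatError(ValueError):
    """Malformed sequence input; the message names the offending record."""


@dataclass
class QualSeq:
    """A nucleotide sequence with per-base Phred qualities.

    Used for reads, contigs and (with synthetic Q) reference ORFs.
    ``meta`` carries simulation provenance (source replicon and 0-based
    start coordinate) where available.
    """

    id: str
    seq: str
    quals: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.quals = np.asarray(self.quals, dtype=np.int64)
        if len(self.seq) != len(self.quals):
            raise FormatError(
                f"record {self.id!r}: sequence length {len(self.seq)} != "
                f"quality length {len(self.quals)}"
            )
        bad = set(self.seq.upper()) - IUPAC_NT
        if bad:
            raise FormatError(
                f"record {self.id!r}: non-IUPAC characters {sorted(bad)!r}"
            )

    def __len__(self) -> int:
        return len(self.seq)

    def reverse_complement(self) -> "QualSeq":
        return QualSeq(
            self.id,
            self.seq.translate(_COMPLEMENT)[::-1],
            self.quals[::-1].copy(),
            dict(self.meta),
        )


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def read_fastq(path: str | Path) -> list[QualSeq]:
    """Read Sanger FASTQ into QualSeq records.

    Qualities are validated to lie in [0, 93]; a record whose quality
    string disagrees in length with its sequence is reported by name
    (Biopython raises during parsing; the error is re-wrapped).
    """
    out: list[QualSeq] = []
    try:
        for rec in SeqIO.parse(str(path), "fastq"):
            quals = np.asarray(
                rec.letter_annotations["phred_quality"], dtype=np.int64
            )
            if quals.size and (quals.min() < 0 or quals.max() > 93):
                raise FormatError(
                    f"record {rec.id!r}: Phred quality outside [0, 93]"
                )
            out.append(QualSeq(rec.id, str(rec.seq).upper(), quals))
    except ValueError as exc:  # Biopython length-mismatch etc.
        if isinstance(exc, FormatError):
            raise
        raise FormatError(f"{path}: {exc}") from exc
    return out


def write_fastq(records: Iterable[QualSeq], path: str | Path) -> None:
    recs = []
    for q in records:
        rec = SeqRecord(Seq(q.seq), id=q.id, description="")
        rec.letter_annotations["phred_quality"] = [int(x) for x in q.quals]
        recs.append(rec)
    SeqIO.write(recs, str(path), "fastq")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into an id → uppercase-sequence mapping (order preserved)."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        bad = set(seq) - IUPAC_NT
        if bad:
            raise FormatError(
                f"record {rec.id!r}: non-IUPAC characters {sorted(bad)!r}"
            )
        out[rec.id] = seq
    return out


def write_fasta(seqs: dict[str, str] | Iterable[tuple[str, str]],
                path: str | Path, width: int = 70) -> None:
    items = seqs.items() if isinstance(seqs, dict) else seqs
    with open(path, "w") as fh:
        for name, seq in items:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def as_qualseqs(seqs: dict[str, str], q: int = 60) -> list[QualSeq]:
    """Wrap plain sequences with a constant Phred quality.

    Finished (complete-genome) references carry no quality file; Q=60
    reflects finished-sequence error rates.
    """
    return [QualSeq(name, s, np.full(len(s), q, dtype=np.int64))
            for name, s in seqs.items()]
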