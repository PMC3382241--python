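"""Sequence and annotation I/O, plus the coordinate conventions used package-wide.

All internal coordinates are 0-based half-open intervals on the forward
(top) strand of a scaffold; conversion to 1-based inclusive coordinates
happens only at file-format boundaries (GFF3).  Sequences are restricted to
the alphabet ``{A, C, G, T, N}``: lower-case input is rejected rather than
coerced, because the motif-mismatch semantics of the scanners downstream are
defined only over that alphabet.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

VALID_ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class SequenceAlphabetError(ValueError):
    """A sequence contains characters outside {A, C, G, T, N}."""


def _validate_alphabet(seq: str, context: str = "sequence") -> None:
    for i, ch in enumerate(seq):
        if ch not in VALID_ALPHABET:
            raise SequenceAlphabetError(
                f"illegal character {ch!r} at position {i} in {context}; "
                "allowed alphabet is A, C, G, T, N (upper-case only)"
            )


def revcomp(seq: str) -> str:
    """Reverse complement over {A, C, G, T, N}; N maps to N.

    An involution: ``revcomp(revcomp(s)) == s``.
    """
    _validate_alphabet(seq)
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True, order=True)
class Interval:
    """0-based half-open genomic interval with a strand."""

    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return self.start < other.end and other.start < self.end


def find_gaps(seq: str, min_gap: int = 10) -> list[Interval]:
    """Runs of N of length >= ``min_gap``, as sorted disjoint intervals."""
    gaps: list[Interval] = []
    i = 0
    n = len(seq)
    while i < n:
        if seq[i] == "N":
            j = i
            while j < n and seq[j] == "N":
                j += 1
            if j - i >= min_gap:
                gaps.append(Interval(i, j))
            i = j
        else:
            i += 1
    return gaps


@dataclass
class Scaffold:
    """A named nucleotide sequence with assembly-gap (N-run) annotations."""

    id: str
    seq: str
    gaps: list[Interval] = field(default_factory=list)

    @classmethod
    def from_seq(cls, id: str, seq: str, min_gap: int = 10) -> "Scaffold":
        if not seq:
            raise ValueError(f"scaffold {id!r} has an empty sequence")
        _validate_alphabet(seq, context=f"scaffold {id!r}")
        return cls(id=id, seq=seq, gaps=find_gaps(seq, min_gap=min_gap))

    def __len__(self) -> int:
        return len(self.seq)

    def in_gap(self, iv: Interval) -> bool:
        return any(iv.overlaps(g) for g in self.gaps)


def read_fasta(path: str | Path, min_gap: int = 10) -> list[Scaffold]:
    """Read a FASTA file into validated scaffolds, preserving record order.

    Gap intervals (runs of >= ``min_gap`` N) are computed on load.  An empty
    file yields an empty list with a logged warning.
    """
    path = Path(path)
    scaffolds: list[Scaffold] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq)
        if not seq:
            raise ValueError(f"FASTA record {rec.id!r} in {path} is empty")
        _validate_alphabet(seq, context=f"record {rec.id!r} in {path}")
        scaffolds.append(Scaffold(id=rec.id, seq=seq, gaps=find_gaps(seq, min_gap)))
    if not scaffolds:
        logger.warning("no FASTA records found in %s", path)
    return scaffolds


def write_fasta(scaffolds: Iterable[Scaffold], path: str | Path, width: int = 70) -> None:
    records = [SeqRecord(Seq(s.seq), id=s.id, description="") for s in scaffolds]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def write_gff3(segments: Sequence, path: str | Path, source: str = "igloci") -> None:
    """Write gene segments as GFF3.

    Internal 0-based half-open coordinates become 1-based inclusive columns
    4/5; segment type maps to ``{V,D,J,C}_gene_segment``; functionality,
    defect tags and family assignment travel in column 9 attributes.
    Segments are sorted by (scaffold, start).
    """
    rows = sorted(segments, key=lambda s: (s.scaffold_id, s.coding_interval.start))
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, seg in enumerate(rows):
            iv = seg.coding_interval
            attrs = [f"ID={seg.segment_type}_segment_{i + 1}",
                     f"functionality={seg.functionality}"]
            if seg.defect_reasons:
                attrs.append("defects=" + ",".join(seg.defect_reasons))
            fam = getattr(seg, "family_id", None)
            if fam is not None:
                attrs.append(f"family={fam}")
            fh.write("\t".join([
                seg.scaffold_id,
                source,
                f"{seg.segment_type}_gene_segment",
                str(iv.start + 1),
                str(iv.end),
                ".",
                iv.strand,
                ".",
                ";".join(attrs),
            ]) + "\n")
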