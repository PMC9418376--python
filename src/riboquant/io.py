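"""File I/O: FASTQ reads and SAM/BAM alignments."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import pysam
from Bio import SeqIO

__all__ = ["Read", "AlignmentRecord", "read_fastq", "write_fastq",
           "read_alignments", "write_sam"]


@dataclass(frozen=True)
class Read:
    id: str
    sequence: str
    quality: str | None = None


@dataclass(frozen=True)
class AlignmentRecord:
    """Ungapped alignment, 1-based closed interval [start, end]."""

    read_id: str
    molecule: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def read_fastq(path: str | Path) -> Iterator[Read]:
    for rec in SeqIO.parse(str(path), "fastq"):
        qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
        yield Read(rec.id, str(rec.seq), qual)


def write_fastq(reads: Iterable[Read], path: str | Path, quality_char: str = "I") -> int:
    n = 0
    with open(path, "w") as fh:
        for r in reads:
            qual = r.quality if r.quality is not None else quality_char * len(r.sequence)
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{qual}\n")
            n += 1
    return n


def read_alignments(path: str | Path) -> list[AlignmentRecord]:
    """Load mapped records from SAM/BAM (pysam; format inferred from content)."""
    records: list[AlignmentRecord] = []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for aln in fh.fetch(until_eof=True):
            if aln.is_unmapped:
                continue
            records.append(
                AlignmentRecord(
                    read_id=aln.query_name,
                    molecule=aln.reference_name,
                    start=aln.reference_start + 1,       # 0-based -> 1-based
                    end=aln.reference_end,               # exclusive 0-based == closed 1-based
                )
            )
    return records


def write_sam(records: Iterable[AlignmentRecord], lengths: dict[str, int],
              path: str | Path, sequences: dict[str, str] | None = None) -> int:
    """Write ungapped records as plain-text SAM (FLAG 0, full-match CIGAR)."""
    n = 0
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        for name, L in lengths.items():
            fh.write(f"@SQ\tSN:{name}\tLN:{L}\n")
        for rec in records:
            seq = "*"
            if sequences is not None:
                seq = sequences[rec.molecule][rec.start - 1 : rec.end]
            fh.write(
                f"{rec.read_id}\t0\t{rec.molecule}\t{rec.start}\t255\t"
                f"{rec.length}M\t*\t0\t0\t{seq}\t*\n"
            )
            n += 1
    return n
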