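"""FASTA and table I/O shared across the pipeline (Biopython-backed)."""

from __future__ import annotations

import os
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioRecord

from .model import SequenceRecord


def read_fasta(path) -> list[SequenceRecord]:
    """Read a FASTA (or FASTQ, by extension) file into SequenceRecords."""
    fmt = "fastq" if str(path).endswith((".fq", ".fastq")) else "fasta"
    return [SequenceRecord(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), fmt)]


def write_fasta(records: Iterable[SequenceRecord], path, width: int = 60) -> None:
    """Write records as FASTA wrapped at ``width`` columns."""
    os.makedirs(os.path.dirname(os.path.abspath(str(path))), exist_ok=True)
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def to_bio(records: Iterable[SequenceRecord]) -> list[BioRecord]:
    return [BioRecord(Seq(r.seq), id=r.id, description="") for r in records]
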