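"""FASTA reading/writing for protein records."""

from __future__ import annotations

import os
from typing import Iterable

from Bio import SeqIO

from .domain_scan import ProteinRecord


def read_fasta(path: str | os.PathLike) -> list[ProteinRecord]:
    """Load a multi-record protein FASTA (wrapped or unwrapped)."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(
            ProteinRecord(
                id=rec.id,
                sequence=str(rec.seq),
                description=rec.description if rec.description != rec.id else None,
            )
        )
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | os.PathLike) -> None:
    """Write records wrapped at 60 columns (byte-deterministic)."""
    with open(path, "w") as fh:
        fh.write(format_fasta(records))


def format_fasta(records: Iterable[ProteinRecord]) -> str:
    chunks = []
    for rec in records:
        header = rec.id if not rec.description else f"{rec.id} {rec.description}"
        chunks.append(f">{header}\n")
        seq = rec.sequence
        for i in range(0, len(seq), 60):
            chunks.append(seq[i : i + 60] + "\n")
    return "".join(chunks)
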