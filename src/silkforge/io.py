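"""Shared sequence and table readers/writers.

FASTA/FASTQ handling is delegated to Biopython's SeqIO; the wrappers here
add the dialect rules the rest of the package relies on (sequences
uppercased on read, duplicate-id detection, Sanger Phred+33 qualities) and
keep every on-disk artefact plain text.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "write_fastq",
    "write_tsv",
    "read_tsv",
]


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into ``[(id, sequence), ...]``.

    Sequences are uppercased and multi-line records concatenated.
    Duplicate ids or empty sequences raise ``ValueError``.
    """
    path = Path(path)
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    dupes: list[str] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"empty sequence for record {rec.id!r} in {path}")
        if rec.id in seen:
            dupes.append(rec.id)
        seen.add(rec.id)
        records.append((rec.id, seq))
    if dupes:
        raise ValueError(f"duplicate ids in {path}: {sorted(set(dupes))}")
    return records


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path, width: int = 60) -> None:
    records = list(records)
    if not records:
        raise ValueError("refusing to write empty FASTA")
    recs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(recs)


def read_fastq(path: str | Path) -> list[tuple[str, str, str]]:
    """Read FASTQ (Sanger Phred+33) into ``[(id, sequence, quality), ...]``."""
    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
        out.append((rec.id, str(rec.seq).upper(), qual))
    return out


def write_fastq(records: Iterable[tuple[str, str, str | None]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq, qual in records:
            if qual is None:
                qual = "I" * len(seq)
            if len(qual) != len(seq):
                raise ValueError(f"quality/sequence length mismatch for {name!r}")
            fh.write(f"@{name}\n{seq}\n+\n{qual}\n")


def write_tsv(rows: Iterable[Sequence], path: str | Path, header: Sequence[str] | None = None) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        if header is not None:
            w.writerow(header)
        for row in rows:
            w.writerow(row)


def read_tsv(path: str | Path, header: bool = True) -> tuple[list[str] | None, list[list[str]]]:
    with open(path, newline="") as fh:
        r = csv.reader(fh, delimiter="\t")
        rows = list(r)
    if not rows:
        return (None, [])
    if header:
        return (rows[0], rows[1:])
    return (None, rows)
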