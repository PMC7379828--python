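"""Thin FASTA/FASTQ readers and writers (Biopython-backed, gzip-aware)."""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable, List, Tuple

from Bio import SeqIO


def _open(path, mode="rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def _fmt(path) -> str:
    name = str(path)
    if name.endswith(".gz"):
        name = name[:-3]
    if name.endswith((".fa", ".fasta", ".fna")):
        return "fasta"
    return "fastq"


def read_sequences(path) -> List[Tuple[str, str]]:
    """All (record_id, uppercase sequence) records of a FASTA/FASTQ file."""
    with _open(path) as fh:
        return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(fh, _fmt(path))]


def read_pairs(path1, path2) -> List[Tuple[str, str]]:
    """Mate-paired sequences from two synchronised FASTQ/FASTA files."""
    r1 = read_sequences(path1)
    r2 = read_sequences(path2)
    if len(r1) != len(r2):
        raise ValueError(f"mate files differ in record count: {len(r1)} vs {len(r2)}")
    return [(s1, s2) for (_, s1), (_, s2) in zip(r1, r2)]


def write_fastq(records: Iterable[Tuple[str, str]], path) -> int:
    """Write (id, seq) records as FASTQ with uniform placeholder qualities."""
    n = 0
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")
            n += 1
    return n


def write_fasta(records: Iterable[Tuple[str, str]], path) -> int:
    n = 0
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")
            n += 1
    return n
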