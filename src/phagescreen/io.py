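"""File helpers: FASTQ/FASTA, design tables, digests.

FASTQ parsing uses Biopython's ``FastqGeneralIterator`` (the fast
path); writing emits standard 4-line records with a constant
placeholder quality, since no downstream step consumes qualities.
"""

from __future__ import annotations

import gzip
import hashlib
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

__all__ = [
    "read_fastq_sequences",
    "write_fastq",
    "read_fasta",
    "read_design",
    "sha256_file",
]


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq_sequences(path: str | Path) -> list[str]:
    """Sequences of a (optionally gzipped) FASTQ file."""
    with _open_text(path) as fh:
        return [seq for _title, seq, _qual in FastqGeneralIterator(fh)]


def write_fastq(
    path: str | Path,
    sequences: Iterable[str],
    id_prefix: str = "read",
    quality_char: str = "I",
) -> int:
    """Write sequences as 4-line FASTQ records; returns record count."""
    n = 0
    with _open_text(path, "wt") as fh:
        for i, seq in enumerate(sequences, start=1):
            fh.write(f"@{id_prefix}_{i}\n{seq}\n+\n{quality_char * len(seq)}\n")
            n = i
    return n


def read_fasta(path: str | Path) -> dict[str, str]:
    """id -> sequence for a FASTA file."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def read_design(path: str | Path) -> pd.DataFrame:
    """Design TSV with at least sample_id / condition / replicate columns
    (optionally a ``fastq`` path column)."""
    df = pd.read_csv(path, sep="\t")
    needed = {"sample_id", "condition", "replicate"}
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"design lacks columns {sorted(missing)}")
    return df


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
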