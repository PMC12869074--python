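"""FASTA/FASTQ input handling (plain or gzip) built on Bio.SeqIO."""
from __future__ import annotations

import gzip
import os
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

PathLike = str | os.PathLike

_FASTA_EXT = {".fa", ".fasta", ".fna", ".ffn", ".frn"}
_FASTQ_EXT = {".fq", ".fastq"}


def sniff_format(path: PathLike) -> str:
    """Infer 'fasta' or 'fastq' from the file name (ignoring .gz)."""
    suffixes = Path(path).suffixes
    if suffixes and suffixes[-1] == ".gz":
        suffixes = suffixes[:-1]
    ext = suffixes[-1].lower() if suffixes else ""
    if ext in _FASTA_EXT:
        return "fasta"
    if ext in _FASTQ_EXT:
        return "fastq"
    raise ValueError(f"cannot infer sequence format from {path!r}")


def open_text(path: PathLike, mode: str = "rt"):
    """Open a possibly-gzipped text file."""
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def iter_records(source, fmt: str | None = None) -> Iterator[SeqRecord]:
    """Yield SeqRecords from a path or pass through an iterable.

    ``source`` may be a FASTA/FASTQ path (gzip ok), an iterable of
    SeqRecords, of ``(id, seq)`` tuples, or of bare sequence strings.
    """
    if isinstance(source, (str, os.PathLike)):
        fmt = fmt or sniff_format(source)
        if not os.path.exists(source):
            raise FileNotFoundError(f"input file not found: {source}")
        with open_text(source) as fh:
            yield from SeqIO.parse(fh, fmt)
        return
    for i, rec in enumerate(source):
        if isinstance(rec, SeqRecord):
            yield rec
        elif isinstance(rec, str):
            yield SeqRecord(Seq(rec), id=f"seq{i}", description="")
        else:
            rid, seq = rec
            yield SeqRecord(Seq(seq), id=str(rid), description="")


def write_records(records: Iterable[SeqRecord], path: PathLike, fmt: str | None = None) -> int:
    """Write records to FASTA/FASTQ (gzip by extension); returns count."""
    fmt = fmt or sniff_format(path)
    with open_text(path, "wt") as fh:
        return SeqIO.write(records, fh, fmt)
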