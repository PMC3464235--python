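"""FASTA/FASTQ I/O and the run-length sidecar format.

Sequence parsing goes through Biopython's fast iterators; writing is plain
text so the files round-trip bit-exactly.  The sidecar format stores the
run lengths needed to decompress HC-transformed reads: one tab-separated
record per read — read id, compressed length, comma-separated run lengths.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Iterator, TextIO

from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .errors import InputFormatError
from .hc import HCRecord


def read_fasta(path: str | Path) -> Iterator[tuple[str, str]]:
    """Yield ``(read_id, seq)``; multi-line FASTA accepted, id = first token."""
    with open(path) as fh:
        for title, seq in SimpleFastaParser(fh):
            yield title.split()[0], seq.upper()


def read_fastq(path: str | Path) -> Iterator[tuple[str, str]]:
    """Yield ``(read_id, seq)``; qualities are parsed but dropped (the HC
    transformation defines no quality-string counterpart)."""
    with open(path) as fh:
        for title, seq, _qual in FastqGeneralIterator(fh):
            yield title.split()[0], seq.upper()


def read_seqs(path: str | Path) -> Iterator[tuple[str, str]]:
    """Dispatch on extension: .fq/.fastq -> FASTQ, anything else -> FASTA."""
    suffix = Path(path).suffix.lower()
    if suffix in {".fq", ".fastq"}:
        return read_fastq(path)
    return read_fasta(path)


def write_fasta(records: Iterable[tuple[str, str]], out: str | Path | TextIO, width: int = 80) -> None:
    own = isinstance(out, (str, Path))
    fh = open(out, "w") if own else out
    try:
        for read_id, seq in records:
            fh.write(f">{read_id}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
    finally:
        if own:
            fh.close()


def write_fastq(records: Iterable[tuple[str, str, str]], out: str | Path) -> None:
    with open(out, "w") as fh:
        for read_id, seq, qual in records:
            fh.write(f"@{read_id}\n{seq}\n+\n{qual}\n")


def write_runlengths(records: Iterable[HCRecord], out: str | Path) -> None:
    """Write the run-length sidecar for a set of compressed records."""
    with open(out, "w") as fh:
        for rec in records:
            runs = ",".join(str(r) for r in rec.run_lengths)
            fh.write(f"{rec.read_id}\t{len(rec.compressed_seq)}\t{runs}\n")


def read_runlengths(path: str | Path) -> Iterator[tuple[str, list[int]]]:
    """Yield ``(read_id, run_lengths)`` from a sidecar file."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise InputFormatError(f"sidecar line {lineno}: expected 3 fields, got {len(parts)}")
            read_id, n, runs_str = parts
            runs = [int(x) for x in runs_str.split(",")] if runs_str else []
            if len(runs) != int(n):
                raise InputFormatError(
                    f"sidecar line {lineno}: declared length {n} != {len(runs)} run lengths"
                )
            yield read_id, runs
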