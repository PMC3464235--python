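"""Concatenation of compressed long reads into a pseudo-reference.

Short-read aligners expect a small number of chromosome-sized reference
sequences, not 10^5 separate kilobase contigs.  The compressed long reads
are therefore concatenated into pseudo-chromosome "chunks" separated by
poly-N spacers whose length equals the original short-read length, so no
short read can align across the junction between two long reads.  The
layout is recorded in an index that maps any global chunk position back to
(long read, local position) or to a spacer.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

from .errors import ConfigurationError, ContractViolationError
from .hc import HCRecord
from .seqio import write_fasta


class _Spacer:
    def __repr__(self) -> str:  # pragma: no cover
        return "SPACER"


#: Sentinel returned by :func:`ConcatenatedReference.locate` for poly-N positions.
SPACER = _Spacer()

CHUNK_PREFIX = "hc_chunk"


@dataclass
class Interval:
    lr_id: str
    chunk_id: int
    start: int  # global, 0-based
    end: int  # global, half-open


class ConcatenatedReference:
    """Compressed LRs packed into poly-N-separated chunks with an invertible index."""

    def __init__(self, spacer_len: int, max_chunk_len: int) -> None:
        if spacer_len < 1:
            raise ConfigurationError("spacer_len must be >= 1")
        self.spacer_len = spacer_len
        self.max_chunk_len = max_chunk_len
        self.chunks: list[str] = []
        self.index: list[Interval] = []
        self._starts_by_chunk: list[list[int]] = []
        self._ivals_by_chunk: list[list[Interval]] = []
        self._by_lr: dict[str, Interval] = {}

    @property
    def chunk_names(self) -> list[str]:
        return [f"{CHUNK_PREFIX}_{i:03d}" for i in range(len(self.chunks))]

    def chunk_id_for(self, name: str) -> int:
        prefix = f"{CHUNK_PREFIX}_"
        if not name.startswith(prefix):
            raise ContractViolationError(f"unknown chunk name {name!r}")
        cid = int(name[len(prefix):])
        if not 0 <= cid < len(self.chunks):
            raise ContractViolationError(f"unknown chunk name {name!r}")
        return cid

    def interval_for(self, lr_id: str) -> Interval:
        return self._by_lr[lr_id]

    def locate(self, chunk_id: int, global_pos: int) -> tuple[str, int] | _Spacer:
        """Map a 0-based global chunk position to (lr_id, local_pos) or SPACER."""
        if not 0 <= chunk_id < len(self.chunks):
            raise ContractViolationError(f"chunk {chunk_id} out of range")
        if not 0 <= global_pos < len(self.chunks[chunk_id]):
            raise ContractViolationError(
                f"position {global_pos} out of bounds for chunk {chunk_id}"
            )
        starts = self._starts_by_chunk[chunk_id]
        i = bisect_right(starts, global_pos) - 1
        if i < 0:
            return SPACER
        ival = self._ivals_by_chunk[chunk_id][i]
        if global_pos < ival.end:
            return ival.lr_id, global_pos - ival.start
        return SPACER


def build_reference(
    compressed_lrs: Iterable[HCRecord],
    spacer_len: int,
    max_chunk_len: int = 250_000_000,
) -> ConcatenatedReference:
    """Pack compressed LRs into chunks, preserving input order.

    A new chunk is started when appending the next LR (plus the spacer
    separating it from the previous one) would exceed ``max_chunk_len``.
    No spacer trails the final LR of a chunk.
    """
    ref = ConcatenatedReference(spacer_len, max_chunk_len)
    spacer = "N" * spacer_len
    parts: list[str] = []
    cur_len = 0

    def _close_chunk() -> None:
        nonlocal parts, cur_len
        if parts:
            ref.chunks.append("".join(parts))
            parts = []
            cur_len = 0

    for rec in compressed_lrs:
        lr_len = len(rec.compressed_seq)
        if lr_len == 0:
            continue
        if lr_len > max_chunk_len:
            raise ConfigurationError(
                f"LR {rec.read_id!r} (compressed length {lr_len}) exceeds max_chunk_len {max_chunk_len}"
            )
        if parts and cur_len + spacer_len + lr_len > max_chunk_len:
            _close_chunk()
        chunk_id = len(ref.chunks)
        if parts:
            parts.append(spacer)
            cur_len += spacer_len
        start = cur_len
        parts.append(rec.compressed_seq)
        cur_len += lr_len
        ival = Interval(rec.read_id, chunk_id, start, cur_len)
        ref.index.append(ival)
        ref._by_lr[rec.read_id] = ival
    _close_chunk()

    for cid in range(len(ref.chunks)):
        ivals = [iv for iv in ref.index if iv.chunk_id == cid]
        ref._ivals_by_chunk.append(ivals)
        ref._starts_by_chunk.append([iv.start for iv in ivals])
    return ref


def write_reference(ref: ConcatenatedReference, fasta_path: str | Path, index_path: str | Path) -> None:
    """Write the chunks as FASTA (the aligner's reference) and the index as TSV."""
    write_fasta(zip(ref.chunk_names, ref.chunks), fasta_path)
    with open(index_path, "w") as fh:
        fh.write("lr_id\tchunk\tstart\tend\n")
        for iv in ref.index:
            fh.write(f"{iv.lr_id}\t{iv.chunk_id}\t{iv.start}\t{iv.end}\n")


def iter_positions(ref: ConcatenatedReference) -> Iterator[tuple[int, int, object]]:
    """Exhaustive (chunk_id, global_pos, locate-result) scan — test helper."""
    for cid, chunk in enumerate(ref.chunks):
        for pos in range(len(chunk)):
            yield cid, pos, ref.locate(cid, pos)
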