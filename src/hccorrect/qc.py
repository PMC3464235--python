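"""Quality control of compressed short reads.

Very short compressed reads and reads with uncertain bases ('N') cause
spurious alignments, so they are dropped before the alignment stage.  Both
counts are taken on the COMPRESSED sequence: an N run of any length
compresses to a single N and counts once.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

from .hc import HCRecord


@dataclass
class QCParams:
    """Filter thresholds, counted on the compressed sequence.

    min_non_n: minimum number of non-N compressed bases (default 40 — a
        75 bp read compresses to ~48 bp, so this keeps typical reads while
        dropping those too short to align reliably).
    max_n: maximum number of N compressed bases (default 1).
    """

    min_non_n: int = 40
    max_n: int = 1

    def __post_init__(self) -> None:
        if self.min_non_n < 0 or self.max_n < 0:
            raise ValueError("QC thresholds must be non-negative")


@dataclass
class QCReport:
    kept: int = 0
    discarded: int = 0
    by_rule: dict[str, int] = field(default_factory=lambda: {"min_non_n": 0, "max_n": 0})

    @property
    def total(self) -> int:
        return self.kept + self.discarded


def passes_qc(compressed_sr: HCRecord, params: QCParams | None = None) -> bool:
    """True iff the compressed read has >= min_non_n non-N bases and <= max_n N bases."""
    params = params or QCParams()
    n_count = compressed_sr.compressed_seq.count("N")
    non_n = len(compressed_sr.compressed_seq) - n_count
    return non_n >= params.min_non_n and n_count <= params.max_n


def filter_srs(
    srs: Iterable[HCRecord], params: QCParams | None = None, report: QCReport | None = None
) -> Iterator[HCRecord]:
    """Yield reads passing QC in input order, tallying discards per rule.

    A read failing both rules is tallied once under each rule but
    discarded once.  Pass a :class:`QCReport` to collect the counts.
    """
    params = params or QCParams()
    for rec in srs:
        n_count = rec.compressed_seq.count("N")
        non_n = len(rec.compressed_seq) - n_count
        ok = True
        if non_n < params.min_non_n:
            ok = False
            if report is not None:
                report.by_rule["min_non_n"] += 1
        if n_count > params.max_n:
            ok = False
            if report is not None:
                report.by_rule["max_n"] += 1
        if report is not None:
            if ok:
                report.kept += 1
            else:
                report.discarded += 1
        if ok:
            yield rec
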