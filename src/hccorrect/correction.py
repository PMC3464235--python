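"""Consensus correction of compressed long reads from short-read pileups.

Correction points come in four types: homopolymer-compression points (a
compressed position whose run length differs between LR and SRs), point
mismatches, deletions and insertions.  Each point is treated independently:
the short-read evidence covering it is decompressed temporarily and the
consensus replaces the point.  Insertions are treated as a whole in the gap
between two compressed positions and inserted only when a majority of the
covering short reads carry an insertion there.

After correction, all remaining (SR-uncovered) compressed positions are
decompressed from the long read's own run lengths, and the output is
trimmed to the span between the left-most and right-most SR-covered points.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

from .align import SRAlignment
from .errors import ContractViolationError
from .hc import HCRecord

#: Sentinel consensus outcome: delete the column.
DELETE = object()


@dataclass
class CorrectionPileup:
    """Per-compressed-position stack of decompressed short-read evidence.

    depth[i] counts the SR alignments with an event (match, mismatch or
    deletion) at position i — the SR-covered depth (SCD).  Insertions alone
    confer no coverage.  ``depth[i] >= len(base_evidence[i]) +
    deletion_evidence[i]`` everywhere, with equality at columns touched by
    no alignment-terminal match (terminal matches cover but abstain).
    """

    lr: HCRecord
    depth: list[int]
    base_evidence: list[list[str]]
    deletion_evidence: list[int]
    insertion_evidence: list[list[str]]  # per gap (i, i+1); "" = covering SR without insertion


@dataclass
class ECLongRead:
    """A corrected, decompressed, trimmed long read.

    covered_mask flags output bases derived from SR-covered positions (or
    from inserted SR evidence); scd carries the source position's SR-covered
    depth per output base.  trim_bounds are half-open compressed-LR
    coordinates of the SR-covered span.
    """

    read_id: str
    source_id: str
    seq: str
    covered_mask: list[bool]
    scd: list[int]
    trim_bounds: tuple[int, int]


def build_pileup(lr: HCRecord, alignments: Iterable[SRAlignment]) -> CorrectionPileup:
    """Stack decompressed SR evidence over the compressed LR, order-invariantly.

    Match/mismatch events contribute the SR's full decompressed run for
    that column (e.g. "TTT" when the SR had a 3-run); deletion events count
    against the column; insertion events contribute the decompressed
    inserted string to the gap after their anchor.  Every gap interior to
    an alignment's span additionally records "" for alignments without an
    insertion there, so insertion majorities are over all covering SRs.

    The SR's terminal compressed positions get special treatment: a
    homopolymer run truncated by the read boundary reports only a lower
    bound on its true length, so a terminal match contributes coverage but
    abstains from the run-length vote; insertions involving terminal SR
    positions — typical read-end overhang artifacts — are dropped.
    Terminal mismatches still testify (base identity is informative even
    when the run length is not).
    """
    n = len(lr.compressed_seq)
    depth = [0] * n
    base_evidence: list[list[str]] = [[] for _ in range(n)]
    deletion_evidence = [0] * n
    insertion_evidence: list[list[str]] = [[] for _ in range(max(n - 1, 0))]
    for aln in alignments:
        if aln.lr_id != lr.read_id:
            raise ContractViolationError(
                f"alignment of {aln.sr_id!r} targets {aln.lr_id!r}, not {lr.read_id!r}"
            )
        sr = aln.sr_record
        consumed = [
            ev.sr_pos + (ev.sr_len - 1 if ev.kind == "I" else 0)
            for ev in aln.events
            if ev.sr_pos is not None
        ]
        lo = min(consumed, default=0)
        hi = max(consumed, default=0)
        span_min, span_max = None, None
        inserts: dict[int, str] = {}
        for ev in aln.events:
            if not 0 <= ev.lr_pos < n:
                raise ContractViolationError(
                    f"event at {ev.lr_pos} outside LR {lr.read_id!r} of length {n}"
                )
            terminal = False
            if ev.sr_pos is not None:
                last = ev.sr_pos + (ev.sr_len - 1 if ev.kind == "I" else 0)
                terminal = ev.sr_pos <= lo or last >= hi
            if ev.kind in ("M", "X"):
                depth[ev.lr_pos] += 1
                if not (terminal and ev.kind == "M"):
                    base_evidence[ev.lr_pos].append(sr.run(ev.sr_pos))
            elif ev.kind == "D":
                depth[ev.lr_pos] += 1
                deletion_evidence[ev.lr_pos] += 1
            elif not terminal:  # interior insertion
                ins = "".join(sr.run(ev.sr_pos + t) for t in range(ev.sr_len))
                inserts[ev.lr_pos] = inserts.get(ev.lr_pos, "") + ins
            if ev.kind != "I":
                if span_min is None or ev.lr_pos < span_min:
                    span_min = ev.lr_pos
                if span_max is None or ev.lr_pos > span_max:
                    span_max = ev.lr_pos
        if span_min is not None:
            for gap in range(span_min, span_max):
                insertion_evidence[gap].append(inserts.get(gap, ""))
    return CorrectionPileup(lr, depth, base_evidence, deletion_evidence, insertion_evidence)


def consensus_column(
    lr_base: str, lr_run: int, evidence: Sequence[str], deletions: int = 0
) -> str:
    """Consensus replacement for one covered column.

    Candidates are each distinct decompressed evidence string plus column
    deletion (weighted by the number of deleting SRs).  A strict plurality
    wins; any tie keeps the LR's own decompressed run (conservative: never
    edit without majority support).  With no evidence at all the LR's own
    run is returned.
    """
    own = lr_base * lr_run
    total = len(evidence) + deletions
    if total == 0:
        return own
    counts: Counter = Counter(evidence)
    candidates: list[tuple[object, int]] = list(counts.items())
    if deletions:
        candidates.append((DELETE, deletions))
    best = max(c for _, c in candidates)
    winners = [cand for cand, c in candidates if c == best]
    if len(winners) > 1:
        return own
    winner = winners[0]
    return "" if winner is DELETE else winner  # type: ignore[return-value]


def consensus_insertion(gap_evidence: Sequence[str]) -> str:
    """Consensus insertion for one gap between compressed positions.

    Inserts only when strictly more than half of the covering SRs carry a
    non-empty insertion; the plurality inserted string wins, ties broken by
    lexicographic order (which also prefers the shorter of a prefix pair).
    """
    nonempty = [s for s in gap_evidence if s]
    if 2 * len(nonempty) <= len(gap_evidence):
        return ""
    counts = Counter(nonempty)
    best = max(counts.values())
    return min(s for s, c in counts.items() if c == best)


def correct_lr(
    lr: HCRecord, pileup: CorrectionPileup, min_depth: int = 1
) -> ECLongRead | None:
    """Correct, decompress and trim one long read.

    Within the span from the left-most to the right-most SR-covered
    position, covered columns (depth >= max(1, min_depth)) are replaced by
    their consensus, uncovered columns are decompressed from the LR's own
    run lengths, and interior gaps receive majority insertions.  Positions
    outside the span are discarded.  Returns None when nothing is covered.
    """
    depth = pileup.depth
    covered = [i for i, d in enumerate(depth) if d >= 1]
    if not covered:
        return None
    left, right = covered[0], covered[-1]
    floor = max(1, min_depth)
    pieces: list[str] = []
    mask: list[bool] = []
    scd: list[int] = []

    def _emit(s: str, flag: bool, d: int) -> None:
        pieces.append(s)
        mask.extend([flag] * len(s))
        scd.extend([d] * len(s))

    for i in range(left, right + 1):
        if depth[i] >= floor:
            rep = consensus_column(
                lr.compressed_seq[i],
                lr.run_lengths[i],
                pileup.base_evidence[i],
                pileup.deletion_evidence[i],
            )
        else:
            rep = lr.run(i)
        _emit(rep, depth[i] >= 1, depth[i])
        if i < right:
            ins = consensus_insertion(pileup.insertion_evidence[i])
            if ins:
                _emit(ins, True, min(depth[i], depth[i + 1]))
    seq = "".join(pieces)
    # a consensus deletion at the boundary can leave uncovered bases at the
    # ends; trim to the outermost SR-covered output base
    if not any(mask):
        return None
    first = mask.index(True)
    last = len(mask) - 1 - mask[::-1].index(True)
    seq = seq[first : last + 1]
    mask = mask[first : last + 1]
    scd = scd[first : last + 1]
    return ECLongRead(
        read_id=f"{lr.read_id}/{left}_{right + 1}",
        source_id=lr.read_id,
        seq=seq,
        covered_mask=mask,
        scd=scd,
        trim_bounds=(left, right + 1),
    )


def raw_segment(lr: HCRecord, trim_bounds: tuple[int, int]) -> str:
    """The rLR: the raw LR decompressed over the same SR-covered span as the
    ecLR, without any correction — the paired uncorrected baseline."""
    left, right = trim_bounds
    return lr.decompress_slice(left, right)
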