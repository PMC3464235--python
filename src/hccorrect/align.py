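"""Short-read-to-long-read alignment in homopolymer-compressed space.

The pipeline aligns compressed short reads against the concatenated
compressed-LR reference.  Production runs can delegate to any external
short-read aligner (BWA-class) through :func:`run_external_aligner`;
the built-in aligner here is a k-mer-seeded, affine-gap local aligner meant
for test- and desk-scale data, emitting standard SAM so that both routes
feed the same :func:`parse_sam` adapter.

Coordinates are 0-based half-open internally; 1-based only at the SAM
boundary.  All evidence is expressed on the forward strand of the long
read: minus-strand short reads are reverse-complemented (their run lengths
reversed) before events are produced.
"""

from __future__ import annotations

import subprocess
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pysam

from .errors import ConfigurationError, ContractViolationError, InputFormatError, PipelineError
from .hc import HCRecord
from .reference import SPACER, ConcatenatedReference


@dataclass(frozen=True)
class Scoring:
    """Affine local-alignment scoring.  A gap of length k scores
    ``gap_open + k * gap_extend`` (i.e. -(3 + k) with the defaults)."""

    match: int = 1
    mismatch: int = -2
    gap_open: int = -3
    gap_extend: int = -1


DEFAULT_SCORING = Scoring()


@dataclass
class Event:
    """One alignment column on the compressed long read.

    kind 'M' (match) / 'X' (mismatch): consumes one LR and one SR position.
    kind 'D': the SR skips LR position ``lr_pos`` (sr_pos is None).
    kind 'I': the SR carries ``sr_len`` extra bases anchored AFTER ``lr_pos``
    (i.e. in the gap between lr_pos and lr_pos+1), starting at ``sr_pos``.
    """

    kind: str
    lr_pos: int
    sr_pos: int | None = None
    sr_len: int = 1


@dataclass
class SRAlignment:
    """One short read placed on one compressed long read."""

    sr_id: str
    lr_id: str
    strand: str  # '+' or '-'
    lr_start: int  # compressed-LR coordinate, 0-based
    lr_end: int  # half-open
    events: list[Event]
    sr_record: HCRecord  # oriented to the LR forward strand
    score: int | None = None


@dataclass
class AlignmentResult:
    score: int
    q_start: int
    q_end: int
    t_start: int
    t_end: int
    ops: str  # over {'=', 'X', 'I', 'D'}; I consumes query, D consumes target


def local_align(query: str, target: str, scoring: Scoring = DEFAULT_SCORING) -> AlignmentResult | None:
    """Optimal affine-gap local (Smith-Waterman/Gotoh) alignment.

    Returns None when the best score is < 1.  Among equal-scoring optima,
    the one with the lowest target start (then lowest query start) is
    returned; traceback prefers diagonal steps, then closing a gap, for
    determinism.
    """
    m, n = len(query), len(target)
    if m == 0 or n == 0:
        return None
    NEG = -(10**9)
    oe = scoring.gap_open + scoring.gap_extend
    ext = scoring.gap_extend
    H = [[0] * (n + 1) for _ in range(m + 1)]
    E = [[NEG] * (n + 1) for _ in range(m + 1)]  # ending with 'D' (target gap run)
    F = [[NEG] * (n + 1) for _ in range(m + 1)]  # ending with 'I' (query gap run)
    best = 0
    best_cells: list[tuple[int, int]] = []
    for i in range(1, m + 1):
        qi = query[i - 1]
        Hi, Hi1, Ei, Fi, Fi1 = H[i], H[i - 1], E[i], F[i], F[i - 1]
        for j in range(1, n + 1):
            e = Hi[j - 1] + oe
            e2 = Ei[j - 1] + ext
            if e2 > e:
                e = e2
            f = Hi1[j] + oe
            f2 = Fi1[j] + ext
            if f2 > f:
                f = f2
            h = Hi1[j - 1] + (scoring.match if qi == target[j - 1] else scoring.mismatch)
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0:
                h = 0
            Ei[j] = e
            Fi[j] = f
            Hi[j] = h
            if h > best:
                best = h
                best_cells = [(i, j)]
            elif h == best and h > 0 and len(best_cells) < 64:
                best_cells.append((i, j))
    if best < 1:
        return None
    candidates = [_traceback(H, E, F, query, target, scoring, i, j) for i, j in best_cells]
    return min(candidates, key=lambda r: (r.t_start, r.q_start, r.t_end, r.q_end))


def _traceback(H, E, F, query, target, scoring, i, j) -> AlignmentResult:
    oe = scoring.gap_open + scoring.gap_extend
    q_end, t_end, score = i, j, H[i][j]
    ops: list[str] = []
    state = "H"
    while True:
        if state == "H":
            h = H[i][j]
            if h == 0:
                break
            eq = query[i - 1] == target[j - 1]
            s = scoring.match if eq else scoring.mismatch
            if h == H[i - 1][j - 1] + s:
                ops.append("=" if eq else "X")
                i -= 1
                j -= 1
            elif h == E[i][j]:
                state = "E"
            else:
                state = "F"
        elif state == "E":
            ops.append("D")
            if E[i][j] == H[i][j - 1] + oe:
                state = "H"
            j -= 1
        else:  # state == "F"
            ops.append("I")
            if F[i][j] == H[i - 1][j] + oe:
                state = "H"
            i -= 1
    return AlignmentResult(score, i, q_end, j, t_end, "".join(reversed(ops)))


def glocal_align(query: str, target: str, scoring: Scoring = DEFAULT_SCORING) -> AlignmentResult | None:
    """Semi-global alignment: the whole query against any target substring.

    This mirrors the behaviour of production short-read aligners, which
    align the read end-to-end rather than clipping locally: a read spanning
    a cluster of long-read errors still contributes evidence through it.
    Target-end gaps are free; query gaps anywhere are penalized.  Among
    equal-scoring optima the lowest target end (then start) wins.
    """
    m, n = len(query), len(target)
    if m == 0 or n == 0:
        return None
    NEG = -(10**9)
    oe = scoring.gap_open + scoring.gap_extend
    ext = scoring.gap_extend
    H = [[0] * (n + 1) for _ in range(m + 1)]
    E = [[NEG] * (n + 1) for _ in range(m + 1)]
    F = [[NEG] * (n + 1) for _ in range(m + 1)]
    for i in range(1, m + 1):
        H[i][0] = F[i][0] = oe + (i - 1) * ext
    for i in range(1, m + 1):
        qi = query[i - 1]
        Hi, Hi1, Ei, Fi, Fi1 = H[i], H[i - 1], E[i], F[i], F[i - 1]
        for j in range(1, n + 1):
            e = Hi[j - 1] + oe
            e2 = Ei[j - 1] + ext
            if e2 > e:
                e = e2
            f = Hi1[j] + oe
            f2 = Fi1[j] + ext
            if f2 > f:
                f = f2
            h = Hi1[j - 1] + (scoring.match if qi == target[j - 1] else scoring.mismatch)
            if e > h:
                h = e
            if f > h:
                h = f
            Ei[j] = e
            Fi[j] = f
            Hi[j] = h
    best_j = min(range(n + 1), key=lambda j: (-H[m][j], j))
    score = H[m][best_j]
    # traceback from (m, best_j) to row 0; unaligned target ends are free
    i, j = m, best_j
    ops: list[str] = []
    state = "H"
    while i > 0:
        if state == "H":
            h = H[i][j]
            if j > 0:
                eq = query[i - 1] == target[j - 1]
                s = scoring.match if eq else scoring.mismatch
                if h == H[i - 1][j - 1] + s:
                    ops.append("=" if eq else "X")
                    i -= 1
                    j -= 1
                    continue
            if j > 0 and h == E[i][j]:
                state = "E"
            else:
                state = "F"
        elif state == "E":
            ops.append("D")
            if E[i][j] == H[i][j - 1] + oe:
                state = "H"
            j -= 1
        else:  # F
            ops.append("I")
            if F[i][j] == H[i - 1][j] + oe or j == 0:
                state = "H"
            i -= 1
    return AlignmentResult(score, 0, m, j, best_j, "".join(reversed(ops)))


def _events_from_ops(ops: str, q_start: int, t_start: int) -> list[Event]:
    events: list[Event] = []
    qpos, tpos = q_start, t_start
    idx = 0
    L = len(ops)
    while idx < L:
        op = ops[idx]
        if op in "=X":
            events.append(Event("M" if op == "=" else "X", tpos, qpos))
            qpos += 1
            tpos += 1
            idx += 1
        elif op == "D":
            events.append(Event("D", tpos))
            tpos += 1
            idx += 1
        else:  # 'I' run, anchored after the previous target position
            run = 0
            start = qpos
            while idx < L and ops[idx] == "I":
                run += 1
                qpos += 1
                idx += 1
            if tpos > t_start:  # local alignments never start with a gap, but be safe
                events.append(Event("I", tpos - 1, start, run))
    return events


def _seed_clusters(query: str, index: dict, k: int, band: int,
                   max_candidates: int = 20, min_hits: int = 1):
    """Group exact k-mer hits into diagonal clusters per chunk.

    ``min_hits`` discards clusters supported by fewer seeds — used with
    short rescue seeds, where single hits are mostly random collisions.
    """
    diag_hits: dict[int, list[int]] = {}
    for qpos in range(0, len(query) - k + 1):
        kmer = query[qpos : qpos + k]
        if "N" in kmer:
            continue
        for cid, tpos in index.get(kmer, ()):
            diag_hits.setdefault(cid, []).append(tpos - qpos)
    clusters: list[tuple[int, int, int, int]] = []  # (cid, dmin, dmax, n_hits)
    for cid, diags in diag_hits.items():
        diags.sort()
        dmin = dmax = diags[0]
        count = 1
        for d in diags[1:]:
            if d - dmax <= band:
                dmax = d
                count += 1
            else:
                clusters.append((cid, dmin, dmax, count))
                dmin = dmax = d
                count = 1
        clusters.append((cid, dmin, dmax, count))
    clusters = [c for c in clusters if c[3] >= min_hits]
    clusters.sort(key=lambda c: (-c[3], c[0], c[1]))
    return clusters[:max_candidates]


@dataclass
class Placement:
    """A candidate location of an oriented short read on the reference."""

    score: int
    chunk_id: int
    t_start: int
    t_end: int
    q_start: int
    q_end: int
    ops: str
    strand: str
    oriented: HCRecord


class BuiltinAligner:
    """k-mer-seeded banded local aligner against a ConcatenatedReference.

    Seeds are exact k-mer matches; each diagonal cluster is refined by an
    optimal alignment inside a window extending ``band`` positions either
    side of the cluster's diagonals, so ``band`` bounds the net indel
    drift an alignment may accumulate.  Reads without any primary-seed
    placement are retried with shorter rescue seeds (``rescue_k``, off
    when None) requiring at least two supporting hits per cluster —
    long-read error clusters can interrupt every full-length seed while
    still leaving a confidently alignable read.
    """

    def __init__(
        self,
        ref: ConcatenatedReference,
        k: int = 12,
        band: int = 20,
        min_score: int = 6,
        mode: str = "glocal",
        rescue_k: int | None = 8,
        scoring: Scoring = DEFAULT_SCORING,
    ) -> None:
        if mode not in ("glocal", "local"):
            raise ConfigurationError(f"unknown alignment mode {mode!r}")
        if rescue_k is not None and rescue_k >= k:
            raise ConfigurationError("rescue_k must be shorter than k")
        self.ref = ref
        self.k = k
        self.band = band
        self.min_score = min_score
        self.mode = mode
        self.rescue_k = rescue_k
        self.scoring = scoring
        self.index = self._build_index(k)
        self.rescue_index = self._build_index(rescue_k) if rescue_k else None

    def _build_index(self, k: int) -> dict[str, list[tuple[int, int]]]:
        index: dict[str, list[tuple[int, int]]] = {}
        for cid, chunk in enumerate(self.ref.chunks):
            for pos in range(len(chunk) - k + 1):
                kmer = chunk[pos : pos + k]
                if "N" in kmer:
                    continue
                index.setdefault(kmer, []).append((cid, pos))
        return index

    def map_read(self, rec: HCRecord) -> list[Placement]:
        """All non-overlapping placements with score >= min_score, best first.

        Ordering (and hence the primary placement) is by score, then lowest
        reference position, then '+' strand.
        """
        placements = self._map_with(rec, self.index, self.k, min_hits=1)
        if not placements and self.rescue_index is not None:
            placements = self._map_with(rec, self.rescue_index, self.rescue_k, min_hits=2)
        placements.sort(key=lambda p: (-p.score, p.chunk_id, p.t_start, p.strand != "+"))
        kept: list[Placement] = []
        for p in placements:
            if not any(
                k.chunk_id == p.chunk_id and p.t_start < k.t_end and k.t_start < p.t_end
                for k in kept
            ):
                kept.append(p)
        return kept

    def _map_with(
        self, rec: HCRecord, index: dict, k: int, min_hits: int
    ) -> list[Placement]:
        placements: list[Placement] = []
        align = glocal_align if self.mode == "glocal" else local_align
        for strand, orec in (("+", rec), ("-", rec.reverse_complement())):
            q = orec.compressed_seq
            if len(q) < k:
                continue
            for cid, dmin, dmax, _ in _seed_clusters(
                q, index, k, self.band, min_hits=min_hits
            ):
                chunk = self.ref.chunks[cid]
                w0 = max(0, dmin - self.band)
                w1 = min(len(chunk), dmax + len(q) + self.band)
                res = align(q, chunk[w0:w1], self.scoring)
                if res is not None and res.score >= self.min_score:
                    placements.append(
                        Placement(
                            res.score,
                            cid,
                            w0 + res.t_start,
                            w0 + res.t_end,
                            res.q_start,
                            res.q_end,
                            res.ops,
                            strand,
                            orec,
                        )
                    )
        return placements


def align_builtin(
    sr: HCRecord,
    lr: HCRecord,
    band: int | None = None,
    min_score: int = 1,
    scoring: Scoring = DEFAULT_SCORING,
) -> SRAlignment | None:
    """Best local alignment of one compressed SR against one compressed LR.

    Both orientations are tried; ties are broken toward the lowest LR start,
    then the '+' strand.  With ``band`` set, candidate diagonals come from
    exact 12-mer seeds and the search is restricted to windows around them
    (falling back to the full matrix when no seed exists); with ``band=None``
    the full dynamic-programming matrix is searched, which is exact.
    Returns None when the best score is below ``min_score``.
    """
    if not sr.compressed_seq or not lr.compressed_seq:
        return None
    best: tuple | None = None
    for strand, orec in (("+", sr), ("-", sr.reverse_complement())):
        q = orec.compressed_seq
        results: list[AlignmentResult] = []
        if band is None:
            res = local_align(q, lr.compressed_seq, scoring)
            if res is not None:
                results.append(res)
        else:
            index: dict[str, list[tuple[int, int]]] = {}
            k = 12
            for pos in range(len(lr.compressed_seq) - k + 1):
                index.setdefault(lr.compressed_seq[pos : pos + k], []).append((0, pos))
            clusters = _seed_clusters(q, index, k, band)
            if not clusters:
                res = local_align(q, lr.compressed_seq, scoring)
                if res is not None:
                    results.append(res)
            for _, dmin, dmax, _n in clusters:
                w0 = max(0, dmin - band)
                w1 = min(len(lr.compressed_seq), dmax + len(q) + band)
                res = local_align(q, lr.compressed_seq[w0:w1], scoring)
                if res is not None:
                    results.append(
                        AlignmentResult(res.score, res.q_start, res.q_end, w0 + res.t_start, w0 + res.t_end, res.ops)
                    )
        for res in results:
            key = (-res.score, res.t_start, strand != "+")
            if best is None or key < best[0]:
                best = (key, res, strand, orec)
    if best is None or best[1].score < min_score:
        return None
    _, res, strand, orec = best
    return SRAlignment(
        sr_id=sr.read_id,
        lr_id=lr.read_id,
        strand=strand,
        lr_start=res.t_start,
        lr_end=res.t_end,
        events=_events_from_ops(res.ops, res.q_start, res.t_start),
        sr_record=orec,
        score=res.score,
    )


# ---------------------------------------------------------------------------
# SAM emission


def _cigar_from_ops(ops: str, q_start: int, q_len: int, q_end: int) -> str:
    parts: list[tuple[int, str]] = []
    if q_start:
        parts.append((q_start, "S"))
    for op in ops:
        sam_op = "M" if op in "=X" else op
        if parts and parts[-1][1] == sam_op:
            parts[-1] = (parts[-1][0] + 1, sam_op)
        else:
            parts.append((1, sam_op))
    if q_len - q_end:
        parts.append((q_len - q_end, "S"))
    return "".join(f"{n}{op}" for n, op in parts)


def sam_header(ref: ConcatenatedReference) -> str:
    lines = ["@HD\tVN:1.6\tSO:unknown"]
    for name, chunk in zip(ref.chunk_names, ref.chunks):
        lines.append(f"@SQ\tSN:{name}\tLN:{len(chunk)}")
    lines.append("@PG\tID:hccorrect\tPN:hccorrect")
    return "\n".join(lines) + "\n"


def placement_to_sam_line(
    sr_id: str, p: Placement, ref: ConcatenatedReference, secondary: bool = False
) -> str:
    flag = 0
    if p.strand == "-":
        flag |= 16
    if secondary:
        flag |= 256
    cigar = _cigar_from_ops(p.ops, p.q_start, len(p.oriented.compressed_seq), p.q_end)
    return "\t".join(
        [
            sr_id,
            str(flag),
            ref.chunk_names[p.chunk_id],
            str(p.t_start + 1),
            "0" if secondary else "60",
            cigar,
            "*",
            "0",
            "0",
            p.oriented.compressed_seq,
            "*",
            f"AS:i:{p.score}",
        ]
    )


def alignment_to_sam_line(aln: SRAlignment, ref: ConcatenatedReference) -> str:
    """Render an SRAlignment back to SAM against the concatenated reference."""
    iv = ref.interval_for(aln.lr_id)
    ops: list[str] = []
    sr_positions = [e.sr_pos for e in aln.events if e.sr_pos is not None]
    q_start = min(sr_positions) if sr_positions else 0
    q_end = (
        max(e.sr_pos + (e.sr_len if e.kind == "I" else 1) for e in aln.events if e.sr_pos is not None)
        if sr_positions
        else 0
    )
    for e in aln.events:
        if e.kind == "M":
            ops.append("=")
        elif e.kind == "X":
            ops.append("X")
        elif e.kind == "D":
            ops.append("D")
        else:
            ops.append("I" * e.sr_len)
    flag = 16 if aln.strand == "-" else 0
    cigar = _cigar_from_ops("".join(ops), q_start, len(aln.sr_record.compressed_seq), q_end)
    return "\t".join(
        [
            aln.sr_id,
            str(flag),
            ref.chunk_names[iv.chunk_id],
            str(iv.start + aln.lr_start + 1),
            "60",
            cigar,
            "*",
            "0",
            "0",
            aln.sr_record.compressed_seq,
            "*",
        ]
    )


def builtin_align_to_sam(
    ref: ConcatenatedReference,
    srs: Iterable[HCRecord],
    out_sam: str | Path,
    k: int = 12,
    band: int = 20,
    min_score: int = 6,
    mode: str = "glocal",
    keep_multimapped: bool = False,
) -> dict[str, int]:
    """Map every SR with the built-in aligner and write a SAM file.

    Only the primary placement is written unless ``keep_multimapped`` is
    set, in which case additional placements are written as secondary
    records.  Returns mapped/unmapped counts.
    """
    aligner = BuiltinAligner(ref, k=k, band=band, min_score=min_score, mode=mode)
    counts = {"mapped": 0, "unmapped": 0, "secondary": 0}
    with open(out_sam, "w") as fh:
        fh.write(sam_header(ref))
        for rec in srs:
            placements = aligner.map_read(rec)
            if not placements:
                counts["unmapped"] += 1
                continue
            counts["mapped"] += 1
            fh.write(placement_to_sam_line(rec.read_id, placements[0], ref) + "\n")
            if keep_multimapped:
                for p in placements[1:]:
                    counts["secondary"] += 1
                    fh.write(placement_to_sam_line(rec.read_id, p, ref, secondary=True) + "\n")
    return counts


# ---------------------------------------------------------------------------
# SAM consumption

_ALLOWED_CIGAR = {0, 1, 2, 4, 5, 7, 8}  # M I D S H = X


def parse_sam(
    sam_path: str | Path,
    ref: ConcatenatedReference,
    sr_table: dict[str, HCRecord],
    keep_multimapped: bool = False,
) -> tuple[list[SRAlignment], dict[str, int]]:
    """Translate SAM records against the concatenated reference into SRAlignments.

    Records overlapping any spacer position are discarded (spacers exist to
    forbid cross-LR alignments); unmapped records are skipped; secondary and
    supplementary records are skipped unless ``keep_multimapped``.  M
    operations are classified into match/mismatch by comparison with the
    in-memory reference.  Insertions at the very edge of the aligned span
    have no anchor gap inside the covered region and are dropped.
    """
    counts = {
        "records": 0,
        "unmapped": 0,
        "secondary_skipped": 0,
        "spacer_overlap": 0,
        "parsed": 0,
        "edge_insertions": 0,
    }
    alignments: list[SRAlignment] = []
    known = set(ref.chunk_names)
    with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as sam:
        for name in sam.references:
            if name not in known:
                raise InputFormatError(
                    f"SAM header declares unknown reference {name!r}; "
                    "was the alignment run against a different reference?"
                )
        for read in sam:
            counts["records"] += 1
            if read.is_unmapped:
                counts["unmapped"] += 1
                continue
            if (read.is_secondary or read.is_supplementary) and not keep_multimapped:
                counts["secondary_skipped"] += 1
                continue
            cig = read.cigartuples or []
            bad = [op for op, _ in cig if op not in _ALLOWED_CIGAR]
            if bad:
                raise InputFormatError(
                    f"record {read.query_name!r}: unsupported CIGAR operation code {bad[0]}"
                )
            try:
                chunk_id = ref.chunk_id_for(read.reference_name)
            except ContractViolationError as exc:
                raise InputFormatError(f"record {read.query_name!r}: {exc}") from exc
            if read.query_name not in sr_table:
                raise InputFormatError(f"record {read.query_name!r}: read id not in SR table")
            ref_start = read.reference_start
            ref_len = sum(length for op, length in cig if op in (0, 2, 7, 8))
            if ref_len == 0:
                counts["unmapped"] += 1
                continue
            ref_end = ref_start + ref_len
            loc_a = ref.locate(chunk_id, ref_start)
            loc_b = ref.locate(chunk_id, ref_end - 1)
            if loc_a is SPACER or loc_b is SPACER or loc_a[0] != loc_b[0]:
                counts["spacer_overlap"] += 1
                continue
            lr_id = loc_a[0]
            iv = ref.interval_for(lr_id)
            rec = sr_table[read.query_name]
            if read.is_reverse:
                rec = rec.reverse_complement()
            chunk_seq = ref.chunks[chunk_id]
            events: list[Event] = []
            qpos = 0
            rpos = ref_start
            for op, length in cig:
                if op in (4, 5):  # S / H both consume oriented-read positions here
                    qpos += length
                elif op in (0, 7, 8):
                    for _ in range(length):
                        if op == 0:
                            kind = "M" if rec.compressed_seq[qpos] == chunk_seq[rpos] else "X"
                        else:
                            kind = "M" if op == 7 else "X"
                        events.append(Event(kind, rpos - iv.start, qpos))
                        qpos += 1
                        rpos += 1
                elif op == 2:
                    for _ in range(length):
                        events.append(Event("D", rpos - iv.start))
                        rpos += 1
                else:  # op == 1, insertion
                    if rpos == ref_start or rpos == ref_end:
                        counts["edge_insertions"] += 1
                    else:
                        events.append(Event("I", rpos - 1 - iv.start, qpos, length))
                    qpos += length
            counts["parsed"] += 1
            alignments.append(
                SRAlignment(
                    sr_id=read.query_name,
                    lr_id=lr_id,
                    strand="-" if read.is_reverse else "+",
                    lr_start=ref_start - iv.start,
                    lr_end=ref_end - iv.start,
                    events=events,
                    sr_record=rec,
                    score=read.get_tag("AS") if read.has_tag("AS") else None,
                )
            )
    return alignments, counts


def run_external_aligner(
    cmd_template: str, sr_fasta: str | Path, ref_fasta: str | Path, out_sam: str | Path
) -> Path:
    """Invoke a user-configured aligner command and return the SAM path.

    The template must contain the placeholders ``{reads}``, ``{reference}``
    and ``{output}``.  A non-zero exit or missing output aborts the
    pipeline with the tail of the tool's stderr.
    """
    for placeholder in ("{reads}", "{reference}", "{output}"):
        if placeholder not in cmd_template:
            raise ConfigurationError(f"aligner command template missing placeholder {placeholder}")
    cmd = cmd_template.format(reads=str(sr_fasta), reference=str(ref_fasta), output=str(out_sam))
    proc = subprocess.run(cmd, shell=True, capture_output=True, text=True)
    if proc.returncode != 0:
        raise PipelineError(
            f"external aligner exited with status {proc.returncode}; stderr tail:\n"
            + proc.stderr[-2000:]
        )
    if not Path(out_sam).exists():
        raise PipelineError(f"external aligner produced no output at {out_sam}")
    return Path(out_sam)
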