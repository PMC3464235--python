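"""Evaluation metrics: sequence identity, SR coverage, and depth-stratified accuracy.

Reads are evaluated against their true source sequence (synthetic mode,
where per-read provenance is known) or any reference sequence, using
edit-distance alignment (edlib, infix mode: the read aligns inside the
longer truth sequence with free truth-end gaps).

Quantities:

* sequence identity I of a read — matches over all alignment columns
  (matches + mismatches + gap bases in either sequence) by default; a
  span-based alternative (matches / aligned read length) is available.
* SP, the SR-covered sequence percentage — covered length / read length.
* SCD-stratified match table — every output position binned by its
  SR-covered depth (0..7 and >7), tallying matches vs truth per bin.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import edlib
import pandas as pd

from .correction import ECLongRead
from .errors import ContractViolationError

IDENTITY_FORMULAS = ("gap_inclusive", "span_based")
#: Identity histogram bin edges: I<=0.8, 0.8<I<=0.9, 0.9<I<=0.95, 0.95<I<=1.
IDENTITY_BIN_EDGES = (0.8, 0.9, 0.95, 1.0)
SCD_BIN_LABELS = ("0", "1", "2", "3", "4", "5", "6", "7", ">7")


@dataclass
class EvalAlignment:
    """Column counts of one read-to-reference alignment."""

    query_id: str
    matches: int
    mismatches: int
    query_gap_bases: int  # columns where the query has a gap (reference base skipped)
    target_gap_bases: int  # columns where the reference has a gap (query base inserted)

    @property
    def aligned_query_span(self) -> int:
        return self.matches + self.mismatches + self.target_gap_bases


def _edlib_cigar(query: str, target: str, mode: str = "HW") -> list[tuple[int, str]]:
    res = edlib.align(query, target, task="path", mode=mode)
    if res["cigar"] is None:
        raise ContractViolationError("edlib produced no alignment path")
    out: list[tuple[int, str]] = []
    num = ""
    for ch in res["cigar"]:
        if ch.isdigit():
            num += ch
        else:
            out.append((int(num), ch))
            num = ""
    return out


def evaluate_alignment(query_id: str, query: str, target: str, mode: str = "HW") -> EvalAlignment:
    """Align ``query`` against ``target`` and count alignment columns.

    Mode "HW" (infix) leaves unaligned reference ends unpenalized and
    uncounted — appropriate for a read drawn from within a longer truth
    sequence.  In edlib's extended CIGAR, 'I' consumes the query (an
    inserted read base) and 'D' consumes the target (a skipped truth base).
    """
    if not query or not target:
        raise ContractViolationError("cannot evaluate an empty sequence")
    counts = {"=": 0, "X": 0, "I": 0, "D": 0}
    for length, op in _edlib_cigar(query, target, mode):
        counts[op] += length
    return EvalAlignment(query_id, counts["="], counts["X"], counts["D"], counts["I"])


def sequence_identity(a: EvalAlignment, formula: str = "gap_inclusive") -> float:
    """Sequence identity I in [0, 1].

    gap_inclusive: matches / (matches + mismatches + gap bases on both
    sides) — every alignment column counts.  span_based: matches / aligned
    query span.
    """
    if formula == "gap_inclusive":
        denom = a.matches + a.mismatches + a.query_gap_bases + a.target_gap_bases
    elif formula == "span_based":
        denom = a.aligned_query_span
    else:
        raise ContractViolationError(f"unknown identity formula {formula!r}")
    if denom == 0:
        raise ContractViolationError("identity undefined: empty alignment")
    return a.matches / denom


def sr_covered_percentage(ec: ECLongRead) -> float:
    """SP: fraction of output bases derived from SR-covered positions."""
    if not ec.seq:
        raise ContractViolationError("SP undefined for an empty read")
    return sum(ec.covered_mask) / len(ec.seq)


def per_base_match(query: str, target: str, mode: str = "HW") -> list[bool]:
    """For each query base, whether it aligns to an identical target base.

    Mismatching and inserted query bases are False; deleted target bases
    correspond to no query position and are not represented.
    """
    out: list[bool] = []
    for length, op in _edlib_cigar(query, target, mode):
        if op == "=":
            out.extend([True] * length)
        elif op in ("X", "I"):
            out.extend([False] * length)
        # 'D' consumes no query base
    return out


def _scd_bin(d: int) -> str:
    return str(d) if d <= 7 else ">7"


def scd_match_table(
    ec_reads: Iterable[ECLongRead], truths: Mapping[str, str], mode: str = "HW"
) -> pd.DataFrame:
    """Depth-stratified accuracy: positions binned by SCD, matches vs truth.

    ``truths`` maps each read's source id to its true source sequence.
    Reads without truth are skipped and tallied in the frame's attrs.
    """
    matches = {b: 0 for b in SCD_BIN_LABELS}
    mismatches = {b: 0 for b in SCD_BIN_LABELS}
    skipped = 0
    for ec in ec_reads:
        truth = truths.get(ec.source_id)
        if truth is None:
            skipped += 1
            continue
        flags = per_base_match(ec.seq, truth, mode)
        for flag, d in zip(flags, ec.scd):
            b = _scd_bin(d)
            if flag:
                matches[b] += 1
            else:
                mismatches[b] += 1
    rows = []
    for b in SCD_BIN_LABELS:
        total = matches[b] + mismatches[b]
        rows.append(
            {
                "scd_bin": b,
                "matches": matches[b],
                "mismatches": mismatches[b],
                "match_fraction": matches[b] / total if total else float("nan"),
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["skipped_no_truth"] = skipped
    return df


def identity_histogram(
    identities: Iterable[float], bin_edges: Sequence[float] = IDENTITY_BIN_EDGES
) -> pd.DataFrame:
    """Histogram of identities over (-inf, e1], (e1, e2], ..., matching the
    conventional reporting bins I<=0.8 / 0.8-0.9 / 0.9-0.95 / 0.95-1."""
    edges = list(bin_edges)
    labels = [f"I<={edges[0]}"] + [f"{lo}<I<={hi}" for lo, hi in zip(edges, edges[1:])]
    counts = [0] * len(labels)
    total = 0
    for ident in identities:
        total += 1
        for i, hi in enumerate(edges):
            if ident <= hi:
                counts[i] += 1
                break
        else:
            counts[-1] += 1
    return pd.DataFrame(
        {
            "identity_bin": labels,
            "count": counts,
            "fraction": [c / total if total else 0.0 for c in counts],
        }
    )


def region_identities(
    ec: ECLongRead, truth: str, formula: str = "gap_inclusive", mode: str = "HW"
) -> dict[str, float | None]:
    """Identity computed separately over SR-covered and SR-uncovered regions.

    The read is aligned to truth once; each alignment column is assigned to
    the covered or uncovered class of its query base (columns where the
    query has a gap inherit the class of the preceding query base).
    Returns None for a class with no columns.
    """
    counts = {
        True: {"=": 0, "X": 0, "I": 0, "D": 0},
        False: {"=": 0, "X": 0, "I": 0, "D": 0},
    }
    qpos = 0
    cls = ec.covered_mask[0] if ec.covered_mask else True
    for length, op in _edlib_cigar(ec.seq, truth, mode):
        for _ in range(length):
            if op == "D":
                counts[cls]["D"] += 1
            else:
                cls = ec.covered_mask[qpos]
                counts[cls][op] += 1
                qpos += 1
    out: dict[str, float | None] = {}
    for key, name in ((True, "covered"), (False, "uncovered")):
        c = counts[key]
        a = EvalAlignment(ec.read_id, c["="], c["X"], c["D"], c["I"])
        total = c["="] + c["X"] + c["I"] + c["D"]
        out[name] = sequence_identity(a, formula) if total else None
    return out
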