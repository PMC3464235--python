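"""Consensus rules, pileup construction, trimming and recovery properties."""

import random

import pytest

from hccorrect.align import BuiltinAligner, Event, SRAlignment, builtin_align_to_sam, parse_sam
from hccorrect.correction import (
    build_pileup,
    consensus_column,
    consensus_insertion,
    correct_lr,
    raw_segment,
)
from hccorrect.errors import ContractViolationError
from hccorrect.hc import HCRecord, compress
from hccorrect.reference import build_reference


@pytest.mark.parametrize(
    "lr_base, lr_run, evidence, deletions, expected",
    [
        ("A", 1, ["AAA", "AAA", "A"], 0, "AAA"),  # HC point: plurality run wins
        ("C", 1, ["T", "T", "T"], 0, "T"),  # point mismatch corrected
        ("G", 1, ["G"], 1, "G"),  # 1-1 tie with deletion: LR retained
        ("A", 2, [], 0, "AA"),  # no evidence: own run decompressed
        ("C", 1, [], 2, ""),  # unanimous deletion removes the column
        ("T", 3, ["T", "TT"], 0, "TTT"),  # tie between runs: LR's own run kept
        ("G", 1, ["A", "A", "G"], 0, "A"),  # substitution outvoted
    ],
)
def test_consensus_column(lr_base, lr_run, evidence, deletions, expected):
    assert consensus_column(lr_base, lr_run, evidence, deletions) == expected


@pytest.mark.parametrize(
    "gap_evidence, expected",
    [
        (["", "", "ACG"], ""),  # no majority of inserting SRs
        (["T", "T", ""], "T"),  # 2 of 3 insert: plurality string
        ([], ""),  # no covering SRs
        (["A", "C"], "A"),  # both SRs insert: majority holds, lexicographic tie-break
        (["AA", "CC", "AA"], "AA"),
        (["A", "C", "G"], "A"),  # all insert, full tie: lexicographic
    ],
)
def test_consensus_insertion(gap_evidence, expected):
    assert consensus_insertion(gap_evidence) == expected


def _aln(lr, sr_seq, lr_start, kinds=None, sr_id="s"):
    """All-match alignment helper over compressed coordinates."""
    rec = compress(sr_seq, sr_id)
    events = [
        Event("M", lr_start + i, i) for i in range(len(rec.compressed_seq))
    ]
    return SRAlignment(sr_id, lr.read_id, "+", lr_start,
                       lr_start + len(rec.compressed_seq), events, rec)


def test_pileup_empty():
    lr = compress("ACGTACGTAC", "lr")
    pile = build_pileup(lr, [])
    assert pile.depth == [0] * 10
    assert all(not e for e in pile.base_evidence)
    assert correct_lr(lr, pile) is None


def test_pileup_single_alignment_span():
    lr = compress("ACGTACGTACGTACGTACGT", "lr")  # compressed length 20
    aln = _aln(lr, lr.compressed_seq[5:15], 5)
    pile = build_pileup(lr, aln and [aln])
    assert pile.depth == [0] * 5 + [1] * 10 + [0] * 5
    # insertion gaps interior to the alignment record the empty string
    assert all(pile.insertion_evidence[g] == [""] for g in range(5, 14))


def test_pileup_depth_accounting_and_order_invariance():
    """depth[i] == |base_evidence[i]| + deletions[i]; pileups and corrected
    output are invariant under alignment order."""
    rng = random.Random(13)
    lr = compress("".join(rng.choice("ACGT") for _ in range(300)), "lr")
    n = len(lr.compressed_seq)
    alignments = []
    for i in range(12):
        start = rng.randrange(0, n - 40)
        rec_seq = lr.compressed_seq[start : start + 30]
        rec = compress(rec_seq, f"s{i}")
        events = []
        for j, _ in enumerate(rec.compressed_seq):
            kind = "D" if rng.random() < 0.1 else ("X" if rng.random() < 0.1 else "M")
            if kind == "D":
                events.append(Event("D", start + j))
            else:
                events.append(Event(kind, start + j, j))
        alignments.append(SRAlignment(f"s{i}", "lr", "+", start, start + 30, events, rec))
    pile = build_pileup(lr, alignments)
    # independent per-column recount (mirroring the terminal-match rule)
    exp_depth = [0] * n
    exp_votes = [0] * n
    for aln in alignments:
        cons = [e.sr_pos for e in aln.events if e.sr_pos is not None]
        lo, hi = min(cons), max(cons)
        for e in aln.events:
            if e.kind in ("M", "X", "D"):
                exp_depth[e.lr_pos] += 1
            if e.kind == "X" or (e.kind == "M" and lo < e.sr_pos < hi) or e.kind == "D":
                exp_votes[e.lr_pos] += 1
    for i in range(n):
        assert pile.depth[i] == exp_depth[i]
        assert len(pile.base_evidence[i]) + pile.deletion_evidence[i] == exp_votes[i]
        assert pile.depth[i] >= len(pile.base_evidence[i]) + pile.deletion_evidence[i]
        if pile.depth[i] == 0:
            assert not pile.base_evidence[i]
    shuffled = alignments[:]
    rng.shuffle(shuffled)
    pile2 = build_pileup(lr, shuffled)
    assert pile2.depth == pile.depth
    assert [sorted(e) for e in pile2.base_evidence] == [sorted(e) for e in pile.base_evidence]
    ec1 = correct_lr(lr, pile)
    ec2 = correct_lr(lr, pile2)
    assert ec1.seq == ec2.seq and ec1.scd == ec2.scd


def test_event_out_of_bounds_rejected():
    lr = compress("ACGTACGT", "lr")
    rec = compress("ACG", "s")
    bad = SRAlignment("s", "lr", "+", 6, 9, [Event("M", 9, 0)], rec)
    with pytest.raises(ContractViolationError):
        build_pileup(lr, [bad])


def _tile_reads(truth, length, step):
    return [truth[i : i + length] for i in range(0, len(truth) - length + 1, step)]


def test_all_four_correction_point_types_recover_truth_exactly():
    """Agreeing depth-3 evidence corrects a homopolymer-run error, a point
    mismatch, a deletion and an insertion in one read, reproducing the true
    source exactly.

    Truth:  GC AA C G TTT A C GG C A TT GC
    LR:     GC AAA C A TTT A - GG C A G TT GC
    (run 2->3, G->A substitution, C deleted, G inserted)
    """
    truth = "GCAACGTTTACGGCATTGC"
    lr = compress("GCAAACATTTAGGCAGTTGC", "lr")
    assert lr.compressed_seq == "GCACATAGCAGTGC"
    sr = compress(truth, "s")
    assert sr.compressed_seq == "GCACGTACGCATGC"
    events = []
    # sr col -> lr col, walking the designed edit script
    for sr_col, lr_col in [(0, 0), (1, 1), (2, 2), (3, 3)]:
        events.append(Event("M", lr_col, sr_col))
    events.append(Event("X", 4, 4))  # truth G vs LR A
    for sr_col, lr_col in [(5, 5), (6, 6)]:
        events.append(Event("M", lr_col, sr_col))
    events.append(Event("I", 6, 7, 1))  # deleted C restored after LR col 6
    for sr_col, lr_col in [(8, 7), (9, 8), (10, 9)]:
        events.append(Event("M", lr_col, sr_col))
    events.append(Event("D", 10))  # LR's inserted G skipped
    for sr_col, lr_col in [(11, 11), (12, 12), (13, 13)]:
        events.append(Event("M", lr_col, sr_col))
    alns = [
        SRAlignment(f"s{i}", "lr", "+", 0, 14, list(events), compress(truth, f"s{i}"))
        for i in range(3)
    ]
    ec = correct_lr(lr, build_pileup(lr, alns))
    assert ec is not None
    assert ec.seq == truth
    assert all(ec.covered_mask)


def test_error_free_srs_recover_truth_through_full_pipeline():
    """Tiled error-free SRs over 15%-error LRs: recovery is near-exact,
    with residual edits confined to alignment-ambiguous repeats and dense
    long-read error clusters where coverage drops."""
    import tempfile, pathlib
    import edlib

    for trial_seed in (21, 22, 23):
        rng = random.Random(trial_seed)
        # truth with homopolymer runs
        parts, prev = [], ""
        while sum(len(p) for p in parts) < 1200:
            b = rng.choice("ACGT")
            if b == prev:
                continue
            parts.append(b * rng.choice([1, 1, 2, 3, 4]))
            prev = b
        truth = "".join(parts)
        # noisy LR: substitutions and indels at ~15%
        lr_seq = []
        for ch in truth:
            r = rng.random()
            if r < 0.06:
                continue  # deletion
            if r < 0.07:
                lr_seq.append(rng.choice("ACGT".replace(ch, "")))
            else:
                lr_seq.append(ch)
            if rng.random() < 0.08:
                lr_seq.append(rng.choice("ACGT"))
        lr = compress("".join(lr_seq), "lr")
        srs = [compress(s, f"s{i}") for i, s in enumerate(_tile_reads(truth, 75, 10))]
        ref = build_reference([lr], spacer_len=75)
        with tempfile.TemporaryDirectory() as td:
            sam = pathlib.Path(td) / "a.sam"
            builtin_align_to_sam(ref, srs, sam)
            alignments, _ = parse_sam(sam, ref, {r.read_id: r for r in srs})
        pile = build_pileup(lr, alignments)
        ec = correct_lr(lr, pile)
        assert ec is not None
        assert len(ec.seq) >= 0.8 * len(truth)
        dist = edlib.align(ec.seq, truth, mode="HW")["editDistance"]
        assert dist / len(truth) <= 0.03
        # trim contract: both ends SR-covered
        assert ec.covered_mask[0] and ec.covered_mask[-1]


def test_zero_coverage_returns_none():
    lr = compress("AACCGGTT", "lr")
    assert correct_lr(lr, build_pileup(lr, [])) is None


def test_partial_coverage_trimming():
    """Coverage only over compressed positions [5, 20) trims the output to
    exactly the decompression of that span (corrected)."""
    rng = random.Random(31)
    seq, prev = [], ""
    while len(seq) < 50:
        b = rng.choice("ACGT")
        if b != prev:
            seq.append(b)
            prev = b
    lr = HCRecord("lr", None, "".join(seq), [rng.choice([1, 2, 3]) for _ in range(50)])
    lr = HCRecord("lr", lr.decompress(), lr.compressed_seq, lr.run_lengths)
    # one SR matching positions [5, 20) exactly, with the LR's own run lengths
    sr_seq = lr.decompress_slice(5, 20)
    rec = compress(sr_seq, "s")
    events = [Event("M", 5 + i, i) for i in range(len(rec.compressed_seq))]
    aln = SRAlignment("s", "lr", "+", 5, 20, events, rec)
    ec = correct_lr(lr, build_pileup(lr, [aln]))
    assert ec.trim_bounds == (5, 20)
    assert ec.seq == lr.decompress_slice(5, 20)
    assert ec.read_id == "lr/5_20"
    assert raw_segment(lr, ec.trim_bounds) == lr.decompress_slice(5, 20)


def test_uncovered_interior_positions_unedited():
    """Columns without evidence are decompressed from the LR's own runs."""
    lr = compress("AATTCCGGAATT", "lr")  # compressed ATCGAT, runs of 2
    rec = compress("AA", "s1")
    rec2 = compress("TT", "s2")
    alns = [
        SRAlignment("s1", "lr", "+", 0, 1, [Event("M", 0, 0)], rec),
        SRAlignment("s2", "lr", "+", 5, 6, [Event("M", 5, 0)], rec2),
    ]
    ec = correct_lr(lr, build_pileup(lr, alns))
    # interior positions 1..4 keep their own decompressed runs
    assert ec.seq == "AATTCCGGAATT"
    assert ec.covered_mask == [True] * 2 + [False] * 8 + [True] * 2
    assert ec.scd == [1, 1, 0, 0, 0, 0, 0, 0, 0, 0, 1, 1]


def test_min_depth_floor():
    lr = compress("ACGTACGT", "lr")
    rec = compress("ACCCG", "s")  # lone SR claims a 3-run C at position 1
    events = [Event("M", i, i) for i in range(3)]
    aln = SRAlignment("s", "lr", "+", 0, 3, events, rec)
    pile = build_pileup(lr, [aln])
    assert correct_lr(lr, pile, min_depth=1).seq == "ACCCG"
    # with a depth floor of 2 the lone SR cannot edit, only cover
    assert correct_lr(lr, pile, min_depth=2).seq == "ACG"


def test_terminal_run_evidence_is_neutral():
    """An SR whose alignment starts inside a homopolymer run must not
    shorten it: terminal matches cover but abstain from the run vote."""
    lr = compress("GTTGGG", "lr")  # compressed GTG, runs [1,2,3]
    # interior reads carry the true 2-run; a boundary read starts on the 2nd T
    full = compress("GTTG", "f")  # compressed GTG runs [1,2,1]
    events_full = [Event("M", i, i) for i in range(3)]
    boundary = compress("TGGG", "b")  # compressed TG runs [1,3]
    events_b = [Event("M", 1, 0), Event("M", 2, 1)]
    alns = [
        SRAlignment("f", "lr", "+", 0, 3, events_full, full),
        SRAlignment("b", "lr", "+", 1, 3, events_b, boundary),
    ]
    pile = build_pileup(lr, alns)
    # at position 1 the boundary read's truncated 1-run abstains
    assert pile.base_evidence[1] == ["TT"]
    assert pile.depth[1] == 2
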