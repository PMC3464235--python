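"""Seeded simulator of transcripts, noisy long reads and accurate short reads.

The generator emulates the data regime the pipeline targets: a modest
number of kilobase-scale cDNA long reads with a high (~15%), indel-dominated
error rate that is further elevated inside homopolymer runs — the
single-molecule error mode homopolymer compression is designed to absorb —
plus deep, fixed-length short reads with a low (~2%) substitution error rate
and occasional uncertain 'N' bases.

Ground truth is first-class: every long read and short read carries a
provenance record back to its source transcript, so evaluation never
depends on re-alignment.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .errors import ConfigurationError
from .hc import revcomp
from .seqio import write_fasta, write_fastq

BASES = "ACGT"
_OTHER = {b: BASES.replace(b, "") for b in BASES}


@dataclass
class SimParams:
    """Simulation parameters (defaults define the study conditions).

    Transcripts are 500-8,000 bp with geometrically distributed homopolymer
    run lengths (hp_run_p = 0.65 gives a mean run of ~1.54 bp, i.e. an HC
    compression ratio of ~0.65, matching genomic sequence rather than the
    0.75 of i.i.d. bases).  Long-read error rates sum to 0.15 and are
    indel-dominated; hp_bias multiplies the indel rates inside homopolymer
    runs of length >= 3, with the outside rates rescaled so the overall
    rates stay at their stated values.  Short reads are fixed-length 75 bp
    with 2% substitution error.
    """

    n_transcripts: int = 20
    transcript_len_range: tuple[int, int] = (500, 8000)
    hp_run_p: float = 0.65
    lr_per_transcript: int = 1
    lr_mismatch_rate: float = 0.01
    lr_insertion_rate: float = 0.08
    lr_deletion_rate: float = 0.06
    hp_bias: float = 3.0
    sr_len: int = 75
    sr_depth: float = 10.0
    sr_error: float = 0.02
    sr_n_rate: float = 0.002
    seed: int = 0

    def validate(self) -> None:
        for name in ("lr_mismatch_rate", "lr_insertion_rate", "lr_deletion_rate", "sr_error", "sr_n_rate", "hp_run_p"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        if self.lr_mismatch_rate + self.lr_insertion_rate + self.lr_deletion_rate > 0.5:
            raise ConfigurationError("long-read error rates must sum to <= 0.5")
        if self.hp_bias < 0 or self.sr_depth < 0:
            raise ConfigurationError("hp_bias and sr_depth must be non-negative")
        if self.transcript_len_range[0] < 1 or self.transcript_len_range[0] > self.transcript_len_range[1]:
            raise ConfigurationError("invalid transcript_len_range")
        if self.sr_len < 1:
            raise ConfigurationError("sr_len must be >= 1")


@dataclass
class SimDataset:
    params: SimParams
    transcripts: list[tuple[str, str]] = field(default_factory=list)
    lrs: list[tuple[str, str]] = field(default_factory=list)
    #: lr_id -> (transcript_id, per-LR-base provenance ops)
    lr_provenance: dict[str, tuple[str, list[tuple[str, int | None]]]] = field(default_factory=dict)
    srs: list[tuple[str, str]] = field(default_factory=list)
    #: sr_id -> (transcript_id, start, end, strand)
    sr_provenance: dict[str, tuple[str, int, int, str]] = field(default_factory=dict)

    @property
    def truth_by_id(self) -> dict[str, str]:
        return dict(self.transcripts)

    def truth_for_lr(self, lr_id: str) -> str:
        return self.truth_by_id[self.lr_provenance[lr_id][0]]

    def write(self, out_dir: str | Path) -> dict[str, str]:
        """Write truth FASTA, LR FASTA, SR FASTQ, provenance TSVs and a manifest."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "truth": str(out / "truth.fa"),
            "lr": str(out / "lr.fa"),
            "sr": str(out / "sr.fq"),
            "lr_provenance": str(out / "lr_provenance.tsv"),
            "sr_provenance": str(out / "sr_provenance.tsv"),
            "manifest": str(out / "manifest.json"),
        }
        write_fasta(self.transcripts, paths["truth"])
        write_fasta(self.lrs, paths["lr"])
        write_fastq(((rid, seq, "I" * len(seq)) for rid, seq in self.srs), paths["sr"])
        with open(paths["lr_provenance"], "w") as fh:
            fh.write("lr_id\ttranscript_id\tops\n")
            for lr_id, (tid, ops) in self.lr_provenance.items():
                enc = ",".join(f"{op}{'' if pos is None else pos}" for op, pos in ops)
                fh.write(f"{lr_id}\t{tid}\t{enc}\n")
        with open(paths["sr_provenance"], "w") as fh:
            fh.write("sr_id\ttranscript_id\tstart\tend\tstrand\n")
            for sr_id, (tid, start, end, strand) in self.sr_provenance.items():
                fh.write(f"{sr_id}\t{tid}\t{start}\t{end}\t{strand}\n")
        manifest = {"params": asdict(self.params), "paths": paths,
                    "n_transcripts": len(self.transcripts), "n_lrs": len(self.lrs), "n_srs": len(self.srs)}
        with open(paths["manifest"], "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return paths


def simulate_truth(params: SimParams, rng: np.random.Generator | None = None) -> list[tuple[str, str]]:
    """Generate transcripts with homopolymer-enriched composition.

    Each run takes a base different from the previous one, with geometric
    run length (mean 1/hp_run_p), giving a heavier homopolymer tail than
    i.i.d. sequence and an expected HC compression ratio of ~hp_run_p.
    """
    params.validate()
    rng = rng or np.random.default_rng(params.seed)
    lo, hi = params.transcript_len_range
    transcripts = []
    for t in range(params.n_transcripts):
        length = int(rng.integers(lo, hi + 1))
        parts: list[str] = []
        total = 0
        prev = ""
        while total < length:
            base = BASES[rng.integers(0, 4)]
            if base == prev:
                continue
            run = int(rng.geometric(params.hp_run_p))
            run = min(run, length - total)
            parts.append(base * run)
            total += run
            prev = base
        transcripts.append((f"tx_{t:04d}", "".join(parts)))
    return transcripts


def _run_mask(seq: str, min_run: int = 3) -> np.ndarray:
    """Boolean mask of positions inside homopolymer runs of length >= min_run."""
    mask = np.zeros(len(seq), dtype=bool)
    i = 0
    n = len(seq)
    while i < n:
        j = i
        while j < n and seq[j] == seq[i]:
            j += 1
        if j - i >= min_run:
            mask[i:j] = True
        i = j
    return mask


def simulate_lr(
    truth: list[tuple[str, str]], params: SimParams, rng: np.random.Generator | None = None
) -> tuple[list[tuple[str, str]], dict[str, tuple[str, list[tuple[str, int | None]]]]]:
    """Generate noisy long reads (one or more per transcript) with provenance.

    Errors are drawn i.i.d. per truth base.  Indel rates inside homopolymer
    runs >= 3 are ``hp_bias`` times the outside rates; outside rates are
    rescaled so the transcript-wide expected rates equal the stated ones.
    Provenance ops per emitted LR base: ('M', truth_pos) faithful copy,
    ('S', truth_pos) substitution, ('I', None) inserted base; deleted truth
    bases emit no LR base.
    """
    params.validate()
    rng = rng or np.random.default_rng(params.seed + 1)
    lrs: list[tuple[str, str]] = []
    provenance: dict[str, tuple[str, list[tuple[str, int | None]]]] = {}
    for tid, seq in truth:
        in_run = _run_mask(seq)
        f = float(in_run.mean())
        scale = 1.0 / ((1.0 - f) + params.hp_bias * f) if f > 0 else 1.0
        for j in range(params.lr_per_transcript):
            lr_id = f"lr_{tid}_{j}"
            bases: list[str] = []
            ops: list[tuple[str, int | None]] = []
            n = len(seq)
            u = rng.random((n, 3))
            ins_choices = rng.integers(0, 4, n)
            sub_choices = rng.integers(0, 3, n)
            for pos in range(n):
                bias = params.hp_bias * scale if in_run[pos] else scale
                p_del = params.lr_deletion_rate * bias
                p_ins = params.lr_insertion_rate * bias
                if u[pos, 0] >= p_del:
                    if u[pos, 1] < params.lr_mismatch_rate:
                        bases.append(_OTHER[seq[pos]][sub_choices[pos]])
                        ops.append(("S", pos))
                    else:
                        bases.append(seq[pos])
                        ops.append(("M", pos))
                if u[pos, 2] < p_ins:
                    bases.append(BASES[ins_choices[pos]])
                    ops.append(("I", None))
            lrs.append((lr_id, "".join(bases)))
            provenance[lr_id] = (tid, ops)
    return lrs, provenance


def simulate_sr(
    truth: list[tuple[str, str]], params: SimParams, rng: np.random.Generator | None = None
) -> tuple[list[tuple[str, str]], dict[str, tuple[str, int, int, str]]]:
    """Sample fixed-length short reads uniformly along transcripts.

    Per transcript the read count is Poisson with mean len*depth/sr_len;
    strands are random; substitution errors at sr_error, then N replacement
    at sr_n_rate.  Transcripts shorter than sr_len yield no reads.
    """
    params.validate()
    rng = rng or np.random.default_rng(params.seed + 2)
    srs: list[tuple[str, str]] = []
    provenance: dict[str, tuple[str, int, int, str]] = {}
    counter = 0
    for tid, seq in truth:
        n = len(seq)
        if n < params.sr_len:
            continue
        n_reads = int(rng.poisson(n * params.sr_depth / params.sr_len))
        if n_reads == 0:
            continue
        starts = rng.integers(0, n - params.sr_len + 1, n_reads)
        strands = rng.random(n_reads) < 0.5
        for start, minus in zip(starts, strands):
            start = int(start)
            end = start + params.sr_len
            frag = seq[start:end]
            strand = "-" if minus else "+"
            if minus:
                frag = revcomp(frag)
            read = list(frag)
            errs = rng.random(params.sr_len)
            subs = rng.integers(0, 3, params.sr_len)
            ns = rng.random(params.sr_len)
            for i in range(params.sr_len):
                if errs[i] < params.sr_error:
                    read[i] = _OTHER[read[i]][subs[i]]
                if ns[i] < params.sr_n_rate:
                    read[i] = "N"
            sr_id = f"sr_{counter:07d}"
            counter += 1
            srs.append((sr_id, "".join(read)))
            provenance[sr_id] = (tid, start, end, strand)
    return srs, provenance


def simulate(params: SimParams) -> SimDataset:
    """Run the full generator deterministically from ``params.seed``."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    child = rng.spawn(3)
    transcripts = simulate_truth(params, child[0])
    lrs, lr_prov = simulate_lr(transcripts, params, child[1])
    srs, sr_prov = simulate_sr(transcripts, params, child[2])
    return SimDataset(params, transcripts, lrs, lr_prov, srs, sr_prov)
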