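"""Orchestration of the five correction steps.

1. homopolymer-compress long and short reads;
2. quality-control the compressed short reads;
3. build the concatenated poly-N-spaced reference and align the compressed
   short reads against it (built-in aligner or an external command);
4. consensus-correct each long read from its short-read pileup;
5. decompress and trim each output to its SR-covered span.

The library entry point is :func:`run_correction`; the CLI wraps it.
"""

from __future__ import annotations

import tempfile
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Iterable

import pandas as pd

from .align import builtin_align_to_sam, parse_sam, run_external_aligner
from .correction import ECLongRead, build_pileup, correct_lr, raw_segment
from .errors import ConfigurationError
from .hc import HCRecord, compress
from .qc import QCParams, QCReport, filter_srs
from .reference import build_reference, write_reference
from .seqio import write_fasta


@dataclass
class PipelineConfig:
    """Tunable pipeline parameters.

    spacer_len None means AUTO: use the maximum observed original SR length,
    which guarantees no SR alignment can bridge two LRs through a spacer.
    """

    qc_min_non_n: int = 40
    qc_max_n: int = 1
    spacer_len: int | None = None
    max_chunk_len: int = 250_000_000
    aligner: str = "builtin"  # "builtin" or "external"
    aligner_cmd: str | None = None
    kmer: int = 12
    band: int = 20
    min_score: int = 6
    align_mode: str = "glocal"  # "glocal": SR aligned end-to-end; "local": clipped
    keep_multimapped: bool = False
    min_depth: int = 1
    identity_formula: str = "gap_inclusive"
    seed: int = 0

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Parse a flat ``key = value`` configuration file (# comments allowed)."""
        known = {f.name: f.type for f in fields(cls)}
        kwargs: dict = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ConfigurationError(f"config line {lineno}: expected key = value")
                key, _, value = line.partition("=")
                key, value = key.strip(), value.strip()
                if key not in known:
                    raise ConfigurationError(f"config line {lineno}: unknown key {key!r}")
                kwargs[key] = _coerce(key, value)
        return cls(**kwargs)

    def validate(self) -> None:
        if self.aligner not in ("builtin", "external"):
            raise ConfigurationError(f"aligner must be 'builtin' or 'external', got {self.aligner!r}")
        if self.aligner == "external" and not self.aligner_cmd:
            raise ConfigurationError("external aligner selected but aligner_cmd not set")
        if self.align_mode not in ("glocal", "local"):
            raise ConfigurationError(f"unknown align_mode {self.align_mode!r}")
        if self.identity_formula not in ("gap_inclusive", "span_based"):
            raise ConfigurationError(f"unknown identity_formula {self.identity_formula!r}")
        if self.min_depth < 1:
            raise ConfigurationError("min_depth must be >= 1")


def _coerce(key: str, value: str):
    if value.upper() in ("AUTO", "NONE"):
        return None
    if value.lower() in ("true", "false"):
        return value.lower() == "true"
    try:
        return int(value)
    except ValueError:
        return value


@dataclass
class CorrectionResult:
    ec_reads: list[ECLongRead]
    rlr_seqs: dict[str, str]  # ecLR read_id -> raw segment over the same span
    counts: dict[str, int]
    qc_report: QCReport
    report: pd.DataFrame = field(default_factory=pd.DataFrame)


def run_correction(
    lr_seqs: Iterable[tuple[str, str]],
    sr_seqs: Iterable[tuple[str, str]],
    config: PipelineConfig | None = None,
    work_dir: str | Path | None = None,
) -> CorrectionResult:
    """Run the full correction pipeline on in-memory reads.

    ``work_dir`` holds the intermediate reference FASTA and SAM; a
    temporary directory is used when omitted.
    """
    config = config or PipelineConfig()
    config.validate()
    counts: dict[str, int] = {}

    # step 1: HC transformation
    compressed_lrs = [compress(seq, rid) for rid, seq in lr_seqs]
    sr_original_lens: list[int] = []
    compressed_srs: list[HCRecord] = []
    for rid, seq in sr_seqs:
        sr_original_lens.append(len(seq))
        compressed_srs.append(compress(seq, rid))
    counts["lrs_in"] = len(compressed_lrs)
    counts["srs_in"] = len(compressed_srs)

    # step 2: SR quality control
    qc_report = QCReport()
    qc_params = QCParams(config.qc_min_non_n, config.qc_max_n)
    kept_srs = list(filter_srs(compressed_srs, qc_params, qc_report))
    counts["srs_kept"] = qc_report.kept

    # step 3: reference construction + alignment
    spacer = config.spacer_len
    if spacer is None:
        spacer = max(sr_original_lens, default=75)
    ref = build_reference(compressed_lrs, spacer, config.max_chunk_len)
    counts["chunks"] = len(ref.chunks)

    if work_dir is None:
        tmp = tempfile.TemporaryDirectory(prefix="hccorrect_")
        wdir = Path(tmp.name)
    else:
        tmp = None
        wdir = Path(work_dir)
        wdir.mkdir(parents=True, exist_ok=True)
    try:
        sam_path = wdir / "sr_vs_ref.sam"
        if not kept_srs or not compressed_lrs:
            alignments: list = []
            counts["alignments_parsed"] = 0
        else:
            if config.aligner == "builtin":
                map_counts = builtin_align_to_sam(
                    ref,
                    kept_srs,
                    sam_path,
                    k=config.kmer,
                    band=config.band,
                    min_score=config.min_score,
                    mode=config.align_mode,
                    keep_multimapped=config.keep_multimapped,
                )
                counts.update({f"aligner_{k}": v for k, v in map_counts.items()})
            else:
                ref_fasta = wdir / "reference.fa"
                sr_fasta = wdir / "sr_compressed.fa"
                write_reference(ref, ref_fasta, wdir / "reference_index.tsv")
                write_fasta(((r.read_id, r.compressed_seq) for r in kept_srs), sr_fasta)
                run_external_aligner(config.aligner_cmd, sr_fasta, ref_fasta, sam_path)
            sr_table = {r.read_id: r for r in kept_srs}
            alignments, sam_counts = parse_sam(
                sam_path, ref, sr_table, keep_multimapped=config.keep_multimapped
            )
            counts.update({f"sam_{k}": v for k, v in sam_counts.items()})
            counts["alignments_parsed"] = len(alignments)
    finally:
        if tmp is not None:
            tmp.cleanup()

    # steps 4-5: pileup, consensus correction, decompression, trimming
    by_lr: dict[str, list] = {}
    for aln in alignments:
        by_lr.setdefault(aln.lr_id, []).append(aln)
    ec_reads: list[ECLongRead] = []
    rlr_seqs: dict[str, str] = {}
    rows = []
    uncovered = 0
    for lr in compressed_lrs:
        pile = build_pileup(lr, by_lr.get(lr.read_id, []))
        ec = correct_lr(lr, pile, min_depth=config.min_depth)
        if ec is None:
            uncovered += 1
            continue
        ec_reads.append(ec)
        rlr_seqs[ec.read_id] = raw_segment(lr, ec.trim_bounds)
        covered = sum(ec.covered_mask)
        rows.append(
            {
                "read_id": ec.read_id,
                "original_length": len(lr.original_seq),
                "output_length": len(ec.seq),
                "trim_start": ec.trim_bounds[0],
                "trim_end": ec.trim_bounds[1],
                "sp": covered / len(ec.seq),
                "mean_scd": sum(ec.scd) / len(ec.scd),
            }
        )
    counts["lrs_corrected"] = len(ec_reads)
    counts["lrs_uncovered"] = uncovered
    report = pd.DataFrame(rows)
    return CorrectionResult(ec_reads, rlr_seqs, counts, qc_report, report)


def write_outputs(result: CorrectionResult, out_dir: str | Path) -> dict[str, str]:
    """Write ecLR FASTA, paired rLR FASTA, per-read report and SCD tracks."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "eclr": str(out / "eclr.fa"),
        "rlr": str(out / "rlr.fa"),
        "report": str(out / "read_report.tsv"),
        "scd": str(out / "eclr_scd.tsv"),
    }
    write_fasta(((ec.read_id, ec.seq) for ec in result.ec_reads), paths["eclr"])
    write_fasta(sorted(result.rlr_seqs.items()), paths["rlr"])
    result.report.to_csv(paths["report"], sep="\t", index=False)
    with open(paths["scd"], "w") as fh:
        fh.write("read_id\tscd\n")
        for ec in result.ec_reads:
            fh.write(ec.read_id + "\t" + ",".join(map(str, ec.scd)) + "\n")
    return paths
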