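"""Shared fixtures: one desk-scale simulation + pipeline run reused by the
end-to-end property tests, and a smaller one for fast unit checks."""

import pytest

from hccorrect.metrics import (
    evaluate_alignment,
    region_identities,
    scd_match_table,
    sequence_identity,
)
from hccorrect.pipeline import PipelineConfig, run_correction
from hccorrect.synthetic import SimParams, simulate

#: Study conditions for the end-to-end evaluation: 20 transcripts, 15%
#: indel-dominated LR error with 3x homopolymer bias, SR depth 5, SR error 2%.
STUDY_PARAMS = SimParams(n_transcripts=20, sr_depth=5.0, seed=0)


@pytest.fixture(scope="session")
def study_sim():
    return simulate(STUDY_PARAMS)


@pytest.fixture(scope="session")
def study_result(study_sim):
    return run_correction(study_sim.lrs, study_sim.srs, PipelineConfig())


@pytest.fixture(scope="session")
def study_truths(study_sim):
    return {
        lr_id: study_sim.truth_by_id[tid]
        for lr_id, (tid, _) in study_sim.lr_provenance.items()
    }


@pytest.fixture(scope="session")
def study_eval(study_result, study_truths):
    """Per-read identities and region identities for the study run."""
    rows = []
    for ec in study_result.ec_reads:
        truth = study_truths[ec.source_id]
        ec_i = sequence_identity(evaluate_alignment(ec.read_id, ec.seq, truth))
        rlr_i = sequence_identity(
            evaluate_alignment(ec.read_id, study_result.rlr_seqs[ec.read_id], truth)
        )
        regions = region_identities(ec, truth)
        covered_n = sum(ec.covered_mask)
        rows.append(
            {
                "ec": ec,
                "ec_identity": ec_i,
                "rlr_identity": rlr_i,
                "covered_identity": regions["covered"],
                "uncovered_identity": regions["uncovered"],
                "covered_bases": covered_n,
                "uncovered_bases": len(ec.seq) - covered_n,
            }
        )
    return rows


@pytest.fixture(scope="session")
def study_scd_table(study_result, study_truths):
    return scd_match_table(study_result.ec_reads, study_truths)


@pytest.fixture(scope="session")
def small_sim():
    return simulate(SimParams(n_transcripts=4, transcript_len_range=(500, 1500), sr_depth=8.0, seed=3))


@pytest.fixture(scope="session")
def small_result(small_sim):
    return run_correction(small_sim.lrs, small_sim.srs, PipelineConfig())
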