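"""Shared fixtures: synthetic recordings at the study's standard conditions.

Heavy artifacts (cohorts, processed recordings) are session-scoped so the
signal-chain unit tests and the acceptance tests share one computation.
"""

import numpy as np
import pytest

from cardiomech.core_io import PipelineConfig
from cardiomech.pipeline import build_feature_matrices, process_recording
from cardiomech.synth import SynthConfig, generate_cohort, generate_recording


@pytest.fixture(scope="session")
def config():
    return PipelineConfig()


@pytest.fixture(scope="session")
def clean_recording():
    """Zero-noise, artifact-free 40 s recording with ground truth."""
    cfg = SynthConfig(duration=40.0, noise_sd=0.0, artifact_rate=0.0, seed=11)
    return generate_recording(cfg)


@pytest.fixture(scope="session")
def clean_processed(clean_recording, config):
    rec, gt = clean_recording
    return process_recording(rec, M=500.0, N=11.2, config=config)


@pytest.fixture(scope="session")
def lownoise_recording():
    """noise_sd = 0.05 (the generator default), no artifacts, 60 s."""
    cfg = SynthConfig(duration=60.0, noise_sd=0.05, artifact_rate=0.0, seed=21)
    return generate_recording(cfg)


@pytest.fixture(scope="session")
def lownoise_processed(lownoise_recording, config):
    rec, gt = lownoise_recording
    return process_recording(rec, M=500.0, N=11.2, config=config)


@pytest.fixture(scope="session")
def burst_recording():
    """Recording with strong motion-artifact bursts for mask recovery tests."""
    cfg = SynthConfig(duration=60.0, noise_sd=0.05, artifact_rate=6.0,
                      artifact_gain=10.0, seed=31)
    return generate_recording(cfg)


@pytest.fixture(scope="session")
def e2e_cohort():
    """Healthy vs severe cohort at the end-to-end study conditions:
    10 subjects per class, 300 s recordings, generator defaults, seed 0.
    With ~100 features, cohorts much smaller than this admit spurious
    perfect separators of the training subjects by chance."""
    return generate_cohort(10, SynthConfig(duration=300.0), seed=0,
                           labels=("healthy", "severe"))


@pytest.fixture(scope="session")
def e2e_matrices(e2e_cohort):
    recs = [r for r, _ in e2e_cohort]
    return build_feature_matrices(recs, M=500.0, N=10.0)


@pytest.fixture(scope="session")
def bo_cohort():
    """Smaller cohort (3/class, 120 s) for the filter-optimization runs."""
    return generate_cohort(3, SynthConfig(duration=120.0), seed=7,
                           labels=("healthy", "severe"))


#: beats whose J peak lies closer than this to a chunk edge have part of
#: their waveform support outside the chunk and are not scoreable
EDGE_MARGIN_S = 0.2


def truth_in_chunk(gt, chunk, margin=EDGE_MARGIN_S):
    """Ground-truth beat times falling inside a chunk, chunk-relative."""
    t = gt.beat_times
    sel = (t >= chunk.start_time + margin) & (t < chunk.start_time + chunk.N - margin)
    return t[sel] - chunk.start_time


def score_beats(beat_set, gt, chunk, tol=0.150, margin=EDGE_MARGIN_S):
    """(recall, precision, abs errors) vs truth, excluding edge beats on
    both sides of the comparison."""
    from cardiomech.beats import match_beats
    truth = truth_in_chunk(gt, chunk, margin)
    det = beat_set.fused_peak_times
    det = det[(det >= margin) & (det < chunk.N - margin)]
    return match_beats(det, truth, tol)
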