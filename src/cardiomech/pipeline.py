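"""End-to-end orchestration: recording -> chunks -> beats -> fiducials -> features.

This is the glue the classifier layer and the (M, N) filter optimizer call:
given raw recordings it rebuilds the chunk-level and subject-level feature
matrices from scratch for any RMS-window length M (ms) and chunk length N (s).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from . import beats as beats_mod
from . import features as feat_mod
from . import fiducials as fid_mod
from . import preprocess as pre_mod
from .core_io import FeatureMatrix, PipelineConfig, Recording

log = logging.getLogger("cardiomech")


def extract_chunk_features(chunk, config: PipelineConfig):
    """Feature dict (103) for one chunk, or None if the chunk is excluded.

    Exclusion reasons: unusable beat detection, <50% valid fiducial rows,
    fewer than 3 valid interval rows, or fewer than 3 NN intervals.
    Returns ``(features_or_None, fiducial_table)``.
    """
    beat_set = beats_mod.detect_beats(chunk, config)
    table = fid_mod.annotate_chunk(chunk, beat_set, config)
    if not beat_set.usable or len(table) == 0:
        return None, table
    if fid_mod.validity_fraction(table) < config.min_valid_beat_fraction:
        log.debug("chunk %s: <%d%% valid beats, excluded", chunk.chunk_id,
                  int(100 * config.min_valid_beat_fraction))
        return None, table
    block = feat_mod.interval_block(table)
    nn = feat_mod.nn_series(table, config)
    if len(block) < 3 or len(nn) < 3:
        return None, table
    feats = feat_mod.gcg_interval_features(block)
    feats.update(feat_mod.time_hrv_features(nn, config))
    return feats, table


def process_recording(rec: Recording, M: float | None = None,
                      N: float | None = None, overlap: float | None = None,
                      config: PipelineConfig | None = None):
    """Run the full signal chain on one recording.

    Returns a dict with keys ``chunks``, ``mask``, ``chunk_features``
    (list of (chunk_id, label, dict)) and ``fiducial_tables``.
    """
    config = config or PipelineConfig()
    chunks, mask = pre_mod.preprocess_recording(rec, M, N, overlap, config)
    chunk_feats, tables = [], []
    for chunk in chunks:
        feats, table = extract_chunk_features(chunk, config)
        tables.append(table)
        if feats is not None:
            chunk_feats.append((chunk.chunk_id, rec.label, feats))
    return {"chunks": chunks, "mask": mask, "chunk_features": chunk_feats,
            "fiducial_tables": tables}


def subject_features(rec: Recording, result: dict,
                     config: PipelineConfig | None = None):
    """Subject-level feature dict (133) pooling all valid beats of a subject.

    GCG statistics and the NN series pool every valid (beat, axis) row /
    every chunk-wise NN interval of the subject; frequency-HRV features come
    from the raw artifact-masked recording.  Returns None if the subject has
    too few valid beats.
    """
    config = config or PipelineConfig()
    tables = [t for t in result["fiducial_tables"] if len(t)]
    if not tables:
        return None
    pooled = pd.concat(tables, ignore_index=True)
    block = feat_mod.interval_block(pooled)
    nn = feat_mod.nn_series(pooled, config)
    if len(block) < 3 or len(nn) < 3:
        return None
    feats = feat_mod.gcg_interval_features(block)
    feats.update(feat_mod.time_hrv_features(nn, config))
    feats.update(feat_mod.freq_hrv_features(rec, result["mask"], config))
    return feats


def build_feature_matrices(recordings, M: float | None = None,
                           N: float | None = None, overlap: float | None = None,
                           config: PipelineConfig | None = None,
                           levels=("chunk", "subject"),
                           policy: str = "drop") -> dict:
    """Chunk-level and/or subject-level FeatureMatrix for a cohort.

    ``recordings`` is an iterable of Recording.  Returns a dict keyed by
    level; raises if a requested level ends up empty.
    """
    config = config or PipelineConfig()
    chunk_rows, subj_rows = [], []
    for rec in recordings:
        result = process_recording(rec, M, N, overlap, config)
        chunk_rows.extend(result["chunk_features"])
        if "subject" in levels:
            sf = subject_features(rec, result, config)
            if sf is not None:
                subj_rows.append((rec.subject_id, rec.label, sf))
    out = {}
    if "chunk" in levels:
        out["chunk"] = feat_mod.assemble_matrix(chunk_rows, "chunk", policy)
    if "subject" in levels:
        out["subject"] = feat_mod.assemble_matrix(subj_rows, "subject", policy)
    return out


def subject_of(sample_id: str) -> str:
    """Chunk ids are '<subject>/cNNN'; subject ids pass through unchanged."""
    return sample_id.split("/")[0]
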