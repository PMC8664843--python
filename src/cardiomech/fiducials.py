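"""Per-beat fiducial annotation on the gyrocardiogram X and Y axes.

After an additional 1-10 Hz zero-phase band-pass, each beat window is
annotated with the classical gyrocardiographic fiducials — J (dominant
positive peak), I/K (nearest local minima before/after J), L (first local
maximum after K) and A (last local maximum before I) — plus the
maximum-acceleration point P: the sample where the magnitude of the first
difference of the angular-rate signal (i.e. angular acceleration) is
largest within the beat, and its amplitude MA.  Beats in which a required
extremum is absent, or the recovered ordering A<I<J<K<L fails, are flagged
invalid and excluded from interval statistics — never silently guessed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.signal import argrelextrema

from .beats import BeatSet
from .core_io import PipelineConfig
from .preprocess import CleanChunk, bandpass

#: FiducialTable column layout
FIDUCIAL_COLUMNS = ("chunk", "beat", "axis", "t_A", "t_I", "t_J", "t_K",
                    "t_L", "t_P", "MA", "valid")

ANNOTATED_AXES = {"gcg_x": "gyr_x", "gcg_y": "gyr_y"}


def _local_extrema(x: np.ndarray, kind: str) -> np.ndarray:
    comp = np.less if kind == "min" else np.greater
    return argrelextrema(x, comp)[0]


def annotate_beat(axis_signal: np.ndarray, fs: float, j_time: float,
                  beat_window: tuple, config: PipelineConfig | None = None) -> dict:
    """Annotate one beat on one (already 1-10 Hz filtered) axis signal.

    Times are in seconds on the signal's own axis.  Returns a dict with
    keys ``t_A .. t_P, MA, valid``; a missing extremum or an ordering
    violation yields ``valid=False`` with NaN times.
    """
    config = config or PipelineConfig()
    w0, w1 = beat_window
    if not w0 <= j_time <= w1:
        raise ValueError("j_time must lie inside the beat window")
    a_idx = max(int(np.ceil(w0 * fs)), 0)
    b_idx = min(int(np.floor(w1 * fs)) + 1, len(axis_signal))
    seg = axis_signal[a_idx:b_idx]
    row = {k: np.nan for k in ("t_A", "t_I", "t_J", "t_K", "t_L", "t_P", "MA")}
    row["valid"] = False
    if len(seg) < 5:
        return row

    # J: local signed maximum nearest the detector's peak
    half = int(round(config.axis_refine_halfwidth_s * fs))
    j0 = int(round(j_time * fs)) - a_idx
    lo, hi = max(j0 - half, 0), min(j0 + half + 1, len(seg))
    j = lo + int(np.argmax(seg[lo:hi]))

    mins = _local_extrema(seg, "min")
    maxs = _local_extrema(seg, "max")
    ik_w = int(round(config.ik_window_s * fs))
    al_w = int(round(config.al_window_s * fs))

    pre = mins[(mins < j) & (mins >= j - ik_w)]
    post = mins[(mins > j) & (mins <= j + ik_w)]
    if len(pre) == 0 or len(post) == 0:
        return row
    i_pt, k_pt = pre[-1], post[0]
    after_k = maxs[(maxs > k_pt) & (maxs <= k_pt + al_w)]
    before_i = maxs[(maxs < i_pt) & (maxs >= i_pt - al_w)]
    if len(after_k) == 0 or len(before_i) == 0:
        return row
    l_pt, a_pt = after_k[0], before_i[-1]
    if not (a_pt < i_pt < j < k_pt < l_pt):
        return row

    # P / MA: extremum of |angular acceleration| over the whole beat window
    dseg = np.abs(np.diff(seg)) * fs
    p_pt = int(np.argmax(dseg))
    row.update(t_A=(a_pt + a_idx) / fs, t_I=(i_pt + a_idx) / fs,
               t_J=(j + a_idx) / fs, t_K=(k_pt + a_idx) / fs,
               t_L=(l_pt + a_idx) / fs, t_P=(p_pt + a_idx) / fs,
               MA=float(dseg[p_pt]), valid=True)
    return row


def annotate_chunk(chunk: CleanChunk, beats: BeatSet,
                   config: PipelineConfig | None = None) -> pd.DataFrame:
    """Annotate every detected beat on GCG_X and GCG_Y.

    The beat window spans 40% of the preceding inter-beat interval before
    J to 60% after (the first beat borrows the following interval),
    clipped to the chunk.  Returns a FiducialTable DataFrame, one row per
    (beat, axis); empty if the chunk was flagged unusable.
    """
    config = config or PipelineConfig()
    if not beats.usable:
        return pd.DataFrame(columns=list(FIDUCIAL_COLUMNS))
    fs = chunk.fs
    dur = len(chunk.samples) / fs
    rows = []
    for axis, ch in ANNOTATED_AXES.items():
        sig = bandpass(chunk.channel(ch), fs, config.bandpass_order,
                       *config.fiducial_band)
        j_times = beats.per_axis_peak_times.get(ch, beats.fused_peak_times)
        fused = beats.fused_peak_times
        for b, jt in enumerate(j_times):
            prev_ibi = (fused[b] - fused[b - 1]) if b > 0 else (fused[1] - fused[0])
            w0 = max(jt - config.beat_window_before * prev_ibi, 0.0)
            w1 = min(jt + config.beat_window_after * prev_ibi, dur - 1.0 / fs)
            row = annotate_beat(sig, fs, jt, (w0, w1), config)
            row.update(chunk=chunk.chunk_id, beat=b, axis=axis)
            rows.append(row)
    df = pd.DataFrame(rows, columns=list(FIDUCIAL_COLUMNS))
    return df


def validity_fraction(table: pd.DataFrame) -> float:
    """Fraction of valid rows; 0.0 for an empty table."""
    return float(table["valid"].mean()) if len(table) else 0.0
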