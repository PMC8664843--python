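"""Heartbeat detection from the fused linear+angular envelope.

The three accelerometer axes and the three gyroscope axes are each fused
into a per-sample RMS resultant; a Hilbert-transform envelope of each
resultant is smoothed with a zero-phase 2 Hz low-pass, median-normalized
(the two modalities carry different physical units) and summed.  Beats are
the peaks of that summation signal, found with an adaptive dual-threshold
tracker in the Pan-Tompkins tradition: exponentially updated signal/noise
levels, a 300 ms refractory period, and a search-back pass at 1.66x the
running beat interval.  Each fused peak is then refined per axis to the
local signed maximum of the band-passed axis signal within +/-25 ms.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import signal as sps
from scipy.signal import hilbert

from .core_io import ACC_CHANNELS, GYR_CHANNELS, IMU_CHANNELS, PipelineConfig
from .preprocess import CleanChunk, lowpass


def axis_rms_fuse(channels: np.ndarray) -> np.ndarray:
    """Per-sample RMS across exactly three same-length channels."""
    channels = np.asarray(channels, dtype=float)
    if channels.ndim != 2 or channels.shape[1] != 3:
        raise ValueError("expected an (n, 3) channel matrix")
    return np.sqrt(np.mean(channels ** 2, axis=1))


def hilbert_envelope(x, fs: float, smooth: bool = True,
                     config: PipelineConfig | None = None) -> np.ndarray:
    """Magnitude of the analytic signal, optionally 2 Hz low-passed."""
    x = np.asarray(x, dtype=float)
    if len(x) < 4:
        raise ValueError("signal too short for an analytic envelope")
    env = np.abs(hilbert(x))
    if smooth:
        config = config or PipelineConfig()
        env = lowpass(env, fs, config.envelope_lowpass_order,
                      config.envelope_lowpass_hz)
    return env


@dataclasses.dataclass
class BeatSet:
    """Fused beat times plus per-axis refined peak times for one chunk."""

    fused_peak_times: np.ndarray             # s, relative to chunk start
    per_axis_peak_times: dict                # axis name -> s array
    chunk_ref: str = ""
    usable: bool = True


def _adaptive_peaks(e: np.ndarray, fs: float, config: PipelineConfig) -> np.ndarray:
    """Adaptive dual-threshold peak picking on the summation envelope."""
    refr = int(round(config.refractory_s * fs))
    cand, _ = sps.find_peaks(e)
    # zero-phase filtering leaves transients at the chunk edges; candidates
    # there are artifacts, not beats
    guard = int(round(config.envelope_edge_guard_s * fs))
    cand = cand[(cand >= guard) & (cand < len(e) - guard)]
    if len(cand) == 0:
        return np.array([], dtype=int)
    # initialize levels from the interior candidate peaks (robust to edge
    # transients that would inflate a time-windowed maximum)
    spk = float(np.percentile(e[cand], 90))
    npk = float(np.median(e))
    w = config.spk_weight
    frac = config.threshold_fraction

    accepted: list[int] = []
    rejected: list[int] = []
    intervals: list[int] = []

    def thr() -> float:
        return npk + frac * (spk - npk)

    def accept(idx: int, amp: float):
        nonlocal spk
        if accepted:
            intervals.append(idx - accepted[-1])
        accepted.append(idx)
        spk = w * amp + (1 - w) * spk

    for idx in cand:
        if accepted and idx - accepted[-1] < refr:
            continue
        if e[idx] > thr():
            accept(idx, e[idx])
        else:
            rejected.append(idx)
            npk = w * e[idx] + (1 - w) * npk
        # search-back: a missed beat leaves a gap > 1.66x the running interval
        if accepted and len(intervals) >= 2:
            run_int = float(np.mean(intervals[-8:]))
            gap_from = accepted[-1]
            if idx - gap_from > config.searchback_factor * run_int:
                inside = [r for r in rejected
                          if gap_from + refr <= r <= idx - refr
                          and e[r] > 0.5 * thr()]
                if inside:
                    best = max(inside, key=lambda r: e[r])
                    rejected.remove(best)
                    # re-insert in time order and rebuild the interval list
                    accepted.append(best)
                    accepted.sort()
                    intervals = list(np.diff(accepted))
                    spk = w * e[best] + (1 - w) * spk
    return np.asarray(accepted, dtype=int)


def detect_beats(chunk: CleanChunk, config: PipelineConfig | None = None) -> BeatSet:
    """Detect beats in one clean chunk and refine peaks per axis.

    The summation signal is ``normalize(env_SCG) + normalize(env_GCG)``
    where each envelope is divided by its own chunk median.  A chunk in
    which fewer than two beats are found is flagged unusable (never a
    crash) and is excluded downstream.
    """
    config = config or PipelineConfig()
    fs = chunk.fs
    env_sum = np.zeros(len(chunk.samples))
    for group in (ACC_CHANNELS, GYR_CHANNELS):
        resultant = axis_rms_fuse(np.column_stack([chunk.channel(c) for c in group]))
        env = hilbert_envelope(resultant, fs, smooth=True, config=config)
        med = np.median(env)
        env_sum += env / med if med > 0 else env
    peak_idx = _adaptive_peaks(env_sum, fs, config)
    fused_times = peak_idx / fs
    if len(peak_idx) < 2:
        return BeatSet(fused_times, {}, chunk_ref=chunk.chunk_id, usable=False)

    half = int(round(config.axis_refine_halfwidth_s * fs))
    per_axis = {}
    for ch in IMU_CHANNELS:
        sig = chunk.channel(ch)
        times = np.empty(len(peak_idx))
        for k, p in enumerate(peak_idx):
            a, b = max(p - half, 0), min(p + half + 1, len(sig))
            times[k] = (a + int(np.argmax(sig[a:b]))) / fs
        per_axis[ch] = times
    return BeatSet(fused_times, per_axis, chunk_ref=chunk.chunk_id, usable=True)


def match_beats(detected: np.ndarray, truth: np.ndarray, tol: float = 0.150):
    """Greedy one-to-one matching of detected beat times to ground truth.

    Returns ``(recall, precision, abs_errors_s)`` with matches constrained
    to ``|detected - truth| <= tol`` seconds.
    """
    detected = np.asarray(detected, float)
    truth = np.asarray(truth, float)
    if len(truth) == 0:
        return (np.nan, np.nan, np.array([]))
    used = np.zeros(len(detected), bool)
    errors = []
    for t in truth:
        if len(detected) == 0:
            break
        d = np.abs(detected - t)
        d[used] = np.inf
        j = int(np.argmin(d))
        if d[j] <= tol:
            used[j] = True
            errors.append(d[j])
    n_match = len(errors)
    recall = n_match / len(truth)
    precision = n_match / len(detected) if len(detected) else np.nan
    return recall, precision, np.asarray(errors)
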