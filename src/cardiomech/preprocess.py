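"""Band-pass filtering, RMS motion-artifact masking and chunk segmentation.

Accelerometer (SCG) channels are band-passed at 1-45 Hz and gyroscope (GCG)
channels at 1-20 Hz with a zero-phase 4th-order Butterworth filter, so
fiducial timing is not skewed by group delay.  Motion artifacts are flagged
wherever a sliding root-mean-square of the combined 6-axis resultant exceeds
twice its median; flagged regions are never spliced — each maximal clean run
is tiled independently into fixed-length chunks, and runs shorter than one
chunk are discarded.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import signal

from .core_io import ACC_CHANNELS, GYR_CHANNELS, IMU_CHANNELS, PipelineConfig, Recording


def bandpass(x, fs: float, order: int, lo: float, hi: float) -> np.ndarray:
    """Zero-phase (forward-backward) Butterworth band-pass.

    The effective magnitude order doubles under filtfilt; this is
    documented behaviour, not compensated.
    """
    x = np.asarray(x, dtype=float)
    if not 0 < lo < hi:
        raise ValueError("need 0 < lo < hi")
    if hi >= fs / 2:
        raise ValueError(f"high cut-off {hi} Hz must be below Nyquist {fs / 2} Hz")
    sos = signal.butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, x, axis=0)


def lowpass(x, fs: float, order: int, hi: float) -> np.ndarray:
    """Zero-phase Butterworth low-pass."""
    if hi >= fs / 2:
        raise ValueError("cut-off must be below Nyquist")
    sos = signal.butter(order, hi, btype="lowpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, np.asarray(x, dtype=float), axis=0)


def moving_rms(x, fs: float, M: float) -> np.ndarray:
    """Centered sliding-window RMS with window length ``M`` milliseconds.

    Edges are handled by window truncation, so the output has the input's
    length and a constant input maps to |constant| everywhere.
    """
    x = np.asarray(x, dtype=float)
    w = int(round(M / 1000.0 * fs))
    if w < 2:
        raise ValueError("RMS window must span at least 2 samples")
    if w > len(x):
        raise ValueError("RMS window longer than signal")
    kernel = np.ones(w)
    ssum = signal.convolve(x * x, kernel, mode="same")
    count = signal.convolve(np.ones_like(x), kernel, mode="same")
    return np.sqrt(np.maximum(ssum / count, 0.0))


@dataclasses.dataclass
class ArtifactMask:
    """Per-sample keep/reject mask built from the RMS artifact filter."""

    keep: np.ndarray          # bool, aligned to samples
    M: float                  # RMS window, ms
    threshold: float          # = 2 x median of the RMS-filter output

    @property
    def kept_fraction(self) -> float:
        return float(np.mean(self.keep))

    def clean_runs(self) -> list[tuple[int, int]]:
        """Maximal [start, stop) index runs of kept samples."""
        k = np.asarray(self.keep, bool)
        if not k.any():
            return []
        edges = np.flatnonzero(np.diff(np.concatenate([[False], k, [False]]).astype(int)))
        return list(zip(edges[::2], edges[1::2]))

    def intervals(self, fs: float) -> list[tuple[float, float]]:
        """Rejected (artifact) intervals in seconds."""
        r = ~np.asarray(self.keep, bool)
        if not r.any():
            return []
        edges = np.flatnonzero(np.diff(np.concatenate([[False], r, [False]]).astype(int)))
        return [(a / fs, b / fs) for a, b in zip(edges[::2], edges[1::2])]


@dataclasses.dataclass
class CleanChunk:
    """A contiguous artifact-free segment of band-passed signal."""

    samples: np.ndarray       # (floor(N*fs), 6), canonical channel order
    start_time: float         # s, in the source recording
    source_subject: str
    N: float                  # chunk length, s
    fs: float
    label: str | None = None
    chunk_id: str = ""

    def channel(self, name: str) -> np.ndarray:
        return self.samples[:, IMU_CHANNELS.index(name)]


def bandpass_recording(rec: Recording, config: PipelineConfig | None = None) -> np.ndarray:
    """Band-pass the six IMU channels (SCG 1-45 Hz, GCG 1-20 Hz by default)."""
    config = config or PipelineConfig()
    out = np.empty((rec.n_samples, 6))
    for i, ch in enumerate(IMU_CHANNELS):
        band = config.scg_band if ch in ACC_CHANNELS else config.gcg_band
        out[:, i] = bandpass(rec.channel(ch), rec.fs, config.bandpass_order, *band)
    return out


def artifact_mask(rec: Recording, M: float | None = None,
                  config: PipelineConfig | None = None,
                  filtered: np.ndarray | None = None) -> ArtifactMask:
    """Flag motion artifacts on the joint 6-axis resultant magnitude.

    The sliding RMS of the per-sample root-mean-square across all six
    band-passed channels is compared against twice its median; samples at
    or below the threshold are kept (ties kept), and the mask applies to
    all channels jointly so they stay synchronized.
    """
    config = config or PipelineConfig()
    if M is None:
        M = config.rms_window_ms
    if filtered is None:
        filtered = bandpass_recording(rec, config)
    resultant = np.sqrt(np.mean(filtered ** 2, axis=1))
    env = moving_rms(resultant, rec.fs, M)
    threshold = 2.0 * float(np.median(env))
    keep = env <= threshold
    return ArtifactMask(keep=keep, M=M, threshold=threshold)


def segment_chunks(rec: Recording, mask: ArtifactMask, N: float,
                   overlap: float = 0.0,
                   config: PipelineConfig | None = None,
                   filtered: np.ndarray | None = None) -> list[CleanChunk]:
    """Tile each maximal clean run with N-second windows.

    Windows start at the run start with stride ``N*(1-overlap)``; trailing
    partial windows and runs shorter than N are discarded.  Chunks carry
    the band-passed samples.
    """
    if not 0 <= overlap < 1:
        raise ValueError("overlap must lie in [0, 1)")
    config = config or PipelineConfig()
    if filtered is None:
        filtered = bandpass_recording(rec, config)
    n = int(np.floor(N * rec.fs))
    stride = max(int(round(N * (1.0 - overlap) * rec.fs)), 1)
    chunks = []
    for a, b in mask.clean_runs():
        start = a
        while start + n <= b:
            chunks.append(CleanChunk(
                samples=filtered[start:start + n].copy(),
                start_time=start / rec.fs,
                source_subject=rec.subject_id, N=N, fs=rec.fs,
                label=rec.label,
                chunk_id=f"{rec.subject_id}/c{len(chunks):03d}"))
            start += stride
    return chunks


def preprocess_recording(rec: Recording, M: float | None = None,
                         N: float | None = None, overlap: float | None = None,
                         config: PipelineConfig | None = None):
    """Band-pass, mask artifacts and segment one recording.

    Returns ``(chunks, mask)``.  ``M`` (ms) and ``N`` (s) default to the
    literature values of the config (500 ms, 10 s).
    """
    config = config or PipelineConfig()
    N = config.chunk_seconds if N is None else N
    overlap = config.chunk_overlap if overlap is None else overlap
    filtered = bandpass_recording(rec, config)
    mask = artifact_mask(rec, M, config, filtered=filtered)
    chunks = segment_chunks(rec, mask, N, overlap, config, filtered=filtered)
    return chunks, mask
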