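"""The 133-wide cardiomechanical feature space.

Three blocks:

* **Time-domain HRV** (15) — computed on the NN series, the successive
  differences of consecutive GCG J-peak times: AVNN, SDNN, RMSSD, pNN50,
  median/skewness/kurtosis, histogram entropies (ENN, self-entropy SENN,
  conditional entropy CENN), and the Poincare-map indices VAI, VLI, SD1,
  SD2 and SD1/SD2.
* **GCG timing intervals** (11 x 8 = 88) — IVCT (J-I), LVET (K-J),
  IVRT (L-K), L-I, L-J, K-I, P-I, P-J, K-P, L-P and the MA amplitude,
  each summarized by mean, median, std, skewness, kurtosis, entropy,
  min and max over all valid (beat, axis) rows in scope.
* **Frequency-domain HRV** (6 x 5 = 30) — Welch band powers VLF
  (0.0033-0.04 Hz), LF (0.04-0.15 Hz), HF (0.15-0.4 Hz), the LF/HF ratio
  and total power, per raw (artifact-masked, non-band-passed) IMU axis.

Chunk-level matrices carry 88 + 15 = 103 columns (chunks are too short
for the HRV spectral bands); subject-level matrices carry all 133.

All standard deviations are population-style (divide by n); skewness and
kurtosis are the Fisher moment ratios, kurtosis not excess-adjusted and
bias-uncorrected, so that independent brute-force oracles are unambiguous.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd
from scipy import signal as sps

from .core_io import FeatureMatrix, PipelineConfig, Recording
from .preprocess import ArtifactMask

# ---------------------------------------------------------------------------
# canonical feature names

TIME_HRV_FEATURES = (
    "AVNN_time", "SDNN_time", "RMSSD_time", "pNN50_time", "NN_med_time",
    "NN_sk_time", "NN_ku_time", "ENN_time", "SENN_time", "CENN_time",
    "VAI_time", "VLI_time", "SD1_time", "SD2_time", "SD1/SD2_time",
)

GCG_PARAMS = ("IVCT", "LVET", "IVRT", "LI", "LJ", "KI", "PI", "PJ", "KP", "LP", "MA")
GCG_STATS = ("mean", "median", "std", "sk", "ku", "entropy", "min", "max")
GCG_FEATURES = tuple(f"{p}_{s}_GCG" for p in GCG_PARAMS for s in GCG_STATS)

FREQ_AXES = ("SCG_X", "SCG_Y", "SCG_Z", "GCG_X", "GCG_Y", "GCG_Z")
_AXIS_TO_CHANNEL = {"SCG_X": "acc_x", "SCG_Y": "acc_y", "SCG_Z": "acc_z",
                    "GCG_X": "gyr_x", "GCG_Y": "gyr_y", "GCG_Z": "gyr_z"}
FREQ_MEASURES = ("vlf_HRV", "lf_HRV", "hf_HRV", "lfhfRatio", "TotalPow")
FREQ_FEATURES = tuple(f"{m}_{a}_freq" for a in FREQ_AXES for m in FREQ_MEASURES)

CHUNK_LEVEL_FEATURES = GCG_FEATURES + TIME_HRV_FEATURES              # 103
SUBJECT_LEVEL_FEATURES = GCG_FEATURES + TIME_HRV_FEATURES + FREQ_FEATURES

VLF_BAND = (0.0033, 0.04)
LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.4)


# ---------------------------------------------------------------------------
# scalar statistics

def _pop_std(x: np.ndarray) -> float:
    return float(np.sqrt(np.mean((x - np.mean(x)) ** 2)))


def _skewness(x: np.ndarray) -> float:
    m = np.mean(x)
    m2 = np.mean((x - m) ** 2)
    if m2 == 0:
        return 0.0
    return float(np.mean((x - m) ** 3) / m2 ** 1.5)


def _kurtosis(x: np.ndarray) -> float:
    """Moment-ratio kurtosis (a normal sample tends to 3); constants map to 0."""
    m = np.mean(x)
    m2 = np.mean((x - m) ** 2)
    if m2 == 0:
        return 0.0
    return float(np.mean((x - m) ** 4) / m2 ** 2)


def shannon_entropy(x: np.ndarray, bin_width: float | None = None) -> float:
    """Shannon entropy (bits) of a fixed-width histogram.

    Default bin width is Freedman-Diaconis; a zero width (constant data or
    zero IQR) degrades to a single bin, entropy 0.
    """
    x = np.asarray(x, float)
    if bin_width is None:
        q75, q25 = np.percentile(x, [75, 25])
        bin_width = 2.0 * (q75 - q25) / len(x) ** (1.0 / 3.0)
    if bin_width <= 0 or np.ptp(x) == 0:
        return 0.0
    edges = _bin_edges(x.min(), x.max(), bin_width)
    counts, _ = np.histogram(x, bins=edges)
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log2(p)).sum())


def _bin_edges(lo: float, hi: float, width: float) -> np.ndarray:
    n = max(int(np.ceil((hi - lo) / width)), 1)
    return lo + width * np.arange(n + 1)


def descriptive_stats(x: np.ndarray) -> dict:
    """The 8 summary statistics of the GCG interval block."""
    x = np.asarray(x, float)
    return {"mean": float(np.mean(x)), "median": float(np.median(x)),
            "std": _pop_std(x), "sk": _skewness(x), "ku": _kurtosis(x),
            "entropy": shannon_entropy(x), "min": float(np.min(x)),
            "max": float(np.max(x))}


# ---------------------------------------------------------------------------
# NN series

def nn_series(fiducials: pd.DataFrame, config: PipelineConfig | None = None) -> np.ndarray:
    """NN intervals (ms): differences of consecutive valid J times.

    Uses the designated NN axis (GCG_Y by default).  Intervals bridging an
    invalid or missing beat are dropped; chunk boundaries are never bridged.
    """
    config = config or PipelineConfig()
    axis = {"gyr_y": "gcg_y", "gyr_x": "gcg_x"}.get(config.nn_axis, config.nn_axis)
    sub = fiducials[fiducials["axis"] == axis]
    out = []
    for _, grp in sub.groupby("chunk", sort=False):
        grp = grp.sort_values("beat")
        beats = grp["beat"].to_numpy()
        tj = grp["t_J"].to_numpy(float)
        valid = grp["valid"].to_numpy(bool)
        for i in range(len(grp) - 1):
            if valid[i] and valid[i + 1] and beats[i + 1] == beats[i] + 1:
                out.append((tj[i + 1] - tj[i]) * 1000.0)
    return np.asarray(out)


# ---------------------------------------------------------------------------
# time-domain HRV (15)

def poincare_pairs(nn: np.ndarray):
    return nn[:-1], nn[1:]


def nn_entropies(nn: np.ndarray, bin_ms: float) -> tuple:
    """(ENN, SENN, CENN) from one shared joint binning of Poincare pairs.

    ENN is the entropy of the NN_{i+1} marginal, SENN the mutual
    information I(NN_{i+1}; NN_i), CENN the conditional entropy
    H(NN_{i+1} | NN_i); ENN = SENN + CENN holds by construction.
    """
    x, y = poincare_pairs(nn)
    lo, hi = min(x.min(), y.min()), max(x.max(), y.max())
    edges = _bin_edges(lo, hi + 1e-9, bin_ms)
    joint, _, _ = np.histogram2d(x, y, bins=(edges, edges))
    joint /= joint.sum()
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)

    def h(p):
        p = p[p > 0]
        return float(-(p * np.log2(p)).sum())

    enn = h(py)
    senn = h(px) + h(py) - h(joint.ravel())   # mutual information
    cenn = enn - senn
    return enn, senn, cenn


def time_hrv_features(nn: np.ndarray, config: PipelineConfig | None = None) -> dict:
    """The 15 time-domain HRV features of one NN series (ms)."""
    config = config or PipelineConfig()
    nn = np.asarray(nn, float)
    if len(nn) < 3:
        raise ValueError("need at least 3 NN intervals")
    diffs = np.diff(nn)
    avnn = float(np.mean(nn))
    nn50 = int(np.sum(np.abs(diffs) > 50.0))
    denom = len(nn) if config.pnn50_denominator == "total_nn" else len(diffs)
    x, y = poincare_pairs(nn)
    theta = np.degrees(np.arctan2(y, x))
    dist = np.hypot(x, y)
    sd1 = _pop_std(np.abs(diffs) / math.sqrt(2.0))
    if config.sd2_convention == "as_printed":
        # subtracting the constant 2*AVNN inside a standard deviation is a
        # no-op: SD2 as printed is identically SD1
        sd2 = _pop_std(np.abs(diffs) / math.sqrt(2.0) - 2.0 * avnn)
    else:
        sd2 = _pop_std((x + y) / math.sqrt(2.0))
    enn, senn, cenn = nn_entropies(nn, config.nn_bin_ms)
    feats = {
        "AVNN_time": avnn,
        "SDNN_time": _pop_std(nn),
        "RMSSD_time": float(np.sqrt(np.mean(diffs ** 2))),
        "pNN50_time": nn50 / denom,
        "NN_med_time": float(np.median(nn)),
        "NN_sk_time": _skewness(nn),
        "NN_ku_time": _kurtosis(nn),
        "ENN_time": enn,
        "SENN_time": senn,
        "CENN_time": cenn,
        "VAI_time": float(np.mean(np.abs(theta - 45.0))),
        "VLI_time": float(np.sqrt(np.mean((dist - np.mean(dist)) ** 2))),
        "SD1_time": sd1,
        "SD2_time": sd2,
        "SD1/SD2_time": sd1 / sd2 if sd2 > 0 else np.nan,
    }
    return feats


# ---------------------------------------------------------------------------
# GCG interval block (11 x 8 = 88)

def interval_block(fiducials: pd.DataFrame) -> pd.DataFrame:
    """Per-(beat, axis) values of the 11 GCG parameters, valid rows only.

    Interval columns are in milliseconds; MA keeps its angular-acceleration
    amplitude units.
    """
    v = fiducials[fiducials["valid"].astype(bool)].copy()
    ms = lambda a, b: (v[a].to_numpy(float) - v[b].to_numpy(float)) * 1000.0
    out = pd.DataFrame({
        "chunk": v["chunk"].to_numpy(), "beat": v["beat"].to_numpy(),
        "axis": v["axis"].to_numpy(),
        "IVCT": ms("t_J", "t_I"), "LVET": ms("t_K", "t_J"),
        "IVRT": ms("t_L", "t_K"), "LI": ms("t_L", "t_I"),
        "LJ": ms("t_L", "t_J"), "KI": ms("t_K", "t_I"),
        "PI": ms("t_P", "t_I"), "PJ": ms("t_P", "t_J"),
        "KP": ms("t_K", "t_P"), "LP": ms("t_L", "t_P"),
        "MA": v["MA"].to_numpy(float),
    })
    return out


def gcg_interval_features(intervals: pd.DataFrame) -> dict:
    """The 88 interval statistics, both annotated axes pooled."""
    if len(intervals) < 3:
        raise ValueError("need at least 3 valid (beat, axis) rows")
    feats = {}
    for p in GCG_PARAMS:
        stats = descriptive_stats(intervals[p].to_numpy(float))
        for s in GCG_STATS:
            feats[f"{p}_{s}_GCG"] = stats[s]
    return feats


# ---------------------------------------------------------------------------
# frequency-domain HRV (6 x 5 = 30)

def _band_power(f: np.ndarray, pxx: np.ndarray, lo: float, hi: float) -> float:
    m = (f >= lo) & (f <= hi)
    if m.sum() < 2:
        return 0.0
    return float(np.trapezoid(pxx[m], f[m]))


def freq_hrv_features(rec: Recording, mask: ArtifactMask | None = None,
                      config: PipelineConfig | None = None) -> dict:
    """Welch band powers per raw IMU axis on the kept signal runs.

    The Welch segment length defaults to ``welch_segment_s`` but adapts
    down to half the longest kept run (artifact masking rarely leaves
    uninterrupted 240 s stretches), never below ``welch_min_segment_s``;
    if even that leaves no usable run the axis features are NaN (flagged
    missing).  PSDs of qualifying runs are averaged weighted by run length.
    """
    config = config or PipelineConfig()
    fs = rec.fs
    if mask is None:
        runs = [(0, rec.n_samples)]
    else:
        runs = mask.clean_runs()
    longest = max((b - a for a, b in runs), default=0)
    nperseg = min(int(round(config.welch_segment_s * fs)), longest // 2)
    if nperseg < int(round(config.welch_min_segment_s * fs)):
        nperseg = 0
    runs = [(a, b) for a, b in runs if nperseg and (b - a) >= 2 * nperseg]
    if rec.duration < 300.0:
        warnings.warn("recording shorter than 300 s: VLF resolution is poor",
                      stacklevel=2)
    feats = {}
    for ax in FREQ_AXES:
        sig = rec.channel(_AXIS_TO_CHANNEL[ax])
        psum, wsum = None, 0.0
        for a, b in runs:
            f, pxx = sps.welch(sig[a:b], fs=fs, window="hann", nperseg=nperseg,
                               noverlap=int(nperseg * config.welch_overlap))
            w = b - a
            psum = pxx * w if psum is None else psum + pxx * w
            wsum += w
        if psum is None:
            for m in FREQ_MEASURES:
                feats[f"{m}_{ax}_freq"] = np.nan
            continue
        pxx = psum / wsum
        vlf = _band_power(f, pxx, *VLF_BAND)
        lf = _band_power(f, pxx, *LF_BAND)
        hf = _band_power(f, pxx, *HF_BAND)
        total = _band_power(f, pxx, VLF_BAND[0], fs / 2.0)
        feats[f"vlf_HRV_{ax}_freq"] = vlf
        feats[f"lf_HRV_{ax}_freq"] = lf
        feats[f"hf_HRV_{ax}_freq"] = hf
        feats[f"lfhfRatio_{ax}_freq"] = lf / hf if hf > 0 else np.nan
        feats[f"TotalPow_{ax}_freq"] = total
    return feats


# ---------------------------------------------------------------------------
# manifest / assembly

def feature_manifest() -> pd.DataFrame:
    """Machine-readable manifest: (name, block, definition) per feature."""
    rows = []
    defs = {
        "AVNN_time": "mean(NN)", "SDNN_time": "pop-std(NN)",
        "RMSSD_time": "sqrt(mean(diff(NN)^2))",
        "pNN50_time": "#(|diff(NN)|>50ms) / #NN",
        "NN_med_time": "median(NN)", "NN_sk_time": "skewness(NN)",
        "NN_ku_time": "kurtosis(NN)",
        "ENN_time": "H(NN_{i+1}) [bits, fixed bins]",
        "SENN_time": "I(NN_{i+1}; NN_i)", "CENN_time": "H(NN_{i+1}|NN_i)",
        "VAI_time": "mean|theta_i - 45deg|",
        "VLI_time": "sqrt(mean(l_i - mean l)^2)",
        "SD1_time": "pop-std(|diff(NN)|/sqrt2)",
        "SD2_time": "as printed: identical to SD1 (shift-invariant std)",
        "SD1/SD2_time": "SD1/SD2",
    }
    for n in TIME_HRV_FEATURES:
        rows.append((n, "time_hrv", defs[n]))
    for p in GCG_PARAMS:
        for s in GCG_STATS:
            rows.append((f"{p}_{s}_GCG", "gcg_interval", f"{s} of {p} (ms)"))
    for a in FREQ_AXES:
        for m in FREQ_MEASURES:
            rows.append((f"{m}_{a}_freq", "freq_hrv", f"{m} Welch PSD of {a}"))
    return pd.DataFrame(rows, columns=["name", "block", "definition"])


def assemble_matrix(samples: list, level: str = "chunk",
                    policy: str = "drop") -> FeatureMatrix:
    """Assemble per-sample feature dicts into a FeatureMatrix.

    ``samples`` is a list of ``(sample_id, label, feature_dict)``.  Column
    order is canonical (GCG block, time-HRV block, then frequency-HRV at
    subject level).  ``policy`` governs NaN handling: ``"drop"`` removes
    samples with any missing feature, ``"raise"`` errors.
    """
    names = CHUNK_LEVEL_FEATURES if level == "chunk" else SUBJECT_LEVEL_FEATURES
    if not samples:
        raise ValueError("no samples to assemble")
    rows, ids, labels = [], [], []
    for sid, label, feats in samples:
        extra = set(feats) - set(names)
        if extra - set(SUBJECT_LEVEL_FEATURES):
            raise ValueError(f"unknown feature names: {sorted(extra)[:3]}")
        rows.append([feats.get(n, np.nan) for n in names])
        ids.append(sid)
        labels.append(label)
    values = np.asarray(rows, float)
    bad = ~np.isfinite(values).all(axis=1)
    if bad.any():
        if policy == "raise":
            raise ValueError(f"{bad.sum()} sample(s) with missing features")
        values = values[~bad]
        ids = [s for s, b in zip(ids, bad) if not b]
        labels = [l for l, b in zip(labels, bad) if not b]
        if not ids:
            raise ValueError("all samples dropped by NaN policy")
    return FeatureMatrix(values, names, tuple(ids), tuple(labels))
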