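"""Data containers and text I/O for 6-axis cardiomechanical recordings.

A recording is a synchronous multi-channel sample matrix from a chest-worn
IMU: a 3-axis accelerometer (seismocardiogram, SCG) and a 3-axis gyroscope
(gyrocardiogram, GCG), optionally with a reference ECG channel.  Files are
plain delimited text with a ``# key: value`` comment header so fixtures stay
diffable; all timestamps are seconds from recording start, intervals are
reported downstream in milliseconds.
"""

from __future__ import annotations

import dataclasses
import io
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

#: canonical channel order; ECG, when present, is always last
IMU_CHANNELS = ("acc_x", "acc_y", "acc_z", "gyr_x", "gyr_y", "gyr_z")
ACC_CHANNELS = IMU_CHANNELS[:3]
GYR_CHANNELS = IMU_CHANNELS[3:]

LABELS = ("healthy", "mild", "moderate", "severe")


class SchemaError(ValueError):
    """A recording file is missing a mandatory channel or header field."""


class FormatError(ValueError):
    """A recording file's contents violate the format contract."""


@dataclasses.dataclass
class Recording:
    """Synchronous 6-axis (+ optional ECG) sample matrix.

    Parameters
    ----------
    samples : ndarray, shape (n_samples, n_channels)
        One column per channel, canonical order.
    channel_names : tuple of str
        ``acc_x .. gyr_z`` and optionally ``ecg`` last.
    fs : float
        Sampling rate in Hz.
    subject_id : str
        Opaque subject identifier.
    label : str or None
        One of ``healthy/mild/moderate/severe``, or None if unlabeled.
    """

    samples: np.ndarray
    channel_names: tuple
    fs: float
    subject_id: str = ""
    label: str | None = None

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        self.channel_names = tuple(self.channel_names)
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.samples.ndim != 2 or self.samples.shape[1] != len(self.channel_names):
            raise ValueError("samples must be (n_samples, n_channels)")
        if not np.isfinite(self.samples).all():
            raise FormatError("recording contains non-finite samples")
        missing = [c for c in IMU_CHANNELS if c not in self.channel_names]
        if missing:
            raise SchemaError(f"missing mandatory channel(s): {', '.join(missing)}")
        if self.label is not None and self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs

    def channel(self, name: str) -> np.ndarray:
        """Return one channel by name (never by position)."""
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise KeyError(name) from None
        return self.samples[:, idx]

    def channels(self, names: Sequence[str]) -> np.ndarray:
        """Return an (n_samples, len(names)) view of the named channels."""
        return np.column_stack([self.channel(n) for n in names])


@dataclasses.dataclass
class FeatureMatrix:
    """Named-column numeric table with one label per sample."""

    values: np.ndarray
    feature_names: tuple
    sample_ids: tuple
    labels: tuple

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.feature_names = tuple(self.feature_names)
        self.sample_ids = tuple(str(s) for s in self.sample_ids)
        self.labels = tuple(self.labels)
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("duplicate feature names")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample_ids")
        if self.values.shape != (len(self.sample_ids), len(self.feature_names)):
            raise ValueError("values shape inconsistent with names/ids")
        if len(self.labels) != len(self.sample_ids):
            raise ValueError("labels length mismatch")
        if self.values.size and not np.isfinite(self.values).all():
            raise ValueError("feature matrix contains NaN/inf after assembly")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(self.feature_names),
                          index=list(self.sample_ids))
        df.index.name = "sample_id"
        df["label"] = list(self.labels)
        return df

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "FeatureMatrix":
        """Build from a DataFrame whose last column is the label."""
        if "label" not in df.columns:
            raise ValueError("DataFrame must carry a 'label' column")
        feats = [c for c in df.columns if c != "label"]
        return cls(df[feats].to_numpy(dtype=float), tuple(feats),
                   tuple(str(i) for i in df.index), tuple(df["label"]))

    def subset(self, sample_ids: Sequence[str]) -> "FeatureMatrix":
        """Row subset preserving the given id order."""
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in sample_ids]
        return FeatureMatrix(self.values[idx], self.feature_names,
                             tuple(self.sample_ids[i] for i in idx),
                             tuple(self.labels[i] for i in idx))

    def select_features(self, names: Sequence[str]) -> "FeatureMatrix":
        pos = {f: i for i, f in enumerate(self.feature_names)}
        idx = [pos[n] for n in names]
        return FeatureMatrix(self.values[:, idx], tuple(names),
                             self.sample_ids, self.labels)


# ---------------------------------------------------------------------------
# readers / writers


def write_recording(rec: Recording, path) -> None:
    """Write a recording as CSV with a '#'-comment key:value header."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# fs: {rec.fs!r}\n")
        fh.write(f"# subject_id: {rec.subject_id}\n")
        fh.write(f"# label: {rec.label if rec.label is not None else 'unlabeled'}\n")
        fh.write("# units: acc=m/s^2 gyr=deg/s\n")
        cols = ["time"] + list(rec.channel_names)
        fh.write(",".join(cols) + "\n")
        mat = np.column_stack([rec.times, rec.samples])
        np.savetxt(fh, mat, delimiter=",", fmt="%.9g")


def read_recording(path, schema: dict | None = None) -> Recording:
    """Read a recording written by :func:`write_recording`.

    ``schema`` may map file column names to canonical channel names for
    files produced elsewhere.  Channels are reordered canonically; a time
    column, when present, is validated against the declared sampling rate.
    """
    path = Path(path)
    header: dict[str, str] = {}
    data_lines = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                body = line[1:].strip()
                if ":" in body:
                    k, v = body.split(":", 1)
                    header[k.strip()] = v.strip()
            else:
                data_lines.append(line)
    if "fs" not in header:
        raise SchemaError("header does not declare fs")
    fs = float(header["fs"])
    df = pd.read_csv(io.StringIO("".join(data_lines)))
    if schema:
        df = df.rename(columns=schema)
    missing = [c for c in IMU_CHANNELS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory channel(s): {', '.join(missing)}")
    if "time" in df.columns:
        t = df["time"].to_numpy(float)
        if len(t) > 1:
            dt = np.diff(t)
            if np.abs(dt - 1.0 / fs).max() > 1.0 / fs:  # 1-sample tolerance
                raise FormatError("non-uniform timestamps inconsistent with fs")
    names = list(IMU_CHANNELS) + (["ecg"] if "ecg" in df.columns else [])
    label = header.get("label", "unlabeled")
    return Recording(df[names].to_numpy(float), tuple(names), fs,
                     subject_id=header.get("subject_id", ""),
                     label=None if label == "unlabeled" else label)


def write_feature_matrix(matrix: FeatureMatrix, path) -> None:
    """Write a feature matrix as CSV: header row, one row per sample, label last."""
    matrix.to_dataframe().to_csv(Path(path), float_format="%.17g")


def read_feature_matrix(path) -> FeatureMatrix:
    df = pd.read_csv(Path(path), index_col="sample_id")
    if len(df) == 0:  # header-only file: pandas types the empty label column float
        df["label"] = df["label"].astype(object)
    return FeatureMatrix.from_dataframe(df)


# ---------------------------------------------------------------------------
# configuration


@dataclasses.dataclass
class PipelineConfig:
    """Every numeric tunable of the pipeline; overridable from YAML."""

    # band-pass (Butterworth, zero-phase)
    scg_band: tuple = (1.0, 45.0)
    gcg_band: tuple = (1.0, 20.0)
    fiducial_band: tuple = (1.0, 10.0)
    bandpass_order: int = 4
    # artifact RMS filter
    rms_window_ms: float = 500.0
    # chunking
    chunk_seconds: float = 10.0
    chunk_overlap: float = 0.0
    # envelope / beat detection
    envelope_lowpass_hz: float = 2.0
    envelope_lowpass_order: int = 2
    envelope_edge_guard_s: float = 0.2
    refractory_s: float = 0.300
    searchback_factor: float = 1.66
    spk_weight: float = 0.125
    threshold_fraction: float = 0.25
    axis_refine_halfwidth_s: float = 0.025
    # fiducial search windows (s)
    ik_window_s: float = 0.150
    al_window_s: float = 0.200
    beat_window_before: float = 0.40
    beat_window_after: float = 0.60
    min_valid_beat_fraction: float = 0.50
    # HRV
    nn_axis: str = "gcg_y"
    pnn50_denominator: str = "total_nn"  # or "n_diffs"
    sd2_convention: str = "as_printed"   # or "conventional"
    nn_bin_ms: float = 1000.0 / 128.0
    # frequency HRV (Welch)
    welch_segment_s: float = 120.0
    welch_min_segment_s: float = 30.0
    welch_overlap: float = 0.5

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("scg_band", "gcg_band", "fiducial_band"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({f.name: (list(v) if isinstance(v, tuple) else v)
                            for f in dataclasses.fields(self)
                            for v in [getattr(self, f.name)]}, fh)
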