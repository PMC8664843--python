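"""Synthetic 6-axis cardiomechanical recordings with exact ground truth.

Each heartbeat is a train of Gaussian lobes — one signed lobe per fiducial
point (A, I, J, K, L on the annotated gyroscope axes) — so the extrema of
the analytic waveform sit exactly at the configured fiducial times.  Beat
placement follows an AR(1) inter-beat-interval (IBI) series with a
controllable mean, SD and lag-1 autocorrelation.  Broadband sensor noise
and sporadic high-amplitude motion-artifact bursts are added on top, and
everything the generator draws is recorded in a :class:`GroundTruth` so the
pipeline can be scored without patient data.

Disease classes (mild/moderate/severe aortic stenosis) are encoded
morphologically: a progressively longer isovolumetric relaxation interval
(the K→L spacing) and a larger maximum-acceleration (MA) amplitude, i.e.
a steeper systolic upstroke.  IBI statistics are identical across classes
by default, so class separation lives in the beat shape, not in heart-rate
variability.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .core_io import IMU_CHANNELS, LABELS, Recording

REFRACTORY_FLOOR_MS = 300.0

#: fiducial lobe centers relative to J (ms) and signed amplitudes for the
#: annotated gyroscope axes.  Alternating signs make the waveform oscillatory
#: and give the local-extremum annotator unambiguous targets.
_BASE_OFFSETS_MS = {"A": -140.0, "I": -70.0, "J": 0.0, "K": 65.0, "L": 130.0}
_BASE_AMPLITUDES = {"A": 0.5, "I": -0.85, "J": 1.6, "K": -0.9, "L": 0.85}
_LOBE_SIGMA_MS = 12.0

#: per-class morphology: shift of the L lobe (lengthens IVRT = L-K) and the
#: MA scalar multiplying the systolic I-J-K complex (steeper slopes around J).
CLASS_MORPHOLOGY = {
    "healthy": {"l_shift_ms": 0.0, "ma_scale": 1.0},
    "mild": {"l_shift_ms": 15.0, "ma_scale": 1.25},
    "moderate": {"l_shift_ms": 30.0, "ma_scale": 1.5},
    "severe": {"l_shift_ms": 45.0, "ma_scale": 2.0},
}

#: non-annotated axes carry a simpler lobe train so that every axis shows a
#: positive local maximum at J for per-axis peak refinement.
_PLAIN_AMPLITUDES = {"I": -0.5, "J": 1.0, "K": -0.4}


@dataclasses.dataclass
class Morphology:
    """Fiducial offsets (ms, relative to J) and signed lobe amplitudes."""

    offsets_ms: dict
    amplitudes: dict
    ma_scale: float = 1.0
    sigma_ms: float = _LOBE_SIGMA_MS

    @classmethod
    def for_class(cls, label: str) -> "Morphology":
        spec = CLASS_MORPHOLOGY[label]
        off = dict(_BASE_OFFSETS_MS)
        off["L"] = off["L"] + spec["l_shift_ms"]
        amp = dict(_BASE_AMPLITUDES)
        for p in ("I", "J", "K"):
            amp[p] = amp[p] * spec["ma_scale"]
        return cls(off, amp, ma_scale=spec["ma_scale"])

    def validate(self):
        o = self.offsets_ms
        if not (o["A"] < o["I"] < o["J"] < o["K"] < o["L"]):
            raise ValueError("fiducial offsets must satisfy A<I<J<K<L")


@dataclasses.dataclass
class SynthConfig:
    duration: float = 120.0          # s
    fs: float = 256.0                # Hz
    mean_ibi: float = 800.0          # ms
    sdnn_target: float = 50.0        # ms
    ibi_ar1: float = 0.4             # lag-1 autocorrelation, in [0, 1)
    class_label: str = "healthy"
    morphology: Morphology | None = None
    noise_sd: float = 0.05           # relative to per-axis template RMS
    artifact_rate: float = 2.0       # bursts per minute
    artifact_gain: float = 10.0      # burst amplitude / template RMS
    seed: int = 0

    def __post_init__(self):
        if self.class_label not in LABELS:
            raise ValueError(f"unknown class label {self.class_label!r}")
        if self.morphology is None:
            self.morphology = Morphology.for_class(self.class_label)
        self.morphology.validate()
        if not 0 <= self.ibi_ar1 < 1:
            raise ValueError("ibi_ar1 must lie in [0, 1)")
        if self.mean_ibi - 4.0 * self.sdnn_target <= REFRACTORY_FLOOR_MS:
            raise ValueError(
                "infeasible IBI config: mean_ibi - 4*sdnn_target must exceed "
                f"the {REFRACTORY_FLOOR_MS:.0f} ms refractory floor")


@dataclasses.dataclass
class GroundTruth:
    """Everything the generator knows about a synthetic recording."""

    beat_times: np.ndarray                  # J-peak times, s
    fiducials: dict                         # axis -> {point -> times (s)}; plus "MA" amplitudes
    artifact_intervals: list                # (start, end) s
    nn_series_true: np.ndarray              # ms, successive J-time differences
    label: str


def generate_ibi_series(config: SynthConfig, n: int,
                        rng: np.random.Generator | None = None) -> np.ndarray:
    """Stationary AR(1) IBI series (ms) around ``mean_ibi`` with population
    SD ``sdnn_target`` and lag-1 autocorrelation ``ibi_ar1``."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    mu, sd, a = config.mean_ibi, config.sdnn_target, config.ibi_ar1
    if sd == 0:
        return np.full(n, mu)
    x = np.empty(n)
    x[0] = mu + sd * rng.standard_normal()
    innov_sd = sd * np.sqrt(1.0 - a * a)
    eps = innov_sd * rng.standard_normal(n - 1)
    for i in range(1, n):
        x[i] = mu + a * (x[i - 1] - mu) + eps[i - 1]
    return x


def generate_beat_waveform(config: SynthConfig, axis: str):
    """Analytic single-beat snippet for one IMU axis.

    Returns ``(t, snippet, fiducial_times_s, ma)`` where ``t`` spans the
    beat support relative to J (s), ``fiducial_times_s`` maps each fiducial
    to its offset from J in seconds (annotated gyroscope axes only), and
    ``ma`` is the peak |first difference|*fs of the snippet.
    """
    if axis not in IMU_CHANNELS:
        raise ValueError(f"unknown axis {axis!r}")
    m = config.morphology
    fs = config.fs
    annotated = axis in ("gyr_x", "gyr_y")
    if annotated:
        lobes = {p: (m.offsets_ms[p] / 1000.0, m.amplitudes[p]) for p in m.offsets_ms}
    else:
        lobes = {p: (_BASE_OFFSETS_MS[p] / 1000.0,
                     _PLAIN_AMPLITUDES[p] * m.ma_scale)
                 for p in _PLAIN_AMPLITUDES}
    sigma = m.sigma_ms / 1000.0
    lo = min(c for c, _ in lobes.values()) - 5 * sigma
    hi = max(c for c, _ in lobes.values()) + 5 * sigma
    n0 = int(np.floor(lo * fs))
    n1 = int(np.ceil(hi * fs))
    t = np.arange(n0, n1 + 1) / fs
    snippet = np.zeros_like(t)
    for center, amp in lobes.values():
        snippet += amp * np.exp(-0.5 * ((t - center) / sigma) ** 2)
    fid = {p: c for p, (c, _) in lobes.items()} if annotated else {}
    if len(t) > 1:
        d = np.abs(np.diff(snippet))
        k = int(np.argmax(d))
        ma = float(d[k]) * fs
        if annotated:
            # P: steepest point of the analytic template (midpoint of the
            # first-difference sample pair)
            fid["P"] = float((t[k] + t[k + 1]) / 2.0)
    else:
        ma = 0.0
    return t, snippet, fid, ma


def _split_rngs(seed: int):
    ss = np.random.SeedSequence(seed)
    return [np.random.default_rng(s) for s in ss.spawn(3)]


def generate_recording(config: SynthConfig) -> tuple[Recording, GroundTruth]:
    """Synthesize one labeled 6-axis recording and its ground truth.

    Beats are placed at cumulative IBI times; per-axis templates are
    superposed, white noise with SD ``noise_sd`` x template RMS is added,
    and Poisson-timed artifact bursts (0.5-2 s, all channels jointly) are
    injected with amplitude ``artifact_gain`` x template RMS.
    """
    fs = config.fs
    n_total = int(round(config.duration * fs))
    # IBI draws come from their own substream so morphology-only config
    # changes leave the beat timing identical under the same seed.
    rng_ibi, rng_noise, rng_art = _split_rngs(config.seed)

    n_beats_max = int(np.ceil(config.duration * 1000.0 / config.mean_ibi)) + 2
    ibis_ms = generate_ibi_series(config, n_beats_max, rng_ibi)
    t0 = 0.6  # first J peak, leaves room for the pre-J part of the template
    beat_times = t0 + np.concatenate([[0.0], np.cumsum(ibis_ms[:-1])]) / 1000.0
    margin = 0.4  # keep full beat support inside the recording
    beat_times = beat_times[beat_times < config.duration - margin]
    if len(beat_times) < 2:
        raise ValueError("duration too short for 2 beats")

    samples = np.zeros((n_total, len(IMU_CHANNELS)))
    fiducials: dict[str, dict] = {}
    for ci, axis in enumerate(IMU_CHANNELS):
        t_rel, snippet, fid, ma = generate_beat_waveform(config, axis)
        offset0 = int(round(t_rel[0] * fs))
        sig = samples[:, ci]
        for bt in beat_times:
            j_idx = int(round(bt * fs))
            a = j_idx + offset0
            b = a + len(snippet)
            sig[max(a, 0):min(b, n_total)] += snippet[max(-a, 0):len(snippet) - max(b - n_total, 0)]
        if axis in ("gyr_x", "gyr_y"):
            gx = "gcg_x" if axis == "gyr_x" else "gcg_y"
            fiducials[gx] = {p: beat_times + dt for p, dt in fid.items()}
            fiducials[gx]["MA"] = np.full(len(beat_times), ma)

    rms = np.sqrt(np.mean(samples ** 2, axis=0))
    rms[rms == 0] = 1.0
    if config.noise_sd > 0:
        samples += rng_noise.standard_normal(samples.shape) * (config.noise_sd * rms)

    artifact_intervals: list[tuple[float, float]] = []
    if config.artifact_rate > 0:
        n_bursts = rng_art.poisson(config.artifact_rate * config.duration / 60.0)
        for _ in range(n_bursts):
            length = rng_art.uniform(0.5, 2.0)
            start = rng_art.uniform(0.0, max(config.duration - length, 0.0))
            a, b = int(start * fs), int((start + length) * fs)
            burst = rng_art.standard_normal((b - a, samples.shape[1]))
            samples[a:b] += burst * (config.artifact_gain * rms)
            artifact_intervals.append((a / fs, b / fs))
    artifact_intervals.sort()

    nn_true = np.diff(beat_times) * 1000.0
    rec = Recording(samples, IMU_CHANNELS, fs, subject_id=f"synth-{config.seed}",
                    label=config.class_label)
    gt = GroundTruth(beat_times=beat_times, fiducials=fiducials,
                     artifact_intervals=artifact_intervals,
                     nn_series_true=nn_true, label=config.class_label)
    return rec, gt


def _subject_morphology(label: str, rng: np.random.Generator,
                        amp_sd: float, offset_jitter_ms: float) -> Morphology:
    """Per-subject morphology: class template plus inter-subject variability
    (lognormal overall amplitude scale, small fiducial-offset jitter)."""
    m = Morphology.for_class(label)
    scale = float(np.exp(rng.normal(0.0, amp_sd)))
    off = {p: v + rng.normal(0.0, offset_jitter_ms) for p, v in m.offsets_ms.items()}
    off["J"] = 0.0  # J anchors the beat time
    morph = Morphology(off, {p: a * scale for p, a in m.amplitudes.items()},
                       ma_scale=m.ma_scale, sigma_ms=m.sigma_ms)
    morph.validate()
    return morph


def generate_cohort(n_per_class: int, base_config: SynthConfig | None = None,
                    seed: int = 0, labels: Sequence[str] = LABELS,
                    amp_sd: float = 0.10,
                    offset_jitter_ms: float = 3.0) -> list[tuple[Recording, GroundTruth]]:
    """Balanced labeled cohort; per-subject seeds spawn from the master seed.

    Subjects within a class share the class template but differ by a
    lognormal overall amplitude factor (SD ``amp_sd`` on the log scale)
    and Gaussian fiducial-offset jitter (SD ``offset_jitter_ms``), so
    within-class feature spread is non-degenerate, as in a real cohort.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    if base_config is None:
        base_config = SynthConfig()
    out = []
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_per_class * len(labels))
    k = 0
    for label in labels:
        for i in range(n_per_class):
            child = children[k]
            cfg_seed = int(child.generate_state(1)[0] % (2 ** 31))
            jitter_rng = np.random.default_rng(child.spawn(1)[0])
            morph = _subject_morphology(label, jitter_rng, amp_sd,
                                        offset_jitter_ms)
            cfg = dataclasses.replace(base_config, class_label=label,
                                      morphology=morph, seed=cfg_seed)
            rec, gt = generate_recording(cfg)
            rec.subject_id = f"{label}-{i:02d}"
            out.append((rec, gt))
            k += 1
    return out
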