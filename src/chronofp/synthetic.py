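"""Synthetic multichannel scalp-EEG with planted preictal cascades.

Interictal background is per-channel colored (1/f-shaped) noise from a
first-order autoregressive filter at EEG-plausible microvolt amplitude. The
period preceding each seizure onset is structured as up to three
chronologically ordered *stages*; each stage multiplies the power of chosen
frequency bands by a configurable factor (implemented by adding independent
band-limited noise), which is exactly the kind of change the spectral
band-power features respond to. Ictal/postictal morphology is not modelled;
downstream labeling skips a configurable post-onset exclusion zone.

With ``effect_size=0`` the preictal stages are statistically identical to
background, giving null patients for calibration experiments.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal

from .features import BAND_RANGES

#: International 10-20 scalp montage, 19 electrodes.
CHANNELS_1020: tuple[str, ...] = (
    "Fp1", "Fp2", "F3", "F4", "C3", "C4", "P3", "P4", "O1", "O2",
    "F7", "F8", "T3", "T4", "T5", "T6", "Fz", "Cz", "Pz",
)


class FixtureError(ValueError):
    """A patient fixture on disk is malformed; the message names the field."""


@dataclass(frozen=True)
class StageSpec:
    """One preictal stage: index 1 is farthest from onset."""

    index: int
    duration_min: float
    band_deltas: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 1 <= self.index <= 3:
            raise ValueError("stage index must be in 1..3")
        if self.duration_min <= 0:
            raise ValueError("stage duration must be positive")
        for band, delta in self.band_deltas.items():
            if band not in BAND_RANGES:
                raise ValueError(f"unknown band {band!r}")
            if delta < 1.0:
                raise ValueError("band_deltas are power multipliers >= 1")


@dataclass(frozen=True)
class NoiseModel:
    """AR(1)-filtered white noise: amplitude in microvolts RMS, pole at ar_coeff."""

    amplitude_uv: float = 20.0
    ar_coeff: float = 0.95


def default_stages() -> list[StageSpec]:
    """Three 10-min stages with distinct band signatures (theta, alpha, beta)."""
    return [
        StageSpec(1, 10.0, {"theta": 4.0}),
        StageSpec(2, 10.0, {"alpha": 4.0}),
        StageSpec(3, 10.0, {"beta": 4.0}),
    ]


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic patient.

    Defaults are desk-scale: the 19-channel 256 Hz montage of scalp EEG with
    four lead seizures, but inter-seizure gaps of tens of minutes rather
    than hours. All downstream code takes durations from configuration.
    """

    n_channels: int = 19
    fs: float = 256.0
    n_seizures: int = 4
    interictal_gap_min: float = 60.0
    preictal_stages: list[StageSpec] = field(default_factory=default_stages)
    noise_model: NoiseModel = field(default_factory=NoiseModel)
    effect_size: float = 1.0
    sph_min: float = 5.0
    tail_min: float = 10.0
    seed: int = 0

    @property
    def preictal_span_min(self) -> float:
        """Total planted span before onset: stages plus the SPH buffer."""
        return sum(s.duration_min for s in self.preictal_stages) + self.sph_min

    def validate(self) -> None:
        if self.n_seizures < 1:
            raise ValueError("n_seizures must be >= 1")
        if self.n_channels < 1 or self.n_channels > len(CHANNELS_1020):
            raise ValueError(f"n_channels must be 1..{len(CHANNELS_1020)}")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        idx = [s.index for s in self.preictal_stages]
        if idx != sorted(idx) or len(set(idx)) != len(idx):
            raise ValueError("stages must have distinct, increasing indices")
        if self.interictal_gap_min <= self.preictal_span_min:
            raise ValueError(
                f"interictal gap ({self.interictal_gap_min} min) must exceed the "
                f"preictal span ({self.preictal_span_min} min); seizures would overlap"
            )

    def stage_intervals(self, onset_s: float) -> list[tuple[int, float, float]]:
        """(index, start_s, end_s) of each stage; stage windows tile the
        interval ending SPH before the onset, farthest stage first."""
        out = []
        end = onset_s - self.sph_min * 60.0
        total = sum(s.duration_min for s in self.preictal_stages)
        start = end - total * 60.0
        for st in self.preictal_stages:
            stop = start + st.duration_min * 60.0
            out.append((st.index, start, stop))
            start = stop
        return out


@dataclass
class EEGRecording:
    """Continuous multichannel signal with seizure-onset annotations."""

    data: np.ndarray  # (n_channels, n_samples), microvolts
    fs: float
    channel_names: list[str]
    onsets: np.ndarray  # seconds from record start, strictly increasing

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, float)
        if self.data.ndim != 2:
            raise ValueError("data must be (channels, samples)")
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError("channel_names length must match channel count")
        if np.any(np.diff(self.onsets) <= 0):
            raise ValueError("onsets must be strictly increasing")
        if self.onsets.size and (self.onsets[0] <= 0
                                 or self.onsets[-1] >= self.duration_s):
            raise ValueError("onsets must lie strictly inside the record")

    @property
    def duration_s(self) -> float:
        return self.data.shape[1] / self.fs

    def slice_time(self, t0: float, t1: float | None = None) -> "EEGRecording":
        """Sub-recording on [t0, t1); onset times re-referenced to the slice."""
        i0 = int(round(t0 * self.fs))
        i1 = self.data.shape[1] if t1 is None else int(round(t1 * self.fs))
        keep = (self.onsets >= t0) & (self.onsets < i1 / self.fs)
        return EEGRecording(
            data=self.data[:, i0:i1],
            fs=self.fs,
            channel_names=list(self.channel_names),
            onsets=self.onsets[keep] - t0,
        )


def _ar1_background(rng: np.random.Generator, n_channels: int, n_samples: int,
                    model: NoiseModel) -> np.ndarray:
    a = model.ar_coeff
    # stationary AR(1) variance = sigma^2 / (1 - a^2); pick sigma for target RMS
    sigma = model.amplitude_uv * np.sqrt(1.0 - a * a)
    white = rng.standard_normal((n_channels, n_samples)) * sigma
    return signal.lfilter([1.0], [1.0, -a], white, axis=-1)


def _ar1_band_power(model: NoiseModel, fs: float, lo: float, hi: float,
                    n_grid: int = 2048) -> float:
    """Background power in [lo, hi] from the analytic AR(1) spectrum."""
    a = model.ar_coeff
    sigma2 = model.amplitude_uv ** 2 * (1.0 - a * a)
    f = np.linspace(lo, hi, n_grid)
    # one-sided PSD of AR(1) driven by white noise of variance sigma2
    psd = 2.0 * sigma2 / (fs * np.abs(1.0 - a * np.exp(-2j * np.pi * f / fs)) ** 2)
    return float(np.trapezoid(psd, f))


def generate_patient(config: SyntheticConfig) -> EEGRecording:
    """Generate one annotated synthetic patient.

    Onset *i* (1-based) sits at ``i * interictal_gap_min``; each onset is
    preceded by the configured stage cascade, whose band-power multipliers
    are ``1 + effect_size * (delta - 1)``. Identical config and seed give
    bit-identical output.
    """
    config.validate()
    fs = config.fs
    gap_s = config.interictal_gap_min * 60.0
    onsets = np.array([(i + 1) * gap_s for i in range(config.n_seizures)])
    duration_s = onsets[-1] + config.tail_min * 60.0
    n_samples = int(round(duration_s * fs))

    rng = np.random.default_rng(config.seed)
    data = _ar1_background(rng, config.n_channels, n_samples, config.noise_model)

    stage_by_index = {s.index: s for s in config.preictal_stages}
    for onset in onsets:
        for idx, start_s, stop_s in config.stage_intervals(onset):
            st = stage_by_index[idx]
            i0, i1 = int(round(start_s * fs)), int(round(stop_s * fs))
            if i0 < 0:
                raise ValueError("preictal stages extend before record start")
            seg_len = i1 - i0
            for band, delta in st.band_deltas.items():
                mult = 1.0 + config.effect_size * (delta - 1.0)
                if mult <= 1.0:
                    continue
                lo, hi = BAND_RANGES[band]
                hi = min(hi, fs / 2 * 0.999)
                target_var = (mult - 1.0) * _ar1_band_power(
                    config.noise_model, fs, lo, hi)
                sos = signal.butter(4, [lo, hi], btype="bandpass", fs=fs,
                                    output="sos")
                extra = signal.sosfiltfilt(
                    sos, rng.standard_normal((config.n_channels, seg_len)),
                    axis=-1)
                std = extra.std(axis=-1, keepdims=True)
                std[std == 0] = 1.0
                data[:, i0:i1] += extra / std * np.sqrt(target_var)

    names = list(CHANNELS_1020[: config.n_channels])
    return EEGRecording(data=data.astype(np.float32), fs=fs,
                        channel_names=names, onsets=onsets)


# ---------------------------------------------------------------------------
# fixture I/O: one .npz array container + JSON annotation sidecar
# ---------------------------------------------------------------------------

def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def write_fixture(recording: EEGRecording, path) -> None:
    """Write a patient fixture: ``<path>.npz``-style container + JSON sidecar."""
    path = Path(path)
    np.savez_compressed(path, data=recording.data)
    meta = {
        "fs": recording.fs,
        "channel_names": list(recording.channel_names),
        "onset_seconds": [float(t) for t in recording.onsets],
        "n_samples": int(recording.data.shape[1]),
    }
    _sidecar(path).write_text(json.dumps(meta, indent=1))


def read_fixture(path) -> EEGRecording:
    """Read a patient fixture; malformed files raise :class:`FixtureError`."""
    path = Path(path)
    npz_path = path if path.suffix == ".npz" else path.with_suffix(".npz")
    side = _sidecar(path)
    if not side.exists():
        raise FixtureError(f"missing annotation sidecar {side}")
    try:
        meta = json.loads(side.read_text())
    except json.JSONDecodeError as exc:
        raise FixtureError(f"annotation sidecar is not valid JSON: {exc}") from exc
    for key in ("fs", "channel_names", "onset_seconds", "n_samples"):
        if key not in meta:
            raise FixtureError(f"annotation sidecar missing field {key!r}")
    try:
        with np.load(npz_path) as npz:
            if "data" not in npz:
                raise FixtureError("fixture container missing array 'data'")
            data = npz["data"]
    except FixtureError:
        raise
    except Exception as exc:
        raise FixtureError(f"unreadable fixture container 'data': {exc}") from exc
    if data.shape[1] != meta["n_samples"]:
        raise FixtureError(
            f"field 'n_samples': sidecar says {meta['n_samples']} but "
            f"container holds {data.shape[1]} (truncated file?)"
        )
    if data.shape[0] != len(meta["channel_names"]):
        raise FixtureError("field 'channel_names': length does not match data")
    return EEGRecording(
        data=data,
        fs=float(meta["fs"]),
        channel_names=list(meta["channel_names"]),
        onsets=np.asarray(meta["onset_seconds"], float),
    )
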