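"""Windowing and univariate linear EEG features.

Recordings are cut into non-overlapping 5-second windows and, per channel
and window, a fixed manifest of 59 linear univariate features is computed:

* spectral (45): absolute and relative power of 8 classical bands (delta,
  theta, alpha, beta and four gamma sub-bands), total power, mean frequency,
  alpha peak frequency, spectral edge frequency at 50% and the cumulative
  power at that edge, plus a fixed list of 24 pairwise band-power ratios;
* temporal (8): the four statistical moments, the three Hjorth parameters
  and the decorrelation time (first zero crossing of the autocorrelation);
* time-frequency (6): Daubechies-4 wavelet energies of detail levels D1-D5
  and the final approximation A5.

Degenerate windows (zero variance / zero total power) yield 0 for every
quantity that would otherwise be 0/0; no feature is ever NaN.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pywt
from scipy import fft as sfft
from scipy import signal, stats

WINDOW_SECONDS = 5.0

#: (name, low Hz, high Hz) — half-open [low, high), the last band closed.
BANDS: tuple[tuple[str, float, float], ...] = (
    ("delta", 0.5, 4.0),
    ("theta", 4.0, 8.0),
    ("alpha", 8.0, 13.0),
    ("beta", 13.0, 30.0),
    ("gamma1", 30.0, 47.0),
    ("gamma2", 53.0, 75.0),
    ("gamma3", 75.0, 97.0),
    ("gamma4", 103.0, 128.0),
)

BAND_RANGES: dict[str, tuple[float, float]] = {n: (lo, hi) for n, lo, hi in BANDS}

#: The fixed 24 band-power ratio pairs (numerator, denominator): all pairs
#: among the four classical bands (6), each classical band against each
#: gamma sub-band (16), and two within-gamma contrasts (2).
RATIO_PAIRS: tuple[tuple[str, str], ...] = (
    ("delta", "theta"), ("delta", "alpha"), ("delta", "beta"),
    ("theta", "alpha"), ("theta", "beta"), ("alpha", "beta"),
    ("delta", "gamma1"), ("delta", "gamma2"), ("delta", "gamma3"), ("delta", "gamma4"),
    ("theta", "gamma1"), ("theta", "gamma2"), ("theta", "gamma3"), ("theta", "gamma4"),
    ("alpha", "gamma1"), ("alpha", "gamma2"), ("alpha", "gamma3"), ("alpha", "gamma4"),
    ("beta", "gamma1"), ("beta", "gamma2"), ("beta", "gamma3"), ("beta", "gamma4"),
    ("gamma1", "gamma2"), ("gamma3", "gamma4"),
)

WAVELET = "db4"
WAVELET_LEVELS = 5
WELCH_NPERSEG = 256

SPECTRAL_NAMES: tuple[str, ...] = (
    tuple(f"pow_{b}" for b, _, _ in BANDS)
    + tuple(f"relpow_{b}" for b, _, _ in BANDS)
    + ("total_power", "mean_frequency", "alpha_peak_frequency", "sef50", "sef50_power")
    + tuple(f"ratio_{a}_{b}" for a, b in RATIO_PAIRS)
)
TEMPORAL_NAMES: tuple[str, ...] = (
    "mean", "variance", "skewness", "kurtosis",
    "hjorth_activity", "hjorth_mobility", "hjorth_complexity",
    "decorrelation_time",
)
WAVELET_NAMES: tuple[str, ...] = tuple(
    f"wav_energy_d{i}" for i in range(1, WAVELET_LEVELS + 1)
) + (f"wav_energy_a{WAVELET_LEVELS}",)

FEATURE_NAMES: tuple[str, ...] = SPECTRAL_NAMES + TEMPORAL_NAMES + WAVELET_NAMES
N_FEATURES = len(FEATURE_NAMES)
assert N_FEATURES == 59, f"feature manifest drifted: {N_FEATURES}"


@dataclass
class FeatureTable:
    """Per-window feature matrix with its column manifest.

    ``values`` is (n_windows, n_channels * 59); columns are grouped by
    channel, in manifest order within each channel. ``window_times`` are the
    window *start* times in seconds from record start.
    """

    values: np.ndarray
    window_times: np.ndarray
    manifest: list[tuple[str, str]] = field(repr=False)

    def __post_init__(self) -> None:
        if self.values.shape[1] != len(self.manifest):
            raise ValueError("manifest length does not match column count")

    @property
    def n_channels(self) -> int:
        return len({ch for ch, _ in self.manifest})

    def to_dataframe(self) -> pd.DataFrame:
        cols = [f"{ch}:{name}" for ch, name in self.manifest]
        df = pd.DataFrame(self.values, columns=cols)
        df.insert(0, "time_s", self.window_times)
        return df

    def save_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def load_csv(cls, path) -> "FeatureTable":
        df = pd.read_csv(path)
        if "time_s" not in df.columns:
            raise ValueError("feature table missing 'time_s' column")
        times = df.pop("time_s").to_numpy()
        manifest = []
        for col in df.columns:
            ch, _, name = col.partition(":")
            if not name:
                raise ValueError(f"malformed feature column name {col!r}")
            manifest.append((ch, name))
        return cls(df.to_numpy(float), times, manifest)


def segment(recording) -> tuple[np.ndarray, np.ndarray]:
    """Cut a recording into non-overlapping 5-s windows.

    Returns ``(windows, times)`` where windows has shape
    (n_windows, n_channels, fs*5) and times holds window start seconds.
    The trailing remainder shorter than one window is dropped.
    """
    wlen = int(round(recording.fs * WINDOW_SECONDS))
    n_samples = recording.data.shape[1]
    n_win = n_samples // wlen
    if n_win == 0:
        raise ValueError(
            f"recording of {n_samples / recording.fs:.2f}s is shorter than one "
            f"{WINDOW_SECONDS}s window"
        )
    trimmed = recording.data[:, : n_win * wlen]
    windows = trimmed.reshape(recording.data.shape[0], n_win, wlen).swapaxes(0, 1)
    times = np.arange(n_win) * WINDOW_SECONDS
    return windows, times


# ---------------------------------------------------------------------------
# feature families (batched over windows; rows = windows)
# ---------------------------------------------------------------------------

def band_powers(psd: np.ndarray, freqs: np.ndarray,
                bands=BANDS) -> np.ndarray:
    """Integrate a one-sided PSD over frequency bands ([low, high), last closed)."""
    df = freqs[1] - freqs[0]
    out = np.empty(psd.shape[:-1] + (len(bands),))
    for j, (_, lo, hi) in enumerate(bands):
        if j == len(bands) - 1:
            mask = (freqs >= lo) & (freqs <= hi)
        else:
            mask = (freqs >= lo) & (freqs < hi)
        out[..., j] = psd[..., mask].sum(axis=-1) * df
    return out


def _welch(X: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    nperseg = min(WELCH_NPERSEG, X.shape[-1])
    freqs, psd = signal.welch(X, fs=fs, nperseg=nperseg, axis=-1)
    return freqs, psd


def spectral_features_batch(X: np.ndarray, fs: float) -> np.ndarray:
    """The 45 spectral features for each row of X (n_windows, n_samples)."""
    freqs, psd = _welch(X, fs)
    lo_total = BANDS[0][1]
    total_mask = freqs >= lo_total
    df = freqs[1] - freqs[0]

    absp = band_powers(psd, freqs, BANDS)                   # (n, 8)
    total = psd[:, total_mask].sum(axis=-1) * df            # (n,)
    # threshold well below any physical uV^2 power: a detrended constant
    # window leaves only ~1e-30 of floating-point residue
    ok = total > 1e-20
    safe_total = np.where(ok, total, 1.0)
    relp = np.where(ok[:, None], absp / safe_total[:, None], 0.0)

    f_t = freqs[total_mask]
    p_t = psd[:, total_mask]
    mean_freq = np.where(ok, (p_t * f_t).sum(axis=-1) * df / safe_total, 0.0)

    # spectral edge at 50% of total power, and the cumulative power there
    cum = np.cumsum(p_t, axis=-1) * df
    half = 0.5 * total
    edge_idx = np.argmax(cum >= half[:, None], axis=-1)
    sef50 = np.where(ok, f_t[edge_idx], 0.0)
    sef50_power = np.where(ok, np.take_along_axis(cum, edge_idx[:, None], -1)[:, 0], 0.0)

    a_lo, a_hi = BAND_RANGES["alpha"]
    a_mask = (freqs >= a_lo) & (freqs <= a_hi)
    f_a = freqs[a_mask]
    alpha_peak = np.where(ok, f_a[np.argmax(psd[:, a_mask], axis=-1)], 0.0)

    idx = {name: j for j, (name, _, _) in enumerate(BANDS)}
    ratios = np.empty((X.shape[0], len(RATIO_PAIRS)))
    for j, (num, den) in enumerate(RATIO_PAIRS):
        d = absp[:, idx[den]]
        good = d > 1e-20
        ratios[:, j] = np.where(good, absp[:, idx[num]] / np.where(good, d, 1.0), 0.0)

    return np.column_stack(
        [absp, relp, total, mean_freq, alpha_peak, sef50, sef50_power, ratios]
    )


def temporal_features_batch(X: np.ndarray, fs: float) -> np.ndarray:
    """The 8 time-domain features for each row of X."""
    mean = X.mean(axis=-1)
    var = X.var(axis=-1)
    ok = var > 0

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant rows raise precision warnings
        skew = np.where(ok, np.nan_to_num(stats.skew(X, axis=-1)), 0.0)
        kurt = np.where(ok, np.nan_to_num(stats.kurtosis(X, axis=-1)), 0.0)

    dx = np.diff(X, axis=-1) * fs
    var_dx = dx.var(axis=-1)
    mobility = np.where(ok, np.sqrt(np.where(ok, var_dx / np.where(ok, var, 1.0), 0.0)), 0.0)
    ddx = np.diff(dx, axis=-1) * fs
    ok2 = var_dx > 0
    mob2 = np.where(ok2, np.sqrt(np.where(ok2, ddx.var(axis=-1) / np.where(ok2, var_dx, 1.0), 0.0)), 0.0)
    complexity = np.where(mobility > 0, mob2 / np.where(mobility > 0, mobility, 1.0), 0.0)

    decorr = _decorrelation_time(X, fs, ok)

    return np.column_stack([mean, var, skew, kurt, var, mobility, complexity, decorr])


def _decorrelation_time(X: np.ndarray, fs: float, ok: np.ndarray) -> np.ndarray:
    """Lag (seconds) of the first nonpositive value of the autocorrelation.

    A zero-variance window is assigned the minimum lag of one sample.
    Windows whose autocorrelation never crosses zero get the full window
    length.
    """
    L = X.shape[-1]
    nfft = sfft.next_fast_len(2 * L - 1)
    Xc = X - X.mean(axis=-1, keepdims=True)
    F = sfft.rfft(Xc, n=nfft, axis=-1)
    acf = sfft.irfft(F * np.conj(F), n=nfft, axis=-1)[..., :L]
    crossed = acf[..., 1:] <= 0
    any_cross = crossed.any(axis=-1)
    first = np.argmax(crossed, axis=-1) + 1
    lag = np.where(any_cross, first, L)
    lag = np.where(ok, lag, 1)
    return lag / fs


def wavelet_features_batch(X: np.ndarray) -> np.ndarray:
    """Energies of db4 detail levels D1..D5 and approximation A5.

    Uses the orthogonal (periodized) DWT, so the level energies sum to the
    signal energy exactly (Parseval).
    """
    if X.shape[-1] < 2 ** WAVELET_LEVELS:
        raise ValueError(
            f"window of {X.shape[-1]} samples too short for "
            f"{WAVELET_LEVELS}-level decomposition"
        )
    coeffs = pywt.wavedec(X, WAVELET, mode="periodization",
                          level=WAVELET_LEVELS, axis=-1)
    # coeffs = [A5, D5, D4, D3, D2, D1]
    approx = coeffs[0]
    details = coeffs[1:][::-1]  # D1 .. D5
    energies = [np.square(d).sum(axis=-1) for d in details]
    energies.append(np.square(approx).sum(axis=-1))
    return np.column_stack(energies)


def spectral_features(samples: np.ndarray, fs: float) -> dict[str, float]:
    """Named spectral features of a single window."""
    vals = spectral_features_batch(np.asarray(samples, float)[None, :], fs)[0]
    return dict(zip(SPECTRAL_NAMES, vals))


def temporal_features(samples: np.ndarray, fs: float) -> dict[str, float]:
    """Named time-domain features of a single window."""
    vals = temporal_features_batch(np.asarray(samples, float)[None, :], fs)[0]
    return dict(zip(TEMPORAL_NAMES, vals))


def wavelet_features(samples: np.ndarray) -> dict[str, float]:
    """Named wavelet-energy features of a single window."""
    vals = wavelet_features_batch(np.asarray(samples, float)[None, :])[0]
    return dict(zip(WAVELET_NAMES, vals))


def window_features(samples: np.ndarray, fs: float) -> dict[str, float]:
    """All 59 features of a single window, in manifest order."""
    out = spectral_features(samples, fs)
    out.update(temporal_features(samples, fs))
    out.update(wavelet_features(samples))
    return out


# ---------------------------------------------------------------------------
# preprocessing and full-table extraction
# ---------------------------------------------------------------------------

def bandpass_notch(recording, highpass: float = 0.5, notch: float = 50.0,
                   notch_q: float = 30.0):
    """Zero-phase 0.5 Hz high-pass plus power-line notch.

    Stands in for manual artifact screening of raw scalp EEG; optional and
    harmless on clean synthetic data.
    """
    from .synthetic import EEGRecording

    data = np.asarray(recording.data, float)
    if highpass:
        sos = signal.butter(4, highpass, btype="highpass", fs=recording.fs,
                            output="sos")
        data = signal.sosfiltfilt(sos, data, axis=-1)
    if notch:
        b, a = signal.iirnotch(notch, notch_q, fs=recording.fs)
        data = signal.filtfilt(b, a, data, axis=-1)
    return EEGRecording(
        data=data.astype(recording.data.dtype),
        fs=recording.fs,
        channel_names=list(recording.channel_names),
        onsets=np.array(recording.onsets, float),
    )


def extract_features(recording) -> FeatureTable:
    """Compute the full windows x (channels x 59) feature table."""
    windows, times = segment(recording)
    n_win, n_ch, _ = windows.shape
    values = np.empty((n_win, n_ch * N_FEATURES))
    manifest: list[tuple[str, str]] = []
    for c in range(n_ch):
        ch_name = recording.channel_names[c]
        X = np.ascontiguousarray(windows[:, c, :], dtype=float)
        try:
            block = np.column_stack([
                spectral_features_batch(X, recording.fs),
                temporal_features_batch(X, recording.fs),
                wavelet_features_batch(X),
            ])
        except Exception as exc:  # pragma: no cover - defensive context
            raise RuntimeError(f"feature extraction failed on channel "
                               f"{ch_name!r}: {exc}") from exc
        if not np.all(np.isfinite(block)):
            bad_win, bad_col = np.argwhere(~np.isfinite(block))[0]
            raise RuntimeError(
                f"non-finite feature {FEATURE_NAMES[bad_col % N_FEATURES]!r} "
                f"in window {bad_win}, channel {ch_name!r}"
            )
        values[:, c * N_FEATURES:(c + 1) * N_FEATURES] = block
        manifest.extend((ch_name, name) for name in FEATURE_NAMES)
    return FeatureTable(values=values, window_times=times, manifest=manifest)
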