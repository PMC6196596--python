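"""Frequency and time-frequency features per sensor.

The transfer task produces roughly eight movement cycles of about two
seconds each in healthy performance, so the short-time Fourier transform
uses a 2 s rectangular window with 50% overlap (0.5 Hz bins at 100 Hz).
Per axis: mean spectral energy, spectral component entropy and the mean
magnitudes of the first five non-DC STFT components (0.5-2.5 Hz), plus six
wavelet features — the sums of absolute Daubechies-2 coefficients of the
five detail levels and the level-5 approximation — 13 values per axis,
39 per sensor.

The time signal is low-passed (zero-phase Butterworth, 20 Hz) before the
STFT to stabilise the low-frequency components; the wavelet decomposition
runs on the raw signal so high-frequency jerk content is retained.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pywt
from scipy import signal as sps

from .io_core import TriaxialSignal, ValidationError
from .registry import FREQ_AXIS_FEATURES, sensor_freq_feature_names

logger = logging.getLogger(__name__)

WINDOW_LEN = 200  # 2 s at 100 Hz
HOP = 100  # 50% overlap


@dataclass
class StftSpectrogram:
    """One-sided STFT magnitudes, windows x (window_len/2 + 1) bins."""

    magnitudes: np.ndarray
    window_len: int = WINDOW_LEN
    hop: int = HOP

    @property
    def bin_hz(self) -> float:
        return 100.0 / self.window_len

    def __post_init__(self) -> None:
        self.magnitudes = np.asarray(self.magnitudes, dtype=float)
        if self.magnitudes.ndim != 2 or self.magnitudes.shape[0] < 1:
            raise ValidationError("spectrogram needs >= 1 window")
        if self.magnitudes.shape[1] != self.window_len // 2 + 1:
            raise ValidationError("bins must equal window_len/2 + 1")
        if np.any(self.magnitudes < 0):
            raise ValidationError("magnitudes must be >= 0")


def lowpass(signal: np.ndarray, cutoff_hz: float = 20.0, order: int = 4,
            fs: float = 100.0) -> np.ndarray:
    """Zero-phase (forward-backward) Butterworth low-pass; length preserved."""
    if cutoff_hz >= fs / 2:
        raise ValidationError(f"cutoff {cutoff_hz} Hz must be below Nyquist {fs / 2}")
    sos = sps.butter(order, cutoff_hz, btype="low", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, np.asarray(signal, dtype=float))


def stft_rect(signal: np.ndarray) -> StftSpectrogram:
    """Rectangular-window STFT magnitudes; trailing partial window dropped.

    Magnitudes are unnormalised DFT moduli: a unit sinusoid centred on a
    bin peaks at window_len/2.
    """
    signal = np.asarray(signal, dtype=float)
    if len(signal) < WINDOW_LEN:
        raise ValidationError("need >= 2 s of signal")
    n_windows = (len(signal) - WINDOW_LEN) // HOP + 1
    starts = HOP * np.arange(n_windows)
    frames = signal[starts[:, None] + np.arange(WINDOW_LEN)[None, :]]
    mags = np.abs(np.fft.rfft(frames, axis=1))
    return StftSpectrogram(magnitudes=mags)


def _window_power(spec: StftSpectrogram) -> np.ndarray:
    """Mean signal power per window via Parseval (two-sided accounting)."""
    m2 = spec.magnitudes**2
    weights = np.full(m2.shape[1], 2.0)
    weights[0] = 1.0
    if spec.window_len % 2 == 0:
        weights[-1] = 1.0
    return (m2 @ weights) / spec.window_len**2


def spectral_energy(spec: StftSpectrogram) -> float:
    """Mean per-window signal power (g^2); a unit sinusoid gives 0.5."""
    return float(np.mean(_window_power(spec)))


def component_entropy(spec: StftSpectrogram) -> float:
    """Shannon entropy (nats) of the normalised non-DC power spectrum,
    averaged over windows; all-zero windows are skipped (0 if every window
    is zero).  The DC bin is excluded — the static gravity component
    carries no movement information and would otherwise dominate the
    distribution."""
    m2 = spec.magnitudes[:, 1:] ** 2
    totals = m2.sum(axis=1)
    nonzero = totals > 0
    if not np.any(nonzero):
        logger.warning("all-zero spectrogram: component entropy 0")
        return 0.0
    p = m2[nonzero] / totals[nonzero, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log(p), 0.0)
    return float(np.mean(-terms.sum(axis=1)))


def stft_component_means(spec: StftSpectrogram) -> tuple[float, ...]:
    """Mean magnitude of components 1-5 (0.5-2.5 Hz; DC excluded)."""
    return tuple(float(v) for v in spec.magnitudes[:, 1:6].mean(axis=0))


def wpd_features(signal: np.ndarray, wavelet: str = "db2", levels: int = 5) -> tuple[float, ...]:
    """Six wavelet features: sum of |detail coefficients| at levels 1..5
    plus sum of |approximation coefficients| at level 5 (Daubechies 2,
    symmetric padding)."""
    signal = np.asarray(signal, dtype=float)
    if len(signal) < 32:
        raise ValidationError("series too short for 5-level wavelet decomposition")
    coeffs = pywt.wavedec(signal, wavelet, mode="symmetric", level=levels)
    # coeffs = [cA_L, cD_L, ..., cD_1]
    details = coeffs[:0:-1]  # cD_1 .. cD_L
    feats = [float(np.sum(np.abs(d))) for d in details]
    feats.append(float(np.sum(np.abs(coeffs[0]))))
    return tuple(feats)


def freq_features_sensor(signal: TriaxialSignal) -> dict[str, float]:
    """The 39 frequency-domain features of one sensor, keyed by registry name."""
    out: dict[str, float] = {}
    for ax, sig in signal.axes().items():
        spec = stft_rect(lowpass(sig, fs=signal.fs))
        c = stft_component_means(spec)
        w = wpd_features(sig)
        vals = {
            "spectral_energy": spectral_energy(spec),
            "component_entropy": component_entropy(spec),
            **{f"stft_c{i + 1}": c[i] for i in range(5)},
            **{f"wpd_l{i + 1}": w[i] for i in range(6)},
        }
        for feat in FREQ_AXIS_FEATURES:
            out[f"{signal.placement.value}.{ax}.{feat}"] = vals[feat]
    expected = sensor_freq_feature_names(signal.placement.value)
    return {name: out[name] for name in expected}
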