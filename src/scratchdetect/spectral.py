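"""Time-frequency analysis and kernel smoothing.

The detector works on a short-time Fourier transform with ~3 ms Gaussian-
tapered bins (128 samples at 44.1 kHz, 256 at 96 kHz) and 3/4 overlap. Power
above a frequency cut (10 kHz by default) is summed per frame and smoothed
with a triangular kernel of ~8 ms bandwidth — a crude matched filter, since a
single scratch is an ~8 ms triangular burst of high-band energy.

Smoothing kernels are normalized to unit sum and convolutions use reflection
padding, so a constant series passes through unchanged and the series mean is
(approximately) preserved.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np

__all__ = [
    "Spectrogram",
    "PowerSeries",
    "default_window_samples",
    "stft",
    "iter_stft_chunks",
    "band_power",
    "smooth_triangular",
    "smooth_gaussian",
    "smooth_gaussian_mixture",
]


@dataclass
class Spectrogram:
    """STFT coefficients on a uniform frame grid.

    ``coef`` is frames x freqs, complex; ``frame_times_s`` are window-center
    times; ``freqs_hz`` spans [0, Nyquist].
    """

    frame_times_s: np.ndarray
    freqs_hz: np.ndarray
    coef: np.ndarray
    sample_rate_hz: int
    hop_samples: int

    @property
    def power(self) -> np.ndarray:
        return np.abs(self.coef) ** 2

    @property
    def frame_dt_s(self) -> float:
        return self.hop_samples / self.sample_rate_hz

    @property
    def n_frames(self) -> int:
        return self.coef.shape[0]


@dataclass
class PowerSeries:
    """A non-negative series on the uniform STFT frame grid."""

    times_s: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=np.float64)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.times_s.shape != self.values.shape:
            raise ValueError("times and values must have equal length")

    @property
    def dt_s(self) -> float:
        if len(self.times_s) < 2:
            return 0.0
        return float(self.times_s[1] - self.times_s[0])

    def __len__(self) -> int:
        return len(self.values)

    def slice(self, start_s: float, end_s: float) -> "PowerSeries":
        """Restrict to frames with center time in [start_s, end_s]."""
        mask = (self.times_s >= start_s) & (self.times_s <= end_s)
        return PowerSeries(self.times_s[mask], self.values[mask])


def default_window_samples(sample_rate_hz: int) -> int:
    """~3 ms analysis window: 128 samples at 44.1 kHz, 256 at 96 kHz,
    and the nearest power of two to 3 ms otherwise."""
    if sample_rate_hz == 44100:
        return 128
    if sample_rate_hz == 96000:
        return 256
    return int(2 ** round(np.log2(0.003 * sample_rate_hz)))


def _gaussian_window(window_samples: int, sigma_fraction: float = 1.0 / 6.0) -> np.ndarray:
    # sigma = window/6 puts the taper at ~1% of peak at the edges
    n = np.arange(window_samples) - (window_samples - 1) / 2.0
    sigma = sigma_fraction * window_samples
    return np.exp(-0.5 * (n / sigma) ** 2)


def _frame_geometry(n_samples: int, window_samples: int, overlap_fraction: float):
    if window_samples < 8:
        raise ValueError("window_samples must be >= 8")
    if not 0 <= overlap_fraction < 1:
        raise ValueError("overlap_fraction must be in [0, 1)")
    hop = int(round(window_samples * (1.0 - overlap_fraction)))
    hop = max(hop, 1)
    if n_samples < window_samples:
        raise ValueError(
            f"signal ({n_samples} samples) shorter than one window ({window_samples})"
        )
    n_frames = (n_samples - window_samples) // hop + 1
    return hop, n_frames


def stft(
    channel: np.ndarray,
    sample_rate_hz: int,
    window_samples: int | None = None,
    overlap_fraction: float = 0.75,
    window_sigma_fraction: float = 1.0 / 6.0,
) -> Spectrogram:
    """Short-time Fourier transform with a Gaussian taper.

    Frame count is ``floor((n - window) / hop) + 1`` with
    ``hop = window * (1 - overlap_fraction)``; frame times are window centers.
    """
    channel = np.asarray(channel, dtype=np.float64)
    if window_samples is None:
        window_samples = default_window_samples(sample_rate_hz)
    hop, n_frames = _frame_geometry(len(channel), window_samples, overlap_fraction)
    window = _gaussian_window(window_samples, window_sigma_fraction)
    idx = np.arange(window_samples)[None, :] + hop * np.arange(n_frames)[:, None]
    coef = np.fft.rfft(channel[idx] * window, axis=1)
    freqs = np.fft.rfftfreq(window_samples, d=1.0 / sample_rate_hz)
    times = (np.arange(n_frames) * hop + (window_samples - 1) / 2.0) / sample_rate_hz
    return Spectrogram(
        frame_times_s=times,
        freqs_hz=freqs,
        coef=coef,
        sample_rate_hz=sample_rate_hz,
        hop_samples=hop,
    )


def iter_stft_chunks(
    channel: np.ndarray,
    sample_rate_hz: int,
    window_samples: int | None = None,
    overlap_fraction: float = 0.75,
    window_sigma_fraction: float = 1.0 / 6.0,
    chunk_frames: int = 65536,
) -> Iterator[tuple[int, np.ndarray]]:
    """Yield ``(first_frame_index, coef_chunk)`` blocks of the STFT.

    Identical frames to :func:`stft`, but never materializes the full
    coefficient matrix — hour-long recordings at 3/4 overlap have millions of
    frames, and the detection and feature passes only need per-frame
    reductions of the spectrum.
    """
    channel = np.asarray(channel, dtype=np.float64)
    if window_samples is None:
        window_samples = default_window_samples(sample_rate_hz)
    hop, n_frames = _frame_geometry(len(channel), window_samples, overlap_fraction)
    window = _gaussian_window(window_samples, window_sigma_fraction)
    col = np.arange(window_samples)[None, :]
    for start in range(0, n_frames, chunk_frames):
        stop = min(start + chunk_frames, n_frames)
        idx = col + hop * np.arange(start, stop)[:, None]
        yield start, np.fft.rfft(channel[idx] * window, axis=1)


def frame_times(
    n_samples: int,
    sample_rate_hz: int,
    window_samples: int | None = None,
    overlap_fraction: float = 0.75,
) -> np.ndarray:
    """Frame-center times matching :func:`stft` / :func:`iter_stft_chunks`."""
    if window_samples is None:
        window_samples = default_window_samples(sample_rate_hz)
    hop, n_frames = _frame_geometry(n_samples, window_samples, overlap_fraction)
    return (np.arange(n_frames) * hop + (window_samples - 1) / 2.0) / sample_rate_hz


def band_power(spec: Spectrogram, low_cut_hz: float) -> PowerSeries:
    """Per-frame power summed over frequencies >= ``low_cut_hz``."""
    nyquist = spec.sample_rate_hz / 2.0
    if low_cut_hz >= nyquist:
        raise ValueError(f"low_cut {low_cut_hz} Hz at or above Nyquist {nyquist} Hz")
    mask = spec.freqs_hz >= low_cut_hz
    values = np.sum(np.abs(spec.coef[:, mask]) ** 2, axis=1)
    return PowerSeries(times_s=spec.frame_times_s.copy(), values=values)


def _convolve_reflect(values: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Convolve with a unit-sum symmetric kernel under reflection padding."""
    half = len(kernel) // 2
    if half == 0:
        return values.copy()
    if len(values) == 1:
        return values.copy()
    pad = min(half, len(values) - 1)
    padded = np.pad(values, half, mode="reflect") if pad == half else None
    if padded is None:
        # series shorter than kernel half-width: reflect repeatedly
        padded = np.pad(values, half, mode="symmetric")
    return np.convolve(padded, kernel, mode="valid")


def _triangular_kernel(bandwidth_s: float, dt_s: float) -> np.ndarray:
    half = int(np.floor(bandwidth_s / dt_s - 1e-12))
    offsets = np.arange(-half, half + 1)
    weights = 1.0 - np.abs(offsets) * dt_s / bandwidth_s
    return weights / weights.sum()


def smooth_triangular(series: PowerSeries, bandwidth_s: float = 0.008) -> PowerSeries:
    """Triangular (matched-filter) smoothing with half-width ``bandwidth_s``."""
    if len(series) < 2:
        return PowerSeries(series.times_s.copy(), series.values.copy())
    if bandwidth_s <= series.dt_s:
        raise ValueError("bandwidth must exceed the frame spacing")
    kernel = _triangular_kernel(bandwidth_s, series.dt_s)
    return PowerSeries(series.times_s.copy(), _convolve_reflect(series.values, kernel))


def _gaussian_kernel(sigma_s: float, dt_s: float) -> np.ndarray:
    half = max(1, int(np.ceil(4.0 * sigma_s / dt_s)))
    offsets = np.arange(-half, half + 1) * dt_s
    weights = np.exp(-0.5 * (offsets / sigma_s) ** 2)
    return weights / weights.sum()


def smooth_gaussian(series: PowerSeries, sigma_s: float) -> PowerSeries:
    """Gaussian smoothing, kernel truncated at +/-4 sigma."""
    if sigma_s <= 0:
        raise ValueError("sigma_s must be positive")
    if len(series) < 2:
        return PowerSeries(series.times_s.copy(), series.values.copy())
    kernel = _gaussian_kernel(sigma_s, series.dt_s)
    return PowerSeries(series.times_s.copy(), _convolve_reflect(series.values, kernel))


def smooth_gaussian_mixture(
    series: PowerSeries,
    sigmas_s: tuple[float, float],
    weights: tuple[float, float] = (0.5, 0.5),
) -> PowerSeries:
    """Weighted sum of two Gaussian smoothers (weights >= 0, sum 1)."""
    w1, w2 = weights
    if w1 < 0 or w2 < 0 or abs(w1 + w2 - 1.0) > 1e-9:
        raise ValueError("mixture weights must be non-negative and sum to 1")
    out = np.zeros_like(series.values, dtype=np.float64)
    for sigma, w in zip(sigmas_s, weights):
        if w == 0:
            continue
        out += w * smooth_gaussian(series, sigma).values
    return PowerSeries(series.times_s.copy(), out)
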