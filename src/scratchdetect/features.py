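"""Per-island feature extraction for the second-pass classifier.

Each candidate island is described by 117 numbers:

* six transformed time series (three triangular-smoothed band powers above
  10/15/20 kHz, a Gaussian re-smoothing, a two-Gaussian-mixture re-smoothing,
  and per-frame cosine similarity with a learned scratch template spectrum),
  each summarized by eighteen extraction statistics built around the same
  peak rule as the first pass (6 x 18 = 108);
* eight spectral moments of the island's raw audio from a coarser (50 ms)
  spectrogram: first and second frequency moments of the time-mean and
  time-max magnitude spectra, for plain and squared magnitudes;
* the island duration.

A statistic without enough support (e.g. the standard deviation of inter-peak
gaps when there are fewer than three peaks) is coded exactly -1 so the
classifier can treat "undefined" as its own signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .audio_io import AudioRecording, LabelTrack
from .islands import CandidateIsland, DetectionConfig, detect_peaks
from .spectral import (
    PowerSeries,
    Spectrogram,
    band_power,
    frame_times,
    iter_stft_chunks,
    smooth_gaussian,
    smooth_gaussian_mixture,
    smooth_triangular,
    stft,
)

__all__ = [
    "TemplateSpectrum",
    "FeatureConfig",
    "FeatureVector",
    "TRANSFORM_NAMES",
    "STAT_NAMES",
    "MOMENT_NAMES",
    "feature_names",
    "build_transforms",
    "learn_template",
    "extract_stats",
    "fwhm",
    "spectral_moments",
    "featurize",
    "featurize_islands",
    "feature_frame",
]

UNDEFINED = -1.0

TRANSFORM_NAMES = ("tri10k", "tri15k", "tri20k", "gauss", "gaussmix", "template")

STAT_NAMES = (
    "n_peaks", "gap_mean", "gap_sd",
    "series_mean", "series_median", "series_min", "series_max", "series_sd",
    "peak_mean", "peak_median", "peak_min", "peak_max", "peak_sd",
    "fwhm_mean", "fwhm_median", "fwhm_min", "fwhm_max", "fwhm_sd",
)

MOMENT_NAMES = tuple(
    f"moment_c{i}_j{j}_k{k}" for i in (1, 2) for j in (1, 2) for k in (1, 2)
)


def feature_names() -> list[str]:
    """The fixed 117-name feature order (108 transform stats + 8 moments
    + duration)."""
    names = [f"{t}_{s}" for t in TRANSFORM_NAMES for s in STAT_NAMES]
    names.extend(MOMENT_NAMES)
    names.append("duration_s")
    return names


@dataclass
class TemplateSpectrum:
    """Unit-L2-norm average magnitude spectrum of training scratches, on the
    detection STFT frequency grid."""

    freqs_hz: np.ndarray
    mean_magnitude: np.ndarray

    def __post_init__(self) -> None:
        self.freqs_hz = np.asarray(self.freqs_hz, dtype=np.float64)
        self.mean_magnitude = np.asarray(self.mean_magnitude, dtype=np.float64)
        norm = np.linalg.norm(self.mean_magnitude)
        if norm <= 0:
            raise ValueError("template spectrum must be non-zero")
        self.mean_magnitude = self.mean_magnitude / norm


@dataclass(frozen=True)
class FeatureConfig:
    """Feature-bank parameters.

    ``gauss_sigma_s`` re-smooths the 10 kHz band power (default 8 ms, the
    matched-filter bandwidth); the mixture adds a 25 ms component — half a
    scratch period — so adjacent scratches blur into one hump. The peak rule
    inside extraction reuses the detection threshold unless
    ``peak_threshold_h`` overrides it; the template-similarity series lives on
    a cosine [0, 1] scale so it has its own threshold.
    """

    gauss_sigma_s: float = 0.008
    mixture_sigmas_s: tuple[float, float] = (0.008, 0.025)
    mixture_weights: tuple[float, float] = (0.5, 0.5)
    peak_threshold_h: float | None = None
    template_peak_threshold: float = 0.05
    moments_window_s: float = 0.050
    moments_overlap_s: float = 0.0385
    moments_channel: int | None = None  # None: channel with most island power
    mid_cut_hz: float = 15_000.0
    high_cut_hz: float = 20_000.0


@dataclass
class FeatureVector:
    """Ordered named features for one island."""

    island_id: int
    values: dict[str, float] = field(default_factory=dict)

    def as_array(self) -> np.ndarray:
        return np.asarray(list(self.values.values()), dtype=np.float64)


def build_transforms(
    recording: AudioRecording,
    template: TemplateSpectrum,
    det_config: DetectionConfig,
    feat_config: FeatureConfig | None = None,
) -> dict[str, PowerSeries]:
    """Compute the six transformed series on the detection frame grid.

    Per channel, one chunked STFT pass accumulates the three band powers and
    the per-frame cosine similarity with the template; smoothing follows.
    The per-channel transforms are averaged across microphones.
    """
    feat_config = feat_config or FeatureConfig()
    sr = recording.sample_rate_hz
    times = frame_times(recording.n_samples, sr,
                        overlap_fraction=det_config.stft_overlap)
    cuts = (det_config.low_cut_hz, feat_config.mid_cut_hz, feat_config.high_cut_hz)
    acc = {name: np.zeros(len(times)) for name in TRANSFORM_NAMES}
    for ch in recording.channels:
        bands = [np.empty(len(times)) for _ in cuts]
        cos = np.empty(len(times))
        masks = None
        tmpl = None
        for start, coef in iter_stft_chunks(
            ch, sr, overlap_fraction=det_config.stft_overlap
        ):
            if masks is None:
                freqs = np.fft.rfftfreq(2 * (coef.shape[1] - 1), d=1.0 / sr)
                if len(freqs) != len(template.freqs_hz) or not np.allclose(
                    freqs, template.freqs_hz
                ):
                    raise ValueError("template frequency grid does not match STFT")
                masks = [freqs >= c for c in cuts]
                tmpl = template.mean_magnitude
            mag = np.abs(coef)
            sl = slice(start, start + coef.shape[0])
            for b, mask in zip(bands, masks):
                b[sl] = np.sum(mag[:, mask] ** 2, axis=1)
            norms = np.linalg.norm(mag, axis=1)
            dots = mag @ tmpl
            with np.errstate(invalid="ignore", divide="ignore"):
                c = np.where(norms > 0, dots / norms, 0.0)  # zero frame -> 0
            cos[sl] = c
        bw = det_config.smooth_bandwidth_s
        t1 = smooth_triangular(PowerSeries(times, bands[0]), bw)
        acc["tri10k"] += t1.values
        acc["tri15k"] += smooth_triangular(PowerSeries(times, bands[1]), bw).values
        acc["tri20k"] += smooth_triangular(PowerSeries(times, bands[2]), bw).values
        acc["gauss"] += smooth_gaussian(t1, feat_config.gauss_sigma_s).values
        acc["gaussmix"] += smooth_gaussian_mixture(
            t1, feat_config.mixture_sigmas_s, feat_config.mixture_weights
        ).values
        acc["template"] += cos
    n_ch = recording.n_channels
    return {name: PowerSeries(times, acc[name] / n_ch) for name in TRANSFORM_NAMES}


def learn_template(
    recording: AudioRecording,
    scratch_labels: LabelTrack,
    det_config: DetectionConfig,
) -> TemplateSpectrum:
    """Average the magnitude spectra of all STFT frames inside training
    scratch intervals (all channels pooled) and L2-normalize."""
    bouts = scratch_labels.scratch_intervals()
    if not bouts:
        raise ValueError("template learning requires at least one scratch label")
    sr = recording.sample_rate_hz
    times = frame_times(recording.n_samples, sr,
                        overlap_fraction=det_config.stft_overlap)
    in_bout = np.zeros(len(times), dtype=bool)
    for iv in bouts:
        in_bout |= (times >= iv.onset_s) & (times < iv.offset_s)
    if not in_bout.any():
        raise ValueError("no STFT frames fall inside the scratch labels")
    total = None
    freqs = None
    for ch in recording.channels:
        for start, coef in iter_stft_chunks(
            ch, sr, overlap_fraction=det_config.stft_overlap
        ):
            sel = in_bout[start:start + coef.shape[0]]
            if not sel.any():
                continue
            mag = np.abs(coef[sel])
            if total is None:
                total = mag.sum(axis=0)
                freqs = np.fft.rfftfreq(2 * (coef.shape[1] - 1), d=1.0 / sr)
            else:
                total += mag.sum(axis=0)
    return TemplateSpectrum(freqs_hz=freqs, mean_magnitude=total)


def _stat_block(values: np.ndarray) -> list[float]:
    """mean, median, min, max, sd with the -1 undefined coding
    (sd needs >= 2 values)."""
    if len(values) == 0:
        return [UNDEFINED] * 5
    sd = float(np.std(values, ddof=1)) if len(values) >= 2 else UNDEFINED
    return [float(np.mean(values)), float(np.median(values)),
            float(np.min(values)), float(np.max(values)), sd]


def fwhm(segment: PowerSeries, peak_time_s: float) -> float:
    """Full width at half maximum of the peak at ``peak_time_s``.

    Walks outward from the peak to the crossings of half the peak height,
    linearly interpolating between frames; a missing crossing is clamped to
    the segment edge.
    """
    i = int(np.argmin(np.abs(segment.times_s - peak_time_s)))
    v, t = segment.values, segment.times_s
    half_height = v[i] / 2.0
    left = t[0]
    for j in range(i - 1, -1, -1):
        if v[j] <= half_height:
            denom = v[j + 1] - v[j]
            frac = (v[j + 1] - half_height) / denom if denom > 0 else 0.0
            left = t[j + 1] + frac * (t[j] - t[j + 1])
            break
    right = t[-1]
    for j in range(i + 1, len(v)):
        if v[j] <= half_height:
            denom = v[j - 1] - v[j]
            frac = (v[j - 1] - half_height) / denom if denom > 0 else 0.0
            right = t[j - 1] + frac * (t[j] - t[j - 1])
            break
    return float(right - left)


def extract_stats(
    segment: PowerSeries,
    det_config: DetectionConfig,
    threshold_h: float | None = None,
) -> dict[str, float]:
    """The eighteen extraction statistics of one transformed segment.

    Peaks are found with the same local-maximum rule as candidate collection
    (threshold ``threshold_h``, defaulting to the detection ``h``). Undefined
    statistics are coded -1.
    """
    if len(segment) == 0:
        raise ValueError("empty segment")
    cfg = det_config if threshold_h is None else replace(
        det_config, threshold_h=threshold_h)
    peaks = detect_peaks(segment, cfg)
    peak_times = np.asarray([p.time_s for p in peaks])
    peak_heights = np.asarray([p.height for p in peaks])
    gaps = np.diff(peak_times)
    out: dict[str, float] = {"n_peaks": float(len(peaks))}
    out["gap_mean"] = float(np.mean(gaps)) if len(gaps) >= 1 else UNDEFINED
    out["gap_sd"] = float(np.std(gaps, ddof=1)) if len(gaps) >= 2 else UNDEFINED
    for name, val in zip(STAT_NAMES[3:8], _stat_block(segment.values)):
        out[name] = val
    for name, val in zip(STAT_NAMES[8:13], _stat_block(peak_heights)):
        out[name] = val
    widths = np.asarray([fwhm(segment, p.time_s) for p in peaks])
    for name, val in zip(STAT_NAMES[13:18], _stat_block(widths)):
        out[name] = val
    return out


def spectral_moments(
    island_audio: np.ndarray,
    sample_rate_hz: int,
    config: FeatureConfig | None = None,
) -> dict[str, float]:
    """Frequency moments of an island's raw audio.

    A coarse STFT (50 ms bins, 38.5 ms overlap, Gaussian taper) gives
    magnitudes |c(t, w)|; c1(w) is their time-mean and c2(w) their time-max.
    The returned moments are

        m_{i,j,k} = sum_w w^k c_i(w)^j / sum_w c_i(w)^j,  (i,j,k) in {1,2}^3

    in Hz^k. Islands shorter than one bin are zero-padded; an all-zero island
    is coded -1 throughout.
    """
    config = config or FeatureConfig()
    island_audio = np.asarray(island_audio, dtype=np.float64)
    window = int(round(config.moments_window_s * sample_rate_hz))
    if len(island_audio) < window:
        island_audio = np.pad(island_audio, (0, window - len(island_audio)))
    overlap_fraction = config.moments_overlap_s / config.moments_window_s
    spec = stft(island_audio, sample_rate_hz, window_samples=window,
                overlap_fraction=overlap_fraction)
    mag = np.abs(spec.coef)
    if not np.any(mag > 0):
        return {name: UNDEFINED for name in MOMENT_NAMES}
    c = {1: mag.mean(axis=0), 2: mag.max(axis=0)}
    w = spec.freqs_hz
    out: dict[str, float] = {}
    for i in (1, 2):
        for j in (1, 2):
            weights = c[i] ** j
            denom = weights.sum()
            for k in (1, 2):
                name = f"moment_c{i}_j{j}_k{k}"
                out[name] = (
                    float(np.sum(w ** k * weights) / denom)
                    if denom > 0 else UNDEFINED
                )
    return out


def _island_samples(
    island: CandidateIsland, recording: AudioRecording, channel: int
) -> np.ndarray:
    sr = recording.sample_rate_hz
    lo = max(0, int(np.floor(island.start_s * sr)))
    hi = min(recording.n_samples, int(np.ceil(island.end_s * sr)))
    return recording.channels[channel][lo:hi]


def featurize(
    island: CandidateIsland,
    recording: AudioRecording,
    template: TemplateSpectrum,
    det_config: DetectionConfig,
    feat_config: FeatureConfig | None = None,
    transforms: dict[str, PowerSeries] | None = None,
) -> FeatureVector:
    """Assemble the full 117-value feature vector for one island.

    ``transforms`` may be precomputed once per recording (see
    :func:`featurize_islands`); otherwise they are built here.
    """
    feat_config = feat_config or FeatureConfig()
    if transforms is None:
        transforms = build_transforms(recording, template, det_config, feat_config)
    values: dict[str, float] = {}
    for tname in TRANSFORM_NAMES:
        segment = transforms[tname].slice(island.start_s, island.end_s)
        thr = (feat_config.template_peak_threshold if tname == "template"
               else feat_config.peak_threshold_h)
        stats = extract_stats(segment, det_config, threshold_h=thr)
        for sname in STAT_NAMES:
            values[f"{tname}_{sname}"] = stats[sname]
    if feat_config.moments_channel is not None:
        ch = feat_config.moments_channel
    else:
        powers = [float(np.sum(_island_samples(island, recording, c) ** 2))
                  for c in range(recording.n_channels)]
        ch = int(np.argmax(powers))
    moments = spectral_moments(
        _island_samples(island, recording, ch), recording.sample_rate_hz,
        feat_config)
    values.update(moments)
    values["duration_s"] = island.duration_s
    assert list(values.keys()) == feature_names()
    return FeatureVector(island_id=island.island_id, values=values)


def featurize_islands(
    islands: list[CandidateIsland],
    recording: AudioRecording,
    template: TemplateSpectrum,
    det_config: DetectionConfig,
    feat_config: FeatureConfig | None = None,
) -> list[FeatureVector]:
    """Featurize every island, sharing one transform computation."""
    feat_config = feat_config or FeatureConfig()
    transforms = build_transforms(recording, template, det_config, feat_config)
    return [
        featurize(isl, recording, template, det_config, feat_config, transforms)
        for isl in islands
    ]


def feature_frame(vectors: list[FeatureVector]) -> pd.DataFrame:
    """Feature vectors as a DataFrame indexed by island id."""
    names = feature_names()
    data = {n: [v.values[n] for v in vectors] for n in names}
    return pd.DataFrame(data, index=pd.Index(
        [v.island_id for v in vectors], name="island_id"))
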