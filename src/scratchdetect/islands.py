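"""First pass: peak picking on the smoothed high-band power and chaining
peaks into candidate islands.

A frame time ``t*`` is a peak when its smoothed power is the maximum over the
two-sided 25 ms window around it AND exceeds the window minimum by more than
the threshold ``h`` (a local, not global, threshold — robust to slow drifts
in background level). Peaks from the two microphones are merged (5 ms
tolerance, midpoint rule), then chained: runs of peaks with adjacent gaps
under 120 ms and at least three members become candidate islands, the unit
that the second-pass classifier accepts or rejects.

``h`` is in units of the smoothed power of [-1, 1]-normalized audio; it is
normally set by :func:`calibrate_threshold` to capture ~95% of labeled bouts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import maximum_filter1d, minimum_filter1d

from .audio_io import AudioRecording, LabelTrack
from .spectral import (
    PowerSeries,
    band_power,
    frame_times,
    iter_stft_chunks,
    smooth_triangular,
)

__all__ = [
    "Peak",
    "DetectionConfig",
    "CandidateIsland",
    "detect_peaks",
    "merge_channel_peaks",
    "group_islands",
    "detection_series",
    "find_candidate_islands",
    "calibrate_threshold",
    "capture_fraction",
]


@dataclass(frozen=True)
class Peak:
    """A localized maximum of the smoothed band power."""

    time_s: float
    height: float
    channel: int = 0


@dataclass(frozen=True)
class DetectionConfig:
    """First-pass parameters.

    threshold_h
        Local prominence threshold, in smoothed-power units.
    peak_window_s
        Half-width of the local-maximum window (25 ms: half a scratch period,
        so at most one peak per scratch survives).
    merge_tol_s
        Cross-microphone merge tolerance (5 ms).
    max_gap_s
        Maximum gap between adjacent peaks in a chain (120 ms, a little over
        two scratch periods).
    min_peaks
        Minimum chain length (3 — a bout has at least three scratches).
    low_cut_hz
        Lower edge of the power band (10 kHz, where scratches stand out from
        cage noise).
    smooth_bandwidth_s
        Triangular smoother half-width (~8 ms, one scratch duration).
    """

    threshold_h: float = 1e-3
    peak_window_s: float = 0.025
    merge_tol_s: float = 0.005
    max_gap_s: float = 0.120
    min_peaks: int = 3
    low_cut_hz: float = 10_000.0
    smooth_bandwidth_s: float = 0.008
    stft_overlap: float = 0.75

    def __post_init__(self) -> None:
        for name in ("threshold_h", "peak_window_s", "merge_tol_s", "max_gap_s",
                     "low_cut_hz", "smooth_bandwidth_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.min_peaks < 2:
            raise ValueError("min_peaks must be >= 2")


@dataclass
class CandidateIsland:
    """A chained group of >= ``min_peaks`` merged peaks."""

    start_s: float
    end_s: float
    peak_times_s: list[float]
    recording_id: str = ""
    island_id: int = -1

    def __post_init__(self) -> None:
        if not self.end_s > self.start_s:
            raise ValueError("island must have positive duration")
        if list(self.peak_times_s) != sorted(self.peak_times_s):
            raise ValueError("peak times must be ascending")

    @property
    def n_peaks(self) -> int:
        return len(self.peak_times_s)

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    @property
    def midpoint_s(self) -> float:
        return 0.5 * (self.start_s + self.end_s)


def detect_peaks(
    series: PowerSeries, config: DetectionConfig, channel: int = 0
) -> list[Peak]:
    """Apply the local-maximum peak rule to a power series.

    A point is a peak iff it attains the maximum over the two-sided
    ``peak_window_s`` window (truncated at the series edges) and exceeds the
    window minimum by strictly more than ``threshold_h``. Ties in the window
    maximum are broken toward the earliest time.
    """
    if len(series) == 0:
        raise ValueError("empty series")
    v = series.values
    if len(v) == 1:
        return []
    dt = series.dt_s
    half = max(1, int(np.floor(config.peak_window_s / dt + 1e-9)))
    size = 2 * half + 1
    # 'nearest' padding replicates edge values, equivalent to window truncation
    # for max/min
    wmax = maximum_filter1d(v, size=size, mode="nearest")
    wmin = minimum_filter1d(v, size=size, mode="nearest")
    cand = np.flatnonzero((v >= wmax) & (v - config.threshold_h > wmin))
    peaks: list[Peak] = []
    last_kept = -1
    for i in cand:
        if peaks and i - last_kept <= half and v[i] == v[last_kept]:
            continue  # tie within one window: keep the earliest
        peaks.append(Peak(time_s=float(series.times_s[i]), height=float(v[i]),
                          channel=channel))
        last_kept = int(i)
    return peaks


def merge_channel_peaks(
    peaks_per_channel: list[list[Peak]], merge_tol_s: float = 0.005
) -> np.ndarray:
    """Union peak times across microphones, then merge close pairs.

    Repeatedly replaces the closest pair under ``merge_tol_s`` (leftmost pair
    on ties) by its midpoint until all gaps are >= the tolerance. One-channel
    input passes through unchanged.
    """
    all_times = [p.time_s for ch in peaks_per_channel for p in ch]
    times = np.sort(np.asarray(all_times, dtype=np.float64))
    if len(peaks_per_channel) <= 1:
        return times
    while len(times) > 1:
        gaps = np.diff(times)
        j = int(np.argmin(gaps))
        if gaps[j] >= merge_tol_s:
            break
        mid = 0.5 * (times[j] + times[j + 1])
        times = np.concatenate([times[:j], [mid], times[j + 2:]])
    return times


def group_islands(
    peak_times: np.ndarray,
    config: DetectionConfig,
    recording_id: str = "",
) -> list[CandidateIsland]:
    """Chain peaks with gaps < ``max_gap_s``; drop chains shorter than
    ``min_peaks``; pad island bounds by one peak window on each side."""
    peak_times = np.asarray(peak_times, dtype=np.float64)
    islands: list[CandidateIsland] = []
    if len(peak_times) == 0:
        return islands
    breaks = np.flatnonzero(np.diff(peak_times) >= config.max_gap_s)
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [len(peak_times) - 1]])
    pad = config.peak_window_s
    for s, e in zip(starts, ends):
        chain = peak_times[s:e + 1]
        if len(chain) < config.min_peaks:
            continue
        islands.append(CandidateIsland(
            start_s=max(0.0, float(chain[0]) - pad),
            end_s=float(chain[-1]) + pad,
            peak_times_s=[float(t) for t in chain],
            recording_id=recording_id,
        ))
    for i, isl in enumerate(islands):
        isl.island_id = i
    return islands


def detection_series(
    recording: AudioRecording, config: DetectionConfig
) -> list[PowerSeries]:
    """Per-channel smoothed high-band power (the scan statistic P_t).

    STFT -> power above ``low_cut_hz`` -> triangular smoothing, computed in
    frame chunks so long recordings never materialize a full spectrogram.
    """
    sr = recording.sample_rate_hz
    times = frame_times(recording.n_samples, sr, overlap_fraction=config.stft_overlap)
    nyquist = sr / 2.0
    if config.low_cut_hz >= nyquist:
        raise ValueError("low_cut_hz at or above Nyquist")
    out: list[PowerSeries] = []
    for ch in recording.channels:
        vals = np.empty(len(times), dtype=np.float64)
        mask = None
        for start, coef in iter_stft_chunks(ch, sr, overlap_fraction=config.stft_overlap):
            if mask is None:
                freqs = np.fft.rfftfreq(2 * (coef.shape[1] - 1), d=1.0 / sr)
                mask = freqs >= config.low_cut_hz
            vals[start:start + coef.shape[0]] = np.sum(
                np.abs(coef[:, mask]) ** 2, axis=1)
        series = PowerSeries(times, vals)
        out.append(smooth_triangular(series, config.smooth_bandwidth_s))
    return out


def _islands_from_series(
    series_per_channel: list[PowerSeries],
    config: DetectionConfig,
    recording_id: str = "",
) -> list[CandidateIsland]:
    peaks = [detect_peaks(s, config, channel=i)
             for i, s in enumerate(series_per_channel)]
    merged = merge_channel_peaks(peaks, config.merge_tol_s)
    return group_islands(merged, config, recording_id=recording_id)


def find_candidate_islands(
    recording: AudioRecording, config: DetectionConfig
) -> list[CandidateIsland]:
    """Full first pass: scan statistic per channel, peak picking, cross-
    channel merge, chaining. Returns sorted islands with ids assigned."""
    return _islands_from_series(
        detection_series(recording, config), config, recording_id=recording.id
    )


def capture_fraction(islands: list[CandidateIsland], truth: LabelTrack) -> float:
    bouts = truth.scratch_intervals()
    if not bouts:
        return 1.0
    hit = 0
    for bout in bouts:
        for isl in islands:
            if min(isl.end_s, bout.offset_s) - max(isl.start_s, bout.onset_s) > 0:
                hit += 1
                break
    return hit / len(bouts)


def calibrate_threshold(
    recording: AudioRecording,
    truth: LabelTrack,
    config: DetectionConfig,
    target_capture: float = 0.95,
    n_grid: int = 25,
) -> float:
    """Choose ``h``: the largest value on a log grid whose islands overlap at
    least ``target_capture`` of the labeled scratch bouts.

    The first pass is deliberately permissive — missed bouts here can never be
    recovered by the classifier, while false islands can still be rejected.
    If no grid value reaches the target the grid minimum is returned with a
    warning.
    """
    if not truth.scratch_intervals():
        raise ValueError("calibration requires at least one scratch interval")
    series = detection_series(recording, config)
    lo = min(float(np.min(s.values)) for s in series)
    hi = max(float(np.max(s.values)) for s in series)
    span = hi - lo
    if span <= 0:
        warnings.warn("flat power series; threshold calibration degenerate")
        return config.threshold_h
    grid = span * np.logspace(-4, 0, n_grid)
    best = None
    for h in grid:
        cfg = replace(config, threshold_h=float(h))
        islands = _islands_from_series(series, cfg, recording.id)
        if capture_fraction(islands, truth) >= target_capture:
            best = float(h)  # grid ascends; keep the largest passing h
    if best is None:
        warnings.warn(
            f"no threshold on the grid reaches capture {target_capture}; "
            "returning grid minimum"
        )
        return float(grid[0])
    return best


def islands_to_csv(islands: list[CandidateIsland], path) -> None:
    """Serialize islands as CSV (peak times semicolon-joined)."""
    import csv

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["island_id", "start_s", "end_s", "n_peaks", "peak_times"])
        for isl in islands:
            w.writerow([
                isl.island_id, f"{isl.start_s:.6f}", f"{isl.end_s:.6f}",
                isl.n_peaks, ";".join(f"{t:.6f}" for t in isl.peak_times_s),
            ])


def islands_from_csv(path) -> list[CandidateIsland]:
    """Inverse of :func:`islands_to_csv`."""
    import csv

    out: list[CandidateIsland] = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out.append(CandidateIsland(
                start_s=float(row["start_s"]),
                end_s=float(row["end_s"]),
                peak_times_s=[float(t) for t in row["peak_times"].split(";") if t],
                island_id=int(row["island_id"]),
            ))
    return out
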