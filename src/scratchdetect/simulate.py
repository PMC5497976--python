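"""Synthetic scratch-audio generator with planted ground truth.

Emulates the behavioral statistics of chloroquine-induced scratching in a
caged mouse: scratch bouts of 3-6 individual scratches at a ~50 ms period,
each scratch an ~8 ms band-limited (10-20 kHz) noise burst with a triangular
amplitude envelope; bouts arrive in clusters (Poisson cluster onsets, 1-4
bouts per cluster, 0.3-1.0 s between bouts within a cluster). Two confounder
behaviors are planted alongside:

* grooming — 0.3-3 s of broadband noise with a pseudo-periodic bump envelope
  (irregular 45-110 ms bump spacing), deliberately similar enough to pass
  the first-pass detector some of the time;
* walking — short runs of 3-6 broadband "thumps" with irregular spacing and
  substantial low-frequency mass (occasionally a steady footfall rhythm near
  the scratch period).

A configurable fraction of confounder events are *scratch mimics*: short
trains of narrow high-band bursts at near-scratch periodicity (rhythmic
paw licking, head shakes). These are close to indistinguishable from true
bouts and set the realistic floor on the false discovery rate, mirroring
how real cage audio defeats purely rule-based detectors.

Channel 2, when present, is an attenuated copy delayed by 0.1-0.5 ms plus
independent microphone noise. Everything is determined by the seed.

The confounder timbres are stylized: no published spectra exist for real
cage sounds, so realism of the synthetic timbre cannot be validated — only
the statistics the generator is told to honor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .audio_io import AudioRecording, LabeledInterval, LabelTrack

__all__ = [
    "SimConfig",
    "SyntheticRecording",
    "simulate_recording",
    "summarize_truth",
]


@dataclass(frozen=True)
class SimConfig:
    """Generator parameters; defaults describe the packaged study corpus
    (20 min, two microphones, ~7.5 bouts/min, confounders on)."""

    duration_s: float = 1200.0
    sample_rate_hz: int = 44100
    n_channels: int = 2
    seed: int = 0
    bout_cluster_rate_per_min: float = 3.0
    bouts_per_cluster: tuple[int, int] = (1, 4)
    inter_bout_gap_s: tuple[float, float] = (0.3, 1.0)
    scratches_per_bout: tuple[int, int] = (3, 6)
    intra_bout_period_s: float = 0.050
    intra_bout_jitter_s: float = 0.005
    burst_duration_s: float = 0.008
    burst_band_hz: tuple[float, float] = (10_000.0, 20_000.0)
    snr_db: float = 20.0
    grooming_rate_per_min: float = 5.0
    grooming_duration_s: tuple[float, float] = (0.3, 3.0)
    walking_rate_per_min: float = 14.0
    background_noise_rms: float = 0.005
    channel2_attenuation: float = 0.7
    channel2_delay_s: tuple[float, float] = (0.0001, 0.0005)
    cluster_refractory_s: float = 1.5
    confounder_mimic_fraction: float = 0.25

    def __post_init__(self) -> None:
        if not 1 <= self.n_channels <= 2:
            raise ValueError("1 or 2 channels")
        if self.duration_s <= 0:
            raise ValueError("duration must be positive")
        for lo, hi in (self.bouts_per_cluster, self.inter_bout_gap_s,
                       self.scratches_per_bout, self.burst_band_hz,
                       self.grooming_duration_s, self.channel2_delay_s):
            if lo > hi:
                raise ValueError("ranges must be ordered")
        if self.intra_bout_jitter_s >= self.intra_bout_period_s:
            raise ValueError("period jitter must be below the period mean")
        for name in ("bout_cluster_rate_per_min", "grooming_rate_per_min",
                     "walking_rate_per_min"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class SyntheticRecording:
    """Planted-truth recording: audio, labels, config snapshot and the burst
    onset times of each bout (for generator self-checks)."""

    audio: AudioRecording
    truth: LabelTrack
    config: SimConfig
    scratch_burst_times: list[list[float]] = field(default_factory=list)


def _bandpass_burst(rng, n: int, band: tuple[float, float], sr: int) -> np.ndarray:
    pad = max(64, n)
    noise = rng.standard_normal(n + 2 * pad)
    nyq = sr / 2.0
    hi = min(band[1], 0.98 * nyq)
    sos = butter(4, [band[0] / nyq, hi / nyq], btype="band", output="sos")
    return sosfiltfilt(sos, noise)[pad:pad + n]


def _lowpass_burst(rng, n: int, cut_hz: float, sr: int) -> np.ndarray:
    pad = max(64, n)
    noise = rng.standard_normal(n + 2 * pad)
    sos = butter(4, cut_hz / (sr / 2.0), btype="low", output="sos")
    return sosfiltfilt(sos, noise)[pad:pad + n]


def _rms_scale(x: np.ndarray, target_rms: float) -> np.ndarray:
    r = np.sqrt(np.mean(x ** 2))
    return x * (target_rms / r) if r > 0 else x


def _add(signal: np.ndarray, start_idx: int, piece: np.ndarray) -> None:
    """Add a piece into the signal, truncating at the boundaries."""
    n = len(signal)
    if start_idx >= n or start_idx + len(piece) <= 0:
        return
    lo = max(start_idx, 0)
    hi = min(start_idx + len(piece), n)
    signal[lo:hi] += piece[lo - start_idx:hi - start_idx]


def _scratch_cluster_times(rng, cfg: SimConfig) -> list[list[float]]:
    """Burst onset times per bout; clusters sequential with a refractory gap
    so scratch truth intervals never overlap."""
    rate_s = cfg.bout_cluster_rate_per_min / 60.0
    if rate_s <= 0:
        return []
    bouts: list[list[float]] = []
    t = rng.exponential(1.0 / rate_s)
    last_end = -np.inf
    while t < cfg.duration_s:
        start = max(t, last_end + cfg.cluster_refractory_s)
        n_bouts = int(rng.integers(cfg.bouts_per_cluster[0],
                                   cfg.bouts_per_cluster[1] + 1))
        pos = start
        for _ in range(n_bouts):
            k = int(rng.integers(cfg.scratches_per_bout[0],
                                 cfg.scratches_per_bout[1] + 1))
            onsets = [pos]
            for _ in range(k - 1):
                gap = cfg.intra_bout_period_s + rng.uniform(
                    -cfg.intra_bout_jitter_s, cfg.intra_bout_jitter_s)
                onsets.append(onsets[-1] + gap)
            if onsets[0] < cfg.duration_s:
                bouts.append(onsets)
            pos = onsets[-1] + cfg.burst_duration_s + rng.uniform(
                *cfg.inter_bout_gap_s)
        last_end = pos
        t = start + rng.exponential(1.0 / rate_s)
    return bouts


def _poisson_times(rng, rate_per_min: float, duration_s: float) -> list[float]:
    if rate_per_min <= 0:
        return []
    out = []
    t = rng.exponential(60.0 / rate_per_min)
    while t < duration_s:
        out.append(t)
        t += rng.exponential(60.0 / rate_per_min)
    return out


def _overlaps_any(start: float, end: float, spans: list[tuple[float, float]],
                  margin: float = 0.3) -> bool:
    return any(min(end, b) - max(start, a) > -margin for a, b in spans)


def simulate_recording(config: SimConfig) -> SyntheticRecording:
    """Render the synthetic recording and its ground-truth label track.

    Scratch truth intervals span the envelope support of each bout's bursts;
    grooming and walking intervals carry their own tags. Confounder onsets
    that would collide with a scratch bout are dropped (thinning), keeping
    scratch truth clean. Fully determined by ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    sr = config.sample_rate_hz
    n = int(round(config.duration_s * sr))
    signal = np.zeros(n)
    burst_rms = config.background_noise_rms * 10 ** (config.snr_db / 20.0)
    burst_n = max(8, int(round(config.burst_duration_s * sr)))
    envelope = np.bartlett(burst_n)

    intervals: list[LabeledInterval] = []
    bout_bursts = _scratch_cluster_times(rng, config)
    scratch_spans: list[tuple[float, float]] = []
    kept_bursts: list[list[float]] = []
    for onsets in bout_bursts:
        # real scratch intensity varies between bouts and between swipes
        bout_gain = rng.uniform(0.6, 1.3)
        for onset in onsets:
            burst = _bandpass_burst(rng, burst_n, config.burst_band_hz, sr)
            burst = _rms_scale(burst * envelope,
                               burst_rms * bout_gain * rng.uniform(0.7, 1.4))
            _add(signal, int(round(onset * sr)), burst)
        start = onsets[0]
        end = min(onsets[-1] + config.burst_duration_s, config.duration_s)
        if end > start:
            intervals.append(LabeledInterval(start, end, "scratch"))
            scratch_spans.append((start, end))
            kept_bursts.append(list(onsets))

    def _mimic_train(onset: float) -> float | None:
        """A scratch-like burst train (rhythmic licking / head shake):
        narrow high-band bursts at near-scratch periodicity. Renders the
        audio and returns the end time, or None when it would collide with
        a true bout."""
        k = int(rng.integers(3, 7))
        gaps = np.abs(rng.normal(config.intra_bout_period_s, 0.006, size=k - 1))
        times = onset + np.concatenate([[0.0], np.cumsum(gaps)])
        end = min(times[-1] + config.burst_duration_s, config.duration_s)
        if end <= onset or _overlaps_any(onset, end, scratch_spans):
            return None
        gain = rng.uniform(0.5, 1.3)
        for t in times:
            if t >= config.duration_s:
                break
            burst = _bandpass_burst(rng, burst_n, config.burst_band_hz, sr)
            burst = _rms_scale(burst * envelope,
                               burst_rms * gain * rng.uniform(0.7, 1.4))
            _add(signal, int(round(t * sr)), burst)
        return end

    for onset in _poisson_times(rng, config.grooming_rate_per_min,
                                config.duration_s):
        if rng.uniform() < config.confounder_mimic_fraction:
            end = _mimic_train(onset)
            if end is not None:
                intervals.append(LabeledInterval(onset, end, "grooming"))
            continue
        dur = rng.uniform(*config.grooming_duration_s)
        end = min(onset + dur, config.duration_s)
        if _overlaps_any(onset, end, scratch_spans):
            continue
        m = int(round((end - onset) * sr))
        if m < burst_n:
            continue
        base = _rms_scale(rng.standard_normal(m), 0.3 * burst_rms)
        _add(signal, int(round(onset * sr)), base)
        t = 0.02
        while t < (end - onset) - 0.02:
            # each bump: broadband rub plus a high-band click component, so
            # grooming passes the first-pass band filter some of the time
            bn = int(round(rng.uniform(0.010, 0.025) * sr))
            amp = burst_rms * rng.uniform(0.8, 1.8)
            bump = (_rms_scale(rng.standard_normal(bn), 0.6 * amp)
                    + _rms_scale(_bandpass_burst(rng, bn, config.burst_band_hz,
                                                 sr), amp)) * np.hanning(bn)
            _add(signal, int(round((onset + t) * sr)), bump)
            t += rng.uniform(0.045, 0.110)
        intervals.append(LabeledInterval(onset, end, "grooming"))

    for onset in _poisson_times(rng, config.walking_rate_per_min,
                                config.duration_s):
        if rng.uniform() < config.confounder_mimic_fraction:
            end = _mimic_train(onset)
            if end is not None:
                intervals.append(LabeledInterval(onset, end, "walking"))
            continue
        k = int(rng.integers(3, 7))
        if rng.uniform() < 0.3:
            # a steady footfall rhythm near the scratch period
            base = rng.uniform(0.045, 0.065)
            gaps = base + rng.uniform(-0.008, 0.008, size=k - 1)
        else:
            gaps = rng.uniform(0.040, 0.120, size=k - 1)
        times = onset + np.concatenate([[0.0], np.cumsum(gaps)])
        end = min(times[-1] + 0.025, config.duration_s)
        if _overlaps_any(onset, end, scratch_spans):
            continue
        if end <= onset:
            continue
        for t in times:
            if t >= config.duration_s:
                break
            tn = int(round(rng.uniform(0.010, 0.025) * sr))
            low = _lowpass_burst(rng, tn, 5_000.0, sr)
            high = _bandpass_burst(rng, tn, config.burst_band_hz, sr)
            amp = burst_rms * rng.uniform(0.9, 1.8)
            thump = (_rms_scale(low, 1.5 * amp) + _rms_scale(high, amp)) * \
                np.hanning(tn)
            _add(signal, int(round(t * sr)), thump)
        intervals.append(LabeledInterval(onset, end, "walking"))

    channels = [signal + rng.normal(0.0, config.background_noise_rms, n)]
    if config.n_channels == 2:
        delay = rng.uniform(*config.channel2_delay_s)
        shift = int(round(delay * sr))
        delayed = np.concatenate([np.zeros(shift), signal[:n - shift]])
        channels.append(
            config.channel2_attenuation * delayed
            + rng.normal(0.0, config.background_noise_rms, n)
        )
    peak = max(np.max(np.abs(c)) for c in channels)
    if peak > 1.0:  # keep within the 16-bit PCM range
        channels = [c / (1.01 * peak) for c in channels]
    audio = AudioRecording(
        channels=channels, sample_rate_hz=sr, bit_depth=16,
        id=f"synthetic-seed{config.seed}",
    )
    return SyntheticRecording(
        audio=audio,
        truth=LabelTrack(intervals),
        config=config,
        scratch_burst_times=kept_bursts,
    )


def summarize_truth(
    truth: LabelTrack,
    burst_times: list[list[float]] | None = None,
) -> dict:
    """Descriptive statistics of the planted behavior.

    Returns bout count, duration quantiles (5/25/50/75/95%), inter-bout gap
    statistics, per-behavior counts, and — when burst metadata is supplied —
    scratches-per-bout and intra-bout period statistics.
    """
    if len(truth) == 0:
        raise ValueError("empty label track")
    bouts = truth.scratch_intervals()
    out: dict = {
        "n_intervals": len(truth),
        "behavior_counts": {},
        "n_bouts": len(bouts),
    }
    for iv in truth:
        out["behavior_counts"][iv.behavior] = \
            out["behavior_counts"].get(iv.behavior, 0) + 1
    if bouts:
        durations = np.asarray([iv.duration_s for iv in bouts])
        qs = np.percentile(durations, [5, 25, 50, 75, 95])
        out["duration_quantiles_s"] = dict(zip(("q05", "q25", "q50", "q75", "q95"),
                                               (float(q) for q in qs)))
        gaps = np.asarray([b.onset_s - a.offset_s for a, b in zip(bouts, bouts[1:])])
        if len(gaps):
            out["inter_bout_gap_s"] = {
                "mean": float(np.mean(gaps)),
                "median": float(np.median(gaps)),
            }
    if burst_times:
        counts = np.asarray([len(b) for b in burst_times])
        periods = np.concatenate([np.diff(b) for b in burst_times if len(b) > 1])
        out["scratches_per_bout"] = {
            "mean": float(np.mean(counts)),
            "min": int(np.min(counts)),
            "max": int(np.max(counts)),
        }
        out["intra_bout_period_s"] = {
            "mean": float(np.mean(periods)),
            "sd": float(np.std(periods)),
        }
    return out
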