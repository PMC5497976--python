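import numpy as np
import pytest

from scratchdetect.audio_io import AudioRecording, LabeledInterval, LabelTrack
from scratchdetect.features import (
    FeatureConfig,
    TemplateSpectrum,
    build_transforms,
    extract_stats,
    feature_frame,
    feature_names,
    featurize,
    featurize_islands,
    fwhm,
    learn_template,
    spectral_moments,
)
from scratchdetect.islands import CandidateIsland, DetectionConfig, detection_series
from scratchdetect.spectral import PowerSeries
from conftest import tone


def _series(values, dt=0.001):
    return PowerSeries(np.arange(len(values)) * dt, np.asarray(values, float))


def _bump(center, half_frames, height, n):
    v = np.zeros(n)
    idx = np.arange(-half_frames, half_frames + 1)
    v[center + idx] += height * (1 - np.abs(idx) / (half_frames + 1))
    return v


class TestFeatureNames:
    def test_dimension_is_117(self):
        names = feature_names()
        assert len(names) == 117
        assert len(set(names)) == 117
        assert names[-1] == "duration_s"


class TestExtractStats:
    def test_two_peaks_leave_gap_sd_undefined(self):
        v = _bump(30, 5, 2.0, 120) + _bump(80, 5, 2.0, 120)
        stats = extract_stats(_series(v), DetectionConfig(threshold_h=0.5))
        assert stats["n_peaks"] == 2
        assert stats["gap_sd"] == -1.0
        assert stats["gap_mean"] == pytest.approx(0.050)

    def test_no_peaks_codes_peak_stats_but_not_series_stats(self):
        stats = extract_stats(_series(np.full(100, 2.0)),
                              DetectionConfig(threshold_h=0.5))
        assert stats["n_peaks"] == 0
        for k in ("gap_mean", "gap_sd", "peak_mean", "peak_sd",
                  "fwhm_mean", "fwhm_max"):
            assert stats[k] == -1.0
        assert stats["series_mean"] == pytest.approx(2.0)
        assert stats["series_sd"] == pytest.approx(0.0)

    def test_three_regular_bumps_recover_period_and_width(self):
        n = 200
        v = _bump(50, 8, 4.0, n) + _bump(100, 8, 4.0, n) + _bump(150, 8, 4.0, n)
        stats = extract_stats(_series(v), DetectionConfig(threshold_h=1.0))
        assert stats["n_peaks"] == 3
        assert stats["gap_mean"] == pytest.approx(0.050)
        assert stats["gap_sd"] == pytest.approx(0.0, abs=1e-12)
        assert stats["peak_mean"] == pytest.approx(4.0)
        # triangle of half-width 9 frames: FWHM = 9 ms
        assert stats["fwhm_mean"] == pytest.approx(0.009, abs=1e-4)
        assert stats["fwhm_sd"] == pytest.approx(0.0, abs=1e-12)


class TestFwhm:
    def test_triangle_fwhm_is_half_width(self):
        v = _bump(100, 20, 6.0, 201)
        assert fwhm(_series(v), 0.100) == pytest.approx(0.021, abs=1e-3)

    def test_plateau_fwhm_is_plateau_width(self):
        v = np.zeros(200)
        v[80:121] = 1.0
        assert fwhm(_series(v), 0.100) == pytest.approx(0.041, abs=2e-3)

    def test_gaussian_fwhm_matches_closed_form(self):
        idx = np.arange(400)
        sigma_frames = 15.0
        v = np.exp(-0.5 * ((idx - 200) / sigma_frames) ** 2)
        got = fwhm(_series(v), 0.200)
        assert got == pytest.approx(2.355 * sigma_frames * 0.001, abs=0.001)

    def test_edge_clamped_when_no_crossing(self):
        v = np.linspace(1.0, 2.0, 100)  # never falls to half of the max
        got = fwhm(_series(v), 0.099)
        assert got == pytest.approx(0.099 - 0.0)


class TestSpectralMoments:
    def test_pure_tone_moments_concentrate_at_tone(self):
        m = spectral_moments(tone(8000, 0.3, 44100), 44100)
        for i in (1, 2):
            for j in (1, 2):
                assert m[f"moment_c{i}_j{j}_k1"] == pytest.approx(8000, rel=0.05)
                assert m[f"moment_c{i}_j{j}_k2"] == pytest.approx(
                    8000 ** 2, rel=0.10)

    def test_white_noise_mean_frequency_near_half_nyquist(self, rng):
        m = spectral_moments(rng.standard_normal(44100), 44100)
        assert m["moment_c1_j1_k1"] == pytest.approx(11025, rel=0.10)

    def test_zero_signal_coded_undefined(self):
        m = spectral_moments(np.zeros(4410), 44100)
        assert all(v == -1.0 for v in m.values())

    def test_short_island_zero_padded(self):
        m = spectral_moments(tone(8000, 0.01, 44100), 44100)
        assert m["moment_c1_j1_k1"] == pytest.approx(8000, rel=0.1)


def _template_for(recording, det):
    # flat high-band template on the right grid
    freqs = np.fft.rfftfreq(128, d=1.0 / recording.sample_rate_hz)
    mag = (freqs >= 10_000).astype(float)
    return TemplateSpectrum(freqs_hz=freqs, mean_magnitude=mag)


class TestTransforms:
    def test_t1_equals_detection_series_for_mono(self, rng):
        rec = AudioRecording(channels=[rng.normal(0, 0.1, 44100)],
                             sample_rate_hz=44100)
        det = DetectionConfig()
        transforms = build_transforms(rec, _template_for(rec, det), det)
        expected = detection_series(rec, det)[0]
        assert np.allclose(transforms["tri10k"].values, expected.values)

    def test_template_similarity_bounds_and_zero_frames(self, rng):
        rec = AudioRecording(channels=[np.concatenate(
            [np.zeros(22050), rng.normal(0, 0.1, 22050)])],
            sample_rate_hz=44100)
        det = DetectionConfig()
        t6 = build_transforms(rec, _template_for(rec, det), det)["template"]
        assert np.all(t6.values >= 0.0) and np.all(t6.values <= 1.0 + 1e-12)
        assert t6.values[0] == 0.0  # all-zero frame convention

    def test_template_parallel_frames_give_unit_similarity(self):
        # a 15 kHz tone frame is (nearly) parallel to a template learned
        # from the same tone
        rec = AudioRecording(channels=[tone(15_000, 0.5, 44100)],
                             sample_rate_hz=44100)
        det = DetectionConfig()
        labels = LabelTrack([LabeledInterval(0.1, 0.4, "scratch")])
        template = learn_template(rec, labels, det)
        t6 = build_transforms(rec, template, det)["template"]
        mid = slice(len(t6) // 4, 3 * len(t6) // 4)
        assert np.all(t6.values[mid] > 0.999)

    def test_grid_mismatch_rejected(self, rng):
        rec = AudioRecording(channels=[rng.normal(0, 0.1, 44100)],
                             sample_rate_hz=44100)
        bad = TemplateSpectrum(freqs_hz=np.linspace(0, 22050, 10),
                               mean_magnitude=np.ones(10))
        with pytest.raises(ValueError):
            build_transforms(rec, bad, DetectionConfig())


class TestLearnTemplate:
    def test_constant_spectrum_recovered(self):
        rec = AudioRecording(channels=[tone(12_000, 0.5, 44100)],
                             sample_rate_hz=44100)
        det = DetectionConfig()
        template = learn_template(
            rec, LabelTrack([LabeledInterval(0.1, 0.4, "scratch")]), det)
        peak_bin = int(np.argmax(template.mean_magnitude))
        df = template.freqs_hz[1] - template.freqs_hz[0]
        assert abs(template.freqs_hz[peak_bin] - 12_000) <= df
        assert np.linalg.norm(template.mean_magnitude) == pytest.approx(1.0)

    def test_no_scratch_labels_rejected(self, rng):
        rec = AudioRecording(channels=[rng.normal(0, 0.1, 44100)],
                             sample_rate_hz=44100)
        with pytest.raises(ValueError):
            learn_template(rec, LabelTrack([]), DetectionConfig())

    def test_synthetic_template_is_high_band(self, small_sim, small_corpus):
        template = small_corpus.template
        mag2 = template.mean_magnitude ** 2
        high = mag2[template.freqs_hz >= 10_000].sum()
        assert high > mag2.sum() / 2


@pytest.fixture(scope="module")
def silent_bursts():
    """Two identical synthetic bursts planted in silence, hop-aligned."""
    sr = 44100
    hop = 32
    x = np.zeros(sr * 4)
    rng = np.random.default_rng(0)
    burst = np.sin(2 * np.pi * 15000 * np.arange(400) / sr) * \
        np.bartlett(400) * 0.5
    train = np.zeros(hop * ((3 * 2205) // hop))
    for k in range(3):
        at = k * 2205
        train[at:at + 400] += burst
    offset1, offset2 = 32 * 1000, 32 * 3500  # exact frame multiples
    x[offset1:offset1 + len(train)] += train
    x[offset2:offset2 + len(train)] += train
    rec = AudioRecording(channels=[x], sample_rate_hz=sr)
    t0_1, t0_2 = offset1 / sr, offset2 / sr
    dur = len(train) / sr
    i1 = CandidateIsland(start_s=t0_1, end_s=t0_1 + dur, peak_times_s=[],
                         island_id=0)
    i2 = CandidateIsland(start_s=t0_2, end_s=t0_2 + dur, peak_times_s=[],
                         island_id=1)
    return rec, i1, i2

class TestFeaturize:
    def test_translation_invariance(self, silent_bursts):
        rec, i1, i2 = silent_bursts
        det = DetectionConfig(threshold_h=1e-4)
        template = _template_for(rec, det)
        v1, v2 = featurize_islands([i1, i2], rec, template, det)
        a1, a2 = v1.as_array(), v2.as_array()
        assert np.allclose(a1, a2, rtol=1e-6, atol=1e-9)

    def test_duration_feature(self, silent_bursts):
        rec, i1, _ = silent_bursts
        det = DetectionConfig(threshold_h=1e-4)
        v = featurize(i1, rec, _template_for(rec, det), det)
        assert v.values["duration_s"] == pytest.approx(i1.duration_s)
        assert len(v.values) == 117

    def test_no_nan_or_inf_on_real_corpus(self, small_corpus):
        frame = feature_frame(small_corpus.features)
        assert frame.shape[1] == 117
        assert np.all(np.isfinite(frame.to_numpy()))

    def test_amplitude_scaling_behavior(self, silent_bursts):
        # doubling amplitude with h scaled by 4 leaves peak counts, gaps and
        # template similarity unchanged; power-level stats scale by 4
        rec, i1, _ = silent_bursts
        det = DetectionConfig(threshold_h=1e-4)
        det4 = DetectionConfig(threshold_h=4e-4)
        rec2 = AudioRecording(channels=[2 * rec.channels[0]],
                              sample_rate_hz=rec.sample_rate_hz)
        template = _template_for(rec, det)
        v = featurize(i1, rec, template, det).values
        v2 = featurize(i1, rec2, template, det4).values
        assert v2["tri10k_n_peaks"] == v["tri10k_n_peaks"]
        assert v2["tri10k_gap_mean"] == pytest.approx(v["tri10k_gap_mean"])
        assert v2["template_series_mean"] == pytest.approx(
            v["template_series_mean"], rel=1e-6)
        assert v2["tri10k_series_mean"] == pytest.approx(
            4 * v["tri10k_series_mean"], rel=1e-6)
        assert v2["tri10k_peak_max"] == pytest.approx(
            4 * v["tri10k_peak_max"], rel=1e-6)
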