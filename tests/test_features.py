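import numpy as np
import pytest
from scipy import signal

from snoreforge import (
    Band,
    FULL_BAND,
    PAPER_BANDS,
    SegmentAnnotation,
    SourceSpec,
    Spectrum,
    auto_segment,
    band_powers,
    bandpass,
    estimate_formants,
    estimate_pitch,
    extract_features,
    generate_source,
    snoring_time_index,
    spectral_centroid,
    welch_psd,
)

FS = 12500.0


def tone(f, dur=2.0, fs=FS):
    return np.sin(2 * np.pi * f * np.arange(int(dur * fs)) / fs)


def resonator_sos(f, bw, fs=FS):
    """Two-pole resonator used as the known synthesis filter (oracle)."""
    r = np.exp(-np.pi * bw / fs)
    th = 2 * np.pi * f / fs
    return [1.0, 0.0, 0.0, 1.0, -2 * r * np.cos(th), r * r]


class TestBandpass:
    def test_stopband_50hz(self):
        x = tone(50.0)
        y = bandpass(x, FS)
        atten = 20 * np.log10(np.std(y[2000:-2000]) / np.std(x))
        assert atten <= -40.0

    def test_stopband_5khz(self):
        x = tone(5000.0)
        y = bandpass(x, FS)
        atten = 20 * np.log10(np.std(y[2000:-2000]) / np.std(x))
        assert atten <= -40.0

    def test_passband_1khz(self):
        x = tone(1000.0)
        y = bandpass(x, FS)
        assert abs(20 * np.log10(np.std(y[2000:-2000]) / np.std(x[2000:-2000]))) < 1.0

    def test_zero_in_zero_out(self):
        assert np.allclose(bandpass(np.zeros(5000), FS), 0.0)

    def test_low_fs_rejected(self):
        with pytest.raises(ValueError):
            bandpass(np.zeros(5000), 6000.0)


class TestWelch:
    def test_parseval_white_noise(self, rng):
        x = rng.standard_normal(int(10 * FS))
        sp = welch_psd(x, FS)
        total = np.trapezoid(sp.psd, sp.freqs)
        assert total == pytest.approx(np.var(x), rel=0.05)

    def test_tone_peak_location(self):
        sp = welch_psd(tone(500.0), FS)
        df = sp.freqs[1] - sp.freqs[0]
        assert sp.freqs[np.argmax(sp.psd)] == pytest.approx(500.0, abs=df)

    def test_homogeneity(self, rng):
        x = rng.standard_normal(int(2 * FS))
        a, b = welch_psd(x, FS), welch_psd(2 * x, FS)
        assert np.allclose(b.psd, 4 * a.psd)

    def test_short_segment_rejected(self):
        with pytest.raises(ValueError, match="ms"):
            welch_psd(np.zeros(100), FS)


class TestBandPowers:
    def flat_spectrum(self):
        freqs = np.arange(0, 6251.0, 12.5)
        return Spectrum(freqs=freqs, psd=np.ones_like(freqs))

    def test_flat_psd_uniform_relative_power(self):
        avg_db, rel = band_powers(self.flat_spectrum())
        assert rel == pytest.approx(np.ones(len(PAPER_BANDS)))
        assert avg_db == pytest.approx(np.zeros(len(PAPER_BANDS)), abs=1e-9)

    def test_full_band_relative_power_is_one(self, rng):
        x = rng.standard_normal(int(3 * FS))
        _, rel = band_powers(welch_psd(x, FS))
        assert rel[0] == pytest.approx(1.0)

    def test_tone_lands_in_its_band(self):
        sp = welch_psd(tone(300.0), FS)
        avg_db, _ = band_powers(sp)
        # bands: [full, 100-150, 150-450, 450-600, ...]; 300 Hz -> index 2
        assert int(np.argmax(avg_db[1:])) + 1 == 2

    def test_scaling_shifts_db_only(self, rng):
        x = rng.standard_normal(int(2 * FS))
        a_db, a_rel = band_powers(welch_psd(x, FS))
        b_db, b_rel = band_powers(welch_psd(np.sqrt(10) * x, FS))
        assert b_db - a_db == pytest.approx(10.0 * np.ones_like(a_db), abs=1e-9)
        assert b_rel == pytest.approx(a_rel)

    def test_band_outside_support_rejected(self):
        sp = welch_psd(tone(300.0), FS)
        with pytest.raises(ValueError):
            band_powers(sp, [Band(7000.0, 8000.0)])


class TestCentroid:
    def test_flat_band_midpoint(self):
        freqs = np.arange(0, 6251.0, 1.0)
        sp = Spectrum(freqs=freqs, psd=np.ones_like(freqs))
        assert spectral_centroid(sp, Band(450, 600)) == pytest.approx(525.0, abs=0.5)

    def test_single_tone_centroid(self):
        sp = welch_psd(tone(500.0), FS)
        df = sp.freqs[1] - sp.freqs[0]
        assert spectral_centroid(sp, Band(450, 600)) == pytest.approx(500.0, abs=2 * df)

    def test_two_equal_tones_weighted_mean(self):
        x = tone(1200.0) + tone(1800.0)
        sp = welch_psd(x, FS)
        c = spectral_centroid(sp, Band(1200, 1800))
        assert c == pytest.approx(1500.0, abs=10.0)

    def test_zero_power_returns_nan(self):
        freqs = np.arange(0, 6251.0, 1.0)
        sp = Spectrum(freqs=freqs, psd=np.zeros_like(freqs))
        assert np.isnan(spectral_centroid(sp, Band(450, 600)))

    def test_argmax_variant(self):
        sp = welch_psd(tone(500.0) + 0.2 * tone(550.0), FS)
        c = spectral_centroid(sp, Band(450, 600), mode="argmax")
        df = sp.freqs[1] - sp.freqs[0]
        assert c == pytest.approx(500.0, abs=df)


class TestPitch:
    def test_pure_sinusoid(self):
        assert estimate_pitch(tone(100.0, dur=1.0), FS) == pytest.approx(100.0, abs=1.0)

    def test_pulse_train_with_noise(self, rng):
        spec = SourceSpec(f0=102.0, jitter_pct=0.0, duration_s=1.0)
        x = generate_source(spec, seed=1)
        x = x + rng.normal(0, np.sqrt(np.mean(x**2) / 100), len(x))  # 20 dB SNR
        assert estimate_pitch(x, FS) == pytest.approx(102.0, abs=2.0)

    def test_white_noise_unvoiced(self, rng):
        assert estimate_pitch(rng.standard_normal(int(FS)), FS) is None

    def test_amplitude_invariance(self):
        x = generate_source(SourceSpec(f0=120.0, duration_s=1.0), seed=2)
        assert estimate_pitch(x, FS) == pytest.approx(
            estimate_pitch(7.3 * x, FS), rel=1e-9
        )

    def test_too_short_segment_rejected(self):
        with pytest.raises(ValueError):
            estimate_pitch(np.zeros(100), FS)


class TestFormants:
    def test_recovers_cohort_mean_formants(self, rng):
        """Source-filter synthetic with resonators at the measured means."""
        src = generate_source(SourceSpec(f0=102.1, jitter_pct=2.0, duration_s=1.0), seed=1)
        sos = np.array([resonator_sos(572.1, 80), resonator_sos(1626.1, 100)])
        y = signal.sosfilt(sos, src) + rng.normal(0, 1e-4, len(src))
        f1, f2 = estimate_formants(y, FS)
        assert f1 == pytest.approx(572.1, rel=0.05)
        assert f2 == pytest.approx(1626.1, rel=0.05)

    def test_single_resonator(self, rng):
        src = generate_source(SourceSpec(f0=102.1, jitter_pct=2.0, duration_s=1.0), seed=1)
        y = signal.sosfilt(np.array([resonator_sos(500.0, 80)]), src)
        y = y + rng.normal(0, 1e-4, len(y))
        f1, f2 = estimate_formants(y, FS)
        assert f1 == pytest.approx(500.0, rel=0.05)
        assert f2 is None or f2 > 1000.0

    def test_white_noise_has_no_stable_formant(self, rng):
        f1, f2 = estimate_formants(rng.standard_normal(int(FS)), FS)
        assert f1 is None

    def test_silence_missing(self):
        assert estimate_formants(np.zeros(int(FS)), FS) == (None, None)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            estimate_formants(np.zeros(50), FS)


class TestSnoringTimeIndex:
    def test_basic_ratio(self):
        anns = [SegmentAnnotation(0.0, 360.0, sleep_stage="N2")]
        sti = snoring_time_index(anns, {"N2": 3600.0})
        assert sti["N2"] == pytest.approx(0.1)

    def test_no_snores_zero_everywhere(self):
        sti = snoring_time_index([], {"N1": 600.0, "N2": 1200.0})
        assert sti == {"N1": 0.0, "N2": 0.0}

    def test_two_segments_sum(self):
        anns = [
            SegmentAnnotation(0.0, 30.0, sleep_stage="N3"),
            SegmentAnnotation(100.0, 130.0, sleep_stage="N3"),
        ]
        assert snoring_time_index(anns, {"N3": 300.0})["N3"] == pytest.approx(0.2)

    def test_overfull_stage_rejected(self):
        anns = [SegmentAnnotation(0.0, 400.0, sleep_stage="N2")]
        with pytest.raises(ValueError):
            snoring_time_index(anns, {"N2": 300.0})


class TestAutoSegment:
    def test_three_bursts_recovered(self, rng):
        burst = generate_source(SourceSpec(f0=102.1, duration_s=0.5), seed=2)
        sil = np.zeros(int(0.5 * FS))
        x = np.concatenate([sil, burst, sil, burst, sil, burst, sil])
        x = x + rng.normal(0, 1e-5, len(x))
        segs = auto_segment(x, FS)
        assert len(segs) == 3
        for seg, start in zip(segs, (0.5, 1.5, 2.5)):
            assert seg.start_s == pytest.approx(start, abs=0.05)
            assert seg.end_s == pytest.approx(start + 0.5, abs=0.05)

    def test_silence_empty(self):
        assert auto_segment(np.zeros(int(FS)), FS) == []

    def test_continuous_tone_single_segment(self):
        segs = auto_segment(tone(300.0, dur=1.0), FS)
        assert len(segs) == 1
        assert segs[0].start_s == pytest.approx(0.0, abs=0.05)
        assert segs[0].end_s == pytest.approx(1.0, abs=0.05)


class TestExtractFeatures:
    def test_full_vector_on_synthetic_snore(self, mean_subject):
        from snoreforge import synthesize_snore

        rec = synthesize_snore(mean_subject, seed=3)
        fset = extract_features(rec.samples, rec.fs)
        assert fset.rel_power[0] == pytest.approx(1.0)
        for band, c in zip(PAPER_BANDS, fset.centroid_hz):
            assert band.f_lo <= c <= band.f_hi
        assert fset.pitch_hz == pytest.approx(102.1, abs=3.0)
        truth_f1 = rec.truth["prediction"]["f1_hz"]
        assert fset.f1_hz == pytest.approx(truth_f1, rel=0.10)
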