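"""Reference loudness model: Cam scale, ear filter, excitation,
specific loudness, phon calibration and temporal smoothing."""

import numpy as np
import pytest

from phonmeter.frontend import AudioSignal, SILENCE_FLOOR_DB, band_spectra, scale_to_rms_level
from phonmeter.soundgen import SoundSpec, synthesize
from phonmeter.teacher import (
    BandSpectrum,
    CHANNEL_CAMS,
    DEFAULT_EAR,
    SmootherConfig,
    LoudnessTrace,
    _asymmetric_smooth,
    cam_from_frequency,
    ear_filter,
    excitation_pattern,
    frequency_from_cam,
    instantaneous_sones,
    overall_loudness,
    specific_loudness,
)
from conftest import tone_signal


class TestCamScale:
    def test_printed_octave_spans(self):
        # the octave 200-400 Hz spans 3.6 Cams; 4000-8000 Hz spans 6.2 Cams
        assert cam_from_frequency(400) - cam_from_frequency(200) == pytest.approx(
            3.6, abs=0.05
        )
        assert cam_from_frequency(8000) - cam_from_frequency(4000) == pytest.approx(
            6.2, abs=0.05
        )

    def test_zero_point_and_1khz_value(self):
        assert cam_from_frequency(0.0) == 0.0
        assert cam_from_frequency(1000.0) == pytest.approx(15.62, abs=0.01)

    def test_strictly_increasing_and_invertible(self):
        f = np.linspace(0, 8000, 400)
        cams = cam_from_frequency(f)
        assert np.all(np.diff(cams) > 0)
        assert frequency_from_cam(cams) == pytest.approx(f, abs=1e-6)

    def test_negative_frequency_rejected(self):
        with pytest.raises(ValueError):
            cam_from_frequency(-1.0)


class TestEarFilter:
    def test_canal_resonance_and_low_frequency_attenuation(self, bands):
        gain = DEFAULT_EAR.combined_gain(np.array([100.0, 1000.0, 3000.0]))
        assert gain[2] > gain[1]      # ear-canal resonance near 3 kHz
        assert gain[0] < gain[1]      # middle-ear attenuation at 100 Hz

    def test_flat_input_shifted_by_transfer_curve(self, bands):
        flat = BandSpectrum(levels=np.full(61, 60.0))
        out = ear_filter(flat, bands)
        expected = 60.0 + DEFAULT_EAR.combined_gain(bands.centers_hz)
        assert out.levels == pytest.approx(np.maximum(expected, SILENCE_FLOOR_DB))

    def test_out_of_range_frequency_rejected(self):
        with pytest.raises(ValueError):
            DEFAULT_EAR.combined_gain(np.array([10000.0]))


class TestExcitationPattern:
    def test_single_1khz_component_peaks_near_cam_15_6(self):
        levels = np.full(61, SILENCE_FLOOR_DB)
        freqs = np.linspace(50, 7900, 61)
        idx = int(np.argmin(np.abs(freqs - 1000.0)))
        levels[idx] = 60.0
        exc = excitation_pattern(levels, freqs)
        peak_cam = CHANNEL_CAMS[int(np.argmax(exc))]
        assert abs(peak_cam - cam_from_frequency(freqs[idx])) < 0.5

    def test_floor_input_gives_floor_excitation(self):
        levels = np.full(61, SILENCE_FLOOR_DB)
        freqs = np.linspace(50, 7900, 61)
        exc = excitation_pattern(levels, freqs)
        # total stimulus power is tiny, so no channel can exceed the
        # power sum of all floor components
        total_db = 10 * np.log10(61 * 10 ** (SILENCE_FLOOR_DB / 10.0))
        assert np.all(exc <= total_db + 1e-9)

    def test_distant_components_add_in_power(self):
        freqs = np.linspace(50, 7900, 61)
        f_a, f_b = 250.0, 6000.0  # far more than 10 Cams apart
        ia = int(np.argmin(np.abs(freqs - f_a)))
        ib = int(np.argmin(np.abs(freqs - f_b)))
        base = np.full(61, -200.0)  # effectively no background
        la, lb, lab = base.copy(), base.copy(), base.copy()
        la[ia] = 60.0
        lb[ib] = 60.0
        lab[ia] = 60.0
        lab[ib] = 60.0
        ea = 10 ** (excitation_pattern(la, freqs) / 10.0)
        eb = 10 ** (excitation_pattern(lb, freqs) / 10.0)
        eab = 10 ** (excitation_pattern(lab, freqs) / 10.0)
        both = 10 * np.log10(ea + eb)
        assert 10 * np.log10(eab) == pytest.approx(both, abs=0.1)


class TestSpecificLoudness:
    def test_far_below_threshold_is_negligible(self):
        n = specific_loudness(np.full(150, -40.0))
        assert np.all(n < 1e-4)

    def test_mid_level_growth_is_compressive(self):
        n60 = specific_loudness(np.full(150, 60.0))
        n70 = specific_loudness(np.full(150, 70.0))
        assert np.all(n70 > n60)
        assert np.all(n70 / n60 < 10.0)  # less than the 10x intensity ratio

    def test_channelwise_map_preserves_uniformity(self):
        n = specific_loudness(np.full(150, 50.0))
        # channels with the same threshold parameters respond identically;
        # all channels at/above 500 Hz share constants
        hi = CHANNEL_CAMS > cam_from_frequency(500.0)
        assert np.allclose(n[hi], n[hi][0])

    def test_summation_is_linear_in_n_prime(self):
        rng = np.random.default_rng(0)
        n_prime = rng.uniform(0, 2, 150)
        assert instantaneous_sones(2 * n_prime) == pytest.approx(
            2 * instantaneous_sones(n_prime)
        )
        assert instantaneous_sones(np.zeros(150)) == 0.0


class TestPhonCalibration:
    def test_1khz_identity_by_construction(self, teacher):
        sig = tone_signal(1000.0, 60.0)
        _, levels = band_spectra(sig, teacher.bands, hop=560)
        phons = np.asarray(teacher.phons_from_levels(levels))
        assert phons == pytest.approx(60.0, abs=0.25)

    def test_mapping_strictly_increasing(self, teacher):
        levels, sones = teacher.calibration_curve
        assert np.all(np.diff(sones) > 0)
        phons = teacher.phons_from_sones(sones)
        assert np.all(np.diff(phons) > 0)

    def test_phon_identity_20_to_100_db(self, teacher):
        for level in range(20, 101, 10):
            sig = tone_signal(1000.0, float(level))
            _, lv = band_spectra(sig, teacher.bands, hop=560)
            phons = np.mean(teacher.phons_from_levels(lv))
            assert phons == pytest.approx(level, abs=0.5)

    def test_loudness_monotone_in_level_for_fixed_shape(self, teacher):
        rng = np.random.default_rng(1)
        shape = rng.uniform(-10.0, 0.0, 61)
        # stay below the 110-phon reporting range where the scale saturates
        phons = [
            float(teacher.phons_from_levels(shape + offset))
            for offset in np.arange(20.0, 81.0, 5.0)
        ]
        assert np.all(np.diff(phons) > 0)

    def test_white_noise_louder_than_tone_and_excess_shrinks(self, teacher):
        rng = np.random.default_rng(2)
        excesses = []
        for level in (60.0, 100.0):
            noise = scale_to_rms_level(
                AudioSignal(rng.standard_normal(16000)), level
            )
            _, lv = band_spectra(noise, teacher.bands, hop=560)
            noise_phons = float(np.mean(teacher.phons_from_levels(lv)))
            excesses.append(noise_phons - level)
        assert excesses[0] > 0  # spectral loudness summation at 60 dB
        assert excesses[1] < excesses[0]  # the excess shrinks at high level

    def test_bandwidth_growth_does_not_reduce_loudness(self, teacher):
        # fixed-level pink noise centred at 1 kHz, widening bandwidth
        phons = []
        for bw in (0.2, 0.5, 1.0, 2.0, 3.0):
            spec = SoundSpec(
                kind="bandpass_noise", level_db=60.0, frequency=1000.0,
                bandwidth_oct=bw, slope_db_oct=-3.0, seed=9,
            )
            sig = synthesize(spec)
            _, lv = band_spectra(sig, teacher.bands, hop=560)
            phons.append(float(np.mean(teacher.phons_from_levels(lv))))
        # beyond roughly one ERB the loudness level must not decrease
        assert np.all(np.diff(phons) > -0.5)
        assert phons[-1] > phons[0]


class TestSmoothing:
    def test_constant_input_is_a_fixed_point(self, teacher):
        inst = np.full(3000, 60.0)
        trace = teacher.smooth_trace(np.arange(3000) * 1e-3, inst)
        assert trace.short_term[-1] == pytest.approx(60.0, abs=0.1)
        assert trace.long_term[-1] == pytest.approx(60.0, abs=0.5)

    def test_attack_faster_than_release(self):
        x = np.concatenate([np.zeros(10), np.ones(2000), np.zeros(4000)])
        y = _asymmetric_smooth(x, 0.045, 0.02)
        up = np.argmax(y >= 0.9) - 10
        down = np.argmax(y[2010:] <= 0.1)
        assert up < down

    def test_long_term_smoother_than_short_term(self, teacher):
        rng = np.random.default_rng(3)
        inst = np.clip(60 + 15 * rng.standard_normal(2000), 0, 110)
        trace = teacher.smooth_trace(np.arange(2000) * 1e-3, inst)
        d_short = np.mean(np.abs(np.diff(trace.short_term)))
        d_long = np.mean(np.abs(np.diff(trace.long_term)))
        assert d_long <= d_short

    def test_invalid_smoother_coefficients_rejected(self):
        with pytest.raises(ValueError):
            SmootherConfig(short_attack=0.02, short_release=0.045)

    def test_empty_series_rejected(self, teacher):
        with pytest.raises(ValueError):
            teacher.smooth_trace(np.array([]), np.array([]))


class TestOverallLoudness:
    def test_maximum_of_long_term(self):
        times = np.arange(5) * 1e-3
        trace = LoudnessTrace(
            times=times,
            instantaneous=np.array([0, 50, 80, 50, 0.0]),
            short_term=np.array([0, 30, 60, 55, 40.0]),
            long_term=np.array([0, 10, 20, 25, 24.0]),
        )
        assert overall_loudness(trace) == 25.0
        const = LoudnessTrace(times, np.full(5, 40.0), np.full(5, 40.0),
                              np.full(5, 40.0))
        assert overall_loudness(const) == 40.0

    def test_spike_judged_by_long_term_not_instantaneous(self, teacher):
        inst = np.zeros(2000)
        inst[1000] = 90.0
        trace = teacher.smooth_trace(np.arange(2000) * 1e-3, inst)
        assert trace.overall < 90.0
        assert trace.overall == pytest.approx(np.max(trace.long_term))
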