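"""Fourier analysis: F0/F1/phase conventions, SUM image, noise spectrum."""

import numpy as np
import pytest

from facile import (
    ImagingSession,
    StimulusSpec,
    compute_sum_image,
    f1_analysis,
    noise_spectrum,
    pixelwise_maps,
)

FR = 25.0


def brute_force_dft_bin(x, k):
    """Direct DFT summation at bin k (independent oracle)."""
    n = len(x)
    return sum(x[j] * np.exp(-2j * np.pi * k * j / n) for j in range(n))


class TestSumImage:
    def test_single_frame_is_identity(self):
        frame = np.random.default_rng(0).normal(size=(8, 9))
        s = ImagingSession(frame[None], frame_rate=FR)
        np.testing.assert_array_equal(compute_sum_image(s), frame)

    def test_additivity_and_mean_identity(self):
        s = ImagingSession(np.ones((2, 4, 5)), frame_rate=FR)
        np.testing.assert_array_equal(compute_sum_image(s), 2 * np.ones((4, 5)))
        stack = np.random.default_rng(1).normal(size=(7, 6, 5))
        s = ImagingSession(stack, frame_rate=FR)
        np.testing.assert_allclose(
            compute_sum_image(s), 7 * stack.mean(axis=0), rtol=1e-9
        )


class TestF1Analysis:
    def test_constant_trace(self, stim):
        f0, f1, _ = f1_analysis(np.full(250, 7.0), FR, stim)
        assert f0 == pytest.approx(7.0)
        assert f1 == pytest.approx(0.0, abs=1e-12)

    def test_cosine_amplitude_convention(self, stim):
        t = np.arange(1250) / FR
        trace = 1.0 + 0.5 * np.cos(2 * np.pi * stim.frequency * t)
        f0, f1, phase = f1_analysis(trace, FR, stim)
        assert f0 == pytest.approx(1.0, abs=1e-12)
        assert f1 == pytest.approx(0.5, abs=1e-12)
        assert phase == pytest.approx(0.0, abs=1e-9)

    def test_square_wave_closed_form_even_samples(self):
        # 0.25 Hz at 25 Hz -> N = 100 samples/period (even): the sampled
        # square-wave fundamental is exactly 4/(N sin(pi/N))
        stim = StimulusSpec(frequency=0.25)
        n_per = 100
        t = np.arange(4 * n_per) / FR
        trace = np.where(np.mod(t * stim.frequency, 1.0) < 0.5, 2.0, 0.0)
        f0, f1, _ = f1_analysis(trace, FR, stim)
        assert f0 == pytest.approx(1.0, abs=1e-12)
        assert f1 == pytest.approx(4 / (n_per * np.sin(np.pi / n_per)), rel=1e-9)

    def test_square_wave_at_study_frequency(self, stim):
        # 0.2 Hz at 25 Hz sampling: F1/F0 ~ 4/pi, checked against a direct
        # DFT summation oracle
        t = np.arange(625) / FR  # 5 cycles, 125 samples each
        trace = np.where(np.mod(t * stim.frequency, 1.0) < 0.5, 2.0, 0.0)
        f0, f1, phase = f1_analysis(trace, FR, stim)
        x = brute_force_dft_bin(trace, k=5)
        assert f1 == pytest.approx(2 * abs(x) / 625, rel=1e-9)
        assert phase == pytest.approx(np.angle(x), abs=1e-9)
        assert f1 / f0 == pytest.approx(4 / np.pi, rel=0.01)

    def test_dc_offset_invariance(self, stim):
        rng = np.random.default_rng(2)
        trace = rng.normal(10, 1, 500)
        f0a, f1a, pa = f1_analysis(trace, FR, stim)
        f0b, f1b, pb = f1_analysis(trace + 5.0, FR, stim)
        assert f1b == pytest.approx(f1a, rel=1e-12)
        assert pb == pytest.approx(pa, abs=1e-12)
        assert f0b == pytest.approx(f0a + 5.0, rel=1e-12)

    def test_whole_cycle_truncation_no_leakage(self, stim):
        t = np.arange(500) / FR
        trace = 2.0 + 0.3 * np.cos(2 * np.pi * stim.frequency * t)
        f1s = [f1_analysis(trace, FR, stim, n_cycles=c)[1] for c in (1, 2, 3, "auto")]
        assert max(f1s) - min(f1s) < 1e-9

    def test_antiphase_returns_phase_plus_pi(self, stim):
        t = np.arange(375) / FR
        on = 1.0 + 0.2 * np.cos(2 * np.pi * stim.frequency * t + 0.7)
        off = 1.0 - 0.2 * np.cos(2 * np.pi * stim.frequency * t + 0.7)
        _, _, p_on = f1_analysis(on, FR, stim)
        _, _, p_off = f1_analysis(off, FR, stim)
        diff = np.angle(np.exp(1j * (p_off - p_on - np.pi)))
        assert abs(diff) < 1e-6

    def test_parseval_identity_against_brute_force(self):
        # mean(x^2) = A0^2 + sum_k>0 A_k^2 / 2 with A_k = 2|X_k|/N (odd N)
        rng = np.random.default_rng(3)
        x = rng.normal(size=25)
        spectrum = [brute_force_dft_bin(x, k) for k in range(13)]
        a0 = abs(spectrum[0]) / 25
        aks = [2 * abs(c) / 25 for c in spectrum[1:]]
        total = a0**2 + 0.5 * sum(a**2 for a in aks)
        assert total == pytest.approx(np.mean(x**2), rel=1e-6)

    def test_onset_frame_anchors_phase(self):
        stim_late = StimulusSpec(frequency=0.2, onset_frame=50)
        t = np.arange(625) / FR
        trace = 1.0 + 0.5 * np.cos(2 * np.pi * 0.2 * (t - 50 / FR))
        _, f1, phase = f1_analysis(trace, FR, stim_late)
        assert f1 == pytest.approx(0.5, rel=1e-6)
        assert phase == pytest.approx(0.0, abs=1e-9)

    def test_errors(self, stim):
        with pytest.raises(ValueError, match="whole stimulus cycle"):
            f1_analysis(np.ones(50), FR, stim)  # < 1 cycle (125 samples)
        with pytest.raises(ValueError, match="Nyquist"):
            f1_analysis(np.ones(500), FR, StimulusSpec(frequency=13.0))


class TestPixelwiseMaps:
    def test_matches_per_trace_analysis(self, stim):
        rng = np.random.default_rng(4)
        stack = rng.normal(50, 5, (250, 6, 7))
        s = ImagingSession(stack, frame_rate=FR)
        maps = pixelwise_maps(s, stim)
        for y in range(6):
            for x in range(7):
                f0, f1, ph = f1_analysis(stack[:, y, x], FR, stim)
                assert maps.f0_map[y, x] == pytest.approx(f0, rel=1e-9)
                assert maps.f1_amp_map[y, x] == pytest.approx(f1, rel=1e-9, abs=1e-12)
                assert maps.f1_phase_map[y, x] == pytest.approx(ph, abs=1e-9)
        np.testing.assert_allclose(
            maps.norm_map, maps.f1_amp_map / maps.f0_map, rtol=1e-9
        )

    def test_constant_video_gives_zero_maps(self, stim):
        s = ImagingSession(np.full((250, 5, 5), 3.0), frame_rate=FR)
        maps = pixelwise_maps(s, stim)
        assert np.all(maps.f1_amp_map < 1e-12)
        assert np.all(maps.norm_map < 1e-12)
        assert maps.valid_mask.all()

    def test_dc_offset_shifts_f0_only(self, stim):
        rng = np.random.default_rng(5)
        stack = rng.normal(50, 5, (250, 4, 4))
        m1 = pixelwise_maps(ImagingSession(stack, frame_rate=FR), stim)
        m2 = pixelwise_maps(ImagingSession(stack + 10.0, frame_rate=FR), stim)
        np.testing.assert_allclose(m2.f1_amp_map, m1.f1_amp_map, rtol=1e-9, atol=1e-12)
        np.testing.assert_allclose(m2.f0_map, m1.f0_map + 10.0, rtol=1e-9)

    def test_nonpositive_f0_flagged_invalid(self, stim):
        stack = np.full((250, 3, 3), 2.0)
        stack[:, 1, 1] = -1.0
        maps = pixelwise_maps(ImagingSession(stack, frame_rate=FR), stim)
        assert not maps.valid_mask[1, 1]
        assert maps.norm_map[1, 1] == 0.0
        assert maps.valid_mask[0, 0]


class TestNoiseSpectrum:
    def test_zero_trace(self):
        est = noise_spectrum(np.zeros(3000), FR)
        assert est.mean_amp == 0.0
        assert est.sd_amp == 0.0
        assert est.n_bins >= 3

    def test_in_band_cosine_concentrates_in_one_bin(self):
        n = 2500  # 100 s -> df = 0.01 Hz
        t = np.arange(n) / FR
        a = 0.8
        trace = a * np.cos(2 * np.pi * 11.0 * t)
        est = noise_spectrum(trace, FR, band=(10, 12))
        x = np.fft.rfft(trace)
        freqs = np.fft.rfftfreq(n, 1 / FR)
        sel = (freqs >= 10) & (freqs <= 12)
        amps = 2 * np.abs(x[sel]) / n
        assert est.mean_amp == pytest.approx(amps.mean(), rel=1e-9)
        # all band energy in the 11 Hz bin
        assert amps.max() == pytest.approx(a, rel=1e-9)
        assert est.mean_amp == pytest.approx(a / est.n_bins, rel=1e-6)

    def test_white_noise_matches_rayleigh_closed_form(self):
        # band amplitudes of white noise are Rayleigh(sigma*sqrt(2/N));
        # their mean is sigma*sqrt(pi/N)
        sigma, n = 2.0, 3000
        rng = np.random.default_rng(6)
        means = [
            noise_spectrum(rng.normal(0, sigma, n), FR).mean_amp for _ in range(200)
        ]
        expected = sigma * np.sqrt(np.pi / n)
        assert np.mean(means) == pytest.approx(expected, rel=0.02)

    def test_band_errors_name_bin_count(self):
        with pytest.raises(ValueError, match="Nyquist"):
            noise_spectrum(np.zeros(1000), FR, band=(10, 13))
        with pytest.raises(ValueError, match="only 2 DFT bins"):
            # 25 samples at 25 Hz -> df = 1 Hz -> bins at 10, 11, 12... but
            # 12 < 12.5 Nyquist; use a band with 2 bins
            noise_spectrum(np.zeros(25), FR, band=(10, 11))
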