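"""Signal chain: centralization, bandpass, SNR, per-cycle AC, Q, rates.

Oracles are deliberately naive re-implementations (loops, closed forms,
frequency-response integrals) independent of the library code paths.
"""

import numpy as np
import pytest
from hypothesis import given, strategies as st_h
from scipy import signal as sps

import facepulse as fp
from facepulse.signals import SignalError
from facepulse.synthetic import harmonic_sum


def _windowed_mean_oracle(x, win):
    """Loop-based centered sliding mean, truncated at the edges."""
    out = np.empty_like(x, dtype=float)
    half_lo = (win - 1) // 2
    half_hi = win - 1 - half_lo
    for i in range(x.size):
        a = max(0, i - half_lo)
        b = min(x.size, i + half_hi + 1)
        out[i] = x[i] - x[a:b].mean()
    return out


class TestSlidingMeanCentralize:
    def test_constant_series_maps_to_zero(self):
        out = fp.sliding_mean_centralize(np.full(200, 7.5), 1.0, 40.0)
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_linear_ramp_interior_zero_edges_nonzero(self):
        x = np.arange(200, dtype=float)
        out = fp.sliding_mean_centralize(x, 1.0, 40.0)  # 41-tap centered window
        np.testing.assert_allclose(out[41:-41], 0.0, atol=1e-9)
        assert abs(out[0]) > 1  # truncated edge window is one-sided

    def test_matches_loop_oracle(self, rng):
        x = rng.normal(size=300)
        out = fp.sliding_mean_centralize(x, 1.0, 40.0)
        np.testing.assert_allclose(out, _windowed_mean_oracle(x, 41), atol=1e-10)

    def test_sinusoid_attenuation_matches_boxcar_response(self):
        # removal of the 41-tap boxcar mean leaves gain |1 - H_box(f)|
        fps, f0, win = 40.0, 1.0, 41
        t = np.arange(2000) / fps
        x = np.sin(2 * np.pi * f0 * t)
        out = fp.sliding_mean_centralize(x, 1.0, fps)
        gain = np.ptp(out[win:-win]) / 2.0
        h_box = (np.sin(np.pi * f0 * win / fps)
                 / (win * np.sin(np.pi * f0 / fps)))
        assert gain == pytest.approx(abs(1.0 - h_box), abs=0.02)

    def test_window_longer_than_series_rejected(self):
        with pytest.raises(SignalError):
            fp.sliding_mean_centralize(np.zeros(10), 1.0, 40.0)

    @given(st_h.floats(-50, 50), st_h.floats(0.5, 3.0))
    def test_affine_invariance(self, offset, scale):
        x = np.sin(np.arange(160) / 5.0)
        base = fp.sliding_mean_centralize(x, 1.0, 40.0)
        shifted = fp.sliding_mean_centralize(scale * x + offset, 1.0, 40.0)
        np.testing.assert_allclose(shifted, scale * base, atol=1e-8)


class TestBandpass:
    def test_in_band_tone_amplitude_and_phase_preserved(self):
        fps = 40.0
        t = np.arange(1200) / fps
        x = np.sin(2 * np.pi * 1.0 * t)
        y = fp.bandpass(x, 0.5, 4.0, fps)
        mid = slice(200, 1000)
        assert 0.95 <= np.ptp(y[mid]) / 2 <= 1.05
        # zero-phase: the peak within one interior cycle shifts < 1 frame
        cycle = slice(600, 640)
        assert abs(np.argmax(x[cycle]) - np.argmax(y[cycle])) <= 1

    def test_stopband_tone_suppressed(self):
        fps = 40.0
        t = np.arange(4000) / fps
        x = np.sin(2 * np.pi * 0.1 * t)
        y = fp.bandpass(x, 0.5, 4.0, fps)
        assert np.abs(y[400:-400]).max() < 0.05

    def test_zero_in_zero_out(self):
        np.testing.assert_array_equal(fp.bandpass(np.zeros(500), 0.5, 4.0, 40.0),
                                      np.zeros(500))

    def test_band_outside_nyquist_rejected(self):
        with pytest.raises(SignalError, match="Nyquist"):
            fp.bandpass(np.zeros(500), 0.5, 30.0, 40.0)


def _snr_oracle(x, f):
    num = den = 0.0
    for fi, xi in zip(f, x):
        num += fi * fi
        den += (fi - xi) ** 2
    return 10.0 * np.log10(num / den)


class TestSNR:
    def test_plug_in_values(self):
        # sum f^2 = 100 over 4 samples, sum (f-x)^2 = 10 -> 10 dB
        f = np.array([5.0, 5.0, 5.0, 5.0])
        x = f + np.array([1.0, -1.0, 2.0, -2.0])
        assert fp.compute_snr(x, f) == pytest.approx(10.0)

    def test_equal_power_ratio_gives_zero_db(self):
        f = np.array([1.0, 0.0])
        x = f + np.array([1.0, 0.0])
        assert fp.compute_snr(x, f) == pytest.approx(0.0)

    def test_identical_series_warn_inf(self):
        with pytest.warns(UserWarning, match="unbounded"):
            assert fp.compute_snr(np.ones(5), np.ones(5)) == np.inf

    def test_matches_loop_oracle_to_1e12(self, rng):
        x = rng.normal(size=400)
        f = fp.bandpass(x, 0.5, 4.0, 40.0)
        assert fp.compute_snr(x, f) == pytest.approx(_snr_oracle(x, f), rel=1e-12)

    def test_noisy_tone_matches_analytic_expectation(self):
        """Eq-style SNR on tone + white noise vs. a frequency-domain
        expectation computed from the filter's actual response."""
        fps, f0, amp, sd, n = 40.0, 1.2, 1.0, 0.5, 2400
        sos = sps.butter(5, [0.5, 4.0], btype="bandpass", fs=fps, output="sos")
        w, h = sps.sosfreqz(sos, worN=8192, fs=fps)
        g2 = np.abs(h) ** 4          # forward-backward power gain
        k0 = np.argmin(np.abs(w - f0))
        # E[sum f^2] ~ tone power * gain + noise through |H|^4
        exp_num = (amp ** 2 / 2) * n * g2[k0] + sd ** 2 * n * g2.mean()
        # E[sum (f-x)^2]: forward-backward filtering is zero phase with real
        # power transfer |H|^2, so the residual gain is (1 - |H|^2)^2
        r2 = (1 - np.abs(h) ** 2) ** 2
        exp_den = (amp ** 2 / 2) * n * r2[k0] + sd ** 2 * n * r2.mean()
        expected_db = 10 * np.log10(exp_num / exp_den)

        t = np.arange(n) / fps
        vals = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            x = amp * np.sin(2 * np.pi * f0 * t) + rng.normal(0, sd, n)
            vals.append(fp.compute_snr(x, fp.bandpass(x, 0.5, 4.0, fps)))
        assert np.mean(vals) == pytest.approx(expected_db, abs=0.5)


class TestACPerCycle:
    def test_constant_segment_rms_is_abs_value(self):
        pulse = np.full(40, -3.0)
        ac, span = fp.compute_ac_per_cycle(pulse, np.array([0, 20, 40]))
        np.testing.assert_allclose(ac, 3.0)
        np.testing.assert_allclose(span, 0.0)

    def test_unit_sinusoid_over_one_period(self):
        n = 1000
        s = np.sin(2 * np.pi * np.arange(n) / n)
        ac, _ = fp.compute_ac_per_cycle(s, np.array([0, n]))
        assert ac[0] == pytest.approx(1 / np.sqrt(2), rel=1e-4)

    def test_synthetic_waveform_rms_and_vanishing_std(self):
        fps, f0, amp = 40.0, 1.0, 10.0
        t = np.arange(1600) / fps
        pulse = amp * harmonic_sum(2 * np.pi * f0 * t)
        troughs = fp.detect_peaks(pulse, fps).troughs
        ac, _ = fp.compute_ac_per_cycle(pulse, troughs)
        theta = np.linspace(0, 2 * np.pi, 200000, endpoint=False)
        expected = amp * np.sqrt(np.mean(harmonic_sum(theta) ** 2))
        np.testing.assert_allclose(ac, expected, rtol=0.02)
        assert np.std(ac) < 0.05 * expected

    def test_short_cycles_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="skipped"):
            ac, _ = fp.compute_ac_per_cycle(np.ones(50), np.array([0, 1, 30]))
        assert ac.size == 1


class TestQValue:
    def test_single_recording(self):
        assert fp.compute_q([10.0], [2.0]) == 8.0

    def test_mean_over_recordings(self):
        assert fp.compute_q([10.0, 12.0], [1.0, 3.0]) == 9.0

    def test_empty_rejected(self):
        with pytest.raises(SignalError):
            fp.compute_q([], [])

    def test_q_monotone_in_amplitude(self, rng):
        fps = 40.0
        t = np.arange(1200) / fps
        noise = rng.normal(0, 1.0, t.size)
        qs = []
        for amp in (1.0, 2.0, 4.0):
            raw = 120 + amp * harmonic_sum(2 * np.pi * 1.2 * t) + noise
            sig = fp.RegionSignal.from_raw(0, raw, fps)
            train = fp.detect_peaks(sig.pulse, fps)
            snr = fp.compute_snr(sig.centralized, sig.pulse)
            ac, _ = fp.compute_ac_per_cycle(sig.pulse, train.troughs)
            qs.append(fp.compute_q([snr], [np.std(ac)]))
        assert qs[0] < qs[1] < qs[2]


class TestRateEstimation:
    def test_heart_rate_recovered_within_half_bpm(self):
        fps = 40.0
        t = np.arange(int(30 * fps)) / fps
        pulse = harmonic_sum(2 * np.pi * 1.2 * t)
        est = fp.estimate_rate(pulse, fps, (0.5, 4.0))
        assert est.bpm == pytest.approx(72.0, abs=0.5)
        assert est.confident

    def test_breath_rate_recovered_within_half_bpm(self):
        fps = 40.0
        t = np.arange(int(30 * fps)) / fps
        breath = np.sin(2 * np.pi * 0.3 * t)
        est = fp.estimate_rate(breath, fps, (0.2, 0.5))
        assert est.bpm == pytest.approx(18.0, abs=0.5)

    def test_white_noise_flags_low_confidence(self, rng):
        x = rng.normal(size=1200)
        with pytest.warns(UserWarning, match="low-confidence"):
            est = fp.estimate_rate(x, 40.0, (0.5, 4.0))
        assert not est.confident

    def test_too_short_series_rejected(self):
        with pytest.raises(SignalError):
            fp.estimate_rate(np.zeros(100), 40.0, (0.5, 4.0))


class TestPipelineLinearity:
    """Scaling all pixel values by c scales the signal chain by c, leaves
    SNR (a power ratio) unchanged, and scales AC by c."""

    def test_scaling_propagates_correctly(self, rng):
        fps, c = 40.0, 3.7
        t = np.arange(1200) / fps
        raw = 120 + 3 * harmonic_sum(2 * np.pi * 1.2 * t) + rng.normal(0, 0.5, t.size)
        a = fp.RegionSignal.from_raw(0, raw, fps)
        b = fp.RegionSignal.from_raw(0, c * raw, fps)
        np.testing.assert_allclose(b.centralized, c * a.centralized, atol=1e-8)
        np.testing.assert_allclose(b.pulse, c * a.pulse, atol=1e-8)
        snr_a = fp.compute_snr(a.centralized, a.pulse)
        snr_b = fp.compute_snr(b.centralized, b.pulse)
        assert snr_b == pytest.approx(snr_a, abs=1e-9)
        troughs = fp.detect_peaks(a.pulse, fps).troughs
        ac_a, _ = fp.compute_ac_per_cycle(a.pulse, troughs)
        ac_b, _ = fp.compute_ac_per_cycle(b.pulse, troughs)
        np.testing.assert_allclose(ac_b, c * ac_a, rtol=1e-9)
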