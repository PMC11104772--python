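import numpy as np
import pytest

from ciliaflow import (
    AnalysisConfig,
    CiliaSimParams,
    RoiSpec,
    analyze_video,
    detrend,
    dominant_frequency,
    power_spectrum,
    simulate_cilia_video,
)
from ciliaflow.benchmarks import naive_dft_power
from ciliaflow.roi_sampling import RoiTrace


def make_trace(values, rate=1000.0):
    return RoiTrace(roi=RoiSpec(10, 10, 11), values=np.asarray(values, float), frame_rate_hz=rate)


def tone(freq, n=1000, rate=1000.0, amplitude=1.0, phase=0.0):
    t = np.arange(n) / rate
    return amplitude * np.sin(2 * np.pi * freq * t + phase)


class TestDetrend:
    def test_constant_trace_mean_detrend_is_zero(self):
        out = detrend(make_trace(np.full(32, 0.7)), method="mean")
        np.testing.assert_allclose(out.values, 0.0, atol=1e-12)

    def test_exact_ramp_linear_detrend_is_zero(self):
        t = np.arange(64)
        out = detrend(make_trace(0.2 + 0.003 * t), method="linear")
        np.testing.assert_allclose(out.values, 0.0, atol=1e-10)

    def test_sinusoid_plus_ramp_leaves_sinusoid(self):
        """Residual must match an independent normal-equations line fit."""
        t = np.arange(500, dtype=float)
        wave = 0.1 * np.sin(2 * np.pi * 30 * t / 1000)
        y = 0.4 + 0.0005 * t + wave
        out = detrend(make_trace(y), method="linear")
        # brute-force least squares via the normal equations
        X = np.column_stack([np.ones_like(t), t])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        expected = y - X @ beta
        np.testing.assert_allclose(out.values, expected, atol=1e-10)

    def test_output_mean_is_zero(self):
        rng = np.random.default_rng(0)
        for method in ("mean", "linear"):
            out = detrend(make_trace(rng.uniform(0, 1, 100)), method=method)
            assert abs(out.values.mean()) < 1e-10

    def test_unknown_method_errors(self):
        with pytest.raises(ValueError, match="unknown detrend"):
            detrend(make_trace(np.zeros(10)), method="spline")


class TestPowerSpectrum:
    def test_bin_centered_tone_concentrates_in_one_bin(self):
        spec = power_spectrum(make_trace(tone(28.0)), window="rect")
        peak_bin = int(np.argmax(spec.power))
        assert spec.freqs_hz[peak_bin] == 28.0
        others = np.delete(spec.power, peak_bin)
        assert others.max() < 1e-10 * spec.power[peak_bin]

    def test_unit_tone_energy_in_peak_bin(self):
        n = 1000
        spec = power_spectrum(make_trace(tone(28.0, n=n)), window="rect")
        assert spec.power.max() == pytest.approx(n / 2, rel=1e-9)

    def test_zero_trace_gives_zero_power(self):
        spec = power_spectrum(make_trace(np.zeros(64)))
        np.testing.assert_array_equal(spec.power, 0.0)

    def test_too_short_trace_errors(self):
        with pytest.raises(ValueError, match="too short"):
            power_spectrum(make_trace(np.zeros(4)))

    def test_axes_conventions(self):
        spec = power_spectrum(make_trace(np.random.default_rng(1).normal(size=250)))
        assert spec.freqs_hz.size == 250 // 2 + 1
        assert spec.freqs_hz[-1] == 500.0
        assert spec.freqs_hz[1] - spec.freqs_hz[0] == pytest.approx(1000.0 / 250)

    @pytest.mark.parametrize("window", ["rect", "hann"])
    def test_matches_naive_dft_oracle(self, window):
        rng = np.random.default_rng(7)
        for n in (64, 129, 500):
            values = rng.standard_normal(n)
            spec = power_spectrum(make_trace(values), window=window)
            w = np.ones(n) if window == "rect" else 0.5 - 0.5 * np.cos(
                2 * np.pi * np.arange(n) / n
            )
            ref = naive_dft_power(values, w)
            np.testing.assert_allclose(spec.power, ref, rtol=0, atol=1e-9 * ref.max())

    def test_parseval_for_rect_window(self):
        rng = np.random.default_rng(3)
        values = rng.standard_normal(512)
        spec = power_spectrum(make_trace(values), window="rect")
        assert spec.power.sum() == pytest.approx(np.sum(values**2), rel=1e-9)


class TestDominantFrequency:
    def test_finds_tone_in_band(self):
        spec = power_spectrum(make_trace(tone(28.0)), window="rect")
        est = dominant_frequency(spec, band_hz=(5, 100), snr_min=3.0)
        assert est.cbf_hz == 28.0
        assert est.passed_qc

    def test_all_zero_spectrum_fails_qc(self):
        spec = power_spectrum(make_trace(np.zeros(64)))
        est = dominant_frequency(spec)
        assert not est.passed_qc
        assert np.isnan(est.cbf_hz)

    def test_off_bin_tone_within_one_bin(self):
        """Leakage cannot move the peak further than the bin spacing."""
        n, rate, true = 1024, 1000.0, 33.3
        spec = power_spectrum(make_trace(tone(true, n=n, rate=rate), rate=rate), window="hann")
        est = dominant_frequency(spec)
        assert abs(est.cbf_hz - true) <= rate / n

    def test_scale_invariance(self):
        spec = power_spectrum(make_trace(tone(40.0) + 0.05 * np.random.default_rng(5).normal(size=1000)))
        est1 = dominant_frequency(spec)
        spec.power = spec.power * 37.5
        est2 = dominant_frequency(spec)
        assert est1.cbf_hz == est2.cbf_hz
        assert est1.snr == pytest.approx(est2.snr)
        assert est1.passed_qc == est2.passed_qc

    def test_band_outside_spectrum_errors(self):
        spec = power_spectrum(make_trace(tone(28.0)))
        with pytest.raises(ValueError, match="band"):
            dominant_frequency(spec, band_hz=(600, 700))

    def test_band_excludes_out_of_band_peak(self):
        trace = make_trace(tone(3.0) + 0.2 * tone(40.0))
        spec = power_spectrum(trace, window="rect")
        est = dominant_frequency(spec, band_hz=(5, 100))
        assert est.cbf_hz == 40.0


class TestAnalyzeVideo:
    def test_recovers_true_cbf_for_every_qc_roi(self, cilia_scene):
        stack, mask, truth = cilia_scene
        table = analyze_video(stack, mask, AnalysisConfig(seed=1))
        qc = table[table["passed_qc"]]
        assert len(qc) >= 10
        bin_hz = 1000.0 / stack.n_frames
        assert (np.abs(qc["cbf_hz"] - truth["cbf_hz"]) <= bin_hz).all()

    def test_zero_amplitude_video_has_no_qc_pass(self):
        params = CiliaSimParams(frame_count=256, amplitude=0.0, noise_sigma=0.02, seed=4)
        stack, mask, _ = simulate_cilia_video(params)
        table = analyze_video(stack, mask, AnalysisConfig(seed=2))
        # pure noise: flat spectra, so the peak/median QC rejects everything
        assert table["passed_qc"].sum() == 0

    def test_deterministic_under_fixed_seed(self, cilia_scene):
        stack, mask, _ = cilia_scene
        t1 = analyze_video(stack, mask, AnalysisConfig(seed=9))
        t2 = analyze_video(stack, mask, AnalysisConfig(seed=9))
        assert t1.equals(t2)

    def test_reports_resolution_and_band(self, cilia_scene):
        stack, mask, _ = cilia_scene
        table = analyze_video(stack, mask, AnalysisConfig(seed=0))
        assert (table["freq_resolution_hz"] == 1000.0 / stack.n_frames).all()
        assert (table["band_low_hz"] == 5.0).all()
        assert (table["band_high_hz"] == 100.0).all()
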