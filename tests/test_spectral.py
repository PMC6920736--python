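"""Spectral chain: periodograms, band detection, normalization, line fits."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_spectrum
from qusradiomics.rf_core import RFFrame
from qusradiomics.spectral import (
    AnalysisBand,
    PowerSpectrum,
    attenuation_correct,
    detect_band,
    estimate_attenuation,
    fit_spectral_line,
    normalize_spectrum,
    window_spectrum,
)


def sinusoid_frame(f_mhz=8.0, n_axial=512, n_lines=8, fs=40.0):
    t = np.arange(n_axial) / fs  # microseconds
    line = np.sin(2 * np.pi * f_mhz * t)
    return RFFrame(np.tile(line[:, None], (1, n_lines)), fs=fs)


class TestWindowSpectrum:
    def test_sinusoid_peak_at_its_frequency(self):
        spec = window_spectrum(sinusoid_frame(8.0), 0, 256, 0, 8)
        assert spec.freqs[np.argmax(spec.power)] == pytest.approx(8.0, abs=0.05)

    def test_zero_gate_gives_zero_power(self):
        frame = RFFrame(np.zeros((256, 8)))
        spec = window_spectrum(frame, 0, 64, 0, 8)
        assert np.all(spec.power == 0)

    def test_identical_lines_equal_single_line_periodogram(self):
        frame = sinusoid_frame(6.0, n_lines=6)
        multi = window_spectrum(frame, 10, 128, 0, 6)
        # mean of identical periodograms equals any one of them: compare with
        # a window of different width over the same identical lines
        multi2 = window_spectrum(frame, 10, 128, 0, 4)
        np.testing.assert_allclose(multi.power, multi2.power, rtol=1e-12)

    def test_window_outside_frame(self):
        frame = sinusoid_frame()
        with pytest.raises(IndexError):
            window_spectrum(frame, 500, 64, 0, 8)

    def test_window_too_small(self):
        frame = sinusoid_frame()
        with pytest.raises(ValueError):
            window_spectrum(frame, 0, 16, 0, 8)

    def test_gate_center_depth(self):
        frame = sinusoid_frame(n_axial=512)
        spec = window_spectrum(frame, 100, 101, 0, 8)
        assert spec.center_depth == pytest.approx(150 * frame.axial_pixel_cm)


def test_spectrum_csv_export(tmp_path):
    from qusradiomics.spectral import spectrum_to_csv

    s = make_spectrum(np.linspace(1, 2, 16), in_db=True)
    path = tmp_path / "spec.csv"
    spectrum_to_csv(s, path)
    data = np.loadtxt(path, delimiter=",", skiprows=1)
    np.testing.assert_allclose(data[:, 0], s.freqs)
    np.testing.assert_allclose(data[:, 1], s.power)
    assert path.read_text().splitlines()[0] == "frequency_mhz,power_db"


class TestDetectBand:
    def test_gaussian_spectrum_band(self):
        freqs = np.linspace(0, 20, 801)
        sigma = 3.0 / np.sqrt(np.log(4.0))  # -6 dB half-width exactly 3 MHz
        power = np.exp(-((freqs - 8.0) ** 2) / sigma**2)
        b = detect_band(make_spectrum(power, freqs))
        assert b.f_lo == pytest.approx(5.0, abs=0.05)
        assert b.f_hi == pytest.approx(11.0, abs=0.05)
        assert b.f_mid == pytest.approx(8.0, abs=0.05)

    def test_flat_spectrum_spans_axis_with_warning(self):
        freqs = np.linspace(0, 20, 101)
        with pytest.warns(UserWarning, match="never crossed"):
            b = detect_band(make_spectrum(np.ones(101), freqs))
        assert b.f_lo == freqs[1]
        assert b.f_hi == freqs[-2]  # interior bins only (0 < f < Nyquist)

    def test_bimodal_band_around_taller_peak_matches_scan_oracle(self):
        rng = np.random.default_rng(3)
        freqs = np.linspace(0, 20, 401)
        power = (
            1.0 * np.exp(-((freqs - 6.0) ** 2) / 1.0)
            + 0.6 * np.exp(-((freqs - 14.0) ** 2) / 1.0)
            + 0.01 * rng.random(401)
        )
        b = detect_band(make_spectrum(power, freqs))
        # oracle: brute-force contiguous scan from the global interior max
        interior = np.arange(1, 400)
        peak = interior[np.argmax(power[interior])]
        thr = power[peak] / 4
        lo = peak
        while lo - 1 >= 1 and power[lo - 1] >= thr:
            lo -= 1
        hi = peak
        while hi + 1 <= 399 and power[hi + 1] >= thr:
            hi += 1
        assert (b.f_lo, b.f_hi) == (freqs[lo], freqs[hi])
        assert 4.5 < b.f_lo < b.f_hi < 8.0  # taller peak only


class TestNormalize:
    def test_identity_is_zero_db(self):
        s = make_spectrum(np.full(64, 2.5))
        out = normalize_spectrum(s, s)
        np.testing.assert_allclose(out.power, 0.0, atol=1e-12)
        assert out.in_db

    def test_tenfold_is_ten_db(self):
        r = make_spectrum(np.full(64, 0.3))
        s = make_spectrum(np.full(64, 3.0))
        np.testing.assert_allclose(normalize_spectrum(s, r).power, 10.0, atol=1e-9)

    def test_random_pair_matches_log_ratio_oracle(self):
        rng = np.random.default_rng(11)
        a = rng.random(128) + 0.1
        b = rng.random(128) + 0.1
        out = normalize_spectrum(make_spectrum(a), make_spectrum(b))
        np.testing.assert_allclose(out.power, 10 * np.log10(a / b), rtol=1e-12)

    def test_grid_mismatch_raises(self):
        s = make_spectrum(np.ones(64))
        r = PowerSpectrum(np.linspace(0, 10, 64), np.ones(64))
        with pytest.raises(ValueError):
            normalize_spectrum(s, r)

    def test_zero_reference_in_band_raises(self):
        r = np.ones(64)
        r[32] = 0.0
        with pytest.raises(ValueError, match="band"):
            normalize_spectrum(
                make_spectrum(np.ones(64)), make_spectrum(r), AnalysisBand(5, 15)
            )


class TestAttenuation:
    def make_norm(self, depth, power):
        return make_spectrum(power, in_db=True, center_depth=depth)

    def test_zero_depth_trend_returns_reference_alpha(self, band):
        freqs = np.linspace(0, 20, 64)
        spectra = [
            PowerSpectrum(freqs, np.full(64, -3.0), center_depth=d, in_db=True)
            for d in (1.0, 1.5, 2.0)
        ]
        est = estimate_attenuation(spectra, band, alpha_ref=0.5)
        assert est.alpha == pytest.approx(0.5, abs=1e-9)

    def test_constructed_slope_recovers_alpha(self, band):
        freqs = np.linspace(0, 20, 256)
        delta = 0.2  # alpha_sample - alpha_ref
        spectra = [
            PowerSpectrum(
                freqs, -4.0 * delta * freqs * d, center_depth=d, in_db=True
            )
            for d in (1.0, 1.4, 1.8, 2.2)
        ]
        est = estimate_attenuation(spectra, band, alpha_ref=0.5)
        assert est.alpha == pytest.approx(0.7, abs=1e-9)
        assert est.fit_r2 == pytest.approx(1.0, abs=1e-9)

    def test_two_depths_insufficient(self, band):
        freqs = np.linspace(0, 20, 64)
        spectra = [
            PowerSpectrum(freqs, np.zeros(64), center_depth=d, in_db=True)
            for d in (1.0, 2.0)
        ]
        with pytest.raises(ValueError):
            estimate_attenuation(spectra, band)

    def test_negative_clamp_warns(self, band):
        freqs = np.linspace(0, 20, 64)
        spectra = [
            PowerSpectrum(freqs, +4.0 * 0.4 * freqs * d, center_depth=d, in_db=True)
            for d in (1.0, 1.5, 2.0)
        ]
        with pytest.warns(UserWarning, match="clamped"):
            est = estimate_attenuation(spectra, band, alpha_ref=0.1)
        assert est.alpha == 0.0


class TestAttenuationCorrect:
    def test_equal_alphas_identity(self):
        s = make_spectrum(np.linspace(-5, 5, 64), in_db=True)
        out = attenuation_correct(s, 0.5, 0.5, 2.0)
        np.testing.assert_array_equal(out.power, s.power)

    def test_point_compensation_magnitude(self):
        freqs = np.linspace(0, 20, 201)
        s = PowerSpectrum(freqs, np.zeros(201), in_db=True)
        out = attenuation_correct(s, 1.0, 0.5, 2.0)
        idx = np.argmin(np.abs(freqs - 8.0))
        assert out.power[idx] == pytest.approx(4 * 0.5 * 8 * 2)  # 32 dB

    def test_zero_depth_identity(self):
        s = make_spectrum(np.linspace(-5, 5, 64), in_db=True)
        np.testing.assert_array_equal(attenuation_correct(s, 1.0, 0.2, 0.0).power, s.power)


class TestSpectralLineFit:
    def band_5_11(self):
        return AnalysisBand(5.0, 11.0)

    def test_exact_line_recovery(self):
        freqs = np.linspace(0, 20, 401)
        s = PowerSpectrum(freqs, -2.0 * freqs + 3.0, in_db=True)
        fit = fit_spectral_line(s, self.band_5_11())
        assert fit.SS == pytest.approx(-2.0, abs=1e-12)
        assert fit.SI == pytest.approx(3.0, abs=1e-12)
        assert fit.MBF == pytest.approx(-13.0, abs=1e-12)

    def test_constant_zero(self):
        s = make_spectrum(np.zeros(64), in_db=True)
        fit = fit_spectral_line(s, self.band_5_11())
        assert (fit.SS, fit.SI, fit.MBF) == (0.0, 0.0, 0.0)

    def test_noisy_lines_match_normal_equations_oracle(self):
        rng = np.random.default_rng(42)
        freqs = np.linspace(0, 20, 256)
        band = self.band_5_11()
        sel = band.mask(freqs)
        for _ in range(100):
            power = rng.normal(-1.5, 1.0) * freqs + rng.normal(0, 5) + rng.normal(
                0, 0.8, size=freqs.size
            )
            fit = fit_spectral_line(PowerSpectrum(freqs, power, in_db=True), band)
            # closed-form normal equations on the in-band bins
            A = np.column_stack([freqs[sel], np.ones(sel.sum())])
            slope, intercept = np.linalg.solve(A.T @ A, A.T @ power[sel])
            assert fit.SS == pytest.approx(slope, abs=1e-9)
            assert fit.SI == pytest.approx(intercept, abs=1e-9)
            assert fit.MBF == pytest.approx(intercept + slope * band.f_mid, abs=1e-9)

    def test_out_of_band_bins_do_not_matter(self):
        rng = np.random.default_rng(7)
        freqs = np.linspace(0, 20, 256)
        band = self.band_5_11()
        power = rng.normal(size=256)
        fit1 = fit_spectral_line(PowerSpectrum(freqs, power, in_db=True), band)
        power2 = power.copy()
        power2[~band.mask(freqs)] = rng.normal(100, 50, size=(~band.mask(freqs)).sum())
        fit2 = fit_spectral_line(PowerSpectrum(freqs, power2, in_db=True), band)
        assert fit1 == fit2

    def test_too_few_bins(self):
        s = make_spectrum(np.zeros(10), freqs=np.linspace(0, 40, 10), in_db=True)
        with pytest.raises(ValueError):
            fit_spectral_line(s, AnalysisBand(5, 11))

    @settings(max_examples=50, deadline=None)
    @given(
        slope=st.floats(-10, 10),
        intercept=st.floats(-50, 50),
        noise_seed=st.integers(0, 2**31 - 1),
    )
    def test_mbf_identity_property(self, slope, intercept, noise_seed):
        """MBF == SI + SS * f_mid holds for every fit (least-squares identity)."""
        rng = np.random.default_rng(noise_seed)
        freqs = np.linspace(0, 20, 128)
        power = slope * freqs + intercept + rng.normal(0, 2, 128)
        band = AnalysisBand(4.0, 12.0)
        fit = fit_spectral_line(PowerSpectrum(freqs, power, in_db=True), band)
        assert fit.MBF == pytest.approx(fit.SI + fit.SS * band.f_mid, abs=1e-9)

    def test_amplitude_doubling_shifts_si_mbf_not_ss(self):
        rng = np.random.default_rng(9)
        freqs = np.linspace(0, 20, 256)
        lin = rng.random(256) + 0.5
        ref = make_spectrum(np.ones(256), freqs=freqs)
        band = self.band_5_11()
        f1 = fit_spectral_line(normalize_spectrum(make_spectrum(lin, freqs=freqs), ref), band)
        # doubling RF amplitude quadruples power
        f2 = fit_spectral_line(
            normalize_spectrum(make_spectrum(4 * lin, freqs=freqs), ref), band
        )
        shift = 20 * np.log10(2)
        assert f2.SS == pytest.approx(f1.SS, abs=1e-9)
        assert f2.SI - f1.SI == pytest.approx(shift, abs=1e-9)
        assert f2.MBF - f1.MBF == pytest.approx(shift, abs=1e-9)
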