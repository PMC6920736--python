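"""Sliding-window power spectra and the spectral-parameter chain.

The quantitative-ultrasound spectral parameters are obtained from gated RF
windows: each window is Hann-tapered and Fourier transformed per scan line,
the per-line periodograms are averaged, the result is normalized (in dB) by a
tissue-mimicking reference phantom spectrum taken from the same depth to
cancel the system/transducer transfer function, corrected for the
frequency- and depth-proportional attenuation difference between sample and
phantom (point compensation at the gate-center depth), and finally a straight
line is regressed through the normalized dB spectrum inside the transducer's
-6 dB analysis band.  The line yields the three first-order parameters:

* SS  — spectral slope, dB/MHz
* SI  — 0-MHz (spectral) intercept, dB
* MBF — mid-band fit, the fitted value at the band center, dB

MBF = SI + SS * f_mid holds by the least-squares identity.

Attenuation of the sample is estimated by the spectral-log-difference method:
the depth-slope of the normalized dB power at each frequency is proportional
to -4 (alpha_sample - alpha_ref) f, so regressing the per-frequency depth
slopes on frequency recovers a single linear-in-frequency coefficient in
dB cm^-1 MHz^-1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal.windows import hann

from .rf_core import GeometryError, RFFrame

__all__ = [
    "PowerSpectrum",
    "AnalysisBand",
    "SpectralFit",
    "AttenuationEstimate",
    "window_spectrum",
    "detect_band",
    "normalize_spectrum",
    "estimate_attenuation",
    "attenuation_correct",
    "fit_spectral_line",
]

MIN_GATE_LINES = 4
MIN_GATE_SAMPLES = 32
DEFAULT_FFT_PAD = 4


@dataclass
class PowerSpectrum:
    """Averaged periodogram of one gated window (or a phantom reference).

    ``power`` is linear unless ``in_db`` is set.  ``center_depth`` (cm) and
    ``center_lateral`` (mm) locate the gate center in the frame.
    """

    freqs: np.ndarray
    power: np.ndarray
    center_depth: float = 0.0
    center_lateral: float = 0.0
    n_lines_averaged: int = 1
    in_db: bool = False

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if self.freqs.shape != self.power.shape or self.freqs.ndim != 1:
            raise ValueError("freqs and power must be congruent 1-D arrays")
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("frequency grid must be strictly increasing")
        if not self.in_db and np.any(self.power < 0):
            raise ValueError("linear power must be non-negative")
        if self.n_lines_averaged < 1:
            raise ValueError("n_lines_averaged must be >= 1")


@dataclass(frozen=True)
class AnalysisBand:
    """Frequency band (MHz) over which spectral fits are performed."""

    f_lo: float
    f_hi: float

    def __post_init__(self) -> None:
        if not 0 < self.f_lo < self.f_hi:
            raise ValueError(f"invalid band ({self.f_lo}, {self.f_hi})")

    @property
    def f_mid(self) -> float:
        return 0.5 * (self.f_lo + self.f_hi)

    def mask(self, freqs: np.ndarray) -> np.ndarray:
        return (freqs >= self.f_lo) & (freqs <= self.f_hi)


@dataclass(frozen=True)
class SpectralFit:
    """Linear-regression parameters of a normalized dB spectrum."""

    SS: float  # dB/MHz
    SI: float  # dB
    MBF: float  # dB
    band: AnalysisBand


@dataclass(frozen=True)
class AttenuationEstimate:
    alpha: float  # dB cm^-1 MHz^-1
    fit_r2: float


def spectrum_to_csv(spectrum: PowerSpectrum, path) -> None:
    """Export a spectrum as a 2-column CSV (frequency_mhz, power[_db])."""
    header = "frequency_mhz,power_db" if spectrum.in_db else "frequency_mhz,power"
    np.savetxt(
        path,
        np.column_stack([spectrum.freqs, spectrum.power]),
        delimiter=",",
        header=header,
        comments="",
    )


def window_spectrum(
    frame: RFFrame,
    axial_start: int,
    axial_len: int,
    line_start: int,
    n_lines: int,
    fft_pad: int = DEFAULT_FFT_PAD,
) -> PowerSpectrum:
    """Averaged Hann-tapered periodogram of a rectangular RF gate.

    Each scan line in the gate is tapered, zero-padded to ``fft_pad`` times
    the gate length, and its periodogram computed; the window's power
    spectrum is the mean periodogram across lines.
    """
    if axial_start < 0 or line_start < 0 or axial_len <= 0 or n_lines <= 0:
        raise IndexError("window indices must be non-negative with positive extent")
    if axial_start + axial_len > frame.n_axial or line_start + n_lines > frame.n_lines:
        raise IndexError("window extends outside the frame")
    if n_lines < MIN_GATE_LINES or axial_len < MIN_GATE_SAMPLES:
        raise ValueError(
            f"window must span >= {MIN_GATE_LINES} lines and "
            f">= {MIN_GATE_SAMPLES} axial samples"
        )
    gate = frame.samples[
        axial_start : axial_start + axial_len, line_start : line_start + n_lines
    ]
    taper = hann(axial_len, sym=False)
    nfft = int(fft_pad * axial_len)
    spectra = np.abs(np.fft.rfft(gate * taper[:, None], n=nfft, axis=0)) ** 2
    power = spectra.mean(axis=1)
    freqs = np.fft.rfftfreq(nfft, d=1.0 / frame.fs)  # MHz
    center_depth = frame.start_depth + (
        axial_start + (axial_len - 1) / 2.0
    ) * frame.axial_pixel_cm
    center_lateral = (line_start + (n_lines - 1) / 2.0) * frame.lateral_pitch
    return PowerSpectrum(
        freqs=freqs,
        power=power,
        center_depth=center_depth,
        center_lateral=center_lateral,
        n_lines_averaged=n_lines,
    )


def detect_band(reference_mean_spectrum: PowerSpectrum) -> AnalysisBand:
    """-6 dB analysis band of a reference spectrum.

    The band is the maximal contiguous interval around the global peak
    (restricted to 0 < f < Nyquist) where the power stays at or above a
    quarter of the peak power.  It is determined once per dataset from the
    reference phantom so that features are comparable across subjects.
    """
    spec = reference_mean_spectrum
    valid = (spec.freqs > 0) & (spec.freqs < spec.freqs[-1])
    if not valid.any():
        raise ValueError("spectrum has no interior frequency bins")
    power = spec.power if not spec.in_db else 10.0 ** (spec.power / 10.0)
    interior = np.where(valid)[0]
    peak_val = power[interior].max()
    peaks = interior[power[interior] == peak_val]
    if len(peaks) > 1:
        warnings.warn("non-unique spectral maximum; using lowest frequency")
    peak_idx = peaks[0]
    threshold = peak_val / 4.0
    above = power >= threshold
    lo = peak_idx
    while lo - 1 >= interior[0] and above[lo - 1]:
        lo -= 1
    hi = peak_idx
    while hi + 1 <= interior[-1] and above[hi + 1]:
        hi += 1
    if lo == interior[0] and hi == interior[-1]:
        warnings.warn("-6 dB threshold never crossed; band spans full axis")
    return AnalysisBand(spec.freqs[lo], spec.freqs[hi])


def normalize_spectrum(
    sample: PowerSpectrum,
    reference: PowerSpectrum,
    band: AnalysisBand | None = None,
) -> PowerSpectrum:
    """Reference-phantom normalization: 10 log10(sample / reference), dB.

    The reference must come from the same gate depth as the sample so the
    depth-dependent system response cancels.  Bins where the reference power
    vanishes are NaN (an error if they fall inside ``band``).
    """
    if sample.in_db or reference.in_db:
        raise ValueError("normalize_spectrum expects linear-power inputs")
    if sample.freqs.shape != reference.freqs.shape or not np.allclose(
        sample.freqs, reference.freqs
    ):
        raise ValueError("sample and reference frequency grids differ")
    ref = reference.power
    bad = ref <= 0
    if band is not None and np.any(bad & band.mask(sample.freqs)):
        raise ValueError("reference power vanishes inside the analysis band")
    if band is None and bad.all():
        raise ValueError("reference power is identically zero")
    with np.errstate(divide="ignore", invalid="ignore"):
        db = 10.0 * np.log10(np.where(bad, np.nan, sample.power / np.where(bad, 1.0, ref)))
    return PowerSpectrum(
        freqs=sample.freqs.copy(),
        power=db,
        center_depth=sample.center_depth,
        center_lateral=sample.center_lateral,
        n_lines_averaged=sample.n_lines_averaged,
        in_db=True,
    )


def estimate_attenuation(
    normalized_spectra: list[PowerSpectrum],
    band: AnalysisBand,
    alpha_ref: float = 0.0,
) -> AttenuationEstimate:
    """Spectral-log-difference attenuation estimate, dB cm^-1 MHz^-1.

    For each in-band frequency, the normalized dB power is regressed on the
    gate-center depth; the per-frequency depth slopes are then regressed on
    frequency, whose slope equals -4 (alpha_sample - alpha_ref).  The
    returned alpha is alpha_ref plus that differential, clamped at zero.
    """
    if len(normalized_spectra) < 3:
        raise ValueError("attenuation estimation needs >= 3 depths")
    depths = np.array([s.center_depth for s in normalized_spectra])
    if depths.max() - depths.min() < 0.5:
        raise ValueError("depth span must be >= 0.5 cm")
    freqs = normalized_spectra[0].freqs
    for s in normalized_spectra:
        if not s.in_db:
            raise ValueError("expected dB-normalized spectra")
        if not np.allclose(s.freqs, freqs):
            raise ValueError("spectra must share one frequency grid")
    sel = band.mask(freqs)
    f = freqs[sel]
    P = np.stack([s.power[sel] for s in normalized_spectra])  # (depth, freq)
    finite = np.isfinite(P).all(axis=0)
    f, P = f[finite], P[:, finite]
    if f.size < 5:
        raise ValueError("too few finite in-band bins for attenuation fit")
    # depth regression, vectorized over frequency
    design = np.column_stack([depths, np.ones_like(depths)])
    slopes = np.linalg.lstsq(design, P, rcond=None)[0][0]  # dB/cm at each f
    # frequency regression of the depth slopes
    m, b = np.polyfit(f, slopes, 1)
    pred = m * f + b
    ss_res = float(np.sum((slopes - pred) ** 2))
    ss_tot = float(np.sum((slopes - slopes.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    alpha = alpha_ref - m / 4.0
    if alpha < 0:
        warnings.warn(f"attenuation estimate {alpha:.3f} clamped to 0")
        alpha = 0.0
    return AttenuationEstimate(alpha=alpha, fit_r2=r2)


def attenuation_correct(
    normalized: PowerSpectrum,
    alpha_sample: float,
    alpha_ref: float,
    depth: float,
) -> PowerSpectrum:
    """Point-compensation attenuation correction at the gate-center depth.

    Adds back the round-trip differential loss 4 (alpha_s - alpha_r) f z in
    dB, with z the gate-center depth in cm and f in MHz.
    """
    if depth < 0:
        raise ValueError("depth must be >= 0")
    if not normalized.in_db:
        raise ValueError("attenuation correction applies to dB spectra")
    corrected = normalized.power + 4.0 * (alpha_sample - alpha_ref) * normalized.freqs * depth
    return PowerSpectrum(
        freqs=normalized.freqs.copy(),
        power=corrected,
        center_depth=normalized.center_depth,
        center_lateral=normalized.center_lateral,
        n_lines_averaged=normalized.n_lines_averaged,
        in_db=True,
    )


def fit_spectral_line(corrected: PowerSpectrum, band: AnalysisBand) -> SpectralFit:
    """Ordinary least squares of in-band dB power on frequency.

    SS is the slope (dB/MHz), SI the 0-MHz intercept (dB) and MBF the fitted
    value at the band center (dB); bins outside the band never influence the
    fit.
    """
    if not corrected.in_db:
        raise ValueError("spectral line is fitted to dB spectra")
    sel = band.mask(corrected.freqs) & np.isfinite(corrected.power)
    if sel.sum() < 5:
        raise ValueError("need >= 5 in-band frequency bins")
    ss, si = np.polyfit(corrected.freqs[sel], corrected.power[sel], 1)
    return SpectralFit(SS=float(ss), SI=float(si), MBF=float(si + ss * band.f_mid), band=band)
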