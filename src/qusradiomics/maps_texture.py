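"""Parametric maps over the ROI and GLCM texture radiomics.

A sliding 2 x 2 mm window (94% overlap by default) is moved over the lymph
node; every window whose center lies inside the ROI runs the full estimation
chain — spectral line fit (MBF/SS/SI), backscatter-coefficient inversion
(ASD/AAC for Gaussian and Anderson form factors) and scatterer spacing (SAS)
— producing eight parametric maps on the window-step lattice.

Texture of each map is summarized by the gray-level co-occurrence matrix
(GLCM): the map is min-max quantized to 16 gray tones, co-occurrence
probabilities p(i, j) are accumulated at four inter-pixel distances and four
directions (0, 45, 90, 135 degrees, symmetric), and four features are read
off each GLCM:

    contrast     sum (i-j)^2 p(i,j)
    correlation  [sum i j p(i,j) - mu_x mu_y] / (sigma_x sigma_y)
    energy       sum p(i,j)^2
    homogeneity  sum p(i,j) / (1 + (i-j)^2)

with mu/sigma the marginal row/column moments.  A subject's feature vector
is the 8 map means plus the per-feature average over the 16 GLCMs of each
map: 40 named features.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .rf_core import EmptyROIError, ReferenceData, RFFrame, ROIMask
from . import spectral as sp
from . import scatterer as sc

__all__ = [
    "MAP_NAMES",
    "TEXTURE_NAMES",
    "FEATURE_NAMES",
    "DISPLAY_FEATURE_NAMES",
    "ParametricMap",
    "GLCM",
    "TextureFeatures",
    "FeatureVector",
    "ExtractionConfig",
    "build_parametric_maps",
    "quantize_map",
    "compute_glcm",
    "glcm_features",
    "aggregate_subject_features",
]

MAP_NAMES = ["MBF", "SS", "SI", "SAS", "ASD_gau", "ASD_and", "AAC_gau", "AAC_and"]
TEXTURE_NAMES = ["con", "cor", "ene", "hom"]
FEATURE_NAMES = MAP_NAMES + [f"{m}-{t}" for m in MAP_NAMES for t in TEXTURE_NAMES]

#: machine name -> the display name used in the source study's tables
DISPLAY_FEATURE_NAMES = {
    name: name.replace("ASD_gau", "ASD (gau)")
    .replace("ASD_and", "ASD (and)")
    .replace("AAC_gau", "AAC (gau)")
    .replace("AAC_and", "AAC (and)")
    for name in FEATURE_NAMES
}

MAP_UNITS = {
    "MBF": "dB",
    "SS": "dB/MHz",
    "SI": "dB",
    "SAS": "mm",
    "ASD_gau": "um",
    "ASD_and": "um",
    "AAC_gau": "dB",
    "AAC_and": "dB",
}


@dataclass
class ParametricMap:
    """Per-window QUS parameter image on the window-step lattice."""

    values: np.ndarray  # 2-D, NaN outside ROI / undefined
    name: str
    units: str
    pixel_pitch: float  # mm

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("map values must be 2-D")
        if self.name not in MAP_NAMES:
            raise ValueError(f"unknown map name {self.name!r}")
        if not np.isfinite(self.values).any():
            warnings.warn(f"parametric map {self.name} has no finite pixels")

    @property
    def finite_mean(self) -> float:
        vals = self.values[np.isfinite(self.values)]
        return float(vals.mean()) if vals.size else float("nan")

    def save_png(self, path) -> None:
        """Quick-look preview; NaN pixels render transparent."""
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        masked = np.ma.masked_invalid(self.values)
        plt.imsave(path, masked, cmap="viridis")


@dataclass
class GLCM:
    """Normalized 16x16 co-occurrence probabilities at one displacement."""

    p: np.ndarray
    distance: int
    direction: int  # degrees: 0 | 45 | 90 | 135
    symmetric: bool = True

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        if self.p.ndim != 2 or self.p.shape[0] != self.p.shape[1]:
            raise ValueError("GLCM must be square")
        if np.any(self.p < 0) or abs(self.p.sum() - 1.0) > 1e-12:
            raise ValueError("GLCM must be non-negative and sum to 1")
        if self.symmetric and not np.allclose(self.p, self.p.T, atol=1e-14):
            raise ValueError("symmetric GLCM must equal its transpose")


@dataclass(frozen=True)
class TextureFeatures:
    con: float
    cor: float  # NaN when the marginal variance vanishes
    ene: float
    hom: float


class FeatureVector(dict):
    """Exactly the 40 named radiomic features; NaN marks a missing value."""

    def __init__(self, values: dict[str, float]):
        if set(values) != set(FEATURE_NAMES):
            missing = set(FEATURE_NAMES) - set(values)
            extra = set(values) - set(FEATURE_NAMES)
            raise ValueError(f"feature vector mismatch: missing {sorted(missing)}, extra {sorted(extra)}")
        super().__init__({k: float(values[k]) for k in FEATURE_NAMES})

    def as_array(self, names: list[str] | None = None) -> np.ndarray:
        return np.array([self[k] for k in (names or FEATURE_NAMES)])


# displacement (drow, dcol) per direction, for distance 1
_DIRECTION_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


@dataclass
class ExtractionConfig:
    """Geometry and estimator settings for map building and texture."""

    window_mm: float = 2.0
    overlap_frac: float = 0.94
    fft_pad: int = 4
    Ng: int = 16
    distances: tuple[int, ...] = (1, 2, 3, 4)
    directions: tuple[int, ...] = (0, 45, 90, 135)
    ar_order: int = 10
    sas_prominence: float = 3.0
    asd_grid_um: tuple[float, float, float] = (1.0, 150.0, 0.1)  # lo, hi, step
    band: sp.AnalysisBand | None = None  # override the reference-derived band

    def __post_init__(self) -> None:
        if not (0 <= self.overlap_frac < 1):
            raise ValueError("overlap_frac must lie in [0, 1)")
        if self.Ng < 2:
            raise ValueError("Ng must be >= 2")
        if any(d not in _DIRECTION_OFFSETS for d in self.directions):
            raise ValueError("directions must be among 0, 45, 90, 135")

    @property
    def step_mm(self) -> float:
        return self.window_mm * (1.0 - self.overlap_frac)

    @property
    def a_grid(self) -> np.ndarray:
        lo, hi, step = self.asd_grid_um
        return np.arange(lo, hi + step / 2, step)


# ---------------------------------------------------------------------------
# Map building


def _reference_spectrum_at(
    reference: ReferenceData,
    axial_start: int,
    axial_len: int,
    line_starts: np.ndarray,
    n_lines: int,
    fft_pad: int,
) -> sp.PowerSpectrum:
    """Depth-matched phantom spectrum: mean periodogram over frames and
    lateral positions at one axial gate."""
    powers = []
    spec = None
    for frame in reference.phantom_frames:
        for ls in line_starts:
            spec = sp.window_spectrum(frame, axial_start, axial_len, int(ls), n_lines, fft_pad)
            powers.append(spec.power)
    return sp.PowerSpectrum(
        freqs=spec.freqs,
        power=np.mean(powers, axis=0),
        center_depth=spec.center_depth,
        center_lateral=0.0,
        n_lines_averaged=n_lines * len(powers),
    )


def build_parametric_maps(
    frame: RFFrame,
    roi: ROIMask,
    reference: ReferenceData,
    config: ExtractionConfig | None = None,
) -> list[ParametricMap]:
    """Run the full window-level estimation chain over the ROI.

    Returns the eight maps (MBF, SS, SI, SAS, ASD/AAC for both form-factor
    models) on the window-step lattice; lattice pixels whose window center
    falls outside the ROI are NaN, as are windows with undefined SAS.
    """
    config = config or ExtractionConfig()
    roi.validate_against(frame)
    reference.validate_against(frame)

    ax_len = max(sp.MIN_GATE_SAMPLES, round(config.window_mm * 1e3 / frame.axial_pixel_um))
    n_lines = max(sp.MIN_GATE_LINES, round(config.window_mm / frame.lateral_pitch))
    ax_step = max(1, round(config.step_mm * 1e3 / frame.axial_pixel_um))
    ln_step = max(1, round(config.step_mm / frame.lateral_pitch))

    ax_starts = np.arange(0, frame.n_axial - ax_len + 1, ax_step)
    ln_starts = np.arange(0, frame.n_lines - n_lines + 1, ln_step)
    if ax_starts.size == 0 or ln_starts.size == 0:
        raise EmptyROIError("frame smaller than a single analysis window")

    centers_ax = ax_starts + ax_len // 2
    centers_ln = ln_starts + n_lines // 2
    in_roi = roi.mask[np.ix_(centers_ax, centers_ln)]
    if not in_roi.any():
        raise EmptyROIError("ROI contains no window centers")

    # reference spectra per axial gate (lateral positions average out speckle)
    ref_lines = ln_starts[:: max(1, len(ln_starts) // 16)]
    ref_specs = {
        int(a): _reference_spectrum_at(reference, int(a), ax_len, ref_lines, n_lines, config.fft_pad)
        for a in ax_starts[in_roi.any(axis=1)]
    }

    band = config.band
    if band is None:
        mean_ref = sp.PowerSpectrum(
            freqs=next(iter(ref_specs.values())).freqs,
            power=np.mean([s.power for s in ref_specs.values()], axis=0),
        )
        band = sp.detect_band(mean_ref)

    # subject attenuation from laterally-averaged normalized spectra vs depth
    norm_by_depth = []
    for ai, a in enumerate(ax_starts):
        cols = np.where(in_roi[ai])[0]
        if cols.size == 0:
            continue
        powers = [
            sp.window_spectrum(frame, int(a), ax_len, int(ln_starts[c]), n_lines, config.fft_pad)
            for c in cols
        ]
        mean_spec = sp.PowerSpectrum(
            freqs=powers[0].freqs,
            power=np.mean([p.power for p in powers], axis=0),
            center_depth=powers[0].center_depth,
            n_lines_averaged=n_lines * len(powers),
        )
        norm_by_depth.append(sp.normalize_spectrum(mean_spec, ref_specs[int(a)], band))
    depths = [s.center_depth for s in norm_by_depth]
    if len(norm_by_depth) >= 3 and max(depths) - min(depths) >= 0.5:
        atten = sp.estimate_attenuation(norm_by_depth, band, alpha_ref=reference.alpha_ref)
        alpha_sample = atten.alpha
    else:
        warnings.warn("ROI too shallow for attenuation estimation; using reference alpha")
        alpha_sample = reference.alpha_ref

    shape = (len(ax_starts), len(ln_starts))
    maps = {name: np.full(shape, np.nan) for name in MAP_NAMES}
    for ai, a in enumerate(ax_starts):
        for li in np.where(in_roi[ai])[0]:
            ls = int(ln_starts[li])
            spec = sp.window_spectrum(frame, int(a), ax_len, ls, n_lines, config.fft_pad)
            norm = sp.normalize_spectrum(spec, ref_specs[int(a)], band)
            corr = sp.attenuation_correct(
                norm, alpha_sample, reference.alpha_ref, norm.center_depth
            )
            fit = sp.fit_spectral_line(corr, band)
            maps["MBF"][ai, li] = fit.MBF
            maps["SS"][ai, li] = fit.SS
            maps["SI"][ai, li] = fit.SI
            bsc = sc.compute_bsc(corr, reference.bsc_ref, band)
            for model, key_asd, key_aac in (
                ("gaussian", "ASD_gau", "AAC_gau"),
                ("anderson", "ASD_and", "AAC_and"),
            ):
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    est = sc.fit_form_factor(bsc, model, frame.c, config.a_grid)
                maps[key_asd][ai, li] = est.ASD
                maps[key_aac][ai, li] = est.AAC
            gate = frame.samples[a : a + ax_len, ls : ls + n_lines]
            sas = sc.estimate_sas(
                gate,
                reference.planar_spectrum,
                frame.fs,
                frame.c,
                band,
                ar_order=config.ar_order,
                prominence_factor=config.sas_prominence,
            )
            if sas.defined:
                maps["SAS"][ai, li] = sas.SAS

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # all-NaN SAS maps are legitimate
        return [
            ParametricMap(maps[name], name, MAP_UNITS[name], config.step_mm)
            for name in MAP_NAMES
        ]


# ---------------------------------------------------------------------------
# Quantization and GLCM


def quantize_map(pmap: ParametricMap | np.ndarray, Ng: int = 16) -> tuple[np.ndarray, bool]:
    """Uniform min-max quantization of the finite pixels into 0..Ng-1.

    Returns (levels, degenerate): ``levels`` is float with NaN preserved and
    integer gray tones elsewhere (the maximum maps to Ng-1); ``degenerate``
    is set when the map is constant, in which case texture features for the
    map are reported missing.
    """
    values = pmap.values if isinstance(pmap, ParametricMap) else np.asarray(pmap, dtype=float)
    finite = np.isfinite(values)
    out = np.full(values.shape, np.nan)
    vals = values[finite]
    if vals.size == 0 or vals.max() == vals.min():
        return out, True
    levels = np.floor((vals - vals.min()) / (vals.max() - vals.min()) * Ng)
    out[finite] = np.clip(levels, 0, Ng - 1)
    return out, False


def compute_glcm(
    quantized: np.ndarray,
    distance: int,
    direction: int,
    Ng: int = 16,
    symmetric: bool = True,
) -> GLCM | None:
    """Co-occurrence probabilities at one (distance, direction) displacement.

    NaN pixels are excluded pairwise; returns None when the displacement
    yields no valid pixel pair (the empty-GLCM flag).
    """
    if direction not in _DIRECTION_OFFSETS:
        raise ValueError("direction must be one of 0, 45, 90, 135")
    if distance < 1:
        raise ValueError("distance must be >= 1")
    q = np.asarray(quantized, dtype=float)
    dr, dc = (distance * o for o in _DIRECTION_OFFSETS[direction])
    rows, cols = q.shape
    r0 = max(0, -dr)
    r1 = min(rows, rows - dr)
    c0 = max(0, -dc)
    c1 = min(cols, cols - dc)
    if r0 >= r1 or c0 >= c1:
        return None
    a = q[r0:r1, c0:c1]
    b = q[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
    valid = np.isfinite(a) & np.isfinite(b)
    if not valid.any():
        return None
    ia = a[valid].astype(int)
    ib = b[valid].astype(int)
    counts = np.bincount(ia * Ng + ib, minlength=Ng * Ng).reshape(Ng, Ng).astype(float)
    if symmetric:
        counts = counts + counts.T
    return GLCM(counts / counts.sum(), distance=distance, direction=direction, symmetric=symmetric)


def glcm_features(glcm: GLCM) -> TextureFeatures:
    """Contrast, correlation, energy and homogeneity of one GLCM.

    Correlation is NaN (missing) when a marginal standard deviation
    vanishes (e.g. a single-cell GLCM); the other three are always defined.
    """
    p = glcm.p
    n = p.shape[0]
    i = np.arange(n)
    diff2 = (i[:, None] - i[None, :]) ** 2
    con = float(np.sum(diff2 * p))
    ene = float(np.sum(p**2))
    hom = float(np.sum(p / (1.0 + diff2)))
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = float(np.sum(i * px))
    mu_y = float(np.sum(i * py))
    sig_x = float(np.sqrt(np.sum((i - mu_x) ** 2 * px)))
    sig_y = float(np.sqrt(np.sum((i - mu_y) ** 2 * py)))
    if sig_x * sig_y == 0:
        cor = float("nan")
    else:
        cor = float((np.sum(np.outer(i, i) * p) - mu_x * mu_y) / (sig_x * sig_y))
    return TextureFeatures(con=con, cor=cor, ene=ene, hom=hom)


def aggregate_subject_features(
    maps: list[ParametricMap],
    config: ExtractionConfig | None = None,
) -> FeatureVector:
    """Subject-level feature vector: map means plus averaged GLCM textures.

    Per map: the mean of the finite pixels, and each texture feature averaged
    over the (distance x direction) GLCM set, skipping empty GLCMs and
    undefined correlations; maps that are constant, all-NaN, or yield no
    valid GLCM report their textures as missing (NaN).
    """
    config = config or ExtractionConfig()
    if {m.name for m in maps} != set(MAP_NAMES):
        raise ValueError("expected exactly the eight standard maps")
    values: dict[str, float] = {}
    for pmap in maps:
        values[pmap.name] = pmap.finite_mean
        levels, degenerate = quantize_map(pmap, config.Ng)
        glcms = []
        if not degenerate:
            for d in config.distances:
                for theta in config.directions:
                    g = compute_glcm(levels, d, theta, Ng=config.Ng)
                    if g is not None:
                        glcms.append(glcm_features(g))
        for tex in TEXTURE_NAMES:
            vals = [getattr(g, tex) for g in glcms]
            vals = [v for v in vals if np.isfinite(v)]
            values[f"{pmap.name}-{tex}"] = float(np.mean(vals)) if vals else float("nan")
    return FeatureVector(values)
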