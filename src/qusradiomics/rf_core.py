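"""Containers and I/O for raw RF ultrasound frames, ROI masks and reference-phantom data.

An :class:`RFFrame` holds the digitized backscatter voltage of one 2-D imaging
plane (axial sample x scan line) together with the acquisition geometry needed
to convert sample indices to physical depth.  An :class:`ROIMask` delineates
the lymph node on that grid, and :class:`ReferenceData` bundles the
tissue-mimicking phantom acquisitions (known attenuation and backscatter
coefficient) plus the planar-reflector spectrum used for scatterer-spacing
normalization.

Frames are treated as independent 2-D planes; volumetric sweeps are processed
plane by plane upstream of this module.

On-disk layout (HDF5): ``/rf/samples`` (2-D float), ``/rf/meta`` attributes
``fs_mhz, f_center_mhz, c_mps, lateral_pitch_mm, start_depth_cm``,
``/roi/mask`` (2-D uint8); reference files add ``/ref/frames/<i>`` groups in
the same layout, ``/ref/alpha_db_cm_mhz``, ``/ref/bsc`` (columns
frequency_mhz, bsc_sr_cm) and ``/ref/planar_spectrum`` (columns
frequency_mhz, power).  ROI masks may alternatively be a binary PNG raster of
identical dimensions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np
from scipy import ndimage

__all__ = [
    "RFFrame",
    "ROIMask",
    "ReferenceData",
    "GeometryError",
    "FormatError",
    "EmptyROIError",
    "depth_of_sample",
    "load_rf_frame",
    "save_rf_frame",
    "load_roi_mask",
    "save_roi_mask",
    "load_reference",
    "save_reference",
]

#: Soft-tissue standard speed of sound, m/s.
DEFAULT_C = 1540.0
#: mm per scan line for a 3.8 cm field of view over 256 lines.
DEFAULT_LATERAL_PITCH = 38.0 / 256


class GeometryError(ValueError):
    """Acquisition geometry is inconsistent (Nyquist violation, shape mismatch...)."""


class FormatError(ValueError):
    """A container file is missing required datasets or malformed."""


class EmptyROIError(ValueError):
    """An ROI mask selects no pixels."""


@dataclass
class RFFrame:
    """One plane of raw RF backscatter data with its acquisition geometry.

    Parameters
    ----------
    samples
        2-D array, shape (axial samples, scan lines), arbitrary voltage units.
    fs
        Sampling rate, MHz.
    f_center
        Nominal transducer center frequency, MHz.
    c
        Assumed speed of sound, m/s.
    lateral_pitch
        Lateral spacing between scan lines, mm.
    start_depth
        Depth of the first axial sample, cm.
    """

    samples: np.ndarray
    fs: float = 40.0
    f_center: float = 8.0
    c: float = DEFAULT_C
    lateral_pitch: float = DEFAULT_LATERAL_PITCH
    start_depth: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.size == 0:
            raise FormatError("samples must be a non-empty 2-D array")
        if not self.fs > 2.0 * self.f_center:
            raise GeometryError(
                f"sampling rate {self.fs} MHz does not satisfy Nyquist for "
                f"center frequency {self.f_center} MHz"
            )
        if self.lateral_pitch <= 0:
            raise GeometryError("lateral_pitch must be positive")
        if self.c <= 0:
            raise GeometryError("speed of sound must be positive")

    @property
    def n_axial(self) -> int:
        return self.samples.shape[0]

    @property
    def n_lines(self) -> int:
        return self.samples.shape[1]

    @property
    def axial_pixel_um(self) -> float:
        """Axial sample spacing c / (2 fs), micrometres."""
        return self.c / (2.0 * self.fs)

    @property
    def axial_pixel_cm(self) -> float:
        return self.axial_pixel_um * 1e-4

    def geometry_like(self, samples: np.ndarray) -> "RFFrame":
        """New frame with the same geometry but different samples."""
        return RFFrame(
            samples,
            fs=self.fs,
            f_center=self.f_center,
            c=self.c,
            lateral_pitch=self.lateral_pitch,
            start_depth=self.start_depth,
        )


def depth_of_sample(frame: RFFrame, axial_index: int) -> float:
    """Depth of an axial sample in cm.

    The depth refers to the sample itself (0-based index); gate-center depths
    for sliding windows are computed downstream from these.
    """
    idx = int(axial_index)
    if idx < 0 or idx >= frame.n_axial:
        raise IndexError(f"axial index {idx} outside [0, {frame.n_axial})")
    return frame.start_depth + idx * frame.axial_pixel_cm


@dataclass
class ROIMask:
    """Boolean region-of-interest congruent with an :class:`RFFrame`."""

    mask: np.ndarray
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise FormatError("ROI mask must be 2-D")
        if not self.mask.any():
            raise EmptyROIError("ROI mask selects no pixels")
        n_components = ndimage.label(self.mask)[1]
        if n_components > 1:
            warnings.warn(
                f"ROI mask for {self.subject_id or 'subject'} has "
                f"{n_components} connected components",
                stacklevel=2,
            )

    def validate_against(self, frame: RFFrame) -> None:
        if self.mask.shape != frame.samples.shape:
            raise GeometryError(
                f"ROI shape {self.mask.shape} != frame shape {frame.samples.shape}"
            )


@dataclass
class ReferenceData:
    """Reference-phantom acquisitions with known acoustic properties.

    ``bsc_ref`` and ``planar_spectrum`` are 2-column arrays
    (frequency_mhz, value).  ``alpha_ref`` is the phantom attenuation in
    dB cm^-1 MHz^-1.  The planar-reflector spectrum is used only for the
    scatterer-spacing (SAS) normalization.
    """

    phantom_frames: list[RFFrame]
    alpha_ref: float
    bsc_ref: np.ndarray
    planar_spectrum: np.ndarray
    mean_diameter_um: float | None = None

    def __post_init__(self) -> None:
        if not self.phantom_frames:
            raise FormatError("reference requires at least one phantom frame")
        if self.alpha_ref < 0:
            raise GeometryError("reference attenuation must be >= 0")
        self.bsc_ref = np.atleast_2d(np.asarray(self.bsc_ref, dtype=float))
        self.planar_spectrum = np.atleast_2d(
            np.asarray(self.planar_spectrum, dtype=float)
        )
        if self.bsc_ref.shape[1] != 2 or self.planar_spectrum.shape[1] != 2:
            raise FormatError("bsc_ref and planar_spectrum must be 2-column tables")
        if np.any(self.bsc_ref[:, 1] <= 0):
            raise FormatError("reference backscatter coefficient must be positive")

    def validate_against(self, frame: RFFrame) -> None:
        ref = self.phantom_frames[0]
        if ref.samples.shape != frame.samples.shape or ref.fs != frame.fs:
            raise GeometryError("phantom geometry does not match sample geometry")


# ---------------------------------------------------------------------------
# HDF5 I/O

_META_KEYS = {
    "fs_mhz": "fs",
    "f_center_mhz": "f_center",
    "c_mps": "c",
    "lateral_pitch_mm": "lateral_pitch",
    "start_depth_cm": "start_depth",
}

_META_DEFAULTS = {
    "fs": 40.0,
    "f_center": 8.0,
    "c": DEFAULT_C,
    "lateral_pitch": DEFAULT_LATERAL_PITCH,
    "start_depth": 0.0,
}


def _write_frame(group: h5py.Group, frame: RFFrame) -> None:
    group.create_dataset("samples", data=frame.samples)
    meta = group.create_group("meta")
    for key, attr in _META_KEYS.items():
        meta.attrs[key] = getattr(frame, attr)


def _read_frame(group: h5py.Group) -> RFFrame:
    if "samples" not in group:
        raise FormatError(f"missing samples dataset under {group.name}")
    samples = np.asarray(group["samples"])
    kwargs = {}
    meta = group.get("meta")
    for key, attr in _META_KEYS.items():
        if meta is not None and key in meta.attrs:
            kwargs[attr] = float(meta.attrs[key])
        else:
            kwargs[attr] = _META_DEFAULTS[attr]
            warnings.warn(
                f"metadata key {key} missing; using default {kwargs[attr]}",
                stacklevel=3,
            )
    return RFFrame(samples, **kwargs)


def save_rf_frame(path: str | Path, frame: RFFrame, roi: ROIMask | None = None) -> None:
    with h5py.File(path, "w") as fh:
        _write_frame(fh.create_group("rf"), frame)
        if roi is not None:
            grp = fh.create_group("roi")
            grp.create_dataset("mask", data=roi.mask.astype(np.uint8))
            grp.attrs["subject_id"] = roi.subject_id


def load_rf_frame(path: str | Path) -> RFFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with h5py.File(path, "r") as fh:
        if "rf" not in fh:
            raise FormatError(f"{path} has no /rf group")
        return _read_frame(fh["rf"])


def save_roi_mask(path: str | Path, roi: ROIMask) -> None:
    path = Path(path)
    if path.suffix.lower() == ".png":
        from PIL import Image

        Image.fromarray((roi.mask * 255).astype(np.uint8)).save(path)
    else:
        with h5py.File(path, "a") as fh:
            if "roi" in fh:
                del fh["roi"]
            grp = fh.create_group("roi")
            grp.create_dataset("mask", data=roi.mask.astype(np.uint8))
            grp.attrs["subject_id"] = roi.subject_id


def load_roi_mask(path: str | Path, frame: RFFrame, subject_id: str = "") -> ROIMask:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".png":
        from PIL import Image

        raw = np.asarray(Image.open(path))
        if raw.ndim == 3:  # collapse any color channels
            raw = raw[..., 0]
        mask = raw > 0
    else:
        with h5py.File(path, "r") as fh:
            if "roi" not in fh or "mask" not in fh["roi"]:
                raise FormatError(f"{path} has no /roi/mask dataset")
            mask = np.asarray(fh["roi"]["mask"]) > 0
            subject_id = subject_id or str(fh["roi"].attrs.get("subject_id", ""))
    roi = ROIMask(mask, subject_id=subject_id)
    roi.validate_against(frame)
    return roi


def save_reference(path: str | Path, ref: ReferenceData) -> None:
    with h5py.File(path, "w") as fh:
        grp = fh.create_group("ref")
        frames = grp.create_group("frames")
        for i, frame in enumerate(ref.phantom_frames):
            _write_frame(frames.create_group(f"{i:04d}"), frame)
        grp.create_dataset("alpha_db_cm_mhz", data=float(ref.alpha_ref))
        grp.create_dataset("bsc", data=ref.bsc_ref)
        grp.create_dataset("planar_spectrum", data=ref.planar_spectrum)
        if ref.mean_diameter_um is not None:
            grp.attrs["mean_diameter_um"] = ref.mean_diameter_um


def load_reference(path: str | Path) -> ReferenceData:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with h5py.File(path, "r") as fh:
        if "ref" not in fh:
            raise FormatError(f"{path} has no /ref group")
        grp = fh["ref"]
        frames = [
            _read_frame(grp["frames"][name]) for name in sorted(grp["frames"])
        ]
        mean_d = grp.attrs.get("mean_diameter_um")
        return ReferenceData(
            phantom_frames=frames,
            alpha_ref=float(np.asarray(grp["alpha_db_cm_mhz"])),
            bsc_ref=np.asarray(grp["bsc"]),
            planar_spectrum=np.asarray(grp["planar_spectrum"]),
            mean_diameter_um=None if mean_d is None else float(mean_d),
        )
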