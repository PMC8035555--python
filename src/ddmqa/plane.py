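"""Dose-plane data model, I/O, and resampling.

A :class:`DosePlane` is a 2D grid of absolute dose in cGy(RBE) with explicit
physical geometry: pixel pitch in mm and the physical coordinate of the
center of pixel (0, 0), expressed in an isocenter-centered frame.  All
comparisons in this package operate on pairs of planes in that common frame.

Two on-disk formats are supported: an open plain-text ``grid-csv`` dialect
(three header lines -- ``spacing_mm``, ``origin_mm``, ``label`` -- followed by
comma-separated dose rows) and single-frame DICOM RT Dose, whose stored
integers are scaled by the file's dose-grid scaling factor on read.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import RegularGridInterpolator

__all__ = [
    "DosePlane",
    "Criteria",
    "FormatError",
    "GeometryError",
    "read_dose_plane",
    "write_dose_plane",
    "resample_to_search_grid",
    "resample_for_comparison",
    "global_max",
]


class FormatError(ValueError):
    """Raised when an input file cannot be parsed as the named dialect."""


class GeometryError(ValueError):
    """Raised when a dose file lacks the geometry needed to place pixels."""


@dataclass
class DosePlane:
    """A 2D dose grid with physical geometry.

    Parameters
    ----------
    values : ndarray, shape (nrows, ncols)
        Dose in cGy(RBE); finite and non-negative.
    spacing : (float, float)
        Pixel pitch (row, col) in mm; strictly positive.
    origin : (float, float)
        Physical coordinate (row-axis, col-axis) in mm of the *center* of
        pixel (0, 0), in an isocenter-centered frame.  Pixel (i, j) sits at
        ``origin + (i * spacing[0], j * spacing[1])``.
    label : str
        Free text, e.g. ``measured`` / ``calculated`` / ``synthetic``.
    """

    values: np.ndarray
    spacing: tuple[float, float]
    origin: tuple[float, float] = (0.0, 0.0)
    label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.size == 0:
            raise GeometryError("dose plane must be a non-empty 2D array")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("dose values must be finite")
        if np.any(self.values < 0):
            raise ValueError("dose values must be non-negative")
        self.spacing = (float(self.spacing[0]), float(self.spacing[1]))
        if self.spacing[0] <= 0 or self.spacing[1] <= 0:
            raise GeometryError("pixel spacing must be strictly positive")
        self.origin = (float(self.origin[0]), float(self.origin[1]))

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def axis_coords(self, axis: int) -> np.ndarray:
        """Physical coordinates (mm) of pixel centers along ``axis``."""
        n = self.values.shape[axis]
        return self.origin[axis] + self.spacing[axis] * np.arange(n)

    @property
    def extent(self) -> tuple[tuple[float, float], tuple[float, float]]:
        """((row_min, row_max), (col_min, col_max)) of pixel centers, mm."""
        r = self.axis_coords(0)
        c = self.axis_coords(1)
        return ((r[0], r[-1]), (c[0], c[-1]))

    def pixel_positions(self) -> tuple[np.ndarray, np.ndarray]:
        """Meshgrid of physical (row, col) coordinates of every pixel, mm."""
        return np.meshgrid(self.axis_coords(0), self.axis_coords(1), indexing="ij")

    def shifted(self, shift_mm: tuple[float, float]) -> "DosePlane":
        """A copy whose content is translated by ``shift_mm`` (row, col)."""
        return replace(
            self,
            values=self.values.copy(),
            origin=(self.origin[0] + float(shift_mm[0]), self.origin[1] + float(shift_mm[1])),
        )

    def interpolator(self, fill_value: float = 0.0) -> RegularGridInterpolator:
        """Bilinear interpolator in physical coordinates; outside -> fill."""
        return RegularGridInterpolator(
            (self.axis_coords(0), self.axis_coords(1)),
            self.values,
            method="linear",
            bounds_error=False,
            fill_value=fill_value,
        )


@dataclass
class Criteria:
    """Comparison tolerances for gamma and DDM scoring.

    dose_pct
        Dose tolerance (the gamma ``dose difference`` criterion and the DDM
        pass tolerance), % of the normalization dose.
    distance_mm
        Gamma distance-to-agreement criterion, mm.
    search_radius_mm
        DDM fixed search radius r, mm (set from machine spot accuracy).
    low_dose_cutoff_pct
        Measured pixels at or below this % of the normalization dose are
        excluded from scoring.
    normalization
        ``global``: dose differences as % of the plane maximum.
        ``local``: as % of the dose at the measured point.
    max_dose_from
        Which plane supplies the global maximum: ``calculated`` (default;
        noise-free) or ``measured``.
    """

    dose_pct: float = 3.0
    distance_mm: float = 2.0
    search_radius_mm: float = 1.0
    low_dose_cutoff_pct: float = 10.0
    normalization: str = "global"
    max_dose_from: str = "calculated"

    def __post_init__(self) -> None:
        for name in ("dose_pct", "distance_mm", "search_radius_mm", "low_dose_cutoff_pct"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not self.low_dose_cutoff_pct < 100:
            raise ValueError("low_dose_cutoff_pct must be in (0, 100)")
        if self.normalization not in ("global", "local"):
            raise ValueError("normalization must be 'global' or 'local'")
        if self.max_dose_from not in ("calculated", "measured"):
            raise ValueError("max_dose_from must be 'calculated' or 'measured'")


# ---------------------------------------------------------------------------
# I/O


def _read_grid_csv(path: str) -> DosePlane:
    with open(path, "r", encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    header: dict[str, list[str]] = {}
    for ln in lines[:3]:
        parts = ln.split(",")
        header[parts[0].strip()] = [p.strip() for p in parts[1:]]
    for key in ("spacing_mm", "origin_mm"):
        if key not in header:
            raise GeometryError(f"grid-csv header missing '{key}' in {path}")
    if "label" not in header:
        raise FormatError(f"grid-csv header missing 'label' in {path}")
    try:
        spacing = (float(header["spacing_mm"][0]), float(header["spacing_mm"][1]))
        origin = (float(header["origin_mm"][0]), float(header["origin_mm"][1]))
    except (IndexError, ValueError) as exc:
        raise GeometryError(f"malformed geometry header in {path}: {exc}") from exc
    label = header["label"][0] if header["label"] else ""
    try:
        values = np.array(
            [[float(v) for v in ln.split(",")] for ln in lines[3:] if ln.strip() != ""]
        )
    except ValueError as exc:
        raise FormatError(f"malformed dose rows in {path}: {exc}") from exc
    if values.ndim != 2:
        raise FormatError(f"ragged or empty dose rows in {path}")
    return DosePlane(values=values, spacing=spacing, origin=origin, label=label)


def _read_dicom_rt_dose(path: str) -> DosePlane:
    import pydicom

    try:
        ds = pydicom.dcmread(path)
    except Exception as exc:  # pydicom raises several error types
        raise FormatError(f"cannot read DICOM file {path}: {exc}") from exc
    try:
        raw = ds.pixel_array
    except Exception as exc:
        raise FormatError(f"DICOM file {path} has no pixel data: {exc}") from exc
    if raw.ndim == 3:
        if raw.shape[0] != 1:
            raise FormatError("multi-frame RT Dose volumes are not supported")
        raw = raw[0]
    scaling = getattr(ds, "DoseGridScaling", None)
    if scaling is None:
        raise GeometryError(f"DICOM file {path} lacks DoseGridScaling")
    spacing_attr = getattr(ds, "PixelSpacing", None)
    position = getattr(ds, "ImagePositionPatient", None)
    if spacing_attr is None or position is None:
        raise GeometryError(f"DICOM file {path} lacks pixel spacing or image position")
    # PixelSpacing is (row pitch, col pitch); ImagePositionPatient (x, y, z)
    # gives the first pixel center as (col, row) in mm.
    spacing = (float(spacing_attr[0]), float(spacing_attr[1]))
    origin = (float(position[1]), float(position[0]))
    values = np.asarray(raw, dtype=float) * float(scaling)
    return DosePlane(values=values, spacing=spacing, origin=origin, label="calculated")


def read_dose_plane(path: str, format_id: str = "grid-csv") -> DosePlane:
    """Read a dose plane from ``path`` in the named dialect.

    ``format_id`` is ``grid-csv`` or ``dicom-rt-dose``.  DICOM stored values
    are multiplied by the file's dose-grid scaling; geometry must be present
    in either format (no silent defaults).
    """
    if not os.path.exists(path):
        raise FormatError(f"no such file: {path}")
    if format_id == "grid-csv":
        return _read_grid_csv(path)
    if format_id == "dicom-rt-dose":
        return _read_dicom_rt_dose(path)
    raise FormatError(f"unknown format_id: {format_id!r}")


def write_dose_plane(plane: DosePlane, path: str) -> None:
    """Write ``plane`` as grid-csv; round-trips exactly via read_dose_plane."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"spacing_mm,{plane.spacing[0]!r},{plane.spacing[1]!r}\n")
        fh.write(f"origin_mm,{plane.origin[0]!r},{plane.origin[1]!r}\n")
        fh.write(f"label,{plane.label}\n")
        for row in plane.values:
            fh.write(",".join(repr(float(v)) for v in row) + "\n")


# ---------------------------------------------------------------------------
# Resampling


def resample_to_search_grid(plane: DosePlane, target_spacing_mm: float) -> DosePlane:
    """Bilinearly resample onto a finer grid covering the same physical extent.

    Intended for the *calculated* plane only: measured pixels are never
    interpolated anywhere in this package.  The output grid spans exactly the
    input bounding box; the realized spacing is the largest value <= target
    that divides each axis extent evenly, so the bounding box is preserved.
    """
    if target_spacing_mm <= 0:
        raise ValueError("target spacing must be strictly positive")
    if target_spacing_mm > min(plane.spacing) + 1e-12:
        raise ValueError("target spacing must not exceed the plane's spacing")
    interp = plane.interpolator()
    coords = []
    spacing_out = []
    for axis in (0, 1):
        lo, hi = plane.extent[axis]
        span = hi - lo
        if span == 0:
            coords.append(np.array([lo]))
            spacing_out.append(plane.spacing[axis])
            continue
        n = int(np.ceil(span / target_spacing_mm - 1e-9)) + 1
        coords.append(np.linspace(lo, hi, n))
        spacing_out.append(span / (n - 1))
    rr, cc = np.meshgrid(coords[0], coords[1], indexing="ij")
    values = interp(np.stack([rr.ravel(), cc.ravel()], axis=1)).reshape(rr.shape)
    return DosePlane(
        values=np.clip(values, 0.0, None),
        spacing=(spacing_out[0], spacing_out[1]),
        origin=(coords[0][0], coords[1][0]),
        label=plane.label,
    )


def resample_for_comparison(
    calculated: DosePlane, measured: DosePlane, target_spacing_mm: float = 0.1
) -> DosePlane:
    """Resample the calculated plane onto the fine search grid used by gamma/DDM.

    The grid is anchored on the measured pixel lattice: its spacing divides
    the measured pitch evenly and its nodes include every measured pixel
    center that falls inside the calculated extent.  This guarantees a test
    point at zero distance from each measured pixel, so an in-place dose
    comparison is always among the candidates.  The grid never extends
    beyond the calculated plane's bounding box.
    """
    if target_spacing_mm <= 0:
        raise ValueError("target spacing must be strictly positive")
    interp = calculated.interpolator()
    coords = []
    spacing_out = []
    for axis in (0, 1):
        k = max(1, int(np.ceil(measured.spacing[axis] / target_spacing_mm - 1e-9)))
        s = measured.spacing[axis] / k
        lo, hi = calculated.extent[axis]
        anchor = measured.origin[axis]
        n_min = int(np.ceil((lo - anchor) / s - 1e-9))
        n_max = int(np.floor((hi - anchor) / s + 1e-9))
        if n_max < n_min:
            raise ValueError("measured and calculated planes do not overlap")
        coords.append(anchor + s * np.arange(n_min, n_max + 1))
        spacing_out.append(s)
    rr, cc = np.meshgrid(coords[0], coords[1], indexing="ij")
    values = interp(np.stack([rr.ravel(), cc.ravel()], axis=1)).reshape(rr.shape)
    return DosePlane(
        values=np.clip(values, 0.0, None),
        spacing=(spacing_out[0], spacing_out[1]),
        origin=(coords[0][0], coords[1][0]),
        label=calculated.label,
    )


def global_max(plane: DosePlane) -> float:
    """Global maximum dose of the plane, cGy(RBE)."""
    return float(np.max(plane.values))
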