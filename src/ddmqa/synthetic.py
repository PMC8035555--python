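"""Synthetic dose planes, delivery errors, and spot-deviation samples.

Emulates the study conditions of a scanned-proton planar QA measurement:

* a *calculated* plane rendered from a field of Gaussian pencil-beam spots
  on a fine treatment-planning grid (default 1 mm);
* a *measured* plane obtained by injecting a controlled delivery error into
  the truth dose and point-sampling it at ion-chamber-array pitch
  (default 7.62 mm), so the detector never interpolates;
* per-spot radial deviations from isocenter drawn from a folded normal
  whose population mean/SD are moment-matched to targets.

Everything is deterministic at a fixed seed.  The detector model is point
sampling (no chamber volume averaging) and the depth dimension is ignored:
planes represent a single measurement depth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import optimize, stats

from .beamlets import BeamletDeviationSet
from .plane import DosePlane

__all__ = [
    "SpotField",
    "ErrorSpec",
    "grid_spot_field",
    "render_plane",
    "apply_error",
    "downsample_to_detector",
    "sample_radial_deviations",
    "uniform_plane",
    "dome_plane",
    "make_pair",
]


@dataclass
class SpotField:
    """Discrete spot-scanning field: Gaussian lateral profiles at depth.

    ``spots`` rows are (row_mm, col_mm, weight, sigma_mm): unit-peak
    Gaussians scaled by weight.  ``extent_mm`` is the rendered bounding box
    ((row_lo, row_hi), (col_lo, col_hi)).
    """

    spots: np.ndarray
    extent_mm: tuple[tuple[float, float], tuple[float, float]]

    def __post_init__(self) -> None:
        self.spots = np.atleast_2d(np.asarray(self.spots, dtype=float))
        if self.spots.size == 0:
            raise ValueError("spot field must contain at least one spot")
        if self.spots.shape[1] != 4:
            raise ValueError("spots must be (row_mm, col_mm, weight, sigma_mm)")
        if np.any(self.spots[:, 2] <= 0) or np.any(self.spots[:, 3] <= 0):
            raise ValueError("spot weights and sigmas must be strictly positive")


@dataclass
class ErrorSpec:
    """A controlled delivery/measurement error to inject.

    kind
        ``global_scale``: multiply all doses by (1 + magnitude/100).
        ``region_offset``: scale doses inside ``region`` by (1 + magnitude/100).
        ``spot_jitter``: re-render with per-spot positional displacements of
        SD ``jitter_mm`` (needs the originating SpotField).
        ``noise``: add zero-mean Gaussian noise of SD magnitude% of max.
    region
        ((row_lo, row_hi), (col_lo, col_hi)) in mm, for region_offset.
    """

    kind: str
    magnitude_pct: float = 0.0
    jitter_mm: float = 0.0
    region: tuple[tuple[float, float], tuple[float, float]] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("global_scale", "region_offset", "spot_jitter", "noise"):
            raise ValueError(f"unknown error kind: {self.kind!r}")
        if self.kind == "region_offset" and self.region is None:
            raise ValueError("region_offset requires a region")


def grid_spot_field(
    half_size_mm: float = 50.0,
    pitch_mm: float = 5.0,
    sigma_mm: float = 5.0,
    margin_mm: float = 15.0,
    weight_fn=None,
) -> SpotField:
    """Regular grid of identical-sigma spots over a square field.

    ``weight_fn(row_mm, col_mm) -> weight`` lets tests shape the fluence
    (e.g. a gentle dome); default is uniform unit weights.
    """
    coords = np.arange(-half_size_mm, half_size_mm + pitch_mm / 2, pitch_mm)
    rr, cc = np.meshgrid(coords, coords, indexing="ij")
    if weight_fn is None:
        w = np.ones(rr.size)
    else:
        w = np.asarray([weight_fn(r, c) for r, c in zip(rr.ravel(), cc.ravel())])
    spots = np.stack(
        [rr.ravel(), cc.ravel(), w, np.full(rr.size, sigma_mm)], axis=1
    )
    lo = -half_size_mm - margin_mm
    hi = half_size_mm + margin_mm
    return SpotField(spots=spots, extent_mm=((lo, hi), (lo, hi)))


def render_plane(
    field: SpotField, spacing_mm: float = 1.0, label: str = "calculated"
) -> DosePlane:
    """Sum of unit-peak Gaussians, dose(p) = sum_k w_k G(p; c_k, sigma_k).

    Deterministic; the grid covers ``field.extent_mm`` at ``spacing_mm``
    with pixel centers starting at the lower extent corner.
    """
    (rlo, rhi), (clo, chi) = field.extent_mm
    rows = np.arange(rlo, rhi + spacing_mm / 2, spacing_mm)
    cols = np.arange(clo, chi + spacing_mm / 2, spacing_mm)
    values = np.zeros((rows.size, cols.size))
    for r0, c0, w, sig in field.spots:
        gr = np.exp(-((rows - r0) ** 2) / (2 * sig**2))
        gc = np.exp(-((cols - c0) ** 2) / (2 * sig**2))
        values += w * np.outer(gr, gc)
    return DosePlane(values=values, spacing=(spacing_mm, spacing_mm),
                     origin=(rows[0], cols[0]), label=label)


def jitter_spots(field: SpotField, sd_mm: float, rng: np.random.Generator) -> SpotField:
    """Displace every spot position by independent N(0, sd) in each axis."""
    jittered = field.spots.copy()
    jittered[:, :2] += rng.normal(0.0, sd_mm, size=(len(jittered), 2))
    return SpotField(spots=jittered, extent_mm=field.extent_mm)


def apply_error(
    plane: DosePlane, spec: ErrorSpec, field: SpotField | None = None
) -> DosePlane:
    """Return a copy of ``plane`` with the specified error injected."""
    rng = np.random.default_rng(spec.seed)
    if spec.kind == "global_scale":
        values = plane.values * (1.0 + spec.magnitude_pct / 100.0)
    elif spec.kind == "region_offset":
        (rlo, rhi), (clo, chi) = spec.region
        (prlo, prhi), (pclo, pchi) = plane.extent
        if rlo < prlo - 1e-9 or rhi > prhi + 1e-9 or clo < pclo - 1e-9 or chi > pchi + 1e-9:
            raise ValueError("error region extends outside the plane")
        rr, cc = plane.pixel_positions()
        inside = (rr >= rlo) & (rr <= rhi) & (cc >= clo) & (cc <= chi)
        values = np.where(inside, plane.values * (1.0 + spec.magnitude_pct / 100.0),
                          plane.values)
    elif spec.kind == "spot_jitter":
        if field is None:
            raise ValueError("spot_jitter requires the originating SpotField")
        moved = jitter_spots(field, spec.jitter_mm, rng)
        out = render_plane(moved, spacing_mm=plane.spacing[0], label="synthetic")
        return DosePlane(values=out.values, spacing=plane.spacing,
                         origin=plane.origin, label="synthetic")
    elif spec.kind == "noise":
        sd = spec.magnitude_pct / 100.0 * float(plane.values.max())
        values = plane.values + rng.normal(0.0, sd, size=plane.values.shape)
        values = np.clip(values, 0.0, None)
    return DosePlane(values=values, spacing=plane.spacing, origin=plane.origin,
                     label="synthetic")


def downsample_to_detector(
    plane: DosePlane, pitch_mm: float = 7.62, label: str = "measured"
) -> DosePlane:
    """Point-sample the plane at ion-chamber pixel centers.

    The detector lattice has the given pitch, is centered on the plane's
    physical center (isocenter for symmetric fields), and only includes
    pixels inside the plane extent.  Values are the interpolated truth dose
    at each chamber center -- point sampling, no volume averaging.
    """
    if pitch_mm <= 0:
        raise ValueError("detector pitch must be strictly positive")
    if pitch_mm < min(plane.spacing):
        raise ValueError("detector pitch must not be finer than the plane grid")
    interp = plane.interpolator()
    coords = []
    for axis in (0, 1):
        lo, hi = plane.extent[axis]
        center = 0.5 * (lo + hi)
        n_half = int(np.floor((hi - center) / pitch_mm + 1e-9))
        coords.append(center + pitch_mm * np.arange(-n_half, n_half + 1))
    rr, cc = np.meshgrid(coords[0], coords[1], indexing="ij")
    values = interp(np.stack([rr.ravel(), cc.ravel()], axis=1)).reshape(rr.shape)
    return DosePlane(values=np.clip(values, 0.0, None),
                     spacing=(pitch_mm, pitch_mm),
                     origin=(coords[0][0], coords[1][0]), label=label)


# ---------------------------------------------------------------------------
# Spot-deviation sampling


def _folded_moments(mu: float, sigma: float) -> tuple[float, float]:
    a = mu / sigma
    mean = sigma * math.sqrt(2 / math.pi) * math.exp(-a * a / 2) + mu * (
        1 - 2 * stats.norm.cdf(-a)
    )
    var = mu * mu + sigma * sigma - mean * mean
    return mean, math.sqrt(max(var, 0.0))


def folded_normal_params(mean_mm: float, sd_mm: float) -> tuple[float, float]:
    """Underlying (mu, sigma) whose folded normal has the target moments.

    Solved numerically to 1e-6; raises for infeasible pairs (a folded
    normal cannot have sd/mean above sqrt(pi/2 - 1) ~ 0.7555).
    """
    if mean_mm <= 0 or sd_mm < 0:
        raise ValueError("mean must be positive and sd non-negative")
    if sd_mm / mean_mm > math.sqrt(math.pi / 2 - 1) - 1e-9:
        raise ValueError("infeasible moment pair for a folded normal")
    if sd_mm == 0:
        return mean_mm, 0.0

    def equations(p):
        mu, sigma = p
        m, s = _folded_moments(mu, abs(sigma))
        return (m - mean_mm, s - sd_mm)

    sol = optimize.root(equations, x0=(mean_mm, sd_mm), tol=1e-10)
    mu, sigma = float(sol.x[0]), abs(float(sol.x[1]))
    m, s = _folded_moments(mu, sigma)
    if abs(m - mean_mm) > 1e-6 or abs(s - sd_mm) > 1e-6:
        raise ValueError("folded-normal moment matching did not converge")
    return mu, sigma


def sample_radial_deviations(
    n: int, mean_target_mm: float = 0.38, sd_target_mm: float = 0.19, seed: int = 0
) -> BeamletDeviationSet:
    """Draw n non-negative radial deviations with the target population moments.

    Folded-normal construction |N(mu, sigma)| with (mu, sigma) moment-matched
    to the targets; uniform weights; deterministic at fixed seed.  Defaults
    are the clinical spot-accuracy figures (mean 0.38 mm, SD 0.19 mm).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    mu, sigma = folded_normal_params(mean_target_mm, sd_target_mm)
    rng = np.random.default_rng(seed)
    if sigma == 0:
        x = np.full(n, mu)
    else:
        x = np.abs(rng.normal(mu, sigma, size=n))
    return BeamletDeviationSet(radial_deviation_mm=x, weight=np.ones(n))


# ---------------------------------------------------------------------------
# Plane-pair presets


def uniform_plane(
    size_mm: float = 100.0,
    dose: float = 100.0,
    spacing_mm: float = 1.0,
    label: str = "calculated",
) -> DosePlane:
    """A homogeneous square dose plane centered on isocenter."""
    n = int(round(size_mm / spacing_mm)) + 1
    half = (n - 1) / 2 * spacing_mm
    return DosePlane(values=np.full((n, n), float(dose)),
                     spacing=(spacing_mm, spacing_mm),
                     origin=(-half, -half), label=label)


def dome_plane(
    half_size_mm: float = 70.0,
    dose: float = 100.0,
    edge_drop: float = 0.15,
    spacing_mm: float = 1.0,
    label: str = "calculated",
) -> DosePlane:
    """A gently domed square field, maximal at isocenter.

    ``dose(rho) = dose * (1 - edge_drop * rho^2 / rho_corner^2)`` where rho
    is the radial distance from isocenter and rho_corner the distance to a
    plane corner.  Models a center-weighted modulated field: a broad
    low-gradient dose maximum surrounded by progressively steeper fall-off,
    with every pixel well above the low-dose cutoff.
    """
    if not 0 < edge_drop < 1:
        raise ValueError("edge_drop must be in (0, 1)")
    n = int(round(2 * half_size_mm / spacing_mm)) + 1
    half = (n - 1) / 2 * spacing_mm
    coords = np.linspace(-half, half, n)
    rr, cc = np.meshgrid(coords, coords, indexing="ij")
    rho2 = rr**2 + cc**2
    values = dose * (1.0 - edge_drop * rho2 / (2 * half**2))
    return DosePlane(values=values, spacing=(spacing_mm, spacing_mm),
                     origin=(-half, -half), label=label)


def make_pair(
    preset: str = "region-error",
    magnitude_pct: float = 5.0,
    seed: int = 0,
    detector_pitch_mm: float = 7.62,
    calc_spacing_mm: float = 1.0,
    shift_mm: tuple[float, float] = (0.0, 0.0),
) -> tuple[DosePlane, DosePlane, dict]:
    """Build a (measured, calculated, manifest) triple with a known error.

    Presets
    -------
    identical
        Measured is the plain detector sampling of the calculated dose.
    region-error
        A 3x3 cm^2 central region of a 10x10 cm homogeneous field is scaled
        by (1 + magnitude/100) -- the classic inserted-deviation experiment.
    global-scale
        The whole delivery is scaled by (1 + magnitude/100) on a gently
        domed spot field (output-drift / underdose signature).
    noise
        Zero-mean measurement noise of SD magnitude% of max on a spot field.
    spot-jitter
        Spot positions displaced by N(0, magnitude) -- for this preset the
        ``magnitude_pct`` argument is read as the jitter SD in mm.

    ``shift_mm`` additionally translates the measured plane content, to
    exercise registration.
    """
    manifest = {
        "preset": preset,
        "magnitude_pct": magnitude_pct,
        "seed": seed,
        "detector_pitch_mm": detector_pitch_mm,
        "shift_mm": list(shift_mm),
    }
    if preset in ("identical", "region-error"):
        calc = uniform_plane(size_mm=100.0, dose=100.0, spacing_mm=calc_spacing_mm)
        measured = downsample_to_detector(calc, pitch_mm=detector_pitch_mm)
        if preset == "region-error":
            # Delivery error: detector pixels inside the region see the
            # scaled dose exactly (the region edge never straddles a pixel).
            spec = ErrorSpec(kind="region_offset", magnitude_pct=magnitude_pct,
                             region=((-15.0, 15.0), (-15.0, 15.0)), seed=seed)
            measured = apply_error(measured, spec)
            measured.label = "measured"
            manifest["region_mm"] = [[-15.0, 15.0], [-15.0, 15.0]]
    elif preset == "global-scale":
        calc = dome_plane(half_size_mm=70.0, dose=100.0, edge_drop=0.15,
                          spacing_mm=calc_spacing_mm)
        truth = apply_error(
            calc, ErrorSpec(kind="global_scale", magnitude_pct=magnitude_pct,
                            seed=seed))
        measured = downsample_to_detector(truth, pitch_mm=detector_pitch_mm)
    elif preset in ("noise", "spot-jitter"):
        spots = grid_spot_field(half_size_mm=50.0, pitch_mm=5.0, sigma_mm=5.0)
        calc = render_plane(spots, spacing_mm=calc_spacing_mm)
        if preset == "noise":
            truth = apply_error(
                calc, ErrorSpec(kind="noise", magnitude_pct=magnitude_pct,
                                seed=seed))
        else:
            truth = apply_error(
                calc, ErrorSpec(kind="spot_jitter", jitter_mm=magnitude_pct,
                                seed=seed), field=spots)
            manifest["jitter_mm"] = magnitude_pct
        measured = downsample_to_detector(truth, pitch_mm=detector_pitch_mm)
    else:
        raise ValueError(f"unknown preset: {preset!r}")
    if shift_mm != (0.0, 0.0):
        measured = measured.shifted(shift_mm)
    return measured, calc, manifest
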