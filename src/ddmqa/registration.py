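"""Measured-to-calculated plane alignment.

Setup and couch positioning introduce a rigid in-plane offset between the
detector and the planning grid; removing it before scoring leaves beamlet
position error as the dominant spatial uncertainty.  Alignment is
translation-only and runs in two stages:

1. a coarse stage that cross-correlates the two dose patterns, masked at a
   fraction of their maxima, on a common fine grid (FFT correlation), and
2. a fine stage that minimizes the full-field sum of squared dose
   differences -- no threshold -- over a continuous sub-pixel shift, with
   the calculated plane evaluated by bilinear interpolation.

Shifts are reported as the (row, col) translation in mm applied to the
measured plane's content so that it aligns with the calculated plane.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .plane import DosePlane, global_max

__all__ = [
    "RegistrationError",
    "RegistrationResult",
    "coarse_register",
    "fine_register",
    "register",
    "track_shifts",
]


class RegistrationError(RuntimeError):
    """Raised when alignment is impossible (e.g. empty coarse mask)."""


@dataclass
class RegistrationResult:
    """Tracked output of the two-stage alignment.

    ``shift_mm`` is the final (row, col) translation in mm applied to the
    measured plane; ``coarse_shift_mm`` is the stage-1 estimate.
    ``residual`` is the final sum of squared dose differences over measured
    pixels.  ``converged`` is False when the fine optimizer failed and the
    coarse shift was retained.
    """

    shift_mm: tuple[float, float]
    coarse_shift_mm: tuple[float, float]
    residual: float
    converged: bool = True
    within_setup_tolerance: bool | None = None

    def magnitude(self) -> float:
        return float(np.hypot(*self.shift_mm))


def _common_grid_spacing(measured: DosePlane, calculated: DosePlane) -> float:
    return min(min(measured.spacing), min(calculated.spacing))


def coarse_register(
    measured: DosePlane, calculated: DosePlane, mask_pct: float = 20.0
) -> tuple[float, float]:
    """Integer-pixel (on the common fine grid) correlation shift, in mm.

    Both patterns are sampled onto a common grid at the finer of the two
    spacings, zeroed below ``mask_pct`` % of their own maxima, and
    cross-correlated by FFT with zero padding.  Ties in the correlation
    peak break toward the smallest |shift|.
    """
    s = _common_grid_spacing(measured, calculated)
    (mr0, mr1), (mc0, mc1) = measured.extent
    (cr0, cr1), (cc0, cc1) = calculated.extent
    r_lo, r_hi = min(mr0, cr0), max(mr1, cr1)
    c_lo, c_hi = min(mc0, cc0), max(mc1, cc1)
    rows = np.arange(r_lo, r_hi + s / 2, s)
    cols = np.arange(c_lo, c_hi + s / 2, s)
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    pts = np.stack([rr.ravel(), cc.ravel()], axis=1)

    def sampled_masked(plane: DosePlane) -> np.ndarray:
        vals = plane.interpolator()(pts).reshape(rr.shape)
        thresh = mask_pct / 100.0 * global_max(plane)
        out = np.where(vals > thresh, vals, 0.0)
        return out

    m = sampled_masked(measured)
    c = sampled_masked(calculated)
    if not np.any(m) or not np.any(c):
        raise RegistrationError(
            f"no pixels above {mask_pct}% of maximum: cannot coarse-align"
        )
    # Cross-correlation c(d) = sum_q M(q) C(q + d); zero-pad to avoid wrap.
    nr, nc = m.shape
    fr, fc = 2 * nr - 1, 2 * nc - 1
    corr = np.fft.irfft2(
        np.fft.rfft2(c, s=(fr, fc)) * np.conj(np.fft.rfft2(m, s=(fr, fc))),
        s=(fr, fc),
    )
    dr = np.fft.fftfreq(fr, d=1.0 / fr).round().astype(int)
    dc = np.fft.fftfreq(fc, d=1.0 / fc).round().astype(int)
    peak = corr.max()
    ties = np.argwhere(corr >= peak - 1e-9 * max(abs(peak), 1.0))
    shifts = np.stack([dr[ties[:, 0]], dc[ties[:, 1]]], axis=1).astype(float) * s
    best = shifts[np.lexsort((np.abs(shifts[:, 1]), np.abs(shifts[:, 0]),
                              np.hypot(shifts[:, 0], shifts[:, 1])))][0]
    return (float(best[0]), float(best[1]))


def _residual_at(measured: DosePlane, calc_interp, shift: np.ndarray) -> float:
    rr, cc = measured.pixel_positions()
    pts = np.stack([(rr + shift[0]).ravel(), (cc + shift[1]).ravel()], axis=1)
    diff = measured.values.ravel() - calc_interp(pts)
    return float(np.dot(diff, diff))


def fine_register(
    measured: DosePlane,
    calculated: DosePlane,
    init_shift: tuple[float, float] = (0.0, 0.0),
) -> RegistrationResult:
    """Continuous least-squares refinement of ``init_shift``.

    Minimizes the sum of squared differences between every measured pixel
    and the calculated dose interpolated at the shifted position (no dose
    threshold).  Nelder-Mead with a 0.01 mm shift-step convergence
    tolerance; the result never has a larger residual than ``init_shift``.
    """
    calc_interp = calculated.interpolator()
    x0 = np.asarray(init_shift, dtype=float)

    def objective(x: np.ndarray) -> float:
        return _residual_at(measured, calc_interp, x)

    res = optimize.minimize(
        objective,
        x0,
        method="Nelder-Mead",
        options={"xatol": 0.01, "fatol": 1e-12, "maxiter": 400},
    )
    init_residual = objective(x0)
    if res.fun <= init_residual:
        shift = (float(res.x[0]), float(res.x[1]))
        residual = float(res.fun)
        converged = bool(res.success)
    else:  # optimizer wandered: keep the coarse shift
        shift = (float(x0[0]), float(x0[1]))
        residual = init_residual
        converged = False
    return RegistrationResult(
        shift_mm=shift,
        coarse_shift_mm=(float(init_shift[0]), float(init_shift[1])),
        residual=residual,
        converged=converged,
    )


def register(
    measured: DosePlane,
    calculated: DosePlane,
    mask_pct: float = 20.0,
    setup_tolerance_mm: float = 2.0,
) -> RegistrationResult:
    """Full two-stage alignment: coarse DFT correlation, then least squares."""
    coarse = coarse_register(measured, calculated, mask_pct=mask_pct)
    result = fine_register(measured, calculated, init_shift=coarse)
    result.coarse_shift_mm = coarse
    result.within_setup_tolerance = result.magnitude() <= setup_tolerance_mm
    return result


def track_shifts(
    results: list[RegistrationResult], tolerance_mm: float = 2.0
) -> dict:
    """Session-level consistency report over tracked registration shifts.

    Returns the per-axis mean shift, the maximum shift magnitude, and the
    indices of results whose shift magnitude exceeds ``tolerance_mm`` (these
    indicate a setup problem rather than beamlet error).
    """
    if not results:
        raise ValueError("track_shifts requires at least one result")
    shifts = np.array([r.shift_mm for r in results], dtype=float)
    mags = np.hypot(shifts[:, 0], shifts[:, 1])
    flagged = [i for i, m in enumerate(mags) if m > tolerance_mm]
    return {
        "n": len(results),
        "mean_shift_mm": (float(shifts[:, 0].mean()), float(shifts[:, 1].mean())),
        "max_shift_mm": float(mags.max()),
        "tolerance_mm": float(tolerance_mm),
        "flagged": flagged,
        "all_within_tolerance": len(flagged) == 0,
    }
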