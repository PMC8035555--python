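"""Instrumented gamma-index engine.

For each measured pixel m the gamma index against a calculated dose
distribution is

    gamma(m) = min_n sqrt( (dist_n / dd_M)^2 + (delta_n / dD_M)^2 )

over the N calculated test points n within the search range, where dist_n
is the Euclidean distance from the measured pixel to test point n, delta_n
is the dose difference (measured - calculated) expressed as % of the global
maximum dose, dd_M is the distance-to-agreement criterion and dD_M the dose
criterion.  gamma <= 1 passes (the boundary convention is configurable).

Beyond the textbook index, this engine records for every pixel the distance
and the *signed* dose difference of the minimizing test point, so the user
can see which axis -- dose or distance -- drove each pixel's score instead
of back-calculating it from the unitless index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._search import ComparisonError, disk_candidates, evaluated_mask, normalization_dose
from .plane import Criteria, DosePlane

__all__ = ["GammaMap", "compute_gamma", "gamma_pass_rate", "gamma_summary"]


@dataclass
class GammaMap:
    """Per-measured-pixel gamma result aligned to the measured grid.

    ``argmin_distance_mm`` and ``argmin_dose_diff_pct`` hold the distance
    and the signed dose difference (% of Max Dose) of the test point that
    minimized gamma, so the index can be reconstructed per pixel:
    ``gamma^2 == (argmin_dist/dd_M)^2 + (argmin_delta/dD_M)^2``.
    Pixels outside ``evaluated_mask`` are NaN.
    """

    values: np.ndarray
    argmin_distance_mm: np.ndarray
    argmin_dose_diff_pct: np.ndarray
    evaluated_mask: np.ndarray
    max_dose: float
    criteria: Criteria

    @property
    def evaluated_values(self) -> np.ndarray:
        return self.values[self.evaluated_mask]


def compute_gamma(
    measured: DosePlane,
    calculated: DosePlane,
    criteria: Criteria,
    max_search_mm: float | None = None,
) -> GammaMap:
    """Gamma index of ``measured`` against a fine-grid ``calculated`` plane.

    ``calculated`` should already be registered and resampled onto the
    search grid (see :func:`ddmqa.plane.resample_for_comparison`); measured
    pixels are never interpolated.  ``max_search_mm`` caps how far the
    minimizer may look (default 3x the DTA criterion; a gamma search can
    otherwise range arbitrarily far when no nearby dose agrees).  Ties in
    the minimizer break toward the smallest distance, then the smallest
    absolute dose difference.
    """
    if max_search_mm is None:
        max_search_mm = 3.0 * criteria.distance_mm
    if max_search_mm < criteria.distance_mm:
        raise ValueError("max_search_mm must be at least the DTA criterion")
    max_dose = normalization_dose(measured, calculated, criteria)
    mask = evaluated_mask(measured, max_dose, criteria.low_dose_cutoff_pct)

    shape = measured.shape
    gamma = np.full(shape, np.nan)
    arg_dist = np.full(shape, np.nan)
    arg_delta = np.full(shape, np.nan)
    any_candidates = False
    had_pixels = bool(mask.any())
    for i, j in zip(*np.nonzero(mask)):
        dist, dose, _ = disk_candidates(measured, calculated, i, j, max_search_mm)
        if dist.size == 0:
            mask[i, j] = False
            continue
        any_candidates = True
        if criteria.normalization == "local":
            ref = measured.values[i, j]
        else:
            ref = max_dose
        delta = 100.0 * (measured.values[i, j] - dose) / ref
        g = np.hypot(dist / criteria.distance_mm, delta / criteria.dose_pct)
        k = np.lexsort((np.abs(delta), dist, g))[0]
        gamma[i, j] = g[k]
        arg_dist[i, j] = dist[k]
        arg_delta[i, j] = delta[k]
    if had_pixels and not any_candidates:
        raise ComparisonError("measured and calculated grids do not overlap")
    return GammaMap(
        values=gamma,
        argmin_distance_mm=arg_dist,
        argmin_dose_diff_pct=arg_delta,
        evaluated_mask=mask,
        max_dose=max_dose,
        criteria=criteria,
    )


def gamma_pass_rate(gmap: GammaMap, boundary_passes: bool = True) -> float:
    """Percentage of evaluated pixels with gamma <= 1 (or < 1 if the
    boundary is configured to fail)."""
    vals = gmap.evaluated_values
    if vals.size == 0:
        raise ValueError("gamma map has no evaluated pixels")
    if boundary_passes:
        passed = vals <= 1.0 + 1e-12
    else:
        passed = vals < 1.0
    return 100.0 * float(np.count_nonzero(passed)) / vals.size


def gamma_summary(gmap: GammaMap) -> dict:
    """Supplementary metrics: max gamma, % of gamma > 1.5, mean gamma."""
    vals = gmap.evaluated_values
    if vals.size == 0:
        raise ValueError("gamma map has no evaluated pixels")
    return {
        "max_gamma": float(vals.max()),
        "pct_above_1p5": 100.0 * float(np.count_nonzero(vals > 1.5)) / vals.size,
        "mean_gamma": float(vals.mean()),
    }
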