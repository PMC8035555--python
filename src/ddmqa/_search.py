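"""Shared disk-search kernel for the gamma and DDM engines.

Both comparisons visit, for each measured pixel, every calculated test
point of the fine search grid within a Euclidean radius of the pixel's
physical position.  This module extracts that candidate set once so the
two scorers stay consistent about disk membership, grid clipping and
normalization.
"""

from __future__ import annotations

import numpy as np

from .plane import Criteria, DosePlane, global_max

_EPS = 1e-9


class ComparisonError(RuntimeError):
    """Raised when measured and calculated grids share no overlap."""


def normalization_dose(measured: DosePlane, calculated: DosePlane, criteria: Criteria) -> float:
    """The global Max Dose used to express dose differences in percent."""
    plane = calculated if criteria.max_dose_from == "calculated" else measured
    max_dose = global_max(plane)
    if max_dose <= 0:
        raise ComparisonError("normalization plane has zero maximum dose")
    return max_dose


def evaluated_mask(measured: DosePlane, max_dose: float, cutoff_pct: float) -> np.ndarray:
    """Measured pixels above the low-dose cutoff (strict, per 'above')."""
    return measured.values > cutoff_pct / 100.0 * max_dose


def disk_candidates(
    measured: DosePlane,
    calculated: DosePlane,
    i: int,
    j: int,
    radius_mm: float,
):
    """Test points of the fine calculated grid within ``radius_mm`` of pixel (i, j).

    Returns ``(dist_mm, calc_dose, truncated)`` where the first two are flat
    arrays over the in-disk test points and ``truncated`` is True when the
    disk extends beyond the calculated grid (the search never leaves it).
    Arrays are empty when the pixel lies wholly outside the calculated grid.
    """
    pr = measured.origin[0] + i * measured.spacing[0]
    pc = measured.origin[1] + j * measured.spacing[1]
    rows = calculated.axis_coords(0)
    cols = calculated.axis_coords(1)
    sr, sc = calculated.spacing
    i0 = max(0, int(np.ceil((pr - radius_mm - rows[0]) / sr - _EPS)))
    i1 = min(len(rows) - 1, int(np.floor((pr + radius_mm - rows[0]) / sr + _EPS)))
    j0 = max(0, int(np.ceil((pc - radius_mm - cols[0]) / sc - _EPS)))
    j1 = min(len(cols) - 1, int(np.floor((pc + radius_mm - cols[0]) / sc + _EPS)))
    truncated = (
        pr - radius_mm < rows[0] - _EPS
        or pr + radius_mm > rows[-1] + _EPS
        or pc - radius_mm < cols[0] - _EPS
        or pc + radius_mm > cols[-1] + _EPS
    )
    if i1 < i0 or j1 < j0:
        return np.empty(0), np.empty(0), True
    dr = rows[i0 : i1 + 1] - pr
    dc = cols[j0 : j1 + 1] - pc
    d2 = dr[:, None] ** 2 + dc[None, :] ** 2
    inside = d2 <= radius_mm**2 + _EPS
    dist = np.sqrt(d2[inside])
    dose = calculated.values[i0 : i1 + 1, j0 : j1 + 1][inside]
    return dist, dose, truncated
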