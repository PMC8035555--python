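"""Dose Difference Minimum (DDM) within a fixed search radius.

DDM replaces the gamma test's distance-to-agreement with a fixed search
distance r, set per clinic from measured beamlet spatial accuracy (here
r = 1.0 mm, the >= 3-sigma bound of spot position deviation).  For each
measured pixel the score is

    DDM(m) = signed dose difference, % of Max Dose, of the calculated test
             point within distance r that minimizes |measured - calculated|

so the dose tolerance is invariant over the whole search disk -- unlike the
gamma ellipse, whose dose tolerance shrinks as distance grows -- and the
output stays in dose units, carrying both magnitude and direction forward
to the user.  Agreement found beyond r is statistically improbable for the
machine and would be a false positive; DDM never searches past r.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._search import ComparisonError, disk_candidates, evaluated_mask, normalization_dose
from .gamma import GammaMap
from .plane import Criteria, DosePlane

__all__ = [
    "DDMMap",
    "HistogramSummary",
    "compute_ddm",
    "ddm_pass_rate",
    "ddm_histogram",
    "ddm_heatmap",
]


@dataclass
class DDMMap:
    """Per-measured-pixel signed minimum dose deviation, % of Max Dose.

    The sign is measured - calculated at the minimizing test point, so a
    positive value is an overdose relative to the plan.  ``truncated_mask``
    flags pixels whose search disk was clipped by the calculated grid edge.
    """

    values: np.ndarray
    evaluated_mask: np.ndarray
    truncated_mask: np.ndarray
    r_mm: float
    max_dose: float
    criteria: Criteria

    @property
    def evaluated_values(self) -> np.ndarray:
        return self.values[self.evaluated_mask]


@dataclass
class HistogramSummary:
    """Dose-deviation histogram with its first two moments.

    ``mu`` is the average dose offset and ``sigma`` the standard deviation
    of the signed deviations, both in % of Max Dose; together with the
    histogram they summarize the direction, magnitude and spread of
    measured-vs-calculated disagreement.
    """

    bin_edges: np.ndarray
    counts: np.ndarray
    mu: float
    sigma: float
    tolerance_pct: float = 3.0

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def n(self) -> int:
        return int(self.counts.sum())


def compute_ddm(
    measured: DosePlane, calculated: DosePlane, criteria: Criteria
) -> DDMMap:
    """Signed minimum dose deviation within ``criteria.search_radius_mm``.

    ``calculated`` must already be registered and resampled onto the fine
    search grid; the radius must be resolvable on that grid.  Over every
    test point at Euclidean distance <= r (closed disk) the point with the
    smallest |measured - calculated| is selected and its *signed* deviation
    recorded, as % of Max Dose.  Ties break toward the smaller distance,
    then the positive sign.  Disks clipped by the calculated grid use the
    available points and are flagged in ``truncated_mask``.
    """
    r = criteria.search_radius_mm
    if r < max(calculated.spacing) - 1e-9:
        raise ValueError(
            "search radius is smaller than the search-grid spacing; "
            "resample the calculated plane more finely"
        )
    max_dose = normalization_dose(measured, calculated, criteria)
    mask = evaluated_mask(measured, max_dose, criteria.low_dose_cutoff_pct)

    shape = measured.shape
    values = np.full(shape, np.nan)
    truncated = np.zeros(shape, dtype=bool)
    any_candidates = False
    had_pixels = bool(mask.any())
    for i, j in zip(*np.nonzero(mask)):
        dist, dose, trunc = disk_candidates(measured, calculated, i, j, r)
        if dist.size == 0:
            mask[i, j] = False
            continue
        any_candidates = True
        truncated[i, j] = trunc
        if criteria.normalization == "local":
            ref = measured.values[i, j]
        else:
            ref = max_dose
        delta = 100.0 * (measured.values[i, j] - dose) / ref
        k = np.lexsort((-np.sign(delta), dist, np.abs(delta)))[0]
        values[i, j] = delta[k]
    if had_pixels and not any_candidates:
        raise ComparisonError("measured and calculated grids do not overlap")
    return DDMMap(
        values=values,
        evaluated_mask=mask,
        truncated_mask=truncated,
        r_mm=r,
        max_dose=max_dose,
        criteria=criteria,
    )


def ddm_pass_rate(
    dmap: DDMMap, tolerance_pct: float = 3.0, boundary_passes: bool = False
) -> float:
    """Percentage of evaluated pixels with |DDM| below the dose tolerance.

    The comparison is strict (< tolerance) by default; set
    ``boundary_passes`` to accept deviations exactly at tolerance.
    """
    vals = np.abs(dmap.evaluated_values)
    if vals.size == 0:
        raise ValueError("DDM map has no evaluated pixels")
    if boundary_passes:
        passed = vals <= tolerance_pct + 1e-12
    else:
        passed = vals < tolerance_pct
    return 100.0 * float(np.count_nonzero(passed)) / vals.size


def ddm_histogram(
    dmap: DDMMap, bin_width_pct: float = 0.5, tolerance_pct: float = 3.0
) -> HistogramSummary:
    """Histogram of signed deviations with mean (mu) and spread (sigma).

    Bin edges sit at half-integer multiples of the bin width so bin centers
    fall on whole multiples (0, +-w, +-2w, ...), covering the full value
    range.  Rendering convention (see :func:`plot_histogram`): logarithmic
    count axis, red tolerance lines at +-tolerance, dashed guides at 1% and
    10% of the evaluated pixel count.
    """
    if bin_width_pct <= 0:
        raise ValueError("bin width must be strictly positive")
    vals = dmap.evaluated_values
    if vals.size == 0:
        raise ValueError("DDM map has no evaluated pixels")
    w = bin_width_pct
    k_lo = int(np.floor(vals.min() / w + 0.5))
    k_hi = int(np.ceil(vals.max() / w - 0.5))
    edges = (np.arange(k_lo, k_hi + 2) - 0.5) * w
    counts, _ = np.histogram(vals, bins=edges)
    return HistogramSummary(
        bin_edges=edges,
        counts=counts,
        mu=float(vals.mean()),
        sigma=float(vals.std()),
        tolerance_pct=tolerance_pct,
    )


def ddm_heatmap(
    dmap: DDMMap,
    gamma_map: GammaMap | None = None,
    measured: DosePlane | None = None,
    ax=None,
    cmap: str = "coolwarm",
):
    """Signed DDM heat map on the measured grid, with optional gamma overlay.

    Positive (overdose) and negative (underdose) deviations are shown on a
    diverging scale symmetric about zero, axes in mm.  When ``gamma_map``
    is given, every evaluated pixel with gamma > 1 is marked with an
    asterisk, mirroring the side-by-side reading of the two tests.
    Returns ``(ax, display_array)``.
    """
    import matplotlib.pyplot as plt

    if gamma_map is not None and gamma_map.values.shape != dmap.values.shape:
        raise ValueError("gamma map and DDM map shapes differ")
    if ax is None:
        _, ax = plt.subplots()
    disp = np.where(dmap.evaluated_mask, dmap.values, np.nan)
    finite = disp[np.isfinite(disp)]
    vmax = float(np.max(np.abs(finite))) if finite.size else 1.0
    vmax = max(vmax, 1e-6)
    if measured is not None:
        sr, sc = measured.spacing
        (r0, r1), (c0, c1) = measured.extent
        extent = (c0 - sc / 2, c1 + sc / 2, r1 + sr / 2, r0 - sr / 2)
        xlabel, ylabel = "x (mm)", "y (mm)"
    else:
        extent = None
        xlabel, ylabel = "col pixel", "row pixel"
    im = ax.imshow(
        disp,
        cmap=cmap,
        vmin=-vmax,
        vmax=vmax,
        origin="upper",
        extent=extent,
        interpolation="nearest",
    )
    ax.set_xlabel(xlabel)
    ax.set_ylabel(ylabel)
    ax.set_title(f"DDM ΔDmin(r={dmap.r_mm:g} mm), % of max dose")
    plt.colorbar(im, ax=ax, label="dose deviation (%)")
    if gamma_map is not None:
        fail = gamma_map.evaluated_mask & (gamma_map.values > 1.0)
        fi, fj = np.nonzero(fail)
        if measured is not None:
            xs = measured.origin[1] + fj * measured.spacing[1]
            ys = measured.origin[0] + fi * measured.spacing[0]
        else:
            xs, ys = fj, fi
        ax.plot(xs, ys, linestyle="none", marker="*", color="k", markersize=8)
    return ax, disp


def plot_histogram(summaries, ax=None, labels=None, colors=None):
    """Render one or more DDM histograms in the standard report style.

    Logarithmic count axis, red vertical lines at +-tolerance, dashed
    horizontal guides at 1% and 10% of the pixel count, and a mu/sigma
    annotation per histogram.
    """
    import matplotlib.pyplot as plt

    if isinstance(summaries, HistogramSummary):
        summaries = [summaries]
    if ax is None:
        _, ax = plt.subplots()
    for idx, summary in enumerate(summaries):
        label = labels[idx] if labels else f"μ={summary.mu:.2f}%, σ={summary.sigma:.2f}%"
        color = colors[idx] if colors else None
        ax.stairs(np.maximum(summary.counts, 0), summary.bin_edges,
                  label=label, color=color, fill=(idx == 0), alpha=0.6)
    ax.set_yscale("log")
    n = summaries[0].n
    tol = summaries[0].tolerance_pct
    ax.axvline(-tol, color="red", linestyle="-")
    ax.axvline(tol, color="red", linestyle="-")
    for frac in (0.01, 0.10):
        if n * frac >= 1:
            ax.axhline(n * frac, color="gray", linestyle="--", linewidth=0.8)
    ax.set_xlabel("dose deviation (% of max dose)")
    ax.set_ylabel("pixel count (log)")
    ax.legend()
    return ax
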