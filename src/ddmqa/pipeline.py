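"""End-to-end plane comparison: register, resample, score, summarize.

``compare_planes`` runs the full measurement-analysis chain on a measured
and a calculated dose plane and returns a bundle holding the registration
result, the instrumented gamma map, the DDM map, the deviation histogram,
and a JSON-serializable :class:`ComparisonReport`.  The same chain backs
the command-line interface.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np

from . import __version__
from .ddm import DDMMap, HistogramSummary, compute_ddm, ddm_heatmap, ddm_histogram, ddm_pass_rate, plot_histogram
from .gamma import GammaMap, compute_gamma, gamma_pass_rate, gamma_summary
from .plane import Criteria, DosePlane, resample_for_comparison
from .registration import RegistrationResult, register

__all__ = ["ComparisonReport", "ComparisonBundle", "compare_planes", "render_report"]


def _plane_digest(plane: DosePlane) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(plane.values).tobytes())
    h.update(repr((plane.spacing, plane.origin)).encode())
    return h.hexdigest()[:16]


@dataclass
class ComparisonReport:
    """Flat, JSON-serializable summary of a plane comparison."""

    criteria: dict
    registration: dict
    gamma: dict
    ddm: dict
    histogram: dict
    version: str = __version__
    inputs: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "criteria": self.criteria,
            "inputs": self.inputs,
            "registration": self.registration,
            "gamma": self.gamma,
            "ddm": self.ddm,
            "histogram": self.histogram,
        }

    def to_json(self, **kwargs) -> str:
        kwargs.setdefault("indent", 2)
        kwargs.setdefault("sort_keys", True)
        return json.dumps(self.to_dict(), **kwargs)


@dataclass
class ComparisonBundle:
    """Full comparison output: report plus the per-pixel maps behind it."""

    report: ComparisonReport
    measured: DosePlane
    calculated_fine: DosePlane
    registration: RegistrationResult
    gamma_map: GammaMap
    ddm_map: DDMMap
    histogram: HistogramSummary


def compare_planes(
    measured: DosePlane,
    calculated: DosePlane,
    criteria: Criteria | None = None,
    do_register: bool = True,
    search_spacing_mm: float = 0.1,
    bin_width_pct: float = 0.5,
    mask_pct: float = 20.0,
) -> ComparisonBundle:
    """Register, resample, and score a measured/calculated plane pair.

    The measured plane is aligned to the calculated plane (coarse DFT
    correlation on a 20%-of-max mask, then full-field least squares), the
    calculated plane is resampled onto the fine search grid anchored on the
    aligned measured lattice, and both the gamma test (dose_pct /
    distance_mm) and the DDM test (dose_pct within search_radius_mm) are
    evaluated.  Deterministic: identical inputs give identical reports.
    """
    criteria = criteria or Criteria()
    if do_register:
        reg = register(measured, calculated, mask_pct=mask_pct)
        aligned = measured.shifted(reg.shift_mm)
    else:
        reg = RegistrationResult(shift_mm=(0.0, 0.0), coarse_shift_mm=(0.0, 0.0),
                                 residual=float("nan"), converged=True)
        aligned = measured
    fine = resample_for_comparison(calculated, aligned, search_spacing_mm)
    gmap = compute_gamma(aligned, fine, criteria)
    dmap = compute_ddm(aligned, fine, criteria)
    hist = ddm_histogram(dmap, bin_width_pct=bin_width_pct,
                         tolerance_pct=criteria.dose_pct)
    gsum = gamma_summary(gmap)
    report = ComparisonReport(
        criteria={
            "dose_pct": criteria.dose_pct,
            "distance_mm": criteria.distance_mm,
            "search_radius_mm": criteria.search_radius_mm,
            "low_dose_cutoff_pct": criteria.low_dose_cutoff_pct,
            "normalization": criteria.normalization,
            "max_dose_from": criteria.max_dose_from,
        },
        registration={
            "dy_mm": reg.shift_mm[0],
            "dx_mm": reg.shift_mm[1],
            "coarse_dy_mm": reg.coarse_shift_mm[0],
            "coarse_dx_mm": reg.coarse_shift_mm[1],
            "residual": reg.residual if np.isfinite(reg.residual) else None,
            "converged": reg.converged,
        },
        gamma={
            "pass_rate_pct": gamma_pass_rate(gmap),
            "max_gamma": gsum["max_gamma"],
            "pct_above_1p5": gsum["pct_above_1p5"],
            "mean_gamma": gsum["mean_gamma"],
            "n_evaluated": int(gmap.evaluated_mask.sum()),
        },
        ddm={
            "pass_rate_pct": ddm_pass_rate(dmap, tolerance_pct=criteria.dose_pct),
            "r_mm": dmap.r_mm,
            "max_abs_deviation_pct": float(np.max(np.abs(dmap.evaluated_values))),
            "mean_within_1pct": bool(abs(float(dmap.evaluated_values.mean())) < 1.0),
            "n_evaluated": int(dmap.evaluated_mask.sum()),
            "n_truncated": int(dmap.truncated_mask.sum()),
        },
        histogram={
            "mu_pct": hist.mu,
            "sigma_pct": hist.sigma,
            "bin_width_pct": bin_width_pct,
            "bin_edges": [float(e) for e in hist.bin_edges],
            "counts": [int(c) for c in hist.counts],
            "tolerance_pct": hist.tolerance_pct,
        },
        inputs={
            "measured": _plane_digest(measured),
            "calculated": _plane_digest(calculated),
        },
    )
    return ComparisonBundle(
        report=report,
        measured=aligned,
        calculated_fine=fine,
        registration=reg,
        gamma_map=gmap,
        ddm_map=dmap,
        histogram=hist,
    )


def render_report(bundle: ComparisonBundle, out_png: str) -> None:
    """Two-row composite figure: dose planes on top, heat map + histogram below.

    Measured and calculated panels, the signed DDM heat map with gamma-fail
    asterisks, and the log-count deviation histogram with tolerance lines
    and the mu/sigma annotation.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(2, 2, figsize=(11, 9))
    reg = bundle.report.registration
    for ax, plane, title in (
        (axes[0, 0], bundle.measured,
         f"Measured (Δx={reg['dx_mm']:.2f} mm, Δy={reg['dy_mm']:.2f} mm)"),
        (axes[0, 1], bundle.calculated_fine, "Calculated"),
    ):
        sr, sc = plane.spacing
        (r0, r1), (c0, c1) = plane.extent
        im = ax.imshow(plane.values, origin="upper", cmap="viridis",
                       extent=(c0 - sc / 2, c1 + sc / 2, r1 + sr / 2, r0 - sr / 2))
        ax.set_title(title)
        ax.set_xlabel("x (mm)")
        ax.set_ylabel("y (mm)")
        fig.colorbar(im, ax=ax, label="dose (cGy RBE)")
    ddm_heatmap(bundle.ddm_map, gamma_map=bundle.gamma_map,
                measured=bundle.measured, ax=axes[1, 0])
    plot_histogram(bundle.histogram, ax=axes[1, 1])
    axes[1, 1].set_title(
        f"DDM {bundle.report.ddm['pass_rate_pct']:.2f}% | "
        f"γ {bundle.report.gamma['pass_rate_pct']:.2f}%"
    )
    fig.tight_layout()
    fig.savefig(out_png, dpi=120)
    plt.close(fig)


def per_pixel_table(bundle: ComparisonBundle):
    """Per-pixel CSV-ready table: position, dose, gamma (with its minimizer's
    distance and signed dose difference), and DDM."""
    import pandas as pd

    m = bundle.measured
    rr, cc = m.pixel_positions()
    mask = bundle.gamma_map.evaluated_mask | bundle.ddm_map.evaluated_mask
    return pd.DataFrame(
        {
            "row_mm": rr[mask],
            "col_mm": cc[mask],
            "measured_dose": m.values[mask],
            "gamma": bundle.gamma_map.values[mask],
            "gamma_argmin_dist_mm": bundle.gamma_map.argmin_distance_mm[mask],
            "gamma_argmin_dose_diff_pct": bundle.gamma_map.argmin_dose_diff_pct[mask],
            "ddm_pct": bundle.ddm_map.values[mask],
            "ddm_truncated": bundle.ddm_map.truncated_mask[mask],
        }
    )
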