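"""Acceptance-region geometry: gamma ellipse vs DDM rectangle.

Plotting dose tolerance against distance, a gamma test's passing region is
one quadrant of an ellipse with semiaxes (DTA, dose %): its dose tolerance
shrinks as distance grows.  The DDM passing region is a rectangle (r, dose
%): the dose tolerance is invariant across the whole search distance.  The
area under each boundary (AUC, in %*mm) measures how much combined
dose/distance variation each test forgives, and the overlap of the gamma
quadrant with the *machine-relevant* rectangle (deviations the delivery
system can actually produce) measures how many relevant points the gamma
test is able to accept.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "AcceptanceRegion",
    "ellipse_quadrant_auc",
    "rectangle_auc",
    "relevant_coverage",
]


@dataclass
class AcceptanceRegion:
    """A passing region in (distance, dose) space with its area."""

    shape: str  # "ellipse_quadrant" | "rectangle"
    dose_semiaxis_pct: float
    distance_semiaxis_mm: float

    def __post_init__(self) -> None:
        if self.shape not in ("ellipse_quadrant", "rectangle"):
            raise ValueError("shape must be 'ellipse_quadrant' or 'rectangle'")
        if self.dose_semiaxis_pct <= 0 or self.distance_semiaxis_mm <= 0:
            raise ValueError("semiaxes must be strictly positive")

    @property
    def auc(self) -> float:
        if self.shape == "ellipse_quadrant":
            return ellipse_quadrant_auc(self.dose_semiaxis_pct, self.distance_semiaxis_mm)
        return rectangle_auc(self.dose_semiaxis_pct, self.distance_semiaxis_mm)


def ellipse_quadrant_auc(dose_pct: float, dta_mm: float) -> float:
    """Area of one quadrant of the gamma ellipse: pi * dose * dta / 4, %*mm."""
    if dose_pct <= 0 or dta_mm <= 0:
        raise ValueError("criteria must be strictly positive")
    return math.pi * dose_pct * dta_mm / 4.0


def rectangle_auc(dose_pct: float, r_mm: float) -> float:
    """Area of the DDM acceptance rectangle: dose * r, %*mm."""
    if dose_pct <= 0 or r_mm <= 0:
        raise ValueError("criteria must be strictly positive")
    return dose_pct * r_mm


def _ellipse_area_integral(dose_pct: float, dta_mm: float, x: float) -> float:
    """Area under dose_pct * sqrt(1 - (t/dta)^2) for t in [0, x], x <= dta."""
    u = min(x / dta_mm, 1.0)
    return dose_pct * dta_mm / 2.0 * (math.asin(u) + u * math.sqrt(1.0 - u * u))


def relevant_coverage(
    ellipse: tuple[float, float], relevant: tuple[float, float]
) -> float:
    """Fraction of the machine-relevant rectangle a gamma quadrant accepts.

    ``ellipse`` is (dose %, DTA mm); ``relevant`` is (dose %, r mm), the
    rectangle of deviations within both the clinical dose tolerance and
    the machine's achievable spot accuracy, under a uniform area measure.
    Closed-form elliptic-segment integral.
    """
    e_dose, e_dta = ellipse
    r_dose, r_mm = relevant
    if min(e_dose, e_dta, r_dose, r_mm) <= 0:
        raise ValueError("all semiaxes must be strictly positive")
    x_max = min(e_dta, r_mm)
    if e_dose <= r_dose:
        # The ellipse never exceeds the rectangle's dose bound.
        inter = _ellipse_area_integral(e_dose, e_dta, x_max)
    else:
        # Ellipse height crosses r_dose at x_star; capped at r_dose before it.
        x_star = e_dta * math.sqrt(1.0 - (r_dose / e_dose) ** 2)
        if x_max <= x_star:
            inter = r_dose * x_max
        else:
            inter = r_dose * x_star + (
                _ellipse_area_integral(e_dose, e_dta, x_max)
                - _ellipse_area_integral(e_dose, e_dta, x_star)
            )
    return inter / (r_dose * r_mm)
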