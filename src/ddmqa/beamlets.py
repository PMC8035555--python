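"""Spot-position accuracy statistics and the empirical search radius.

The DDM search radius r is not a free tolerance: it is derived from
measured delivery-system performance.  Scanned proton spots deviate
radially from the x-ray isocenter by small amounts; sampling those
deviations over time and weighting them by clinical use frequency gives a
probability-weighted distribution whose upper quantile bounds how far a
real spot can plausibly land from its nominal position.  Dose agreement
found beyond that bound is coincidental.  This module computes the
weighted descriptive statistics (four moments), the sigma distance of a
limit from the mean, the weighted fraction of spots inside the limit,
one-sided location tests against the limit, and the recommended r.
"""

from __future__ import annotations

from dataclasses import dataclass

import math

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "BeamletDeviationSet",
    "DeviationSummary",
    "read_deviations",
    "summarize_deviations",
    "normal_model_fraction_below",
    "recommend_search_radius",
    "weighted_deviation_histogram",
]


@dataclass
class BeamletDeviationSet:
    """Per-spot radial deviations from isocenter with clinical-use weights."""

    radial_deviation_mm: np.ndarray
    weight: np.ndarray

    def __post_init__(self) -> None:
        self.radial_deviation_mm = np.asarray(self.radial_deviation_mm, dtype=float)
        self.weight = np.asarray(self.weight, dtype=float)
        if self.radial_deviation_mm.ndim != 1 or self.radial_deviation_mm.size == 0:
            raise ValueError("deviations must be a non-empty 1D array")
        if self.weight.shape != self.radial_deviation_mm.shape:
            raise ValueError("weights must match deviations in shape")
        if np.any(self.radial_deviation_mm < 0):
            raise ValueError("radial deviations are non-negative by construction")
        if np.any(self.weight < 0) or not np.any(self.weight > 0):
            raise ValueError("weights must be >= 0 with at least one positive")

    @property
    def n(self) -> int:
        return int(self.radial_deviation_mm.size)


@dataclass
class DeviationSummary:
    n: int
    range_mm: tuple[float, float]
    mean_mm: float
    sd_mm: float
    skewness: float
    kurtosis: float
    sigma_limit: float
    frac_below_limit: float
    p_t: float | None
    p_wilcoxon: float | None


def read_deviations(path: str) -> BeamletDeviationSet:
    """Read a ``radial_deviation_mm, weight`` CSV into a deviation set."""
    df = pd.read_csv(path)
    if "radial_deviation_mm" not in df.columns:
        raise ValueError(f"{path}: missing column 'radial_deviation_mm'")
    weight = df["weight"].to_numpy() if "weight" in df.columns else np.ones(len(df))
    return BeamletDeviationSet(df["radial_deviation_mm"].to_numpy(), weight)


def _weighted_moments(x: np.ndarray, w: np.ndarray) -> tuple[float, float, float, float]:
    wsum = w.sum()
    mean = float(np.sum(w * x) / wsum)
    var = float(np.sum(w * (x - mean) ** 2) / wsum)
    sd = math.sqrt(var)
    if sd > 0:
        skew = float(np.sum(w * (x - mean) ** 3) / wsum) / sd**3
        kurt = float(np.sum(w * (x - mean) ** 4) / wsum) / sd**4 - 3.0
    else:
        skew = 0.0
        kurt = 0.0
    return mean, sd, skew, kurt


def _weight_resampled(dev: BeamletDeviationSet, seed: int = 0) -> np.ndarray:
    """Samples drawn proportionally to weight, for the rank-based test.

    Uniform weights pass the samples through unchanged; otherwise the set is
    resampled (size n, fixed seed) with probability proportional to weight.
    """
    w = dev.weight
    if np.allclose(w, w[0]):
        return dev.radial_deviation_mm
    rng = np.random.default_rng(seed)
    idx = rng.choice(dev.n, size=dev.n, p=w / w.sum())
    return dev.radial_deviation_mm[idx]


def summarize_deviations(
    dev: BeamletDeviationSet, limit_mm: float = 1.0, seed: int = 0
) -> DeviationSummary:
    """Weighted four-moment summary and one-sided tests against a limit.

    ``sigma_limit`` is how many weighted standard deviations the limit sits
    above the weighted mean; ``frac_below_limit`` is the weighted fraction
    of spots strictly inside the limit.  The one-sided Student's t and
    Wilcoxon signed-rank tests ask whether the average deviation is below
    the limit; with fewer than two samples (or zero spread, for the rank
    test) the p-values are None.
    """
    x = dev.radial_deviation_mm
    w = dev.weight
    mean, sd, skew, kurt = _weighted_moments(x, w)
    sigma_limit = float("inf") if sd == 0 else (limit_mm - mean) / sd
    frac_below = float(np.sum(w[x < limit_mm]) / w.sum())
    p_t = p_w = None
    if dev.n >= 2:
        sample = _weight_resampled(dev, seed=seed)
        if np.ptp(sample) > 0:
            p_t = float(stats.ttest_1samp(sample, limit_mm, alternative="less").pvalue)
            p_w = float(
                stats.wilcoxon(sample - limit_mm, alternative="less").pvalue
            )
    return DeviationSummary(
        n=dev.n,
        range_mm=(float(x.min()), float(x.max())),
        mean_mm=mean,
        sd_mm=sd,
        skewness=skew,
        kurtosis=kurt,
        sigma_limit=sigma_limit,
        frac_below_limit=frac_below,
        p_t=p_t,
        p_wilcoxon=p_w,
    )


def normal_model_fraction_below(mean_mm: float, sd_mm: float, limit_mm: float) -> float:
    """Normal-model probability that a deviation falls below the limit.

    Large-sample (central-limit) approximation Phi((limit - mean) / sd);
    the underlying deviation distribution is non-normal (it is bounded
    below by zero), so this is an approximation the data support only in
    bulk, not in the extreme tail.
    """
    if sd_mm <= 0:
        raise ValueError("sd must be strictly positive")
    return float(stats.norm.cdf((limit_mm - mean_mm) / sd_mm))


def recommend_search_radius(
    dev: BeamletDeviationSet, confidence: float = 0.997
) -> float:
    """Smallest radius covering the given weighted fraction of deviations.

    Returns the smallest observed deviation r with weighted
    P(deviation <= r) >= confidence, rounded *up* to 0.1 mm (a conservative
    search radius).  The default 0.997 is the 3-sigma coverage convention.
    """
    if not 0 < confidence <= 1:
        raise ValueError("confidence must be in (0, 1]")
    order = np.argsort(dev.radial_deviation_mm, kind="stable")
    x = dev.radial_deviation_mm[order]
    cw = np.cumsum(dev.weight[order]) / dev.weight.sum()
    idx = int(np.searchsorted(cw, confidence - 1e-12))
    idx = min(idx, x.size - 1)
    return float(math.ceil(x[idx] * 10 - 1e-9) / 10)


def weighted_deviation_histogram(
    dev: BeamletDeviationSet, bin_width_mm: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Probability-weighted histogram of radial deviations.

    Returns ``(bin_edges, mass)`` where ``mass`` sums to 1 -- the
    probability that a clinically delivered spot lands in each radial bin.
    """
    if bin_width_mm <= 0:
        raise ValueError("bin width must be strictly positive")
    x = dev.radial_deviation_mm
    hi = max(float(x.max()), bin_width_mm)
    n_bins = int(math.ceil(hi / bin_width_mm - 1e-9))
    edges = bin_width_mm * np.arange(n_bins + 1)
    if edges[-1] < hi:
        edges = np.append(edges, edges[-1] + bin_width_mm)
    mass, _ = np.histogram(x, bins=edges, weights=dev.weight)
    return edges, mass / dev.weight.sum()
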