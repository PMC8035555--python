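"""Independent brute-force references for the gamma and DDM engines.

Deliberately naive: a double loop over every calculated pixel, with no
index windowing or vectorized candidate extraction, so that agreement with
the engines is a genuine cross-check rather than a shared code path.
"""

import math

import numpy as np


def brute_gamma(measured, calculated, criteria, max_search_mm):
    """Exhaustive per-pixel gamma over every calculated pixel in range."""
    max_dose = (np.max(calculated.values)
                if criteria.max_dose_from == "calculated"
                else np.max(measured.values))
    cutoff = criteria.low_dose_cutoff_pct / 100.0 * max_dose
    out = np.full(measured.values.shape, np.nan)
    for i in range(measured.values.shape[0]):
        for j in range(measured.values.shape[1]):
            mval = measured.values[i, j]
            if mval <= cutoff:
                continue
            pr = measured.origin[0] + i * measured.spacing[0]
            pc = measured.origin[1] + j * measured.spacing[1]
            best = math.inf
            for a in range(calculated.values.shape[0]):
                for b in range(calculated.values.shape[1]):
                    qr = calculated.origin[0] + a * calculated.spacing[0]
                    qc = calculated.origin[1] + b * calculated.spacing[1]
                    dist = math.sqrt((pr - qr) ** 2 + (pc - qc) ** 2)
                    if dist > max_search_mm + 1e-9:
                        continue
                    ref = mval if criteria.normalization == "local" else max_dose
                    delta = 100.0 * (mval - calculated.values[a, b]) / ref
                    g = math.hypot(dist / criteria.distance_mm,
                                   delta / criteria.dose_pct)
                    best = min(best, g)
            if best < math.inf:
                out[i, j] = best
    return out


def brute_ddm(measured, calculated, criteria):
    """Exhaustive per-pixel signed minimum dose deviation within r."""
    r = criteria.search_radius_mm
    max_dose = (np.max(calculated.values)
                if criteria.max_dose_from == "calculated"
                else np.max(measured.values))
    cutoff = criteria.low_dose_cutoff_pct / 100.0 * max_dose
    out = np.full(measured.values.shape, np.nan)
    for i in range(measured.values.shape[0]):
        for j in range(measured.values.shape[1]):
            mval = measured.values[i, j]
            if mval <= cutoff:
                continue
            pr = measured.origin[0] + i * measured.spacing[0]
            pc = measured.origin[1] + j * measured.spacing[1]
            best = None
            for a in range(calculated.values.shape[0]):
                for b in range(calculated.values.shape[1]):
                    qr = calculated.origin[0] + a * calculated.spacing[0]
                    qc = calculated.origin[1] + b * calculated.spacing[1]
                    dist = math.sqrt((pr - qr) ** 2 + (pc - qc) ** 2)
                    if dist > r + 1e-9:
                        continue
                    ref = mval if criteria.normalization == "local" else max_dose
                    delta = 100.0 * (mval - calculated.values[a, b]) / ref
                    if best is None or abs(delta) < abs(best):
                        best = delta
            if best is not None:
                out[i, j] = best
    return out
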