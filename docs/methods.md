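# Methods

## Problem and data model

Patient-specific QA for scanned-beam radiotherapy compares a measured 2D
dose plane (an ion-chamber array at 7.62 mm pitch, absolute dose in
cGy(RBE)) against the treatment-planning-system (TPS) calculation at the
same depth. Both are represented as a `DosePlane`: a 2D array with a
(row, col) pixel pitch in mm and the physical coordinate of the center of
pixel (0, 0) in an isocenter-centered frame (pixel-center convention,
0-based indices, Euclidean in-plane distances). The calculated plane may be
interpolated freely; measured pixels are never interpolated — every score
is attached to a physical chamber reading.

## The two comparison metrics

**Gamma index.** For measured pixel m and the N calculated test points n
within the search range,

    γ(m) = min_n sqrt( (dist_n / Δd_M)² + (δ_n / ΔD_M)² ),

with dist_n the Euclidean distance to test point n, δ_n the dose
difference (measured − calculated) as a percent of the global maximum
dose, Δd_M the distance-to-agreement (DTA) criterion and ΔD_M the dose
criterion. γ ≤ 1 passes. The passing region in (distance, dose) space is
one quadrant of an ellipse: the tolerated dose error shrinks as distance
grows. The engine is *instrumented*: for every pixel it records the
distance and the signed dose difference of the minimizing test point, so
the user can attribute each score to its dose or distance component
without back-calculating from the unitless index.

**Dose Difference Minimum (DDM).** ΔDmin(r) replaces the DTA with a fixed
search radius r:

    DDM(m) = δ of the test point within distance ≤ r (closed disk)
             minimizing |measured − calculated|,

reported *signed*, as a percent of maximum dose. The dose tolerance is
invariant over the whole disk (a cylindrical acceptance region), and the
output stays in dose units, so a histogram of per-pixel DDM values shows
the magnitude and direction of disagreement directly. A pixel passes when
|DDM| is strictly below the dose tolerance (3% default); the boundary
convention is a switch, as is γ's (γ = 1.0 passes by default).

The radius r is not a tolerance to negotiate: it is the upper bound of
where a correctly functioning delivery system can actually put a pencil
beam. Agreement found beyond r is statistically improbable and therefore a
false positive. The γ engine, by contrast, is allowed to search beyond its
DTA (capped at 3×Δd_M by default, a bounded-runtime compromise for the
textbook unbounded search).

## Deriving r from spot accuracy

`beamlets` ingests per-spot radial deviations from the x-ray isocenter
with clinical-use frequency weights. It computes weighted four-moment
descriptive statistics, the sigma distance of a limit from the mean
((limit − mean)/sd), the weighted fraction of spots inside the limit, a
normal-model coverage Φ((limit − mean)/sd) (a large-sample approximation —
the underlying distribution is non-normal because deviations are
non-negative), and one-sided Student's t and Wilcoxon signed-rank tests of
the mean against the limit. Weights enter moments and quantiles as
frequency weights; the rank test runs on a weight-proportional resample
(deterministic, and a pass-through for uniform weights).
`recommend_search_radius` returns the smallest radius covering a target
weighted fraction of deviations (default 0.997, the 3σ convention),
rounded *up* to 0.1 mm. For deviations with mean 0.38 mm and SD 0.19 mm —
the delivery-system figures the defaults emulate — this yields r = 1.0 mm,
with ≈ 99.9% of spots inside 1 mm.

Caveat: the extreme empirical quantile of a finite sample has a long right
tail. At n = 10⁴ the 0.999-coverage radius rounds to 1.0 mm for most random
draws but can round to 1.1 mm; the package reports what the sample
supports rather than clamping.

## Acceptance-region geometry

`sensitivity` quantifies the ellipse-vs-rectangle trade in closed form:
quarter-ellipse area π·ΔD_M·Δd_M/4, rectangle area ΔD_M·r (both in %·mm),
and the fraction of the *machine-relevant* rectangle (|δ| ≤ ΔD_M,
dist ≤ r) covered by a γ quadrant, via the elliptic-segment integral.
"Relevant points" are taken under a uniform area measure over the
rectangle; with equal axes the coverage is exactly π/4 ≈ 78.5%, and a
3%/2 mm quadrant covers ≈ 95.7% of the 3% × 1 mm rectangle. A
probability-weighted measure (weighting distance by the spot-deviation
density) would give different coverages; that variant is noted, not
implemented.

## Registration

Setup and couch error are removed before scoring so that beamlet position
error dominates the spatial residual. The model is translation-only
(Δx, Δy); rotation and deformation are out of scope. Stage 1 samples both
planes onto a common grid at the finer of the two spacings, zeroes values
at or below 20% of each plane's maximum, and cross-correlates by FFT with
zero padding; correlation-peak ties break toward the smallest |shift|.
Stage 2 minimizes the full-field (no threshold) sum of squared differences
between measured pixels and the bilinearly interpolated calculated dose
over a continuous shift, with Nelder–Mead (shift-step tolerance 0.01 mm);
if the optimizer fails to improve on the coarse shift, the coarse shift is
retained and flagged. Shifts are tracked per session (`track_shifts`,
default 2 mm setup tolerance) because consistent shifts indicate a
systematic setup offset, not a delivery problem. On gradient-free
(uniform) planes the objective is flat and the initial shift is returned
unchanged.

## The fine search grid

Scoring uses the calculated plane resampled to a fine grid (default target
0.1 mm, ≥ 10× finer than r = 1 mm so disk discretization is negligible).
The grid is anchored on the measured pixel lattice: its spacing divides
the detector pitch evenly and its nodes include every measured pixel
center inside the calculated extent. Consequences: an in-place
(zero-distance) test point always exists, so |DDM| is bounded by the
in-place dose difference, a flat +ΔD_M offset sits exactly on the γ = 1
boundary, and every pixel passing γ at (ΔD_M, d) also passes DDM at
(ΔD_M, r = d). The grid never extends beyond the calculated plane; disks
clipped at the edge use the available points and are flagged
(`truncated_mask`).

Tie-breaking is deterministic: γ minimizer ties resolve to the smallest
distance, then the smallest |δ|; DDM ties to the smallest distance, then
the positive sign. The low-dose cutoff excludes measured pixels at or
below 10% of the normalization dose (strict "above").

## Normalization

"Global maximum of the dose plane" is ambiguous between the two planes.
The default is the calculated plane's maximum (noise-free and independent
of delivery error); `Criteria.max_dose_from="measured"` switches to the
measured maximum, and `normalization="local"` divides by the measured
pixel's own dose instead. The choice matters for systematic output errors:
under calculated-max normalization an exactly −3% scaled delivery produces
per-pixel deviations of −3·C/Cmax ≥ −3, which sits on (never beyond) the
γ = 1 boundary, so the γ test reports no failures. Under measured-max
normalization the same delivery gives −3.09% in the flat interior and the
γ test fails precisely the low-gradient pixels while steep-gradient pixels
escape spatially — the characteristic false-negative signature of a
clinically tolerable global offset. The underdose demonstration in the
acceptance tests therefore uses measured-max normalization, stated here as
the package's reading of that scenario.

## Synthetic data

The generator produces the study conditions the package is tested under:

- **Calculated planes** on a 1 mm grid: a homogeneous 10×10 cm field
  (inserted-error experiments), a Gaussian-spot field (spot σ 5 mm, pitch
  5 mm — typical scanned-beam lateral parameters at depth), or an analytic
  domed field (half-size 70 mm, 15% corner drop) giving a broad
  low-gradient maximum with gradient increasing radially.
- **Measured planes** by point-sampling the error-injected truth dose at
  7.62 mm detector pitch centered on isocenter. Point sampling, not
  chamber volume averaging, consistent with the per-pixel treatment;
  volume averaging is a noted extension.
- **Errors**: global scale, region offset (3×3 cm² at +5..15% — the
  classic degeneracy experiment, applied on the detector lattice so the
  region edge never straddles a chamber), spot-position jitter
  (re-rendered), and zero-mean noise. All deterministic at a fixed seed.
- **Spot deviations**: |N(µ, σ)| with (µ, σ) moment-matched numerically
  (tolerance 10⁻⁶) so the *population* mean/SD equal the targets
  (0.38/0.19 mm defaults); an infeasible pair (sd/mean > √(π/2 − 1)) is
  rejected.

What the generator does not emulate: depth-dose structure, detector
volume averaging and noise floors, heterogeneity, output drift within a
session, and rotational setup error. Passing tests therefore demonstrate
algorithmic correctness and the published qualitative signatures on
controlled inputs, not clinical performance on real measurement sets.

## Problem sizes and runtime choices

Tests and demonstrations use 13×13 to 19×19 measured grids over 100–140 mm
fields with 0.05–0.2 mm search grids — sizes at which the exhaustive
brute-force oracles (double loops over every calculated pixel) remain
cheap, and chosen as representative of a single-field array measurement.
Engine-vs-oracle equivalence is asserted to 1e-12 relative tolerance (the
engine and oracle may differ in floating-point evaluation order).

## Known limitations

- 2D only; the volumetric extension of DDM is out of scope.
- Translation-only registration; fiducial- or image-based alignment of the
  detector to the beam isocenter is a hardware-level improvement the
  software cannot supply.
- The γ search cap (3×Δd_M) can, in principle, report a larger γ than an
  unbounded search would for pixels whose best agreement is extremely far
  away; such pixels are deep failures under either reading.
- Local normalization divides by the measured pixel dose; other local
  conventions exist.
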