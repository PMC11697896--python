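# Methods

## Model

The cerebral aqueduct is treated as a quasi-steady laminar conduit of circular
cross-section whose diameter varies along its length. Each centerline element
of length ΔL and diameter D contributes a Poiseuille resistance

    R_i = 128 µ ΔL_i / (π D_i⁴),

and the trans-aqueductal pressure difference at flow rate Q is ΔP = R·Q with
R = Σ R_i. With µ in mPa·s and geometry in mm, R carries mPa·s/mm³ and R·Q
(mm³/s) gives ΔP in mPa, reported in Pa and mmHg. Defaults: µ = 0.71 mPa·s
(water at 36 °C), ρ = 1000 kg/m³.

The quasi-steady approximation is justified a posteriori by the dimensionless
numbers the package computes per element: Womersley α = (D/2)·√(ωρ/µ)
(ω = 2π / cardiac period) around 3 and Reynolds Re = 4ρQ/(πµD) well below
2000 in healthy adults. Inertial (unsteady) terms are deliberately out of
scope; at α ≈ 3 their neglect underestimates the cardiac-driven ΔP somewhat,
which is a known property of this class of estimate, not a target of this
package.

## Morphology pipeline

1. **Projection.** Maximum-intensity projection over 2–3 user-chosen sagittal
   slices (slice choice is an input; there is no automatic selection).
2. **Resampling.** Bilinear interpolation to 0.03 × 0.03 mm². Coordinates are
   0-based pixel indices; physical position = index × spacing.
3. **Threshold.** The user draws a line crossing the lumen wall at the
   narrowest point. The maximum-gradient edge along the line is located with
   a centred difference spanning one *acquisition* pixel — on an upsampled
   image the profile is piecewise linear, so a one-sample difference is
   constant across the steepest segment and its argmax is numerically
   meaningless. The threshold returned is the mid-level between the extreme
   intensities in a small 2D patch around the located edge: for a symmetric
   edge-spread function this equals the intensity at the maximum gradient,
   and reading it from the flanking levels makes it insensitive to where the
   edge falls relative to the acquisition grid. This stability matters
   because resistance scales as D⁻⁴: a half-pixel threshold ambiguity is a
   ±40 % resistance error.
4. **Binarisation.** Lumen = intensity ≥ threshold, minus an optional
   exclusion mask (e.g. cerebellar CSF). The largest connected component
   containing the start point is kept.
5. **Centerline.** Minimum-cost path between the user start/end points with
   per-pixel cost 1/(1+d²), d the distance-to-boundary in pixels, so the path
   rides the ridge of the distance transform while connectivity is
   guaranteed; resampled to one-pixel steps and smoothed with an 11-point
   moving average. Measured accuracy on phantoms: ≈ 0.02 mm mean deviation
   from the generating axis.
6. **Elements.** The path is split into n equal-arc elements (default 100).
   Per element, the diameter is the chord through the segment midpoint
   perpendicular to the local tangent, between the two 0.5-crossings of the
   bilinearly interpolated binary mask (0.25-pixel marching step, linear
   subpixel interpolation). The tangent angle is reported in degrees versus
   the image x-axis. A 100-element discretisation reproduces the continuous
   resistance integral of a smooth taper to ≈ 0.01 %.
7. **Trim.** The endpoint is the first element where cumulative resistance
   reaches 95 % of the total; R, L, Ls, D-mean, D-min, the mean Womersley
   number and the maximum Reynolds number are confined to the retained
   section (the element containing the crossing is kept whole), while
   L-defined keeps the full user-delimited length. The start point is always
   retained — the low-resistance distal flare into the 4th ventricle is what
   the rule removes.

## Flow pipeline

1. **ROI.** Per pixel, the fraction of non-DC spectral power in the cardiac
   band (default 0.7–2.5 Hz; the respiratory band is 0.1–0.5 Hz — both bands
   bracket the healthy ranges of cardiac 0.54–1.23 s and respiratory
   2.7–6.4 s periods and are configurable). The fraction map is thresholded
   by Otsu's method, floored at the midpoint between the background median
   and the map maximum (plain Otsu under-thresholds when the true region is
   a handful of pixels), and the component nearest the seed (image centre by
   default) is kept, then grown into neighbouring pixels whose velocity
   curves correlate with the core mean above 4/√n — these rim pixels carry
   real partial-volume flow that raw band power cannot separate from noise.
   A manual override mask bypasses detection.
2. **De-aliasing.** Temporal unwrapping with period 2·VENC (exact whenever
   the true inter-sample change stays below the VENC).
3. **Background.** Stationary tissue = pixels of a 3–10-pixel annulus around
   the ROI with low cardiac power fraction and temporal SD in the annulus'
   lowest quartile; their spatio-temporal mean becomes the new zero. Fallback
   (with a warning): lowest-SD decile of the whole image.
4. **Flow curve.** Q(t) = Σ_ROI v·(pixel area), positive toward the 3rd
   ventricle.
5. **Cycles and ensemble.** Cut points are flow minima (one per 0.8·Tc
   window, successive cuts within [0.6, 1.4]·Tc, Tc from the cardiac spectral
   peak); partial first/last segments are discarded; at least 3 cycles are
   required. Each cycle is cubic-spline resampled to 32 phases of its own
   duration (left-closed grid, so the period is covered without duplicating
   the wrap-around point); the ensemble mean, sample SD (k−1, equal weight
   per cycle) and limits of agreement mean ± 1.96·SD follow.
6. **Decomposition.** Qc± are the extremes of the mean cycle; Qb± are the
   excursions of the *global* LOA extremes beyond them (the alternative —
   same-phase LOA−mean gaps — would differ only when the LOA extreme shifts
   phase; the global reading matches how the envelope is drawn). SV is the
   mean of the positive and negative lobes of the mean cycle integrated over
   the mean period; Q-net its time average; Tb the dominant respiratory-band
   spectral peak of the continuous curve; D-PC the equivalent diameter of the
   ROI area.
7. **Cardiac phases.** An artery-edge flow curve on the same time base is
   resampled over the aqueduct's own cycle windows (shared phase origin);
   systole runs from its steepest upslope to the slope zero-crossing with the
   steepest following descent, and the aqueduct mean cycle is integrated over
   each phase.

ΔP metrics multiply the trimmed R by each directional flow; peak-to-peak
values are plain sums (ΔPc⁺+ΔPc⁻, ΔPb⁺+ΔPb⁻) and ΔPb/ΔPc % is computed per
dataset from its own components. The pressure "gradient curve" is the
cumulative-resistance profile times a chosen flow (Qc⁺ by default).

## Synthetic data

No reference datasets exist, so validation rests on two generators with
analytic ground truth.

**Morphological phantoms** render a planar-arc tube (default length 15 mm,
curvature 0.07 /mm → tortuosity ≈ 1.04, the healthy range) with uniform,
tapering, Gaussian-stenosis or distally flared radius profiles (lumen 100,
background 10) into 0.6 × 0.6 × 1.2 mm³ voxels by in-plane partial-volume
averaging on a supersampled grid, with optional Rician noise. The ground
truth includes the axis polyline, the radius profile, landmark suggestions
and the fine-quadrature (2·10⁵-point trapezoid) resistance oracle. The
slice direction is centre-sampled by default (thin-slice limit): integrating
over the full 1.2 mm slab softens the projected edge asymmetrically (the
through-plane chord shrinks toward the in-plane edge) and biases any
threshold-based width measurement; in that mode recovered resistance is
wrong by factors, not percents, which is an honest property of thick-slab
projections rather than of this implementation. Likewise an optional
in-plane Gaussian PSF is off by default; at a realistic σ ≈ 0.25 mm the
narrowest lumens (≈ 1 mm) no longer saturate, a single global threshold
cannot fit both narrow and wide sections, and 15–30 % resistance errors
appear. Passing the phantom suite therefore demonstrates correctness of the
measurement chain on partial-volume-limited data, not robustness to
reconstruction blur — on real acquisitions the D⁻⁴ amplification of edge
uncertainty remains the dominant error source. A perfectly straight
axis-aligned tube keeps a constant sub-voxel grid phase and shows ~+10 %
resistance error (grid-phase aliasing); any realistic curvature decorrelates
the phase along the tube and removes it.

**Velocity-series phantoms** lay a ground-truth flow Q(t) onto a
pixel-averaged parabolic profile inside a 1.5 mm-radius disk (the apparent,
partial-volume-spread calibre) on a 2 × 2 mm² grid, normalised so the
pixel-area-weighted sum equals Q(t) exactly per frame, then add a static
offset, optional supra-VENC arterial disks (wrapped into (−VENC, VENC]) and
Gaussian velocity noise. Q(t) combines a two-harmonic cardiac waveform
(trough/peak ratio 1.10; peak 169 mm³/s → mean cardiac peak ≈ 177 mm³/s)
with respiratory amplitude modulation and a baseline shift. Matching the
reported directional breath components (127/119 mm³/s, ≈ 70 % of cardiac)
under the LOA definition admits two mechanism mixes; the baseline-dominant
one (modulation 0.016, shift 88.9 mm³/s) is the default because it also
produces a genuine respiratory spectral line, making the respiratory-period
estimator meaningful. The ground truth stores the LOA-defined breath
components computed from the analytic, noise-free ensemble (the quantity the
method defines), alongside the raw mechanistic extremes.

Known quantified behaviours at the default study conditions (300 frames,
87 ms, VENC 100 mm/s, SNR 10 on the peak pixel velocity): Tc recovered to
0.2 %, Qc to ≤ 5 %, Qb overestimated by ≈ +10 % on average (the LOA SD
includes measurement noise — real acquisitions share this inflation), and
Tb quantised to the spectral bins of a 26 s record (±6 %).

## Numerical choices and degenerate inputs

- Ties in the gradient argmax break to the first sample along the line;
  binarisation uses ≥ (CSF is bright on these sequences).
- Start/end landmarks snap to the lumen within 5 pixels; disconnected
  endpoints, empty lumens, flat threshold profiles, chords that leave the
  mask (with the element index) and series with fewer than 3 complete cycles
  raise typed errors with remediation hints.
- Cycle SD uses the k−1 denominator and equal weight per cycle regardless of
  duration; LOA bounds are inclusive.
- All randomness is seeded; generators are bit-reproducible given their seed,
  and reports embed the full configuration and package version.

## Problem sizes

The validation suite uses 15–20 mm phantoms (≈ 30–40 voxels across) at the
stated voxel sizes, 100 elements, 300-frame series, 10 seeds for recovery
statistics and 200 cycles for the LOA coverage estimate; each phantom
processes in well under a second on one CPU.
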