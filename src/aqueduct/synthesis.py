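"""Synthetic inputs with known ground truth.

No reference datasets ship with the package, so every pipeline stage is
validated against phantoms generated here:

* :func:`make_phantom_volume` renders a curved tube of known radius profile
  into a 3D morphological volume with partial-volume averaging and optional
  Rician noise — emulating a high-resolution steady-state (BFFE-like)
  acquisition of the aqueduct.
* :func:`make_phantom_series` lays a known flow waveform — periodic cardiac
  pulsation, slower respiratory amplitude/baseline modulation, static-tissue
  offset, optionally aliased arterial disks and Gaussian noise — onto a 2D+t
  velocity image, emulating a real-time phase-contrast acquisition.

Both generators are deterministic given their seed and return a ground-truth
record alongside the images, including :func:`analytic_resistance`, the
fine-quadrature hydraulic-resistance oracle used by the end-to-end tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .physics import FluidConstants

__all__ = [
    "GeometrySpec",
    "FlowSpec",
    "DiskRoi",
    "uniform_radius",
    "tapered_radius",
    "stenosed_radius",
    "flared_radius",
    "make_phantom_volume",
    "analytic_resistance",
    "make_phantom_series",
    "wrap_velocity",
    "two_harmonic_waveform",
]


# ---------------------------------------------------------------------------
# radius-profile families (all return radius in mm as a function of arc s, mm)
# ---------------------------------------------------------------------------

def uniform_radius(r: float) -> Callable[[np.ndarray], np.ndarray]:
    """Constant radius tube."""
    return lambda s: np.full_like(np.asarray(s, dtype=float), r)


def tapered_radius(r_start: float, r_end: float, length: float) -> Callable[[np.ndarray], np.ndarray]:
    """Linear taper from ``r_start`` at s=0 to ``r_end`` at s=length."""
    return lambda s: r_start + (r_end - r_start) * np.asarray(s, dtype=float) / length


def stenosed_radius(
    r0: float, depth: float, width: float, center: float
) -> Callable[[np.ndarray], np.ndarray]:
    """Gaussian narrowing of given depth (mm) and width (mm, SD) at ``center``."""
    return lambda s: r0 - depth * np.exp(-((np.asarray(s, dtype=float) - center) ** 2) / (2 * width**2))


def flared_radius(
    r0: float, r_flare: float, length: float, flare_start_frac: float = 0.8
) -> Callable[[np.ndarray], np.ndarray]:
    """Uniform tube opening smoothly into a distal flare (4th-ventricle end)."""

    def profile(s: np.ndarray) -> np.ndarray:
        s = np.asarray(s, dtype=float)
        s0 = flare_start_frac * length
        ramp = np.clip((s - s0) / (length - s0), 0.0, 1.0)
        return r0 + (r_flare - r0) * 0.5 * (1 - np.cos(np.pi * ramp))

    return profile


@dataclass
class GeometrySpec:
    """Parametric description of a tubular phantom.

    The tube axis lies in one sagittal plane (constant slice coordinate):
    either straight or a planar circular arc of the given curvature.  Healthy
    aqueducts are 10–24 mm long with lumen diameters of 1.5–2.5 mm and a
    tortuosity of only 1.03–1.08, hence the defaults.
    """

    radius_profile: Callable[[np.ndarray], np.ndarray] = field(
        default_factory=lambda: uniform_radius(1.0)
    )
    length: float = 15.0  # mm
    axis_curvature: float = 0.07  # 1/mm; 0 = straight tube (healthy tortuosity ~1.04)
    spacing: tuple[float, float, float] = (1.2, 0.6, 0.6)  # (slice, row, col) mm
    lumen_intensity: float = 100.0
    background_intensity: float = 10.0
    noise_sd: float = 0.0  # Rician noise scale, intensity units
    psf_sigma: float = 0.0  # optional in-plane reconstruction PSF (Gaussian SD), mm
    supersample: tuple[int, int, int] = (1, 6, 6)  # (slice, row, col) subsamples
    margin: float = 3.0  # in-plane padding around the tube, mm
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.length > 0:
            raise ValueError("length must be positive")
        s = np.linspace(0.0, self.length, 512)
        if np.any(self.radius_profile(s) <= 0):
            raise ValueError("radius profile must be positive everywhere")

    def axis_points(self, s: np.ndarray) -> np.ndarray:
        """In-plane (y, x) axis coordinates in mm at arc positions ``s``."""
        s = np.asarray(s, dtype=float)
        k = self.axis_curvature
        if abs(k) < 1e-12:
            return np.stack([np.zeros_like(s), s], axis=-1)
        theta = k * s
        y = (1.0 - np.cos(theta)) / k
        x = np.sin(theta) / k
        return np.stack([y, x], axis=-1)

    def axis_tangents(self, s: np.ndarray) -> np.ndarray:
        s = np.asarray(s, dtype=float)
        theta = self.axis_curvature * s
        return np.stack([np.sin(theta), np.cos(theta)], axis=-1)


def analytic_resistance(
    spec: GeometrySpec,
    const: FluidConstants = FluidConstants(),
    s_start: float = 0.0,
    s_end: float | None = None,
    n_points: int = 200_001,
) -> float:
    """Fine-quadrature Poiseuille resistance of the phantom, mPa·s/mm³.

    Integrates ``128 µ / (π D(s)⁴) ds`` over ``[s_start, s_end]`` with a
    trapezoidal rule on ``n_points`` samples (default 2·10⁵); the oracle the
    image pipeline is benchmarked against.
    """
    if s_end is None:
        s_end = spec.length
    s = np.linspace(s_start, s_end, n_points)
    d = 2.0 * spec.radius_profile(s)
    integrand = 128.0 * const.mu / (math.pi * d**4)
    return float(np.trapezoid(integrand, s))


def make_phantom_volume(spec: GeometrySpec) -> tuple["np.ndarray", dict]:
    """Render the tube into a 3D volume; return ``(intensities, ground_truth)``.

    Intensities are ``background + (lumen-background)·f`` where ``f`` is the
    voxel's partial-volume fraction inside the tube, estimated on a per-axis
    subgrid given by ``spec.supersample``.  The default ``(1, 6, 6)`` samples
    each slice at its centre plane (the thin-slice limit, which keeps the
    projected lumen edge a symmetric partial-volume ramp) while averaging
    over the in-plane voxel footprint; set the slice factor above 1 to
    integrate over the full slab thickness instead, which softens the
    projected edge asymmetrically the way thick-slice acquisitions do.
    Rician noise (magnitude of a complex Gaussian) is added when
    ``noise_sd > 0``.  The array is indexed ``(slice, row, col)`` with voxel
    size ``spec.spacing``; the tube axis sits at the centre of the middle
    slice.

    The ground-truth record carries the analytic axis polyline, radius
    profile, landmark suggestions and the quadrature resistance oracle.
    """
    dz, dy, dx = spec.spacing
    ds = 0.02
    s_fine = np.arange(0.0, spec.length + ds / 2, ds)
    axis = spec.axis_points(s_fine)  # (N, 2) in (y, x) mm
    radii = np.asarray(spec.radius_profile(s_fine), dtype=float)
    r_max = float(radii.max())
    if 2 * radii.min() < 2 * min(dy, dx):  # lumen narrower than 2 in-plane voxels
        import warnings

        warnings.warn("tube lumen under-resolved by the voxel grid", stacklevel=2)

    # grid extents: in-plane bounding box of the axis plus radius and margin
    y_lo = axis[:, 0].min() - r_max - spec.margin
    y_hi = axis[:, 0].max() + r_max + spec.margin
    x_lo = axis[:, 1].min() - r_max - spec.margin
    x_hi = axis[:, 1].max() + r_max + spec.margin
    ny = int(math.ceil((y_hi - y_lo) / dy))
    nx = int(math.ceil((x_hi - x_lo) / dx))
    # slices: axis at the centre of the middle slice
    half_z = r_max + dz
    nz = 2 * int(math.ceil(half_z / dz)) + 1
    z_axis = (nz // 2 + 0.5) * dz  # mm, centre of middle slice
    origin_y, origin_x = y_lo, x_lo  # mm position of voxel (row=0/col=0) corner

    fz, fy, fx = (max(1, int(f)) for f in spec.supersample)
    zc = (np.add.outer(np.arange(nz), (np.arange(fz) + 0.5) / fz)).ravel() * dz
    yc = (np.add.outer(np.arange(ny), (np.arange(fy) + 0.5) / fy)).ravel() * dy + origin_y
    xc = (np.add.outer(np.arange(nx), (np.arange(fx) + 0.5) / fx)).ravel() * dx + origin_x

    tree = cKDTree(axis)
    yy, xx = np.meshgrid(yc, xc, indexing="ij")
    pts = np.stack([yy.ravel(), xx.ravel()], axis=-1)
    d2d, idx = tree.query(pts, workers=-1)
    r_here = radii[idx]
    d2d_sq = (d2d**2).reshape(ny * fy, nx * fx)
    r_sq = (r_here**2).reshape(ny * fy, nx * fx)

    frac = np.empty((nz, ny, nx), dtype=float)
    dz_axis_sq = (zc - z_axis) ** 2
    for iz in range(nz):
        sl = dz_axis_sq[iz * fz : (iz + 1) * fz]
        inside = d2d_sq[None, :, :] + sl[:, None, None] <= r_sq[None, :, :]
        sub_frac = inside.mean(axis=0)  # averaged over slice-direction subsamples
        if spec.psf_sigma > 0:
            # in-plane reconstruction point-spread (k-space apodisation),
            # applied to the continuous object before voxel averaging
            sub_frac = ndimage.gaussian_filter(
                sub_frac, sigma=(spec.psf_sigma / (dy / fy), spec.psf_sigma / (dx / fx))
            )
        frac[iz] = sub_frac.reshape(ny, fy, nx, fx).mean(axis=(1, 3))

    intensities = spec.background_intensity + (
        spec.lumen_intensity - spec.background_intensity
    ) * frac
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        g1 = rng.normal(0.0, spec.noise_sd, intensities.shape)
        g2 = rng.normal(0.0, spec.noise_sd, intensities.shape)
        intensities = np.sqrt((intensities + g1) ** 2 + g2**2)

    # landmark suggestions (all in mm, in-plane image coordinates (y, x)
    # relative to the pixel (0, 0) *centre* of the projection)
    axis_img = axis - np.array([origin_y + 0.5 * dy, origin_x + 0.5 * dx])
    # draw the threshold line at the narrowest *interior* point, away from
    # the rounded end caps where the profile is not a clean tube crossing
    interior = (s_fine >= 0.15 * spec.length) & (s_fine <= 0.85 * spec.length)
    i_narrow = int(np.flatnonzero(interior)[np.argmin(radii[interior])])
    tang = spec.axis_tangents(s_fine[i_narrow : i_narrow + 1])[0]
    normal = np.array([tang[1], -tang[0]])
    reach = radii[i_narrow] + 1.5
    line = (axis_img[i_narrow] - normal * reach, axis_img[i_narrow] + normal * reach)

    inset = 0.75  # keep landmarks clear of the rounded end caps, mm
    i0 = int(np.searchsorted(s_fine, inset))
    i1 = int(np.searchsorted(s_fine, spec.length - inset))
    mid = nz // 2
    ground_truth = {
        "s_mm": s_fine,
        "axis_mm": axis_img,  # projection-plane coordinates
        "radius_mm": radii,
        "z_axis_mm": z_axis,
        "origin_yx_mm": (origin_y, origin_x),
        "slice_indices": [mid - 1, mid, mid + 1],
        "start_yx_mm": tuple(axis_img[i0]),
        "end_yx_mm": tuple(axis_img[i1]),
        "landmark_inset_mm": inset,
        "threshold_line_mm": (tuple(line[0]), tuple(line[1])),
        "analytic_resistance": analytic_resistance(spec),
        "analytic_resistance_landmarked": analytic_resistance(
            spec, s_start=inset, s_end=spec.length - inset
        ),
        "length_landmarked_mm": spec.length - 2 * inset,
    }
    return intensities, ground_truth


# ---------------------------------------------------------------------------
# velocity-series phantom
# ---------------------------------------------------------------------------

def wrap_velocity(v: np.ndarray, venc: float) -> np.ndarray:
    """Alias velocities into ``(-venc, venc]`` by multiples of 2·venc."""
    return -(np.mod(-(np.asarray(v, dtype=float)) + venc, 2.0 * venc) - venc)


def two_harmonic_waveform(amp2: float = 0.45, phase2: float = 2.9) -> np.ndarray:
    """Harmonic description of the default cardiac flow shape.

    Returns the (amplitude, phase) rows of the fundamental and second
    harmonic: a fast systolic peak with a slower return, qualitatively the
    shape seen in aqueductal CSF flow.  The defaults give a trough-to-peak
    magnitude ratio of 1.10, matching the observed asymmetry between the
    two flow directions in healthy adults (peak flow toward the 3rd
    ventricle ≈ 169 mm³/s versus ≈ 186 mm³/s toward the 4th).  The waveform
    is normalised at use time so its maximum equals the requested peak flow.
    """
    return np.array([[1.0, 0.0], [amp2, phase2]])


@dataclass
class DiskRoi:
    """Circular flow-carrying region on the velocity image (mm units)."""

    center: tuple[float, float] | None = None  # (y, x) mm; None = image centre
    radius: float = 1.5  # mm; apparent aqueduct radius on phase images


@dataclass
class ArteryDisk:
    """Artery-like disk with supra-VENC velocity for aliasing tests."""

    center: tuple[float, float]  # (y, x) mm
    radius: float = 2.0  # mm
    mean_velocity: float = 120.0  # mm/s (above a 100 mm/s VENC => aliases)
    pulse_amplitude: float = 60.0  # mm/s


@dataclass
class FlowSpec:
    """Generator settings for a synthetic real-time phase-contrast series.

    Defaults reproduce the healthy-adult regime: cardiac period 0.85 s,
    respiratory period 4.1 s, directional cardiac peak flows of ~169 (4th→3rd)
    and ~186 mm³/s (3rd→4th, mean peak 177), and a breath-driven component of
    roughly 70 % of the cardiac one.  Breathing acts through two mechanisms —
    amplitude scaling of the cardiac waveform (``mod_depth``) and a baseline
    shift (``baseline_amp``); their defaults are calibrated so that the
    95 %-limits-of-agreement breath-driven peaks of the noise-free ensemble
    are ~127 (4th→3rd) and ~119 mm³/s, the values reported for free
    breathing.  Because both mechanisms ride the same respiratory phase,
    those near-symmetric directional values together with the asymmetric
    cardiac waveform pin the mix to a baseline-shift-dominant solution; a
    modulation-dominant solution (mod_depth 0.5, baseline_amp 7) reproduces
    the same Qb± but leaves almost no direct respiratory spectral line.
    """

    tc: float = 0.85  # cardiac period, s
    tb: float = 4.1  # respiratory period, s
    qc_peak: float = 169.0  # peak 4th->3rd cardiac flow, mm³/s (mean peak Qc ~ 177)
    waveform: np.ndarray | str = "two-harmonic"  # harmonic table or "sine"
    mod_depth: float = 0.016  # respiratory amplitude modulation, fraction
    baseline_amp: float = 88.9  # respiratory baseline shift, mm³/s
    offset: float = 0.0  # static-tissue velocity offset, mm/s
    noise_sd: float = 0.0  # velocity noise SD, mm/s
    n_frames: int = 300
    dt: float = 0.087  # s/frame
    venc: float = 100.0  # mm/s
    pixel_size: float = 2.0  # mm
    shape: tuple[int, int] = (32, 32)
    arteries: Sequence[ArteryDisk] = ()
    supersample: int = 8  # subsamples per pixel axis for disk coverage
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.tc < self.tb:
            raise ValueError("cardiac period must be shorter than respiratory period")
        if self.n_frames * self.dt <= 3 * self.tb:
            raise ValueError("series must span more than 3 respiratory cycles")

    def harmonics(self) -> np.ndarray:
        if isinstance(self.waveform, str):
            if self.waveform == "sine":
                return np.array([[1.0, 0.0]])
            if self.waveform == "two-harmonic":
                return two_harmonic_waveform()
            raise ValueError(f"unknown waveform {self.waveform!r}")
        return np.asarray(self.waveform, dtype=float)

    def cardiac_waveform(self, t: np.ndarray) -> np.ndarray:
        """Zero-mean cardiac flow waveform, scaled to peak ``qc_peak``."""
        h = self.harmonics()
        phase = 2.0 * math.pi * np.asarray(t, dtype=float) / self.tc

        def raw(ph: np.ndarray) -> np.ndarray:
            out = np.zeros_like(ph)
            for k, (a, p0) in enumerate(h, start=1):
                out += a * np.sin(k * ph + p0)
            return out

        ref = raw(np.linspace(0.0, 2.0 * math.pi, 4096, endpoint=False))
        return self.qc_peak * raw(phase) / ref.max()

    def true_flow(self, t: np.ndarray) -> np.ndarray:
        """Ground-truth aqueduct flow rate Q(t), mm³/s."""
        resp = np.sin(2.0 * math.pi * np.asarray(t, dtype=float) / self.tb)
        return (1.0 + self.mod_depth * resp) * self.cardiac_waveform(t) + self.baseline_amp * resp


def _disk_coverage(
    shape: tuple[int, int], pixel_size: float, center: tuple[float, float], radius: float, f: int
) -> np.ndarray:
    """Fractional pixel coverage of a disk, by subpixel sampling."""
    ny, nx = shape
    sub = (np.arange(f) + 0.5) / f
    y = (np.add.outer(np.arange(ny), sub).ravel() + 0.0) * pixel_size
    x = (np.add.outer(np.arange(nx), sub).ravel() + 0.0) * pixel_size
    yy, xx = np.meshgrid(y - center[0], x - center[1], indexing="ij")
    inside = (yy**2 + xx**2 <= radius**2).astype(float)
    return inside.reshape(ny, f, nx, f).mean(axis=(1, 3))


def _parabolic_weights(
    shape: tuple[int, int], pixel_size: float, center: tuple[float, float], radius: float, f: int
) -> np.ndarray:
    """Pixel-averaged Poiseuille (parabolic) profile, arbitrary scale."""
    ny, nx = shape
    sub = (np.arange(f) + 0.5) / f
    y = np.add.outer(np.arange(ny), sub).ravel() * pixel_size
    x = np.add.outer(np.arange(nx), sub).ravel() * pixel_size
    yy, xx = np.meshgrid(y - center[0], x - center[1], indexing="ij")
    rr = (yy**2 + xx**2) / radius**2
    prof = np.clip(1.0 - rr, 0.0, None)
    return prof.reshape(ny, f, nx, f).mean(axis=(1, 3))


def _true_cycle_metrics(spec: FlowSpec, duration: float, n_phase: int = 32) -> dict:
    """Cycle-ensemble ground truth from the analytic flow curve.

    Cuts the noise-free Q(t) at the exact cardiac-waveform minima, resamples
    each cycle at ``n_phase`` phases analytically, and applies the ensemble
    definitions (mean cycle, SD, mean ± 1.96·SD limits of agreement).  The
    breath-driven truth is defined through the same LOA convention the
    estimator targets; the mechanistic extremes (modulation of the peak plus
    baseline shift) are recorded separately.
    """
    # phase of the waveform minimum within one period
    tt = np.linspace(0.0, spec.tc, 8192, endpoint=False)
    t_min = float(tt[np.argmin(spec.cardiac_waveform(tt))])
    starts = np.arange(t_min, duration - spec.tc + 1e-12, spec.tc)
    phases = np.arange(n_phase) / n_phase * spec.tc
    cyc = np.stack([spec.true_flow(s + phases) for s in starts])
    mean = cyc.mean(axis=0)
    sd = cyc.std(axis=0, ddof=1)
    qc_plus = float(mean.max())
    qc_minus = float(-mean.min())
    qb_plus = float((mean + 1.96 * sd).max() - qc_plus)
    qb_minus = float(-(mean - 1.96 * sd).min() - qc_minus)
    wave_peak = spec.qc_peak
    wave_trough = float(-spec.cardiac_waveform(tt).min())
    return {
        "qc_plus": qc_plus,
        "qc_minus": qc_minus,
        "qc": 0.5 * (qc_plus + qc_minus),
        "qb_plus": qb_plus,
        "qb_minus": qb_minus,
        "qb": 0.5 * (qb_plus + qb_minus),
        "qb_plus_mechanistic": spec.mod_depth * wave_peak + spec.baseline_amp,
        "qb_minus_mechanistic": spec.mod_depth * wave_trough + spec.baseline_amp,
        "q_net": float(mean.mean()),
        "sv": float(
            0.5 * (np.clip(mean, 0, None).sum() + np.clip(-mean, 0, None).sum()) * spec.tc / n_phase
        ),
        "n_cycles": len(starts),
    }


def make_phantom_series(spec: FlowSpec, roi_geometry: DiskRoi | None = None) -> tuple[np.ndarray, dict]:
    """Render a 2D+t velocity series; return ``(velocities, ground_truth)``.

    The ground-truth flow ``Q(t)`` is laid onto a pixel-averaged parabolic
    profile inside the aqueduct disk and normalised so that the pixel-area
    weighted sum inside the true region equals ``Q(t)`` exactly at every
    frame, before offset, arteries and noise are applied.  Velocities are
    wrapped into ``(-venc, venc]`` (aliasing) after all contributions.
    """
    roi = roi_geometry or DiskRoi()
    ny, nx = spec.shape
    center = roi.center or ((ny // 2 + 0.5) * spec.pixel_size, (nx // 2 + 0.5) * spec.pixel_size)
    pixel_area = spec.pixel_size**2
    if math.pi * roi.radius**2 < pixel_area:
        raise ValueError("aqueduct disk smaller than one pixel")

    weights = _parabolic_weights(spec.shape, spec.pixel_size, center, roi.radius, spec.supersample)
    roi_true = weights > 0
    weights /= weights.sum() * pixel_area  # so that sum(v*area) == Q

    t = np.arange(spec.n_frames) * spec.dt
    q_true = spec.true_flow(t)
    vel = q_true[:, None, None] * weights[None, :, :]
    vel += spec.offset

    for artery in spec.arteries:
        cov = _disk_coverage(spec.shape, spec.pixel_size, artery.center, artery.radius, spec.supersample)
        pulse = artery.mean_velocity + artery.pulse_amplitude * np.sin(
            2.0 * math.pi * t / spec.tc
        )
        vel += pulse[:, None, None] * cov[None, :, :]

    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        vel = vel + rng.normal(0.0, spec.noise_sd, vel.shape)

    vel = wrap_velocity(vel, spec.venc)

    ground_truth = {
        "times": t,
        "q_true": q_true,
        "tc": spec.tc,
        "tb": spec.tb,
        "qc_peak": spec.qc_peak,
        "offset": spec.offset,
        "roi_mask": roi_true,
        "roi_weights": weights,
        "roi_center_mm": center,
        "roi_radius_mm": roi.radius,
        "pixel_area_mm2": pixel_area,
        **_true_cycle_metrics(spec, spec.n_frames * spec.dt),
    }
    return vel, ground_truth
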