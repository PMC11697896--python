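"""End-to-end pipelines tying the processing stages together.

Each ``run_*`` function consumes a configuration dictionary (mirrored by the
command-line interface), executes the corresponding pipeline and writes JSON
and text/CSV reports; the functional cores (``morphology_pipeline``,
``flow_pipeline``) operate on in-memory objects and are what the tests and
the acceptance script drive.

Landmark and ROI sidecar coordinates refer to 0-based pixel indices of the
*acquired* grids (the projection's in-plane grid for morphology, the
velocity image grid for flow); the morphology pipeline rescales them to the
enhanced-resolution grid internally.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np

from . import io as aqio
from . import flow as fl
from . import morphology as mo
from .physics import FluidConstants
from .pressure import PressureMetrics, compute_pressure_metrics, pressure_gradient_curve

logger = logging.getLogger("aqueduct")

__all__ = ["morphology_pipeline", "flow_pipeline", "run_morpho", "run_flow", "run_deltap", "run_simulate"]


def morphology_pipeline(
    volume: mo.MorphVolume,
    landmarks: mo.Landmarks,
    slice_indices: list[int],
    n_elements: int = 100,
    target_spacing: float = 0.03,
    const: FluidConstants = FluidConstants(),
    cardiac_period: float = 0.85,
    peak_flow: float = 177.0,
) -> mo.AqueductModel:
    """MIP → resample → threshold → binarise → centerline → elements →
    resistance profile → 95 % trim → dimensionless summaries.

    Landmark coordinates are given on the projection's acquired grid and are
    rescaled to the enhanced grid here.
    """
    if n_elements < 10:
        import warnings

        warnings.warn(f"n_elements={n_elements} is a coarse discretisation", stacklevel=2)
    logger.info("MIP over slices %s", slice_indices)
    proj = mo.mip_project(volume, slice_indices)
    landmarks.validate_bounds(proj.intensities.shape)
    logger.info("resampling %s px -> %.3g mm", proj.intensities.shape, target_spacing)
    img = mo.resample_image(proj, target_spacing)
    sy = proj.spacing[0] / target_spacing
    sx = proj.spacing[1] / target_spacing
    scale = np.array([sy, sx])

    def px(pt) -> tuple[float, float]:
        return tuple(np.asarray(pt, dtype=float) * scale)

    line = (px(landmarks.threshold_line[0]), px(landmarks.threshold_line[1]))
    threshold = mo.gradient_threshold(img, line, gradient_scale=max(proj.spacing))
    logger.info("binarisation threshold %.3g", threshold)
    mask = landmarks.exclusion_mask
    if mask is not None and mask.shape != img.intensities.shape:
        from scipy import ndimage as ndi

        zoom = (img.intensities.shape[0] / mask.shape[0], img.intensities.shape[1] / mask.shape[1])
        mask = ndi.zoom(mask.astype(float), zoom, order=0) > 0.5
    binary = mo.binarize(img, threshold, mask)
    path = mo.extract_centerline(binary, px(landmarks.start_point), px(landmarks.end_point))
    logger.info("centerline length %.2f mm", path.length)
    elements = mo.build_elements(binary, path, n_elements)
    profile = mo.resistance_profile(elements, const, path=path)
    model = mo.trim_endpoint_95(profile)
    model = mo.summarize_morphology(model, cardiac_period, peak_flow, const)
    logger.info("R=%.2f mPa·s/mm³ over %d/%d elements", model.R, model.endpoint_index_95, n_elements)
    return model


def flow_pipeline(
    series: fl.VelocitySeries,
    override_mask: np.ndarray | None = None,
    seed_point: tuple[float, float] | None = None,
    cardiac_band: tuple[float, float] = fl.CARDIAC_BAND,
    respiratory_band: tuple[float, float] = fl.RESPIRATORY_BAND,
    n_phase: int = 32,
    arterial_mask: np.ndarray | None = None,
) -> dict:
    """ROI detection → de-aliasing → background correction → flow curve →
    cycle segmentation → 32-point ensemble → cardiac/breath metrics.

    Returns a dict with the intermediate objects (``roi``, ``curve``,
    ``cycles``, ``ensemble``) and the final ``metrics``; adds ``phases``
    when an arterial-edge mask is supplied.
    """
    roi = fl.detect_roi(series, cardiac_band, seed_point, override_mask)
    logger.info("ROI: %d px, D-PC %.2f mm", int(roi.mask.sum()), roi.equivalent_diameter)
    unwrapped = fl.dealias(series.velocities, series.venc)
    series = fl.VelocitySeries(unwrapped, series.dt, series.pixel_area, series.venc)
    series = fl.background_correct(series, roi, cardiac_band)
    curve = fl.compute_flow_curve(series, roi)
    cycles = fl.segment_cycles(curve, cardiac_band=cardiac_band)
    ensemble = fl.build_ensemble(cycles, n_phase)
    metrics = fl.flow_metrics(ensemble, curve, roi, respiratory_band)
    logger.info(
        "Tc=%.3f s, Qc=%.1f, Qb=%.1f mm³/s over %d cycles",
        metrics.Tc, metrics.Qc, metrics.Qb, ensemble.n_cycles,
    )
    out = {"roi": roi, "curve": curve, "cycles": cycles, "ensemble": ensemble, "metrics": metrics}
    if arterial_mask is not None:
        art_roi = fl.RoiMask(arterial_mask, series.pixel_area)
        art_curve = fl.compute_flow_curve(series, art_roi)
        out["phases"] = fl.cardiac_phase_split(art_curve, cycles, n_phase)
    return out


# ---------------------------------------------------------------------------
# file-level runners
# ---------------------------------------------------------------------------

def run_morpho(cfg: dict) -> dict:
    """Morphology pipeline on files; writes ``morpho.json`` + ``morpho.txt``."""
    volume = aqio.load_volume(cfg["volume"], cfg.get("spacing"))
    proj_shape = volume.intensities.shape[1:]
    side = aqio.load_landmarks(cfg["landmarks"], proj_shape)
    slice_indices = cfg.get("slice_indices") or side["slice_indices"]
    if slice_indices is None:
        raise ValueError("slice indices required (CLI flag or landmark sidecar)")
    const = FluidConstants(cfg.get("mu", 0.71), cfg.get("rho", 1000.0))
    model = morphology_pipeline(
        volume,
        side["landmarks"],
        list(slice_indices),
        n_elements=cfg.get("n_elements", 100),
        target_spacing=cfg.get("target_spacing", 0.03),
        const=const,
        cardiac_period=cfg.get("cardiac_period", 0.85),
        peak_flow=cfg.get("peak_flow", 177.0),
    )
    out_dir = Path(cfg.get("out_dir", "."))
    payload = {
        "R": model.R,
        "L": model.L,
        "Ls": model.Ls,
        "L_over_Ls": model.tortuosity,
        "L_defined": model.L_defined,
        "D_mean": model.D_mean,
        "D_min": model.D_min,
        "womersley_mean": model.womersley_mean,
        "reynolds_max": model.reynolds_max,
        "endpoint_index_95": model.endpoint_index_95,
        "total_resistance_untrimmed": model.profile.total,
        "elements": [
            {"length": e.length, "diameter": e.diameter, "tangent_angle": e.tangent_angle,
             "r": float(r), "cumulative_r": float(c)}
            for e, r, c in zip(model.profile.elements, model.profile.r_per_element,
                               model.profile.cumulative_r)
        ],
    }
    aqio.save_report(out_dir / "morpho.json", payload, cfg)
    aqio.write_text_table(
        out_dir / "morpho.txt",
        [
            ("R", model.R, "mPa·s/mm³"),
            ("L", model.L, "mm"),
            ("Ls", model.Ls, "mm"),
            ("L/Ls", model.tortuosity, "-"),
            ("L-defined", model.L_defined, "mm"),
            ("D-mean", model.D_mean, "mm"),
            ("D-min", model.D_min, "mm"),
            ("Womersley-mean", model.womersley_mean, "-"),
            ("Reynold-max", model.reynolds_max, "-"),
        ],
    )
    return payload


def run_flow(cfg: dict) -> dict:
    """Flow pipeline on files; writes ``flow.json`` + curve CSVs."""
    if "venc" not in cfg or "dt" not in cfg or "pixel_size" not in cfg:
        raise ValueError("dt, venc and pixel_size are required")
    series = aqio.load_velocity_series(
        cfg["series"], cfg["dt"], cfg["venc"], cfg["pixel_size"], cfg.get("velocity_unit", "mm/s")
    )
    shape = series.velocities.shape[1:]
    override = aqio.load_roi_mask(cfg["roi_mask"], shape) if cfg.get("roi_mask") else None
    arterial = aqio.load_roi_mask(cfg["arterial_roi"], shape) if cfg.get("arterial_roi") else None
    res = flow_pipeline(
        series,
        override_mask=override,
        seed_point=cfg.get("seed_point"),
        cardiac_band=tuple(cfg.get("cardiac_band", fl.CARDIAC_BAND)),
        respiratory_band=tuple(cfg.get("respiratory_band", fl.RESPIRATORY_BAND)),
        n_phase=cfg.get("n_phase", 32),
        arterial_mask=arterial,
    )
    m: fl.FlowMetrics = res["metrics"]
    ens: fl.CycleEnsemble = res["ensemble"]
    payload = {
        "Qc_plus": m.Qc_plus, "Qc_minus": m.Qc_minus, "Qc": m.Qc,
        "Qb_plus": m.Qb_plus, "Qb_minus": m.Qb_minus, "Qb": m.Qb,
        "SV": m.SV, "Q_net": m.Q_net, "Tc": m.Tc, "Tb": m.Tb, "D_PC": m.D_PC,
        "n_cycles": ens.n_cycles,
        "roi_pixels": np.argwhere(res["roi"].mask),
        "mean_curve": ens.mean_curve, "sd_curve": ens.sd_curve,
        "loa_upper": ens.loa_upper, "loa_lower": ens.loa_lower,
    }
    if "phases" in res:
        ph = res["phases"]
        payload["cardiac_phases"] = {
            "systole_start": ph.systole_start, "systole_end": ph.systole_end,
            "systolic_volume": ph.systolic_volume, "diastolic_volume": ph.diastolic_volume,
        }
    out_dir = Path(cfg.get("out_dir", "."))
    aqio.save_report(out_dir / "flow.json", payload, cfg)
    import pandas as pd

    pd.DataFrame({"time_s": res["curve"].times, "flow_mm3_s": res["curve"].flow}).to_csv(
        out_dir / "flow_curve.csv", index=False
    )
    pd.DataFrame(
        {
            "phase": np.arange(ens.n_phase) / ens.n_phase,
            "mean": ens.mean_curve, "sd": ens.sd_curve,
            "loa_upper": ens.loa_upper, "loa_lower": ens.loa_lower,
        }
    ).to_csv(out_dir / "flow_cycle.csv", index=False)
    return payload


def run_deltap(cfg: dict) -> dict:
    """Combine morphology and flow reports into the pressure report."""
    morpho = aqio.load_report(cfg["morpho_json"])
    flow = aqio.load_report(cfg["flow_json"])
    aqio.check_subject_match(morpho, flow)
    fm = fl.FlowMetrics(
        Qc_plus=flow["Qc_plus"], Qc_minus=flow["Qc_minus"],
        Qb_plus=flow["Qb_plus"], Qb_minus=flow["Qb_minus"],
        SV=flow["SV"], Q_net=flow["Q_net"], Tc=flow["Tc"], Tb=flow["Tb"], D_PC=flow["D_PC"],
    )
    pm: PressureMetrics = compute_pressure_metrics(morpho["R"], fm)
    # rebuild the trimmed resistance profile for the gradient curve
    from .physics import ElementGeometry

    n95 = morpho["endpoint_index_95"]
    elements = [
        ElementGeometry(e["length"], e["diameter"], e["tangent_angle"])
        for e in morpho["elements"][:n95]
    ]
    profile = mo.resistance_profile(elements, FluidConstants(
        (morpho.get("config") or {}).get("mu", 0.71), (morpho.get("config") or {}).get("rho", 1000.0)
    ))
    q_grad = cfg.get("gradient_flow", fm.Qc_plus)
    grad = pressure_gradient_curve(profile, q_grad)
    payload = {
        "dPc_plus": pm.dPc_plus, "dPc_minus": pm.dPc_minus, "dPc": pm.dPc,
        "dPb_plus": pm.dPb_plus, "dPb_minus": pm.dPb_minus, "dPb": pm.dPb,
        "p2p_cardiac_pa": pm.p2p_cardiac, "p2p_breath_pa": pm.p2p_breath,
        "p2p_cardiac_mmhg": pm.p2p_cardiac_mmhg, "p2p_breath_mmhg": pm.p2p_breath_mmhg,
        "ratio_b_over_c_pct": pm.ratio_b_over_c,
        "gradient_flow": q_grad,
        "gradient_arclength_mm": grad.arclength,
        "gradient_delta_p_pa": grad.delta_p,
    }
    out_dir = Path(cfg.get("out_dir", "."))
    aqio.save_report(out_dir / "deltap.json", payload, cfg)
    import pandas as pd

    pd.DataFrame({"arclength_mm": grad.arclength, "delta_p_pa": grad.delta_p}).to_csv(
        out_dir / "deltap_gradient.csv", index=False
    )
    aqio.write_text_table(
        out_dir / "deltap.txt",
        [
            ("dPc+", pm.dPc_plus, "Pa"), ("dPc-", pm.dPc_minus, "Pa"), ("dPc", pm.dPc, "Pa"),
            ("dPb+", pm.dPb_plus, "Pa"), ("dPb-", pm.dPb_minus, "Pa"), ("dPb", pm.dPb, "Pa"),
            ("p2p cardiac", pm.p2p_cardiac, "Pa"),
            ("p2p breath", pm.p2p_breath, "Pa"),
            ("p2p cardiac", pm.p2p_cardiac_mmhg, "mmHg"),
            ("p2p breath", pm.p2p_breath_mmhg, "mmHg"),
            ("dPb/dPc", pm.ratio_b_over_c, "%"),
        ],
    )
    return payload


def run_simulate(cfg: dict) -> dict:
    """Generate phantom inputs (volume or velocity series) with ground truth."""
    from . import synthesis as syn

    out_dir = Path(cfg.get("out_dir", "."))
    out_dir.mkdir(parents=True, exist_ok=True)
    kind = cfg.get("kind", "volume")
    seed = cfg.get("seed", 0)
    import nibabel as nib

    if kind == "volume":
        profiles = {
            "uniform": syn.uniform_radius(cfg.get("radius", 1.0)),
            "taper": syn.tapered_radius(cfg.get("radius", 1.25), cfg.get("radius_end", 0.5),
                                        cfg.get("length", 15.0)),
            "stenosis": syn.stenosed_radius(cfg.get("radius", 1.1), cfg.get("depth", 0.5),
                                            cfg.get("width", 2.0), cfg.get("length", 15.0) / 2),
            "flare": syn.flared_radius(cfg.get("radius", 1.0), cfg.get("radius_end", 1.8),
                                       cfg.get("length", 15.0)),
        }
        spec = syn.GeometrySpec(
            radius_profile=profiles[cfg.get("profile", "uniform")],
            length=cfg.get("length", 15.0),
            axis_curvature=cfg.get("curvature", 0.07),
            noise_sd=cfg.get("noise_sd", 0.0),
            seed=seed,
        )
        vol, gt = syn.make_phantom_volume(spec)
        affine = np.diag([*spec.spacing, 1.0])
        nib.save(nib.Nifti1Image(vol.astype(np.float32), affine), out_dir / "phantom_volume.nii.gz")
        dy = spec.spacing[1]
        to_px = lambda p: [float(p[0]) / dy, float(p[1]) / spec.spacing[2]]
        sidecar = {
            "indexing": "0-based",
            "threshold_line": [to_px(gt["threshold_line_mm"][0]), to_px(gt["threshold_line_mm"][1])],
            "start_point": to_px(gt["start_yx_mm"]),
            "end_point": to_px(gt["end_yx_mm"]),
            "slice_indices": gt["slice_indices"],
        }
        import json

        (out_dir / "landmarks.json").write_text(json.dumps(sidecar, indent=1))
        aqio.save_report(out_dir / "ground_truth.json", {
            "analytic_resistance": gt["analytic_resistance"],
            "analytic_resistance_landmarked": gt["analytic_resistance_landmarked"],
            "length_landmarked_mm": gt["length_landmarked_mm"],
            "axis_mm": gt["axis_mm"], "radius_mm": gt["radius_mm"], "s_mm": gt["s_mm"],
        }, cfg)
        return {"volume": str(out_dir / "phantom_volume.nii.gz")}

    if kind == "series":
        spec = syn.FlowSpec(
            tc=cfg.get("tc", 0.85), tb=cfg.get("tb", 4.1),
            qc_peak=cfg.get("qc_peak", 169.0),
            noise_sd=cfg.get("noise_sd", 0.0), offset=cfg.get("offset", 0.0),
            n_frames=cfg.get("n_frames", 300), dt=cfg.get("dt", 0.087),
            venc=cfg.get("venc", 100.0), seed=seed,
        )
        vel, gt = syn.make_phantom_series(spec)
        affine = np.diag([spec.pixel_size, spec.pixel_size, spec.dt, 1.0])
        nib.save(
            nib.Nifti1Image(np.moveaxis(vel, 0, 2).astype(np.float32), affine),
            out_dir / "phantom_series.nii.gz",
        )
        import json

        (out_dir / "roi_true.json").write_text(json.dumps(
            {"pixels": np.argwhere(gt["roi_mask"]).tolist()}, indent=1
        ))
        aqio.save_report(out_dir / "ground_truth.json", {
            k: gt[k] for k in ("times", "q_true", "tc", "tb", "qc_plus", "qc_minus", "qc",
                               "qb_plus", "qb_minus", "qb", "offset")
        }, cfg)
        return {"series": str(out_dir / "phantom_series.nii.gz")}

    raise ValueError(f"unknown simulation kind {kind!r}")
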