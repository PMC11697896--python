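"""Readers and writers for the pipeline's inputs and reports.

Images come in as NIfTI (.nii/.nii.gz) files or DICOM series directories;
landmarks and regions of interest as JSON sidecars with 0-based pixel
coordinates; results go out as JSON (full double precision, with the run
configuration and package version embedded for provenance) plus
human-readable tab-delimited text and CSV tables.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, is_dataclass
from pathlib import Path
from typing import Any

import numpy as np

from .flow import VelocitySeries
from .morphology import Landmarks, MorphVolume


def _read_dicom_stack(directory: Path) -> tuple[np.ndarray, dict]:
    """Read a DICOM series directory, sorted by instance number."""
    import pydicom

    files = sorted(p for p in directory.iterdir() if p.is_file() and not p.name.startswith("."))
    slices = []
    for f in files:
        try:
            ds = pydicom.dcmread(str(f))
        except Exception:
            continue
        slices.append(ds)
    if not slices:
        raise IOError(f"no readable DICOM files in {directory}")
    slices.sort(key=lambda d: int(getattr(d, "InstanceNumber", 0)))
    arr = np.stack([s.pixel_array.astype(float) for s in slices])
    first = slices[0]
    meta = {
        "pixel_spacing": [float(v) for v in getattr(first, "PixelSpacing", [1.0, 1.0])],
        "slice_thickness": float(getattr(first, "SliceThickness", 1.0)),
    }
    # apply rescale slope/intercept when present (phase images store scaled values)
    slope = float(getattr(first, "RescaleSlope", 1.0))
    intercept = float(getattr(first, "RescaleIntercept", 0.0))
    if slope != 1.0 or intercept != 0.0:
        arr = arr * slope + intercept
    return arr, meta


def load_volume(path: str | Path, spacing: tuple[float, float, float] | None = None) -> MorphVolume:
    """Load a 3D morphological volume (NIfTI file or DICOM directory).

    The first array axis is the slice-select axis.  ``spacing`` overrides
    the header voxel size (slice, row, col) in mm.
    """
    path = Path(path)
    if path.is_dir():
        arr, meta = _read_dicom_stack(path)
        sp = spacing or (meta["slice_thickness"], *meta["pixel_spacing"])
        return MorphVolume(arr, tuple(float(s) for s in sp))
    import nibabel as nib

    img = nib.load(str(path))
    arr = np.asanyarray(img.dataobj, dtype=float)
    if arr.ndim != 3:
        raise IOError(f"expected a 3D volume, got shape {arr.shape}")
    sp = spacing or tuple(float(z) for z in img.header.get_zooms()[:3])
    return MorphVolume(arr, tuple(sp))


def load_velocity_series(
    path: str | Path,
    dt: float,
    venc: float,
    pixel_size: float,
    velocity_unit: str = "mm/s",
) -> VelocitySeries:
    """Load a 2D+t velocity series (NIfTI with time as third axis, or DICOM).

    Values are interpreted as velocities in ``velocity_unit`` ("mm/s" or
    "cm/s") and returned in mm/s, indexed (frame, row, col).
    """
    path = Path(path)
    if path.is_dir():
        arr, _ = _read_dicom_stack(path)  # already (frame, row, col)
    else:
        import nibabel as nib

        img = nib.load(str(path))
        arr = np.asanyarray(img.dataobj, dtype=float)
        if arr.ndim != 3:
            raise IOError(f"expected a 2D+t series, got shape {arr.shape}")
        arr = np.moveaxis(arr, 2, 0)  # (row, col, t) -> (t, row, col)
    scale = {"mm/s": 1.0, "cm/s": 10.0}.get(velocity_unit)
    if scale is None:
        raise ValueError(f"unknown velocity unit {velocity_unit!r}")
    return VelocitySeries(arr * scale, dt=dt, pixel_area=pixel_size**2, venc=venc)


def load_landmarks(path: str | Path, shape: tuple[int, int]) -> dict:
    """Load the landmark sidecar (JSON, 0-based pixel coordinates).

    Expected keys: ``threshold_line`` (two [row, col] points), ``start_point``,
    ``end_point``; optional ``mask_polygon`` (list of [row, col] vertices of
    the exclusion region), ``slice_indices``, and an explicit ``indexing``
    field which must be "0-based".
    """
    with open(path) as fh:
        data = json.load(fh)
    indexing = data.get("indexing", "0-based")
    if indexing != "0-based":
        raise ValueError(f"landmark sidecar must declare 0-based indexing, got {indexing!r}")
    mask = None
    if data.get("mask_polygon"):
        from skimage.draw import polygon2mask

        mask = polygon2mask(shape, np.asarray(data["mask_polygon"], dtype=float))
    landmarks = Landmarks(
        threshold_line=(tuple(data["threshold_line"][0]), tuple(data["threshold_line"][1])),
        start_point=tuple(data["start_point"]),
        end_point=tuple(data["end_point"]),
        exclusion_mask=mask,
    )
    return {"landmarks": landmarks, "slice_indices": data.get("slice_indices")}


def load_roi_mask(path: str | Path, shape: tuple[int, int]) -> np.ndarray:
    """Load a manual ROI (JSON with ``pixels`` [[r, c], ...] or ``polygon``)."""
    with open(path) as fh:
        data = json.load(fh)
    mask = np.zeros(shape, dtype=bool)
    if "pixels" in data:
        for r, c in data["pixels"]:
            mask[int(r), int(c)] = True
    elif "polygon" in data:
        from skimage.draw import polygon2mask

        mask = polygon2mask(shape, np.asarray(data["polygon"], dtype=float))
    else:
        raise ValueError("ROI sidecar needs a 'pixels' or 'polygon' key")
    return mask


def _jsonify(obj: Any) -> Any:
    if isinstance(obj, Path):
        return str(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if is_dataclass(obj) and not isinstance(obj, type):
        return _jsonify(asdict(obj))
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    return obj


def save_report(path: str | Path, payload: dict, config: dict | None = None) -> None:
    """Write a JSON report with the run configuration and version embedded."""
    from . import __version__

    body = {"aqueduct_version": __version__, "config": _jsonify(config or {}), **_jsonify(payload)}
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(body, fh, indent=1)


def load_report(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def check_subject_match(report_a: dict, report_b: dict) -> None:
    """Warn when two reports to be combined carry different subject IDs."""
    a = (report_a.get("config") or {}).get("subject_id")
    b = (report_b.get("config") or {}).get("subject_id")
    if a and b and a != b:
        warnings.warn(f"combining reports from different subjects: {a!r} vs {b!r}", stacklevel=2)


def write_text_table(path: str | Path, rows: list[tuple[str, Any, str]]) -> None:
    """Tab-delimited name/value/unit table, 1-2 decimals for readability."""
    lines = []
    for name, value, unit in rows:
        if isinstance(value, float):
            value = f"{value:.2f}"
        lines.append(f"{name}\t{value}\t{unit}")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text("\n".join(lines) + "\n")
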