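import numpy as np
import pytest

from aqueduct import morphology as mo
from aqueduct import synthesis as syn


def run_morphology_on_phantom(spec: syn.GeometrySpec, n_elements: int = 100):
    """Drive the image pipeline on a phantom using its suggested landmarks."""
    vol_arr, gt = syn.make_phantom_volume(spec)
    volume = mo.MorphVolume(vol_arr, spec.spacing)
    img = mo.resample_image(mo.mip_project(volume, gt["slice_indices"]), 0.03)
    ts = 0.03
    line = tuple(tuple(np.asarray(p) / ts) for p in gt["threshold_line_mm"])
    threshold = mo.gradient_threshold(img, line)
    binary = mo.binarize(img, threshold)
    path = mo.extract_centerline(
        binary,
        tuple(np.asarray(gt["start_yx_mm"]) / ts),
        tuple(np.asarray(gt["end_yx_mm"]) / ts),
    )
    elements = mo.build_elements(binary, path, n_elements)
    profile = mo.resistance_profile(elements, path=path)
    return {"gt": gt, "binary": binary, "path": path, "elements": elements, "profile": profile}


@pytest.fixture(scope="session")
def uniform_phantom():
    """Curved uniform tube, D = 2 mm, L = 15 mm, processed end to end."""
    return run_morphology_on_phantom(
        syn.GeometrySpec(radius_profile=syn.uniform_radius(1.0), length=15.0)
    )


@pytest.fixture(scope="session")
def straight_phantom():
    return run_morphology_on_phantom(
        syn.GeometrySpec(radius_profile=syn.uniform_radius(1.0), length=15.0, axis_curvature=0.0)
    )


@pytest.fixture(scope="session")
def taper_phantom():
    """Linear taper, D = 2.5 -> 1.0 mm over 15 mm."""
    return run_morphology_on_phantom(
        syn.GeometrySpec(radius_profile=syn.tapered_radius(1.25, 0.5, 15.0), length=15.0)
    )


@pytest.fixture(scope="session")
def stenosis_phantom():
    """Gaussian stenosis: D 2.2 mm narrowing to 1.2 mm mid-tube."""
    return run_morphology_on_phantom(
        syn.GeometrySpec(radius_profile=syn.stenosed_radius(1.1, 0.5, 2.0, 7.5), length=15.0)
    )
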