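"""Shared fixtures: a straight-tube phantom carried through the early
pipeline stages once per session."""

import numpy as np
import pytest

import limbictract as lt
from limbictract.tracking import RoiSpec


@pytest.fixture(scope="session")
def scheme():
    return lt.default_scheme()


@pytest.fixture(scope="session")
def tube(scheme):
    """Straight-tube phantom with noise-free DWI, fitted maps and tracking."""
    spec = lt.PhantomSpec()  # 40x16x16 grid, 2 mm voxels, tube along x
    tensors, mask, truth = lt.make_phantom(spec)
    dwi = lt.simulate_dwi(tensors, scheme, s0=1000.0, noise_sigma=0.0)
    fitted = lt.fit_tensor(dwi, scheme, grid=spec.grid)
    maps = lt.scalar_maps(fitted)
    e1 = lt.principal_directions(fitted)
    streamlines = lt.track_all(maps["fa"], e1)
    return {
        "spec": spec,
        "grid": spec.grid,
        "tensors": tensors,
        "mask": mask,
        "truth": truth,
        "dwi": dwi,
        "fitted": fitted,
        "maps": maps,
        "e1": e1,
        "streamlines": streamlines,
    }


@pytest.fixture(scope="session")
def tube_bundle(tube):
    """ROI-selected, oriented bundle and its mean curve."""
    grid = tube["grid"]
    origin = RoiSpec(kind="sagittal", slice_index=10, name="origin")
    far = RoiSpec(kind="sagittal", slice_index=30, name="far")
    bundle = lt.select_by_rois(tube["streamlines"], [origin, far], grid, name="tube")
    bundle = lt.orient_bundle(bundle, origin, grid)
    curve = lt.mean_curve(bundle, orientation_tag="origin_to_end")
    return {"bundle": bundle, "curve": curve, "origin": origin, "far": far}


@pytest.fixture(scope="session")
def crossing(scheme):
    """Two orthogonal tubes crossing at 90 degrees; the crossing voxels keep
    the x-tube's tensor, so any track turning between tubes would violate
    the 50-degree angle threshold."""
    shape = (40, 40, 12)
    vs = (2.0, 2.0, 2.0)
    mid = np.array(shape) * np.array(vs) / 2.0
    spec_x = lt.PhantomSpec(
        grid_shape=shape, voxel_size=vs, tube_radius=4.0,
        centerline=lt.synthetic.straight_centerline(
            [7.0, mid[1], mid[2]], [shape[0] * vs[0] - 7.0, mid[1], mid[2]]),
    )
    spec_y = lt.PhantomSpec(
        grid_shape=shape, voxel_size=vs, tube_radius=4.0,
        centerline=lt.synthetic.straight_centerline(
            [mid[0], 7.0, mid[2]], [mid[0], shape[1] * vs[1] - 7.0, mid[2]]),
    )
    tx, mx, _ = lt.make_phantom(spec_x)
    ty, my, _ = lt.make_phantom(spec_y)
    coeffs = ty.coeffs.copy()
    coeffs[mx] = tx.coeffs[mx]  # x-tube wins in the crossing
    tensors = lt.TensorVolume(coeffs=coeffs, grid=spec_x.grid)
    maps = lt.scalar_maps(tensors)
    e1 = lt.principal_directions(tensors)
    return {
        "grid": spec_x.grid,
        "maps": maps,
        "e1": e1,
        "mask_x": mx,
        "mask_y": my,
        "center": mid,
        "radius": 4.0,
    }
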