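"""Shared fixtures: a reduced-scale calibration run and a tree-recovery run.

Both are session-scoped because they carry the only expensive computations in
the suite (tens of seconds each); every other test is sub-second.
"""

from __future__ import annotations

import numpy as np
import pytest

from vesscal.calibration import run_phantom_calibration
from vesscal.phantom import (
    TreePhantomSpec,
    calibration_phantom,
    generate_tree_volume,
)
from vesscal.segmentation import (
    flood_fill_segment,
    map_attribute_to_tree,
    skeletonize,
)
from vesscal.vesselness import VesselnessParams, multiscale_vesselness


@pytest.fixture(scope="session")
def smoke_calibration():
    """Reduced calibration phantom (6 tubes, 3.14-30 px, kernel scales 1-15)
    pushed through the full workflow.  Same geometry and parameters as the
    production phantom, scaled down to keep the suite fast; the slope/R
    contract is identical because the relation is linear through the range."""
    phantom = calibration_phantom(3.14, 30.0, n_tubes=6, nz=96)
    params = VesselnessParams(scales=tuple(float(s) for s in range(1, 16)))
    model, points, extras = run_phantom_calibration(
        phantom, params, return_intermediates=True
    )
    return {
        "phantom": phantom,
        "params": params,
        "model": model,
        "points": points,
        **extras,
    }


@pytest.fixture(scope="session")
def tree_recovery(smoke_calibration):
    """Three-generation branching phantom (diameters 28 -> 16.8 -> 10.1 px)
    segmented and skeletonized; per-segment S_MAX read from the central half
    of each branch and converted to caliber with the smoke calibration."""
    spec = TreePhantomSpec(
        n_generations=3, root_diameter=28.0, child_ratio=0.6,
        branch_angle=35.0, rng_seed=7,
    )
    phantom = generate_tree_volume(spec, (160, 160, 160))
    params = smoke_calibration["params"]
    result = multiscale_vesselness(phantom.voxels, params)
    seed = np.unravel_index(int(np.argmax(result.probability)),
                            result.probability.shape)
    mask = flood_fill_segment(result.probability, [seed], 0.05)
    tree = skeletonize(mask, probability=result.probability)
    map_attribute_to_tree(tree, result.s_max, "s_max")

    model = smoke_calibration["model"]
    coords = tree.coords().astype(float)          # (n, 3) in (z, y, x)
    s_vals = tree.node_attribute("s_max")

    pairs = []  # (d_ct_px, true diameter px), one per ground-truth segment
    for seg in phantom.ground_truth:
        p0 = np.asarray(seg.p0)[::-1]  # -> (z, y, x)
        p1 = np.asarray(seg.p1)[::-1]
        picked = []
        for t in np.linspace(0.3, 0.7, 17):  # central portion, clear of joints
            axis_pt = p0 + t * (p1 - p0)
            d = np.linalg.norm(coords - axis_pt, axis=1)
            near = d <= seg.diameter / 2.0 + 2.0
            picked.extend(s_vals[near])
        if not picked:
            continue
        s_mean = float(np.mean(picked))
        d_ct_px = (s_mean - model.intercept) / model.slope
        pairs.append((d_ct_px, seg.diameter))
    return {
        "spec": spec, "phantom": phantom, "tree": tree,
        "model": model, "pairs": pairs, "vesselness": result,
    }
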