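"""Maximum-intensity forward projection of volumes and centerline trees.

Parallel-beam orthographic geometry: the viewer looks along the volume z axis
(array axis 0) after the volume has been rotated by the view angle about the
vertical y axis (array axis 1).  View angle 0 is the frontal view; +/-45 are
the right/left anterior oblique views.  The same rotation geometry is used for
resampled volume projections and for point (tree-node) projections so the two
kinds of image are co-registered pixel for pixel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as _ndi

__all__ = [
    "Projection2D",
    "max_intensity_project",
    "project_tree_attribute",
    "project_points",
    "projection_shape",
]


@dataclass
class Projection2D:
    """A 2D projection image: rows are y, columns the rotated x axis."""

    pixels: np.ndarray
    view_angle: float  # degrees about the vertical axis, normalized [0, 360)
    pixel_size: float = 1.0
    kind: str = "intensity"

    def __post_init__(self):
        p = np.asarray(self.pixels)
        if p.ndim != 2:
            raise ValueError("projection pixels must be 2D")
        if not np.all(np.isfinite(p)):
            raise ValueError("projection contains non-finite pixels")
        self.pixels = p
        self.view_angle = float(self.view_angle) % 360.0


def _rotation_terms(angle_deg: float) -> tuple[float, float]:
    a = math.radians(angle_deg % 360.0)
    return math.cos(a), math.sin(a)


def projection_shape(vol_shape: tuple[int, int, int], angle_deg: float) -> tuple[int, int]:
    """Output (rows, cols) of a projection of a (z, y, x) volume at ``angle``."""
    nz, ny, nx = vol_shape
    c, s = _rotation_terms(angle_deg)
    out_nx = int(math.ceil(abs(c) * nx + abs(s) * nz))
    return ny, out_nx


def _rotated_extent(vol_shape, angle_deg):
    nz, ny, nx = vol_shape
    c, s = _rotation_terms(angle_deg)
    out_nx = int(math.ceil(abs(c) * nx + abs(s) * nz))
    out_nz = int(math.ceil(abs(s) * nx + abs(c) * nz))
    return out_nz, out_nx


def project_points(
    points_zyx: np.ndarray, angle_deg: float, vol_shape: tuple[int, int, int]
) -> np.ndarray:
    """Map (z, y, x) volume coordinates to (row, col) projection coordinates."""
    pts = np.atleast_2d(np.asarray(points_zyx, dtype=float))
    nz, ny, nx = vol_shape
    c, s = _rotation_terms(angle_deg)
    out_nz, out_nx = _rotated_extent(vol_shape, angle_deg)
    cx_in, cz_in = (nx - 1) / 2.0, (nz - 1) / 2.0
    cx_out, cz_out = (out_nx - 1) / 2.0, (out_nz - 1) / 2.0
    x = pts[:, 2] - cx_in
    z = pts[:, 0] - cz_in
    col = c * x - s * z + cx_out
    rows = pts[:, 1]
    return np.stack([rows, col], axis=1)


def max_intensity_project(
    vol, angle_deg: float = 0.0, pixel_size: float = 1.0
) -> Projection2D:
    """Maximum intensity projection at a view angle about the vertical axis.

    The volume is resampled onto the rotated grid with trilinear interpolation
    (the rotation acts only in the x-z plane, so the resampling is done slice
    by slice in y), then reduced by a per-ray maximum along the viewing axis.
    Angle 0 takes the exact per-column maximum with no resampling.
    """
    voxels = getattr(vol, "voxels", vol)
    voxels = np.asarray(voxels)
    if voxels.ndim != 3:
        raise ValueError("expected a 3D volume")
    angle = float(angle_deg) % 360.0
    if angle == 0.0:
        return Projection2D(pixels=voxels.max(axis=0), view_angle=0.0,
                            pixel_size=pixel_size, kind="intensity")

    nz, ny, nx = voxels.shape
    c, s = _rotation_terms(angle)
    out_nz, out_nx = _rotated_extent(voxels.shape, angle)
    cx_in, cz_in = (nx - 1) / 2.0, (nz - 1) / 2.0
    cx_out, cz_out = (out_nx - 1) / 2.0, (out_nz - 1) / 2.0

    # inverse map: source (z, x) for every rotated (z', x')
    zp, xp = np.meshgrid(
        np.arange(out_nz, dtype=np.float64) - cz_out,
        np.arange(out_nx, dtype=np.float64) - cx_out,
        indexing="ij",
    )
    x_src = c * xp + s * zp + cx_in
    z_src = -s * xp + c * zp + cz_in
    coords = np.stack([z_src, x_src])

    cval = float(voxels.min())
    out = np.full((ny, out_nx), cval, dtype=np.float64)
    for j in range(ny):  # rotation is y-invariant; resample per slice
        rot = _ndi.map_coordinates(
            voxels[:, j, :].astype(np.float64), coords, order=1,
            mode="constant", cval=cval,
        )
        out[j] = rot.max(axis=0)
    return Projection2D(pixels=out, view_angle=angle,
                        pixel_size=pixel_size, kind="intensity")


def project_tree_attribute(
    tree,
    attribute: str,
    angle_deg: float = 0.0,
    dims: tuple[int, int] | None = None,
    dilate: int = 0,
    pixel_size: float = 1.0,
) -> Projection2D:
    """Orthographic projection of a per-node tree attribute.

    Node coordinates are rotated with the same geometry as
    :func:`max_intensity_project`, splatted to the nearest pixel and combined
    by maximum; background pixels hold the null value 0.  ``dilate=1`` widens
    every splat to 3x3 (useful for display and for robust line sampling).
    """
    nodes = list(tree.graph.nodes)
    if not nodes:
        raise ValueError("tree has no nodes")
    values = []
    coords = []
    for n in nodes:
        data = tree.graph.nodes[n]
        if attribute not in data or data[attribute] is None:
            raise ValueError(f"attribute {attribute!r} is not set on node {n}")
        values.append(float(data[attribute]))
        coords.append(data["coord"])
    coords = np.asarray(coords, dtype=float)
    values = np.asarray(values)

    if dims is None:
        dims = projection_shape(tree.volume_shape, angle_deg)
    rows_cols = project_points(coords, angle_deg, tree.volume_shape)
    rows = np.round(rows_cols[:, 0]).astype(int)
    cols = np.round(rows_cols[:, 1]).astype(int)

    img = np.zeros(dims, dtype=float)
    nr, nc = dims
    for r0, c0, v in sorted(zip(rows, cols, values), key=lambda t: (t[0], t[1], t[2])):
        for dr in range(-dilate, dilate + 1):
            for dc in range(-dilate, dilate + 1):
                r, c = r0 + dr, c0 + dc
                if 0 <= r < nr and 0 <= c < nc and img[r, c] < v:
                    img[r, c] = v
    return Projection2D(pixels=img, view_angle=angle_deg,
                        pixel_size=pixel_size, kind="attribute")
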