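"""Kernel-scale calibration: S_MAX vs projected caliber, and D_CT conversion.

The per-voxel argmax Gaussian kernel scale (S_MAX) is a surrogate for vessel
caliber but carries no physical unit.  A phantom of tubes with known,
geometrically spaced diameters is pushed through the same pipeline as real
data: maximum-intensity projection -> FWHM caliber (D_PROJ, px) on one hand,
vesselness -> segmentation -> centerline -> S_MAX projection on the other.
Line selections across each tube yield paired (D_PROJ, S_MAX) readings --
D_PROJ as the FWHM of the intensity profile, S_MAX as the maximum value on
the same line in the S_MAX projection -- averaged over replicate positions
along the tube.  An ordinary least-squares line through the per-tube points
is the calibration; its inverse maps S_MAX to a contrast-free caliber

    D_CT = (S_MAX - intercept) / slope * voxel_size   [mm].
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import projection, segmentation, vesselness
from .caliber2d import LineSelection, fwhm_diameter
from .phantom import PhantomVolume, TubeSpec, tube_axis

__all__ = [
    "CalibrationPoint",
    "CalibrationModel",
    "ComparisonResult",
    "LinearFit",
    "fit_linear",
    "fit_calibration",
    "collect_calibration_points",
    "phantom_line_selections",
    "smax_to_diameter",
    "diameter_to_smax",
    "compare_dct_dang",
    "run_phantom_calibration",
]


@dataclass(frozen=True)
class CalibrationPoint:
    """Per-tube averaged (D_PROJ, S_MAX) pair."""

    d_proj: float       # px, FWHM from the intensity projection
    s_max: float        # mean of per-line maximum projected argmax scale
    n_replicates: int = 1

    def __post_init__(self):
        if not (self.d_proj > 0 and self.s_max > 0):
            raise ValueError("d_proj and s_max must be positive")


@dataclass(frozen=True)
class CalibrationModel:
    """Linear S_MAX = slope * D_PROJ + intercept calibration."""

    slope: float        # scale units per px
    intercept: float    # scale units
    r: float            # Pearson correlation of the fitted points
    n_points: int

    def __post_init__(self):
        if self.n_points < 3:
            raise ValueError("a calibration needs at least 3 points")
        if not -1.0 <= self.r <= 1.0 + 1e-12:
            raise ValueError("correlation out of range")


@dataclass
class ComparisonResult:
    """D_CT vs D_ANG agreement regression (D_CT regressed on D_ANG, the
    composite-figure orientation; the reverse fit is kept for transparency)."""

    slope: float
    intercept: float    # mm
    r: float
    n: int
    pairs: list = field(default_factory=list)
    reverse_slope: float = float("nan")
    reverse_intercept: float = float("nan")


@dataclass(frozen=True)
class LinearFit:
    slope: float
    intercept: float
    r: float
    degenerate: bool = False


def fit_linear(points) -> LinearFit:
    """Ordinary least squares of y on x plus the Pearson correlation.

    ``points`` is an iterable of (x, y) pairs.  Constant y gives slope 0 and
    r reported as 0 with the ``degenerate`` flag; constant x is an error.
    """
    pts = np.asarray(list(points), dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
        raise ValueError("need at least two (x, y) pairs")
    x, y = pts[:, 0], pts[:, 1]
    sx = x.std()
    if sx == 0:
        raise ValueError("x values are all equal; regression is degenerate")
    sy = y.std()
    slope = float(np.cov(x, y, bias=True)[0, 1] / sx ** 2)
    intercept = float(y.mean() - slope * x.mean())
    if sy == 0:
        return LinearFit(slope=slope, intercept=intercept, r=0.0, degenerate=True)
    r = float(np.corrcoef(x, y)[0, 1])
    return LinearFit(slope=slope, intercept=intercept, r=r)


def fit_calibration(points: list[CalibrationPoint]) -> CalibrationModel:
    """OLS of S_MAX on D_PROJ over the per-tube calibration points."""
    if len(points) < 3:
        raise ValueError("a calibration needs at least 3 points")
    fit = fit_linear([(p.d_proj, p.s_max) for p in points])
    return CalibrationModel(slope=fit.slope, intercept=fit.intercept,
                            r=fit.r, n_points=len(points))


def smax_to_diameter(s_max, model: CalibrationModel, voxel_size: float):
    """Convert S_MAX to a contrast-free caliber D_CT in mm.

    The exact algebraic inverse of the calibration line, scaled by the
    effective voxel size.  Values at or below the intercept are non-physical
    and come back as NaN so report writers can exclude them.
    """
    if not voxel_size > 0:
        raise ValueError("voxel_size must be positive")
    s = np.asarray(s_max, dtype=float)
    d = (s - model.intercept) / model.slope * voxel_size
    d = np.where(s > model.intercept, d, np.nan)
    return float(d) if np.isscalar(s_max) else d


def diameter_to_smax(diameter_px, model: CalibrationModel):
    """Forward model: expected S_MAX for a caliber in px."""
    return model.intercept + model.slope * np.asarray(diameter_px, dtype=float)


def compare_dct_dang(pairs) -> ComparisonResult:
    """Regression of contrast-free D_CT against angiographic D_ANG (mm)."""
    pts = [(float(a), float(c)) for c, a in (tuple(p) for p in pairs)]
    if len(pts) < 3:
        raise ValueError("need at least 3 (d_ct, d_ang) pairs")
    fwd = fit_linear(pts)                       # y = d_ct, x = d_ang
    rev = fit_linear([(y, x) for x, y in pts])  # y = d_ang, x = d_ct
    return ComparisonResult(
        slope=fwd.slope, intercept=fwd.intercept, r=fwd.r, n=len(pts),
        pairs=[(c, a) for a, c in pts],
        reverse_slope=rev.slope, reverse_intercept=rev.intercept,
    )


# ---------------------------------------------------------------------------
# Phantom measurement protocol


def phantom_line_selections(
    phantom: PhantomVolume,
    view_angle: float,
    tail: float = 15.0,
    n_parallel: int = 5,
) -> list[LineSelection]:
    """One measurement line per tube, placed from phantom ground truth.

    Each line crosses the projected tube strip perpendicular to the projected
    axis at the tube's mid-volume position, extending ``tail`` px beyond the
    tube surface on both sides for baseline estimation.
    """
    lines = []
    nz = phantom.shape[0]
    for i, spec in enumerate(phantom.ground_truth):
        if not isinstance(spec, TubeSpec):
            raise ValueError("phantom ground truth must be TubeSpec items")
        point, u = tube_axis(spec, phantom.shape)
        if abs(u[2]) < 1e-9:
            raise ValueError("tube axis perpendicular to z is not measurable "
                             "in this view")
        # axis position at the volume's central z slice
        t_mid = ((nz - 1) / 2.0 - point[2]) / u[2]
        mid = point + t_mid * u  # (x, y, z)
        p_img = projection.project_points(
            [(mid[2], mid[1], mid[0])], view_angle, phantom.shape
        )[0]  # (row, col)
        axis_img = _projected_axis_direction(u, view_angle)
        normal = np.array([-axis_img[1], axis_img[0]])  # (row, col) normal
        half = spec.diameter / 2.0 + tail
        # LineSelection endpoints are (x, y) = (col, row)
        p0 = (p_img[1] - half * normal[1], p_img[0] - half * normal[0])
        p1 = (p_img[1] + half * normal[1], p_img[0] + half * normal[0])
        lines.append(LineSelection(p0=p0, p1=p1, n_parallel=n_parallel,
                                   label=f"tube{i}_d{spec.diameter:.2f}"))
    return lines


def _projected_axis_direction(u_xyz: np.ndarray, view_angle: float) -> np.ndarray:
    """Unit (row, col) direction of a projected 3D axis at a view angle."""
    c = math.cos(math.radians(view_angle))
    s = math.sin(math.radians(view_angle))
    col = c * u_xyz[0] - s * u_xyz[2]
    row = u_xyz[1]
    n = math.hypot(row, col)
    if n < 1e-9:
        raise ValueError("axis is parallel to the viewing direction")
    return np.array([row / n, col / n])


def collect_calibration_points(
    intensity_proj: projection.Projection2D,
    smax_proj: projection.Projection2D,
    lines: list[LineSelection],
    n_replicates: int = 25,
    replicate_step: float = 2.0,
    min_valid_fraction: float = 0.6,
) -> list[CalibrationPoint]:
    """Paired (D_PROJ, S_MAX) readings, one point per line (per tube).

    Each line is replicated at ``n_replicates`` positions stepped along the
    tube (perpendicular to the line); at each position D_PROJ is the FWHM of
    the intensity profile and S_MAX the maximum value of the S_MAX projection
    on the line.  The point is the mean over valid replicates.
    """
    if intensity_proj.view_angle != smax_proj.view_angle:
        raise ValueError("projections must share one view angle")
    points = []
    for line in lines:
        nx_, ny_ = line.normal()  # perpendicular to line = along the tube
        d_vals, s_vals = [], []
        offsets = (np.arange(n_replicates) - (n_replicates - 1) / 2.0) * replicate_step
        for off in offsets:
            shifted = line.shifted(off * nx_, off * ny_)
            try:
                m = fwhm_diameter(intensity_proj.pixels, shifted)
            except ValueError:
                continue
            s_line = _line_max_nearest(smax_proj.pixels, shifted)
            if s_line <= 0:
                continue
            d_vals.append(m.d_fwhm)
            s_vals.append(s_line)
        if len(d_vals) < max(1, int(min_valid_fraction * n_replicates)):
            raise ValueError(
                f"line {line.label or line.p0} misses the tube on one of the "
                f"projections ({len(d_vals)}/{n_replicates} valid replicates)"
            )
        points.append(CalibrationPoint(
            d_proj=float(np.mean(d_vals)), s_max=float(np.mean(s_vals)),
            n_replicates=len(d_vals),
        ))
    return points


def _line_max_nearest(image: np.ndarray, line: LineSelection) -> float:
    """Maximum of an image along a line, nearest-pixel sampling.

    Used on sparse attribute projections where bilinear sampling would dilute
    splatted values with background zeros.
    """
    length = line.length
    n = max(2, int(math.ceil(length / 0.25)) + 1)
    s = np.linspace(0.0, 1.0, n)
    xs = np.round(line.p0[0] + (line.p1[0] - line.p0[0]) * s).astype(int)
    ys = np.round(line.p0[1] + (line.p1[1] - line.p0[1]) * s).astype(int)
    h, w = image.shape
    ok = (ys >= 0) & (ys < h) & (xs >= 0) & (xs < w)
    if not ok.any():
        return 0.0
    return float(image[ys[ok], xs[ok]].max())


# ---------------------------------------------------------------------------
# End-to-end phantom calibration


def run_phantom_calibration(
    phantom: PhantomVolume,
    params: vesselness.VesselnessParams | None = None,
    view_angle: float | None = None,
    threshold: float = 0.05,
    n_replicates: int = 25,
    replicate_step: float = 2.0,
    return_intermediates: bool = False,
):
    """Full calibration workflow on a tube phantom.

    vesselness -> flood fill (seeded at the tube axes) -> skeletonize ->
    map S_MAX -> project the tree attribute and the intensity volume at the
    phantom's own view -> per-tube line measurements -> OLS fit.

    Returns ``(model, points)`` or, with ``return_intermediates``, a third
    dict holding the vesselness result, mask, tree and projections.
    """
    if params is None:
        params = vesselness.VesselnessParams()
    specs = phantom.ground_truth
    if view_angle is None:
        # the phantom's natural view: its own y-rotation, in which the tube
        # strips project without overlap
        view_angle = float(specs[0].axis_rotation[1])

    result = vesselness.multiscale_vesselness(phantom.voxels, params)

    seeds = []
    for spec in specs:
        point, u = tube_axis(spec, phantom.shape)
        t_mid = ((phantom.shape[0] - 1) / 2.0 - point[2]) / u[2]
        mid = point + t_mid * u
        seed = (int(round(mid[2])), int(round(mid[1])), int(round(mid[0])))
        seeds.append(_snap_seed(result.probability, seed, threshold))
    mask = segmentation.flood_fill_segment(result.probability, seeds, threshold)
    tree = segmentation.skeletonize(mask, probability=result.probability)
    segmentation.map_attribute_to_tree(tree, result.s_max, "s_max")

    intensity_proj = projection.max_intensity_project(phantom.voxels, view_angle)
    smax_proj = projection.project_tree_attribute(
        tree, "s_max", view_angle, dims=intensity_proj.pixels.shape, dilate=1
    )
    lines = phantom_line_selections(phantom, view_angle)
    points = collect_calibration_points(
        intensity_proj, smax_proj, lines,
        n_replicates=n_replicates, replicate_step=replicate_step,
    )
    model = fit_calibration(points)
    if return_intermediates:
        extras = {
            "vesselness": result, "mask": mask, "tree": tree,
            "intensity_projection": intensity_proj, "smax_projection": smax_proj,
            "lines": lines, "view_angle": view_angle,
        }
        return model, points, extras
    return model, points


def _snap_seed(prob: np.ndarray, seed, threshold: float, radius: int = 3):
    """Return the seed, or the highest-probability voxel in a small
    neighborhood when the nominal seed falls below the threshold."""
    if prob[seed] >= threshold:
        return seed
    z, y, x = seed
    sl = tuple(slice(max(0, c - radius), min(n, c + radius + 1))
               for c, n in zip((z, y, x), prob.shape))
    sub = prob[sl]
    dz, dy, dx = np.unravel_index(int(np.argmax(sub)), sub.shape)
    return (sl[0].start + dz, sl[1].start + dy, sl[2].start + dx)
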