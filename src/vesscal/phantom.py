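"""Synthetic phantoms: tube volumes, branching trees, and bolus angiography.

The tube phantom emulates the in-silico calibration target: long cylinders of
known diameter spanning the volume, bright (water-dense vessel) on a dark
(air-filled parenchyma) background, tilted by a fixed extrinsic rotation so
that no tube is axis-aligned.  Voxel values are sub-voxel occupancy fractions
(partial-volume edges), which is what real CT reconstructions exhibit and what
an FWHM caliber measure assumes.

Coordinate conventions: voxel arrays are indexed ``(z, y, x)``; geometric
vectors are written ``(x, y, z)`` with x = array axis 2, y = axis 1 (the
vertical/projection-rotation axis), z = axis 0.  Extrinsic rotations are
applied in x-then-y-then-z order about the volume center.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TubeSpec",
    "PhantomVolume",
    "TreePhantomSpec",
    "TreeSegment",
    "AngioSequence",
    "rotation_matrix",
    "tube_axis",
    "generate_tube_volume",
    "calibration_phantom",
    "default_calibration_phantom",
    "generate_tree_volume",
    "generate_angio_sequence",
    "CALIBRATION_DIAMETER_RANGE",
    "CALIBRATION_ROTATION",
]

#: Diameter range (px) and rotation (degrees about x, y, z) of the default
#: calibration phantom.
CALIBRATION_DIAMETER_RANGE = (3.14, 62.8)
CALIBRATION_ROTATION = (30.0, 15.0, 0.0)


def rotation_matrix(rx_deg: float, ry_deg: float, rz_deg: float) -> np.ndarray:
    """Extrinsic rotation matrix, x-then-y-then-z order, acting on (x, y, z)."""
    ax, ay, az = (math.radians(a) for a in (rx_deg, ry_deg, rz_deg))
    cx, sx = math.cos(ax), math.sin(ax)
    cy, sy = math.cos(ay), math.sin(ay)
    cz, sz = math.cos(az), math.sin(az)
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return rz @ ry @ rx


@dataclass(frozen=True)
class TubeSpec:
    """One straight tube: bright cylinder of given diameter.

    ``center_offset`` is an (x, y, z) displacement of the tube axis from the
    volume center, in voxels.  ``axis_rotation`` rotates the canonical +z tube
    axis (extrinsic, x-then-y-then-z, degrees).
    """

    diameter: float
    center_offset: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis_rotation: tuple[float, float, float] = (0.0, 0.0, 0.0)
    foreground_value: float = 1.0
    background_value: float = 0.0

    def __post_init__(self):
        if not self.diameter > 0:
            raise ValueError("tube diameter must be positive")
        if not self.foreground_value > self.background_value:
            raise ValueError("foreground_value must exceed background_value "
                             "(bright tube on dark background)")

    def direction(self) -> np.ndarray:
        """Unit axis direction (x, y, z)."""
        return rotation_matrix(*self.axis_rotation) @ np.array([0.0, 0.0, 1.0])


@dataclass
class PhantomVolume:
    """A generated volume plus the ground truth that produced it."""

    voxels: np.ndarray
    voxel_size: float = 1.0
    ground_truth: list = field(default_factory=list)
    rng_seed: int | None = None

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


@dataclass(frozen=True)
class TreePhantomSpec:
    """Parameters of a binary branching vascular-tree phantom."""

    n_generations: int
    root_diameter: float
    child_ratio: float = 0.7
    branch_angle: float = 35.0
    rng_seed: int = 0
    length_scale: float = 3.0  # segment length = length_scale * diameter

    def __post_init__(self):
        if self.n_generations < 1:
            raise ValueError("n_generations must be >= 1")
        if not 0 < self.child_ratio < 1:
            raise ValueError("child_ratio must be in (0, 1)")
        if self.terminal_diameter() < 2.0:
            raise ValueError(
                f"terminal diameter {self.terminal_diameter():.2f} px < 2 px; "
                "raise root_diameter or child_ratio"
            )

    def terminal_diameter(self) -> float:
        return self.root_diameter * self.child_ratio ** (self.n_generations - 1)


@dataclass(frozen=True)
class TreeSegment:
    """Ground truth for one cylinder segment of a tree phantom."""

    segment_id: int
    parent_id: int  # -1 for the root
    p0: tuple[float, float, float]  # (x, y, z) start, voxels
    p1: tuple[float, float, float]  # (x, y, z) end
    diameter: float
    generation: int  # 1-based from the root


@dataclass
class AngioSequence:
    """An ordered stack of 2D frames from a (synthetic) bolus acquisition."""

    frames: np.ndarray  # (t, rows, cols)
    frame_interval: float = 1.0 / 30.0
    bolus_onset_frame: int = 0
    ground_truth_diameters: dict = field(default_factory=dict)
    bolus_peak_frame: int | None = None

    def __post_init__(self):
        f = np.asarray(self.frames)
        if f.ndim != 3:
            raise ValueError("frames must be a (t, rows, cols) stack")
        if f.shape[0] < 11:
            raise ValueError("at least 11 frames are required "
                             "(the temporal moving-average window must fit)")
        self.frames = f

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


# ---------------------------------------------------------------------------
# Tube rasterization


def _volume_center(dims: tuple[int, int, int]) -> np.ndarray:
    nz, ny, nx = dims
    return np.array([(nx - 1) / 2.0, (ny - 1) / 2.0, (nz - 1) / 2.0])


def tube_axis(spec: TubeSpec, dims: tuple[int, int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Axis of a tube inside a volume: (point, unit direction), both (x, y, z)."""
    point = _volume_center(dims) + np.asarray(spec.center_offset, dtype=float)
    return point, spec.direction()


def _line_distance(p1, u1, p2, u2) -> float:
    """Minimum distance between two infinite lines."""
    cross = np.cross(u1, u2)
    norm = np.linalg.norm(cross)
    d = np.asarray(p2, float) - np.asarray(p1, float)
    if norm < 1e-9:  # parallel
        return float(np.linalg.norm(d - np.dot(d, u1) * u1))
    return float(abs(np.dot(d, cross)) / norm)


def generate_tube_volume(
    specs: list[TubeSpec],
    dims: tuple[int, int, int],
    supersampling: int = 3,
) -> PhantomVolume:
    """Rasterize non-overlapping tubes into a volume of shape ``dims`` (z, y, x).

    Voxel values are sub-voxel occupancy fractions mapped onto
    [background, foreground]; only voxels within one half-diagonal of a tube
    surface are supersampled (``supersampling**3`` points per voxel), interior
    and exterior voxels are classified from the voxel-center radius directly.
    """
    if supersampling < 1:
        raise ValueError("supersampling must be >= 1")
    dims = tuple(int(n) for n in dims)
    if len(dims) != 3 or any(n < 2 for n in dims):
        raise ValueError(f"dims must be three integers >= 2, got {dims}")
    if specs:
        dmax = max(s.diameter for s in specs)
        if any(n < 2 * dmax for n in dims):
            raise ValueError(
                f"dims {dims} must be at least twice the largest tube "
                f"diameter ({dmax:.1f} px) along every axis"
            )
        bg = specs[0].background_value
        if any(s.background_value != bg for s in specs):
            raise ValueError("all tubes must share one background_value")
    else:
        bg = 0.0

    axes = [tube_axis(s, dims) for s in specs]
    for i in range(len(specs)):
        for j in range(i + 1, len(specs)):
            dist = _line_distance(axes[i][0], axes[i][1], axes[j][0], axes[j][1])
            if dist < (specs[i].diameter + specs[j].diameter) / 2.0:
                raise ValueError(
                    f"tubes {i} and {j} overlap (axis distance {dist:.2f} px "
                    "< sum of radii); calibration requires isolated tubes"
                )

    nz, ny, nx = dims
    vol = np.full(dims, bg, dtype=np.float32)
    zz = np.arange(nz, dtype=np.float32)[:, None, None]
    yy = np.arange(ny, dtype=np.float32)[None, :, None]
    xx = np.arange(nx, dtype=np.float32)[None, None, :]

    half_diag = math.sqrt(3.0) / 2.0
    sub = (np.arange(supersampling) + 0.5) / supersampling - 0.5

    for spec, (point, u) in zip(specs, axes):
        r = spec.diameter / 2.0
        dx, dy, dz = xx - point[0], yy - point[1], zz - point[2]
        t = u[0] * dx + u[1] * dy + u[2] * dz
        rad2 = (dx * dx + dy * dy + dz * dz) - t * t
        del t
        rad = np.sqrt(np.maximum(rad2, 0.0))
        del rad2
        occ = (rad <= r).astype(np.float32)
        if supersampling > 1:
            shell = np.abs(rad - r) <= half_diag + 0.05
            idx = np.nonzero(shell)
            if idx[0].size:
                pz = idx[0].astype(np.float64)
                py = idx[1].astype(np.float64)
                px = idx[2].astype(np.float64)
                count = np.zeros(idx[0].size)
                for oz in sub:
                    for oy in sub:
                        for ox in sub:
                            sx = px + ox - point[0]
                            sy = py + oy - point[1]
                            sz = pz + oz - point[2]
                            st = u[0] * sx + u[1] * sy + u[2] * sz
                            sr2 = sx * sx + sy * sy + sz * sz - st * st
                            count += sr2 <= r * r
                occ[idx] = count / supersampling ** 3
        del rad
        np.maximum(vol, bg + (spec.foreground_value - bg) * occ, out=vol)
        del occ

    return PhantomVolume(voxels=vol, ground_truth=list(specs), rng_seed=None)


# ---------------------------------------------------------------------------
# Calibration phantom layout


def _bitonic_order(n: int) -> list[int]:
    """Index order placing the largest diameter mid-row, e.g. 0,2,4,...,5,3,1."""
    largest_odd = n - 1 if (n - 1) % 2 == 1 else n - 2
    return list(range(0, n, 2)) + list(range(largest_odd, 0, -2))


def calibration_phantom(
    diam_min: float = CALIBRATION_DIAMETER_RANGE[0],
    diam_max: float = CALIBRATION_DIAMETER_RANGE[1],
    n_tubes: int = 10,
    rotation: tuple[float, float, float] = CALIBRATION_ROTATION,
    supersampling: int = 3,
    nz: int | None = None,
    projected_gap: float | None = None,
    margin: float = 4.0,
) -> PhantomVolume:
    """Parallel-tube calibration phantom with geometrically spaced diameters.

    All tubes share the same axis rotation.  Tube centers sit in the plane
    through the volume center perpendicular to the common axis, in a single
    row along the rotated x direction with an alternating transverse zigzag.
    The row direction is chosen so that at view angle ``rotation[1]`` (the
    phantom's own y-rotation, its natural view) the projected tube strips are
    separated by at least ``projected_gap`` px, while in 3D no two tube
    surfaces come closer than the largest tube diameter.
    """
    if n_tubes < 2:
        raise ValueError("need at least 2 tubes")
    if not 0 < diam_min < diam_max:
        raise ValueError("need 0 < diam_min < diam_max")
    diam = diam_min * (diam_max / diam_min) ** (np.arange(n_tubes) / (n_tubes - 1))
    order = _bitonic_order(n_tubes)
    d = diam[order]

    gap = projected_gap if projected_gap is not None else max(20.0, 0.56 * diam_max)
    # zigzag amplitude: lift adjacent pairs so 3D surface clearance >= diam_max
    need = 0.0
    for a, b in zip(d, d[1:]):
        m = (a + b) / 2.0
        need = max(need, (m + diam_max) ** 2 - (m + gap) ** 2)
    zig = 0.5 * math.sqrt(max(need, 0.0)) + 1.0

    px = np.zeros(n_tubes)
    for i in range(1, n_tubes):
        px[i] = px[i - 1] + (d[i - 1] + d[i]) / 2.0 + gap
    px -= px.mean()
    py = np.array([zig if i % 2 == 0 else -zig for i in range(n_tubes)])

    rot = rotation_matrix(*rotation)
    e1 = rot @ np.array([1.0, 0.0, 0.0])
    e2 = rot @ np.array([0.0, 1.0, 0.0])
    u = rot @ np.array([0.0, 0.0, 1.0])
    offsets = [px[i] * e1 + py[i] * e2 for i in range(n_tubes)]

    if nz is None:
        nz = int(math.ceil(2 * diam_max / 8.0 + 1)) * 8
        nz = max(nz, 96)
    if nz < 2 * diam_max:
        raise ValueError(f"nz={nz} is smaller than twice the largest diameter")

    # required x/y extents: track tube surfaces over the z-range of the volume
    if abs(u[2]) < 1e-6:
        raise ValueError("tube axis may not be perpendicular to z")
    half_x = half_y = 0.0
    for off, di in zip(offsets, d):
        for z_edge in (0.0, float(nz - 1)):
            t = (z_edge - off[2]) / u[2]
            p = off + t * u
            half_x = max(half_x, abs(p[0]) + di / 2.0)
            half_y = max(half_y, abs(p[1]) + di / 2.0)
    nx = int(math.ceil((half_x + margin) * 2 / 8.0)) * 8
    ny = int(math.ceil((half_y + margin) * 2 / 8.0)) * 8
    ny = max(ny, int(math.ceil(2 * diam_max / 8.0 + 1)) * 8)
    nx = max(nx, int(math.ceil(2 * diam_max / 8.0 + 1)) * 8)

    specs = [
        TubeSpec(
            diameter=float(di),
            center_offset=tuple(float(v) for v in off),
            axis_rotation=tuple(float(a) for a in rotation),
        )
        for di, off in zip(d, offsets)
    ]
    vol = generate_tube_volume(specs, (nz, ny, nx), supersampling=supersampling)

    # construction guarantee: surfaces no closer than the largest diameter
    pts = [tube_axis(s, vol.shape) for s in vol.ground_truth]
    for i in range(n_tubes):
        for j in range(i + 1, n_tubes):
            clear = _line_distance(pts[i][0], pts[i][1], pts[j][0], pts[j][1]) \
                - (specs[i].diameter + specs[j].diameter) / 2.0
            if clear < diam_max - 1e-6:
                raise AssertionError("internal layout error: clearance violated")
    return vol


def default_calibration_phantom() -> PhantomVolume:
    """The standard calibration phantom: 10 tubes, 3.14-62.8 px, rotated
    (30, 15, 0) degrees, geometric diameter spacing, supersampling 3."""
    return calibration_phantom()


# ---------------------------------------------------------------------------
# Branching tree phantom


def generate_tree_volume(
    spec: TreePhantomSpec, dims: tuple[int, int, int]
) -> PhantomVolume:
    """Binary branching tree of cylinder segments growing along +z.

    Each bifurcation tilts the two children by ``branch_angle`` degrees away
    from the parent direction, in a plane whose azimuth is drawn from the
    seeded RNG; segment length is ``length_scale * diameter``.  Ground truth
    records every segment with its diameter and generation.
    """
    dims = tuple(int(n) for n in dims)
    rng = np.random.default_rng(spec.rng_seed)
    nz, ny, nx = dims
    base = np.array([(nx - 1) / 2.0, (ny - 1) / 2.0, 2.0])  # (x, y, z)

    segments: list[TreeSegment] = []

    def grow(p0: np.ndarray, direction: np.ndarray, diameter: float,
             generation: int, parent: int) -> None:
        length = spec.length_scale * diameter
        p1 = p0 + direction * length
        seg_id = len(segments)
        segments.append(TreeSegment(
            segment_id=seg_id, parent_id=parent,
            p0=tuple(float(v) for v in p0), p1=tuple(float(v) for v in p1),
            diameter=float(diameter), generation=generation,
        ))
        if generation >= spec.n_generations:
            return
        azimuth = rng.uniform(0.0, 2.0 * np.pi)
        theta = math.radians(spec.branch_angle)
        # orthonormal frame around the parent direction
        ref = np.array([1.0, 0.0, 0.0])
        if abs(np.dot(ref, direction)) > 0.9:
            ref = np.array([0.0, 1.0, 0.0])
        a = np.cross(direction, ref)
        a /= np.linalg.norm(a)
        b = np.cross(direction, a)
        for phi in (azimuth, azimuth + np.pi):
            lateral = math.cos(phi) * a + math.sin(phi) * b
            child_dir = math.cos(theta) * direction + math.sin(theta) * lateral
            child_dir /= np.linalg.norm(child_dir)
            grow(p1, child_dir, diameter * spec.child_ratio, generation + 1, seg_id)

    grow(base, np.array([0.0, 0.0, 1.0]), spec.root_diameter, 1, -1)

    vol = np.zeros(dims, dtype=np.float32)
    for seg in segments:
        _rasterize_capsule(vol, np.array(seg.p0), np.array(seg.p1), seg.diameter / 2.0)

    return PhantomVolume(voxels=vol, ground_truth=segments, rng_seed=spec.rng_seed)


def _rasterize_capsule(vol: np.ndarray, p0: np.ndarray, p1: np.ndarray, r: float) -> None:
    """Set voxels within radius ``r`` of segment p0-p1 to 1 (rounded caps)."""
    nz, ny, nx = vol.shape
    lo = np.minimum(p0, p1) - r - 1
    hi = np.maximum(p0, p1) + r + 1
    x0, x1 = max(0, int(lo[0])), min(nx, int(hi[0]) + 2)
    y0, y1 = max(0, int(lo[1])), min(ny, int(hi[1]) + 2)
    z0, z1 = max(0, int(lo[2])), min(nz, int(hi[2]) + 2)
    if x0 >= x1 or y0 >= y1 or z0 >= z1:
        return
    zz = np.arange(z0, z1, dtype=np.float32)[:, None, None]
    yy = np.arange(y0, y1, dtype=np.float32)[None, :, None]
    xx = np.arange(x0, x1, dtype=np.float32)[None, None, :]
    d = p1 - p0
    length2 = float(np.dot(d, d))
    tx, ty, tz = xx - p0[0], yy - p0[1], zz - p0[2]
    if length2 > 0:
        t = np.clip((d[0] * tx + d[1] * ty + d[2] * tz) / length2, 0.0, 1.0)
    else:
        t = 0.0
    cx = tx - t * d[0]
    cy = ty - t * d[1]
    cz = tz - t * d[2]
    inside = cx * cx + cy * cy + cz * cz <= r * r
    region = vol[z0:z1, y0:y1, x0:x1]
    region[inside] = 1.0


# ---------------------------------------------------------------------------
# Synthetic 2D bolus angiography


def generate_angio_sequence(
    base: np.ndarray,
    n_frames: int,
    bolus_peak_frame: int,
    noise_sd: float,
    rng_seed: int,
    frame_interval: float = 1.0 / 30.0,
    bolus_onset_frame: int | None = None,
    background: np.ndarray | float = 1.0,
    amplitude: float = 0.5,
    decay_tau: float | None = None,
    ground_truth_diameters: dict | None = None,
) -> AngioSequence:
    """Bolus-enhanced frame sequence: static background minus a time-varying
    vessel attenuation pattern (iodinated vessels are darker) plus i.i.d.
    Gaussian noise.

    ``base`` is a 2D vessel pattern in [0, 1] (e.g. a normalized maximum
    intensity projection of a phantom).  Enhancement ramps linearly from
    ``bolus_onset_frame`` to ``bolus_peak_frame`` and decays exponentially
    afterwards with time constant ``decay_tau`` frames.
    """
    base = np.asarray(base, dtype=np.float32)
    if base.ndim != 2:
        raise ValueError("base must be a 2D image")
    if n_frames < 11:
        raise ValueError("n_frames must be >= 11")
    if not 0 <= bolus_peak_frame < n_frames:
        raise ValueError("bolus_peak_frame must lie within the sequence")
    if bolus_onset_frame is None:
        bolus_onset_frame = max(0, bolus_peak_frame - max(1, n_frames // 4))
    if decay_tau is None:
        decay_tau = max(1.0, (n_frames - bolus_peak_frame) / 3.0)

    t = np.arange(n_frames, dtype=np.float64)
    a = np.zeros(n_frames)
    ramp = bolus_peak_frame - bolus_onset_frame
    if ramp > 0:
        rising = (t >= bolus_onset_frame) & (t <= bolus_peak_frame)
        a[rising] = (t[rising] - bolus_onset_frame) / ramp
    a[t == bolus_peak_frame] = 1.0
    after = t > bolus_peak_frame
    a[after] = np.exp(-(t[after] - bolus_peak_frame) / decay_tau)

    bg = np.broadcast_to(np.asarray(background, dtype=np.float32), base.shape)
    frames = bg[None] - amplitude * a[:, None, None].astype(np.float32) * base[None]
    if noise_sd > 0:
        rng = np.random.default_rng(rng_seed)
        frames = frames + rng.normal(0.0, noise_sd, frames.shape).astype(np.float32)
    else:
        frames = frames.copy()

    return AngioSequence(
        frames=frames.astype(np.float32),
        frame_interval=frame_interval,
        bolus_onset_frame=int(bolus_onset_frame),
        ground_truth_diameters=dict(ground_truth_diameters or {}),
        bolus_peak_frame=int(bolus_peak_frame),
    )
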