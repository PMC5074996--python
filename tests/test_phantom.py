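"""Tube, tree and bolus-sequence phantom generators."""

import numpy as np
import pytest

from vesscal.phantom import (
    TreePhantomSpec,
    TubeSpec,
    calibration_phantom,
    generate_angio_sequence,
    generate_tree_volume,
    generate_tube_volume,
    rotation_matrix,
    tube_axis,
)
from vesscal.phantom import _line_distance


def _fwhm_bruteforce(x, v):
    """Dense half-maximum crossing scan, independent of the caliber module."""
    half = (v.min() + v.max()) / 2.0
    above = np.nonzero(v >= half)[0]
    return x[above[-1]] - x[above[0]]


class TestTubeVolume:
    def test_axis_aligned_cross_section_area(self):
        vol = generate_tube_volume(
            [TubeSpec(diameter=10.0)], (24, 32, 32), supersampling=1
        )
        areas = vol.voxels.sum(axis=(1, 2))
        # lattice-point count of a disc of radius 5 deviates from pi r^2 by
        # the Gauss-circle error (~2.5 voxels at this radius)
        assert np.all(np.abs(areas - np.pi * 25.0) <= 2.6)
        assert set(np.unique(vol.voxels)) <= {0.0, 1.0}

    def test_empty_spec_list_gives_uniform_background(self):
        vol = generate_tube_volume([], (8, 8, 8))
        assert np.all(vol.voxels == 0.0)

    def test_rotated_tube_fwhm_width(self):
        spec = TubeSpec(diameter=20.0, axis_rotation=(30.0, 15.0, 0.0))
        vol = generate_tube_volume([spec], (64, 64, 64), supersampling=3)
        point, u = tube_axis(spec, vol.shape)
        # brute-force profile scan perpendicular to the analytic cylinder axis
        perp = np.cross(u, [0.0, 0.0, 1.0])
        perp /= np.linalg.norm(perp)
        t = np.linspace(-18, 18, 1441)
        pts = point[None, :] + t[:, None] * perp[None, :]  # (x, y, z)
        from scipy.ndimage import map_coordinates

        prof = map_coordinates(
            vol.voxels.astype(float), [pts[:, 2], pts[:, 1], pts[:, 0]], order=1
        )
        width = _fwhm_bruteforce(t, prof)
        assert width == pytest.approx(20.0, abs=1.0)

    def test_overlapping_tubes_rejected(self):
        specs = [
            TubeSpec(diameter=10.0),
            TubeSpec(diameter=10.0, center_offset=(6.0, 0.0, 0.0)),
        ]
        with pytest.raises(ValueError, match="overlap"):
            generate_tube_volume(specs, (24, 48, 48))

    def test_deterministic(self):
        spec = TubeSpec(diameter=8.0, axis_rotation=(10.0, 20.0, 0.0))
        a = generate_tube_volume([spec], (32, 32, 32))
        b = generate_tube_volume([spec], (32, 32, 32))
        assert np.array_equal(a.voxels, b.voxels)

    def test_dims_must_accommodate_tubes(self):
        with pytest.raises(ValueError, match="twice the largest"):
            generate_tube_volume([TubeSpec(diameter=20.0)], (24, 64, 64))

    def test_invalid_specs(self):
        with pytest.raises(ValueError):
            TubeSpec(diameter=0.0)
        with pytest.raises(ValueError):
            TubeSpec(diameter=5.0, foreground_value=0.0, background_value=1.0)

    def test_voxelization_error_shrinks_with_supersampling(self):
        spec = TubeSpec(diameter=7.3, axis_rotation=(30.0, 15.0, 0.0))
        point = None
        errors = []
        for ss in (1, 2, 4):
            vol = generate_tube_volume([spec], (32, 32, 32), supersampling=ss)
            point, u = tube_axis(spec, vol.shape)
            perp = np.cross(u, [0.0, 0.0, 1.0])
            perp /= np.linalg.norm(perp)
            t = np.linspace(-10, 10, 2001)
            pts = point[None, :] + t[:, None] * perp[None, :]
            from scipy.ndimage import map_coordinates

            prof = map_coordinates(
                vol.voxels.astype(float), [pts[:, 2], pts[:, 1], pts[:, 0]],
                order=1,
            )
            errors.append(abs(_fwhm_bruteforce(t, prof) - 7.3))
        assert errors[2] <= errors[0] + 0.02
        assert errors[2] <= 0.3

    def test_rotation_preserves_length_normalized_volume(self):
        d = 10.0
        straight = generate_tube_volume([TubeSpec(diameter=d)], (48, 48, 48))
        rot = generate_tube_volume(
            [TubeSpec(diameter=d, axis_rotation=(30.0, 15.0, 0.0))], (48, 48, 48)
        )

        def per_length(vol, spec):
            point, u = tube_axis(spec, vol.shape)
            # chord length of the axis inside the volume
            ts = []
            for axis in range(3):
                if abs(u[axis]) > 1e-12:
                    for bound in (0.0, vol.shape[2 - axis] - 1.0):
                        ts.append((bound - point[axis]) / u[axis])
            ts = sorted(t for t in ts)
            inside = [
                t for t in ts
                if all(-1e-9 <= (point + t * u)[i] <= vol.shape[2 - i] - 1 + 1e-9
                       for i in range(3))
            ]
            length = max(inside) - min(inside)
            return vol.voxels.sum() / length

        a = per_length(straight, straight.ground_truth[0])
        b = per_length(rot, rot.ground_truth[0])
        assert abs(a - b) / a < 0.02


@pytest.fixture(scope="module")
def layout():
    # supersampling 1 keeps this layout check cheap; tube placement and
    # ground truth are identical to the production phantom
    return calibration_phantom(supersampling=1)


class TestCalibrationPhantom:
    def test_diameter_range(self, layout):
        d = sorted(s.diameter for s in layout.ground_truth)
        assert d[0] == pytest.approx(3.14)
        assert d[-1] == pytest.approx(62.8)
        assert len(d) == 10

    def test_surface_clearance_at_least_largest_diameter(self, layout):
        specs = layout.ground_truth
        dmax = max(s.diameter for s in specs)
        axes = [tube_axis(s, layout.shape) for s in specs]
        for i in range(len(specs)):
            for j in range(i + 1, len(specs)):
                gap = _line_distance(*axes[i], *axes[j]) - (
                    specs[i].diameter + specs[j].diameter) / 2.0
                assert gap >= dmax - 1e-6

    def test_all_tubes_share_rotation(self, layout):
        assert all(s.axis_rotation == (30.0, 15.0, 0.0)
                   for s in layout.ground_truth)

    def test_deterministic(self):
        a = calibration_phantom(3.14, 12.0, n_tubes=3, nz=96)
        b = calibration_phantom(3.14, 12.0, n_tubes=3, nz=96)
        assert np.array_equal(a.voxels, b.voxels)


class TestTreeVolume:
    def test_single_generation_is_one_cylinder(self):
        spec = TreePhantomSpec(n_generations=1, root_diameter=10.0, rng_seed=0)
        vol = generate_tree_volume(spec, (48, 48, 48))
        assert len(vol.ground_truth) == 1
        seg = vol.ground_truth[0]
        # straight cylinder: every occupied slice has the same disc area
        zs = np.nonzero(vol.voxels.any(axis=(1, 2)))[0]
        interior = zs[3:-3]
        areas = vol.voxels[interior].sum(axis=(1, 2))
        assert np.all(np.abs(areas - np.pi * 25.0) <= 3.0)
        assert seg.generation == 1 and seg.parent_id == -1

    def test_terminal_diameter_ground_truth(self):
        spec = TreePhantomSpec(n_generations=3, root_diameter=20.0,
                               child_ratio=0.7, rng_seed=1)
        vol = generate_tree_volume(spec, (160, 160, 160))
        terminal = [s.diameter for s in vol.ground_truth if s.generation == 3]
        assert len(terminal) == 4
        assert all(d == pytest.approx(20.0 * 0.7 ** 2) for d in terminal)

    def test_seed_determinism(self):
        spec = TreePhantomSpec(n_generations=2, root_diameter=12.0, rng_seed=5)
        a = generate_tree_volume(spec, (96, 96, 96))
        b = generate_tree_volume(spec, (96, 96, 96))
        assert np.array_equal(a.voxels, b.voxels)

    def test_terminal_diameter_below_two_px_rejected(self):
        with pytest.raises(ValueError, match="terminal diameter"):
            TreePhantomSpec(n_generations=4, root_diameter=5.0, child_ratio=0.5)


class TestAngioSequence:
    def _base(self):
        img = np.zeros((32, 32), dtype=np.float32)
        img[:, 14:18] = 1.0
        return img

    def test_pre_onset_frames_equal_background(self):
        seq = generate_angio_sequence(self._base(), 40, 20, 0.0, 0,
                                      bolus_onset_frame=10)
        assert np.array_equal(seq.frames[0], np.ones((32, 32), np.float32))
        assert np.array_equal(seq.frames[9], seq.frames[0])

    def test_max_enhancement_at_peak(self):
        seq = generate_angio_sequence(self._base(), 40, 17, 0.0, 0)
        enh = seq.frames[0][None] - seq.frames  # darker = more enhancement
        vessel = self._base() > 0
        per_frame = enh[:, vessel].sum(axis=1)
        assert int(np.argmax(per_frame)) == 17

    def test_seed_determinism(self):
        a = generate_angio_sequence(self._base(), 30, 12, 0.05, 42)
        b = generate_angio_sequence(self._base(), 30, 12, 0.05, 42)
        assert np.array_equal(a.frames, b.frames)

    def test_too_few_frames_rejected(self):
        with pytest.raises(ValueError):
            generate_angio_sequence(self._base(), 8, 4, 0.0, 0)


def test_rotation_matrix_order():
    # x-then-y-then-z extrinsic: R = Rz Ry Rx; check against a hand case
    r = rotation_matrix(90.0, 0.0, 0.0)
    assert np.allclose(r @ [0, 0, 1], [0, -1, 0], atol=1e-12)
    r = rotation_matrix(0.0, 90.0, 0.0)
    assert np.allclose(r @ [0, 0, 1], [1, 0, 0], atol=1e-12)
    r = rotation_matrix(30.0, 15.0, 0.0)
    u = r @ [0, 0, 1]
    assert np.allclose(np.linalg.norm(u), 1.0)
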