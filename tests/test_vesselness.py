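"""Hessian computation, eigenvalue sorting, and the vesselness functional."""

import numpy as np
import pytest
from scipy import ndimage as ndi

from vesscal.phantom import TubeSpec, generate_tube_volume
from vesscal.vesselness import (
    HessianEigenvalues,
    HessianField,
    VesselnessParams,
    hessian_at_scale,
    multiscale_vesselness,
    sorted_eigenvalues,
    vesselness_at_scale,
)


def _const_field(m, shape=(4, 4, 4)):
    """HessianField with the same symmetric 3x3 matrix at every voxel."""
    m = np.asarray(m, dtype=float)
    full = lambda v: np.full(shape, v)
    return HessianField(scale=1.0, gamma=0.0,
                        d00=full(m[0, 0]), d11=full(m[1, 1]), d22=full(m[2, 2]),
                        d01=full(m[0, 1]), d02=full(m[0, 2]), d12=full(m[1, 2]))


class TestHessian:
    def test_constant_volume_zero(self):
        h = hessian_at_scale(np.full((16, 16, 16), 3.7), 2.0)
        for comp in (h.d00, h.d11, h.d22, h.d01, h.d02, h.d12):
            assert np.abs(comp).max() < 1e-8

    def test_quadratic_ramp_second_derivative(self):
        # Gaussian smoothing preserves polynomials of degree <= 2 away from
        # the boundary: d2/dx2 of a*x^2 is 2a, normalized by S**gamma.
        a = 0.05
        n = 48
        x = np.arange(n, dtype=float)
        vol = np.broadcast_to(a * x ** 2, (n, n, n)).copy()
        s, gamma = 2.0, 2.0
        h = hessian_at_scale(vol, s, gamma=gamma)
        interior = (slice(16, -16),) * 3
        assert h.d22[interior] == pytest.approx(2 * a * s ** gamma, rel=1e-3)
        assert np.abs(h.d00[interior]).max() < 1e-6
        assert np.abs(h.d01[interior]).max() < 1e-6

    def test_axis_swap_symmetry(self):
        rng = np.random.default_rng(0)
        vol = ndi.gaussian_filter(rng.standard_normal((24, 28, 32)), 2)
        h = hessian_at_scale(vol, 2.0)
        ht = hessian_at_scale(vol.transpose(2, 1, 0), 2.0)
        # swapping z and x swaps d00<->d22 and mirrors the off-diagonals
        assert np.allclose(ht.d00, h.d22.transpose(2, 1, 0), atol=1e-10)
        assert np.allclose(ht.d22, h.d00.transpose(2, 1, 0), atol=1e-10)
        assert np.allclose(ht.d01, h.d12.transpose(2, 1, 0), atol=1e-10)

    def test_matches_spatial_convolution_oracle(self):
        # independent oracle: truncated-kernel Gaussian derivatives with
        # reflective boundary from scipy.ndimage
        rng = np.random.default_rng(1)
        vol = rng.standard_normal((30, 34, 38))
        s = 3.0
        h = hessian_at_scale(vol, s, gamma=0.0)
        pairs = [
            (h.d00, (2, 0, 0)), (h.d11, (0, 2, 0)), (h.d22, (0, 0, 2)),
            (h.d01, (1, 1, 0)), (h.d02, (1, 0, 1)), (h.d12, (0, 1, 1)),
        ]
        for ours, orders in pairs:
            ref = ndi.gaussian_filter(vol, s, order=orders, mode="reflect")
            scale = max(np.abs(ref).max(), 1e-12)
            assert np.abs(ours - ref).max() / scale < 2e-3

    def test_scale_too_large_rejected(self):
        with pytest.raises(ValueError, match="half the smallest"):
            hessian_at_scale(np.zeros((16, 64, 64)), 9.0)
        with pytest.raises(ValueError):
            hessian_at_scale(np.zeros((16, 16, 16)), 0.0)


class TestEigenvalues:
    def test_diagonal_field_sorted_by_magnitude(self):
        eig = sorted_eigenvalues(_const_field(np.diag([-1.0, -4.0, 0.5])))
        assert np.all(eig.lam1 == 0.5)
        assert np.all(eig.lam2 == -1.0)
        assert np.all(eig.lam3 == -4.0)

    def test_zero_matrix(self):
        eig = sorted_eigenvalues(_const_field(np.zeros((3, 3))))
        for lam in (eig.lam1, eig.lam2, eig.lam3):
            assert np.all(lam == 0.0)

    def test_rotation_invariance_against_lapack_oracle(self):
        rng = np.random.default_rng(2)
        d = np.diag(rng.normal(size=3) * 5)
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        m = q @ d @ q.T
        eig = sorted_eigenvalues(_const_field(m))
        ref = np.linalg.eigvalsh(m)
        ref = ref[np.argsort(np.abs(ref))]
        got = np.array([eig.lam1[0, 0, 0], eig.lam2[0, 0, 0], eig.lam3[0, 0, 0]])
        assert got == pytest.approx(ref, abs=1e-9)

    def test_random_fields_match_lapack_oracle(self):
        rng = np.random.default_rng(3)
        n = 500
        mats = rng.standard_normal((n, 3, 3))
        mats = (mats + mats.transpose(0, 2, 1)) / 2
        field = HessianField(
            scale=1.0, gamma=0.0,
            d00=mats[:, 0, 0].reshape(n, 1, 1),
            d11=mats[:, 1, 1].reshape(n, 1, 1),
            d22=mats[:, 2, 2].reshape(n, 1, 1),
            d01=mats[:, 0, 1].reshape(n, 1, 1),
            d02=mats[:, 0, 2].reshape(n, 1, 1),
            d12=mats[:, 1, 2].reshape(n, 1, 1),
        )
        eig = sorted_eigenvalues(field)
        got = np.stack([eig.lam1, eig.lam2, eig.lam3], axis=-1).reshape(n, 3)
        ref = np.linalg.eigvalsh(mats)
        ref = np.take_along_axis(ref, np.argsort(np.abs(ref), axis=1), axis=1)
        assert np.abs(np.abs(got) - np.abs(ref)).max() < 1e-8
        # sorted magnitudes and the multiset of values both agree
        assert np.abs(np.sort(got, axis=1) - np.sort(ref, axis=1)).max() < 1e-8


class TestVesselnessFunctional:
    def _eig(self, l1, l2, l3):
        full = lambda v: np.full((2, 2, 2), float(v))
        return HessianEigenvalues(lam1=full(l1), lam2=full(l2), lam3=full(l3))

    def test_zero_eigenvalues_zero_vesselness(self):
        v = vesselness_at_scale(self._eig(0, 0, 0), VesselnessParams(), c=1.0)
        assert np.all(v == 0.0)

    def test_ideal_bright_tube_closed_form(self):
        # lam = (0, -k, -k), k >> c: R_A = 1, R_B = 0, structureness -> 1,
        # so V -> 1 - exp(-1 / (2 alpha^2)) = 1 - e^-2 at alpha = 0.5
        k = 100.0
        params = VesselnessParams(alpha=0.5)
        v = vesselness_at_scale(self._eig(0, -k, -k), params, c=k / 1000.0)
        assert v[0, 0, 0] == pytest.approx(1.0 - np.exp(-2.0), abs=1e-6)

    def test_ideal_bright_plate_suppressed(self):
        v = vesselness_at_scale(self._eig(0, 0, -50.0), VesselnessParams(), c=1.0)
        assert np.all(v == 0.0)

    def test_wrong_polarity_zero(self):
        v = vesselness_at_scale(self._eig(0, 50.0, 50.0), VesselnessParams(), c=1.0)
        assert np.all(v == 0.0)
        dark = VesselnessParams(polarity="dark")
        v = vesselness_at_scale(self._eig(0, 50.0, 50.0), dark, c=0.01)
        assert np.all(v > 0.5)

    def test_values_in_unit_interval_no_nan(self):
        rng = np.random.default_rng(4)
        eig = sorted_eigenvalues(_const_field(np.zeros((3, 3)), shape=(1, 1, 1)))
        # random eigenvalue fields incl. exact zeros
        l = rng.standard_normal((3, 11, 11, 11))
        l[:, ::3] = 0.0
        eig = HessianEigenvalues(lam1=l[0], lam2=l[1], lam3=l[2])
        v = vesselness_at_scale(eig, VesselnessParams(), c=0.7)
        assert np.all(np.isfinite(v))
        assert v.min() >= 0.0 and v.max() <= 1.0


class TestMultiscale:
    def test_constant_volume_null_everywhere(self):
        res = multiscale_vesselness(
            np.full((24, 24, 24), 5.0),
            VesselnessParams(scales=(1.0, 2.0, 3.0)),
        )
        assert np.all(res.probability == 0.0)
        assert np.all(res.s_max == 0.0)

    def test_smax_values_are_scales_or_null(self):
        vol = generate_tube_volume([TubeSpec(diameter=8.0)], (32, 32, 32)).voxels
        params = VesselnessParams(scales=tuple(float(s) for s in range(1, 7)))
        res = multiscale_vesselness(vol, params)
        got = set(np.unique(res.s_max))
        assert got <= set(params.scales) | {0.0}
        assert np.all(res.s_max[res.probability == 0] == 0.0)
        assert res.probability.min() >= 0.0 and res.probability.max() <= 1.0

    def test_tube_centerline_smax_tracks_diameter(self):
        # a 20 px tube should peak near 0.3447 * 20 ~ 7 (one scale step slack)
        vol = generate_tube_volume([TubeSpec(diameter=20.0)], (64, 72, 72)).voxels
        params = VesselnessParams(scales=tuple(float(s) for s in range(1, 31)))
        res = multiscale_vesselness(vol, params)
        c = res.s_max[32, 35, 35]
        assert abs(c - 0.3447 * 20.0) <= 1.0 + 1e-6

    def test_larger_tube_larger_centerline_smax(self):
        specs = [
            TubeSpec(diameter=10.0, center_offset=(-45.0, 0.0, 0.0)),
            TubeSpec(diameter=40.0, center_offset=(35.0, 0.0, 0.0)),
        ]
        vol = generate_tube_volume(specs, (80, 96, 176))
        params = VesselnessParams(scales=tuple(float(s) for s in range(1, 16)))
        res = multiscale_vesselness(vol.voxels, params)
        mid_small = res.s_max[40, 47, 87 - 45]
        mid_large = res.s_max[40, 47, 87 + 35]
        assert mid_large > mid_small

    def test_contrast_invariant_argmax_with_auto_c(self):
        vol = generate_tube_volume([TubeSpec(diameter=10.0)], (40, 40, 40)).voxels
        params = VesselnessParams(scales=tuple(float(s) for s in range(1, 9)))
        a = multiscale_vesselness(vol, params)
        b = multiscale_vesselness(vol * 7.5, params)
        assert np.array_equal(a.s_max, b.s_max)
        assert b.c_resolved == pytest.approx(7.5 * a.c_resolved, rel=1e-5)

    def test_rotation_leaves_centerline_smax_within_one_step(self):
        d = 12.0
        params = VesselnessParams(scales=tuple(float(s) for s in range(1, 10)))
        straight = generate_tube_volume([TubeSpec(diameter=d)], (48, 48, 48))
        rot = generate_tube_volume(
            [TubeSpec(diameter=d, axis_rotation=(30.0, 15.0, 0.0))], (48, 48, 48)
        )

        def centerline_median(vol):
            res = multiscale_vesselness(vol.voxels, params)
            spec = vol.ground_truth[0]
            from vesscal.phantom import tube_axis

            point, u = tube_axis(spec, vol.shape)
            svals = []
            for t in np.linspace(-10, 10, 21):
                p = point + t * u
                svals.append(res.s_max[int(round(p[2])), int(round(p[1])),
                                       int(round(p[0]))])
            return np.median(svals)

        assert abs(centerline_median(straight) - centerline_median(rot)) <= 1.0

    def test_empty_scales_rejected(self):
        with pytest.raises(ValueError):
            VesselnessParams(scales=())
        with pytest.raises(ValueError):
            VesselnessParams(scales=(2.0, 1.0))
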