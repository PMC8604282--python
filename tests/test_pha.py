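"""PHA recoding: phase, height, normals, gravity recovery, entropy."""

import numpy as np
import pytest

import weedspot as ws
from weedspot.camera import CameraRig, intrinsics_matrix
from weedspot.pha import (
    RecodeParams,
    compute_gravity_angle,
    compute_height,
    compute_phase,
    estimate_gravity,
    estimate_normals,
    image_entropy,
    recode_to_pha,
    render_depth_8bit,
)
from weedspot.rgbd_io import DepthRaster


def _flat(value, shape=(8, 8)):
    return DepthRaster(np.full(shape, float(value)))


class TestPhase:
    def test_phase_vanishes_at_zero_depth_limit(self):
        # d = 0 itself is the invalid sentinel; the formula's phi(0) = 0 is
        # reached continuously from above
        phi = compute_phase(_flat(1e-6), RecodeParams(l=100))
        np.testing.assert_allclose(phi, 0.0, atol=1e-7)

    def test_exact_wrap_maps_to_zero(self):
        phi = compute_phase(_flat(200 * np.pi), RecodeParams(l=100))
        np.testing.assert_allclose(phi, 0.0, atol=1e-12)

    def test_half_period_gives_pi(self):
        phi = compute_phase(_flat(100 * np.pi), RecodeParams(l=100))
        np.testing.assert_allclose(phi, np.pi)

    def test_periodic_in_depth_with_period_2_pi_l(self):
        params = RecodeParams(l=64)
        period = 2 * np.pi * params.l
        base = np.linspace(10, 1500, 64).reshape(8, 8)
        p0 = compute_phase(DepthRaster(base), params)
        p1 = compute_phase(DepthRaster(base + period), params)
        p2 = compute_phase(DepthRaster(base + 3 * period), params)
        np.testing.assert_allclose(p0, p1, atol=1e-9)
        np.testing.assert_allclose(p0, p2, atol=1e-9)

    def test_range_half_open(self):
        rng = np.random.default_rng(0)
        phi = compute_phase(DepthRaster(rng.uniform(1, 5000, (32, 32))), RecodeParams(l=64))
        assert np.all(phi >= 0) and np.all(phi < 2 * np.pi)

    def test_l_zero_rejected(self):
        with pytest.raises(ValueError):
            RecodeParams(l=0)

    def test_holes_rejected(self):
        vals = np.full((4, 4), 500.0)
        vals[0, 0] = 0.0
        with pytest.raises(ValueError, match="hole-free"):
            compute_phase(DepthRaster(vals), RecodeParams())


class TestHeight:
    @pytest.mark.parametrize("d,expected", [(2000.0, 0.0), (1500.0, 500.0)])
    def test_arithmetic(self, d, expected):
        H = compute_height(_flat(d), d_max=2000.0)
        np.testing.assert_allclose(H, expected)

    def test_constant_depth_zero_height_with_per_image_dmax(self):
        depth = _flat(777.0)
        H = compute_height(depth, d_max=float(depth.values.max()))
        np.testing.assert_array_equal(H, 0.0)

    def test_dmax_below_observed_rejected(self):
        with pytest.raises(ValueError, match="below the observed"):
            compute_height(_flat(900.0), d_max=800.0)


def _nadir_rig(size=64, fx=80.0):
    return CameraRig.identity(fx, fx, (size - 1) / 2, (size - 1) / 2)


class TestNormals:
    def test_fronto_parallel_plane_normals_on_axis(self):
        rig = _nadir_rig()
        n = estimate_normals(_flat(700.0, (64, 64)), rig, window=5)
        # oriented toward the camera: -z
        angles = np.degrees(np.arccos(np.clip(-n[..., 2], -1, 1)))
        assert angles.max() < 0.5

    def test_tilted_plane_recovers_tilt_angle(self):
        rig = _nadir_rig()
        vv, uu = np.mgrid[0:64, 0:64].astype(float)
        Kinv = np.linalg.inv(rig.K_depth)
        rays = np.stack([uu, vv, np.ones_like(uu)], axis=-1) @ Kinv.T
        tilt = np.deg2rad(10.0)
        normal = np.array([np.sin(tilt), 0.0, np.cos(tilt)])  # plane normal
        depth = 700.0 / (rays @ normal)
        n = estimate_normals(DepthRaster(depth), rig, window=5)
        interior = n[5:-5, 5:-5]
        ang = np.degrees(np.arccos(np.clip(-(interior @ normal), -1, 1)))
        assert np.median(ang) < 0.5

    def test_window_size_invariance_on_noiseless_plane(self):
        rig = _nadir_rig()
        depth = _flat(700.0, (64, 64))
        n3 = estimate_normals(depth, rig, window=3)
        n7 = estimate_normals(depth, rig, window=7)
        dots = np.clip(np.abs((n3 * n7).sum(axis=-1)), -1, 1)
        assert np.degrees(np.arccos(dots)).max() < 0.5

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            estimate_normals(_flat(700.0), _nadir_rig(8), window=4)


class TestGravity:
    def test_single_direction_limit(self):
        normals = np.tile([0.0, 0.0, 1.0], (100, 1))
        est = estimate_gravity(normals)
        np.testing.assert_allclose(np.abs(est.g), [0, 0, 1], atol=1e-9)
        assert est.g[2] > 0  # sign fixed toward the camera down-axis

    def test_floor_dominates_fifty_fifty_split(self):
        # half the normals on the down-axis (parallel set), half on x
        # (perpendicular set): the eigen update must keep g on the floor axis
        normals = np.concatenate(
            [np.tile([0.0, 0.0, 1.0], (50, 1)), np.tile([1.0, 0.0, 0.0], (50, 1))]
        )
        est = estimate_gravity(normals)
        ang = np.degrees(np.arccos(np.clip(est.g @ np.array([0, 0, 1.0]), -1, 1)))
        assert ang < 0.5
        assert est.n_parallel == 50 and est.n_perpendicular == 50

    def test_recovery_on_synthetic_scene(self, small_scene, small_pha):
        # a single coarse 96x96 scene: loose bound here; the tight median
        # bound over many scenes lives in the acceptance suite
        est = small_pha.gravity
        ang = np.degrees(np.arccos(np.clip(abs(est.g @ small_scene.true_gravity), -1, 1)))
        assert ang <= 5.0
        assert est.converged

    def test_printed_objective_variant_runs(self):
        rng = np.random.default_rng(0)
        normals = rng.standard_normal((500, 3))
        normals[:400] = [0, 0, 1.0]
        normals /= np.linalg.norm(normals, axis=1, keepdims=True)
        est = estimate_gravity(normals, RecodeParams(gravity_objective="printed"))
        assert np.isfinite(est.objective)

    def test_no_normals_rejected(self):
        with pytest.raises(ValueError):
            estimate_gravity(np.zeros((0, 3)))


class TestGravityAngle:
    def test_parallel_perpendicular_antiparallel(self):
        g = np.array([0.0, 0.0, 1.0])
        normals = np.array([[0, 0, 1.0], [1, 0, 0.0], [0, 0, -1.0]])
        np.testing.assert_allclose(compute_gravity_angle(normals, g), [0.0, 90.0, 180.0])

    def test_non_unit_gravity_rejected(self):
        with pytest.raises(ValueError):
            compute_gravity_angle(np.array([[0, 0, 1.0]]), np.array([0, 0, 2.0]))


class TestRecode:
    def test_constant_plane_quantized_height_zero(self):
        rig = _nadir_rig(32)
        pha = recode_to_pha(_flat(700.0, (32, 32)), rig)
        assert np.all(pha.quantized[..., 1] == 0)

    def test_channel_ranges_and_finiteness(self, small_pha):
        assert small_pha.quantized.dtype == np.uint8
        assert np.all(small_pha.phase >= 0) and np.all(small_pha.phase < 2 * np.pi)
        assert np.all(small_pha.height >= 0) and np.all(small_pha.height <= small_pha.d_max)
        assert np.all(small_pha.angle >= 0) and np.all(small_pha.angle <= 180)
        for arr in (small_pha.phase, small_pha.height, small_pha.angle):
            assert np.isfinite(arr).all()

    def test_deterministic(self, filled_depth, small_scene):
        a = recode_to_pha(filled_depth, small_scene.camera)
        b = recode_to_pha(filled_depth, small_scene.camera)
        np.testing.assert_array_equal(a.quantized, b.quantized)

    def test_quantization_monotone_per_channel(self):
        # larger depth -> larger rendered height byte is monotone decreasing;
        # phase bytes are monotone in phase
        rig = _nadir_rig(16)
        d1 = recode_to_pha(_flat(650.0, (16, 16)), rig, RecodeParams(d_max=700))
        d2 = recode_to_pha(_flat(690.0, (16, 16)), rig, RecodeParams(d_max=700))
        assert d1.quantized[..., 1].mean() > d2.quantized[..., 1].mean()


class TestEntropy:
    def test_constant_image_zero_bits(self):
        assert image_entropy(np.full((32, 32), 7, dtype=np.uint8)) == 0.0

    def test_two_equal_values_one_bit(self):
        img = np.zeros((16, 16), dtype=np.uint8)
        img[:, 8:] = 200
        assert image_entropy(img) == pytest.approx(1.0)

    def test_uniform_256_values_eight_bits(self):
        img = np.arange(256, dtype=np.uint8).reshape(16, 16)
        assert image_entropy(img) == pytest.approx(8.0)

    def test_three_channel_averaging(self):
        img = np.zeros((16, 16, 3), dtype=np.uint8)
        img[:, 8:, 0] = 5  # 1 bit in channel 0, 0 bits elsewhere
        assert image_entropy(img) == pytest.approx(1.0 / 3.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            image_entropy(np.zeros((0, 0), dtype=np.uint8))

    def test_pha_carries_more_information_than_raw_depth(self, small_pha, filled_depth):
        depth8 = render_depth_8bit(filled_depth, small_pha.d_max)
        assert image_entropy(small_pha.quantized) > image_entropy(depth8)
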