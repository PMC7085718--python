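"""Geometric core: densification, warping, smoothing, composition,
scaling-and-squaring and Jacobian determinants, each checked against an
independent oracle (explicit convolutions, analytic fields, two-stage
warping)."""

import numpy as np
import pytest
from scipy import ndimage

from semreg import bspline
from conftest import smooth_random_field


def triple_box_response(kernel: int, length: int, pos: int) -> np.ndarray:
    """Oracle: impulse convolved three times with a normalised k-box."""
    box = np.ones(kernel) / kernel
    resp = np.zeros(length)
    resp[pos] = 1.0
    for _ in range(3):
        resp = np.convolve(resp, box, mode="same")
    return resp


class TestDensify:
    def test_constant_grid_partition_of_unity(self):
        ctrl = np.full((2, 4, 4), 2.5, dtype=np.float32)
        field = bspline.densify(ctrl, (16, 16), 5, spacing=4)
        assert np.abs(field - 2.5).max() < 1e-5

    def test_zero_grid(self):
        field = bspline.densify(np.zeros((2, 4, 4)), (16, 16), 3, spacing=4)
        assert np.abs(field).max() == 0.0

    @pytest.mark.parametrize("kernel", [3, 5, 7])
    def test_impulse_matches_triple_box_convolution(self, kernel):
        # spacing 1 makes the upsampling the identity, isolating the pooling
        n = 41
        ctrl = np.zeros((2, n, n), dtype=np.float32)
        ctrl[0, n // 2, n // 2] = 1.0
        field = bspline.densify(ctrl, (n, n), kernel, spacing=1)
        resp = triple_box_response(kernel, n, n // 2)
        expected = np.outer(resp, resp)
        assert np.abs(field[0] - expected).max() < 1e-5
        assert np.abs(field[1]).max() == 0.0

    def test_linearity(self, rng):
        g1 = rng.normal(size=(2, 5, 5)).astype(np.float32)
        g2 = rng.normal(size=(2, 5, 5)).astype(np.float32)
        a, b = 1.7, -0.6
        lhs = bspline.densify(a * g1 + b * g2, (20, 20), 5, spacing=4)
        rhs = a * bspline.densify(g1, (20, 20), 5, spacing=4) + b * bspline.densify(
            g2, (20, 20), 5, spacing=4
        )
        assert np.abs(lhs - rhs).max() < 1e-4

    def test_parameter_errors(self):
        ctrl = np.zeros((2, 4, 4))
        with pytest.raises(ValueError):
            bspline.densify(ctrl, (16, 16), 4, spacing=4)  # even kernel
        with pytest.raises(ValueError):
            bspline.densify(ctrl, (16, 16), 17, spacing=4)  # kernel > grid
        with pytest.raises(ValueError):
            bspline.densify(np.zeros((2, 1, 4)), (16, 16), 3, spacing=4)
        with pytest.raises(ValueError):
            bspline.densify(ctrl, (32, 32), 3, spacing=4)  # cannot cover


class TestWarp:
    def test_zero_field_is_identity(self, rng):
        img = rng.random((12, 12)).astype(np.float32)
        zero = np.zeros((2, 12, 12), dtype=np.float32)
        assert np.array_equal(bspline.warp(img, zero, mode="nearest"), img)
        assert np.abs(bspline.warp(img, zero) - img).max() < 1e-6

    def test_integer_translation(self, rng):
        img = rng.random((10, 10)).astype(np.float32)
        field = np.zeros((2, 10, 10), dtype=np.float32)
        field[0] = 3.0  # Dx=3: output(x,y) = source(x+3, y)
        out = bspline.warp(img, field)
        assert np.allclose(out[:, :7], img[:, 3:], atol=1e-6)

    def test_subpixel_shift_on_ramp(self):
        # source(x, y) = x; Dx = 0.5 -> interior output = x + 0.5
        img = np.tile(np.arange(10, dtype=np.float32), (10, 1))
        field = np.zeros((2, 10, 10), dtype=np.float32)
        field[0] = 0.5
        out = bspline.warp(img, field)
        expected = img + 0.5
        assert np.abs(out[:, :-1] - expected[:, :-1]).max() < 1e-5

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            bspline.warp(np.zeros((8, 8)), np.zeros((2, 10, 10)))

    def test_out_of_bounds_clamps_to_border(self):
        img = np.arange(16, dtype=np.float32).reshape(4, 4)
        field = np.full((2, 4, 4), 100.0, dtype=np.float32)
        out = bspline.warp(img, field)
        assert np.all(out == img[-1, -1])


class TestSmoothField:
    def test_constant_unchanged(self):
        field = np.full((2, 9, 9), -1.5, dtype=np.float32)
        out = bspline.smooth_field(field, 3, passes=2)
        assert np.abs(out - field).max() < 1e-6

    def test_kernel_one_identity(self, rng):
        field = rng.normal(size=(2, 7, 7)).astype(np.float32)
        assert np.array_equal(bspline.smooth_field(field, 1, passes=4), field)

    def test_impulse_matches_box_convolution_oracle(self):
        field = np.zeros((2, 15, 15), dtype=np.float32)
        field[0, 7, 7] = 4.0
        out = bspline.smooth_field(field, 3, passes=2)
        oracle = field[0]
        for _ in range(2):
            oracle = ndimage.uniform_filter(oracle, size=3, mode="nearest")
        assert np.abs(out[0] - oracle).max() < 1e-6


class TestCompose:
    def test_constant_translations_commute(self):
        t1 = np.zeros((2, 10, 10), dtype=np.float32)
        t2 = np.zeros((2, 10, 10), dtype=np.float32)
        t1[0], t1[1] = 1.0, -2.0
        t2[0], t2[1] = 0.5, 1.5
        for mode in ("additive", "transform"):
            out = bspline.compose(t1, t2, mode=mode)
            assert np.abs(out[:, 3:-3, 3:-3] - (t1 + t2)[:, 3:-3, 3:-3]).max() < 1e-6

    def test_zero_inner_returns_outer(self, rng):
        outer = smooth_random_field((16, 16), 2.0, seed=3, spacing=4)
        zero = np.zeros_like(outer)
        for mode in ("additive", "transform"):
            assert np.abs(bspline.compose(outer, zero, mode=mode) - outer).max() < 1e-6

    def test_additive_commutative(self, rng):
        a = rng.normal(size=(2, 8, 8)).astype(np.float32)
        b = rng.normal(size=(2, 8, 8)).astype(np.float32)
        assert np.array_equal(
            bspline.compose(a, b, "additive"), bspline.compose(b, a, "additive")
        )

    def test_transform_mode_matches_two_stage_warp(self):
        """One warp by compose(v2, v1, transform) == warp by v1 then by v2.

        Linear fields and a linear image keep bilinear interpolation exact,
        so the only deviation is the composition formula itself."""
        H = W = 32
        yy, xx = np.mgrid[0:H, 0:W].astype(np.float32)
        v1 = np.stack([0.05 * xx - 0.02 * yy, 0.03 * yy + 1.0])
        v2 = np.stack([-0.04 * xx + 0.5, 0.02 * xx + 0.01 * yy])
        img = 0.7 * xx + 0.3 * yy
        two_stage = bspline.warp(bspline.warp(img, v1), v2)
        one_stage = bspline.warp(img, bspline.compose(v2, v1, "transform"))
        interior = (slice(4, -4), slice(4, -4))
        assert np.abs(two_stage[interior] - one_stage[interior]).max() < 1e-3

    def test_transform_mode_closed_form_on_linear_fields(self):
        """Bilinear resampling of a linear inner field is exact, so the
        transform-mode output has an analytic form V2(x) + V1(x + V2(x))."""
        H = W = 24
        yy, xx = np.mgrid[0:H, 0:W].astype(np.float32)
        a, b, c, d = 0.05, -0.03, 0.02, 0.04
        v1 = np.stack([a * xx + b * yy, c * xx])
        v2 = np.stack([d * yy + 0.3, -0.02 * xx])
        got = bspline.compose(v2, v1, "transform")
        nx, ny = xx + v2[0], yy + v2[1]
        expected = np.stack([v2[0] + a * nx + b * ny, v2[1] + c * nx])
        interior = (slice(None), slice(2, -2), slice(2, -2))
        assert np.abs(got[interior] - expected[interior]).max() < 1e-5

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            bspline.compose(np.zeros((2, 8, 8)), np.zeros((2, 9, 9)))


class TestScalingAndSquaring:
    def test_zero_velocity(self):
        out = bspline.scaling_and_squaring(np.zeros((2, 16, 16)), steps=6)
        assert np.abs(out).max() == 0.0

    def test_constant_translation_preserved(self):
        vel = np.zeros((2, 16, 16), dtype=np.float32)
        vel[0] = 2.0
        out = bspline.scaling_and_squaring(vel, steps=6)
        assert np.abs(out - vel).max() < 1e-4

    def test_moderate_velocity_is_diffeomorphic(self):
        for seed in range(5):
            vel = smooth_random_field((64, 64), 5.0, seed=seed)
            field = bspline.scaling_and_squaring(vel, steps=6)
            det = bspline.jacobian_determinant(field)
            assert (det[2:-2, 2:-2] <= 0).sum() == 0

    def test_quadratic_convergence_to_velocity(self):
        """||sas(v) - v||_inf shrinks ~quadratically with the magnitude."""
        base = smooth_random_field((32, 32), 4.0, seed=7)
        errs = []
        for scale in (1.0, 0.5, 0.25):
            vel = base * scale
            out = bspline.scaling_and_squaring(vel, steps=6)
            errs.append(np.abs(out - vel)[:, 4:-4, 4:-4].max())
        assert errs[1] < 0.35 * errs[0]
        assert errs[2] < 0.35 * errs[1]


class TestJacobianDeterminant:
    def test_zero_field(self):
        det = bspline.jacobian_determinant(np.zeros((2, 12, 12)))
        assert np.abs(det - 1.0).max() == 0.0

    @pytest.mark.parametrize("a,b", [(0.1, -0.2), (0.5, 0.5), (-0.3, 0.0)])
    def test_linear_field_analytic(self, a, b):
        yy, xx = np.mgrid[0:16, 0:16].astype(np.float32)
        field = np.stack([a * xx, b * yy])
        det = bspline.jacobian_determinant(field)
        assert np.abs(det[1:-1, 1:-1] - (1 + a) * (1 + b)).max() < 1e-4

    def test_folding_flagged_negative(self):
        yy, xx = np.mgrid[0:16, 0:16].astype(np.float32)
        field = np.stack([-2.0 * xx, np.zeros_like(yy)])
        det = bspline.jacobian_determinant(field)
        assert np.all(det[1:-1, 1:-1] < 0)
        assert np.abs(det[1:-1, 1:-1] + 1.0).max() < 1e-4

    def test_matches_brute_force_finite_differences(self):
        """Independent oracle: per-pixel 2x2 gradient assembled in loops."""
        field = smooth_random_field((20, 20), 3.0, seed=5)
        det = bspline.jacobian_determinant(field)
        for y in range(1, 19):
            for x in range(1, 19):
                dxdx = (field[0, y, x + 1] - field[0, y, x - 1]) / 2
                dxdy = (field[0, y + 1, x] - field[0, y - 1, x]) / 2
                dydx = (field[1, y, x + 1] - field[1, y, x - 1]) / 2
                dydy = (field[1, y + 1, x] - field[1, y - 1, x]) / 2
                oracle = (1 + dxdx) * (1 + dydy) - dxdy * dydx
                assert abs(det[y, x] - oracle) < 1e-4
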