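"""Training-objective terms: worked values, invariances and gradient flow."""

import numpy as np
import pytest
from scipy import ndimage

from semreg import bspline, losses
from semreg.losses import LossWeights, deformation_loss, regularization_loss, total_loss
from semreg.nn.autodiff import Tensor
from semreg.nn.optim import Adam
from semreg.synthetic import SceneSpec, generate_pair
from conftest import smooth_random_field


class TestDeformationLoss:
    def test_identical_labels_zero_field(self):
        labels = np.zeros((12, 12), np.int64)
        labels[3:9, 3:9] = 1
        zero = np.zeros((2, 12, 12), np.float32)
        assert deformation_loss(labels, labels, zero, np.ones(2)) == 0.0

    def test_disjoint_masks_give_twice_the_area_fraction(self):
        # two disjoint masks covering fraction p each, zero field -> 2p
        # (both the foreground and the background channel differ on 2p pixels)
        H = W = 16
        p = 4 / (H * W)
        fixed = np.zeros((H, W), np.int64)
        fixed[0:2, 0:2] = 1
        moving = np.zeros((H, W), np.int64)
        moving[8:10, 8:10] = 1
        zero = np.zeros((2, H, W), np.float32)
        got = deformation_loss(fixed, moving, zero, np.ones(2))
        assert got == pytest.approx(2 * p, rel=1e-6)

    def test_bounded_by_max_weight(self, rng):
        fixed = rng.integers(0, 3, (10, 10))
        moving = rng.integers(0, 3, (10, 10))
        w = np.array([0.5, 1.0, 2.0])
        field = smooth_random_field((10, 10), 3.0, seed=0, spacing=4)
        val = deformation_loss(fixed, moving, field, w)
        assert 0.0 <= val <= w.max()

    def test_symmetric_under_swap_with_zero_field(self, rng):
        fixed = rng.integers(0, 3, (10, 10))
        moving = rng.integers(0, 3, (10, 10))
        zero = np.zeros((2, 10, 10), np.float32)
        w = np.array([1.0, 1.3, 0.7])
        assert deformation_loss(fixed, moving, zero, w) == pytest.approx(
            deformation_loss(moving, fixed, zero, w)
        )

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_true_field_beats_zero_field(self, seed):
        pair = generate_pair(SceneSpec(magnitude=6.0), seed)
        w = np.ones(4)
        with_true = deformation_loss(
            pair.fixed_labels, pair.moving_labels, pair.true_field, w
        )
        with_zero = deformation_loss(
            pair.fixed_labels, pair.moving_labels, np.zeros_like(pair.true_field), w
        )
        assert with_true < with_zero

    def test_out_of_range_label_raises(self):
        labels = np.full((4, 4), 5, np.int64)
        with pytest.raises(ValueError):
            deformation_loss(labels, labels, np.zeros((2, 4, 4)), np.ones(2))


class TestRegularizationLoss:
    def test_constant_field_zero(self):
        field = np.full((2, 10, 10), 3.0, np.float32)
        assert regularization_loss(field, 3, passes=2) == 0.0

    def test_affine_field_zero_in_interior(self):
        yy, xx = np.mgrid[0:20, 0:20].astype(np.float32)
        field = np.stack([0.1 * xx + 0.2 * yy, -0.05 * xx])
        smooth = bspline.smooth_field(field, 3, passes=2)
        interior = (slice(None), slice(3, -3), slice(3, -3))
        assert np.abs((field - smooth)[interior]).max() < 1e-5

    def test_spike_matches_convolution_oracle(self):
        field = np.zeros((2, 15, 15), np.float32)
        field[0, 7, 7] = 2.0
        got = regularization_loss(field, 3, passes=2)
        oracle_smooth = field.copy()
        for _ in range(2):
            oracle_smooth = np.stack(
                [ndimage.uniform_filter(c, size=3, mode="nearest") for c in oracle_smooth]
            )
        oracle = float(((field - oracle_smooth) ** 2).mean())
        assert got == pytest.approx(oracle, rel=1e-5)
        assert got > 0

    def test_invariant_under_constant_shift(self, rng):
        field = smooth_random_field((16, 16), 3.0, seed=1, spacing=4)
        shifted = field + 7.5
        assert regularization_loss(field, 3, 2) == pytest.approx(
            regularization_loss(shifted, 3, 2), abs=1e-5
        )

    def test_even_kernel_rejected(self):
        with pytest.raises(ValueError):
            regularization_loss(np.zeros((2, 8, 8)), 4)


class TestTotalLoss:
    def test_stated_weights_arithmetic(self):
        lw = LossWeights()  # lambda_s=1.0, lambda_r=0.001
        assert total_loss(1.0, 1.0, 0.5, 100.0, lw) == pytest.approx(2.6)

    def test_pure_deformation_ablation(self):
        lw = LossWeights(lambda_s=0.0, lambda_r=0.0)
        assert total_loss(3.0, 4.0, 0.5, 99.0, lw) == 0.5

    def test_all_zero(self):
        assert total_loss(0.0, 0.0, 0.0, 0.0, LossWeights()) == 0.0

    def test_nan_term_raises(self):
        with pytest.raises(ValueError):
            total_loss(np.nan, 0.0, 0.0, 0.0, LossWeights())

    def test_negative_weights_rejected(self):
        with pytest.raises(ValueError):
            LossWeights(lambda_s=-1.0)


class TestGradientFlow:
    def test_one_adam_step_reduces_total_loss(self):
        """The objective is differentiable end-to-end in the control grid."""
        pair = generate_pair(SceneSpec(image_size=(32, 32), magnitude=5.0), 3)
        # start slightly off the identity: at the exact zero field the L1
        # alignment term sits on absolute-value kinks where many partial
        # derivatives vanish and Adam's normalised step is uninformative
        rng = np.random.default_rng(0)
        ctrl = Tensor(
            rng.normal(0.0, 0.5, (1, 2, 8, 8)).astype(np.float32), requires_grad=True
        )
        w = np.ones(4, np.float32)
        lw = LossWeights(lambda_s=0.0, lambda_r=0.001)

        def objective():
            field = bspline.densify_graph(ctrl, (32, 32), 5, 4)
            ld = deformation_loss(pair.fixed_labels[None], pair.moving_labels[None], field, w)
            lr_ = regularization_loss(field, 3, 2)
            return total_loss(Tensor(np.float32(0)), Tensor(np.float32(0)), ld, lr_, lw)

        opt = Adam([ctrl], lr=0.01)
        before = objective()
        before.backward()
        opt.step()
        losses_after = objective()
        assert losses_after.item() < before.item()
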