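"""Registration networks and the two-step cascade.

Each registration network (RegNet) is a strided convolutional encoder that
maps the concatenated class-probability maps of the fixed and moving image
(2L channels at half image resolution) to a 2-channel B-spline control grid
of displacements.  Two stride-2 stages give a control-point spacing of 4
feature pixels (8 image pixels).  The control grid is densified by the
cubic-B-spline pooling cascade; the first step uses a large pooling kernel
(coarse, large deformations), the second a smaller one (refinement).

In the two-step cascade the second network sees the moving features already
warped by the first field, and the final field is the composition of the
two (additive or transform mode).  The final 1x1-style prediction layer of
every RegNet is zero-initialised so training starts from the identity
transform.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import bspline
from .nn.autodiff import Tensor, concat
from .nn.layers import Conv2d, ConvAct, Module

__all__ = [
    "RegNetConfig",
    "RegNet",
    "build_regnet",
    "RegistrationResult",
    "cascade_fields",
    "two_step_register",
    "single_step_register",
]

FEATURE_SPACING = 4  # control-point spacing at feature (half) resolution


@dataclass
class RegNetConfig:
    """Architecture and B-spline scale settings for the cascade."""

    num_labels: int = 4
    kernel1: int = 5            # pooling kernel of the first (coarse) step
    kernel2: int = 3            # pooling kernel of the second (refine) step
    widths: tuple = (48, 96, 192)
    widths_single: tuple = (72, 144, 288)  # one net with the full budget
    combine_mode: str = "transform"
    diffeomorphic: bool = False
    sas_steps: int = 6
    shared_weights: bool = False

    def __post_init__(self):
        if self.kernel1 % 2 == 0 or self.kernel2 % 2 == 0:
            raise ValueError("pooling kernels must be odd")
        if self.kernel1 < self.kernel2:
            raise ValueError("kernel1 must be >= kernel2 (coarse to fine)")
        if self.combine_mode not in ("additive", "transform"):
            raise ValueError(f"unknown combine mode {self.combine_mode!r}")

    @property
    def in_channels(self) -> int:
        return 2 * self.num_labels


class RegNet(Module):
    """Strided encoder: (B, 2L, h, w) features -> (B, 2, h/4, w/4) control grid."""

    def __init__(self, in_channels: int, widths: tuple, rng=None):
        e, f, g = widths
        rng = rng if rng is not None else np.random.default_rng(0)
        self.b1 = ConvAct(in_channels, e, rng=rng)
        self.b2 = ConvAct(e, f, stride=2, rng=rng)
        self.b3 = ConvAct(f, f, rng=rng)
        self.b4 = ConvAct(f, g, stride=2, rng=rng)
        self.b5 = ConvAct(g, g, rng=rng)
        self.b6 = ConvAct(g, g, rng=rng)
        self.head = Conv2d(g, 2, zero_init=True)

    def __call__(self, x: Tensor) -> Tensor:
        for layer in (self.b1, self.b2, self.b3, self.b4, self.b5, self.b6):
            x = layer(x)
        return self.head(x)


def build_regnet(cfg: RegNetConfig, single_step: bool = False, rng=None) -> RegNet:
    widths = cfg.widths_single if single_step else cfg.widths
    return RegNet(cfg.in_channels, widths, rng=rng)


@dataclass
class RegistrationResult:
    """Fields at full image resolution plus warped outputs for one pair."""

    v1: np.ndarray
    v2: np.ndarray | None
    v: np.ndarray
    warped_moving: np.ndarray | None = None
    warped_moving_labels: np.ndarray | None = None


def _as_feature_tensor(f) -> Tensor:
    t = f if isinstance(f, Tensor) else Tensor(np.asarray(f, dtype=np.float32))
    if t.ndim == 3:
        t = t.reshape(1, *t.shape)
    return t


def _predict_field(net: RegNet, ff: Tensor, fm: Tensor, kernel: int, cfg: RegNetConfig) -> Tensor:
    h, w = ff.shape[2], ff.shape[3]
    ctrl = net(concat([ff, fm], axis=1))
    field = bspline.densify_graph(ctrl, (h, w), kernel, FEATURE_SPACING)
    if cfg.diffeomorphic:
        # the network output is read as a stationary velocity field
        field = bspline.scaling_and_squaring_graph(field, cfg.sas_steps)
    return field


def cascade_fields(
    ff, fm, net1: RegNet, net2: RegNet | None, cfg: RegNetConfig
) -> dict[str, Tensor]:
    """Run the cascade on feature maps; returns half- and full-resolution fields.

    Keys: ``v1h``, ``v2h`` (feature-resolution steps, ``v2h`` None for the
    single-step variant), ``vh`` (combined, feature resolution) and ``v``
    (combined, full image resolution, image-pixel units).
    """
    ff = _as_feature_tensor(ff)
    fm = _as_feature_tensor(fm)
    if ff.shape != fm.shape:
        raise ValueError("fixed and moving feature maps must share a shape")
    v1h = _predict_field(net1, ff, fm, cfg.kernel1, cfg)
    if net2 is None:
        vh, v2h = v1h, None
    else:
        fm_warped = bspline.warp_graph(fm, v1h)
        v2h = _predict_field(net2, ff, fm_warped, cfg.kernel2, cfg)
        vh = bspline.compose_graph(v2h, v1h, cfg.combine_mode)
    return {
        "v1h": v1h,
        "v2h": v2h,
        "vh": vh,
        "v": bspline.upscale_field_2x(vh),
    }


def two_step_register(ff, fm, net1, net2, cfg: RegNetConfig) -> RegistrationResult:
    """Numpy-facing cascade: feature maps in, full-resolution fields out."""
    out = cascade_fields(ff, fm, net1, net2, cfg)
    up = lambda t: bspline.upscale_field_2x(t).data[0]
    return RegistrationResult(
        v1=up(out["v1h"]),
        v2=up(out["v2h"]) if out["v2h"] is not None else None,
        v=out["v"].data[0],
    )


def single_step_register(ff, fm, net, cfg: RegNetConfig) -> RegistrationResult:
    """One network with the full parameter budget; ``v = v1``."""
    out = cascade_fields(ff, fm, net, None, cfg)
    return RegistrationResult(
        v1=bspline.upscale_field_2x(out["v1h"]).data[0], v2=None, v=out["v"].data[0]
    )
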