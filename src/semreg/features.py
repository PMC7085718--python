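"""Semantic feature extraction.

A compact U-Net maps a greyscale image (intensities in [0, 1], height and
width divisible by 8) to per-pixel class probabilities at *half* the input
resolution.  The network is shared between the fixed and the moving image
(one instance processes both), and during training it is weakly supervised
with a weighted cross-entropy against the (downsampled) segmentation.

Architecture: 11 convolutions with 3x3 kernels, three of them stride-2,
two nearest-neighbour upsampling stages and two skip connections; LeakyReLU
(0.1) activations, no normalisation layers.  Channel widths scale with
``base_channels`` (default 16 lands near 200k trainable parameters).
"""

from __future__ import annotations

import numpy as np

from .nn import autodiff as ad
from .nn.autodiff import Tensor
from .nn.layers import Conv2d, ConvAct, Module

__all__ = ["FeatureNet", "build_feature_net", "class_weights", "semantic_loss", "downsample_labels"]


class FeatureNet(Module):
    """Encoder-decoder producing softmax class probabilities at half scale."""

    def __init__(self, num_labels: int, base_channels: int = 16, rng=None):
        if num_labels < 2:
            raise ValueError("need at least 2 labels")
        rng = rng if rng is not None else np.random.default_rng(0)
        a, b, c, d = base_channels, 2 * base_channels, 3 * base_channels, 4 * base_channels
        self.num_labels = num_labels
        self.c1 = ConvAct(1, a, rng=rng)
        self.c2 = ConvAct(a, b, stride=2, rng=rng)
        self.c3 = ConvAct(b, b, rng=rng)           # skip, 1/2 scale
        self.c4 = ConvAct(b, c, stride=2, rng=rng)
        self.c5 = ConvAct(c, c, rng=rng)           # skip, 1/4 scale
        self.c6 = ConvAct(c, d, stride=2, rng=rng)
        self.c7 = ConvAct(d, d, rng=rng)
        self.c8 = ConvAct(d + c, c, rng=rng)
        self.c9 = ConvAct(c + b, b, rng=rng)
        self.c10 = ConvAct(b, b, rng=rng)
        self.c11 = Conv2d(b, num_labels, rng=rng)

    def __call__(self, image: Tensor) -> Tensor:
        B, C, H, W = image.shape
        if C != 1:
            raise ValueError("expected a single-channel image batch")
        if H % 8 or W % 8:
            raise ValueError("image height and width must be divisible by 8")
        x = self.c1(image)
        s2 = self.c3(self.c2(x))
        s4 = self.c5(self.c4(s2))
        x = self.c7(self.c6(s4))
        x = ad.concat([ad.upsample_nearest(x, 2), s4], axis=1)
        x = self.c8(x)
        x = ad.concat([ad.upsample_nearest(x, 2), s2], axis=1)
        x = self.c10(self.c9(x))
        return ad.softmax(self.c11(x), axis=1)


def build_feature_net(num_labels: int, base_channels: int = 16, rng=None) -> FeatureNet:
    return FeatureNet(num_labels, base_channels, rng=rng)


def class_weights(
    labels, num_labels: int, floor_count: int | None = None
) -> np.ndarray:
    """Square-root inverse-frequency label weights, normalised to mean 1.

    ``w_l = sqrt(total_pixels / count_l)``, computed over a collection of
    label maps.  A label absent from every map raises unless ``floor_count``
    provides a minimum count.
    """
    if isinstance(labels, np.ndarray) and labels.ndim == 2:
        labels = [labels]
    counts = np.zeros(num_labels, dtype=np.int64)
    total = 0
    for lab in labels:
        lab = np.asarray(lab)
        if lab.min() < 0 or lab.max() >= num_labels:
            raise ValueError("label id out of range")
        counts += np.bincount(lab.ravel(), minlength=num_labels)
        total += lab.size
    if (counts == 0).any():
        if floor_count is None:
            missing = np.flatnonzero(counts == 0).tolist()
            raise ValueError(f"labels {missing} never occur; pass floor_count to proceed")
        counts = np.maximum(counts, floor_count)
    w = np.sqrt(total / counts)
    return (w / w.mean()).astype(np.float32)


def downsample_labels(labels: np.ndarray, factor: int = 2) -> np.ndarray:
    """Nearest-neighbour label downsampling (preserves label identity)."""
    return np.asarray(labels)[..., ::factor, ::factor]


def semantic_loss(probs, truth: np.ndarray, w: np.ndarray):
    """Weighted cross-entropy, averaged over pixels (and batch).

    ``-(1/N) Σ_j w[t_j] log p_{t_j}(x_j)`` with probabilities clipped to
    ``[1e-7, 1]`` before the log.  Accepts an autodiff tensor (returns a
    scalar tensor for backprop) or a plain array (returns a float).
    """
    is_tensor = isinstance(probs, Tensor)
    p = probs if is_tensor else Tensor(np.asarray(probs, dtype=np.float32))
    if p.ndim == 3:
        p = p.reshape(1, *p.shape)
    truth = np.asarray(truth)
    if truth.ndim == 2:
        truth = truth[None]
    if truth.shape != (p.shape[0], p.shape[2], p.shape[3]):
        raise ValueError(
            f"truth shape {truth.shape} does not match probabilities {p.shape}"
        )
    w = np.asarray(w, dtype=np.float32)
    picked = ad.gather_class(p, truth)
    weights = Tensor(w[truth])
    loss = -(weights * picked.clip(1e-7, 1.0).log()).mean()
    return loss if is_tensor else float(loss.data)
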