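"""Training objective for weakly supervised registration.

Three terms: a semantic loss on each image's class-probability prediction
(see :mod:`semreg.features`), a deformation loss measuring label overlap of
the warped moving segmentation against the fixed segmentation, and a
regularisation penalising deviation of the displacement field from a
locally smoothed copy of itself.  Total:

    L = lambda_s * (L_semantic_fixed + L_semantic_moving)
        + L_deform + lambda_r * L_regular

with defaults ``lambda_s = 1.0`` and ``lambda_r = 0.001``.  All terms are
pixel means, which keeps the scalar weights meaningful across image sizes
and batch sizes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import bspline
from .nn import autodiff as ad
from .nn.autodiff import Tensor

__all__ = ["LossWeights", "one_hot", "deformation_loss", "regularization_loss", "total_loss"]


@dataclass
class LossWeights:
    lambda_s: float = 1.0
    lambda_r: float = 0.001
    label_weights: np.ndarray | None = None

    def __post_init__(self):
        if self.lambda_s < 0 or self.lambda_r < 0:
            raise ValueError("loss weights must be non-negative")


def one_hot(labels: np.ndarray, num_labels: int) -> np.ndarray:
    """(B,H,W) or (H,W) integer labels -> float32 (B,L,H,W) indicator channels."""
    labels = np.asarray(labels)
    if labels.ndim == 2:
        labels = labels[None]
    if labels.max() >= num_labels:
        raise ValueError("label id >= num_labels")
    out = np.zeros((labels.shape[0], num_labels, *labels.shape[1:]), dtype=np.float32)
    b, y, x = np.ogrid[: labels.shape[0], : labels.shape[1], : labels.shape[2]]
    out[b, labels, y, x] = 1.0
    return out


def _as_batched_field(field) -> Tensor:
    t = field if isinstance(field, Tensor) else Tensor(np.asarray(field, dtype=np.float32))
    if t.ndim == 3:
        t = t.reshape(1, *t.shape)
    return t


def deformation_loss(fixed_labels, moving_labels, field, w) -> Tensor | float:
    """Weighted mean absolute difference between one-hot label channels.

    Both label maps are one-hot encoded over L classes; every moving channel
    is *bilinearly* warped by ``field`` (soft warping keeps the loss
    differentiable in the field) and compared to the fixed channel:
    ``(1/L) Σ_l w_l · mean_x |Sf_l(x) − T(V, Sm_l)(x)|``.
    """
    w = np.asarray(w, dtype=np.float32)
    L = w.size
    sf = one_hot(fixed_labels, L)
    sm = one_hot(moving_labels, L)
    is_tensor = isinstance(field, Tensor)
    ft = _as_batched_field(field)
    if sf.shape[0] != ft.shape[0]:
        raise ValueError("batch size of labels and field disagree")
    if sf.shape[2:] != tuple(ft.shape[2:]):
        raise ValueError("label maps must share the field's spatial shape")
    warped = bspline.warp_graph(Tensor(sm), ft)
    diff = (Tensor(sf) - warped).abs()
    # per-channel pixel mean, then weighted mean over channels
    wmap = Tensor(w.reshape(1, L, 1, 1))
    loss = (diff * wmap).mean()  # == (1/L) Σ_l w_l mean_x |·| by uniform weighting
    return loss if is_tensor else float(loss.data)


def regularization_loss(field, kernel: int, passes: int = 2) -> Tensor | float:
    """Mean squared deviation of the field from its smoothed version.

    ``V_smooth`` is ``passes`` unit-stride ``kernel``×``kernel`` average
    poolings of ``V``; returns ``mean((V - V_smooth)^2)`` over pixels and
    both displacement channels.
    """
    if kernel < 1 or kernel % 2 == 0:
        raise ValueError("kernel must be odd and >= 1")
    is_tensor = isinstance(field, Tensor)
    ft = _as_batched_field(field)
    smooth = ad.avg_pool_smooth(ft, kernel, passes=passes)
    loss = ((ft - smooth) ** 2).mean()
    return loss if is_tensor else float(loss.data)


def total_loss(semantic_f, semantic_m, deform, regular, lw: LossWeights):
    """``lambda_s*(Ls_f + Ls_m) + L_deform + lambda_r*L_regular``.

    Raises on non-finite terms (training aborts rather than silently
    diverging).
    """
    for name, term in (
        ("semantic_f", semantic_f),
        ("semantic_m", semantic_m),
        ("deform", deform),
        ("regular", regular),
    ):
        val = term.data if isinstance(term, Tensor) else term
        if not np.all(np.isfinite(val)):
            raise ValueError(f"non-finite loss term {name}")
    return lw.lambda_s * (semantic_f + semantic_m) + deform + lw.lambda_r * regular
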