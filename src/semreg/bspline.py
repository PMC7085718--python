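"""B-spline deformation machinery.

Dense displacement fields are arrays of shape ``(2, H, W)`` in pixel units:
channel 0 is the x (column) displacement, channel 1 the y (row)
displacement; 0-based pixel coordinates, origin top-left.  A field is used
for *backward* (pull) warping: the warped output at fixed-grid pixel ``x``
samples the moving image at ``x + D(x)``.

A coarse control grid of displacements is densified into a smooth field by
nearest-neighbour replication followed by three unit-stride average-pooling
passes — the recursive construction of the cubic cardinal B-spline (a cubic
B-spline kernel is three box filters convolved together).  All pooling uses
replicate padding so constant fields are preserved exactly (partition of
unity).

The ``*_graph`` functions mirror the numpy API on autodiff tensors so the
same geometry sits inside the differentiable training objective.
"""

from __future__ import annotations

import numpy as np

from .nn import autodiff as ad
from .nn.autodiff import Tensor, _box1d

__all__ = [
    "densify",
    "warp",
    "smooth_field",
    "compose",
    "scaling_and_squaring",
    "jacobian_determinant",
    "densify_graph",
    "warp_graph",
    "compose_graph",
    "scaling_and_squaring_graph",
    "upscale_field_2x",
    "identity_coords",
]

N_SPLINE_PASSES = 3  # box-filter passes; 3 give the cubic cardinal B-spline


def _check_kernel(kernel: int, shape: tuple[int, int] | None = None) -> None:
    if kernel < 1 or kernel % 2 == 0:
        raise ValueError(f"kernel must be odd and >= 1, got {kernel}")
    if shape is not None and (kernel > shape[-2] or kernel > shape[-1]):
        raise ValueError(f"kernel {kernel} larger than grid {shape[-2:]}")


def _check_field(field: np.ndarray) -> np.ndarray:
    field = np.asarray(field, dtype=np.float32)
    if field.ndim != 3 or field.shape[0] != 2:
        raise ValueError(f"field must have shape (2, H, W), got {field.shape}")
    if not np.all(np.isfinite(field)):
        raise ValueError("field contains non-finite values")
    return field


# ---------------------------------------------------------------------------
# densification
# ---------------------------------------------------------------------------


def densify(
    control: np.ndarray,
    target_shape: tuple[int, int],
    kernel: int,
    spacing: int | None = None,
) -> np.ndarray:
    """Densify a control grid ``(2, h', w')`` to a ``(2, H, W)`` field.

    Nearest-neighbour replication by ``spacing`` (inferred as
    ``ceil(H / h')`` when omitted), top-left crop to ``target_shape``, then
    three unit-stride ``kernel``×``kernel`` average-pooling passes.  The map
    is linear in the control values and maps constants to constants.
    """
    control = np.asarray(control, dtype=np.float32)
    if control.ndim != 3 or control.shape[0] != 2:
        raise ValueError(f"control grid must be (2, h', w'), got {control.shape}")
    if control.shape[1] < 2 or control.shape[2] < 2:
        raise ValueError("control grid must be at least 2x2")
    H, W = target_shape
    _check_kernel(kernel, (H, W))
    if spacing is None:
        spacing = int(np.ceil(max(H / control.shape[1], W / control.shape[2])))
    if control.shape[1] * spacing < H or control.shape[2] * spacing < W:
        raise ValueError(
            f"control grid {control.shape[1:]} at spacing {spacing} cannot cover {target_shape}"
        )
    up = np.repeat(np.repeat(control, spacing, axis=1), spacing, axis=2)[:, :H, :W]
    for _ in range(N_SPLINE_PASSES):
        up = _box1d(_box1d(up, kernel, -1), kernel, -2)
    return up


def smooth_field(field: np.ndarray, kernel: int, passes: int = 1) -> np.ndarray:
    """Unit-stride average-pooling smoothing, replicate padding."""
    field = np.asarray(field, dtype=np.float32)
    _check_kernel(kernel)
    if passes < 1:
        raise ValueError("passes must be >= 1")
    if kernel == 1:
        return field.copy()
    for _ in range(passes):
        field = _box1d(_box1d(field, kernel, -1), kernel, -2)
    return field


# ---------------------------------------------------------------------------
# warping
# ---------------------------------------------------------------------------


def warp(source: np.ndarray, field: np.ndarray, mode: str = "bilinear") -> np.ndarray:
    """Backward-warp ``source`` by ``field``: out(x) = source(x + D(x)).

    ``source`` may be ``(H, W)`` or ``(C, H, W)``; its spatial shape must
    match the field.  ``mode`` is ``"bilinear"`` (intensities, probabilities,
    one-hot channels) or ``"nearest"`` (integer label maps).  Out-of-bounds
    samples clamp to the border.
    """
    field = _check_field(field)
    source = np.asarray(source)
    squeeze = source.ndim == 2
    src = source[None] if squeeze else source
    if src.ndim != 3 or src.shape[1:] != field.shape[1:]:
        raise ValueError(
            f"source spatial shape {source.shape} does not match field {field.shape[1:]}"
        )
    H, W = field.shape[1:]
    xs, ys = np.meshgrid(np.arange(W), np.arange(H))
    cx = xs + field[0]
    cy = ys + field[1]
    if mode == "nearest":
        xi = np.clip(np.rint(cx), 0, W - 1).astype(np.int64)
        yi = np.clip(np.rint(cy), 0, H - 1).astype(np.int64)
        out = src[:, yi, xi]
    elif mode == "bilinear":
        coords = Tensor(np.stack([cx, cy])[None])
        out = ad.bilinear_sample(
            Tensor(src[None].astype(np.float32)), coords
        ).data[0]
    else:
        raise ValueError(f"unknown warp mode {mode!r}")
    out = out.astype(source.dtype if mode == "nearest" else np.float32)
    return out[0] if squeeze else out


# ---------------------------------------------------------------------------
# composition and diffeomorphic integration
# ---------------------------------------------------------------------------


def compose(v_outer: np.ndarray, v_inner: np.ndarray, mode: str = "transform") -> np.ndarray:
    """Combine two displacement fields.

    ``additive``: ``V(x) = v_outer(x) + v_inner(x)``.

    ``transform``: ``V(x) = v_outer(x) + v_inner(x + v_outer(x))`` (bilinear
    resampling of the inner field), so that warping once by ``V`` equals
    warping by ``v_inner`` then by ``v_outer``; in the two-step cascade
    ``v_outer`` is the refinement field V2 and ``v_inner`` the coarse V1.
    """
    v_outer = _check_field(v_outer)
    v_inner = _check_field(v_inner)
    if v_outer.shape != v_inner.shape:
        raise ValueError("fields must share a shape")
    if mode == "additive":
        return v_outer + v_inner
    if mode == "transform":
        return v_outer + warp(v_inner, v_outer, mode="bilinear")
    raise ValueError(f"unknown compose mode {mode!r}")


def scaling_and_squaring(vel: np.ndarray, steps: int = 6) -> np.ndarray:
    """Integrate a stationary velocity field into a displacement field.

    The velocity is scaled by ``2**-steps`` and the resulting small field is
    composed with itself ``steps`` times; for moderate velocities the result
    is diffeomorphic (strictly positive Jacobian determinants).
    """
    vel = _check_field(vel)
    if steps < 1:
        raise ValueError("steps must be >= 1")
    field = vel / (2.0**steps)
    for _ in range(steps):
        field = compose(field, field, mode="transform")
    return field


# ---------------------------------------------------------------------------
# Jacobian analysis
# ---------------------------------------------------------------------------


def jacobian_determinant(field: np.ndarray) -> np.ndarray:
    """Per-pixel determinant of ``I + ∇D`` for the map ``x -> x + D(x)``.

    Central finite differences in the interior, one-sided at the borders
    (``np.gradient``), unit pixel spacing.  The identity field gives 1
    everywhere; values <= 0 flag folding/singularities.
    """
    field = _check_field(field)
    dx_dx = np.gradient(field[0], axis=1)
    dx_dy = np.gradient(field[0], axis=0)
    dy_dx = np.gradient(field[1], axis=1)
    dy_dy = np.gradient(field[1], axis=0)
    return (1.0 + dx_dx) * (1.0 + dy_dy) - dx_dy * dy_dx


# ---------------------------------------------------------------------------
# differentiable graph versions (batched tensors)
# ---------------------------------------------------------------------------


def identity_coords(batch: int, height: int, width: int) -> Tensor:
    """Constant (B,2,H,W) tensor of pixel coordinates (x then y)."""
    xs, ys = np.meshgrid(
        np.arange(width, dtype=np.float32), np.arange(height, dtype=np.float32)
    )
    base = np.stack([xs, ys])[None]
    return Tensor(np.broadcast_to(base, (batch, 2, height, width)).copy())


def densify_graph(
    control: Tensor, target_hw: tuple[int, int], kernel: int, spacing: int
) -> Tensor:
    """Differentiable :func:`densify` for a batched (B,2,h',w') control grid."""
    H, W = target_hw
    _check_kernel(kernel, (H, W))
    up = ad.upsample_nearest(control, spacing)
    up = ad.crop(up, H, W)
    return ad.avg_pool_smooth(up, kernel, passes=N_SPLINE_PASSES)


def warp_graph(src: Tensor, field: Tensor) -> Tensor:
    """Differentiable bilinear backward warp of (B,C,H,W) by (B,2,H,W)."""
    B, _, H, W = field.shape
    coords = identity_coords(B, H, W) + field
    return ad.bilinear_sample(src, coords)


def compose_graph(v_outer: Tensor, v_inner: Tensor, mode: str = "transform") -> Tensor:
    if mode == "additive":
        return v_outer + v_inner
    if mode == "transform":
        return v_outer + warp_graph(v_inner, v_outer)
    raise ValueError(f"unknown compose mode {mode!r}")


def scaling_and_squaring_graph(vel: Tensor, steps: int = 6) -> Tensor:
    field = vel * float(2.0**-steps)
    for _ in range(steps):
        field = compose_graph(field, field, mode="transform")
    return field


def upscale_field_2x(field: Tensor) -> Tensor:
    """Bilinearly upscale a (B,2,h,w) field to (B,2,2h,2w), doubling values.

    Displacements are stored in the pixel units of the grid the field lives
    on, so moving to a grid with half the pixel size doubles the values.
    """
    B, C, h, w = field.shape
    H, W = 2 * h, 2 * w
    xs, ys = np.meshgrid(np.arange(W, dtype=np.float32), np.arange(H, dtype=np.float32))
    # align the pixel-centre lattices of the two grids
    coords = np.stack([(xs + 0.5) / 2 - 0.5, (ys + 0.5) / 2 - 0.5])[None]
    coords = Tensor(np.broadcast_to(coords, (B, 2, H, W)).copy())
    return ad.bilinear_sample(field, coords) * 2.0
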