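"""Synthetic image/label pairs with known ground-truth B-spline deformations.

Two scene families emulate the training regimes the method targets:

* ``"cardiac"`` — a short-axis-like scene: a blood-pool ellipse (label 3)
  nested inside a myocardium ring (label 2), with an adjacent right-
  ventricle-like ellipse (label 1) on dark background.
* ``"face"`` — a large face ellipse (label 1) containing small adjacent
  parts (eyes, mouth) of differing sizes.

Geometry and appearance are decoupled: a label map is rasterised once per
pair, the two intensity images are rendered from the (moving / warped)
label maps with *independent* per-structure contrast jitter and additive
Gaussian noise, emulating inter-subject appearance variation.  The
ground-truth deformation is drawn from the same cubic-B-spline family the
registration model predicts (control-grid noise densified by
:func:`semreg.bspline.densify`), stored in the backward fixed->moving
convention, and rejected/resampled until its Jacobian determinant is
strictly positive everywhere.  Everything is deterministic per seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import bspline
from .metrics import jacobian_summary

__all__ = ["SceneSpec", "SyntheticPair", "make_template", "sample_deformation", "generate_pair", "make_dataset"]

_MAX_RETRIES = 50


@dataclass
class SceneSpec:
    """Desk-scale synthetic regime.

    Defaults: 64x64 images, 4 labels, control-point spacing 8 px and peak
    displacement 10 px — large relative to the ~12 px structures, i.e. the
    large-deformation regime.
    """

    image_size: tuple[int, int] = (64, 64)
    num_labels: int = 4
    scene: str = "cardiac"
    control_spacing: int = 8
    magnitude: float = 10.0          # peak displacement magnitude, px
    contrast_jitter: tuple[float, float] = (0.7, 1.3)
    noise_sigma: float = 0.02

    def __post_init__(self):
        if self.scene not in ("cardiac", "face"):
            raise ValueError(f"unknown scene {self.scene!r}")
        if self.num_labels < 2 or self.num_labels > 5:
            raise ValueError("num_labels must be in [2, 5]")
        if self.magnitude < 0:
            raise ValueError("magnitude must be >= 0")

    @property
    def spline_kernel(self) -> int:
        return 2 * self.control_spacing + 1


@dataclass
class SyntheticPair:
    fixed: np.ndarray
    moving: np.ndarray
    fixed_labels: np.ndarray
    moving_labels: np.ndarray
    true_field: np.ndarray
    seed: int
    magnitude: float


def _ellipse(yy, xx, cy, cx, ry, rx, angle=0.0):
    ca, sa = np.cos(angle), np.sin(angle)
    u = (xx - cx) * ca + (yy - cy) * sa
    v = -(xx - cx) * sa + (yy - cy) * ca
    return (u / rx) ** 2 + (v / ry) ** 2 <= 1.0


def _rasterize(spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    H, W = spec.image_size
    yy, xx = np.mgrid[0:H, 0:W].astype(np.float64)
    margin = spec.magnitude + 4
    labels = np.zeros((H, W), dtype=np.int64)
    scale = min(H, W) / 64.0

    if spec.scene == "cardiac":
        cy = H / 2 + rng.uniform(-3, 3) * scale
        cx = W / 2 + rng.uniform(0, 4) * scale
        r_pool = rng.uniform(5, 7) * scale          # LV blood pool
        thick = rng.uniform(3, 5) * scale           # myocardium thickness
        r_out = r_pool + thick
        if cx + r_out + margin > W or cy + r_out + margin > H:
            raise ValueError("cardiac scene does not fit")
        ring = _ellipse(yy, xx, cy, cx, r_out, r_out)
        pool = _ellipse(yy, xx, cy, cx, r_pool, r_pool)
        rv_cx = cx - r_out - rng.uniform(4, 6) * scale
        rv = _ellipse(
            yy, xx, cy + rng.uniform(-2, 2) * scale, rv_cx,
            rng.uniform(6, 9) * scale, rng.uniform(4, 6) * scale,
            angle=rng.uniform(-0.4, 0.4),
        )
        if spec.num_labels > 1:
            labels[rv] = 1
        if spec.num_labels > 2:
            labels[ring] = 2
        if spec.num_labels > 3:
            labels[pool] = 3
        if spec.num_labels > 4:
            extra = _ellipse(yy, xx, cy - r_out - 5 * scale, cx, 3 * scale, 4 * scale)
            labels[extra] = 4
    else:  # face
        cy = H / 2 + rng.uniform(-2, 2) * scale
        cx = W / 2 + rng.uniform(-2, 2) * scale
        ry = rng.uniform(20, 23) * scale
        rx = rng.uniform(15, 18) * scale
        face = _ellipse(yy, xx, cy, cx, ry, rx)
        labels[face] = 1
        eye_dy = rng.uniform(6, 9) * scale
        eye_dx = rng.uniform(6, 8) * scale
        er = rng.uniform(2, 3) * scale
        if spec.num_labels > 2:
            labels[_ellipse(yy, xx, cy - eye_dy, cx - eye_dx, er, er)] = 2
            labels[_ellipse(yy, xx, cy - eye_dy, cx + eye_dx, er, er)] = 2
        if spec.num_labels > 3:
            labels[_ellipse(yy, xx, cy + rng.uniform(8, 11) * scale, cx,
                            rng.uniform(2, 3) * scale, rng.uniform(5, 7) * scale)] = 3
        if spec.num_labels > 4:
            labels[_ellipse(yy, xx, cy + rng.uniform(1, 3) * scale, cx,
                            rng.uniform(2, 3) * scale, rng.uniform(2, 3) * scale)] = 4
    present = np.unique(labels)
    if len(present) != min(spec.num_labels, len(present)) or present.max() != spec.num_labels - 1:
        raise ValueError("a structure vanished during rasterisation")
    return labels


def render_intensities(labels: np.ndarray, spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    """Piecewise-constant rendering + per-structure contrast jitter + noise."""
    base = np.linspace(0.15, 0.9, spec.num_labels)
    lo, hi = spec.contrast_jitter
    gains = rng.uniform(lo, hi, size=spec.num_labels)
    gains[0] = 1.0  # background stays dark
    img = (base * gains)[labels]
    if spec.noise_sigma > 0:
        img = img + rng.normal(0.0, spec.noise_sigma, img.shape)
    return np.clip(img, 0.0, 1.0).astype(np.float32)


def make_template(spec: SceneSpec, rng_seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Rasterise a randomised scene and render its intensity image."""
    rng = np.random.default_rng(rng_seed)
    for _ in range(_MAX_RETRIES):
        try:
            labels = _rasterize(spec, rng)
            break
        except ValueError:
            continue
    else:
        raise RuntimeError("could not place structures within the image margin")
    return render_intensities(labels, spec, rng), labels


def sample_deformation(spec: SceneSpec, rng_seed: int) -> np.ndarray:
    """Draw a smooth B-spline field with peak magnitude ``spec.magnitude``.

    Control displacements ~ N(0, (magnitude/2)^2) clipped to ±magnitude are
    densified with the model's own pooling cascade and rescaled so the peak
    displacement norm equals the configured magnitude; fields with any
    non-positive Jacobian determinant are rejected and resampled.
    """
    H, W = spec.image_size
    rng = np.random.default_rng(rng_seed)
    if spec.magnitude == 0:
        return np.zeros((2, H, W), dtype=np.float32)
    s = spec.control_spacing
    gh, gw = -(-H // s), -(-W // s)
    for _ in range(_MAX_RETRIES):
        ctrl = rng.normal(0.0, spec.magnitude / 2.0, size=(2, gh, gw))
        ctrl = np.clip(ctrl, -spec.magnitude, spec.magnitude)
        field = bspline.densify(ctrl, (H, W), spec.spline_kernel, spacing=s)
        peak = np.sqrt((field**2).sum(axis=0)).max()
        if peak < 1e-6:
            continue
        field = field * (spec.magnitude / peak)
        _, neg = jacobian_summary(field)
        if neg == 0.0:
            return field.astype(np.float32)
    raise RuntimeError("could not sample a fold-free deformation field")


def generate_pair(spec: SceneSpec, rng_seed: int) -> SyntheticPair:
    """One registration pair with a known ground-truth field.

    The sampled field maps fixed-grid pixels to moving-image samples
    (backward convention), so the fixed label map is the template warped by
    the field and ``warp(moving_labels, true_field, nearest)`` reproduces
    ``fixed_labels`` exactly.  The two intensity images are rendered with
    independent appearance jitter.
    """
    ss = np.random.SeedSequence(rng_seed)
    s_geom, s_field, s_fix, s_mov = [int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(4)]
    for attempt in range(_MAX_RETRIES):
        _, moving_labels = make_template(spec, s_geom + attempt)
        field = sample_deformation(spec, s_field + attempt)
        fixed_labels = bspline.warp(moving_labels, field, mode="nearest")
        if set(np.unique(fixed_labels)) == set(np.unique(moving_labels)):
            break
    else:
        raise RuntimeError("deformation kept destroying structures")
    rng_fix = np.random.default_rng(s_fix)
    rng_mov = np.random.default_rng(s_mov)
    return SyntheticPair(
        fixed=render_intensities(fixed_labels, spec, rng_fix),
        moving=render_intensities(moving_labels, spec, rng_mov),
        fixed_labels=fixed_labels,
        moving_labels=moving_labels,
        true_field=field,
        seed=rng_seed,
        magnitude=spec.magnitude,
    )


def make_dataset(
    spec: SceneSpec,
    n_pairs: int,
    base_seed: int,
    out_dir,
    train_fraction: float = 0.7,
    overwrite: bool = False,
):
    """Write ``n_pairs`` pairs plus a manifest CSV; returns the manifest frame.

    The train/test split column uses a 70/30 default split.  Refuses to
    write into an existing non-empty directory unless ``overwrite`` is set.
    """
    import pandas as pd

    from . import io as sio

    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    from pathlib import Path

    out_dir = Path(out_dir)
    if out_dir.exists() and any(out_dir.iterdir()) and not overwrite:
        raise FileExistsError(f"{out_dir} exists and is not empty (pass overwrite=True)")
    out_dir.mkdir(parents=True, exist_ok=True)
    n_train = int(round(train_fraction * n_pairs))
    rows = []
    for i in range(n_pairs):
        seed = base_seed + i
        pair = generate_pair(spec, seed)
        stem = out_dir / f"pair_{i:04d}"
        paths = {
            "fixed": f"{stem}_fixed.png",
            "moving": f"{stem}_moving.png",
            "fixed_labels": f"{stem}_fixed_labels.png",
            "moving_labels": f"{stem}_moving_labels.png",
            "field": f"{stem}_field.nii.gz",
        }
        sio.save_image(paths["fixed"], pair.fixed)
        sio.save_image(paths["moving"], pair.moving)
        sio.save_labels(paths["fixed_labels"], pair.fixed_labels)
        sio.save_labels(paths["moving_labels"], pair.moving_labels)
        sio.save_field(paths["field"], pair.true_field)
        rows.append(
            {
                "pair_id": i,
                "seed": seed,
                "magnitude": spec.magnitude,
                "split": "train" if i < n_train else "test",
                **paths,
            }
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
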