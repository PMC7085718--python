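"""Shared fixtures: seeded RNGs, small synthetic scenes, and one trained
small-scale model reused by inference-behaviour tests (training it once per
session keeps the suite fast)."""

from __future__ import annotations

import os

# pin BLAS to one thread before numpy loads: reduction order (and thus the
# exact float result of every training run) must not depend on core count
for _var in ("OMP_NUM_THREADS", "OPENBLAS_NUM_THREADS", "MKL_NUM_THREADS"):
    os.environ.setdefault(_var, "1")

import numpy as np
import pytest

from semreg.model import SemanticGuidedRegistration, TrainConfig
from semreg.synthetic import SceneSpec, generate_pair


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def small_spec(**kw) -> SceneSpec:
    defaults = dict(image_size=(32, 32), magnitude=5.0)
    defaults.update(kw)
    return SceneSpec(**defaults)


def small_train_config(**kw) -> TrainConfig:
    defaults = dict(
        epochs=30,
        batch_size=8,
        base_channels=8,
        regnet_widths=(16, 32, 64),
        regnet_widths_single=(24, 48, 96),
        seed=0,
    )
    defaults.update(kw)
    return TrainConfig(**defaults)


@pytest.fixture(scope="session")
def small_pairs():
    spec = small_spec()
    train = [generate_pair(spec, s) for s in range(40)]
    test = [generate_pair(spec, 1000 + s) for s in range(10)]
    return train, test


@pytest.fixture(scope="session")
def small_fit(small_pairs):
    """A trained small-scale guided two-step model (32x32 scenes)."""
    train, test = small_pairs
    model = SemanticGuidedRegistration(train, small_train_config(), val_pairs=test[:4])
    return model.fit()


def smooth_random_field(shape, magnitude, seed, spacing=8):
    """Smooth random field drawn from the B-spline family (test helper)."""
    from semreg import bspline

    rng = np.random.default_rng(seed)
    H, W = shape
    gh, gw = -(-H // spacing), -(-W // spacing)
    ctrl = rng.normal(0.0, 1.0, size=(2, gh, gw))
    field = bspline.densify(ctrl, (H, W), 2 * spacing + 1, spacing=spacing)
    peak = np.sqrt((field**2).sum(axis=0)).max()
    return (field * (magnitude / peak)).astype(np.float32)
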