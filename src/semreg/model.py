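"""End-to-end semantically guided registration: model and results objects.

:class:`SemanticGuidedRegistration` bundles the semantic U-Net and the
two-step RegNet cascade and trains them jointly on image pairs with
segmentation supervision.  :meth:`SemanticGuidedRegistration.fit` returns a
:class:`RegistrationFit` results object carrying the trained networks, the
loss history, validation diagnostics and a ``summary()`` table; inference
(:meth:`RegistrationFit.register`) needs only the two greyscale images.

Training recipe defaults: Adam with learning rate 1e-3 and first-moment
decay 0.97, lambda_s = 1.0, lambda_r = 0.001, field smoothing for the
regulariser with a 3x3 kernel applied twice.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import bspline, io as sio, losses, metrics
from .features import FeatureNet, class_weights, downsample_labels, semantic_loss
from .nn.autodiff import Tensor
from .nn.optim import Adam
from .registration import RegNet, RegNetConfig, RegistrationResult, build_regnet, cascade_fields
from .synthetic import SyntheticPair

__all__ = ["TrainConfig", "SemanticGuidedRegistration", "RegistrationFit", "load_pairs_from_manifest"]


@dataclass
class TrainConfig:
    """Everything a training run needs; embedded verbatim in checkpoints."""

    num_labels: int = 4
    epochs: int = 50
    batch_size: int = 5
    learning_rate: float = 1e-3
    beta1: float = 0.97               # Adam first-moment decay ("momentum")
    lambda_s: float = 1.0
    lambda_r: float = 0.001
    kernel1: int = 5                  # B-spline pooling kernel, step 1
    kernel2: int = 3                  # step 2
    smooth_kernel: int = 3            # regulariser smoothing kernel
    smooth_passes: int = 2
    combine_mode: str = "transform"
    two_step: bool = True
    guided: bool = True
    shared_regnet_weights: bool = False
    diffeomorphic: bool = False
    sas_steps: int = 6
    pretrain_unet: bool = False
    pretrain_epochs: int = 10
    freeze_unet: bool = False
    base_channels: int = 16
    regnet_widths: tuple = (48, 96, 192)
    regnet_widths_single: tuple = (72, 144, 288)
    activation: str = "leaky_relu(0.1), no normalisation layers"
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")
        for k in (self.kernel1, self.kernel2, self.smooth_kernel):
            if k < 1 or k % 2 == 0:
                raise ValueError("kernels must be odd and >= 1")
        if not self.two_step and self.shared_regnet_weights:
            raise ValueError("shared RegNet weights require the two-step mode")

    def regnet_config(self) -> RegNetConfig:
        return RegNetConfig(
            num_labels=self.num_labels,
            kernel1=self.kernel1,
            kernel2=self.kernel2,
            widths=tuple(self.regnet_widths),
            widths_single=tuple(self.regnet_widths_single),
            combine_mode=self.combine_mode,
            diffeomorphic=self.diffeomorphic,
            sas_steps=self.sas_steps,
            shared_weights=self.shared_regnet_weights,
        )


def load_pairs_from_manifest(manifest_path, split: str | None = None) -> list[SyntheticPair]:
    """Read image/label/field files referenced by a dataset manifest CSV."""
    manifest = pd.read_csv(manifest_path)
    if split is not None:
        manifest = manifest[manifest["split"] == split]
    pairs = []
    for _, row in manifest.iterrows():
        pairs.append(
            SyntheticPair(
                fixed=sio.load_image(row["fixed"]),
                moving=sio.load_image(row["moving"]),
                fixed_labels=sio.load_labels(row["fixed_labels"]),
                moving_labels=sio.load_labels(row["moving_labels"]),
                true_field=sio.load_field(row["field"]),
                seed=int(row["seed"]),
                magnitude=float(row["magnitude"]),
            )
        )
    return pairs


def _stack_batch(pairs: list[SyntheticPair], idx: np.ndarray):
    fixed = np.stack([pairs[i].fixed for i in idx])[:, None]
    moving = np.stack([pairs[i].moving for i in idx])[:, None]
    flab = np.stack([pairs[i].fixed_labels for i in idx])
    mlab = np.stack([pairs[i].moving_labels for i in idx])
    return fixed.astype(np.float32), moving.astype(np.float32), flab, mlab


class SemanticGuidedRegistration:
    """Model object: data + configuration; ``fit()`` produces the results."""

    def __init__(
        self,
        train_pairs: list[SyntheticPair],
        config: TrainConfig | None = None,
        val_pairs: list[SyntheticPair] | None = None,
    ):
        if not train_pairs:
            raise ValueError("need at least one training pair")
        self.train_pairs = list(train_pairs)
        self.val_pairs = list(val_pairs) if val_pairs else []
        self.config = config if config is not None else TrainConfig()
        shapes = {p.fixed.shape for p in self.train_pairs}
        if len(shapes) != 1:
            raise ValueError("all training pairs must share an image size")
        (self.image_shape,) = shapes

    @classmethod
    def from_manifest(cls, manifest_path, config: TrainConfig | None = None):
        return cls(
            load_pairs_from_manifest(manifest_path, split="train"),
            config=config,
            val_pairs=load_pairs_from_manifest(manifest_path, split="test"),
        )

    # -- network construction ------------------------------------------------
    def _build_networks(self):
        cfg = self.config
        root = np.random.SeedSequence(cfg.seed)
        seeds = [np.random.default_rng(c.generate_state(1)[0] % 2**31) for c in root.spawn(3)]
        unet = FeatureNet(cfg.num_labels, cfg.base_channels, rng=seeds[0])
        rcfg = cfg.regnet_config()
        if cfg.two_step:
            net1 = build_regnet(rcfg, rng=seeds[1])
            net2 = net1 if cfg.shared_regnet_weights else build_regnet(rcfg, rng=seeds[2])
        else:
            net1 = build_regnet(rcfg, single_step=True, rng=seeds[1])
            net2 = None
        return unet, net1, net2, rcfg

    # -- training -------------------------------------------------------------
    def fit(self, log_path=None, verbose: bool = False) -> "RegistrationFit":
        cfg = self.config
        unet, net1, net2, rcfg = self._build_networks()
        w = class_weights(
            [p.fixed_labels for p in self.train_pairs]
            + [p.moving_labels for p in self.train_pairs],
            cfg.num_labels,
        )
        lw = losses.LossWeights(
            lambda_s=cfg.lambda_s if cfg.guided else 0.0,
            lambda_r=cfg.lambda_r,
            label_weights=w,
        )
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 7]).generate_state(1)[0] % 2**31)
        n = len(self.train_pairs)

        if cfg.pretrain_unet and cfg.guided:
            self._pretrain_unet(unet, w, rng, cfg)

        params = []
        if not cfg.freeze_unet:
            params += unet.parameters()
        params += net1.parameters()
        if net2 is not None and net2 is not net1:
            params += net2.parameters()
        opt = Adam(params, lr=cfg.learning_rate, beta1=cfg.beta1)

        records = []
        best = {"val_dice": -np.inf, "epoch": -1, "weights": None}
        zero = Tensor(np.float32(0.0))
        for epoch in range(cfg.epochs):
            order = rng.permutation(n)
            for step, start in enumerate(range(0, n, cfg.batch_size)):
                idx = order[start : start + cfg.batch_size]
                fixed, moving, flab, mlab = _stack_batch(self.train_pairs, idx)
                ff = unet(Tensor(fixed))
                fm = unet(Tensor(moving))
                if cfg.guided:
                    ls_f = semantic_loss(ff, downsample_labels(flab), w)
                    ls_m = semantic_loss(fm, downsample_labels(mlab), w)
                else:
                    ls_f = ls_m = zero
                fields = cascade_fields(ff, fm, net1, net2, rcfg)
                ld = losses.deformation_loss(flab, mlab, fields["v"], w)
                lr_ = losses.regularization_loss(fields["v"], cfg.smooth_kernel, cfg.smooth_passes)
                loss = losses.total_loss(ls_f, ls_m, ld, lr_, lw)
                opt.zero_grad()
                loss.backward()
                opt.step()
                records.append(
                    {
                        "epoch": epoch,
                        "step": step,
                        "L_semantic": float(ls_f.data + ls_m.data),
                        "L_deform": float(ld.data),
                        "L_regular": float(lr_.data),
                        "total": loss.item(),
                        "val_dice": np.nan,
                    }
                )
            if self.val_pairs:
                vd = self._validation_dice(unet, net1, net2, rcfg)
                records[-1]["val_dice"] = vd
                if vd > best["val_dice"]:
                    best.update(
                        val_dice=vd,
                        epoch=epoch,
                        weights=self._snapshot(unet, net1, net2),
                    )
            if verbose:
                print(f"epoch {epoch}: total={records[-1]['total']:.4f}")

        history = pd.DataFrame.from_records(records)
        if log_path is not None:
            history.to_csv(log_path, index=False)
        fit = RegistrationFit(
            config=cfg,
            unet=unet,
            net1=net1,
            net2=net2,
            regnet_config=rcfg,
            label_weights=w,
            loss_history=history,
            best_val_dice=best["val_dice"] if self.val_pairs else np.nan,
            best_epoch=best["epoch"],
            best_weights=best["weights"],
        )
        return fit

    def _pretrain_unet(self, unet, w, rng, cfg):
        opt = Adam(unet.parameters(), lr=cfg.learning_rate, beta1=cfg.beta1)
        n = len(self.train_pairs)
        for _ in range(cfg.pretrain_epochs):
            order = rng.permutation(n)
            for start in range(0, n, cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                fixed, moving, flab, mlab = _stack_batch(self.train_pairs, idx)
                ff = unet(Tensor(fixed))
                fm = unet(Tensor(moving))
                loss = semantic_loss(ff, downsample_labels(flab), w) + semantic_loss(
                    fm, downsample_labels(mlab), w
                )
                opt.zero_grad()
                loss.backward()
                opt.step()

    @staticmethod
    def _snapshot(unet, net1, net2):
        groups = {"unet": [a.copy() for a in unet.state_arrays()],
                  "net1": [a.copy() for a in net1.state_arrays()]}
        if net2 is not None and net2 is not net1:
            groups["net2"] = [a.copy() for a in net2.state_arrays()]
        return groups

    def _validation_dice(self, unet, net1, net2, rcfg) -> float:
        dices = []
        for p in self.val_pairs:
            v = _infer_field(unet, net1, net2, rcfg, p.fixed, p.moving)
            rep = metrics.evaluate_pair(p.fixed_labels, p.moving_labels, v, self.config.num_labels)
            dices.append(rep.mean_dice)
        return float(np.nanmean(dices))


def _infer_field(unet, net1, net2, rcfg, fixed: np.ndarray, moving: np.ndarray) -> np.ndarray:
    ff = unet(Tensor(fixed[None, None].astype(np.float32)))
    fm = unet(Tensor(moving[None, None].astype(np.float32)))
    return cascade_fields(ff.detach(), fm.detach(), net1, net2, rcfg)["v"].data[0]


@dataclass
class RegistrationFit:
    """Trained registration model: estimates, diagnostics, inference."""

    config: TrainConfig
    unet: FeatureNet
    net1: RegNet
    net2: RegNet | None
    regnet_config: RegNetConfig
    label_weights: np.ndarray
    loss_history: pd.DataFrame
    best_val_dice: float = np.nan
    best_epoch: int = -1
    best_weights: dict | None = None

    def use_best_weights(self) -> None:
        """Restore the checkpoint with the highest validation Dice."""
        if self.best_weights is None:
            raise ValueError("no validation set was used during fitting")
        self.unet.load_state_arrays(self.best_weights["unet"])
        self.net1.load_state_arrays(self.best_weights["net1"])
        if self.net2 is not None and self.net2 is not self.net1:
            self.net2.load_state_arrays(self.best_weights["net2"])

    # -- inference -------------------------------------------------------------
    def predict_field(self, fixed: np.ndarray, moving: np.ndarray) -> np.ndarray:
        """Full-resolution displacement field (2, H, W) for one image pair."""
        fixed = np.asarray(fixed, dtype=np.float32)
        moving = np.asarray(moving, dtype=np.float32)
        if fixed.shape != moving.shape:
            raise ValueError("fixed and moving images must share a shape")
        return _infer_field(self.unet, self.net1, self.net2, self.regnet_config, fixed, moving)

    def register(
        self,
        fixed: np.ndarray,
        moving: np.ndarray,
        moving_labels: np.ndarray | None = None,
    ) -> RegistrationResult:
        """Register one pair; labels (optional) are warped nearest-neighbour."""
        ff = self.unet(Tensor(np.asarray(fixed, dtype=np.float32)[None, None]))
        fm = self.unet(Tensor(np.asarray(moving, dtype=np.float32)[None, None]))
        fields = cascade_fields(ff.detach(), fm.detach(), self.net1, self.net2, self.regnet_config)
        v = fields["v"].data[0]
        up = lambda t: bspline.upscale_field_2x(t.detach()).data[0]
        return RegistrationResult(
            v1=up(fields["v1h"]),
            v2=up(fields["v2h"]) if fields["v2h"] is not None else None,
            v=v,
            warped_moving=bspline.warp(np.asarray(moving, dtype=np.float32), v),
            warped_moving_labels=(
                bspline.warp(moving_labels, v, mode="nearest")
                if moving_labels is not None
                else None
            ),
        )

    # -- evaluation ------------------------------------------------------------
    def evaluate(self, pairs: list[SyntheticPair], zero_field: bool = False):
        """Per-pair metric table + aggregate dict over a list of pairs.

        ``zero_field=True`` scores the unregistered baseline instead of the
        model's predictions.
        """
        rows = []
        for i, p in enumerate(pairs):
            v = (
                np.zeros((2, *p.fixed.shape), dtype=np.float32)
                if zero_field
                else self.predict_field(p.fixed, p.moving)
            )
            rep = metrics.evaluate_pair(p.fixed_labels, p.moving_labels, v, self.config.num_labels)
            rows.append({"pair": i, **rep.as_dict()})
        table = pd.DataFrame(rows)
        aggregate = {
            "mean_dice": float(table["mean_dice"].mean()),
            "mean_contour_dist": float(table["mean_contour_dist"].mean()),
            "jacobian_std": float(table["jacobian_std"].mean()),
            "jacobian_negative_fraction": float(table["jacobian_negative_fraction"].mean()),
        }
        return table, aggregate

    def summary(self) -> str:
        cfg = self.config
        n_unet = self.unet.num_parameters()
        n_reg = self.net1.num_parameters()
        if self.net2 is not None and self.net2 is not self.net1:
            n_reg += self.net2.num_parameters()
        tail = self.loss_history.tail(1).iloc[0] if len(self.loss_history) else None
        lines = [
            "Semantically Guided Registration Results",
            "=" * 44,
            f"mode:            {'two-step' if cfg.two_step else 'single-step'}"
            + (", shared RegNet weights" if cfg.shared_regnet_weights else "")
            + (", diffeomorphic" if cfg.diffeomorphic else ""),
            f"guidance:        {'semantic (lambda_s=%g)' % cfg.lambda_s if cfg.guided else 'none'}",
            f"combine mode:    {cfg.combine_mode}",
            f"B-spline kernels: {cfg.kernel1}/{cfg.kernel2}; smoothing {cfg.smooth_kernel}x{cfg.smooth_kernel} x{cfg.smooth_passes}",
            f"U-Net params:    {n_unet:,}",
            f"RegNet params:   {n_reg:,}",
            f"epochs trained:  {cfg.epochs} (batch {cfg.batch_size}, lr {cfg.learning_rate}, beta1 {cfg.beta1})",
        ]
        if tail is not None:
            lines.append(
                f"final losses:    total={tail['total']:.4f} "
                f"(semantic={tail['L_semantic']:.4f}, deform={tail['L_deform']:.4f}, "
                f"regular={tail['L_regular']:.4f})"
            )
        if np.isfinite(self.best_val_dice):
            lines.append(f"best val Dice:   {self.best_val_dice:.4f} (epoch {self.best_epoch})")
        return "\n".join(lines)

    # -- persistence -----------------------------------------------------------
    def save(self, path) -> None:
        groups = {"unet": self.unet.state_arrays(), "net1": self.net1.state_arrays()}
        if self.net2 is not None and self.net2 is not self.net1:
            groups["net2"] = self.net2.state_arrays()
        groups["label_weights"] = [self.label_weights]
        config = dataclasses.asdict(self.config)
        sio.save_checkpoint(path, groups, config)

    @classmethod
    def load(cls, path) -> "RegistrationFit":
        groups, config = sio.load_checkpoint(path)
        config["regnet_widths"] = tuple(config["regnet_widths"])
        config["regnet_widths_single"] = tuple(config["regnet_widths_single"])
        cfg = TrainConfig(**config)
        model = SemanticGuidedRegistration.__new__(SemanticGuidedRegistration)
        model.config = cfg
        unet, net1, net2, rcfg = SemanticGuidedRegistration._build_networks(model)
        unet.load_state_arrays(groups["unet"])
        net1.load_state_arrays(groups["net1"])
        if net2 is not None and net2 is not net1:
            net2.load_state_arrays(groups["net2"])
        return cls(
            config=cfg,
            unet=unet,
            net1=net1,
            net2=net2,
            regnet_config=rcfg,
            label_weights=groups["label_weights"][0],
            loss_history=pd.DataFrame(),
        )
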