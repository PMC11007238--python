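"""Affinity labels, supervised regressor training, and kd prediction.

Experimental dissociation constants kd (molar) are mapped to the
negative-log scale pKd = -log10(kd) — the convention of the binding
affinity literature — then min-max normalized to [0, 1] using the range of
the *training* split only, so no information from validation or test
labels leaks into the target scale.  The regressor is trained with
mini-batch mean-squared error and Adam; the epoch with the lowest
validation RMSE supplies the returned weights.  Predictions run the chain
backwards: sigmoid output y -> pKd -> kd, so predicted kd always lies
inside the training range (an explicit extrapolation limit).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import nn
from .augment import augmented_grid
from .networks import (
    RegressorSpec, build_regressor, encoder_forward, regressor_forward,
)
from .pocket import Pocket
from .voxelize import GridSpec, gaussian_blur, voxelize_atoms

logger = logging.getLogger("voxbind")

__all__ = [
    "AffinityLabel", "LabelTransform", "TrainConfig",
    "fit_transform_labels", "train_regressor", "predict_affinity",
    "TrainResult",
]


@dataclass(frozen=True)
class AffinityLabel:
    """One labelled complex: kd in molar, pKd derived, y set after fitting."""

    complex_id: str
    kd: float
    y: float | None = None

    def __post_init__(self):
        if not self.kd > 0:
            raise ValueError(f"{self.complex_id}: kd must be > 0 (molar)")

    @property
    def pkd(self) -> float:
        return -math.log10(self.kd)

    @classmethod
    def from_pkd(cls, complex_id: str, pkd: float) -> "AffinityLabel":
        return cls(complex_id=complex_id, kd=10.0 ** (-pkd))


@dataclass
class LabelTransform:
    """Min-max map between pKd and the normalized (0, 1) target scale."""

    pkd_min: float
    pkd_max: float

    def __post_init__(self):
        if not self.pkd_max > self.pkd_min:
            raise ValueError("degenerate label range: pkd_max must exceed pkd_min")

    def forward(self, pkd):
        return (np.asarray(pkd) - self.pkd_min) / (self.pkd_max - self.pkd_min)

    def inverse(self, y):
        return self.pkd_min + np.asarray(y) * (self.pkd_max - self.pkd_min)


def fit_transform_labels(
    train_labels: list[AffinityLabel],
) -> tuple[LabelTransform, list[AffinityLabel]]:
    """Fit min-max on the training split and attach normalized targets."""
    if len(train_labels) < 2:
        raise ValueError("need at least 2 training labels")
    pkds = np.array([lab.pkd for lab in train_labels])
    transform = LabelTransform(pkd_min=float(pkds.min()), pkd_max=float(pkds.max()))
    labelled = [
        AffinityLabel(lab.complex_id, lab.kd, y=float(transform.forward(lab.pkd)))
        for lab in train_labels
    ]
    return transform, labelled


@dataclass
class TrainConfig:
    learning_rate: float = 1e-4
    batch_size: int = 16
    epochs: int = 20
    seed: int = 0
    mode: str = "raw"  # or "encoder"
    augment: bool | None = None  # default: True in raw mode, False in encoder
    max_shift: float = 2.0
    lr_decay_epoch: int | None = None  # step-decay the learning rate here
    lr_decay_factor: float = 0.5
    regressor: RegressorSpec = field(default_factory=RegressorSpec)

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be > 0")
        if self.mode not in ("raw", "encoder"):
            raise ValueError("mode must be 'raw' or 'encoder'")

    @property
    def augment_enabled(self) -> bool:
        return self.mode == "raw" if self.augment is None else self.augment

    def regressor_spec(self) -> RegressorSpec:
        """Mode-resolved architecture: the stride-2 stem suits raw 41-cube
        grids; the smaller encoder latents use an unstrided stem."""
        if self.mode == "encoder" and self.regressor.first_stride != 1:
            return replace(self.regressor, first_stride=1)
        return self.regressor


@dataclass
class TrainResult:
    model: nn.Sequential
    transform: LabelTransform
    history: pd.DataFrame  # epoch, train_loss, val_rmse
    best_epoch: int
    mode: str


def _pocket_grid(p: Pocket, spec: GridSpec) -> np.ndarray:
    return gaussian_blur(voxelize_atoms(p, spec)).values


def _inputs_for(
    pockets: list[Pocket], spec: GridSpec, mode: str, encoder
) -> np.ndarray:
    """Unaugmented model inputs (grids, or encoder latents) as one array."""
    grids = np.stack([_pocket_grid(p, spec) for p in pockets]).astype(np.float32)
    if mode == "encoder":
        if encoder is None:
            raise ValueError("encoder mode requires a pre-trained encoder")
        return encoder_forward(grids, encoder, train=False).astype(np.float32)
    return grids


def train_regressor(
    train: list[tuple[Pocket, AffinityLabel]],
    val: list[tuple[Pocket, AffinityLabel]],
    cfg: TrainConfig | None = None,
    grid_spec: GridSpec | None = None,
    encoder: nn.Sequential | None = None,
) -> TrainResult:
    """MSE-train the regressor; return the weights of the best-validation epoch.

    Raw mode expands the training set each epoch: the original grids plus
    one freshly transformed rigid view of each pocket.  Validation inputs
    stay fixed and unaugmented.  In encoder mode the (frozen) encoder
    latents are computed once up front and augmentation is off by default.
    """
    cfg = cfg or TrainConfig()
    spec = grid_spec or GridSpec()
    if not train or not val:
        raise ValueError("train and validation splits must be non-empty")
    train_ids = {lab.complex_id for _, lab in train}
    if train_ids & {lab.complex_id for _, lab in val}:
        raise ValueError("train and validation splits overlap")

    transform, train_labels = fit_transform_labels([lab for _, lab in train])
    y_train = np.array([lab.y for lab in train_labels], dtype=np.float32)
    y_val = transform.forward([lab.pkd for _, lab in val]).astype(np.float32)

    train_pockets = [p for p, _ in train]
    x_val = _inputs_for([p for p, _ in val], spec, cfg.mode, encoder)
    in_side = x_val.shape[1]
    in_channels = x_val.shape[-1]
    model = build_regressor(in_side, in_channels, cfg.regressor_spec(),
                            seed=cfg.seed)
    model.reseed_dropout(cfg.seed + 17)
    opt = nn.Adam(model.params(), lr=cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed + 1)
    aug_stream = np.random.default_rng(cfg.seed + 2)

    # augmentation expands the training set: each epoch sees the original
    # grids plus one freshly transformed copy of each
    x_train_fixed = _inputs_for(train_pockets, spec, cfg.mode, encoder)

    rows = []
    best = (np.inf, -1, None)
    for epoch in range(cfg.epochs):
        if cfg.lr_decay_epoch is not None and epoch == cfg.lr_decay_epoch:
            opt.lr *= cfg.lr_decay_factor
        if cfg.augment_enabled:
            seeds = aug_stream.integers(0, 2**31 - 1, size=len(train_pockets))
            x_aug = np.stack([
                augmented_grid(p, spec, int(s), cfg.max_shift).values
                for p, s in zip(train_pockets, seeds)
            ]).astype(np.float32)
            x_epoch = np.concatenate([x_train_fixed, x_aug])
            y_epoch = np.concatenate([y_train, y_train])
        else:
            x_epoch, y_epoch = x_train_fixed, y_train
        order = rng.permutation(len(x_epoch))
        losses = []
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            xb, yb = x_epoch[idx], y_epoch[idx]
            model.zero_grad()
            pred = model.forward(xb, train=True)[:, 0]
            err = pred - yb
            losses.append(float(np.mean(err ** 2)))
            model.backward((2.0 * err / len(idx))[:, None].astype(np.float32),
                           need_dx=False)
            opt.step()
        val_pred = model.forward(x_val, train=False, cache=False)[:, 0]
        val_rmse = float(np.sqrt(np.mean((val_pred - y_val) ** 2)))
        rows.append({"epoch": epoch, "train_loss": float(np.mean(losses)),
                     "val_rmse": val_rmse})
        if val_rmse < best[0]:
            best = (val_rmse, epoch,
                    [p.value.copy() for p in model.params()])
        logger.info("epoch %d: train MSE %.4f, val RMSE %.4f",
                    epoch, rows[-1]["train_loss"], val_rmse)
    # restore best-validation weights
    for p, v in zip(model.params(), best[2]):
        p.value[...] = v
    history = pd.DataFrame(rows)
    return TrainResult(model=model, transform=transform, history=history,
                       best_epoch=best[1], mode=cfg.mode)


def predict_affinity(
    items: list[tuple[str, Pocket]],
    model: nn.Sequential,
    transform: LabelTransform,
    mode: str = "raw",
    grid_spec: GridSpec | None = None,
    encoder: nn.Sequential | None = None,
) -> pd.DataFrame:
    """Predict y, pKd and kd per complex; row order follows the input order."""
    if transform is None:
        raise ValueError("a fitted LabelTransform is required")
    spec = grid_spec or GridSpec()
    pockets = [p for _, p in items]
    x = _inputs_for(pockets, spec, mode, encoder)
    y = regressor_forward(x, model, mode=mode, train=False, cache=False)
    y = np.atleast_1d(y).astype(np.float64)
    pkd = transform.inverse(y)
    return pd.DataFrame({
        "complex_id": [cid for cid, _ in items],
        "y": y.astype(float),
        "pkd": pkd.astype(float),
        "kd_molar": (10.0 ** (-pkd)).astype(float),
    })
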