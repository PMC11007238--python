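"""Model architectures: residual encoder, projection head, 3D-CNN regressor.

The encoder maps an ``(41, 41, 41, 8)`` occupancy grid to a
``(23, 23, 23, 32)`` latent volume through one unpadded stem convolution
and eight residual blocks whose first convolution is unpadded — nine
valid 3x3x3 convolutions in total, so each spatial side shrinks by 18.
The projection head pools the latent volume and applies a one-hidden-layer
MLP, producing the low-dimensional embedding used only by the contrastive
loss.  The regressor is a four-convolution 3D CNN with dropout after every
convolution, max pooling after the second and fourth, and a single sigmoid
output on the normalized-affinity scale; it accepts either raw grids
("raw" mode) or encoder latents ("encoder" mode).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass

import numpy as np

from . import nn
from .voxelize import VoxelGrid

__all__ = [
    "EncoderSpec", "ProjectorSpec", "RegressorSpec",
    "build_encoder", "build_projector", "build_regressor",
    "encoder_forward", "project", "regressor_forward",
    "save_checkpoint", "load_checkpoint", "parameter_report",
]

@dataclass(frozen=True)
class EncoderSpec:
    in_channels: int = 8
    channels: int = 32
    residual_blocks: int = 8

    @property
    def side_reduction(self) -> int:
        return 2 * (1 + self.residual_blocks)

    def output_side(self, input_side: int) -> int:
        out = input_side - self.side_reduction
        if out <= 0:
            raise ValueError(
                f"input side {input_side} too small: encoder removes "
                f"{self.side_reduction} voxels of side"
            )
        return out


@dataclass(frozen=True)
class ProjectorSpec:
    in_channels: int = 32
    hidden: int = 256
    projection_dim: int = 128


@dataclass(frozen=True)
class RegressorSpec:
    """Four conv layers; pooling after convs 2 and 4; sigmoid scalar head.

    The first convolution uses stride 2 by default, which halves each
    spatial side before the expensive mid-network layers.
    """

    conv_filters: tuple[int, int, int, int] = (16, 32, 32, 32)
    fc_widths: tuple[int, int] = (256, 64)
    dropout: float = 0.5
    kernel: int = 3
    pool: int = 2
    first_stride: int = 2

    def stride_of(self, layer_index: int) -> int:
        return self.first_stride if layer_index == 0 else 1

    def flat_features(self, input_side: int, in_channels: int) -> int:
        side = input_side
        for i in range(4):
            side = (side - self.kernel) // self.stride_of(i) + 1
            if side <= 0:
                raise ValueError(f"input side {input_side} too small for regressor")
            if i in (1, 3):
                side //= self.pool
        return side ** 3 * self.conv_filters[-1]


def build_encoder(spec: EncoderSpec | None = None, seed: int = 0,
                  dtype=np.float32) -> nn.Sequential:
    spec = spec or EncoderSpec()
    rng = np.random.default_rng(seed)
    layers: list[nn.Layer] = [
        nn.Conv3d(spec.in_channels, spec.channels, 3, padding=0, rng=rng,
                  dtype=dtype),
        nn.BatchNorm(spec.channels, dtype=dtype),
        nn.ReLU(),
    ]
    layers += [nn.ResidualBlock3d(spec.channels, rng, dtype=dtype)
               for _ in range(spec.residual_blocks)]
    return nn.Sequential(layers)


def build_projector(spec: ProjectorSpec | None = None, seed: int = 1,
                    dtype=np.float32) -> nn.Sequential:
    spec = spec or ProjectorSpec()
    rng = np.random.default_rng(seed)
    return nn.Sequential([
        nn.GlobalAvgPool3d(),
        nn.Linear(spec.in_channels, spec.hidden, rng=rng, dtype=dtype),
        nn.ReLU(),
        nn.Linear(spec.hidden, spec.projection_dim, rng=rng, dtype=dtype),
    ])


def build_regressor(input_side: int, in_channels: int,
                    spec: RegressorSpec | None = None, seed: int = 2,
                    dtype=np.float32) -> nn.Sequential:
    """Regressor sized for a concrete input shape.

    ``input_side=41, in_channels=8`` is raw mode; ``23, 32`` encoder mode.
    """
    spec = spec or RegressorSpec()
    rng = np.random.default_rng(seed)
    f = spec.conv_filters
    layers: list[nn.Layer] = []
    cin = in_channels
    for i, cout in enumerate(f):
        layers += [
            nn.Conv3d(cin, cout, spec.kernel, padding=0,
                      stride=spec.stride_of(i), rng=rng, dtype=dtype),
            nn.Dropout(spec.dropout, seed=seed + 100 + i),
            nn.ReLU(),
        ]
        if i in (1, 3):
            layers.append(nn.MaxPool3d(spec.pool))
        cin = cout
    layers.append(nn.Flatten())
    nin = spec.flat_features(input_side, in_channels)
    for width in spec.fc_widths:
        layers += [nn.Linear(nin, width, rng=rng, dtype=dtype), nn.ReLU()]
        nin = width
    layers += [nn.Linear(nin, 1, rng=rng, dtype=dtype), nn.Sigmoid()]
    return nn.Sequential(layers)


def _as_batch(x) -> tuple[np.ndarray, bool]:
    arr = x.values if isinstance(x, VoxelGrid) else np.asarray(x)
    if arr.ndim == 4:
        return arr[None], True
    if arr.ndim == 5:
        return arr, False
    raise ValueError(f"expected 4-D or batched 5-D input, got shape {arr.shape}")


def encoder_forward(grid, encoder: nn.Sequential, train: bool = False,
                    cache: bool = False, update_stats: bool = True) -> np.ndarray:
    """Run the encoder; accepts one grid or a batch, returns latents.

    Evaluation mode (default) uses the stored normalization statistics and
    is deterministic.
    """
    x, single = _as_batch(grid)
    spec_in = encoder.layers[0].cin
    if x.shape[-1] != spec_in:
        raise ValueError(f"expected {spec_in} channels, got {x.shape[-1]}")
    reduction = sum(2 for layer in encoder._walk()
                    if isinstance(layer, nn.Conv3d) and layer.pad == 0)
    if x.shape[1] - reduction <= 0:
        raise ValueError(
            f"input side {x.shape[1]} too small: encoder removes {reduction}"
        )
    h = encoder.forward(x.astype(encoder.params()[0].value.dtype), train=train,
                        cache=cache, update_stats=update_stats)
    return h[0] if single else h


def project(h: np.ndarray, projector: nn.Sequential, train: bool = False,
            cache: bool = False) -> np.ndarray:
    """Pool a latent volume and project it to the contrastive embedding."""
    x, single = _as_batch(h)
    z = projector.forward(x.astype(projector.params()[0].value.dtype),
                          train=train, cache=cache)
    return z[0] if single else z


def regressor_forward(x, regressor: nn.Sequential, mode: str = "raw",
                      train: bool = False, cache: bool = True) -> np.ndarray:
    """Predict normalized affinities in (0, 1); preserves batch order."""
    if mode not in ("raw", "encoder"):
        raise ValueError(f"mode must be 'raw' or 'encoder', got {mode!r}")
    xb, single = _as_batch(x)
    expected = regressor.layers[0].cin
    if xb.shape[-1] != expected:
        raise ValueError(
            f"{mode} mode expects {expected} channels, got {xb.shape[-1]}"
        )
    y = regressor.forward(xb.astype(regressor.params()[0].value.dtype),
                          train=train, cache=cache)[:, 0]
    return y[0] if single else y


def _spec_hash(meta: dict) -> str:
    return hashlib.sha256(
        json.dumps(meta, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def save_checkpoint(path, model: nn.Sequential, meta: dict | None = None):
    """Write model arrays plus a JSON header carrying a spec hash."""
    meta = dict(meta or {})
    meta["spec_hash"] = _spec_hash(meta)
    arrays = {f"arr_{i}": a for i, a in enumerate(model.state_arrays())}
    np.savez(path, header=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path, model: nn.Sequential, expect_meta: dict | None = None) -> dict:
    """Load arrays into ``model`` in place; verifies the spec hash."""
    with np.load(path) as data:
        meta = json.loads(bytes(data["header"]).decode())
        if expect_meta is not None:
            expected = dict(expect_meta)
            expected["spec_hash"] = _spec_hash(expected)
            if expected["spec_hash"] != meta["spec_hash"]:
                raise ValueError(
                    f"checkpoint spec hash {meta['spec_hash']} does not match "
                    f"expected {expected['spec_hash']}"
                )
        targets = model.state_arrays()
        for i, target in enumerate(targets):
            src = data[f"arr_{i}"]
            if src.shape != target.shape:
                raise ValueError(f"checkpoint array {i} shape mismatch")
            target[...] = src
    return meta


def parameter_report(models: dict[str, nn.Sequential]) -> dict[str, int]:
    """Per-network trainable parameter counts (architecture-drift guard)."""
    return {name: nn.parameter_count(m) for name, m in models.items()}
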