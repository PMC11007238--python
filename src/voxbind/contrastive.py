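"""Contrastive self-supervised pre-training of the pocket encoder.

Two rigid-transform views of each pocket are featurized, encoded, and
projected; the NT-Xent objective (normalized-temperature cross entropy
over cosine similarities) pulls the two views of one complex together and
pushes views of different complexes apart.  Both views share one encoder
and one projector (Siamese weights), and the projector exists only for the
loss — downstream regression consumes the encoder latents.

The training loop runs all 2B views of a batch through one cached
forward, computes the loss gradient with respect to the embeddings in
closed form, and backpropagates once.  Activation caches grow linearly
with the batch, which is why the default batch is small (4 complexes =
8 views, roughly 2 GB of cached activations at the 41-cube input).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import nn
from .augment import augmented_grid
from .networks import (
    EncoderSpec, ProjectorSpec, build_encoder, build_projector,
)
from .pocket import Pocket
from .voxelize import GridSpec

logger = logging.getLogger("voxbind")

__all__ = [
    "ContrastiveConfig", "cosine_similarity", "nt_xent_loss",
    "nt_xent_loss_and_grad", "pretrain_encoder", "PretrainResult",
]


@dataclass
class ContrastiveConfig:
    temperature: float = 0.5
    batch_complexes: int = 4
    epochs: int = 1
    learning_rate: float = 1e-4
    seed: int = 0
    max_shift: float = 2.0
    projection_dim: int = 128

    def __post_init__(self):
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")
        if self.batch_complexes < 1:
            raise ValueError("batch_complexes must be >= 1")


def cosine_similarity(z1: np.ndarray, z2: np.ndarray) -> float:
    """cos angle between two nonzero vectors, in [-1, 1]."""
    n1, n2 = np.linalg.norm(z1), np.linalg.norm(z2)
    if n1 == 0 or n2 == 0:
        raise ValueError("cosine similarity undefined for zero vectors")
    return float(np.dot(z1, z2) / (n1 * n2))


def _similarity_logits(Z: np.ndarray, temperature: float):
    norms = np.linalg.norm(Z, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise ValueError("zero embedding in batch")
    zn = Z / norms
    S = (zn @ zn.T) / temperature
    np.fill_diagonal(S, -np.inf)  # self-pairs excluded from candidates
    return zn, norms, S


def nt_xent_loss(embeddings: np.ndarray, temperature: float = 0.5) -> float:
    """NT-Xent loss over 2B embeddings paired as (b, B+b).

    For each anchor a with positive p:
    ``l(a, p) = -log softmax_a(p)`` where the softmax runs over all 2B-1
    other embeddings at the given temperature; the loss is the mean of l
    over all 2B anchors.
    """
    loss, _ = nt_xent_loss_and_grad(embeddings, temperature)
    return loss


def nt_xent_loss_and_grad(
    embeddings: np.ndarray, temperature: float = 0.5
) -> tuple[float, np.ndarray]:
    """Loss plus its analytic gradient with respect to the raw embeddings."""
    if temperature <= 0:
        raise ValueError("temperature must be > 0")
    Z = np.asarray(embeddings, dtype=np.float64)
    two_b = Z.shape[0]
    if two_b < 2 or two_b % 2 != 0:
        raise ValueError("need an even number (>= 2) of paired embeddings")
    b = two_b // 2
    pos = np.concatenate([np.arange(b) + b, np.arange(b)])
    zn, norms, S = _similarity_logits(Z, temperature)
    row_max = S.max(axis=1, keepdims=True)
    lse = row_max[:, 0] + np.log(np.exp(S - row_max).sum(axis=1))
    loss = float(np.mean(lse - S[np.arange(two_b), pos]))

    # dL/dS: softmax rows minus the one-hot positives, averaged over anchors
    P = np.exp(S - lse[:, None])
    dS = P.copy()
    dS[np.arange(two_b), pos] -= 1.0
    dS /= two_b
    np.fill_diagonal(dS, 0.0)
    # S = zn zn^T / tau (off-diagonal), so d zn = (dS + dS^T) zn / tau
    dzn = (dS + dS.T) @ zn / temperature
    # through row normalization: dz = (dzn - zn (zn . dzn)) / ||z||
    dZ = (dzn - zn * np.sum(zn * dzn, axis=1, keepdims=True)) / norms
    return loss, dZ


@dataclass
class PretrainResult:
    encoder: nn.Sequential
    projector: nn.Sequential
    loss_trace: list[float]  # per-epoch mean NT-Xent loss


def pretrain_encoder(
    pockets: list[Pocket],
    spec: GridSpec | None = None,
    cfg: ContrastiveConfig | None = None,
    encoder: nn.Sequential | None = None,
    projector: nn.Sequential | None = None,
) -> PretrainResult:
    """Adam-train encoder and projector with NT-Xent over view pairs.

    Per epoch the complex list is shuffled (seeded), cut into batches of
    ``batch_complexes``, and every complex contributes one freshly sampled
    view pair.  Batches left with a single complex are skipped: one pair
    yields a constant zero loss and no gradient signal.
    """
    spec = spec or GridSpec()
    cfg = cfg or ContrastiveConfig()
    if len(pockets) < 2:
        raise ValueError("pre-training needs at least 2 complexes")
    enc_channels = 32
    if encoder is None:
        encoder = build_encoder(EncoderSpec(in_channels=spec.n_channels),
                                seed=cfg.seed)
    if projector is None:
        projector = build_projector(
            ProjectorSpec(in_channels=enc_channels,
                          projection_dim=cfg.projection_dim),
            seed=cfg.seed + 1,
        )
    opt = nn.Adam(encoder.params() + projector.params(), lr=cfg.learning_rate)
    order_rng = np.random.default_rng(cfg.seed)
    seed_stream = np.random.default_rng(cfg.seed + 7)
    trace: list[float] = []
    for epoch in range(cfg.epochs):
        order = order_rng.permutation(len(pockets))
        epoch_losses: list[float] = []
        for start in range(0, len(order), cfg.batch_complexes):
            batch_idx = order[start:start + cfg.batch_complexes]
            if len(batch_idx) < 2:
                logger.warning(
                    "epoch %d: skipping batch of %d complex(es) — "
                    "a single pair carries no contrastive signal",
                    epoch, len(batch_idx),
                )
                continue
            view_seeds = seed_stream.integers(0, 2**31 - 1,
                                              size=(len(batch_idx), 2))
            grids = []
            for idx, (si, sj) in zip(batch_idx, view_seeds):
                p = pockets[idx]
                grids.append(augmented_grid(p, spec, int(si), cfg.max_shift))
                grids.append(augmented_grid(p, spec, int(sj), cfg.max_shift))
            # views ordered (i of c1, j of c1, ...) -> reorder to pairing
            # (all i views, then all j views)
            bsz = len(batch_idx)
            ordered = [grids[2 * k] for k in range(bsz)] + \
                      [grids[2 * k + 1] for k in range(bsz)]
            # one cached forward over all 2B views, one backward
            xall = np.stack([g.values for g in ordered]).astype(np.float32)
            hall = encoder.forward(xall, train=True, cache=True)
            Z = projector.forward(hall, train=True, cache=True)
            loss, dZ = nt_xent_loss_and_grad(Z, cfg.temperature)
            encoder.zero_grad()
            projector.zero_grad()
            dh = projector.backward(dZ.astype(np.float32))
            encoder.backward(dh, need_dx=False)
            opt.step()
            epoch_losses.append(loss)
        trace.append(float(np.mean(epoch_losses)) if epoch_losses else float("nan"))
        logger.info("pretrain epoch %d: mean NT-Xent loss %.4f", epoch, trace[-1])
    return PretrainResult(encoder=encoder, projector=projector, loss_trace=trace)


def write_loss_trace(path, trace: list[float]):
    with open(path, "w") as fh:
        fh.write("epoch,mean_loss\n")
        for i, v in enumerate(trace):
            fh.write(f"{i},{v}\n")
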