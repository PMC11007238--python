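"""Minimal numpy neural-network engine for 3D convolutional models.

All layers operate channels-last: volumetric activations are
``(B, D, H, W, C)`` and dense activations ``(B, F)``.  Convolutions are
evaluated as im2col + BLAS matmul, and every layer implements an explicit
``backward`` so models train with plain reverse-mode accumulation; no
external autodiff framework is involved.  Gradients accumulate into
``Param.grad`` (call :meth:`Sequential.zero_grad` per step), which lets a
loss over many per-sample passes — as in the contrastive objective — be
backpropagated one sample at a time under a fixed memory footprint.

Default dtype is float32 for speed; pass ``dtype=np.float64`` when building
models for finite-difference gradient checking.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param", "Layer", "Sequential", "Conv3d", "BatchNorm", "ReLU", "Dropout",
    "MaxPool3d", "GlobalAvgPool3d", "CenterCrop3d", "Flatten", "Linear",
    "Sigmoid", "ResidualBlock3d", "Adam", "parameter_count",
]


class Param:
    """A trainable array with an accumulated gradient."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = value
        self.grad = np.zeros_like(value)
        self.name = name


class Layer:
    """Base layer: stateless by default, caches activations for backward."""

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = False, cache: bool = True,
                update_stats: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _pad_spatial(x: np.ndarray, p: int) -> np.ndarray:
    if p == 0:
        return x
    return np.pad(x, ((0, 0), (p, p), (p, p), (p, p), (0, 0)))


class Conv3d(Layer):
    """3D convolution (cross-correlation), kernel k, configurable stride.

    ``padding`` is an integer of zero-padded voxels per side: 0 gives a
    "valid" convolution shrinking each spatial side by k-1; (k-1)//2 gives
    "same" for odd k.  Evaluated as a sum of shifted input slices times
    per-offset weight matrices — one small BLAS matmul per kernel offset —
    which avoids materializing the k^3-fold im2col tensor.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel: int = 3,
                 padding: int = 0, stride: int = 1,
                 rng: np.random.Generator | None = None,
                 dtype=np.float32):
        rng = rng or np.random.default_rng(0)
        self.k = kernel
        self.pad = padding
        self.stride = stride
        self.cin = in_channels
        self.cout = out_channels
        fan_in = in_channels * kernel ** 3
        w = rng.standard_normal((kernel, kernel, kernel, in_channels, out_channels))
        self.W = Param((w * np.sqrt(2.0 / fan_in)).astype(dtype), "conv.W")
        self.b = Param(np.zeros(out_channels, dtype=dtype), "conv.b")
        self._x = None

    def params(self):
        return [self.W, self.b]

    def out_side(self, n: int) -> int:
        return (n + 2 * self.pad - self.k) // self.stride + 1

    def _in_slices(self, out_sides):
        """Strided input slice for each kernel offset."""
        s = self.stride
        for a in range(self.k):
            for bb in range(self.k):
                for cc in range(self.k):
                    yield (a, bb, cc), (
                        slice(None),
                        slice(a, a + s * (out_sides[0] - 1) + 1, s),
                        slice(bb, bb + s * (out_sides[1] - 1) + 1, s),
                        slice(cc, cc + s * (out_sides[2] - 1) + 1, s),
                        slice(None),
                    )

    def forward(self, x, train=False, cache=True, update_stats=True):
        if x.shape[-1] != self.cin:
            raise ValueError(f"expected {self.cin} channels, got {x.shape[-1]}")
        if x.shape[1] + 2 * self.pad - self.k < 0:
            raise ValueError(
                f"input side {x.shape[1]} too small for kernel {self.k} "
                f"with padding {self.pad}"
            )
        self._x = x if cache else None
        xp = _pad_spatial(x, self.pad)
        B = x.shape[0]
        sides = tuple(self.out_side(s) for s in x.shape[1:4])
        y = np.zeros((B, *sides, self.cout), dtype=self.W.value.dtype)
        W = self.W.value
        # batched matmul directly on the strided input views
        for (a, bb, cc), sl in self._in_slices(sides):
            y += np.matmul(xp[sl], W[a, bb, cc])
        y += self.b.value
        return y

    def backward(self, dy, need_dx: bool = True):
        x = self._x
        if x is None:
            raise RuntimeError("backward called without cached forward")
        B = x.shape[0]
        k = self.k
        sides = dy.shape[1:4]
        dy = np.ascontiguousarray(dy)
        self.b.grad += dy.sum(axis=(0, 1, 2, 3))
        xp = _pad_spatial(x, self.pad)
        for (a, bb, cc), sl in self._in_slices(sides):
            # (.., C, mw) @ (.., mw, F) batched over leading axes
            xs_t = xp[sl].transpose(0, 1, 2, 4, 3)
            self.W.grad[a, bb, cc] += np.matmul(xs_t, dy).sum(axis=(0, 1, 2))
        if not need_dx:
            return None
        W = self.W.value
        p = self.pad
        if self.stride == 1:
            # input gradient as a full correlation of dy with the flipped
            # kernel
            pd, ph, pw = xp.shape[1:4]
            dyp = _pad_spatial(dy, k - 1)
            dxp = np.zeros((B, pd, ph, pw, self.cin), dtype=W.dtype)
            for a in range(k):
                for bb in range(k):
                    for cc in range(k):
                        dxp += np.matmul(
                            dyp[:, a:a + pd, bb:bb + ph, cc:cc + pw, :],
                            W[k - 1 - a, k - 1 - bb, k - 1 - cc].T,
                        )
        else:
            # strided scatter-add: each output position feeds its own
            # stride-spaced input sites
            dxp = np.zeros_like(xp)
            for (a, bb, cc), sl in self._in_slices(sides):
                dxp[sl] += np.matmul(dy, W[a, bb, cc].T)
        if p:
            dxp = dxp[:, p:-p, p:-p, p:-p, :]
        return dxp


class BatchNorm(Layer):
    """Batch normalization over all axes but the channel axis.

    Train mode normalizes with batch statistics and maintains running
    statistics (momentum 0.1) for evaluation mode.
    """

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1,
                 dtype=np.float32):
        self.gamma = Param(np.ones(channels, dtype=dtype), "bn.gamma")
        self.beta = Param(np.zeros(channels, dtype=dtype), "bn.beta")
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)
        self.eps = eps
        self.momentum = momentum
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, train=False, cache=True, update_stats=True):
        axes = tuple(range(x.ndim - 1))
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            if update_stats:
                m = self.momentum
                self.running_mean = (1 - m) * self.running_mean + m * mean
                self.running_var = (1 - m) * self.running_var + m * var
        else:
            mean, var = self.running_mean, self.running_var
        istd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * istd
        if cache:
            self._cache = (xhat, istd, train, axes)
        return self.gamma.value * xhat + self.beta.value

    def backward(self, dy):
        xhat, istd, train, axes = self._cache
        self.gamma.grad += (dy * xhat).sum(axis=axes)
        self.beta.grad += dy.sum(axis=axes)
        g = self.gamma.value * istd
        if not train:
            return dy * g
        n = np.prod([xhat.shape[a] for a in axes])
        dsum = dy.sum(axis=axes)
        dxhat_sum = (dy * xhat).sum(axis=axes)
        return g * (dy - dsum / n - xhat * dxhat_sum / n)


class ReLU(Layer):
    def forward(self, x, train=False, cache=True, update_stats=True):
        y = np.maximum(x, 0)
        self._mask = (x > 0) if cache else None
        return y

    def backward(self, dy):
        return dy * self._mask


class Sigmoid(Layer):
    def forward(self, x, train=False, cache=True, update_stats=True):
        # numerically stable piecewise form
        y = np.empty_like(x)
        pos = x >= 0
        y[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
        ex = np.exp(x[~pos])
        y[~pos] = ex / (1.0 + ex)
        self._y = y if cache else None
        return y

    def backward(self, dy):
        return dy * self._y * (1.0 - self._y)


class Dropout(Layer):
    """Inverted dropout; identity in evaluation mode.

    The mask stream is drawn from the layer's own Generator, reseedable via
    :meth:`reseed` so training runs are reproducible.
    """

    def __init__(self, rate: float = 0.5, seed: int = 0):
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = np.random.default_rng(seed)
        self._mask = None

    def reseed(self, seed: int):
        self.rng = np.random.default_rng(seed)

    def forward(self, x, train=False, cache=True, update_stats=True):
        if not train or self.rate == 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        self._mask = mask if cache else None
        return x * mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class MaxPool3d(Layer):
    """Non-overlapping max pooling (window = stride = ``size``).

    Odd trailing voxels are cropped (floor semantics).
    """

    def __init__(self, size: int = 2):
        self.size = size

    def forward(self, x, train=False, cache=True, update_stats=True):
        s = self.size
        B, D, H, W, C = x.shape
        d, h, w = D // s, H // s, W // s
        xc = x[:, : d * s, : h * s, : w * s, :]
        r = xc.reshape(B, d, s, h, s, w, s, C).transpose(0, 1, 3, 5, 7, 2, 4, 6)
        r = r.reshape(B, d, h, w, C, s ** 3)
        idx = r.argmax(axis=-1)
        y = np.take_along_axis(r, idx[..., None], axis=-1)[..., 0]
        if cache:
            self._cache = (x.shape, idx)
        return y

    def backward(self, dy):
        (B, D, H, W, C), idx = self._cache
        s = self.size
        d, h, w = D // s, H // s, W // s
        dr = np.zeros((B, d, h, w, C, s ** 3), dtype=dy.dtype)
        np.put_along_axis(dr, idx[..., None], dy[..., None], axis=-1)
        dr = dr.reshape(B, d, h, w, C, s, s, s).transpose(0, 1, 5, 2, 6, 3, 7, 4)
        dx = np.zeros((B, D, H, W, C), dtype=dy.dtype)
        dx[:, : d * s, : h * s, : w * s, :] = dr.reshape(B, d * s, h * s, w * s, C)
        return dx


class GlobalAvgPool3d(Layer):
    """Mean over the three spatial axes: (B, D, H, W, C) -> (B, C)."""

    def forward(self, x, train=False, cache=True, update_stats=True):
        self._shape = x.shape
        return x.mean(axis=(1, 2, 3))

    def backward(self, dy):
        B, D, H, W, C = self._shape
        return np.broadcast_to(
            dy[:, None, None, None, :], self._shape
        ).astype(dy.dtype) / (D * H * W)


class CenterCrop3d(Layer):
    """Symmetric spatial crop by ``crop`` voxels per side."""

    def __init__(self, crop: int):
        self.crop = crop

    def forward(self, x, train=False, cache=True, update_stats=True):
        c = self.crop
        self._shape = x.shape
        return x[:, c:-c, c:-c, c:-c, :] if c else x

    def backward(self, dy):
        c = self.crop
        if not c:
            return dy
        dx = np.zeros(self._shape, dtype=dy.dtype)
        dx[:, c:-c, c:-c, c:-c, :] = dy
        return dx


class Flatten(Layer):
    def forward(self, x, train=False, cache=True, update_stats=True):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Linear(Layer):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator | None = None, dtype=np.float32):
        rng = rng or np.random.default_rng(0)
        w = rng.standard_normal((in_features, out_features))
        self.W = Param((w * np.sqrt(2.0 / in_features)).astype(dtype), "linear.W")
        self.b = Param(np.zeros(out_features, dtype=dtype), "linear.b")
        self._x = None

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train=False, cache=True, update_stats=True):
        self._x = x if cache else None
        return x @ self.W.value + self.b.value

    def backward(self, dy):
        self.W.grad += self._x.T @ dy
        self.b.grad += dy.sum(axis=0)
        return dy @ self.W.value.T


class Sequential(Layer):
    """Plain layer chain with reverse-order backward."""

    def __init__(self, layers: list[Layer]):
        self.layers = list(layers)

    def params(self):
        out = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def zero_grad(self):
        for p in self.params():
            p.grad[...] = 0

    def forward(self, x, train=False, cache=True, update_stats=True):
        for layer in self.layers:
            x = layer.forward(x, train=train, cache=cache,
                              update_stats=update_stats)
        return x

    def backward(self, dy, need_dx: bool = True):
        for i, layer in reversed(list(enumerate(self.layers))):
            if i == 0 and not need_dx and isinstance(layer, (Conv3d, Sequential)):
                dy = layer.backward(dy, need_dx=False)
            else:
                dy = layer.backward(dy)
        return dy

    def reseed_dropout(self, seed: int):
        i = 0
        for layer in self.layers:
            if isinstance(layer, Dropout):
                layer.reseed(seed + i)
                i += 1
            elif isinstance(layer, (Sequential, ResidualBlock3d)):
                layer.reseed_dropout(seed + 1000 * (i + 1))

    def state_arrays(self) -> list[np.ndarray]:
        """All arrays defining the model: params plus batch-norm statistics."""
        arrays = [p.value for p in self.params()]
        for layer in self._walk():
            if isinstance(layer, BatchNorm):
                arrays.extend([layer.running_mean, layer.running_var])
        return arrays

    def _walk(self):
        for layer in self.layers:
            if isinstance(layer, Sequential):
                yield from layer._walk()
            elif isinstance(layer, ResidualBlock3d):
                yield from layer.main._walk()
            else:
                yield layer


class ResidualBlock3d(Layer):
    """Residual block: three convolutions with batch norm and ReLU.

    The first convolution is unpadded (side shrinks by 2), the next two are
    "same"-padded; the shortcut centre-crops the input by one voxel per
    side so it matches the main path, and the final ReLU follows the
    addition.
    """

    def __init__(self, channels: int, rng: np.random.Generator, dtype=np.float32):
        self.main = Sequential([
            Conv3d(channels, channels, 3, padding=0, rng=rng, dtype=dtype),
            BatchNorm(channels, dtype=dtype),
            ReLU(),
            Conv3d(channels, channels, 3, padding=1, rng=rng, dtype=dtype),
            BatchNorm(channels, dtype=dtype),
            ReLU(),
            Conv3d(channels, channels, 3, padding=1, rng=rng, dtype=dtype),
            BatchNorm(channels, dtype=dtype),
        ])
        self.crop = CenterCrop3d(1)
        self.relu = ReLU()

    def params(self):
        return self.main.params()

    def reseed_dropout(self, seed: int):
        self.main.reseed_dropout(seed)

    def forward(self, x, train=False, cache=True, update_stats=True):
        main = self.main.forward(x, train=train, cache=cache,
                                 update_stats=update_stats)
        short = self.crop.forward(x, train=train, cache=cache)
        return self.relu.forward(main + short, train=train, cache=cache)

    def backward(self, dy):
        dsum = self.relu.backward(dy)
        dx_main = self.main.backward(dsum)
        dx_short = self.crop.backward(dsum)
        return dx_main + dx_short


class Adam:
    """Adaptive-moment optimizer over a fixed parameter list."""

    def __init__(self, params: list[Param], lr: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        if lr <= 0:
            raise ValueError("learning rate must be > 0")
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            m += (1 - b1) * (p.grad - m)
            v += (1 - b2) * (p.grad ** 2 - v)
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def parameter_count(model: Layer) -> int:
    return int(sum(p.value.size for p in model.params()))
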