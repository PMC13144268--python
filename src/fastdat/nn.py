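"""Minimal CNN engine: NumPy layers with hand-written backprop, and a U-Net.

Tensors are float32 and channels-last, shape (batch, height, width, channels).
Convolutions are evaluated as a sum over kernel offsets of one large GEMM
each (via ``np.tensordot``), which keeps the whole forward/backward pass in
BLAS without im2col buffers.  Everything is pure NumPy, so a fixed seed gives
bit-reproducible training on a single CPU.
"""

from __future__ import annotations

import numpy as np

__all__ = ["UNet", "Adam", "mse_loss"]

F32 = np.float32


# ---------------------------------------------------------------------------
# Functional layers: forward returns (out, cache); backward returns input grads
# ---------------------------------------------------------------------------


def conv3x3_forward(x, W, b):
    """Same-padded 3x3 convolution.  W: (3, 3, Cin, Cout), b: (Cout,)."""
    B, H, Wd, _ = x.shape
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
    out = np.broadcast_to(b, (B, H, Wd, b.shape[0])).astype(x.dtype).copy()
    for i in range(3):
        for j in range(3):
            out += np.tensordot(xp[:, i : i + H, j : j + Wd, :], W[i, j], axes=([3], [0]))
    return out, (xp, W)


def conv3x3_backward(dout, cache):
    xp, W = cache
    B, Hp, Wp, Ci = xp.shape
    H, Wd = Hp - 2, Wp - 2
    dW = np.empty_like(W)
    dxp = np.zeros_like(xp)
    for i in range(3):
        for j in range(3):
            patch = xp[:, i : i + H, j : j + Wd, :]
            dW[i, j] = np.tensordot(patch, dout, axes=([0, 1, 2], [0, 1, 2]))
            dxp[:, i : i + H, j : j + Wd, :] += np.tensordot(dout, W[i, j], axes=([3], [1]))
    db = dout.sum(axis=(0, 1, 2))
    return dxp[:, 1:-1, 1:-1, :], dW, db


def conv1x1_forward(x, W, b):
    """Pointwise convolution.  W: (Cin, Cout)."""
    return np.tensordot(x, W, axes=([3], [0])) + b, (x, W)


def conv1x1_backward(dout, cache):
    x, W = cache
    dW = np.tensordot(x, dout, axes=([0, 1, 2], [0, 1, 2]))
    db = dout.sum(axis=(0, 1, 2))
    dx = np.tensordot(dout, W, axes=([3], [1]))
    return dx, dW, db


def relu_forward(x):
    out = np.maximum(x, 0)
    return out, x > 0


def relu_backward(dout, mask):
    return dout * mask


def maxpool2_forward(x):
    """2x2 max pooling; ties resolve to the first element (argmax order)."""
    B, H, W, C = x.shape
    r = x.reshape(B, H // 2, 2, W // 2, 2, C).transpose(0, 1, 3, 2, 4, 5)
    flat = r.reshape(B, H // 2, W // 2, 4, C)
    idx = flat.argmax(axis=3)
    out = np.take_along_axis(flat, idx[:, :, :, None, :], axis=3)[:, :, :, 0, :]
    return out, (idx, x.shape)


def maxpool2_backward(dout, cache):
    idx, shape = cache
    B, H, W, C = shape
    dflat = np.zeros((B, H // 2, W // 2, 4, C), dtype=dout.dtype)
    np.put_along_axis(dflat, idx[:, :, :, None, :], dout[:, :, :, None, :], axis=3)
    return (
        dflat.reshape(B, H // 2, W // 2, 2, 2, C)
        .transpose(0, 1, 3, 2, 4, 5)
        .reshape(B, H, W, C)
    )


def upsample2_forward(x):
    """Nearest-neighbour 2x upsampling."""
    return x.repeat(2, axis=1).repeat(2, axis=2), x.shape


def upsample2_backward(dout, shape):
    B, H, W, C = shape
    return dout.reshape(B, H, 2, W, 2, C).sum(axis=(2, 4))


def mse_loss(pred, target):
    """Mean squared error over all pixels; returns (loss, dpred)."""
    diff = np.asarray(pred) - np.asarray(target)
    loss = float(np.mean(diff.astype(np.float64) ** 2))
    return loss, (2.0 / diff.size) * diff


# ---------------------------------------------------------------------------
# U-Net
# ---------------------------------------------------------------------------


class UNet:
    """Encoder-decoder with skip connections.

    ``depth`` resolution levels with the filter schedule 16, 32, ... doubling
    per level; two same-padded 3x3 conv + ReLU per block; 2x max-pool down
    and nearest-upsample + 3x3 conv up; skips concatenated channel-wise; a
    final 1x1 conv maps to one output channel (linear).
    """

    def __init__(self, depth: int, in_channels: int = 5, base_filters: int = 16, seed: int = 0,
                 dtype=F32):
        if not 1 <= depth <= 5:
            raise ValueError(f"depth must be in 1..5, got {depth}")
        self.depth = depth
        self.in_channels = in_channels
        self.dtype = dtype
        self.filters = [base_filters * 2**i for i in range(depth)]
        self.params: dict[str, np.ndarray] = {}
        rng = np.random.default_rng(int(seed) & 0x7FFFFFFF)

        def add_conv(name, ci, co, k=3):
            fan_in = k * k * ci
            std = np.sqrt(2.0 / fan_in)  # He initialisation for ReLU blocks
            shape = (k, k, ci, co) if k == 3 else (ci, co)
            self.params[f"{name}_W"] = rng.normal(0.0, std, shape).astype(dtype)
            self.params[f"{name}_b"] = np.zeros(co, dtype=dtype)

        ci = in_channels
        for lvl, f in enumerate(self.filters):  # encoder (last level = bottleneck)
            add_conv(f"enc{lvl}a", ci, f)
            add_conv(f"enc{lvl}b", f, f)
            ci = f
        for lvl in range(depth - 2, -1, -1):  # decoder
            f = self.filters[lvl]
            add_conv(f"up{lvl}", self.filters[lvl + 1], f)  # conv after upsample
            add_conv(f"dec{lvl}a", 2 * f, f)  # concat(skip, up)
            add_conv(f"dec{lvl}b", f, f)
        add_conv("out", self.filters[0], 1, k=1)

    # -- plumbing -----------------------------------------------------------

    def n_parameters(self) -> int:
        return sum(p.size for p in self.params.values())

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def load_state_dict(self, state) -> None:
        for k in self.params:
            self.params[k] = np.asarray(state[k], dtype=self.dtype).copy()

    # -- forward / backward -------------------------------------------------

    def _conv_block(self, x, name, caches):
        p = self.params
        x, c1 = conv3x3_forward(x, p[f"{name}a_W"], p[f"{name}a_b"])
        x, m1 = relu_forward(x)
        x, c2 = conv3x3_forward(x, p[f"{name}b_W"], p[f"{name}b_b"])
        x, m2 = relu_forward(x)
        caches[name] = (c1, m1, c2, m2)
        return x

    def _conv_block_backward(self, dout, name, caches, grads):
        c1, m1, c2, m2 = caches[name]
        d = relu_backward(dout, m2)
        d, grads[f"{name}b_W"], grads[f"{name}b_b"] = conv3x3_backward(d, c2)
        d = relu_backward(d, m1)
        d, grads[f"{name}a_W"], grads[f"{name}a_b"] = conv3x3_backward(d, c1)
        return d

    def forward(self, x, want_cache: bool = False):
        """x: (B, H, W, in_channels) float32 -> (B, H, W, 1)."""
        x = np.ascontiguousarray(x, dtype=self.dtype)
        caches: dict = {}
        skips = []
        for lvl in range(self.depth - 1):
            x = self._conv_block(x, f"enc{lvl}", caches)
            skips.append(x)
            x, caches[f"pool{lvl}"] = maxpool2_forward(x)
        x = self._conv_block(x, f"enc{self.depth - 1}", caches)
        for lvl in range(self.depth - 2, -1, -1):
            x, caches[f"upsamp{lvl}"] = upsample2_forward(x)
            x, caches[f"upconv{lvl}"] = conv3x3_forward(
                x, self.params[f"up{lvl}_W"], self.params[f"up{lvl}_b"]
            )
            x, caches[f"uprelu{lvl}"] = relu_forward(x)
            skip = skips[lvl]
            x = np.concatenate([skip, x], axis=3)
            caches[f"cat{lvl}"] = skip.shape[3]
            x = self._conv_block(x, f"dec{lvl}", caches)
        out, caches["out"] = conv1x1_forward(x, self.params["out_W"], self.params["out_b"])
        return (out, caches) if want_cache else out

    def backward(self, dout, caches):
        grads: dict[str, np.ndarray] = {}
        d, grads["out_W"], grads["out_b"] = conv1x1_backward(dout, caches["out"])
        dskips = {}
        for lvl in range(0, self.depth - 1):
            d = self._conv_block_backward(d, f"dec{lvl}", caches, grads)
            nskip = caches[f"cat{lvl}"]
            dskips[lvl] = d[:, :, :, :nskip]
            d = d[:, :, :, nskip:]
            d = relu_backward(d, caches[f"uprelu{lvl}"])
            d, grads[f"up{lvl}_W"], grads[f"up{lvl}_b"] = conv3x3_backward(d, caches[f"upconv{lvl}"])
            d = upsample2_backward(d, caches[f"upsamp{lvl}"])
        d = self._conv_block_backward(d, f"enc{self.depth - 1}", caches, grads)
        for lvl in range(self.depth - 2, -1, -1):
            d = maxpool2_backward(d, caches[f"pool{lvl}"])
            d = d + dskips[lvl]
            d = self._conv_block_backward(d, f"enc{lvl}", caches, grads)
        return grads


class Adam:
    """Adam optimiser over a parameter dict (Kingma & Ba defaults)."""

    def __init__(self, params, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params, grads, lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        correction = np.sqrt(1.0 - b2**self.t) / (1.0 - b1**self.t)
        for k, g in grads.items():
            g = np.asarray(g, dtype=self.m[k].dtype)
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            params[k] -= (lr * correction) * self.m[k] / (np.sqrt(self.v[k]) + self.eps)
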