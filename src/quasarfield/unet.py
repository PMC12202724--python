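"""Minimal 3D convolutional-network engine (numpy, manual backprop).

Provides exactly what the learned dipole inversion needs: 3x3x3 "same"
convolutions, leaky ReLU, 2x average pooling, nearest upsampling, channel
concatenation, an Adam optimizer, and a 3D U-Net assembled from those
pieces.  Everything runs in float32 on the CPU and is deterministic given
the initialization seed.

Layout convention: activations are channels-last, (N, D, H, W, C).  With
C contiguous, every kernel tap becomes a strided batched matmul that BLAS
handles without intermediate copies — this is what makes CPU training
budgets of minutes per model possible.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Conv3d", "UNet3D", "Adam"]

_DT = np.float32

_LEAK = np.float32(0.1)


def _relu_fwd(x):
    # leaky rectifier: the small negative slope keeps units trainable (plain
    # ReLU nets of this size die under L1 sign gradients)
    return np.where(x > 0, x, _LEAK * x)


class Conv3d:
    """3x3x3 (or 1x1x1) convolution with 'same' zero padding, stride 1.

    Implemented as a sum of shifted-slice matmuls, one per kernel tap:
    for each spatial offset the padded input slice (N, D, H, W, C_in) is
    multiplied by that tap's (C_in, C_out) weight plane.
    """

    def __init__(self, c_in: int, c_out: int, ksize: int, rng: np.random.Generator):
        self.c_in, self.c_out, self.k = c_in, c_out, ksize
        fan_in = c_in * ksize**3
        # He initialization (rectifier-heavy network); taps-first layout
        self.W = (rng.standard_normal((ksize, ksize, ksize, c_in, c_out))
                  * np.sqrt(2.0 / fan_in)).astype(_DT)
        self.b = np.zeros(c_out, dtype=_DT)
        self._xp = None

    def forward(self, x: np.ndarray, keep: bool = True) -> np.ndarray:
        n, d, h, w, c = x.shape
        k, p = self.k, self.k // 2
        if k == 1:
            out = x @ self.W[0, 0, 0]
            if keep:
                self._xp = x
        else:
            xp = np.pad(x, ((0, 0), (p, p), (p, p), (p, p), (0, 0)))
            out = np.zeros((n, d, h, w, self.c_out), dtype=_DT)
            for dz in range(k):
                for dy in range(k):
                    for dx in range(k):
                        out += xp[:, dz:dz + d, dy:dy + h, dx:dx + w] @ self.W[dz, dy, dx]
            if keep:
                self._xp = xp
        out += self.b
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, d, h, w, co = dout.shape
        k, p = self.k, self.k // 2
        self.db = dout.sum(axis=(0, 1, 2, 3)).astype(_DT)
        self.dW = np.empty_like(self.W)
        dflat = dout.reshape(-1, co)
        if k == 1:
            x2d = self._xp.reshape(-1, self.c_in)
            self.dW[0, 0, 0] = x2d.T @ dflat
            return dout @ self.W[0, 0, 0].T
        dxp = np.zeros_like(self._xp)
        for dz in range(k):
            for dy in range(k):
                for dx in range(k):
                    sl = self._xp[:, dz:dz + d, dy:dy + h, dx:dx + w]
                    x2d = np.ascontiguousarray(sl).reshape(-1, self.c_in)
                    self.dW[dz, dy, dx] = x2d.T @ dflat
                    dxp[:, dz:dz + d, dy:dy + h, dx:dx + w] += dout @ self.W[dz, dy, dx].T
        return np.ascontiguousarray(dxp[:, p:p + d, p:p + h, p:p + w])


def _avgpool_fwd(x):
    n, d, h, w, c = x.shape
    return x.reshape(n, d // 2, 2, h // 2, 2, w // 2, 2, c).mean(axis=(2, 4, 6))


def _avgpool_bwd(dout):
    up = np.repeat(np.repeat(np.repeat(dout, 2, axis=1), 2, axis=2), 2, axis=3)
    return (up / 8.0).astype(_DT)


def _upsample_fwd(x):
    return np.repeat(np.repeat(np.repeat(x, 2, axis=1), 2, axis=2), 2, axis=3)


def _upsample_bwd(dout):
    n, d, h, w, c = dout.shape
    return dout.reshape(n, d // 2, 2, h // 2, 2, w // 2, 2, c).sum(axis=(2, 4, 6))


class _ConvBlock:
    """conv -> leaky ReLU -> conv -> leaky ReLU."""

    def __init__(self, c_in, c_out, rng):
        self.c1 = Conv3d(c_in, c_out, 3, rng)
        self.c2 = Conv3d(c_out, c_out, 3, rng)

    def forward(self, x, keep=True):
        a = self.c1.forward(x, keep)
        self._m1 = np.where(a > 0, np.float32(1.0), _LEAK) if keep else None
        a = _relu_fwd(a)
        b = self.c2.forward(a, keep)
        self._m2 = np.where(b > 0, np.float32(1.0), _LEAK) if keep else None
        return _relu_fwd(b)

    def backward(self, dout):
        dout = dout * self._m2
        dout = self.c2.backward(dout)
        dout = dout * self._m1
        return self.c1.backward(dout)

    @property
    def convs(self):
        return [self.c1, self.c2]


class UNet3D:
    """Encoder-decoder with skip connections, 1 input and 1 output channel.

    ``depth`` encoder levels; level i carries base_filters * 2**i channels.
    depth=1 degenerates to a plain conv stack (no pooling).  Input spatial
    dims must be divisible by 2**(depth-1).  Activations are channels-last:
    (N, D, H, W, C).
    """

    def __init__(self, depth: int = 3, base_filters: int = 8, seed: int = 0):
        if depth < 1 or base_filters < 1:
            raise ValueError("depth and base_filters must be positive")
        self.depth, self.base = depth, base_filters
        rng = np.random.default_rng(seed)
        ch = [base_filters * 2**i for i in range(depth)]
        self.enc = []
        c_prev = 1
        for i in range(depth - 1):
            self.enc.append(_ConvBlock(c_prev, ch[i], rng))
            c_prev = ch[i]
        self.bottom = _ConvBlock(c_prev, ch[-1], rng)
        self.dec = []
        for i in reversed(range(depth - 1)):
            self.dec.append(_ConvBlock(ch[i + 1] + ch[i], ch[i], rng))
        self.head = Conv3d(ch[0], 1, 1, rng)

    # -- plumbing -----------------------------------------------------------
    def conv_layers(self):
        layers = []
        for blk in self.enc:
            layers += blk.convs
        layers += self.bottom.convs
        for blk in self.dec:
            layers += blk.convs
        layers.append(self.head)
        return layers

    def n_parameters(self) -> int:
        return sum(l.W.size + l.b.size for l in self.conv_layers())

    def check_shape(self, spatial) -> None:
        f = 2 ** (self.depth - 1)
        if any(s % f for s in spatial):
            raise ValueError(
                f"spatial dims {tuple(spatial)} must be divisible by {f} for depth {self.depth}")

    def forward(self, x: np.ndarray, keep: bool = True) -> np.ndarray:
        """x: (N, D, H, W, 1) float32 -> (N, D, H, W, 1)."""
        x = x.astype(_DT, copy=False)
        self.check_shape(x.shape[1:4])
        skips = []
        for blk in self.enc:
            x = blk.forward(x, keep)
            skips.append(x)
            x = _avgpool_fwd(x)
        x = self.bottom.forward(x, keep)
        for blk, skip in zip(self.dec, reversed(skips)):
            x = _upsample_fwd(x)
            x = np.concatenate([x, skip], axis=-1)
            x = blk.forward(x, keep)
        return self.head.forward(x, keep)

    def backward(self, dout: np.ndarray) -> None:
        d = self.head.backward(dout.astype(_DT, copy=False))
        dskips = []
        for blk in reversed(self.dec):
            d = blk.backward(d)
            c_skip = blk.c2.c_out  # skip carries the level's channel count
            d, dskip = d[..., :-c_skip], d[..., -c_skip:]
            dskips.append(dskip)
            d = _upsample_bwd(d)
        d = self.bottom.backward(d)
        # dskips were collected from the last decoder block (full resolution)
        # upward; the encoder is walked deepest-first, so re-reverse
        for blk, dskip in zip(reversed(self.enc), reversed(dskips)):
            d = _avgpool_bwd(d)
            d = d + dskip
            d = blk.backward(d)

    def state(self):
        return [(l.W.copy(), l.b.copy()) for l in self.conv_layers()]

    def load_state(self, state):
        for l, (W, b) in zip(self.conv_layers(), state):
            if l.W.shape != W.shape:
                raise ValueError("weight shape mismatch while loading state")
            l.W, l.b = W.astype(_DT), b.astype(_DT)


class Adam:
    """Adam over a UNet3D's conv layers."""

    def __init__(self, net: UNet3D, lr: float = 2e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.net, self.lr, self.b1, self.b2, self.eps = net, lr, beta1, beta2, eps
        self.t = 0
        self.m = [(np.zeros_like(l.W), np.zeros_like(l.b)) for l in net.conv_layers()]
        self.v = [(np.zeros_like(l.W), np.zeros_like(l.b)) for l in net.conv_layers()]

    def step(self):
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for i, l in enumerate(self.net.conv_layers()):
            for j, (p, g) in enumerate((("W", l.dW), ("b", l.db))):
                m = self.m[i][j]
                v = self.v[i][j]
                m *= self.b1
                m += (1 - self.b1) * g
                v *= self.b2
                v += (1 - self.b2) * g * g
                update = self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
                setattr(l, p, getattr(l, p) - update)
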