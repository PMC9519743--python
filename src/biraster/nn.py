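"""Minimal convolutional-network primitives on numpy with explicit backprop.

These primitives carry the correction network: 2D convolution (reflective
'same' padding, arbitrary stride) via im2col and BLAS matmul, leaky-ReLU and
sigmoid activations, sub-pixel (pixel-shuffle) upsampling, median pooling,
He-normal initialization and an Adam optimizer with decoupled-from-nothing
plain L2 weight decay. Every layer caches what its backward pass needs;
``backward`` consumes the upstream gradient and returns the gradient with
respect to the layer input while accumulating parameter gradients in place.

Feature maps are float32 arrays of shape (batch, channels, height, width).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Module",
    "Conv2d",
    "LeakyReLU",
    "Sigmoid",
    "PixelShuffle",
    "median_pool",
    "pixel_shuffle",
    "pixel_unshuffle",
    "Adam",
    "he_normal",
]


def he_normal(shape, fan_in: int, rng: np.random.Generator) -> np.ndarray:
    """He normal initialization: N(0, sqrt(2/fan_in))."""
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)


class Param:
    """A trainable tensor with its gradient accumulator."""

    __slots__ = ("data", "grad")

    def __init__(self, data: np.ndarray):
        self.data = np.ascontiguousarray(data, dtype=np.float32)
        self.grad = np.zeros_like(self.data)


class Module:
    """Base class: parameter collection plus forward/backward protocol."""

    def params(self) -> list:
        out = []
        for v in self.__dict__.values():
            if isinstance(v, Param):
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v.params())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.params())
                    elif isinstance(item, Param):
                        out.append(item)
        return out

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0.0

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.params()))

    def state_arrays(self) -> list:
        return [p.data for p in self.params()]

    def load_state_arrays(self, arrays) -> None:
        own = self.params()
        if len(arrays) != len(own):
            raise ValueError("checkpoint parameter count mismatch")
        for p, a in zip(own, arrays):
            if p.data.shape != a.shape:
                raise ValueError("checkpoint parameter shape mismatch")
            p.data[...] = a


def _reflect_indices(n: int, pad: int) -> np.ndarray:
    """Source index for each position of a reflect-padded axis (no edge repeat)."""
    return np.pad(np.arange(n), pad, mode="reflect")


class Conv2d(Module):
    """2D convolution with reflective 'same' padding and optional stride.

    Output spatial size is ``ceil(H / stride)``. The im2col tensor is cached
    for the weight-gradient matmul; the input gradient is assembled by a
    col2im scatter over the k*k kernel offsets followed by the adjoint of the
    reflect padding.
    """

    def __init__(self, cin, cout, k=3, stride=1, rng=None, bias=True):
        if k % 2 != 1:
            raise ValueError("odd kernel sizes only")
        rng = rng or np.random.default_rng()
        self.cin, self.cout, self.k, self.stride = cin, cout, k, stride
        self.weight = Param(he_normal((cout, cin, k, k), cin * k * k, rng))
        self.bias = Param(np.zeros(cout, np.float32)) if bias else None
        self._cache = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        B, C, H, W = x.shape
        if C != self.cin:
            raise ValueError(f"expected {self.cin} input channels, got {C}")
        k, s, p = self.k, self.stride, (self.k - 1) // 2
        if p > 0:
            ih = _reflect_indices(H, p)
            iw = _reflect_indices(W, p)
            xp = x[:, :, ih[:, None], iw[None, :]]
        else:
            xp = x
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
        cols = win[:, :, ::s, ::s]  # (B, C, Ho, Wo, k, k)
        Ho, Wo = cols.shape[2], cols.shape[3]
        cols2 = np.ascontiguousarray(cols)
        y = np.tensordot(cols2, self.weight.data, axes=([1, 4, 5], [1, 2, 3]))
        y = np.moveaxis(y, 3, 1)  # (B, Cout, Ho, Wo)
        if self.bias is not None:
            y += self.bias.data[None, :, None, None]
        if train:
            self._cache = (cols2, x.shape, xp.shape)
        return np.ascontiguousarray(y, dtype=np.float32)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        cols, xshape, xpshape = self._cache
        B, C, H, W = xshape
        k, s, p = self.k, self.stride, (self.k - 1) // 2
        Ho, Wo = gy.shape[2], gy.shape[3]
        # parameter gradients
        gw = np.tensordot(gy, cols, axes=([0, 2, 3], [0, 2, 3]))  # (Cout,C,k,k)
        self.weight.grad += gw
        if self.bias is not None:
            self.bias.grad += gy.sum(axis=(0, 2, 3))
        # input gradient: (B,Ho,Wo,C,k,k) then scatter
        gcols = np.tensordot(np.moveaxis(gy, 1, 3), self.weight.data, axes=([3], [0]))
        gxp = np.zeros((B, C, xpshape[2], xpshape[3]), np.float32)
        for ki in range(k):
            for kj in range(k):
                gxp[:, :, ki : ki + (Ho - 1) * s + 1 : s, kj : kj + (Wo - 1) * s + 1 : s] += np.moveaxis(
                    gcols[:, :, :, :, ki, kj], 3, 1
                )
        if p == 0:
            return gxp
        # adjoint of reflect padding, rows then columns
        ih = _reflect_indices(H, p)
        iw = _reflect_indices(W, p)
        grows = gxp[:, :, p : p + H, :].copy()
        for ip in list(range(p)) + list(range(p + H, 2 * p + H)):
            grows[:, :, ih[ip], :] += gxp[:, :, ip, :]
        gx = grows[:, :, :, p : p + W].copy()
        for ipp in list(range(p)) + list(range(p + W, 2 * p + W)):
            gx[:, :, :, iw[ipp]] += grows[:, :, :, ipp]
        return gx


class LeakyReLU(Module):
    def __init__(self, slope: float = 0.2):
        self.slope = slope
        self._mask = None

    def forward(self, x, train: bool = True):
        mask = x >= 0
        y = np.where(mask, x, self.slope * x)
        if train:
            self._mask = mask
        return y.astype(np.float32)

    def backward(self, gy):
        return np.where(self._mask, gy, self.slope * gy).astype(np.float32)


class Sigmoid(Module):
    def __init__(self):
        self._y = None

    def forward(self, x, train: bool = True):
        y = 1.0 / (1.0 + np.exp(-np.clip(x.astype(np.float64), -60.0, 60.0)))
        y = y.astype(np.float32)
        if train:
            self._y = y
        return y

    def backward(self, gy):
        y = self._y
        return (gy * y * (1.0 - y)).astype(np.float32)


def pixel_shuffle(x: np.ndarray, r: int) -> np.ndarray:
    """Rearrange (B, C*r^2, H, W) -> (B, C, H*r, W*r).

    Channel ``c*r*r + i*r + j`` lands at spatial offset (i, j) inside each
    upsampled r x r cell — the standard sub-pixel convolution layout.
    """
    B, Cr2, H, W = x.shape
    if Cr2 % (r * r) != 0:
        raise ValueError("channel count not divisible by r^2")
    C = Cr2 // (r * r)
    y = x.reshape(B, C, r, r, H, W)
    y = y.transpose(0, 1, 4, 2, 5, 3)  # B, C, H, r, W, r
    return np.ascontiguousarray(y.reshape(B, C, H * r, W * r))


def pixel_unshuffle(y: np.ndarray, r: int) -> np.ndarray:
    """Exact inverse of :func:`pixel_shuffle`."""
    B, C, Hr, Wr = y.shape
    if Hr % r or Wr % r:
        raise ValueError("spatial dims not divisible by r")
    H, W = Hr // r, Wr // r
    x = y.reshape(B, C, H, r, W, r).transpose(0, 1, 3, 5, 2, 4)
    return np.ascontiguousarray(x.reshape(B, C * r * r, H, W))


class PixelShuffle(Module):
    def __init__(self, r: int = 2):
        self.r = r

    def forward(self, x, train: bool = True):
        return pixel_shuffle(x, self.r)

    def backward(self, gy):
        return pixel_unshuffle(gy, self.r)


def median_pool(image: np.ndarray, factor: int) -> np.ndarray:
    """Median pooling over non-overlapping factor x factor blocks.

    Accepts 2D images or (B, C, H, W) maps; for blocks with an even number
    of elements the median is the mean of the two central order statistics
    (numpy convention). Dimensions must divide evenly.
    """
    if factor == 1:
        return image
    x = np.asarray(image)
    H, W = x.shape[-2], x.shape[-1]
    if H % factor or W % factor:
        raise ValueError("image dimensions not divisible by pooling factor")
    shape = x.shape[:-2] + (H // factor, factor, W // factor, factor)
    blocks = x.reshape(shape)
    blocks = np.moveaxis(blocks, -3, -2)  # (..., H/f, W/f, f, f)
    flat = blocks.reshape(shape[:-4] + (H // factor, W // factor, factor * factor))
    return np.median(flat, axis=-1).astype(x.dtype)


class Adam:
    """Adam with plain L2 weight decay (added to the gradient)."""

    def __init__(self, params, lr=2e-4, betas=(0.5, 0.999), eps=1e-8, weight_decay=1e-5):
        self.params = list(params)
        self.lr, self.betas, self.eps, self.wd = lr, betas, eps, weight_decay
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            if self.wd:
                g = g + self.wd * p.data
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
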