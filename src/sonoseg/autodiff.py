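"""Minimal reverse-mode autodiff on numpy arrays.

A small tape-based engine providing exactly the operations the U-Net
variants need: 'same' 2-D convolution, 2x2 stride-2 transposed convolution,
2x2 max pooling, channel concatenation, broadcasting add/multiply, the smooth
activations, sigmoid, dropout, and the fixed (non-trainable) sharpening
convolution. Arrays are laid out NHWC. Every primitive's backward pass is
finite-difference-checked in the test suite.
"""

from __future__ import annotations

import numpy as np

from .components import SHARPEN_KERNEL, activation_grad, _ACTIVATIONS


class Tensor:
    """An array node on the autodiff tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward", "name")

    def __init__(self, data, requires_grad=False, parents=(), backward=None, name=None):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p in parents
        )
        self._parents = tuple(parents)
        self._backward = backward
        self.name = name

    @property
    def shape(self):
        return self.data.shape

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def backward(self, grad=None):
        """Reverse-accumulate gradients from this node through the tape."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a seed needs a scalar tensor")
            grad = np.ones_like(self.data)
        order: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative topological sort; graphs can be deep
            node, done = stack.pop()
            if done:
                order.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accumulate(self, grad):
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    def zero_grad(self):
        self.grad = None


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` back down to `shape` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


def constant(data) -> Tensor:
    return Tensor(data, requires_grad=False)


def parameter(data, name=None) -> Tensor:
    return Tensor(np.asarray(data), requires_grad=True, name=name)


def add(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data + b.data, parents=(a, b))

    def bwd(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g, b.data.shape))

    out._backward = bwd
    return out


def mul(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data * b.data, parents=(a, b))

    def bwd(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * a.data, b.data.shape))

    out._backward = bwd
    return out


def act(x: Tensor, name: str) -> Tensor:
    fn, _ = _ACTIVATIONS[name]
    out = Tensor(fn(x.data).astype(x.data.dtype, copy=False), parents=(x,))

    def bwd(g):
        if x.requires_grad:
            x._accumulate(g * activation_grad(name, x.data).astype(x.data.dtype))

    out._backward = bwd
    return out


def sigmoid_t(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-np.clip(x.data, -60, 60)))
    out = Tensor(s.astype(x.data.dtype, copy=False), parents=(x,))

    def bwd(g):
        if x.requires_grad:
            x._accumulate(g * s * (1.0 - s))

    out._backward = bwd
    return out


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """'Same' 2-D convolution (cross-correlation), stride 1, zero padding.

    x: (N, H, W, Cin); w: (kh, kw, Cin, Cout), kh/kw odd; b: (Cout,) or None.
    """
    xd, wd = x.data, w.data
    n, h, wdt, cin = xd.shape
    kh, kw, cin2, cout = wd.shape
    if cin != cin2:
        raise ValueError(f"channel mismatch: input {cin} vs kernel {cin2}")
    ph, pw = kh // 2, kw // 2
    xp = np.pad(xd, ((0, 0), (ph, ph), (pw, pw), (0, 0)))
    out_d = np.zeros((n, h, wdt, cout), dtype=xd.dtype)
    for di in range(kh):
        for dj in range(kw):
            out_d += np.tensordot(
                xp[:, di : di + h, dj : dj + wdt, :], wd[di, dj], axes=([3], [0])
            )
    if b is not None:
        out_d += b.data
    parents = (x, w) if b is None else (x, w, b)
    out = Tensor(out_d, parents=parents)

    def bwd(g):
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 1, 2)))
        if w.requires_grad:
            gw = np.empty_like(wd)
            for di in range(kh):
                for dj in range(kw):
                    gw[di, dj] = np.tensordot(
                        xp[:, di : di + h, dj : dj + wdt, :],
                        g,
                        axes=([0, 1, 2], [0, 1, 2]),
                    )
            w._accumulate(gw)
        if x.requires_grad:
            gxp = np.zeros_like(xp)
            for di in range(kh):
                for dj in range(kw):
                    gxp[:, di : di + h, dj : dj + wdt, :] += np.tensordot(
                        g, wd[di, dj], axes=([3], [1])
                    )
            gx = gxp[:, ph : ph + h, pw : pw + wdt, :] if (ph or pw) else gxp
            x._accumulate(gx)

    out._backward = bwd
    return out


def conv_transpose2x2(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """2x2 transposed convolution with stride 2 (exact 2x upsampling).

    x: (N, H, W, Cin); w: (2, 2, Cin, Cout) -> output (N, 2H, 2W, Cout).
    Non-overlapping: output block (2i+di, 2j+dj) = sum_c x[i,j,c] w[di,dj,c].
    """
    xd, wd = x.data, w.data
    n, h, wdt, cin = xd.shape
    # (N,H,W,Cin) x (2,2,Cin,Cout) -> (N,H,W,2,2,Cout)
    t = np.tensordot(xd, wd, axes=([3], [2]))
    out_d = np.ascontiguousarray(
        t.transpose(0, 1, 3, 2, 4, 5).reshape(n, 2 * h, 2 * wdt, wd.shape[3])
    )
    if b is not None:
        out_d += b.data
    parents = (x, w) if b is None else (x, w, b)
    out = Tensor(out_d, parents=parents)

    def bwd(g):
        gt = g.reshape(n, h, 2, wdt, 2, wd.shape[3]).transpose(0, 1, 3, 2, 4, 5)
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 1, 2)))
        if w.requires_grad:
            # (N,H,W,Cin) x (N,H,W,2,2,Cout) -> (Cin,2,2,Cout)
            gw = np.tensordot(xd, gt, axes=([0, 1, 2], [0, 1, 2]))
            w._accumulate(np.ascontiguousarray(gw.transpose(1, 2, 0, 3)))
        if x.requires_grad:
            gx = np.tensordot(gt, wd, axes=([3, 4, 5], [0, 1, 3]))
            x._accumulate(gx)

    out._backward = bwd
    return out


def maxpool2x2(x: Tensor) -> Tensor:
    """2x2 max pooling, stride 2; ties route their gradient to the first max."""
    xd = x.data
    n, h, w, c = xd.shape
    if h % 2 or w % 2:
        raise ValueError(f"spatial dims must be even for 2x2 pooling, got {h}x{w}")
    r = xd.reshape(n, h // 2, 2, w // 2, 2, c).transpose(0, 1, 3, 5, 2, 4)
    flat = r.reshape(n, h // 2, w // 2, c, 4)
    idx = flat.argmax(axis=-1)
    out_d = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
    out = Tensor(out_d, parents=(x,))

    def bwd(g):
        if x.requires_grad:
            gflat = np.zeros_like(flat)
            np.put_along_axis(gflat, idx[..., None], g[..., None], axis=-1)
            gx = (
                gflat.reshape(n, h // 2, w // 2, c, 2, 2)
                .transpose(0, 1, 4, 2, 5, 3)
                .reshape(n, h, w, c)
            )
            x._accumulate(np.ascontiguousarray(gx))

    out._backward = bwd
    return out


def concat(tensors: list[Tensor]) -> Tensor:
    """Concatenate along the channel (last) axis."""
    out = Tensor(np.concatenate([t.data for t in tensors], axis=-1), parents=tuple(tensors))
    sizes = [t.data.shape[-1] for t in tensors]

    def bwd(g):
        start = 0
        for t, s in zip(tensors, sizes):
            if t.requires_grad:
                t._accumulate(g[..., start : start + s])
            start += s

    out._backward = bwd
    return out


def dropout(x: Tensor, p: float, rng: np.random.Generator | None, training: bool) -> Tensor:
    """Inverted dropout: zero with probability p, rescale by 1/(1-p)."""
    if not training or p <= 0.0:
        return x
    if rng is None:
        raise ValueError("dropout in training mode needs an rng")
    mask = (rng.random(x.data.shape) >= p).astype(x.data.dtype) / (1.0 - p)
    out = Tensor(x.data * mask, parents=(x,))

    def bwd(g):
        if x.requires_grad:
            x._accumulate(g * mask)

    out._backward = bwd
    return out


def sharpen(x: Tensor) -> Tensor:
    """Depthwise convolution with the fixed sharpening kernel (no parameters).

    The kernel is point-symmetric, so the input gradient is the same depthwise
    convolution applied to the output gradient.
    """
    xd = x.data
    n, h, w, c = xd.shape
    if h < 3 or w < 3:
        raise ValueError(f"spatial dims must be >= 3, got {h}x{w}")
    k = SHARPEN_KERNEL.astype(xd.dtype)

    def dwconv(a):
        ap = np.pad(a, ((0, 0), (1, 1), (1, 1), (0, 0)))
        o = np.zeros_like(a)
        for di in range(3):
            for dj in range(3):
                if k[di, dj] != 0.0:
                    o += k[di, dj] * ap[:, di : di + h, dj : dj + w, :]
        return o

    out = Tensor(dwconv(xd), parents=(x,))

    def bwd(g):
        if x.requires_grad:
            x._accumulate(dwconv(g))

    out._backward = bwd
    return out


class Adam:
    """Adam optimizer over a list of parameter Tensors."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.9, eps=1e-7):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p.data -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(
                p.data.dtype
            )

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()
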