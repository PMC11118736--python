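"""Minimal reverse-mode automatic differentiation on numpy arrays.

This module is the numerical core under the recurrent localizer and the
UNet segmenter.  It implements exactly the operations those networks
need — broadcast arithmetic, sigmoid/tanh/relu, elementwise maximum,
channel concatenation, same-padded 2-D convolution (im2col), 2x2 max
pooling, nearest-neighbour upsampling, global pooling and a dense
layer — plus SGD with momentum as an exponentially weighted gradient
average (v = beta*v + (1-beta)*g; theta <- theta - lr*v).

Feature maps are (N, C, H, W) float arrays.  Gradients are accumulated
by a topological backward sweep from a scalar loss.
"""

from __future__ import annotations

from contextlib import contextmanager

import numpy as np

# Global working precision.  Exact contracts (oracle comparisons) use the
# float64 default; the training loops switch to float32, which halves
# memory traffic at no cost to convergence.
DTYPE = np.float64


@contextmanager
def precision(dtype):
    """Temporarily set the dtype used for all new tensors."""
    global DTYPE
    prev = DTYPE
    DTYPE = np.dtype(dtype).type
    try:
        yield
    finally:
        DTYPE = prev


_grad_enabled = True


@contextmanager
def no_grad():
    """Inference mode: ops record no graph, freeing backward buffers."""
    global _grad_enabled
    prev = _grad_enabled
    _grad_enabled = False
    try:
        yield
    finally:
        _grad_enabled = prev


def _node(data, parents, backward):
    if _grad_enabled:
        return Tensor(data, parents=parents, backward=backward)
    return Tensor(data)


class Tensor:
    """A numpy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad=False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad = None
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p in parents
        )
        self._parents = parents
        self._backward = backward

    # -- graph plumbing -------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    def _accum(self, g):
        if not self.requires_grad:
            return
        if self.grad is None:
            self.grad = np.array(g, dtype=DTYPE, copy=True)
        else:
            self.grad += g

    def zero_grad(self):
        self.grad = None

    # -- operator sugar -------------------------------------------------

    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __sub__(self, other):
        return add(self, mul(_wrap(other), -1.0))

    def __rsub__(self, other):
        return add(_wrap(other), mul(self, -1.0))

    def __truediv__(self, other):
        return div(self, other)

    def __neg__(self):
        return mul(self, -1.0)

    def item(self):
        return float(self.data)


def _wrap(x):
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=DTYPE))


def _unbroadcast(grad, shape):
    """Sum `grad` down to `shape` (reverse of numpy broadcasting)."""
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


# -- arithmetic ---------------------------------------------------------


def add(a, b):
    a, b = _wrap(a), _wrap(b)
    out_data = a.data + b.data

    def bw(g):
        a._accum(_unbroadcast(g, a.shape))
        b._accum(_unbroadcast(g, b.shape))

    return _node(out_data, (a, b), bw)


def mul(a, b):
    a, b = _wrap(a), _wrap(b)
    out_data = a.data * b.data

    def bw(g):
        a._accum(_unbroadcast(g * b.data, a.shape))
        b._accum(_unbroadcast(g * a.data, b.shape))

    return _node(out_data, (a, b), bw)


def div(a, b):
    a, b = _wrap(a), _wrap(b)
    out_data = a.data / b.data

    def bw(g):
        a._accum(_unbroadcast(g / b.data, a.shape))
        b._accum(_unbroadcast(-g * a.data / (b.data ** 2), b.shape))

    return _node(out_data, (a, b), bw)


def tsum(a, axis=None, keepdims=False):
    a = _wrap(a)
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def bw(g):
        if axis is None:
            a._accum(np.full_like(a.data, float(g)))
            return
        gg = g
        if not keepdims:
            gg = np.expand_dims(gg, axis)
        a._accum(np.broadcast_to(gg, a.shape))

    return _node(out_data, (a,), bw)


def tmean(a, axis=None, keepdims=False):
    a = _wrap(a)
    n = a.data.size if axis is None else np.prod(
        [a.shape[ax] for ax in (axis if isinstance(axis, tuple) else (axis,))]
    )
    return mul(tsum(a, axis=axis, keepdims=keepdims), 1.0 / float(n))


# -- activations --------------------------------------------------------


def sigmoid(a):
    a = _wrap(a)
    s = 1.0 / (1.0 + np.exp(-a.data))

    def bw(g):
        a._accum(g * s * (1.0 - s))

    return _node(s, (a,), bw)


def tanh(a):
    a = _wrap(a)
    t = np.tanh(a.data)

    def bw(g):
        a._accum(g * (1.0 - t * t))

    return _node(t, (a,), bw)


def relu(a):
    a = _wrap(a)
    mask = a.data > 0

    def bw(g):
        a._accum(g * mask)

    return _node(a.data * mask, (a,), bw)


def maximum(a, b):
    """Elementwise max; ties send the gradient to the first argument."""
    a, b = _wrap(a), _wrap(b)
    take_a = a.data >= b.data
    out_data = np.where(take_a, a.data, b.data)

    def bw(g):
        a._accum(_unbroadcast(g * take_a, a.shape))
        b._accum(_unbroadcast(g * (~take_a), b.shape))

    return _node(out_data, (a, b), bw)


def concat(tensors, axis=1):
    tensors = [_wrap(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t._accum(piece)

    return _node(out_data, tuple(tensors), bw)


def reshape(a, shape):
    a = _wrap(a)

    def bw(g):
        a._accum(g.reshape(a.shape))

    return _node(a.data.reshape(shape), (a,), bw)


def matmul(a, b):
    a, b = _wrap(a), _wrap(b)
    out_data = a.data @ b.data

    def bw(g):
        a._accum(g @ b.data.T)
        b._accum(a.data.T @ g)

    return _node(out_data, (a, b), bw)


# -- convolution (stride 1, same padding) -------------------------------


def _offsets(k, pad, h, w):
    """Valid (dest, src) row/col ranges per kernel offset, no padded copy."""
    for i in range(k):
        di = i - pad
        r0, r1 = max(0, -di), h - max(0, di)
        for j in range(k):
            dj = j - pad
            c0, c1 = max(0, -dj), w - max(0, dj)
            yield i, j, r0, r1, c0, c1, di, dj


def _im2col(x, k, pad):
    n, c, h, w = x.shape
    if k == 1:
        return x.reshape(n, c, h * w)
    cols = np.zeros((n, c, k, k, h, w), dtype=x.dtype)
    for i, j, r0, r1, c0, c1, di, dj in _offsets(k, pad, h, w):
        cols[:, :, i, j, r0:r1, c0:c1] = x[:, :, r0 + di : r1 + di, c0 + dj : c1 + dj]
    return cols.reshape(n, c * k * k, h * w)


def _col2im(dcols, xshape, k, pad):
    n, c, h, w = xshape
    if k == 1:
        return dcols.reshape(n, c, h, w)
    dx = np.zeros((n, c, h, w), dtype=dcols.dtype)
    d = dcols.reshape(n, c, k, k, h, w)
    for i, j, r0, r1, c0, c1, di, dj in _offsets(k, pad, h, w):
        dx[:, :, r0 + di : r1 + di, c0 + dj : c1 + dj] += d[:, :, i, j, r0:r1, c0:c1]
    return dx


def conv2d(x, w, b=None):
    """Same-padded stride-1 convolution.

    x: (N, Cin, H, W); w: (Cout, Cin, k, k) with k odd; b: (Cout,) or None.
    """
    x, w = _wrap(x), _wrap(w)
    n, cin, h, wd = x.shape
    cout, cin_w, k, k2 = w.shape
    if cin != cin_w or k != k2:
        raise ValueError(
            f"kernel {w.shape} incompatible with input {x.shape}"
        )
    if k % 2 == 0:
        raise ValueError("kernel size must be odd for same padding")
    pad = k // 2
    cols = _im2col(x.data, k, pad)  # (N, Cin*k*k, H*W)
    wmat = w.data.reshape(cout, cin * k * k)
    out = np.matmul(wmat[None], cols)
    parents = [x, w]
    if b is not None:
        b = _wrap(b)
        out += b.data[None, :, None]
        parents.append(b)
    out = out.reshape(n, cout, h, wd)

    def bw(g):
        gm = g.reshape(n, cout, h * wd)
        if b is not None:
            b._accum(gm.sum(axis=(0, 2)))
        if w.requires_grad:
            dw = np.matmul(gm, cols.transpose(0, 2, 1)).sum(axis=0)
            w._accum(dw.reshape(w.shape))
        if x.requires_grad or x._parents:
            dcols = np.matmul(wmat.T[None], gm)
            x._accum(_col2im(dcols, x.shape, k, pad))

    return _node(out, tuple(parents), bw)


def maxpool2d(x):
    """2x2 max pooling, stride 2; H and W must be even."""
    x = _wrap(x)
    n, c, h, w = x.shape
    if h % 2 or w % 2:
        raise ValueError(f"maxpool2d needs even spatial dims, got {h}x{w}")
    blocks = x.data.reshape(n, c, h // 2, 2, w // 2, 2)
    flat = blocks.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h // 2, w // 2, 4)
    idx = flat.argmax(axis=-1)
    out = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]

    def bw(g):
        dflat = np.zeros_like(flat)
        np.put_along_axis(dflat, idx[..., None], g[..., None], axis=-1)
        dx = (
            dflat.reshape(n, c, h // 2, w // 2, 2, 2)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(n, c, h, w)
        )
        x._accum(dx)

    return _node(out, (x,), bw)


def upsample2(x):
    """Nearest-neighbour 2x upsampling."""
    x = _wrap(x)
    n, c, h, w = x.shape
    out = np.repeat(np.repeat(x.data, 2, axis=2), 2, axis=3)

    def bw(g):
        dx = g.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5))
        x._accum(dx)

    return _node(out, (x,), bw)


def global_avg_pool(x):
    """(N, C, H, W) -> (N, C)."""
    x = _wrap(x)
    n, c, h, w = x.shape
    out = x.data.mean(axis=(2, 3))

    def bw(g):
        x._accum(np.broadcast_to(g[:, :, None, None], x.shape) / (h * w))

    return _node(out, (x,), bw)


def softmax_cross_entropy(logits, onehot, sample_weights=None):
    """Mean cross-entropy over the batch; fused softmax backward.

    logits: (N, K) Tensor; onehot: (N, K) array; sample_weights: (N,) array
    multiplying each sample's loss term (None = 1).
    """
    logits = _wrap(logits)
    y = np.asarray(onehot, dtype=DTYPE)
    n = logits.shape[0]
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    ez = np.exp(z)
    p = ez / ez.sum(axis=1, keepdims=True)
    ll = -(y * np.log(np.clip(p, 1e-12, None))).sum(axis=1)
    wts = np.ones(n) if sample_weights is None else np.asarray(sample_weights, dtype=DTYPE)
    loss = float((ll * wts).mean())

    def bw(g):
        dl = (p - y) * wts[:, None] / n
        logits._accum(float(g) * dl)

    return _node(loss, (logits,), bw)


# -- parameters and optimisation ---------------------------------------


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def he_init(rng, shape, fan_in):
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Module:
    """Base class: recursively collects Parameters for the optimiser."""

    def parameters(self):
        params = []
        for v in vars(self).values():
            if isinstance(v, Parameter):
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Parameter):
                        params.append(item)
                    elif isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self):
        return {i: p.data.copy() for i, p in enumerate(self.parameters())}

    def load_state_dict(self, state):
        for i, p in enumerate(self.parameters()):
            p.data[...] = state[i]


class Conv2dLayer(Module):
    def __init__(self, rng, in_ch, out_ch, k):
        self.weight = Parameter(he_init(rng, (out_ch, in_ch, k, k), in_ch * k * k))
        self.bias = Parameter(np.zeros(out_ch))

    def __call__(self, x):
        return conv2d(x, self.weight, self.bias)


class LinearLayer(Module):
    def __init__(self, rng, in_f, out_f):
        self.weight = Parameter(he_init(rng, (in_f, out_f), in_f))
        self.bias = Parameter(np.zeros(out_f))

    def __call__(self, x):
        return add(matmul(x, self.weight), self.bias)


class SGDMomentum:
    """theta <- theta - lr*v with v the exponentially weighted gradient
    average v = beta*v + (1-beta)*grad (beta defaults to 0.9)."""

    def __init__(self, params, lr=0.01, beta=0.9):
        self.params = list(params)
        self.lr = lr
        self.beta = beta
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        for p, v in zip(self.params, self.v):
            if p.grad is None:
                continue
            v *= self.beta
            v += (1.0 - self.beta) * p.grad
            p.data -= self.lr * v

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()
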