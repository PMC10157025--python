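"""Minimal reverse-mode autodiff on NumPy arrays for the desk-scale nets.

Just enough machinery for compact encoder-decoder models on CPU: 3x3/1x1
convolutions (im2col), ReLU, 2x2 max pooling, nearest 2x upsampling,
channel concatenation, dense layers, global average pooling, and an Adam
optimizer.  Loss gradients are supplied analytically at the output layer
and propagated with a single topological traversal, so multiple heads can
be trained jointly.  Everything is deterministic given the seed.
"""

from __future__ import annotations

import numpy as np


class Tensor:
    """Array node of the computation tape."""

    __slots__ = ("data", "grad", "parents", "backward_fn", "requires_grad")

    def __init__(self, data, parents=(), backward_fn=None, requires_grad=False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.parents = parents
        self.backward_fn = backward_fn
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)

    @property
    def shape(self):
        return self.data.shape

    def accumulate(self, g):
        self.grad = g if self.grad is None else self.grad + g


def parameter(data) -> Tensor:
    return Tensor(data, requires_grad=True)


def backward(outputs: list[tuple[Tensor, np.ndarray]]) -> None:
    """Propagate seed gradients from several output tensors at once."""
    topo: list[Tensor] = []
    seen: set[int] = set()

    def visit(t: Tensor):
        if id(t) in seen or not t.requires_grad:
            return
        seen.add(id(t))
        for p in t.parents:
            visit(p)
        topo.append(t)

    for t, g in outputs:
        visit(t)
        t.accumulate(np.asarray(g, dtype=np.float64))
    for t in reversed(topo):
        if t.backward_fn is not None and t.grad is not None:
            t.backward_fn(t.grad)


def zero_grad(params: list[Tensor]) -> None:
    for p in params:
        p.grad = None


# ---------------------------------------------------------------------------
# ops (inputs NCHW)


def _im2col(x: np.ndarray, k: int, pad: int) -> np.ndarray:
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    # (n, c, h, w, k, k) -> (n, h, w, c*k*k)
    return win.transpose(0, 2, 3, 1, 4, 5).reshape(n, h, w, c * k * k)


def _col2im(dcols: np.ndarray, x_shape, k: int, pad: int) -> np.ndarray:
    n, c, h, w = x_shape
    dxp = np.zeros((n, c, h + 2 * pad, w + 2 * pad))
    d = dcols.reshape(n, h, w, c, k, k).transpose(0, 3, 1, 2, 4, 5)
    for di in range(k):
        for dj in range(k):
            dxp[:, :, di : di + h, dj : dj + w] += d[:, :, :, :, di, dj]
    return dxp[:, :, pad : pad + h, pad : pad + w] if pad else dxp


def conv2d(x: Tensor, weight: Tensor, bias: Tensor, k: int, pad: int) -> Tensor:
    """Same-size convolution; weight (c_out, c_in*k*k), bias (c_out,)."""
    n, c, h, w = x.shape
    cols = _im2col(x.data, k, pad)  # (n, h, w, c*k*k)
    out = cols @ weight.data.T + bias.data  # (n, h, w, c_out)
    t = Tensor(out.transpose(0, 3, 1, 2), parents=(x, weight, bias))

    def bwd(g):
        gt = g.transpose(0, 2, 3, 1)  # (n, h, w, c_out)
        weight.accumulate(
            gt.reshape(-1, gt.shape[-1]).T @ cols.reshape(-1, cols.shape[-1])
        )
        bias.accumulate(gt.sum(axis=(0, 1, 2)))
        if x.requires_grad:
            x.accumulate(_col2im(gt @ weight.data, x.shape, k, pad))

    t.backward_fn = bwd
    return t


def relu(x: Tensor) -> Tensor:
    pos = x.data > 0
    t = Tensor(x.data * pos, parents=(x,))
    t.backward_fn = lambda g: x.accumulate(g * pos)
    return t


def maxpool2(x: Tensor) -> Tensor:
    n, c, h, w = x.shape
    r = x.data.reshape(n, c, h // 2, 2, w // 2, 2)
    out = r.max(axis=(3, 5))
    hits = r == out[:, :, :, None, :, None]
    share = hits / hits.sum(axis=(3, 5), keepdims=True)  # ties split evenly
    t = Tensor(out, parents=(x,))

    def bwd(g):
        x.accumulate((share * g[:, :, :, None, :, None]).reshape(n, c, h, w))

    t.backward_fn = bwd
    return t


def upsample2(x: Tensor) -> Tensor:
    t = Tensor(np.repeat(np.repeat(x.data, 2, axis=2), 2, axis=3), parents=(x,))

    def bwd(g):
        n, c, h2, w2 = g.shape
        x.accumulate(g.reshape(n, c, h2 // 2, 2, w2 // 2, 2).sum(axis=(3, 5)))

    t.backward_fn = bwd
    return t


def concat(a: Tensor, b: Tensor) -> Tensor:
    ca = a.shape[1]
    t = Tensor(np.concatenate([a.data, b.data], axis=1), parents=(a, b))

    def bwd(g):
        a.accumulate(g[:, :ca])
        b.accumulate(g[:, ca:])

    t.backward_fn = bwd
    return t


def global_avg_pool(x: Tensor) -> Tensor:
    n, c, h, w = x.shape
    t = Tensor(x.data.mean(axis=(2, 3)), parents=(x,))

    def bwd(g):
        x.accumulate(np.broadcast_to(g[:, :, None, None] / (h * w), x.shape).copy())

    t.backward_fn = bwd
    return t


def dense(x: Tensor, weight: Tensor, bias: Tensor) -> Tensor:
    t = Tensor(x.data @ weight.data.T + bias.data, parents=(x, weight, bias))

    def bwd(g):
        weight.accumulate(g.T @ x.data)
        bias.accumulate(g.sum(axis=0))
        x.accumulate(g @ weight.data)

    t.backward_fn = bwd
    return t


# ---------------------------------------------------------------------------
# losses (value + analytic gradient w.r.t. logits / predictions)


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(logits: np.ndarray, target: np.ndarray):
    """Mean binary cross-entropy; returns (loss, dloss/dlogits)."""
    z, y = logits, target
    loss = np.mean(np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z))))
    grad = (sigmoid(z) - y) / z.size
    return float(loss), grad


def soft_dice_loss(logits: np.ndarray, target: np.ndarray, smooth: float = 1.0):
    """1 - soft Dice on sigmoid probabilities, per batch; (loss, grad)."""
    p = sigmoid(logits)
    axes = tuple(range(1, logits.ndim))
    inter = (p * target).sum(axis=axes)
    tot = p.sum(axis=axes) + target.sum(axis=axes)
    dice = (2 * inter + smooth) / (tot + smooth)
    loss = float(np.mean(1.0 - dice))
    # d dice / d p = (2*t*(tot+smooth) - (2*inter+smooth)) / (tot+smooth)^2
    sh = (-1,) + (1,) * (logits.ndim - 1)
    ddice_dp = (
        2 * target * (tot + smooth).reshape(sh) - (2 * inter + smooth).reshape(sh)
    ) / ((tot + smooth) ** 2).reshape(sh)
    grad = -(ddice_dp) * p * (1 - p) / logits.shape[0]
    return loss, grad


def smooth_l1_loss(pred: np.ndarray, target: np.ndarray, beta: float = 0.1):
    """Huber-style box regression loss; (loss, grad)."""
    d = pred - target
    ad = np.abs(d)
    quad = ad < beta
    loss = float(np.mean(np.where(quad, 0.5 * d**2 / beta, ad - 0.5 * beta)))
    grad = np.where(quad, d / beta, np.sign(d)) / d.size
    return loss, grad


# ---------------------------------------------------------------------------
# optimizer


class Adam:
    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * p.grad
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * p.grad**2
            mh = self.m[i] / (1 - self.b1**self.t)
            vh = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mh / (np.sqrt(vh) + self.eps)


def he_conv(rng: np.random.Generator, c_out: int, c_in: int, k: int) -> Tensor:
    fan_in = c_in * k * k
    return parameter(rng.standard_normal((c_out, fan_in)) * np.sqrt(2.0 / fan_in))


def he_dense(rng: np.random.Generator, n_out: int, n_in: int) -> Tensor:
    return parameter(rng.standard_normal((n_out, n_in)) * np.sqrt(2.0 / n_in))
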