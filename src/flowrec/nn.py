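"""Compact reverse-mode automatic differentiation on NumPy arrays.

This is the numerical core behind the neural architectures: a ``Tensor``
that records the operations applied to it and replays them backwards to
accumulate gradients, plus the handful of layers the recommendation models
need (embeddings, dense products, layer normalisation, masked softmax
attention, GRU cells, valid 2-D convolution, max pooling, dropout) and an
Adam optimiser.

Everything is float64 and purely NumPy-based, so a forward pass and a full
training run are bit-reproducible given a seed.  The engine is validated by
central-difference gradient checks in the test suite.

Backward closures receive the output gradient as an argument and never
reference their own output tensor, so a discarded graph frees by reference
counting alone — a training loop creates no garbage cycles.
"""

from __future__ import annotations

import math
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "parameter",
    "constant",
    "add",
    "mul",
    "matmul",
    "relu",
    "sigmoid",
    "tanh",
    "reshape",
    "transpose",
    "tensor_slice",
    "stack",
    "embedding",
    "layer_norm",
    "masked_softmax",
    "dropout",
    "conv2d_valid",
    "maxpool2d",
    "bce_with_logits",
    "gru_layer",
    "Adam",
    "glorot_uniform",
]


class Tensor:
    """A NumPy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward: Callable[[np.ndarray], None] | None = None
        self._parents: tuple[Tensor, ...] = ()

    # -- graph plumbing ---------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            # own a dense copy: g may be a view of another node's gradient
            self.grad = np.array(g, dtype=np.float64)
            if self.grad.shape != self.data.shape:  # scalar broadcast edge case
                self.grad = np.broadcast_to(self.grad, self.data.shape).copy()
        else:
            self.grad += g

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self) -> None:
        """Reverse-mode sweep seeding d(self)/d(self) = 1."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        # iterative DFS post-order (graphs from GRU unrolling get deep)
        visiting: list[tuple[Tensor, bool]] = [(self, False)]
        while visiting:
            node, processed = visiting.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            visiting.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    visiting.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)
                # drop the closure and non-leaf gradient promptly so the
                # spent graph frees as soon as the loss goes out of scope
                node._backward = None
                node._parents = ()
                if node is not self:
                    node.grad = None

    # -- operator sugar ---------------------------------------------------

    def __add__(self, other):
        return add(self, _as_tensor(other))

    def __radd__(self, other):
        return add(_as_tensor(other), self)

    def __mul__(self, other):
        return mul(self, _as_tensor(other))

    def __rmul__(self, other):
        return mul(_as_tensor(other), self)

    def __sub__(self, other):
        other = _as_tensor(other)
        return add(self, mul(other, constant(-1.0)))

    def __matmul__(self, other):
        return matmul(self, _as_tensor(other))

    def __getitem__(self, idx):
        return tensor_slice(self, idx)

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"


def parameter(data) -> Tensor:
    return Tensor(data, requires_grad=True)


def constant(data) -> Tensor:
    return Tensor(data, requires_grad=False)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _node(data, parents: Sequence[Tensor], backward) -> Tensor:
    out = Tensor(data)
    out.requires_grad = any(p.requires_grad for p in parents)
    if out.requires_grad:
        out._parents = tuple(parents)
        out._backward = backward
    return out


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


# -- arithmetic -----------------------------------------------------------


def add(a: Tensor, b: Tensor) -> Tensor:
    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g, b.data.shape))

    return _node(a.data + b.data, (a, b), backward)


def mul(a: Tensor, b: Tensor) -> Tensor:
    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * a.data, b.data.shape))

    return _node(a.data * b.data, (a, b), backward)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    """Batched matrix product, broadcasting over leading axes like np.matmul."""

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g @ np.swapaxes(b.data, -1, -2), a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(np.swapaxes(a.data, -1, -2) @ g, b.data.shape))

    return _node(a.data @ b.data, (a, b), backward)


# -- activations ----------------------------------------------------------


def relu(x: Tensor) -> Tensor:
    def backward(g):
        if x.requires_grad:
            x._accumulate(g * (x.data > 0.0))

    return _node(np.maximum(x.data, 0.0), (x,), backward)


def sigmoid(x: Tensor) -> Tensor:
    out_data = 1.0 / (1.0 + np.exp(-np.clip(x.data, -500, 500)))

    def backward(g):
        if x.requires_grad:
            x._accumulate(g * out_data * (1.0 - out_data))

    return _node(out_data, (x,), backward)


def tanh(x: Tensor) -> Tensor:
    out_data = np.tanh(x.data)

    def backward(g):
        if x.requires_grad:
            x._accumulate(g * (1.0 - out_data * out_data))

    return _node(out_data, (x,), backward)


# -- shape ops ------------------------------------------------------------


def reshape(x: Tensor, shape) -> Tensor:
    def backward(g):
        if x.requires_grad:
            x._accumulate(g.reshape(x.data.shape))

    return _node(x.data.reshape(shape), (x,), backward)


def transpose(x: Tensor, axes) -> Tensor:
    inv = np.argsort(axes)

    def backward(g):
        if x.requires_grad:
            x._accumulate(np.transpose(g, inv))

    return _node(np.transpose(x.data, axes), (x,), backward)


def tensor_slice(x: Tensor, idx) -> Tensor:
    """Basic (non-fancy) indexing with gradient scatter-add."""

    def backward(g):
        if x.requires_grad:
            full = np.zeros_like(x.data)
            full[idx] = g
            x._accumulate(full)

    return _node(x.data[idx], (x,), backward)


def stack(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    tensors = tuple(tensors)

    def backward(g):
        for t, piece in zip(tensors, np.moveaxis(g, axis, 0)):
            if t.requires_grad:
                t._accumulate(piece)

    return _node(np.stack([t.data for t in tensors], axis=axis), tensors, backward)


# -- layers ---------------------------------------------------------------


def embedding(weight: Tensor, ids: np.ndarray) -> Tensor:
    """Row lookup ``weight[ids]``; gradient is a scatter-add over rows."""
    ids = np.asarray(ids)

    def backward(g):
        if weight.requires_grad:
            full = np.zeros_like(weight.data)
            np.add.at(full, ids, g)
            weight._accumulate(full)

    return _node(weight.data[ids], (weight,), backward)


def layer_norm(x: Tensor, gain: Tensor, bias: Tensor, eps: float = 1e-6) -> Tensor:
    """Layer normalisation over the last axis with learned gain and bias."""
    mu = x.data.mean(axis=-1, keepdims=True)
    var = x.data.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv

    def backward(g):
        if gain.requires_grad:
            gain._accumulate(_unbroadcast(g * xhat, gain.data.shape))
        if bias.requires_grad:
            bias._accumulate(_unbroadcast(g, bias.data.shape))
        if x.requires_grad:
            dxhat = g * gain.data
            m1 = dxhat.mean(axis=-1, keepdims=True)
            m2 = (dxhat * xhat).mean(axis=-1, keepdims=True)
            x._accumulate(inv * (dxhat - m1 - xhat * m2))

    return _node(xhat * gain.data + bias.data, (x, gain, bias), backward)


def masked_softmax(x: Tensor, mask: np.ndarray | None = None) -> Tensor:
    """Softmax over the last axis; positions where ``mask`` is False get zero
    probability.  ``mask`` broadcasts against ``x``; a row with no allowed
    position falls back to a full softmax so outputs stay finite."""
    z = x.data
    if mask is not None:
        mask = np.broadcast_to(np.asarray(mask, dtype=bool), z.shape)
        # rows with nothing unmasked: allow everything (degenerate all-pad input)
        dead = ~mask.any(axis=-1, keepdims=True)
        mask = mask | dead
        z = np.where(mask, z, -np.inf)
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=-1, keepdims=True)

    def backward(g):
        if x.requires_grad:
            dot = (g * p).sum(axis=-1, keepdims=True)
            x._accumulate(p * (g - dot))

    return _node(p, (x,), backward)


def dropout(x: Tensor, rate: float, rng: np.random.Generator | None) -> Tensor:
    """Inverted dropout; identity when ``rng`` is None (inference) or rate 0."""
    if rng is None or rate <= 0.0:
        return x
    keep = (rng.random(x.data.shape) >= rate) / (1.0 - rate)
    return mul(x, constant(keep))


def conv2d_valid(x: Tensor, kernel: Tensor, bias: Tensor) -> Tensor:
    """Valid 2-D convolution (cross-correlation), NHWC layout.

    x: (B, H, W, C); kernel: (kh, kw, C, F); bias: (F,).
    """
    kh, kw, cin, f = kernel.data.shape
    windows = np.lib.stride_tricks.sliding_window_view(x.data, (kh, kw), axis=(1, 2))
    # windows: (B, H', W', C, kh, kw)
    out_data = np.einsum("bhwcuv,uvcf->bhwf", windows, kernel.data) + bias.data

    def backward(g):
        if bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 1, 2)))
        if kernel.requires_grad:
            kernel._accumulate(np.einsum("bhwcuv,bhwf->uvcf", windows, g))
        if x.requires_grad:
            gx = np.zeros_like(x.data)
            hp, wp = g.shape[1], g.shape[2]
            for u in range(kh):
                for v in range(kw):
                    # (B,H',W',F) @ (F,C) accumulated at offset (u,v)
                    gx[:, u : u + hp, v : v + wp, :] += g @ kernel.data[u, v].T
            x._accumulate(gx)

    return _node(out_data, (x, kernel, bias), backward)


def maxpool2d(x: Tensor, pool: tuple[int, int] = (2, 2)) -> Tensor:
    """Non-overlapping max pooling with floor division of spatial dims (NHWC)."""
    ph, pw = pool
    b, h, w, c = x.data.shape
    h2, w2 = h // ph, w // pw
    cropped = x.data[:, : h2 * ph, : w2 * pw, :]
    tiles = (
        cropped.reshape(b, h2, ph, w2, pw, c)
        .transpose(0, 1, 3, 5, 2, 4)
        .reshape(b, h2, w2, c, ph * pw)
    )
    arg = tiles.argmax(axis=-1)
    out_data = np.take_along_axis(tiles, arg[..., None], axis=-1)[..., 0]

    def backward(g):
        if x.requires_grad:
            gt = np.zeros_like(tiles)
            np.put_along_axis(gt, arg[..., None], g[..., None], axis=-1)
            gc = (
                gt.reshape(b, h2, w2, c, ph, pw)
                .transpose(0, 1, 4, 2, 5, 3)
                .reshape(b, h2 * ph, w2 * pw, c)
            )
            gx = np.zeros_like(x.data)
            gx[:, : h2 * ph, : w2 * pw, :] = gc
            x._accumulate(gx)

    return _node(out_data, (x,), backward)


def bce_with_logits(
    logits: Tensor, targets: np.ndarray, column_mask: np.ndarray | None = None
) -> Tensor:
    """Mean element-wise binary cross-entropy on logits (numerically stable).

    ``column_mask`` (bool, broadcastable) excludes label columns — e.g. an
    unused padding slot — from both the mean and the gradient.
    """
    z = logits.data
    y = np.asarray(targets, dtype=np.float64)
    loss = np.maximum(z, 0.0) - z * y + np.log1p(np.exp(-np.abs(z)))
    if column_mask is not None:
        m = np.broadcast_to(np.asarray(column_mask, dtype=bool), loss.shape)
        n = m.sum()
        total = float(loss[m].sum() / n)
    else:
        m = None
        n = loss.size
        total = float(loss.mean())

    def backward(g):
        if logits.requires_grad:
            p = 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))
            gz = (p - y) / n
            if m is not None:
                gz = np.where(m, gz, 0.0)
            logits._accumulate(g * gz)

    return _node(total, (logits,), backward)


def gru_layer(
    x_seq: Tensor,
    w: Tensor,
    u: Tensor,
    b: Tensor,
    return_sequences: bool,
) -> Tensor:
    """Gated recurrent unit layer, reset-after gate convention.

    x_seq: (B, T, D); w: (D, 3U) input kernel; u: (U, 3U) recurrent kernel;
    b: (2, 3U) — row 0 input bias, row 1 recurrent bias.  Gate order z, r, h.
    Returns (B, T, U) when ``return_sequences`` else the last state (B, U).
    """
    bsz, t_len, _ = x_seq.data.shape
    units = u.data.shape[0]
    b_in = b[0]
    b_rec = b[1]
    h = constant(np.zeros((bsz, units)))
    states: list[Tensor] = []
    for t in range(t_len):
        xt = x_seq[:, t, :]
        xp = add(matmul(xt, w), b_in)  # (B, 3U)
        hp = add(matmul(h, u), b_rec)  # (B, 3U)
        z = sigmoid(add(xp[:, :units], hp[:, :units]))
        r = sigmoid(add(xp[:, units : 2 * units], hp[:, units : 2 * units]))
        hh = tanh(add(xp[:, 2 * units :], mul(r, hp[:, 2 * units :])))
        one_minus_z = add(constant(1.0), mul(z, constant(-1.0)))
        h = add(mul(z, h), mul(one_minus_z, hh))
        if return_sequences:
            states.append(h)
    if return_sequences:
        return stack(states, axis=1)
    return h


# -- initialisation & optimiser -------------------------------------------


def glorot_uniform(rng: np.random.Generator, shape, fan_in=None, fan_out=None):
    if fan_in is None:
        fan_in = shape[0] if len(shape) >= 2 else shape[0]
    if fan_out is None:
        fan_out = shape[-1]
    limit = math.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Adam:
    """Adam optimiser (Kingma & Ba) with bias correction."""

    def __init__(self, params: Sequence[Tensor], lr: float = 0.001,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7):
        self.params = list(params)
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        lr_t = self.lr * math.sqrt(1 - b2 ** self.t) / (1 - b1 ** self.t)
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.data -= lr_t * m / (np.sqrt(v) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
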