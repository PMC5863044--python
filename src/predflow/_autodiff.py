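"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations the convolutional-LSTM predictive network
needs: 3x3 same-padding convolution, 2x2 max pooling, nearest-neighbour
upsampling, elementwise nonlinearities, channel concatenation/slicing and
a mean-squared-error loss.  Tensors are single images in CHW layout (no
batch axis); the network processes one frame per time step.

A module-level ``no_grad`` context disables graph construction for
inference-only rollouts.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Sequence

import numpy as np

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable graph building inside the context (inference mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


class Tensor:
    """A node in the computation graph: a float32 array plus backward rule."""

    __slots__ = ("data", "grad", "parents", "_backward", "requires_grad", "name")

    def __init__(
        self,
        data: np.ndarray,
        parents: Sequence["Tensor"] = (),
        backward: Callable[[np.ndarray], None] | None = None,
        requires_grad: bool = False,
        name: str = "",
    ):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.parents = tuple(parents) if _GRAD_ENABLED else ()
        self._backward = backward if _GRAD_ENABLED else None
        self.requires_grad = requires_grad
        self.name = name

    @property
    def shape(self):
        return self.data.shape

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor through the graph."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node.parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


def parameter(data: np.ndarray, name: str = "") -> Tensor:
    return Tensor(data, requires_grad=True, name=name)


# ---------------------------------------------------------------- elementwise


def add(a: Tensor, b: Tensor) -> Tensor:
    out = a.data + b.data

    def backward(g):
        a._accumulate(g)
        b._accumulate(g)

    return Tensor(out, (a, b), backward)


def sub(a: Tensor, b: Tensor) -> Tensor:
    out = a.data - b.data

    def backward(g):
        a._accumulate(g)
        b._accumulate(-g)

    return Tensor(out, (a, b), backward)


def mul(a: Tensor, b: Tensor) -> Tensor:
    out = a.data * b.data

    def backward(g):
        a._accumulate(g * b.data)
        b._accumulate(g * a.data)

    return Tensor(out, (a, b), backward)


def sigmoid(x: Tensor) -> Tensor:
    out = 1.0 / (1.0 + np.exp(-np.clip(x.data, -30, 30)))

    def backward(g):
        x._accumulate(g * out * (1.0 - out))

    return Tensor(out, (x,), backward)


def tanh(x: Tensor) -> Tensor:
    out = np.tanh(x.data)

    def backward(g):
        x._accumulate(g * (1.0 - out * out))

    return Tensor(out, (x,), backward)


def relu(x: Tensor) -> Tensor:
    out = np.maximum(x.data, 0.0)

    def backward(g):
        x._accumulate(g * (x.data > 0))

    return Tensor(out, (x,), backward)


def satlu(x: Tensor, cap: float) -> Tensor:
    """Saturating rectifier: clip(x, 0, cap).  Used for pixel predictions."""
    out = np.clip(x.data, 0.0, cap)

    def backward(g):
        x._accumulate(g * ((x.data > 0) & (x.data < cap)))

    return Tensor(out, (x,), backward)


# ------------------------------------------------------------- shape-changing


def concat_channels(tensors: Sequence[Tensor]) -> Tensor:
    out = np.concatenate([t.data for t in tensors], axis=0)
    sizes = [t.data.shape[0] for t in tensors]

    def backward(g):
        ofs = 0
        for t, s in zip(tensors, sizes):
            t._accumulate(g[ofs : ofs + s])
            ofs += s

    return Tensor(out, tuple(tensors), backward)


def slice_channels(x: Tensor, start: int, stop: int) -> Tensor:
    out = x.data[start:stop]

    def backward(g):
        full = np.zeros_like(x.data)
        full[start:stop] = g
        x._accumulate(full)

    return Tensor(out, (x,), backward)


def maxpool2(x: Tensor) -> Tensor:
    """2x2 max pooling, stride 2.  Spatial dims must be even."""
    c, h, w = x.data.shape
    xr = x.data.reshape(c, h // 2, 2, w // 2, 2).transpose(0, 1, 3, 2, 4)
    xr = xr.reshape(c, h // 2, w // 2, 4)
    idx = xr.argmax(axis=3)
    out = np.take_along_axis(xr, idx[..., None], axis=3)[..., 0]

    def backward(g):
        gr = np.zeros((c, h // 2, w // 2, 4), dtype=np.float32)
        np.put_along_axis(gr, idx[..., None], g[..., None], axis=3)
        gx = gr.reshape(c, h // 2, w // 2, 2, 2).transpose(0, 1, 3, 2, 4).reshape(c, h, w)
        x._accumulate(gx)

    return Tensor(out, (x,), backward)


def upsample2(x: Tensor) -> Tensor:
    """Nearest-neighbour 2x spatial upsampling."""
    out = np.repeat(np.repeat(x.data, 2, axis=1), 2, axis=2)

    def backward(g):
        c, h, w = x.data.shape
        gx = g.reshape(c, h, 2, w, 2).sum(axis=(2, 4))
        x._accumulate(gx)

    return Tensor(out, (x,), backward)


def conv2d(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Same-padding stride-1 convolution of a CHW image.

    ``w`` has shape (out_ch, in_ch, kh, kw) with odd kh == kw; ``b`` (out_ch,).
    """
    cin, h, width = x.data.shape
    cout, cin_w, kh, kw = w.data.shape
    assert cin == cin_w, f"channel mismatch {cin} vs {cin_w}"
    ph, pw = kh // 2, kw // 2
    xp = np.pad(x.data, ((0, 0), (ph, ph), (pw, pw)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(1, 2))
    cols = win.transpose(1, 2, 0, 3, 4).reshape(h * width, cin * kh * kw)
    wmat = w.data.reshape(cout, cin * kh * kw)
    out = (cols @ wmat.T + b.data).T.reshape(cout, h, width)

    def backward(g):
        g2 = g.reshape(cout, h * width).T  # (HW, O)
        w._accumulate((g2.T @ cols).reshape(w.data.shape))
        b._accumulate(g.sum(axis=(1, 2)))
        gcols = (g2 @ wmat).reshape(h, width, cin, kh, kw)
        gxp = np.zeros_like(xp)
        for i in range(kh):
            for j in range(kw):
                gxp[:, i : i + h, j : j + width] += gcols[:, :, :, i, j].transpose(2, 0, 1)
        x._accumulate(gxp[:, ph : ph + h, pw : pw + width])

    return Tensor(out, (x, w, b), backward)


def mse(pred: Tensor, target: np.ndarray) -> Tensor:
    """Mean squared error against a constant target array."""
    diff = pred.data - np.asarray(target, dtype=np.float32)
    out = np.array((diff * diff).mean(), dtype=np.float32)
    scale = 2.0 / diff.size

    def backward(g):
        pred._accumulate(g * scale * diff)

    return Tensor(out, (pred,), backward)


class Adam:
    """Adam optimizer with the conventional defaults (lr 1e-3, 0.9/0.999)."""

    def __init__(self, params: Sequence[Tensor], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self) -> None:
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
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
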