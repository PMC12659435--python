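"""A small reverse-mode automatic differentiation engine on NumPy arrays.

The package's two neural components (the recurrent SMILES autoencoder and
the attention/CNN spectral encoder) are desk-scale models trained on CPU,
so a compact tape-based engine is sufficient: a :class:`Tensor` wraps a
float32 ``numpy`` array, records its parents and a backward closure, and
``backward()`` walks the tape in reverse topological order.

Besides generic elementwise/matmul ops, a few fused operations carry
hand-derived gradients where per-op overhead would dominate in Python:
the GRU cell (:func:`gru_step`), embedding lookup, masked softmax
cross-entropy, softmax, layer normalization and a row-wise convolution.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

DTYPE = np.float32


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum a gradient over the axes that broadcasting expanded."""
    if grad.shape == shape:
        return grad
    # sum leading extra axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev",
                 "sparse", "sparse_grads")

    def __init__(self, data, requires_grad: bool = False, _prev: tuple = ()):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = requires_grad
        self._backward = None
        self._prev = _prev
        # large embedding tables opt in to sparse (row-indexed) gradients
        self.sparse = False
        self.sparse_grads: list = []

    # -- bookkeeping -------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    def zero_grad(self) -> None:
        self.grad = None
        self.sparse_grads = []

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        visited: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for parent in node._prev:
                if id(parent) not in visited:
                    stack.append((parent, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def item(self) -> float:
        return float(self.data)

    # -- arithmetic --------------------------------------------------------
    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data,
                     requires_grad=self.requires_grad or other.requires_grad,
                     _prev=(self, other))

        def _bw(g):
            if self.requires_grad or self._prev:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad or other._prev:
                other._accumulate(_unbroadcast(g, other.data.shape))

        out._backward = _bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, requires_grad=self.requires_grad, _prev=(self,))
        out._backward = lambda g: self._accumulate(-g)
        return out

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data,
                     requires_grad=self.requires_grad or other.requires_grad,
                     _prev=(self, other))

        def _bw(g):
            if self.requires_grad or self._prev:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad or other._prev:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        out._backward = _bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return self._lift(other) * self ** -1.0

    def __pow__(self, exponent: float):
        out = Tensor(self.data ** exponent, requires_grad=self.requires_grad,
                     _prev=(self,))
        out._backward = lambda g: self._accumulate(
            g * exponent * self.data ** (exponent - 1.0))
        return out

    def __matmul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data @ other.data,
                     requires_grad=self.requires_grad or other.requires_grad,
                     _prev=(self, other))

        def _bw(g):
            if self.requires_grad or self._prev:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accumulate(_unbroadcast(ga, self.data.shape))
            if other.requires_grad or other._prev:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accumulate(_unbroadcast(gb, other.data.shape))

        out._backward = _bw
        return out

    # -- elementwise nonlinearities ---------------------------------------
    def tanh(self):
        y = np.tanh(self.data)
        out = Tensor(y, requires_grad=self.requires_grad, _prev=(self,))
        out._backward = lambda g: self._accumulate(g * (1.0 - y * y))
        return out

    def sigmoid(self):
        y = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(y, requires_grad=self.requires_grad, _prev=(self,))
        out._backward = lambda g: self._accumulate(g * y * (1.0 - y))
        return out

    def relu(self):
        y = np.maximum(self.data, 0.0)
        out = Tensor(y, requires_grad=self.requires_grad, _prev=(self,))
        out._backward = lambda g: self._accumulate(g * (self.data > 0))
        return out

    def exp(self):
        y = np.exp(self.data)
        out = Tensor(y, requires_grad=self.requires_grad, _prev=(self,))
        out._backward = lambda g: self._accumulate(g * y)
        return out

    def log(self):
        out = Tensor(np.log(self.data), requires_grad=self.requires_grad, _prev=(self,))
        out._backward = lambda g: self._accumulate(g / self.data)
        return out

    # -- reductions & shape ------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                     requires_grad=self.requires_grad, _prev=(self,))

        def _bw(g):
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.data.shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accumulate(np.broadcast_to(gg, self.data.shape).copy())

        out._backward = _bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            scale = 1.0 / self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            scale = 1.0 / np.prod([self.data.shape[a] for a in axes])
        return self.sum(axis=axis, keepdims=keepdims) * scale

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), requires_grad=self.requires_grad,
                     _prev=(self,))
        out._backward = lambda g: self._accumulate(g.reshape(self.data.shape))
        return out

    def transpose(self, axes: Sequence[int]):
        axes = tuple(axes)
        inverse = tuple(np.argsort(axes))
        out = Tensor(self.data.transpose(axes), requires_grad=self.requires_grad,
                     _prev=(self,))
        out._backward = lambda g: self._accumulate(g.transpose(inverse))
        return out


# ---------------------------------------------------------------------------
# fused operations
# ---------------------------------------------------------------------------


def embedding(weight: Tensor, indices: np.ndarray) -> Tensor:
    """Row lookup ``weight[indices]``.

    Backward scatter-adds into a dense gradient, unless the table opted
    into sparse gradients (``weight.sparse``), in which case the touched
    rows are recorded as (indices, row-gradients) pairs for a sparse
    optimizer update.
    """
    idx = np.asarray(indices)
    out = Tensor(weight.data[idx], requires_grad=weight.requires_grad, _prev=(weight,))

    def _bw(g):
        rows = g.reshape(-1, weight.data.shape[1])
        flat = idx.reshape(-1)
        if weight.sparse:
            weight.sparse_grads.append((flat, rows))
            return
        if weight.grad is None:
            weight.grad = np.zeros_like(weight.data)
        np.add.at(weight.grad, flat, rows)

    out._backward = _bw
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    s = e / e.sum(axis=axis, keepdims=True)
    out = Tensor(s, requires_grad=x.requires_grad, _prev=(x,))

    def _bw(g):
        dot = (g * s).sum(axis=axis, keepdims=True)
        x._accumulate(s * (g - dot))

    out._backward = _bw
    return out


def cross_entropy_logits(logits: Tensor, targets: np.ndarray,
                         mask: Optional[np.ndarray] = None) -> Tensor:
    """Mean token-level cross entropy over unmasked positions.

    ``logits``: (N, V); ``targets``: (N,) int; ``mask``: (N,) float/bool,
    positions with mask 0 are excluded from the mean.
    """
    targets = np.asarray(targets).reshape(-1)
    n, _ = logits.data.shape
    if mask is None:
        mask = np.ones(n, dtype=DTYPE)
    mask = np.asarray(mask, dtype=DTYPE).reshape(-1)
    denom = max(float(mask.sum()), 1.0)
    shifted = logits.data - logits.data.max(axis=1, keepdims=True)
    log_z = np.log(np.exp(shifted).sum(axis=1))  # (N,)
    log_p = shifted[np.arange(n), targets] - log_z
    loss_val = -(log_p * mask).sum() / denom
    out = Tensor(loss_val, requires_grad=logits.requires_grad, _prev=(logits,))

    def _bw(g):
        p = np.exp(shifted - np.log(np.exp(shifted).sum(axis=1, keepdims=True)))
        p[np.arange(n), targets] -= 1.0
        logits._accumulate(g * p * (mask / denom)[:, None])

    out._backward = _bw
    return out


def mse(a: Tensor, b: Tensor) -> Tensor:
    """Mean squared error between two tensors of identical shape."""
    diff = a.data - b.data
    out = Tensor(np.mean(diff * diff),
                 requires_grad=a.requires_grad or b.requires_grad, _prev=(a, b))
    scale = 2.0 / diff.size

    def _bw(g):
        if a.requires_grad or a._prev:
            a._accumulate(g * scale * diff)
        if b.requires_grad or b._prev:
            b._accumulate(-g * scale * diff)

    out._backward = _bw
    return out


def layer_norm(x: Tensor, gain: Tensor, bias: Tensor, eps: float = 1e-5) -> Tensor:
    """Layer normalization over the last axis."""
    mu = x.data.mean(axis=-1, keepdims=True)
    xc = x.data - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    out = Tensor(xhat * gain.data + bias.data,
                 requires_grad=True, _prev=(x, gain, bias))
    d = x.data.shape[-1]

    def _bw(g):
        bias._accumulate(_unbroadcast(g, bias.data.shape))
        gain._accumulate(_unbroadcast(g * xhat, gain.data.shape))
        gx = g * gain.data
        # d xhat/dx backward for per-row normalization
        dx = inv * (gx - gx.mean(axis=-1, keepdims=True)
                    - xhat * (gx * xhat).mean(axis=-1, keepdims=True))
        x._accumulate(dx.astype(DTYPE))

    out._backward = _bw
    return out


def gru_step(x: Tensor, h: Tensor, w_x: Tensor, w_h: Tensor,
             b_x: Tensor, b_h: Tensor, mask: Optional[np.ndarray] = None) -> Tensor:
    """One fused GRU step.

    ``x``: (B, E) input, ``h``: (B, H) previous hidden state.  Weights are
    packed by gate as ``[reset | update | candidate]``: ``w_x`` (E, 3H),
    ``w_h`` (H, 3H), biases (3H,).  ``mask`` (B,) carries 1 where the step
    is real and 0 at padding, where the old hidden state passes through.

        r = sigmoid(x W_xr + b_xr + h W_hr + b_hr)
        z = sigmoid(x W_xz + b_xz + h W_hz + b_hz)
        n = tanh(x W_xn + b_xn + r * (h W_hn + b_hn))
        h' = (1 - z) * n + z * h
    """
    B = x.data.shape[0]
    H = h.data.shape[1]
    gx = x.data @ w_x.data + b_x.data  # (B, 3H)
    gh = h.data @ w_h.data + b_h.data
    r = 1.0 / (1.0 + np.exp(-(gx[:, :H] + gh[:, :H])))
    z = 1.0 / (1.0 + np.exp(-(gx[:, H:2 * H] + gh[:, H:2 * H])))
    m = gh[:, 2 * H:]
    n = np.tanh(gx[:, 2 * H:] + r * m)
    h_new = (1.0 - z) * n + z * h.data
    if mask is not None:
        mcol = np.asarray(mask, dtype=DTYPE).reshape(B, 1)
        h_out = mcol * h_new + (1.0 - mcol) * h.data
    else:
        mcol = None
        h_out = h_new
    out = Tensor(h_out, requires_grad=True, _prev=(x, h, w_x, w_h, b_x, b_h))

    def _bw(g):
        if mcol is not None:
            g_new = g * mcol
            g_pass = g * (1.0 - mcol)
        else:
            g_new = g
            g_pass = 0.0
        dz = g_new * (h.data - n) * z * (1.0 - z)
        da_n = g_new * (1.0 - z) * (1.0 - n * n)
        dr = da_n * m * r * (1.0 - r)
        dm = da_n * r
        dgx = np.concatenate([dr, dz, da_n], axis=1)  # (B, 3H)
        dgh = np.concatenate([dr, dz, dm], axis=1)
        if x.requires_grad or x._prev:
            x._accumulate(dgx @ w_x.data.T)
        h._accumulate(g_new * z + dgh @ w_h.data.T + g_pass)
        w_x._accumulate(x.data.T @ dgx)
        w_h._accumulate(h.data.T @ dgh)
        b_x._accumulate(dgx.sum(axis=0))
        b_h._accumulate(dgh.sum(axis=0))

    out._backward = _bw
    return out


def conv_rows(x: Tensor, weight: Tensor, bias: Tensor) -> Tensor:
    """2-D convolution with a (1, k) kernel and 'same' padding.

    ``x``: (B, C_in, H, W); ``weight``: (C_out, C_in, k); ``bias``:
    (C_out,).  The kernel slides along the last (W) axis only, so each
    output row h aggregates a local window of columns of row h.
    """
    B, C, H, W = x.data.shape
    Co, Ci, k = weight.data.shape
    assert Ci == C, "channel mismatch"
    pad = k // 2
    xp = np.pad(x.data, ((0, 0), (0, 0), (0, 0), (pad, pad)))
    # strided windows (B, C, H, W, k); einsum avoids materializing im2col
    win = np.lib.stride_tricks.sliding_window_view(xp, k, axis=3)
    y = np.einsum("bchwk,ock->bohw", win, weight.data, optimize=True) \
        + bias.data.reshape(1, Co, 1, 1)
    out = Tensor(y, requires_grad=True, _prev=(x, weight, bias))

    def _bw(g):
        bias._accumulate(g.sum(axis=(0, 2, 3)))
        weight._accumulate(np.einsum("bohw,bchwk->ock", g, win, optimize=True))
        dwin = np.einsum("bohw,ock->bchwk", g, weight.data, optimize=True)
        dxp = np.zeros_like(xp)
        for j in range(k):
            dxp[:, :, :, j:j + W] += dwin[:, :, :, :, j]
        x._accumulate(dxp[:, :, :, pad:pad + W] if pad else dxp)

    out._backward = _bw
    return out


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    datas = [t.data for t in tensors]
    out = Tensor(np.concatenate(datas, axis=axis), requires_grad=True,
                 _prev=tuple(tensors))
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def _bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            t._accumulate(g[tuple(sl)])

    out._backward = _bw
    return out


def stack(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    out = Tensor(np.stack([t.data for t in tensors], axis=axis),
                 requires_grad=True, _prev=tuple(tensors))

    def _bw(g):
        for i, t in enumerate(tensors):
            t._accumulate(np.take(g, i, axis=axis))

    out._backward = _bw
    return out
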