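"""Layers, parameter containers and the optimizer for the two models.

Includes the intensity-modulated rotary position encoding (intensity-RoPE):
the standard rotary scheme rotates query/key feature pairs by an angle
proportional to the token's *position index*; here the index is replaced by
``intensity * rope_scale``, so the pre-softmax interaction of two peaks
depends only on their intensity difference, and peak order carries no
information (ordering is canonicalized upstream anyway).
"""

from __future__ import annotations

from typing import Iterator, Optional

import numpy as np

from .autograd import DTYPE, Tensor

__all__ = [
    "Module", "Linear", "Adam", "init_uniform", "init_normal",
    "rope_cache", "rotation_pair_matrix", "apply_rope_np", "intensity_rope",
    "gru_forward_np",
]


def init_uniform(rng: np.random.Generator, shape, scale: float) -> Tensor:
    return Tensor(rng.uniform(-scale, scale, size=shape).astype(DTYPE),
                  requires_grad=True)


def init_normal(rng: np.random.Generator, shape, sd: float) -> Tensor:
    return Tensor((rng.standard_normal(shape) * sd).astype(DTYPE),
                  requires_grad=True)


class Module:
    """Minimal parameter container with deterministic parameter order."""

    def named_parameters(self) -> Iterator[tuple[str, Tensor]]:
        for name in sorted(vars(self)):
            value = getattr(self, name)
            if isinstance(value, Tensor) and value.requires_grad:
                yield name, value
            elif isinstance(value, Module):
                for sub, p in value.named_parameters():
                    yield f"{name}.{sub}", p
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        for sub, p in item.named_parameters():
                            yield f"{name}.{i}.{sub}", p
                    elif isinstance(item, Tensor) and item.requires_grad:
                        yield f"{name}.{i}", item

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        if set(own) != set(state):
            missing = set(own) ^ set(state)
            raise KeyError(f"parameter name mismatch: {sorted(missing)[:5]} ...")
        for name, p in own.items():
            if p.data.shape != state[name].shape:
                raise ValueError(f"shape mismatch for {name}")
            p.data = state[name].astype(DTYPE).copy()


class Linear(Module):
    def __init__(self, rng: np.random.Generator, n_in: int, n_out: int):
        scale = 1.0 / np.sqrt(n_in)
        self.weight = init_uniform(rng, (n_in, n_out), scale)
        self.bias = Tensor(np.zeros(n_out, dtype=DTYPE), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Adam:
    """Adam optimizer with bias correction."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def _sparse_step(self, i: int, p) -> None:
        """Sparse-Adam update: only rows touched this step move (their
        momenta use the global timestep for bias correction)."""
        idx = np.concatenate([ix for ix, _ in p.sparse_grads])
        rows = np.concatenate([r for _, r in p.sparse_grads], axis=0)
        uniq, inverse = np.unique(idx, return_inverse=True)
        g = np.zeros((len(uniq), p.data.shape[1]), dtype=p.data.dtype)
        np.add.at(g, inverse, rows)
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        m, v = self.m[i], self.v[i]
        m[uniq] = self.b1 * m[uniq] + (1.0 - self.b1) * g
        v[uniq] = self.b2 * v[uniq] + (1.0 - self.b2) * g * g
        p.data[uniq] -= (self.lr * (m[uniq] / bc1) /
                         (np.sqrt(v[uniq] / bc2) + self.eps)).astype(p.data.dtype)
        p.sparse_grads = []

    def clip_grad_norm(self, max_norm: float) -> float:
        """Scale all gradients so their global L2 norm is at most max_norm."""
        total = 0.0
        for p in self.params:
            if p.grad is not None:
                total += float((p.grad.astype(np.float64) ** 2).sum())
        norm = float(np.sqrt(total))
        if norm > max_norm > 0:
            scale = max_norm / (norm + 1e-12)
            for p in self.params:
                if p.grad is not None:
                    p.grad *= scale
        return norm

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for i, (p, m, v) in enumerate(zip(self.params, self.m, self.v)):
            if p.sparse and p.sparse_grads:
                self._sparse_step(i, p)
                continue
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p.data -= (self.lr * (m / bc1) /
                       (np.sqrt(v / bc2) + self.eps)).astype(DTYPE)


# ---------------------------------------------------------------------------
# intensity-modulated rotary encoding
# ---------------------------------------------------------------------------


def rope_cache(intensities: np.ndarray, head_dim: int, rope_scale: float,
               base: float = 10000.0) -> tuple[np.ndarray, np.ndarray]:
    """cos/sin tables for intensity-RoPE.

    ``intensities``: (..., L) in [0, 1].  The rotary position value of
    token i is ``intensities[i] * rope_scale``; feature pair j rotates at
    frequency ``base**(-2j/head_dim)``.  Returns ``cos``/``sin`` arrays of
    shape (..., L, head_dim) with each pair's angle repeated for its two
    features.
    """
    if head_dim % 2:
        raise ValueError(f"head dimension must be even, got {head_dim}")
    positions = np.asarray(intensities, dtype=np.float64) * rope_scale
    freqs = base ** (-np.arange(0, head_dim, 2, dtype=np.float64) / head_dim)
    angles = positions[..., None] * freqs  # (..., L, head_dim/2)
    angles = np.repeat(angles, 2, axis=-1)
    return np.cos(angles).astype(DTYPE), np.sin(angles).astype(DTYPE)


def rotation_pair_matrix(head_dim: int) -> np.ndarray:
    """Constant matrix P with x @ P = (-x2, x1, -x4, x3, ...)."""
    P = np.zeros((head_dim, head_dim), dtype=DTYPE)
    for j in range(0, head_dim, 2):
        P[j + 1, j] = -1.0
        P[j, j + 1] = 1.0
    return P


def apply_rope_np(x: np.ndarray, intensities: np.ndarray, rope_scale: float,
                  base: float = 10000.0) -> np.ndarray:
    """Rotate a (..., L, D) array by intensity-RoPE (pure NumPy reference).

    Norm-preserving per 2-D feature pair; intensity 0 leaves the vector
    unchanged.
    """
    cos, sin = rope_cache(intensities, x.shape[-1], rope_scale, base)
    rotated = x @ rotation_pair_matrix(x.shape[-1]).astype(x.dtype)
    return x * cos.astype(x.dtype) + rotated * sin.astype(x.dtype)


def intensity_rope(q_or_k, intensities, rope_scale: float,
                   base: float = 10000.0):
    """Intensity-RoPE on a Tensor or ndarray of shape (..., L, D)."""
    if isinstance(q_or_k, Tensor):
        cos, sin = rope_cache(intensities, q_or_k.shape[-1], rope_scale, base)
        P = Tensor(rotation_pair_matrix(q_or_k.shape[-1]))
        return q_or_k * Tensor(cos) + (q_or_k @ P) * Tensor(sin)
    return apply_rope_np(np.asarray(q_or_k), intensities, rope_scale, base)


def gru_forward_np(x_t: np.ndarray, h: np.ndarray, w_x: np.ndarray,
                   w_h: np.ndarray, b_x: np.ndarray, b_h: np.ndarray) -> np.ndarray:
    """Inference-only GRU step mirroring :func:`autograd.gru_step`."""
    H = h.shape[1]
    gx = x_t @ w_x + b_x
    gh = h @ w_h + b_h
    r = 1.0 / (1.0 + np.exp(-(gx[:, :H] + gh[:, :H])))
    z = 1.0 / (1.0 + np.exp(-(gx[:, H:2 * H] + gh[:, H:2 * H])))
    n = np.tanh(gx[:, 2 * H:] + r * gh[:, 2 * H:])
    return (1.0 - z) * n + z * h
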