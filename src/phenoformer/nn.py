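"""Minimal neural-network layers with explicit forward/backward passes.

Everything runs in float32 NumPy on CPU.  Each layer caches what its
backward pass needs; parameters are `Param` objects collected by the model
and updated by `Adam`.  Gradient correctness is established by
finite-difference checks in the test suite.
"""

from __future__ import annotations

import numpy as np

F32 = np.float32


class Param:
    """A trainable tensor with its accumulated gradient."""

    __slots__ = ("value", "grad", "name", "trainable")

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = np.asarray(value, dtype=F32)
        self.grad = np.zeros_like(self.value)
        self.name = name
        self.trainable = True

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


def glorot(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    fan_in, fan_out = shape[0], shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(F32)


class Linear:
    """y = x @ W + b over the last axis."""

    def __init__(self, rng, d_in: int, d_out: int, name: str = "linear"):
        self.W = Param(glorot(rng, (d_in, d_out)), f"{name}.W")
        self.b = Param(np.zeros(d_out, dtype=F32), f"{name}.b")
        self._x = None

    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._x
        self.W.grad += x.reshape(-1, x.shape[-1]).T @ dy.reshape(-1, dy.shape[-1])
        self.b.grad += dy.reshape(-1, dy.shape[-1]).sum(axis=0)
        return dy @ self.W.value.T


class LayerNorm:
    """Normalization over the last axis with learned scale/shift."""

    def __init__(self, d: int, name: str = "ln", eps: float = 1e-5):
        self.gamma = Param(np.ones(d, dtype=F32), f"{name}.gamma")
        self.beta = Param(np.zeros(d, dtype=F32), f"{name}.beta")
        self.eps = eps
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray) -> np.ndarray:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = xc * inv
        self._cache = (xhat, inv)
        return xhat * self.gamma.value + self.beta.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        d = xhat.shape[-1]
        self.gamma.grad += (dy * xhat).reshape(-1, d).sum(axis=0)
        self.beta.grad += dy.reshape(-1, d).sum(axis=0)
        dxhat = dy * self.gamma.value
        # dx = inv/d * (d*dxhat - sum(dxhat) - xhat * sum(dxhat*xhat))
        return (inv / d) * (
            d * dxhat
            - dxhat.sum(axis=-1, keepdims=True)
            - xhat * (dxhat * xhat).sum(axis=-1, keepdims=True))


class Dropout:
    """Inverted dropout; identity when not training."""

    def __init__(self, p: float):
        self.p = p
        self._mask = None

    def forward(self, x: np.ndarray, train: bool, rng: np.random.Generator | None):
        if not train or self.p <= 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.p
        self._mask = (rng.random(x.shape) < keep).astype(F32) / F32(keep)
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy if self._mask is None else dy * self._mask


def softmax_last(x: np.ndarray) -> np.ndarray:
    z = x - x.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class MultiHeadSelfAttention:
    """Standard scaled dot-product multi-head self-attention.

    Stores the most recent attention maps (B, H, T, T) for interpretability.
    """

    def __init__(self, rng, d_model: int, n_heads: int, name: str = "mha"):
        if d_model % n_heads:
            raise ValueError("d_model must be divisible by n_heads")
        self.h = n_heads
        self.dh = d_model // n_heads
        self.wq = Linear(rng, d_model, d_model, f"{name}.q")
        self.wk = Linear(rng, d_model, d_model, f"{name}.k")
        self.wv = Linear(rng, d_model, d_model, f"{name}.v")
        self.wo = Linear(rng, d_model, d_model, f"{name}.o")
        self.attn: np.ndarray | None = None
        self._cache = None

    def params(self):
        return self.wq.params() + self.wk.params() + self.wv.params() + self.wo.params()

    def _split(self, x):  # (B,T,D) -> (B,H,T,dh)
        B, T, _ = x.shape
        return x.reshape(B, T, self.h, self.dh).transpose(0, 2, 1, 3)

    def _merge(self, x):  # (B,H,T,dh) -> (B,T,D)
        B, H, T, dh = x.shape
        return x.transpose(0, 2, 1, 3).reshape(B, T, H * dh)

    def forward(self, x: np.ndarray) -> np.ndarray:
        q = self._split(self.wq.forward(x))
        k = self._split(self.wk.forward(x))
        v = self._split(self.wv.forward(x))
        scale = F32(1.0 / np.sqrt(self.dh))
        scores = (q @ k.transpose(0, 1, 3, 2)) * scale
        attn = softmax_last(scores)
        ctx = attn @ v
        self.attn = attn
        self._cache = (q, k, v, attn, scale)
        return self.wo.forward(self._merge(ctx))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        q, k, v, attn, scale = self._cache
        dctx = self._split(self.wo.backward(dy))
        dattn = dctx @ v.transpose(0, 1, 3, 2)
        dv = attn.transpose(0, 1, 3, 2) @ dctx
        # softmax backward per row
        dscores = attn * (dattn - (dattn * attn).sum(axis=-1, keepdims=True))
        dscores *= scale
        dq = dscores @ k
        dk = dscores.transpose(0, 1, 3, 2) @ q
        dx = self.wq.backward(self._merge(dq))
        dx += self.wk.backward(self._merge(dk))
        dx += self.wv.backward(self._merge(dv))
        return dx


class FeedForward:
    """Position-wise two-layer ReLU network."""

    def __init__(self, rng, d_model: int, d_ff: int, name: str = "ffn"):
        self.l1 = Linear(rng, d_model, d_ff, f"{name}.1")
        self.l2 = Linear(rng, d_ff, d_model, f"{name}.2")
        self._relu_mask = None

    def params(self):
        return self.l1.params() + self.l2.params()

    def forward(self, x: np.ndarray) -> np.ndarray:
        h = self.l1.forward(x)
        self._relu_mask = h > 0
        return self.l2.forward(h * self._relu_mask)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dh = self.l2.backward(dy) * self._relu_mask
        return self.l1.backward(dh)


class EncoderLayer:
    """Post-norm transformer encoder block:
    x -> LN(x + drop(MHA(x))) -> LN(. + drop(FFN(.)))."""

    def __init__(self, rng, d_model: int, n_heads: int, d_ff: int, dropout: float,
                 name: str = "enc"):
        self.mha = MultiHeadSelfAttention(rng, d_model, n_heads, f"{name}.mha")
        self.ffn = FeedForward(rng, d_model, d_ff, f"{name}.ffn")
        self.ln1 = LayerNorm(d_model, f"{name}.ln1")
        self.ln2 = LayerNorm(d_model, f"{name}.ln2")
        self.drop1 = Dropout(dropout)
        self.drop2 = Dropout(dropout)

    def params(self):
        return (self.mha.params() + self.ffn.params()
                + self.ln1.params() + self.ln2.params())

    def forward(self, x: np.ndarray, train: bool = False, rng=None) -> np.ndarray:
        h = self.ln1.forward(x + self.drop1.forward(self.mha.forward(x), train, rng))
        return self.ln2.forward(
            h + self.drop2.forward(self.ffn.forward(h), train, rng))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dh = self.ln2.backward(dy)
        dh = dh + self.ffn.backward(self.drop2.backward(dh))
        dx = self.ln1.backward(dh)
        return dx + self.mha.backward(self.drop1.backward(dx))


class Adam:
    """Adam with optional cosine learning-rate schedule."""

    def __init__(self, params: list[Param], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def step(self, lr: float | None = None) -> None:
        self.t += 1
        lr = self.lr if lr is None else lr
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if not p.trainable:
                continue
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p.value -= F32(lr) * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()


def cosine_lr(epoch: int, max_epochs: int, lr0: float, lr_min_frac: float = 0.01) -> float:
    """Cosine annealing from lr0 down to lr0 * lr_min_frac over max_epochs."""
    lr_min = lr0 * lr_min_frac
    return lr_min + 0.5 * (lr0 - lr_min) * (1 + np.cos(np.pi * epoch / max(1, max_epochs)))
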