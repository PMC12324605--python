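"""Neural building blocks on top of the autograd engine.

Linear maps, layer normalization, exact multi-head self-attention, a
positive-random-feature linear-attention variant for long token panels,
feed-forward blocks, and Adam with gradient clipping. All parameters are
float64 and initialized from an explicit numpy Generator so every model
build is reproducible from a seed.
"""

from __future__ import annotations

import numpy as np

from .autograd import Parameter, Tensor, concat

__all__ = [
    "Module",
    "Linear",
    "LayerNorm",
    "FeedForward",
    "SelfAttention",
    "TransformerLayer",
    "TransformerEncoder",
    "MLP",
    "Adam",
]


class Module:
    """Lightweight parameter container (recursive over attributes/lists)."""

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        seen: set[int] = set()

        def visit(obj):
            if isinstance(obj, Parameter):
                if id(obj) not in seen:
                    seen.add(id(obj))
                    params.append(obj)
            elif isinstance(obj, Module):
                for v in vars(obj).values():
                    visit(v)
            elif isinstance(obj, (list, tuple)):
                for v in obj:
                    visit(v)
            elif isinstance(obj, dict):
                for v in obj.values():
                    visit(v)

        visit(self)
        return params

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError(
                f"state mismatch: {len(arrays)} arrays for {len(params)} parameters"
            )
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError(f"shape mismatch {p.data.shape} vs {a.shape}")
            p.data = np.asarray(a, dtype=np.float64).copy()


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator, bias: bool = True):
        scale = 1.0 / np.sqrt(max(d_in, 1))
        self.weight = Parameter(rng.uniform(-scale, scale, size=(d_in, d_out)))
        self.bias = Parameter(np.zeros(d_out)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        y = x @ self.weight
        if self.bias is not None:
            y = y + self.bias
        return y


class LayerNorm(Module):
    def __init__(self, d: int, eps: float = 1e-5):
        self.gain = Parameter(np.ones(d))
        self.shift = Parameter(np.zeros(d))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=-1, keepdims=True)
        return centered / (var + self.eps).sqrt() * self.gain + self.shift


class FeedForward(Module):
    def __init__(self, d: int, d_hidden: int, rng: np.random.Generator):
        self.fc1 = Linear(d, d_hidden, rng)
        self.fc2 = Linear(d_hidden, d, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).relu())


class SelfAttention(Module):
    """Multi-head self-attention with optional padding mask.

    ``kind='exact'`` is standard softmax attention; ``kind='linear_favor'``
    uses the positive random-feature estimator of the softmax kernel
    (fixed feature matrix drawn at construction), giving linear cost in
    token count at a small, bounded approximation error.
    """

    def __init__(
        self,
        d: int,
        n_heads: int,
        rng: np.random.Generator,
        kind: str = "exact",
        n_features: int = 128,
    ):
        if d % n_heads != 0:
            raise ValueError(f"model dim {d} not divisible by {n_heads} heads")
        self.d = d
        self.n_heads = n_heads
        self.d_head = d // n_heads
        self.kind = kind
        self.wq = Linear(d, d, rng)
        self.wk = Linear(d, d, rng)
        self.wv = Linear(d, d, rng)
        self.wo = Linear(d, d, rng)
        if kind == "linear_favor":
            # Gaussian features fixed for the model's lifetime, drawn from a
            # dedicated stream so exact/linear builds share all other
            # parameters when constructed from the same generator state
            self.features = np.random.default_rng(4099).standard_normal(
                (n_features, self.d_head))
        elif kind != "exact":
            raise ValueError(f"unknown attention kind: {kind!r}")

    def _split_heads(self, x: Tensor, B: int, n: int) -> Tensor:
        # (B, n, d) -> (B, h, n, d_head)
        return x.reshape(B, n, self.n_heads, self.d_head).transpose((0, 2, 1, 3))

    def __call__(self, x: Tensor, pad_mask: np.ndarray | None = None) -> Tensor:
        B, n, _ = x.shape
        q = self._split_heads(self.wq(x), B, n)
        k = self._split_heads(self.wk(x), B, n)
        v = self._split_heads(self.wv(x), B, n)

        if self.kind == "exact":
            logits = (q @ k.swapaxes(-1, -2)) * (1.0 / np.sqrt(self.d_head))
            if pad_mask is not None:
                bias = np.where(pad_mask, -1e9, 0.0)[:, None, None, :]
                logits = logits + bias
            attn = logits.softmax(axis=-1)
            ctx = attn @ v
        else:
            ctx = self._favor(q, k, v, pad_mask)

        ctx = ctx.transpose((0, 2, 1, 3)).reshape(B, n, self.d)
        return self.wo(ctx)

    def _favor(self, q: Tensor, k: Tensor, v: Tensor, pad_mask) -> Tensor:
        scale = self.d_head ** -0.25
        qs, ks = q * scale, k * scale
        m = self.features.shape[0]

        def phi(x: Tensor) -> Tensor:
            proj = x @ self.features.T  # (B,h,n,m)
            sq = (x * x).sum(axis=-1, keepdims=True) * 0.5
            return (proj - sq - proj.data.max()).exp() * (1.0 / np.sqrt(m))

        pq, pk = phi(qs), phi(ks)
        if pad_mask is not None:
            keep = (~pad_mask).astype(float)[:, None, :, None]
            pk = pk * keep
        kv = pk.swapaxes(-1, -2) @ v  # (B,h,m,d_head)
        num = pq @ kv
        den = (pq * pk.sum(axis=-2, keepdims=True)).sum(axis=-1, keepdims=True)
        return num / (den + 1e-12)


class TransformerLayer(Module):
    def __init__(self, d: int, n_heads: int, rng: np.random.Generator, kind: str):
        self.attn = SelfAttention(d, n_heads, rng, kind=kind)
        self.ln1 = LayerNorm(d)
        self.ln2 = LayerNorm(d)
        self.ff = FeedForward(d, 2 * d, rng)

    def __call__(self, x: Tensor, pad_mask=None) -> Tensor:
        x = x + self.attn(self.ln1(x), pad_mask)
        return x + self.ff(self.ln2(x))


class TransformerEncoder(Module):
    """Pre-norm transformer stack; zero layers is the identity map."""

    def __init__(self, d: int, n_layers: int, n_heads: int, rng: np.random.Generator, kind: str = "exact"):
        self.layers = [TransformerLayer(d, n_heads, rng, kind) for _ in range(n_layers)]

    def __call__(self, x: Tensor, pad_mask=None) -> Tensor:
        for layer in self.layers:
            x = layer(x, pad_mask)
        return x


class MLP(Module):
    def __init__(self, dims: list[int], rng: np.random.Generator):
        self.layers = [Linear(a, b, rng) for a, b in zip(dims[:-1], dims[1:])]

    def __call__(self, x: Tensor) -> Tensor:
        for layer in self.layers[:-1]:
            x = layer(x).relu()
        return self.layers[-1](x)


class Adam:
    """Adam with global-norm gradient clipping."""

    def __init__(self, params: list[Parameter], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8, clip_norm: float = 1.0):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.clip_norm = clip_norm
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        grads = [p.grad if p.grad is not None else np.zeros_like(p.data)
                 for p in self.params]
        if self.clip_norm is not None:
            total = np.sqrt(sum(float((g**2).sum()) for g in grads))
            if total > self.clip_norm:
                grads = [g * (self.clip_norm / (total + 1e-12)) for g in grads]
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g**2
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
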