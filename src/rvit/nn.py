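"""Minimal neural-network layers with explicit forward/backward passes.

The transformer here is small enough that plain BLAS-backed NumPy is a
perfectly adequate engine, so each layer implements its own analytic
backward pass instead of relying on an autodiff framework. Every layer
caches what its backward pass needs on a stack, which lets a single module
instance (e.g. the patch projector shared across the k rotation branches)
be called several times per step: backward pops caches in reverse call
order.

Shapes follow the transformer convention ``(batch, tokens, dim)``; images
are ``(batch, H, W, C)``. Default dtype is float32.
"""

from __future__ import annotations

import numpy as np
from scipy.special import erf

DTYPE = np.float32

_INV_SQRT2 = 1.0 / np.sqrt(2.0)
_INV_SQRT2PI = 1.0 / np.sqrt(2.0 * np.pi)


class Parameter:
    """A trainable array with an accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=DTYPE)
        self.grad = np.zeros_like(self.value)

    @property
    def size(self) -> int:
        return self.value.size


class Module:
    """Base class: parameter discovery, gradient reset, train/eval flag."""

    def named_parameters(self, prefix: str = ""):
        for name, attr in vars(self).items():
            full = f"{prefix}{name}" if not prefix else f"{prefix}.{name}"
            if isinstance(attr, Parameter):
                yield full, attr
            elif isinstance(attr, Module):
                yield from attr.named_parameters(full)
            elif isinstance(attr, (list, tuple)):
                for i, item in enumerate(attr):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{i}")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0.0

    def count_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def clear_caches(self) -> None:
        """Drop cached forward activations (recursively)."""
        cache = getattr(self, "_cache", None)
        if isinstance(cache, list):
            cache.clear()
        for attr in vars(self).values():
            if isinstance(attr, Module):
                attr.clear_caches()
            elif isinstance(attr, (list, tuple)):
                for item in attr:
                    if isinstance(item, Module):
                        item.clear_caches()


class Linear(Module):
    """Affine map over the last axis: ``y = x @ W + b``."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 bias: bool = True, init_scale: float = 0.02):
        self.weight = Parameter(rng.normal(0.0, init_scale, size=(d_in, d_out)))
        self.bias = Parameter(np.zeros(d_out)) if bias else None
        self.d_in = d_in
        self.d_out = d_out
        self._cache: list[np.ndarray] = []

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.shape[-1] != self.d_in:
            raise ValueError(
                f"linear layer expects inputs of size {self.d_in}, got {x.shape[-1]}"
            )
        self._cache.append(x)
        y = x @ self.weight.value
        if self.bias is not None:
            y += self.bias.value
        return y

    __call__ = forward

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x = self._cache.pop()
        flat_x = x.reshape(-1, self.d_in)
        flat_g = grad.reshape(-1, self.d_out)
        self.weight.grad += flat_x.T @ flat_g
        if self.bias is not None:
            self.bias.grad += flat_g.sum(axis=0)
        return grad @ self.weight.value.T


class LayerNorm(Module):
    """Layer normalization over the last axis with learnable scale/shift."""

    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))
        self.eps = eps
        self.dim = dim
        self._cache: list[tuple[np.ndarray, np.ndarray]] = []

    def forward(self, x: np.ndarray) -> np.ndarray:
        mu = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv_std
        self._cache.append((xhat, inv_std))
        return self.gamma.value * xhat + self.beta.value

    __call__ = forward

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, inv_std = self._cache.pop()
        flat = grad.reshape(-1, self.dim)
        flat_xhat = xhat.reshape(-1, self.dim)
        self.gamma.grad += (flat * flat_xhat).sum(axis=0)
        self.beta.grad += flat.sum(axis=0)
        dxhat = grad * self.gamma.value
        mean_d = dxhat.mean(axis=-1, keepdims=True)
        mean_dx = (dxhat * xhat).mean(axis=-1, keepdims=True)
        return inv_std * (dxhat - mean_d - xhat * mean_dx)


class GELU(Module):
    """Exact (erf-based) Gaussian error linear unit."""

    def __init__(self):
        self._cache: list[tuple[np.ndarray, np.ndarray]] = []

    def forward(self, x: np.ndarray) -> np.ndarray:
        phi = 0.5 * (1.0 + erf(x * _INV_SQRT2))
        self._cache.append((x, phi))
        return x * phi

    __call__ = forward

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x, phi = self._cache.pop()
        pdf = _INV_SQRT2PI * np.exp(-0.5 * x * x)
        return grad * (phi + x * pdf)


class Dropout(Module):
    """Inverted dropout; identity when ``training`` is False or rate is 0."""

    def __init__(self, rate: float):
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate
        self.rng: np.random.Generator = np.random.default_rng(0)
        self._cache: list[np.ndarray | None] = []

    def reseed(self, seed: int) -> None:
        self.rng = np.random.default_rng(seed)

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if not training or self.rate == 0.0:
            self._cache.append(None)
            return x
        keep = 1.0 - self.rate
        mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        self._cache.append(mask)
        return x * mask

    __call__ = forward

    def backward(self, grad: np.ndarray) -> np.ndarray:
        mask = self._cache.pop()
        return grad if mask is None else grad * mask


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    shifted = x - x.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=axis, keepdims=True)


class MultiHeadAttention(Module):
    """Scaled dot-product multi-head self-attention.

    The per-head width is ``floor(D / heads)``; the output projection maps
    the concatenated head outputs (``heads * d_head``, which may be smaller
    than ``D``) back to ``D``. Dropout is applied to the attention weights.
    """

    def __init__(self, dim: int, heads: int, rng: np.random.Generator,
                 dropout: float = 0.0):
        if heads < 1:
            raise ValueError("need at least one attention head")
        self.dim = dim
        self.heads = heads
        self.d_head = dim // heads
        if self.d_head < 1:
            raise ValueError(f"dim {dim} too small for {heads} heads")
        inner = self.heads * self.d_head
        self.wq = Linear(dim, inner, rng)
        self.wk = Linear(dim, inner, rng)
        self.wv = Linear(dim, inner, rng)
        self.wo = Linear(inner, dim, rng)
        self.drop = Dropout(dropout)
        self._cache: list[tuple] = []

    def _split(self, x: np.ndarray) -> np.ndarray:
        b, t, _ = x.shape
        return x.reshape(b, t, self.heads, self.d_head).transpose(0, 2, 1, 3)

    def _merge(self, x: np.ndarray) -> np.ndarray:
        b, h, t, dh = x.shape
        return np.ascontiguousarray(x.transpose(0, 2, 1, 3)).reshape(b, t, h * dh)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        q = self._split(self.wq(x))
        k = self._split(self.wk(x))
        v = self._split(self.wv(x))
        scale = 1.0 / np.sqrt(self.d_head)
        scores = (q @ k.transpose(0, 1, 3, 2)) * scale
        attn = softmax(scores, axis=-1)
        attn_d = self.drop(attn, training)
        ctx = attn_d @ v
        self._cache.append((q, k, v, attn, attn_d, scale))
        return self.wo(self._merge(ctx))

    __call__ = forward

    def backward(self, grad: np.ndarray) -> np.ndarray:
        q, k, v, attn, attn_d, scale = self._cache.pop()
        d_ctx = self._split(self.wo.backward(grad))
        d_attn_d = d_ctx @ v.transpose(0, 1, 3, 2)
        dv = attn_d.transpose(0, 1, 3, 2) @ d_ctx
        d_attn = self.drop.backward(d_attn_d)
        # softmax jacobian, rows of attn sum to one
        d_scores = attn * (d_attn - (d_attn * attn).sum(axis=-1, keepdims=True))
        d_scores *= scale
        dq = d_scores @ k
        dk = d_scores.transpose(0, 1, 3, 2) @ q
        gx = self.wq.backward(self._merge(dq))
        gx += self.wk.backward(self._merge(dk))
        gx += self.wv.backward(self._merge(dv))
        return gx

    @property
    def attention_last(self) -> np.ndarray | None:
        """Attention weights of the most recent forward (for inspection)."""
        return self._cache[-1][3] if self._cache else None


class MLP(Module):
    """Two affine maps with a GELU in between (the transformer feed-forward)."""

    def __init__(self, dim: int, hidden: int, rng: np.random.Generator):
        self.fc1 = Linear(dim, hidden, rng)
        self.act = GELU()
        self.fc2 = Linear(hidden, dim, rng)

    def forward(self, x: np.ndarray) -> np.ndarray:
        return self.fc2(self.act(self.fc1(x)))

    __call__ = forward

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return self.fc1.backward(self.act.backward(self.fc2.backward(grad)))


class EncoderBlock(Module):
    """Pre-norm transformer block: x + attn(LN(x)), then x + mlp(LN(x))."""

    def __init__(self, dim: int, heads: int, mlp_hidden: int,
                 rng: np.random.Generator, attn_dropout: float = 0.0):
        self.ln1 = LayerNorm(dim)
        self.attn = MultiHeadAttention(dim, heads, rng, dropout=attn_dropout)
        self.ln2 = LayerNorm(dim)
        self.mlp = MLP(dim, mlp_hidden, rng)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        x = x + self.attn(self.ln1(x), training)
        x = x + self.mlp(self.ln2(x))
        return x

    __call__ = forward

    def backward(self, grad: np.ndarray) -> np.ndarray:
        grad = grad + self.ln2.backward(self.mlp.backward(grad))
        grad = grad + self.ln1.backward(self.attn.backward(grad))
        return grad


class DepthwiseConv3x3(Module):
    """Per-channel 3x3 convolution with zero same-padding on (B, H, W, C)."""

    def __init__(self, channels: int, rng: np.random.Generator | None = None,
                 identity_init: bool = False):
        if identity_init or rng is None:
            w = np.zeros((3, 3, channels))
            w[1, 1, :] = 1.0
        else:
            w = rng.normal(0.0, 0.1, size=(3, 3, channels))
            w[1, 1, :] += 1.0  # start near identity for stable training
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(channels))
        self.channels = channels
        self._cache: list[np.ndarray] = []

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.shape[-1] != self.channels:
            raise ValueError(
                f"depthwise conv expects {self.channels} channels, got {x.shape[-1]}"
            )
        b, h, w, c = x.shape
        xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
        self._cache.append(xp)
        y = np.zeros_like(x)
        wv = self.weight.value
        for a in range(3):
            for bb in range(3):
                y += xp[:, a:a + h, bb:bb + w, :] * wv[a, bb]
        return y + self.bias.value

    __call__ = forward

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xp = self._cache.pop()
        b, h, w, c = grad.shape
        self.bias.grad += grad.sum(axis=(0, 1, 2))
        dxp = np.zeros_like(xp)
        wv = self.weight.value
        for a in range(3):
            for bb in range(3):
                self.weight.grad[a, bb] += (
                    grad * xp[:, a:a + h, bb:bb + w, :]
                ).sum(axis=(0, 1, 2))
                dxp[:, a:a + h, bb:bb + w, :] += grad * wv[a, bb]
        return dxp[:, 1:h + 1, 1:w + 1, :]


class DepthwiseStem(Module):
    """Depth-wise 3x3 filter followed by a pointwise (1x1) channel mix.

    Spatial size is preserved (zero same-padding) so the downstream patch
    grid is unchanged; there is no nonlinearity, so identity-initialized
    kernels reproduce the input exactly. The stem still adds expressive
    power over a bare patch projection because the 3x3 support crosses
    patch boundaries.
    """

    def __init__(self, in_channels: int, out_channels: int,
                 rng: np.random.Generator | None = None,
                 identity_init: bool = False):
        if identity_init and out_channels != in_channels:
            raise ValueError("identity init needs out_channels == in_channels")
        self.depthwise = DepthwiseConv3x3(in_channels, rng, identity_init)
        if identity_init or rng is None:
            pw = Linear(in_channels, out_channels, np.random.default_rng(0))
            pw.weight.value[...] = np.eye(in_channels, out_channels)
            pw.bias.value[...] = 0.0
        else:
            pw = Linear(in_channels, out_channels, rng, init_scale=0.1)
        self.pointwise = pw
        self.in_channels = in_channels
        self.out_channels = out_channels

    def forward(self, x: np.ndarray) -> np.ndarray:
        return self.pointwise(self.depthwise(x))

    __call__ = forward

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return self.depthwise.backward(self.pointwise.backward(grad))


def cross_entropy(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy of softmax(logits) against integer labels.

    Returns ``(loss, dloss/dlogits)`` with the gradient already divided by
    the batch size.
    """
    b = logits.shape[0]
    probs = softmax(logits, axis=-1)
    eps = np.finfo(probs.dtype).tiny
    loss = -float(np.mean(np.log(probs[np.arange(b), labels] + eps)))
    grad = probs.copy()
    grad[np.arange(b), labels] -= 1.0
    return loss, grad / b


class Adam:
    """Adam with optional L2 weight decay added to the gradient."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.value
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p.value -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
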