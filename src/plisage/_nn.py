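"""Neural-network building blocks on top of the autodiff engine.

Modules mirror the conventional layer zoo (Linear, LayerNorm, multi-head
attention, pre-LN Transformer blocks) at the scale this package needs.  All
parameter initialisation is driven by an explicit numpy Generator so a single
run seed controls every weight.
"""

from __future__ import annotations

import numpy as np

from ._autodiff import Tensor, dropout

__all__ = [
    "Module", "Linear", "MLP", "LayerNorm", "MultiHeadAttention",
    "TransformerEncoderLayer", "TransformerDecoderLayer", "Adam",
]


class Module:
    """Base class: tracks parameters and submodules by attribute name."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._mods: dict[str, Module] = {}

    def __setattr__(self, name, value):
        if isinstance(value, Tensor) and value.requires_grad:
            self.__dict__.setdefault("_params", {})[name] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_mods", {})[name] = value
        elif isinstance(value, (list, tuple)) and value and all(
            isinstance(v, Module) for v in value
        ):
            for i, v in enumerate(value):
                self.__dict__.setdefault("_mods", {})[f"{name}.{i}"] = v
        object.__setattr__(self, name, value)

    def named_parameters(self, prefix: str = ""):
        for n, p in self._params.items():
            yield prefix + n, p
        for n, m in self._mods.items():
            yield from m.named_parameters(prefix + n + ".")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def state_dict(self) -> dict[str, np.ndarray]:
        return {n: p.data.copy() for n, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]):
        own = dict(self.named_parameters())
        if set(own) != set(state):
            missing = set(own) ^ set(state)
            raise ValueError(f"parameter name mismatch: {sorted(missing)[:5]} ...")
        for n, p in own.items():
            if p.data.shape != state[n].shape:
                raise ValueError(f"shape mismatch for {n}")
            p.data = np.asarray(state[n], dtype=np.float64).copy()


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape=None) -> Tensor:
    lim = np.sqrt(6.0 / (fan_in + fan_out))
    return Tensor(rng.uniform(-lim, lim, size=shape or (fan_in, fan_out)), requires_grad=True)


class Linear(Module):
    def __init__(self, rng, d_in: int, d_out: int, bias: bool = True):
        super().__init__()
        self.w = glorot(rng, d_in, d_out)
        self.b = Tensor(np.zeros(d_out), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        y = x @ self.w
        return y + self.b if self.b is not None else y


class MLP(Module):
    """Fully connected stack with ReLU between layers and optional dropout."""

    def __init__(self, rng, dims: list[int], p_drop: float = 0.0):
        super().__init__()
        self.layers = [Linear(rng, a, b) for a, b in zip(dims[:-1], dims[1:])]
        self.p_drop = p_drop

    def __call__(self, x: Tensor, rng=None, train: bool = False) -> Tensor:
        for i, layer in enumerate(self.layers):
            x = layer(x)
            if i < len(self.layers) - 1:
                x = x.relu()
                if train and self.p_drop > 0:
                    x = dropout(x, self.p_drop, rng, True)
        return x


class LayerNorm(Module):
    def __init__(self, d: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones(d), requires_grad=True)
        self.beta = Tensor(np.zeros(d), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc / (var + self.eps).sqrt() * self.gamma + self.beta


class MultiHeadAttention(Module):
    """Scaled dot-product attention; stores the last softmax weights."""

    def __init__(self, rng, d_model: int, heads: int):
        super().__init__()
        if d_model % heads:
            raise ValueError("d_model must be divisible by heads")
        self.h, self.dk = heads, d_model // heads
        self.wq = Linear(rng, d_model, d_model)
        self.wk = Linear(rng, d_model, d_model)
        self.wv = Linear(rng, d_model, d_model)
        self.wo = Linear(rng, d_model, d_model)
        self.last_weights: np.ndarray | None = None

    def __call__(self, q_in: Tensor, kv_in: Tensor) -> Tensor:
        n, m = q_in.shape[0], kv_in.shape[0]
        split = lambda t, L: t.reshape(L, self.h, self.dk).swapaxes(0, 1)  # (h, L, dk)
        q, k, v = split(self.wq(q_in), n), split(self.wk(kv_in), m), split(self.wv(kv_in), m)
        scores = (q @ k.swapaxes(-1, -2)) * (1.0 / np.sqrt(self.dk))
        attn = scores.softmax(axis=-1)
        self.last_weights = attn.data.copy()
        out = (attn @ v).swapaxes(0, 1).reshape(n, self.h * self.dk)
        return self.wo(out)


class TransformerEncoderLayer(Module):
    """Pre-LN block: x + attn(LN(x)), then x + FF(LN(x))."""

    def __init__(self, rng, d_model: int, heads: int, p_drop: float = 0.0, d_ff: int | None = None):
        super().__init__()
        d_ff = d_ff or 2 * d_model
        self.ln1 = LayerNorm(d_model)
        self.attn = MultiHeadAttention(rng, d_model, heads)
        self.ln2 = LayerNorm(d_model)
        self.ff = MLP(rng, [d_model, d_ff, d_model])
        self.p_drop = p_drop

    def __call__(self, x: Tensor, rng=None, train: bool = False) -> Tensor:
        h = self.ln1(x)
        x = x + dropout(self.attn(h, h), self.p_drop, rng, train)
        x = x + dropout(self.ff(self.ln2(x)), self.p_drop, rng, train)
        return x


class TransformerDecoderLayer(Module):
    """Pre-LN block with self-attention then cross-attention onto `memory`."""

    def __init__(self, rng, d_model: int, heads: int, p_drop: float = 0.0, d_ff: int | None = None):
        super().__init__()
        d_ff = d_ff or 2 * d_model
        self.ln1 = LayerNorm(d_model)
        self.self_attn = MultiHeadAttention(rng, d_model, heads)
        self.ln2 = LayerNorm(d_model)
        self.cross_attn = MultiHeadAttention(rng, d_model, heads)
        self.ln3 = LayerNorm(d_model)
        self.ff = MLP(rng, [d_model, d_ff, d_model])
        self.p_drop = p_drop

    def __call__(self, x: Tensor, memory: Tensor, rng=None, train: bool = False) -> Tensor:
        h = self.ln1(x)
        x = x + dropout(self.self_attn(h, h), self.p_drop, rng, train)
        x = x + dropout(self.cross_attn(self.ln2(x), memory), self.p_drop, rng, train)
        x = x + dropout(self.ff(self.ln3(x)), self.p_drop, rng, train)
        return x


class Adam:
    """Adam with classic L2 weight decay added to the gradient."""

    def __init__(self, params, lr: float = 1e-4, betas=(0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps, self.wd = lr, betas[0], betas[1], eps, weight_decay
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad = np.zeros_like(p.data)

    def step(self):
        self.t += 1
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad if p.grad is not None else np.zeros_like(p.data)
            if self.wd:
                g = g + self.wd * p.data
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
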