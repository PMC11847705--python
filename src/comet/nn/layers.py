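"""Neural-network building blocks on the numpy autodiff core.

Layers follow a light ``Module`` protocol: ``named_parameters()`` yields
``(name, Parameter)`` pairs, parameters carry a ``frozen`` flag that the
optimizer honours, and ``state_dict``/``load_state_dict`` move raw arrays in
and out for checkpointing. Initialization is the uniform fan-in scheme,
seeded through a ``numpy.random.Generator``.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, concat

__all__ = [
    "Parameter", "Module", "Linear", "MLP", "Dropout", "GRU",
    "LayerNorm", "TransformerEncoderLayer", "Embedding",
]


class Parameter(Tensor):
    __slots__ = ("frozen",)

    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=np.float64), requires_grad=True)
        self.frozen = False


def _uniform_fan_in(rng: np.random.Generator, fan_in: int, shape) -> np.ndarray:
    bound = 1.0 / np.sqrt(max(fan_in, 1))
    return rng.uniform(-bound, bound, size=shape)


class Module:
    def _children(self):
        for name, val in vars(self).items():
            if isinstance(val, Parameter):
                yield name, val
            elif isinstance(val, Module):
                yield name, val
            elif isinstance(val, (list, tuple)):
                for i, v in enumerate(val):
                    if isinstance(v, Module):
                        yield f"{name}.{i}", v

    def named_parameters(self):
        for name, val in self._children():
            if isinstance(val, Parameter):
                yield name, val
            else:
                for sub, p in val.named_parameters():
                    yield f"{name}.{sub}", p

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def freeze(self, frozen: bool = True):
        for p in self.parameters():
            p.frozen = frozen

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        missing = set(params) ^ set(state)
        if missing:
            raise ValueError(f"state dict mismatch on keys: {sorted(missing)}")
        for name, p in params.items():
            if p.data.shape != state[name].shape:
                raise ValueError(
                    f"shape mismatch for {name}: "
                    f"{p.data.shape} vs {state[name].shape}")
            p.data = np.array(state[name], dtype=np.float64)


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator,
                 bias: bool = True):
        self.W = Parameter(_uniform_fan_in(rng, in_dim, (in_dim, out_dim)))
        self.b = Parameter(_uniform_fan_in(rng, in_dim, (out_dim,))) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.W
        if self.b is not None:
            out = out + self.b
        return out


class MLP(Module):
    """One-hidden-layer perceptron with rectifier activation."""

    def __init__(self, in_dim: int, hidden_dim: int, out_dim: int,
                 rng: np.random.Generator):
        self.fc1 = Linear(in_dim, hidden_dim, rng)
        self.fc2 = Linear(hidden_dim, out_dim, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).relu())


class Dropout(Module):
    """Inverted dropout; a no-op unless ``training`` and ``rate > 0``."""

    def __init__(self, rate: float):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate

    def __call__(self, x: Tensor, rng: np.random.Generator | None,
                 training: bool) -> Tensor:
        if not training or self.rate == 0.0 or rng is None:
            return x
        keep = (rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * Tensor(keep)


class GRU(Module):
    """Stacked gated-recurrent-unit encoder over padded day sequences.

    Input is ``(B, L, input_dim)`` with a ``(B, L)`` validity mask; padded
    positions leave the hidden state untouched, so front- or back-padding
    both yield the hidden state after the last valid step.
    """

    def __init__(self, input_dim: int, hidden_dim: int, n_layers: int,
                 dropout: float, rng: np.random.Generator):
        self.hidden_dim = hidden_dim
        self.n_layers = n_layers
        self.W, self.U, self.b_ih, self.b_hh = [], [], [], []
        weights = []
        for layer in range(n_layers):
            d_in = input_dim if layer == 0 else hidden_dim
            w = Parameter(_uniform_fan_in(rng, hidden_dim, (d_in, 3 * hidden_dim)))
            u = Parameter(_uniform_fan_in(rng, hidden_dim, (hidden_dim, 3 * hidden_dim)))
            bi = Parameter(_uniform_fan_in(rng, hidden_dim, (3 * hidden_dim,)))
            bh = Parameter(_uniform_fan_in(rng, hidden_dim, (3 * hidden_dim,)))
            weights.append((w, u, bi, bh))
        self._weights = weights
        self.dropout = Dropout(dropout)

    def named_parameters(self):
        for layer, (w, u, bi, bh) in enumerate(self._weights):
            yield f"l{layer}.W", w
            yield f"l{layer}.U", u
            yield f"l{layer}.b_ih", bi
            yield f"l{layer}.b_hh", bh

    def __call__(self, x: Tensor, mask: np.ndarray,
                 rng: np.random.Generator | None = None,
                 training: bool = False) -> Tensor:
        B, L, _ = x.shape
        H = self.hidden_dim
        seq = x
        h = None
        for layer, (w, u, bi, bh) in enumerate(self._weights):
            if layer > 0:
                seq = self.dropout(seq, rng, training)
            # one batched input projection for all timesteps
            d_in = seq.shape[-1]
            gi_all = (seq.reshape(B * L, d_in) @ w + bi).reshape(B, L, 3 * H)
            h = Tensor(np.zeros((B, H)))
            outs = []
            for t in range(L):
                gi = gi_all[:, t, :]
                gh = h @ u + bh
                r = (gi[:, :H] + gh[:, :H]).sigmoid()
                z = (gi[:, H:2 * H] + gh[:, H:2 * H]).sigmoid()
                n = (gi[:, 2 * H:] + r * gh[:, 2 * H:]).tanh()
                h_new = (1.0 - z) * n + z * h
                m = Tensor(mask[:, t:t + 1].astype(float))
                h = m * h_new + (1.0 - m) * h
                if layer < self.n_layers - 1:
                    outs.append(h.reshape(B, 1, H))
            if layer < self.n_layers - 1:
                seq = concat(outs, axis=1)
        return h


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.g = Parameter(np.ones(dim))
        self.b = Parameter(np.zeros(dim))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc * ((var + self.eps) ** -0.5) * self.g + self.b


class TransformerEncoderLayer(Module):
    """Post-norm encoder layer: masked multihead self-attention + FFN."""

    NEG_SCORE = -1e9  # additive score for padded key positions

    def __init__(self, d: int, heads: int, ff_dim: int, dropout: float,
                 rng: np.random.Generator):
        if d % heads != 0:
            raise ValueError("heads must divide model dimension")
        self.d, self.heads, self.dh = d, heads, d // heads
        self.Wq = Linear(d, d, rng)
        self.Wk = Linear(d, d, rng)
        self.Wv = Linear(d, d, rng)
        self.Wo = Linear(d, d, rng)
        self.ff1 = Linear(d, ff_dim, rng)
        self.ff2 = Linear(ff_dim, d, rng)
        self.norm1 = LayerNorm(d)
        self.norm2 = LayerNorm(d)
        self.dropout = Dropout(dropout)

    def _split(self, x: Tensor, B: int, L: int) -> Tensor:
        return x.reshape(B, L, self.heads, self.dh).transpose(0, 2, 1, 3)

    def __call__(self, x: Tensor, key_valid: np.ndarray,
                 rng: np.random.Generator | None = None,
                 training: bool = False) -> Tensor:
        B, L, d = x.shape
        q = self._split(self.Wq(x), B, L)
        k = self._split(self.Wk(x), B, L)
        v = self._split(self.Wv(x), B, L)
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(self.dh))
        bias = np.where(key_valid[:, None, None, :], 0.0, self.NEG_SCORE)
        attn = (scores + Tensor(bias)).softmax(axis=-1)
        ctx = (attn @ v).transpose(0, 2, 1, 3).reshape(B, L, d)
        x = self.norm1(x + self.dropout(self.Wo(ctx), rng, training))
        ff = self.ff2(self.dropout(self.ff1(x).relu(), rng, training))
        return self.norm2(x + ff)


class Embedding(Module):
    def __init__(self, n_tokens: int, d: int, rng: np.random.Generator):
        self.weight = Parameter(rng.normal(0.0, 1.0 / np.sqrt(d), (n_tokens, d)))

    def __call__(self, idx: np.ndarray) -> Tensor:
        return self.weight.take_rows(idx)
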