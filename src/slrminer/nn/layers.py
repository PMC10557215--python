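"""Encoder architectures: a small pre-norm transformer and a BiLSTM baseline.

Both encoders map a batch of wordpiece-id sequences (one sentence or context
window per row, equal lengths within a batch) to per-piece contextual vectors
of width ``d_model``.  The transformer uses learned positional embeddings and
multi-head self-attention; the BiLSTM is the conventional baseline that
combines a left-to-right and a right-to-left recurrent pass, so each piece's
vector carries previous and subsequent context in its two halves.

Parameters are registered in insertion order under dotted names, which fixes
the optimiser update order and makes archives reload bit-exactly.
"""

from __future__ import annotations

import numpy as np

from .autograd import DTYPE, Tensor


class Module:
    """Minimal parameter container with dotted-name collection."""

    def __init__(self) -> None:
        self._params: dict[str, Tensor] = {}
        self._subs: dict[str, "Module"] = {}

    def add_param(self, name: str, data: np.ndarray) -> Tensor:
        t = Tensor(np.asarray(data, dtype=DTYPE))
        t.requires_grad = True
        self._params[name] = t
        return t

    def add_module(self, name: str, mod: "Module") -> "Module":
        self._subs[name] = mod
        return mod

    def params(self, prefix: str = "") -> dict[str, Tensor]:
        out: dict[str, Tensor] = {}
        for n, p in self._params.items():
            out[prefix + n] = p
        for n, m in self._subs.items():
            out.update(m.params(prefix + n + "."))
        return out

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        own = self.params()
        missing = set(own) - set(state)
        if missing:
            raise KeyError(f"missing parameters in state: {sorted(missing)[:5]}")
        for name, t in own.items():
            arr = np.asarray(state[name], dtype=DTYPE)
            if arr.shape != t.data.shape:
                raise ValueError(f"shape mismatch for {name}: {arr.shape} vs {t.data.shape}")
            t.data = arr.copy()

    def state(self) -> dict[str, np.ndarray]:
        return {name: t.data.copy() for name, t in self.params().items()}

    def zero_grad(self) -> None:
        for t in self.params().values():
            t.grad = None


def _normal(rng: np.random.Generator, shape, std: float = 0.02) -> np.ndarray:
    return rng.normal(0.0, std, size=shape).astype(DTYPE)


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        super().__init__()
        self.w = self.add_param("w", _normal(rng, (d_in, d_out)))
        self.b = self.add_param("b", np.zeros(d_out, dtype=DTYPE))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.w + self.b


class Embedding(Module):
    def __init__(self, n: int, d: int, rng: np.random.Generator):
        super().__init__()
        self.w = self.add_param("w", _normal(rng, (n, d)))

    def __call__(self, ids: np.ndarray) -> Tensor:
        return self.w[np.asarray(ids, dtype=np.intp)]


class LayerNorm(Module):
    def __init__(self, d: int, eps: float = 1e-5):
        super().__init__()
        self.g = self.add_param("g", np.ones(d, dtype=DTYPE))
        self.b = self.add_param("b", np.zeros(d, dtype=DTYPE))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc * (var + self.eps).pow(-0.5) * self.g + self.b


class MultiHeadSelfAttention(Module):
    def __init__(self, d: int, heads: int, rng: np.random.Generator):
        super().__init__()
        if d % heads:
            raise ValueError("hidden width must be divisible by the head count")
        self.d, self.h, self.dh = d, heads, d // heads
        self.qkv = self.add_module("qkv", Linear(d, 3 * d, rng))
        self.proj = self.add_module("proj", Linear(d, d, rng))

    def __call__(self, x: Tensor) -> Tensor:
        B, T, d = x.shape
        qkv = self.qkv(x)  # (B,T,3d)
        q = qkv[:, :, : d].reshape(B, T, self.h, self.dh).transpose(0, 2, 1, 3)
        k = qkv[:, :, d : 2 * d].reshape(B, T, self.h, self.dh).transpose(0, 2, 1, 3)
        v = qkv[:, :, 2 * d :].reshape(B, T, self.h, self.dh).transpose(0, 2, 1, 3)
        scores = (q @ k.swapaxes(-1, -2)) * (1.0 / np.sqrt(self.dh))
        attn = scores.softmax(axis=-1)
        out = (attn @ v).transpose(0, 2, 1, 3).reshape(B, T, d)
        return self.proj(out)


class TransformerLayer(Module):
    def __init__(self, d: int, heads: int, rng: np.random.Generator, d_ff: int | None = None):
        super().__init__()
        d_ff = d_ff or 4 * d
        self.ln1 = self.add_module("ln1", LayerNorm(d))
        self.attn = self.add_module("attn", MultiHeadSelfAttention(d, heads, rng))
        self.ln2 = self.add_module("ln2", LayerNorm(d))
        self.ff1 = self.add_module("ff1", Linear(d, d_ff, rng))
        self.ff2 = self.add_module("ff2", Linear(d_ff, d, rng))

    def __call__(self, x: Tensor) -> Tensor:
        x = x + self.attn(self.ln1(x))
        return x + self.ff2(self.ff1(self.ln2(x)).gelu())


class TransformerEncoder(Module):
    """Self-attention encoder producing one contextual vector per wordpiece."""

    kind = "transformer"

    def __init__(self, vocab_size: int, d: int = 128, layers: int = 2, heads: int = 4,
                 max_len: int = 256, seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.vocab_size, self.d_model, self.n_layers = vocab_size, d, layers
        self.heads, self.max_len, self.seed = heads, max_len, seed
        self.tok = self.add_module("tok", Embedding(vocab_size, d, rng))
        self.pos = self.add_module("pos", Embedding(max_len, d, rng))
        self.layers: list[TransformerLayer] = []
        for i in range(layers):
            self.layers.append(self.add_module(f"layer{i}", TransformerLayer(d, heads, rng)))
        self.ln_f = self.add_module("ln_f", LayerNorm(d))

    def config(self) -> dict:
        return {"kind": self.kind, "vocab_size": self.vocab_size, "hidden_width": self.d_model,
                "layers": self.n_layers, "heads": self.heads, "max_len": self.max_len,
                "seed": self.seed}

    def __call__(self, ids: np.ndarray, extra: Tensor | None = None) -> Tensor:
        ids = np.asarray(ids, dtype=np.intp)
        B, T = ids.shape
        if T > self.max_len:
            raise ValueError(f"sequence length {T} exceeds maximum {self.max_len}")
        x = self.tok(ids) + self.pos(np.arange(T))
        if extra is not None:
            x = x + extra
        for layer in self.layers:
            x = layer(x)
        return self.ln_f(x)


class LSTMDirection(Module):
    def __init__(self, d_in: int, d_h: int, rng: np.random.Generator):
        super().__init__()
        k = 1.0 / np.sqrt(d_h)
        self.d_h = d_h
        self.wx = self.add_param("wx", rng.uniform(-k, k, (d_in, 4 * d_h)).astype(DTYPE))
        self.wh = self.add_param("wh", rng.uniform(-k, k, (d_h, 4 * d_h)).astype(DTYPE))
        self.b = self.add_param("b", np.zeros(4 * d_h, dtype=DTYPE))

    def __call__(self, x: Tensor, reverse: bool = False) -> Tensor:
        B, T, _ = x.shape
        dh = self.d_h
        h = Tensor(np.zeros((B, dh), dtype=DTYPE))
        c = Tensor(np.zeros((B, dh), dtype=DTYPE))
        steps = range(T - 1, -1, -1) if reverse else range(T)
        outs: list[Tensor | None] = [None] * T
        for t in steps:
            g = x[:, t, :] @ self.wx + h @ self.wh + self.b
            i = g[:, :dh].sigmoid()
            f = g[:, dh : 2 * dh].sigmoid()
            o = g[:, 2 * dh : 3 * dh].sigmoid()
            u = g[:, 3 * dh :].tanh()
            c = f * c + i * u
            h = o * c.tanh()
            outs[t] = h
        return Tensor.stack(outs, axis=1)  # (B,T,dh)


class BiLSTMEncoder(Module):
    """Bidirectional LSTM baseline: forward and backward passes concatenated.

    ``hidden_width`` must be even; each direction contributes half of every
    output vector.
    """

    kind = "bilstm"

    def __init__(self, vocab_size: int, d: int = 128, layers: int = 1, heads: int = 0,
                 max_len: int = 256, seed: int = 0):
        super().__init__()
        if d % 2:
            raise ValueError("bilstm hidden width must be even")
        rng = np.random.default_rng(seed)
        self.vocab_size, self.d_model, self.n_layers = vocab_size, d, layers
        self.heads, self.max_len, self.seed = 0, max_len, seed
        self.tok = self.add_module("tok", Embedding(vocab_size, d, rng))
        self.fwd: list[LSTMDirection] = []
        self.bwd: list[LSTMDirection] = []
        for i in range(layers):
            d_in = d
            self.fwd.append(self.add_module(f"fwd{i}", LSTMDirection(d_in, d // 2, rng)))
            self.bwd.append(self.add_module(f"bwd{i}", LSTMDirection(d_in, d // 2, rng)))

    def config(self) -> dict:
        return {"kind": self.kind, "vocab_size": self.vocab_size, "hidden_width": self.d_model,
                "layers": self.n_layers, "heads": 0, "max_len": self.max_len, "seed": self.seed}

    def __call__(self, ids: np.ndarray, extra: Tensor | None = None) -> Tensor:
        ids = np.asarray(ids, dtype=np.intp)
        if ids.shape[1] > self.max_len:
            raise ValueError(f"sequence length {ids.shape[1]} exceeds maximum {self.max_len}")
        x = self.tok(ids)
        if extra is not None:
            x = x + extra
        for f, b in zip(self.fwd, self.bwd):
            x = Tensor.concatenate([f(x), b(x, reverse=True)], axis=-1)
        return x


ENCODER_KINDS = {"transformer": TransformerEncoder, "bilstm": BiLSTMEncoder}


def build_encoder(kind: str, vocab_size: int, hidden_width: int = 128, layers: int = 2,
                  heads: int = 4, max_len: int = 256, seed: int = 0) -> Module:
    if kind not in ENCODER_KINDS:
        raise ValueError(f"unknown encoder kind {kind!r}")
    return ENCODER_KINDS[kind](vocab_size, hidden_width, layers, heads, max_len, seed)


def encoder_from_config(cfg: dict) -> Module:
    return build_encoder(cfg["kind"], cfg["vocab_size"], cfg["hidden_width"],
                         cfg["layers"], cfg.get("heads", 0) or 4, cfg["max_len"], cfg["seed"])
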