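"""Neural-network building blocks used by the PSI model.

Layers operate on (3, n_pairs, width) tensors — one slice per structure
(reactant, interpolated, product), one row per atom pair — using batched
matmuls, so every operation is permutation-equivariant over the pair axis by
construction. Projections are row-wise and therefore shared across slices;
only the attention softmax couples rows, and only within a slice.

Weights are float64; initialization is Glorot-uniform from an explicit
numpy Generator so runs are exactly reproducible.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, concatenate


class Module:
    """Base class: named-parameter registry with nesting."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._children: dict[str, "Module"] = {}

    def add_param(self, name: str, value: np.ndarray) -> Tensor:
        t = Tensor(np.asarray(value, dtype=np.float64), requires_grad=True)
        self._params[name] = t
        return t

    def add_child(self, name: str, module: "Module") -> "Module":
        self._children[name] = module
        return module

    def named_parameters(self, prefix: str = ""):
        for name, p in self._params.items():
            yield prefix + name, p
        for cname, child in self._children.items():
            yield from child.named_parameters(prefix + cname + ".")

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        extra = set(state) - set(own)
        if missing or extra:
            raise ValueError(f"state dict mismatch: missing={missing}, extra={extra}")
        for name, p in own.items():
            arr = np.asarray(state[name], dtype=np.float64)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {name}")
            p.data = arr.copy()

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape=None):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape or (fan_in, fan_out))


class Dense(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 zero_init: bool = False):
        super().__init__()
        w = np.zeros((d_in, d_out)) if zero_init else glorot(rng, d_in, d_out)
        self.w = self.add_param("w", w)
        self.b = self.add_param("b", np.zeros(d_out))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.w + self.b


class LayerNorm(Module):
    def __init__(self, width: int, eps: float = 1e-6):
        super().__init__()
        self.gamma = self.add_param("gamma", np.ones(width))
        self.beta = self.add_param("beta", np.zeros(width))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc / (var + self.eps).sqrt() * self.gamma + self.beta


class MultiHeadSelfAttention(Module):
    """Scaled dot-product self-attention over the pair axis, per slice.

    Input (3, rows, width); the QKV/output projections are fused into single
    matmuls and attention is batched over (slice, head).
    """

    def __init__(self, width: int, n_heads: int, rng: np.random.Generator):
        super().__init__()
        if width % n_heads:
            raise ValueError(f"width {width} not divisible by {n_heads} heads")
        self.n_heads = n_heads
        self.d_head = width // n_heads
        self.wqkv = self.add_param("wqkv", glorot(rng, width, width,
                                                  shape=(width, 3 * width)))
        self.wo = self.add_param("wo", glorot(rng, width, width))

    def __call__(self, x: Tensor, blocks=None) -> Tensor:
        """``blocks`` — (start, stop) row ranges that attend only within
        themselves (one range per reaction in a batch); None = one block."""
        n_slices, n_rows, width = x.shape
        h, dh = self.n_heads, self.d_head
        qkv = x @ self.wqkv  # (3, rows, 3*width)
        # -> (3, rows, 3, h, dh) -> (3(qkv), slices, h, rows, dh)
        qkv = qkv.reshape(n_slices, n_rows, 3, h, dh).transpose(2, 0, 3, 1, 4)
        q, k, v = qkv[0], qkv[1], qkv[2]
        if blocks is None:
            blocks = [(0, n_rows)]
        outs = []
        for start, stop in blocks:
            sl = (slice(None), slice(None), slice(start, stop), slice(None))
            qb, kb, vb = q[sl], k[sl], v[sl]
            scores = (qb @ kb.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(dh))
            outs.append(scores.softmax(axis=-1) @ vb)
        out = concatenate(outs, axis=2) if len(outs) > 1 else outs[0]
        out = out.transpose(0, 2, 1, 3).reshape(n_slices, n_rows, width)
        return out @ self.wo


class TransformerEncoderBlock(Module):
    """Pre-norm encoder block: x + MHA(LN(x)), then x + FFN(LN(x))."""

    def __init__(self, width: int, n_heads: int, ffn_mult: int,
                 rng: np.random.Generator):
        super().__init__()
        self.ln1 = self.add_child("ln1", LayerNorm(width))
        self.attn = self.add_child("attn", MultiHeadSelfAttention(width, n_heads, rng))
        self.ln2 = self.add_child("ln2", LayerNorm(width))
        self.ffn1 = self.add_child("ffn1", Dense(width, ffn_mult * width, rng))
        self.ffn2 = self.add_child("ffn2", Dense(ffn_mult * width, width, rng))

    def __call__(self, x: Tensor, blocks=None) -> Tensor:
        x = x + self.attn(self.ln1(x), blocks)
        return x + self.ffn2(self.ffn1(self.ln2(x)).relu())


class GRUCell(Module):
    """Gated recurrent unit with fused gate matmuls; hidden width = input width."""

    def __init__(self, width: int, rng: np.random.Generator):
        super().__init__()
        self.w = self.add_param("w", glorot(rng, width, width, shape=(width, 3 * width)))
        self.u = self.add_param("u", glorot(rng, width, width, shape=(width, 3 * width)))
        self.b = self.add_param("b", np.zeros(3 * width))
        self.width = width

    def __call__(self, x: Tensor, h: Tensor) -> Tensor:
        d = self.width
        gx = x @ self.w + self.b
        gh = h @ self.u
        z = (gx[:, :d] + gh[:, :d]).sigmoid()
        r = (gx[:, d:2 * d] + gh[:, d:2 * d]).sigmoid()
        n = (gx[:, 2 * d:] + r * gh[:, 2 * d:]).tanh()
        return (1.0 - z) * n + z * h


class BiGRU(Module):
    """Bidirectional GRU over the length-3 structure sequence.

    Consumes (3, rows, w) and emits per position the concatenated
    forward/backward hidden states: (3, rows, 2w).
    """

    def __init__(self, width: int, rng: np.random.Generator):
        super().__init__()
        self.fwd = self.add_child("fwd", GRUCell(width, rng))
        self.bwd = self.add_child("bwd", GRUCell(width, rng))
        self.width = width

    def __call__(self, x: Tensor) -> Tensor:
        from .autodiff import stack

        n_slices, n_rows, _ = x.shape
        h0 = Tensor(np.zeros((n_rows, self.width)))
        hs_f, h = [], h0
        for t in range(n_slices):
            h = self.fwd(x[t], h)
            hs_f.append(h)
        hs_b, h = [], h0
        for t in reversed(range(n_slices)):
            h = self.bwd(x[t], h)
            hs_b.append(h)
        hs_b.reverse()
        return stack(
            [concatenate([f, b], axis=1) for f, b in zip(hs_f, hs_b)], axis=0
        )


class MLPHead(Module):
    """Two-layer readout. The output layer is zero-initialized so a freshly
    constructed model predicts the identity ratio (exp(0) = 1)."""

    def __init__(self, d_in: int, hidden: int, d_out: int,
                 rng: np.random.Generator, zero_out: bool = True):
        super().__init__()
        self.fc1 = self.add_child("fc1", Dense(d_in, hidden, rng))
        self.fc2 = self.add_child("fc2", Dense(hidden, d_out, rng, zero_init=zero_out))

    def __call__(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).relu())


class Adam:
    """Adam optimizer over a parameter list."""

    def __init__(self, params: list[Tensor], lr: float = 1e-4,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        self.t += 1
        for k, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
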