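"""Neural building blocks of the tagger.

The network is: token embeddings (optionally replaced by a contextual
encoder's sum-pooled subword vectors, optionally concatenated with a
masked-manner feature embedding) -> BiLSTM -> T layers of bidirectional
graph convolution over the matching graph -> token-wise softmax classifier.

Gate equations follow the classic LSTM formulation: input, forget and output
gates are sigmoids of affine maps of [h_{t-1}, x_t]; the candidate state is a
tanh; the cell mixes candidate and previous cell through the gates.  Each
graph layer computes

    Q_out = relu(rownorm(A_out) @ H @ W_out)
    Q_in  = relu(rownorm(A_in)  @ H @ W_in)
    H'    = LayerNorm(H + relu([Q_out, Q_in] @ W_O))

i.e. the forward branch aggregates, at each match's first token, the state of
its last token, and the backward branch the reverse; the two directions are
fused every layer and a residual connection keeps the encoder states for
tokens that participate in no match (their adjacency rows are all zero, so
they receive only the residual path).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

__all__ = [
    "Parameters",
    "glorot",
    "row_normalize",
    "LSTMCell",
    "run_lstm",
    "BiGCNLayer",
    "AdamOptimizer",
]


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


class Parameters(dict):
    """Named trainable tensors with grad bookkeeping."""

    def new(self, name: str, array: np.ndarray) -> Tensor:
        t = Tensor(array)
        self[name] = t
        return t

    def zero_grad(self) -> None:
        for t in self.values():
            t.grad = None

    def state(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.items()}

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        for k, v in self.items():
            v.data = np.array(state[k], dtype=np.float64)


def row_normalize(a: np.ndarray) -> np.ndarray:
    """Divide each nonzero row of a binary adjacency by its row sum.

    All-zero rows stay all-zero, so isolated tokens aggregate nothing rather
    than dividing by zero.
    """
    a = np.asarray(a, dtype=np.float64)
    sums = a.sum(axis=1, keepdims=True)
    sums[sums == 0.0] = 1.0
    return a / sums


class LSTMCell:
    """One direction of the recurrent encoder; gate order is [i, f, o, g]."""

    def __init__(self, params: Parameters, prefix: str, d_in: int, d_h: int,
                 rng: np.random.Generator):
        self.d_h = d_h
        self.wx = params.new(f"{prefix}.wx", glorot(rng, d_in, 4 * d_h))
        self.wh = params.new(f"{prefix}.wh", glorot(rng, d_h, 4 * d_h))
        b = np.zeros((1, 4 * d_h))
        b[0, d_h : 2 * d_h] = 1.0  # forget-gate bias at 1: standard retention init
        self.b = params.new(f"{prefix}.b", b)

    def run(self, xs: Tensor, reverse: bool = False) -> Tensor:
        """Run over an L x d_in sequence; returns L x d_h hidden states."""
        L = xs.data.shape[0]
        d = self.d_h
        xw = ad.add(ad.matmul(xs, self.wx), self.b)  # L x 4d, bias broadcast
        h = Tensor(np.zeros((1, d)))
        c = Tensor(np.zeros((1, d)))
        order = range(L - 1, -1, -1) if reverse else range(L)
        out: list[Tensor | None] = [None] * L
        for t in order:
            z = ad.add(ad.row(xw, t), ad.matmul(h, self.wh))
            i = ad.sigmoid(ad.cols(z, 0, d))
            f = ad.sigmoid(ad.cols(z, d, 2 * d))
            o = ad.sigmoid(ad.cols(z, 2 * d, 3 * d))
            g = ad.tanh(ad.cols(z, 3 * d, 4 * d))
            c = ad.add(ad.mul(f, c), ad.mul(i, g))
            h = ad.mul(o, ad.tanh(c))
            out[t] = h
        return ad.vstack_rows(out)  # type: ignore[arg-type]


def run_lstm(fwd: LSTMCell, bwd: LSTMCell, xs: Tensor) -> Tensor:
    """Bidirectional pass: concatenate forward and backward states per token."""
    return ad.concat_cols([fwd.run(xs), bwd.run(xs, reverse=True)])


class BiGCNLayer:
    """One bidirectional graph-convolution layer over the matching graph.

    Ablations: ``single_gcn`` drops the backward branch (fusion becomes
    d_h x d_h); ``no_residual`` drops the H_t term inside the normalization;
    ``fuse=False`` (late fusion) returns the two branch updates separately so
    the caller can merge them only after the last layer.
    """

    def __init__(self, params: Parameters, prefix: str, d_h: int,
                 rng: np.random.Generator, single_gcn: bool = False):
        self.single_gcn = single_gcn
        self.w_out = params.new(f"{prefix}.w_out", glorot(rng, d_h, d_h))
        if not single_gcn:
            self.w_in = params.new(f"{prefix}.w_in", glorot(rng, d_h, d_h))
        fan = d_h if single_gcn else 2 * d_h
        self.w_o = params.new(f"{prefix}.w_o", glorot(rng, fan, d_h))

    def branches(self, h: Tensor, a_out_n: Tensor, a_in_n: Tensor) -> tuple[Tensor, Tensor | None]:
        if a_out_n.data.shape[1] != h.data.shape[0]:
            raise ValueError(
                f"adjacency of shape {a_out_n.data.shape} does not match "
                f"hidden states of shape {h.data.shape}"
            )
        q_out = ad.relu(ad.matmul(ad.matmul(a_out_n, h), self.w_out))
        if self.single_gcn:
            return q_out, None
        q_in = ad.relu(ad.matmul(ad.matmul(a_in_n, h), self.w_in))
        return q_out, q_in

    def fuse(self, q_out: Tensor, q_in: Tensor | None) -> Tensor:
        merged = q_out if q_in is None else ad.concat_cols([q_out, q_in])
        return ad.relu(ad.matmul(merged, self.w_o))

    def forward(self, h: Tensor, a_out_n: Tensor, a_in_n: Tensor,
                no_residual: bool = False) -> Tensor:
        update = self.fuse(*self.branches(h, a_out_n, a_in_n))
        pre = update if no_residual else ad.add(h, update)
        return ad.layer_norm(pre)

    def prenorm(self, h: Tensor, a_out_n: Tensor, a_in_n: Tensor) -> Tensor:
        """Residual input before normalization — exposed for inspection."""
        return ad.add(h, self.fuse(*self.branches(h, a_out_n, a_in_n)))


class AdamOptimizer:
    def __init__(self, params: Parameters, lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(v.data) for k, v in params.items()}
        self.v = {k: np.zeros_like(v.data) for k, v in params.items()}

    def step(self, lr: float | None = None) -> None:
        lr = self.lr if lr is None else lr
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for k, p in self.params.items():
            if p.grad is None:
                continue
            m = self.m[k]
            v = self.v[k]
            m *= self.b1
            m += (1.0 - self.b1) * p.grad
            v *= self.b2
            v += (1.0 - self.b2) * p.grad**2
            p.data -= lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
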