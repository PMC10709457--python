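"""A small reverse-mode automatic-differentiation engine on NumPy arrays.

The tagger's computation graphs are tiny (a few hundred nodes per sentence),
so a dynamic tape of NumPy operations is fast enough on a single CPU and
keeps the whole package self-contained.  Only the operations the model needs
are provided; gradients are checked against finite differences in the test
suite.

All arrays are float64, 2-D unless noted.  ``Tensor`` wraps a value and, once
``backward()`` has run from a scalar root, holds ``grad`` of the same shape.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "add",
    "mul",
    "matmul",
    "sigmoid",
    "tanh",
    "relu",
    "row",
    "cols",
    "concat_cols",
    "vstack_rows",
    "layer_norm",
    "softmax_cross_entropy",
    "sum_squares",
    "scale",
]


class Tensor:
    __slots__ = ("data", "grad", "_parents", "_bw")

    def __init__(
        self,
        data,
        parents: tuple["Tensor", ...] = (),
        bw: Callable[[np.ndarray], None] | None = None,
    ):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self._parents = parents
        self._bw = bw

    @property
    def shape(self):
        return self.data.shape

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=np.float64)
        else:
            self.grad += g

    def backward(self) -> None:
        """Reverse-mode sweep from this (scalar) tensor."""
        if self.data.size != 1:
            raise ValueError("backward() must start from a scalar")
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
            for p in node._parents:
                if id(p) not in visited:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._bw is not None and node.grad is not None:
                node._bw(node.grad)

    # convenience operators
    def __add__(self, other: "Tensor") -> "Tensor":
        return add(self, other)

    def __mul__(self, other: "Tensor") -> "Tensor":
        return mul(self, other)

    def __matmul__(self, other: "Tensor") -> "Tensor":
        return matmul(self, other)


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum gradient ``g`` down to ``shape`` (inverse of NumPy broadcasting)."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def add(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data + b.data, (a, b))

    def bw(g):
        a._accumulate(_unbroadcast(g, a.data.shape))
        b._accumulate(_unbroadcast(g, b.data.shape))

    out._bw = bw
    return out


def mul(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data * b.data, (a, b))

    def bw(g):
        a._accumulate(_unbroadcast(g * b.data, a.data.shape))
        b._accumulate(_unbroadcast(g * a.data, b.data.shape))

    out._bw = bw
    return out


def scale(a: Tensor, c: float) -> Tensor:
    out = Tensor(a.data * c, (a,))
    out._bw = lambda g: a._accumulate(g * c)
    return out


def matmul(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data @ b.data, (a, b))

    def bw(g):
        a._accumulate(g @ b.data.T)
        b._accumulate(a.data.T @ g)

    out._bw = bw
    return out


def sigmoid(a: Tensor) -> Tensor:
    y = 1.0 / (1.0 + np.exp(-a.data))
    out = Tensor(y, (a,))
    out._bw = lambda g: a._accumulate(g * y * (1.0 - y))
    return out


def tanh(a: Tensor) -> Tensor:
    y = np.tanh(a.data)
    out = Tensor(y, (a,))
    out._bw = lambda g: a._accumulate(g * (1.0 - y * y))
    return out


def relu(a: Tensor) -> Tensor:
    mask = a.data > 0
    out = Tensor(a.data * mask, (a,))
    out._bw = lambda g: a._accumulate(g * mask)
    return out


def row(a: Tensor, i: int) -> Tensor:
    out = Tensor(a.data[i : i + 1], (a,))

    def bw(g):
        full = np.zeros_like(a.data)
        full[i : i + 1] = g
        a._accumulate(full)

    out._bw = bw
    return out


def cols(a: Tensor, j0: int, j1: int) -> Tensor:
    out = Tensor(a.data[:, j0:j1], (a,))

    def bw(g):
        full = np.zeros_like(a.data)
        full[:, j0:j1] = g
        a._accumulate(full)

    out._bw = bw
    return out


def concat_cols(parts: Sequence[Tensor]) -> Tensor:
    out = Tensor(np.concatenate([p.data for p in parts], axis=1), tuple(parts))
    splits = np.cumsum([p.data.shape[1] for p in parts])[:-1]

    def bw(g):
        for p, piece in zip(parts, np.split(g, splits, axis=1)):
            p._accumulate(piece)

    out._bw = bw
    return out


def vstack_rows(parts: Sequence[Tensor]) -> Tensor:
    """Stack 1 x d row tensors into an L x d tensor."""
    out = Tensor(np.concatenate([p.data for p in parts], axis=0), tuple(parts))
    splits = np.cumsum([p.data.shape[0] for p in parts])[:-1]

    def bw(g):
        for p, piece in zip(parts, np.split(g, splits, axis=0)):
            p._accumulate(piece)

    out._bw = bw
    return out


def layer_norm(a: Tensor, eps: float = 1e-5) -> Tensor:
    """Per-row layer normalization over the hidden (last) dimension.

    No learned gain/bias: the normalization is the plain standardization
    y = (x - mean) / sqrt(var + eps), which keeps the zero-graph case of the
    graph layers exactly analyzable.
    """
    mu = a.data.mean(axis=1, keepdims=True)
    xc = a.data - mu
    var = (xc * xc).mean(axis=1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    y = xc * inv
    out = Tensor(y, (a,))

    def bw(g):
        # dx = inv * (g - mean(g) - y * mean(g * y)), means over the row
        gm = g.mean(axis=1, keepdims=True)
        gym = (g * y).mean(axis=1, keepdims=True)
        a._accumulate(inv * (g - gm - y * gym))

    out._bw = bw
    return out


def softmax_cross_entropy(logits: Tensor, gold: np.ndarray) -> tuple[Tensor, np.ndarray]:
    """Summed negative log-likelihood over tokens, with the probabilities.

    ``gold`` is an int vector of class indices, one per row of ``logits``.
    The loss is the *sum* over rows (not the mean).  Returns (loss tensor,
    probability matrix as a plain array).
    """
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    ez = np.exp(z)
    probs = ez / ez.sum(axis=1, keepdims=True)
    n = logits.data.shape[0]
    nll = -np.log(probs[np.arange(n), gold] + 1e-300).sum()
    out = Tensor(nll, (logits,))

    def bw(g):
        d = probs.copy()
        d[np.arange(n), gold] -= 1.0
        logits._accumulate(float(g) * d)

    out._bw = bw
    return out, probs


def sum_squares(a: Tensor) -> Tensor:
    out = Tensor((a.data * a.data).sum(), (a,))
    out._bw = lambda g: a._accumulate(2.0 * float(g) * a.data)
    return out
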