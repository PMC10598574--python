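"""Minimal reverse-mode automatic differentiation over numpy arrays.

The engine provides exactly the operations the synergy network needs:
broadcast arithmetic, matrix products, row gather/scatter, concatenation,
the usual elementwise nonlinearities, and a piecewise robust-regression
loss. Gradients are accumulated by a topological backward sweep; tests
check every primitive against central finite differences.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "Linear",
    "Adam",
    "as_tensor",
    "concat",
    "gather_rows",
    "segment_sum",
    "relu",
    "leaky_relu",
    "softplus",
    "sigmoid",
    "exp",
    "smooth_l1",
    "dropout",
    "clip_global_norm",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing numpy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum leading broadcast axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A numpy array with an optional gradient tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- bookkeeping ---------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={'yes' if self.requires_grad else 'no'})"

    def _traced(self) -> bool:
        return self.requires_grad or bool(self._parents)

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def item(self) -> float:
        return float(self.data)

    # -- graph construction -------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        if any(p._traced() for p in parents):
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, g: np.ndarray):
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad: np.ndarray | None = None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen and p._traced():
                    stack.append((p, False))
        self._accum(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic ----------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)

        def bwd(g, a=self, b=other):
            if a._traced():
                a._accum(_unbroadcast(g, a.shape))
            if b._traced():
                b._accum(_unbroadcast(g, b.shape))

        return Tensor._make(self.data + other.data, (self, other), bwd)

    __radd__ = __add__

    def __neg__(self):
        def bwd(g, a=self):
            if a._traced():
                a._accum(-g)

        return Tensor._make(-self.data, (self,), bwd)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)

        def bwd(g, a=self, b=other):
            if a._traced():
                a._accum(_unbroadcast(g * b.data, a.shape))
            if b._traced():
                b._accum(_unbroadcast(g * a.data, b.shape))

        return Tensor._make(self.data * other.data, (self, other), bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)

        def bwd(g, a=self, b=other):
            if a._traced():
                a._accum(_unbroadcast(g / b.data, a.shape))
            if b._traced():
                b._accum(_unbroadcast(-g * a.data / b.data**2, b.shape))

        return Tensor._make(self.data / other.data, (self, other), bwd)

    def __pow__(self, p: float):
        def bwd(g, a=self):
            if a._traced():
                a._accum(g * p * a.data ** (p - 1))

        return Tensor._make(self.data**p, (self,), bwd)

    def matmul(self, other):
        other = as_tensor(other)

        def bwd(g, a=self, b=other):
            if a._traced():
                a._accum(_unbroadcast(g @ np.swapaxes(b.data, -1, -2), a.shape))
            if b._traced():
                b._accum(_unbroadcast(np.swapaxes(a.data, -1, -2) @ g, b.shape))

        return Tensor._make(self.data @ other.data, (self, other), bwd)

    __matmul__ = matmul

    # -- reductions & shape --------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        def bwd(g, a=self):
            if not a._traced():
                return
            if axis is None:
                a._accum(np.broadcast_to(g, a.shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                a._accum(np.broadcast_to(gg, a.shape).copy())

        return Tensor._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), bwd)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    @property
    def T(self):
        def bwd(g, a=self):
            if a._traced():
                a._accum(g.T)

        return Tensor._make(self.data.T, (self,), bwd)

    def reshape(self, *shape):
        old = self.data.shape

        def bwd(g, a=self):
            if a._traced():
                a._accum(g.reshape(old))

        return Tensor._make(self.data.reshape(*shape), (self,), bwd)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# -- functional ops -----------------------------------------------------


def relu(x: Tensor) -> Tensor:
    x = as_tensor(x)
    mask = x.data > 0

    def bwd(g, a=x, m=mask):
        if a._traced():
            a._accum(g * m)

    return Tensor._make(np.where(mask, x.data, 0.0), (x,), bwd)


def leaky_relu(x: Tensor, alpha: float = 0.2) -> Tensor:
    x = as_tensor(x)
    mask = x.data > 0

    def bwd(g, a=x, m=mask):
        if a._traced():
            a._accum(g * np.where(m, 1.0, alpha))

    return Tensor._make(np.where(mask, x.data, alpha * x.data), (x,), bwd)


def softplus(x: Tensor) -> Tensor:
    """log(1 + exp(x)), numerically stable for large |x|."""
    x = as_tensor(x)
    out = np.logaddexp(0.0, x.data)
    sig = 1.0 / (1.0 + np.exp(-np.clip(x.data, -500, 500)))

    def bwd(g, a=x, s=sig):
        if a._traced():
            a._accum(g * s)

    return Tensor._make(out, (x,), bwd)


def sigmoid(x: Tensor) -> Tensor:
    x = as_tensor(x)
    s = 1.0 / (1.0 + np.exp(-np.clip(x.data, -500, 500)))

    def bwd(g, a=x, sv=s):
        if a._traced():
            a._accum(g * sv * (1.0 - sv))

    return Tensor._make(s, (x,), bwd)


def exp(x: Tensor) -> Tensor:
    x = as_tensor(x)
    e = np.exp(x.data)

    def bwd(g, a=x, ev=e):
        if a._traced():
            a._accum(g * ev)

    return Tensor._make(e, (x,), bwd)


def concat(tensors, axis: int = -1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g, ts=tensors):
        for t, piece in zip(ts, np.split(g, splits, axis=axis)):
            if t._traced():
                t._accum(piece)

    return Tensor._make(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), bwd)


def gather_rows(x: Tensor, idx) -> Tensor:
    """Select rows of a 2-D tensor; gradient scatter-adds back."""
    x = as_tensor(x)
    idx = np.asarray(idx, dtype=np.intp)

    def bwd(g, a=x, i=idx):
        if a._traced():
            buf = np.zeros_like(a.data)
            np.add.at(buf, i, g)
            a._accum(buf)

    return Tensor._make(x.data[idx], (x,), bwd)


def segment_sum(x: Tensor, idx, n_out: int) -> Tensor:
    """Sum rows of `x` into `n_out` buckets given per-row bucket indices."""
    x = as_tensor(x)
    idx = np.asarray(idx, dtype=np.intp)
    out = np.zeros((n_out,) + x.data.shape[1:])
    np.add.at(out, idx, x.data)

    def bwd(g, a=x, i=idx):
        if a._traced():
            a._accum(g[i])

    return Tensor._make(out, (x,), bwd)


def smooth_l1(pred: Tensor, target: Tensor) -> Tensor:
    """Elementwise robust loss: 0.5 r^2 for |r| < 1, |r| - 0.5 otherwise."""
    pred, target = as_tensor(pred), as_tensor(target)
    r = pred.data - target.data
    quad = np.abs(r) < 1.0
    val = np.where(quad, 0.5 * r * r, np.abs(r) - 0.5)
    dv = np.clip(r, -1.0, 1.0)  # derivative wrt pred, continuous, |.| <= 1

    def bwd(g, a=pred, b=target, d=dv):
        if a._traced():
            a._accum(_unbroadcast(g * d, a.shape))
        if b._traced():
            b._accum(_unbroadcast(-g * d, b.shape))

    return Tensor._make(val, (pred, target), bwd)


def dropout(x: Tensor, p: float, rng: np.random.Generator) -> Tensor:
    """Inverted dropout; identity when p == 0."""
    if p <= 0.0:
        return x
    x = as_tensor(x)
    keep = (rng.random(x.shape) >= p) / (1.0 - p)

    def bwd(g, a=x, k=keep):
        if a._traced():
            a._accum(g * k)

    return Tensor._make(x.data * keep, (x,), bwd)


# -- parameters ---------------------------------------------------------


class Linear:
    """Affine map x @ W + b with optional identity or custom init."""

    def __init__(
        self,
        n_in: int,
        n_out: int,
        rng: np.random.Generator | None = None,
        init: str = "glorot",
        bias: bool = True,
    ):
        if init == "identity":
            if n_in != n_out:
                raise ValueError("identity init requires square map")
            W = np.eye(n_in)
        elif init == "zeros":
            W = np.zeros((n_in, n_out))
        else:
            if rng is None:
                raise ValueError("glorot init requires an rng")
            lim = np.sqrt(6.0 / (n_in + n_out))
            W = rng.uniform(-lim, lim, size=(n_in, n_out))
        self.W = Tensor(W, requires_grad=True)
        self.b = Tensor(np.zeros(n_out), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = as_tensor(x) @ self.W
        if self.b is not None:
            out = out + self.b
        return out

    def tensors(self, prefix: str) -> dict[str, Tensor]:
        d = {f"{prefix}.W": self.W}
        if self.b is not None:
            d[f"{prefix}.b"] = self.b
        return d


def clip_global_norm(params: dict[str, Tensor], max_norm: float) -> float:
    """Scale all gradients so the global L2 norm is at most `max_norm`."""
    sq = 0.0
    for p in params.values():
        if p.grad is not None:
            sq += float((p.grad**2).sum())
    norm = np.sqrt(sq)
    if norm > max_norm > 0:
        scale = max_norm / norm
        for p in params.values():
            if p.grad is not None:
                p.grad *= scale
    return norm


class Adam:
    """Adam optimizer over a named parameter dict."""

    def __init__(self, params: dict[str, Tensor], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.weight_decay = weight_decay
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.t = 0

    def zero_grad(self):
        for p in self.params.values():
            p.grad = None

    def step(self):
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for k, p in self.params.items():
            if p.grad is None:
                continue
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * p.grad
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * p.grad**2
            p.data -= self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)
            if self.weight_decay > 0:
                p.data -= self.lr * self.weight_decay * p.data  # decoupled decay
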