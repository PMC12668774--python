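"""Minimal reverse-mode automatic differentiation over NumPy arrays.

The enhancement network has to train on a single CPU with only the
scientific Python stack available, so instead of depending on a deep
learning framework this module provides exactly the operator set the
model needs: 2-D/1-D convolutions, the axis-collapsing (n x 1)
convolution, per-channel outer products, dense layers, the usual
pointwise nonlinearities, and an Adam optimizer.  All math is float64
and single-threaded NumPy, which makes fixed-seed runs reproducible.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "Module",
    "Conv2d",
    "Conv1d",
    "Dense",
    "Adam",
    "add",
    "mul",
    "concat",
    "conv2d",
    "conv1d",
    "collapse_conv",
    "outer_self",
    "scale_channels",
    "dense",
    "global_avg_pool",
    "crop2d",
    "transpose_last2",
    "leaky_relu",
    "relu",
    "sigmoid",
    "softplus",
    "clamp_max",
    "mean_all",
    "l1_loss",
    "mse_loss",
]


class Tensor:
    """Array node in the autodiff graph.

    ``vjps`` is a sequence of ``(parent, fn)`` pairs where ``fn`` maps the
    gradient at this node to the gradient contribution for ``parent``.
    """

    __slots__ = ("data", "grad", "requires_grad", "_vjps")

    def __init__(self, data, requires_grad: bool = False, vjps=()):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p, _ in vjps)
        self._vjps = tuple(vjps) if self.requires_grad else ()
        self.grad = None

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- graph traversal ------------------------------------------------
    def backward(self, grad=None):
        """Accumulate gradients of this node into every reachable parent."""
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for parent, _ in node._vjps:
                stack.append((parent, False))
        for node in topo:
            node.grad = None
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            g = node.grad
            for parent, vjp in node._vjps:
                if not parent.requires_grad:
                    continue
                contrib = vjp(g)
                parent.grad = contrib if parent.grad is None else parent.grad + contrib

    # -- operator sugar -------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __sub__(self, other):
        return add(self, mul(other, -1.0))

    def __rsub__(self, other):
        return add(mul(self, -1.0), other)

    def __neg__(self):
        return mul(self, -1.0)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``g`` down to ``shape`` (reverse of NumPy broadcasting)."""
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g.reshape(shape)


# ---------------------------------------------------------------------------
# elementwise / structural ops
# ---------------------------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    return Tensor(
        a.data + b.data,
        vjps=[
            (a, lambda g: _unbroadcast(g, a.data.shape)),
            (b, lambda g: _unbroadcast(g, b.data.shape)),
        ],
    )


def mul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    return Tensor(
        a.data * b.data,
        vjps=[
            (a, lambda g: _unbroadcast(g * b.data, a.data.shape)),
            (b, lambda g: _unbroadcast(g * a.data, b.data.shape)),
        ],
    )


def concat(tensors, axis: int = 1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)
    out = np.concatenate([t.data for t in tensors], axis=axis)

    def make_vjp(lo, hi):
        def vjp(g):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            return g[tuple(sl)]

        return vjp

    vjps = [(t, make_vjp(offsets[i], offsets[i + 1])) for i, t in enumerate(tensors)]
    return Tensor(out, vjps=vjps)


def crop2d(x, r0: int, r1: int, c0: int, c1: int) -> Tensor:
    """Crop the trailing two axes to ``[r0:r1, c0:c1]``."""
    x = as_tensor(x)

    def vjp(g):
        gx = np.zeros_like(x.data)
        gx[..., r0:r1, c0:c1] = g
        return gx

    return Tensor(x.data[..., r0:r1, c0:c1], vjps=[(x, vjp)])


def transpose_last2(x) -> Tensor:
    x = as_tensor(x)
    return Tensor(
        np.swapaxes(x.data, -1, -2),
        vjps=[(x, lambda g: np.swapaxes(g, -1, -2))],
    )


def leaky_relu(x, alpha: float = 0.1) -> Tensor:
    x = as_tensor(x)
    mask = np.where(x.data > 0, 1.0, alpha)
    return Tensor(x.data * mask, vjps=[(x, lambda g: g * mask)])


def relu(x) -> Tensor:
    return leaky_relu(x, alpha=0.0)


def sigmoid(x) -> Tensor:
    x = as_tensor(x)
    out = 0.5 * (1.0 + np.tanh(0.5 * x.data))  # numerically stable
    return Tensor(out, vjps=[(x, lambda g: g * out * (1.0 - out))])


def softplus(x) -> Tensor:
    x = as_tensor(x)
    out = np.logaddexp(0.0, x.data)
    sig = 0.5 * (1.0 + np.tanh(0.5 * x.data))
    return Tensor(out, vjps=[(x, lambda g: g * sig)])


def clamp_max(x, hi: float) -> Tensor:
    x = as_tensor(x)
    mask = (x.data < hi).astype(np.float64)
    return Tensor(np.minimum(x.data, hi), vjps=[(x, lambda g: g * mask)])


def mean_all(x) -> Tensor:
    x = as_tensor(x)
    n = x.data.size

    def vjp(g):
        return np.full_like(x.data, float(g) / n)

    return Tensor(x.data.mean(), vjps=[(x, vjp)])


def global_avg_pool(x) -> Tensor:
    """(B, C, H, W) -> (B, C) mean over the spatial axes."""
    x = as_tensor(x)
    B, C, H, W = x.data.shape

    def vjp(g):
        return np.broadcast_to(g[:, :, None, None] / (H * W), x.data.shape).copy()

    return Tensor(x.data.mean(axis=(2, 3)), vjps=[(x, vjp)])


def abs_(x) -> Tensor:
    x = as_tensor(x)
    s = np.sign(x.data)
    return Tensor(np.abs(x.data), vjps=[(x, lambda g: g * s)])


def l1_loss(a, b) -> Tensor:
    return mean_all(abs_(add(a, mul(b, -1.0))))


def mse_loss(a, b) -> Tensor:
    d = add(a, mul(b, -1.0))
    return mean_all(mul(d, d))


# ---------------------------------------------------------------------------
# convolutions
# ---------------------------------------------------------------------------

def conv2d(x, w, b=None, stride: int = 1, pad: int = 0) -> Tensor:
    """2-D convolution; ``x`` (B, Ci, H, W), ``w`` (Co, Ci, kh, kw)."""
    x, w = as_tensor(x), as_tensor(w)
    B, Ci, H, W = x.data.shape
    Co, Ciw, kh, kw = w.data.shape
    if Ci != Ciw:
        raise ValueError(f"channel mismatch: input {Ci}, kernel {Ciw}")
    s = stride
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad))) if pad else x.data
    Hp, Wp = xp.shape[2:]
    oh = (Hp - kh) // s + 1
    ow = (Wp - kw) // s + 1
    out = np.zeros((B, Co, oh, ow))
    for u in range(kh):
        for v in range(kw):
            patch = xp[:, :, u : u + s * oh : s, v : v + s * ow : s]
            out += np.einsum("oc,bchw->bohw", w.data[:, :, u, v], patch, optimize=True)
    if b is not None:
        b = as_tensor(b)
        out += b.data[None, :, None, None]

    def vjp_x(g):
        gx = np.zeros_like(xp)
        for u in range(kh):
            for v in range(kw):
                gx[:, :, u : u + s * oh : s, v : v + s * ow : s] += np.einsum(
                    "oc,bohw->bchw", w.data[:, :, u, v], g, optimize=True
                )
        return gx[:, :, pad : pad + H, pad : pad + W] if pad else gx

    def vjp_w(g):
        gw = np.empty_like(w.data)
        for u in range(kh):
            for v in range(kw):
                patch = xp[:, :, u : u + s * oh : s, v : v + s * ow : s]
                gw[:, :, u, v] = np.einsum("bohw,bchw->oc", g, patch, optimize=True)
        return gw

    vjps = [(x, vjp_x), (w, vjp_w)]
    if b is not None:
        vjps.append((b, lambda g: g.sum(axis=(0, 2, 3))))
    return Tensor(out, vjps=vjps)


def conv1d(x, w, b=None, pad: int = 0) -> Tensor:
    """1-D convolution; ``x`` (B, Ci, n), ``w`` (Co, Ci, kw)."""
    x, w = as_tensor(x), as_tensor(w)
    B, Ci, n = x.data.shape
    Co, Ciw, kw = w.data.shape
    if Ci != Ciw:
        raise ValueError(f"channel mismatch: input {Ci}, kernel {Ciw}")
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad))) if pad else x.data
    on = xp.shape[2] - kw + 1
    out = np.zeros((B, Co, on))
    for v in range(kw):
        out += np.einsum("oc,bcn->bon", w.data[:, :, v], xp[:, :, v : v + on], optimize=True)
    if b is not None:
        b = as_tensor(b)
        out += b.data[None, :, None]

    def vjp_x(g):
        gx = np.zeros_like(xp)
        for v in range(kw):
            gx[:, :, v : v + on] += np.einsum("oc,bon->bcn", w.data[:, :, v], g, optimize=True)
        return gx[:, :, pad : pad + n] if pad else gx

    def vjp_w(g):
        gw = np.empty_like(w.data)
        for v in range(kw):
            gw[:, :, v] = np.einsum("bon,bcn->oc", g, xp[:, :, v : v + on], optimize=True)
        return gw

    vjps = [(x, vjp_x), (w, vjp_w)]
    if b is not None:
        vjps.append((b, lambda g: g.sum(axis=(0, 2))))
    return Tensor(out, vjps=vjps)


def collapse_conv(x, w, b=None) -> Tensor:
    """(n x 1)-kernel convolution collapsing the row axis.

    ``x`` (B, Ci, n, n) and ``w`` (Co, Ci, n) produce (B, Co, n): one
    length-n vector per output channel, out[b,o,j] = sum_ci w[o,c,i]*x[b,c,i,j].
    """
    x, w = as_tensor(x), as_tensor(w)
    if x.data.shape[1] != w.data.shape[1] or x.data.shape[2] != w.data.shape[2]:
        raise ValueError(
            f"collapse_conv shape mismatch: x {x.data.shape} vs kernel {w.data.shape}"
        )
    out = np.einsum("oci,bcij->boj", w.data, x.data, optimize=True)
    if b is not None:
        b = as_tensor(b)
        out += b.data[None, :, None]

    vjps = [
        (x, lambda g: np.einsum("oci,boj->bcij", w.data, g, optimize=True)),
        (w, lambda g: np.einsum("boj,bcij->oci", g, x.data, optimize=True)),
    ]
    if b is not None:
        vjps.append((b, lambda g: g.sum(axis=(0, 2))))
    return Tensor(out, vjps=vjps)


def outer_self(v) -> Tensor:
    """(B, C, n) -> (B, C, n, n) per-channel outer product v v^T."""
    v = as_tensor(v)

    def vjp(g):
        return np.einsum("bcij,bcj->bci", g, v.data, optimize=True) + np.einsum(
            "bcij,bci->bcj", g, v.data, optimize=True
        )

    out = v.data[:, :, :, None] * v.data[:, :, None, :]
    return Tensor(out, vjps=[(v, vjp)])


def scale_channels(x, s) -> Tensor:
    """Multiply (B, C, H, W) by per-sample channel gates (B, C)."""
    x, s = as_tensor(x), as_tensor(s)
    out = x.data * s.data[:, :, None, None]
    return Tensor(
        out,
        vjps=[
            (x, lambda g: g * s.data[:, :, None, None]),
            (s, lambda g: (g * x.data).sum(axis=(2, 3))),
        ],
    )


def dense(x, w, b=None) -> Tensor:
    """(B, C) @ (C, O) + b."""
    x, w = as_tensor(x), as_tensor(w)
    out = x.data @ w.data
    if b is not None:
        b = as_tensor(b)
        out = out + b.data[None, :]
    vjps = [
        (x, lambda g: g @ w.data.T),
        (w, lambda g: x.data.T @ g),
    ]
    if b is not None:
        vjps.append((b, lambda g: g.sum(axis=0)))
    return Tensor(out, vjps=vjps)


# ---------------------------------------------------------------------------
# modules & optimizer
# ---------------------------------------------------------------------------

class Module:
    """Tiny container base class with recursive parameter discovery."""

    def parameters(self) -> dict[str, Tensor]:
        out: dict[str, Tensor] = {}
        for name, val in vars(self).items():
            if isinstance(val, Tensor) and val.requires_grad:
                out[name] = val
            elif isinstance(val, Module):
                for key, sub in val.parameters().items():
                    out[f"{name}.{key}"] = sub
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        for key, sub in item.parameters().items():
                            out[f"{name}.{i}.{key}"] = sub
        return dict(sorted(out.items()))

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters().values())

    def state(self) -> dict[str, np.ndarray]:
        return {k: p.data.copy() for k, p in self.parameters().items()}

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        params = self.parameters()
        missing = set(params) - set(state)
        if missing:
            raise ValueError(f"checkpoint missing parameters: {sorted(missing)}")
        for key, param in params.items():
            arr = np.asarray(state[key], dtype=np.float64)
            if arr.shape != param.data.shape:
                raise ValueError(
                    f"shape mismatch for {key}: checkpoint {arr.shape} vs model {param.data.shape}"
                )
            param.data = arr.copy()


def he_init(rng: np.random.Generator, shape, fan_in: int) -> Tensor:
    scale = np.sqrt(2.0 / max(fan_in, 1))
    return Tensor(rng.normal(0.0, scale, size=shape), requires_grad=True)


class Conv2d(Module):
    def __init__(self, rng, c_in, c_out, k, stride=1, pad=0, bias_init=0.0):
        self.stride, self.pad = stride, pad
        self.w = he_init(rng, (c_out, c_in, k, k), c_in * k * k)
        self.b = Tensor(np.full(c_out, bias_init), requires_grad=True)

    def __call__(self, x):
        return conv2d(x, self.w, self.b, stride=self.stride, pad=self.pad)


class Conv1d(Module):
    def __init__(self, rng, c_in, c_out, k, pad=0):
        self.pad = pad
        self.w = he_init(rng, (c_out, c_in, k), c_in * k)
        self.b = Tensor(np.zeros(c_out), requires_grad=True)

    def __call__(self, x):
        return conv1d(x, self.w, self.b, pad=self.pad)


class Dense(Module):
    def __init__(self, rng, c_in, c_out):
        self.w = he_init(rng, (c_in, c_out), c_in)
        self.b = Tensor(np.zeros(c_out), requires_grad=True)

    def __call__(self, x):
        return dense(x, self.w, self.b)


class Adam:
    def __init__(self, params: dict[str, Tensor], lr=1e-4, betas=(0.9, 0.999), eps=1e-8):
        self.params = dict(sorted(params.items()))
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in self.params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in self.params.items()}

    def zero_grad(self):
        for p in self.params.values():
            p.grad = None

    def step(self):
        self.t += 1
        for key, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[key] = self.b1 * self.m[key] + (1 - self.b1) * g
            self.v[key] = self.b2 * self.v[key] + (1 - self.b2) * g * g
            mhat = self.m[key] / (1 - self.b1**self.t)
            vhat = self.v[key] / (1 - self.b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
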