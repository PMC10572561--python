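"""Minimal reverse-mode automatic differentiation on numpy arrays.

This module is the numerical substrate for the generator/discriminator
networks: a :class:`Tensor` wrapping an ``ndarray``, a small set of
differentiable primitives (elementwise math, reductions, matmul, 2-D
convolution and its transpose, concatenation/slicing), and an Adam
optimizer.  Backward functions are themselves written in terms of the same
primitives, so calling ``backward(create_graph=True)`` yields gradients that
are differentiable again — which is exactly what the WGAN gradient-penalty
term needs (a loss built from the gradient of the critic with respect to its
input).

Conventions: image tensors are NCHW; convolutions use explicit stride and
symmetric zero padding; dtypes are preserved (float32 throughout the
networks, float64 in numerical-gradient tests).
"""

from __future__ import annotations

import contextlib
from typing import Callable, Sequence

import numpy as np

__all__ = ["Tensor", "no_grad", "is_grad_enabled", "cat", "conv2d",
           "conv_transpose2d", "Adam"]

_GRAD_ENABLED = [True]


@contextlib.contextmanager
def no_grad():
    """Context manager disabling graph construction."""
    _GRAD_ENABLED.append(False)
    try:
        yield
    finally:
        _GRAD_ENABLED.pop()


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED[-1]


def _as_tensor(x, like: "Tensor | None" = None) -> "Tensor":
    if isinstance(x, Tensor):
        return x
    # python scalars adopt the companion tensor's dtype so that float32
    # graphs are not silently promoted to float64 by constants
    if like is not None and np.isscalar(x):
        return Tensor(np.asarray(x, dtype=like.dtype), requires_grad=False)
    return Tensor(np.asarray(x), requires_grad=False)


class Tensor:
    """An ndarray with an optional autodiff graph attached."""

    __slots__ = ("data", "requires_grad", "grad", "_parents", "_vjp")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.requires_grad = bool(requires_grad)
        self.grad: "Tensor | None" = None
        self._parents: tuple = ()
        self._vjp: Callable | None = None

    # -- construction of graph nodes -------------------------------------
    @staticmethod
    def _make(data, parents, vjp) -> "Tensor":
        req = is_grad_enabled() and any(p.requires_grad for p in parents)
        out = Tensor(data, requires_grad=req)
        if req:
            out._parents = tuple(parents)
            out._vjp = vjp
        return out

    # -- basic introspection ---------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    @property
    def size(self):
        return self.data.size

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    def __repr__(self):
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # -- backward ---------------------------------------------------------
    def backward(self, grad: "Tensor | None" = None,
                 create_graph: bool = False) -> None:
        """Accumulate gradients of ``self`` into ``.grad`` of all leaves.

        With ``create_graph=True`` the gradients are themselves graph
        nodes, enabling second-order terms (gradient penalty).
        """
        if grad is None:
            if self.size != 1:
                raise ValueError("backward() without an explicit gradient "
                                 "requires a scalar output")
            grad = Tensor(np.ones_like(self.data))

        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))

        grads: dict[int, Tensor] = {id(self): grad}
        ctx = contextlib.nullcontext() if create_graph else no_grad()
        with ctx:
            for node in reversed(topo):
                g = grads.pop(id(node), None)
                if g is None or node._vjp is None:
                    if g is not None and node._vjp is None:
                        node.grad = g if node.grad is None else node.grad + g
                    continue
                parent_grads = node._vjp(g)
                for p, pg in zip(node._parents, parent_grads):
                    if pg is None or not p.requires_grad:
                        continue
                    if id(p) in grads:
                        grads[id(p)] = grads[id(p)] + pg
                    else:
                        grads[id(p)] = pg

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        other = _as_tensor(other, like=self)
        data = self.data + other.data
        a, b = self, other
        return Tensor._make(data, (a, b), lambda g: (
            _unbroadcast(g, a.shape), _unbroadcast(g, b.shape)))

    __radd__ = __add__

    def __neg__(self):
        a = self
        return Tensor._make(-self.data, (a,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other, like=self) + (-self)

    def __mul__(self, other):
        other = _as_tensor(other, like=self)
        a, b = self, other
        data = a.data * b.data
        return Tensor._make(data, (a, b), lambda g: (
            _unbroadcast(g * b, a.shape), _unbroadcast(g * a, b.shape)))

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self * (_as_tensor(other) ** -1.0)

    def __rtruediv__(self, other):
        return _as_tensor(other, like=self) * (self ** -1.0)

    def __pow__(self, p: float):
        a = self
        data = self.data ** p
        return Tensor._make(data, (a,), lambda g: (g * (p * a ** (p - 1.0)),))

    # -- elementwise functions --------------------------------------------
    def exp(self):
        a = self
        out = Tensor._make(np.exp(self.data), (a,), None)
        if out.requires_grad:
            out._vjp = lambda g: (g * out,)
        return out

    def log(self):
        a = self
        return Tensor._make(np.log(self.data), (a,), lambda g: (g / a,))

    def sqrt(self):
        return self ** 0.5

    def tanh(self):
        a = self
        out = Tensor._make(np.tanh(self.data), (a,), None)
        if out.requires_grad:
            out._vjp = lambda g: (g * (1.0 - out * out),)
        return out

    def sigmoid(self):
        a = self
        with np.errstate(over="ignore"):
            y = np.where(self.data >= 0,
                         1.0 / (1.0 + np.exp(-self.data)),
                         np.exp(self.data) / (1.0 + np.exp(self.data)))
        out = Tensor._make(y, (a,), None)
        if out.requires_grad:
            out._vjp = lambda g: (g * out * (1.0 - out),)
        return out

    def logsigmoid(self):
        """Numerically stable log(sigmoid(x))."""
        a = self
        y = -np.logaddexp(0.0, -self.data)
        return Tensor._make(y, (a,), lambda g: (g * (-a).sigmoid(),))

    def leaky_relu(self, slope: float = 0.2):
        a = self
        mask = np.where(self.data > 0, 1.0, slope).astype(self.dtype)
        data = self.data * mask
        mask_t = Tensor(mask)
        return Tensor._make(data, (a,), lambda g: (g * mask_t,))

    def relu(self):
        return self.leaky_relu(0.0)

    def clamp(self, lo: float, hi: float):
        """Clip to [lo, hi]; gradient is passed only inside the range."""
        a = self
        mask = Tensor(((self.data > lo) & (self.data < hi))
                      .astype(self.dtype))
        data = np.clip(self.data, lo, hi)
        return Tensor._make(data, (a,), lambda g: (g * mask,))

    def abs(self):
        a = self
        sign = Tensor(np.sign(self.data))
        return Tensor._make(np.abs(self.data), (a,), lambda g: (g * sign,))

    # -- reductions / shaping ----------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        a = self
        data = self.data.sum(axis=axis, keepdims=keepdims)
        in_shape = self.shape

        def vjp(g):
            gd = g
            if axis is not None and not keepdims:
                ax = axis if isinstance(axis, tuple) else (axis,)
                shp = list(gd.shape)
                for i in sorted(a2 % len(in_shape) for a2 in ax):
                    shp.insert(i, 1)
                gd = gd.reshape(tuple(shp))
            return (gd.broadcast_to(in_shape),)

        return Tensor._make(data, (a,), vjp)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.size
        else:
            ax = axis if isinstance(axis, tuple) else (axis,)
            n = 1
            for i in ax:
                n *= self.shape[i]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, shape):
        a = self
        in_shape = self.shape
        return Tensor._make(self.data.reshape(shape), (a,),
                            lambda g: (g.reshape(in_shape),))

    def transpose(self, axes: Sequence[int]):
        a = self
        axes = tuple(axes)
        inv = tuple(np.argsort(axes))
        return Tensor._make(self.data.transpose(axes), (a,),
                            lambda g: (g.transpose(inv),))

    def broadcast_to(self, shape):
        a = self
        if self.shape == tuple(shape):
            return self
        data = np.broadcast_to(self.data, shape)
        in_shape = self.shape
        return Tensor._make(np.ascontiguousarray(data), (a,),
                            lambda g: (_unbroadcast(g, in_shape),))

    def __getitem__(self, idx):
        a = self
        in_shape = self.shape
        # np.asarray, not ascontiguousarray: the latter promotes 0-d to 1-d
        data = np.asarray(self.data[idx])
        return Tensor._make(data, (a,),
                            lambda g: (_scatter(g, idx, in_shape),))

    def matmul(self, other: "Tensor"):
        a, b = self, _as_tensor(other)
        data = a.data @ b.data
        return Tensor._make(data, (a, b), lambda g: (
            g.matmul(b.transpose((1, 0))), a.transpose((1, 0)).matmul(g)))

    __matmul__ = matmul


def _unbroadcast(g: Tensor, shape: tuple) -> Tensor:
    """Reduce a broadcast gradient back to ``shape``."""
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g.reshape(shape)


def _scatter(g: Tensor, idx, shape) -> Tensor:
    """Inverse of __getitem__: place ``g`` into a zero tensor of ``shape``."""
    parent = g

    def vjp(gg):
        return (gg[idx],)

    data = np.zeros(shape, dtype=g.dtype)
    basic = isinstance(idx, (int, slice)) or (
        isinstance(idx, tuple)
        and all(isinstance(i, (int, slice, type(Ellipsis))) for i in idx))
    if basic:      # non-overlapping view: plain assignment, much faster
        data[idx] = g.data
    else:
        np.add.at(data, idx, g.data)
    return Tensor._make(data, (parent,), vjp)


def grad(output: Tensor, wrt: Tensor, grad_output: Tensor | None = None,
         create_graph: bool = False) -> Tensor:
    """Gradient of ``output`` with respect to ``wrt`` only.

    Unlike :meth:`Tensor.backward`, nothing is accumulated into ``.grad``
    attributes, and only the subgraph connecting ``output`` to ``wrt`` is
    traversed — so evaluating a gradient penalty does not pollute parameter
    gradients.  With ``create_graph=True`` the result is differentiable.
    """
    if grad_output is None:
        if output.size != 1:
            raise ValueError("grad() of a non-scalar needs grad_output")
        grad_output = Tensor(np.ones_like(output.data))

    # mark nodes from which `wrt` is reachable through parent links
    needed: dict[int, bool] = {id(wrt): True}

    def is_needed(node: Tensor) -> bool:
        nid = id(node)
        if nid in needed:
            return needed[nid]
        needed[nid] = False  # guard against cycles (none exist, but safe)
        result = any(p.requires_grad and is_needed(p)
                     for p in node._parents)
        needed[nid] = result
        return result

    if not is_needed(output):
        return Tensor(np.zeros_like(wrt.data))

    topo: list[Tensor] = []
    seen: set[int] = set()
    stack2 = [(output, False)]
    while stack2:
        node, processed = stack2.pop()
        if processed:
            topo.append(node)
            continue
        if id(node) in seen:
            continue
        seen.add(id(node))
        stack2.append((node, True))
        for p in node._parents:
            if p.requires_grad and is_needed(p) and id(p) not in seen:
                stack2.append((p, False))

    grads: dict[int, Tensor] = {id(output): grad_output}
    result: Tensor | None = None
    ctx = contextlib.nullcontext() if create_graph else no_grad()
    with ctx:
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node is wrt:
                result = g if result is None else result + g
                continue
            if node._vjp is None:
                continue
            parent_grads = node._vjp(g)
            for p, pg in zip(node._parents, parent_grads):
                if pg is None or not p.requires_grad or not is_needed(p):
                    continue
                if id(p) in grads:
                    grads[id(p)] = grads[id(p)] + pg
                else:
                    grads[id(p)] = pg
    if result is None:
        result = Tensor(np.zeros_like(wrt.data))
    return result


def cat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    """Concatenate along ``axis``; backward slices the gradient apart."""
    tensors = [_as_tensor(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    offs = np.cumsum([0] + sizes)

    def vjp(g):
        outs = []
        for i in range(len(tensors)):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(int(offs[i]), int(offs[i + 1]))
            outs.append(g[tuple(sl)])
        return tuple(outs)

    return Tensor._make(data, tensors, vjp)


# ---------------------------------------------------------------------------
# convolution primitives
# ---------------------------------------------------------------------------

def _windows(xp: np.ndarray, kh: int, kw: int, stride: int) -> np.ndarray:
    """Sliding windows of a padded NCHW array → (N, C, OH, OW, kh, kw)."""
    v = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    return v[:, :, ::stride, ::stride]


def _conv2d_forward(x: np.ndarray, w: np.ndarray, stride: int,
                    padding: int) -> np.ndarray:
    n, c, h, wd = x.shape
    o, c2, kh, kw = w.shape
    if c != c2:
        raise ValueError(f"conv2d: input channels {c} != weight channels {c2}")
    xp = np.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    win = _windows(xp, kh, kw, stride)          # N,C,OH,OW,kh,kw
    oh, ow = win.shape[2], win.shape[3]
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * oh * ow, c * kh * kw)
    out = cols @ w.reshape(o, -1).T
    return np.ascontiguousarray(
        out.reshape(n, oh, ow, o).transpose(0, 3, 1, 2))


def _conv2d_wgrad(x: np.ndarray, g: np.ndarray, stride: int, padding: int,
                  kh: int, kw: int) -> np.ndarray:
    xp = np.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    win = _windows(xp, kh, kw, stride)
    oh, ow = g.shape[2], g.shape[3]
    win = win[:, :, :oh, :ow]
    return np.einsum("nchwij,nohw->ocij", win, g, optimize=True)


def _dilate(x: Tensor, stride: int, out_h: int, out_w: int) -> Tensor:
    """Insert stride-1 zeros between elements (adjoint of strided sampling)."""
    if stride == 1:
        n, c, h, w = x.shape
        if (h, w) == (out_h, out_w):
            return x
    parent = x
    n, c, h, w = x.shape
    data = np.zeros((n, c, out_h, out_w), dtype=x.dtype)
    data[:, :, ::stride, ::stride][:, :, :h, :w] = x.data

    def vjp(g):
        return (g[:, :, ::stride, ::stride][:, :, :h, :w],)

    return Tensor._make(data, (parent,), vjp)


def conv2d(x: Tensor, w: Tensor, stride: int = 1, padding: int = 0) -> Tensor:
    """2-D cross-correlation, NCHW × (O,C,kh,kw) → NCHW."""
    x, w = _as_tensor(x), _as_tensor(w)
    data = _conv2d_forward(x.data, w.data, stride, padding)
    kh, kw = w.shape[2], w.shape[3]
    x_shape = x.shape

    def vjp(g):
        gx = _conv2d_input_grad(g, w, stride, padding, x_shape)
        # weight gradient: plain numpy; differentiating it again (third
        # order) is not supported.
        gw_data = _conv2d_wgrad(x.data, g.data, stride, padding, kh, kw)
        return (gx, Tensor(gw_data))

    return Tensor._make(data, (x, w), vjp)


def _conv2d_input_grad(g: Tensor, w: Tensor, stride: int, padding: int,
                       x_shape: tuple) -> Tensor:
    """Gradient of conv2d w.r.t. its input, built from primitives so that it
    is differentiable again (needed for the gradient penalty)."""
    n, c, h, wd = x_shape
    kh, kw = w.shape[2], w.shape[3]
    # dilate the output gradient to stride-1 spacing over the padded extent
    dh, dw = h + 2 * padding - kh + 1, wd + 2 * padding - kw + 1
    gd = _dilate(g, stride, dh, dw)
    # full correlation with the spatially flipped, channel-swapped kernel
    w_rot = w[:, :, ::-1, ::-1].transpose((1, 0, 2, 3))
    gx_pad = conv2d(gd, w_rot, stride=1, padding=max(kh, kw) - 1)
    # crop the padding halo back to the input extent
    return gx_pad[:, :, padding:padding + h, padding:padding + wd]


def conv_transpose2d(x: Tensor, w: Tensor, stride: int = 1, padding: int = 0,
                     output_size: tuple | None = None) -> Tensor:
    """Transposed convolution (fractionally-strided), NCHW × (C,O,kh,kw).

    The weight layout follows the convention of the adjoint: ``w`` has shape
    (in_channels, out_channels, kh, kw).  ``output_size`` disambiguates the
    output extent when ``stride > 1``.
    """
    x, w = _as_tensor(x), _as_tensor(w)
    n, c, h, wd = x.shape
    c2, o, kh, kw = w.shape
    if c != c2:
        raise ValueError(f"conv_transpose2d: {c} != {c2} channels")
    if output_size is None:
        out_h = (h - 1) * stride - 2 * padding + kh
        out_w = (wd - 1) * stride - 2 * padding + kw
    else:
        out_h, out_w = output_size
    dh, dw = out_h + 2 * padding - kh + 1, out_w + 2 * padding - kw + 1
    gd = _dilate(x, stride, dh, dw)
    w_rot = w[:, :, ::-1, ::-1].transpose((1, 0, 2, 3))  # (O,C,kh,kw) flipped
    y_pad = conv2d(gd, w_rot, stride=1, padding=max(kh, kw) - 1)
    return y_pad[:, :, padding:padding + out_h, padding:padding + out_w]


# ---------------------------------------------------------------------------
# optimizer
# ---------------------------------------------------------------------------

class Adam:
    """Adam with per-parameter first/second moment estimates."""

    def __init__(self, params: Sequence[Tensor], lr: float = 2e-4,
                 betas: tuple = (0.5, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.b1, self.b2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad.data.astype(p.data.dtype, copy=False)
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            upd = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
            p.data = upd.astype(p.data.dtype, copy=False)

    def state_dict(self) -> dict:
        return {"t": self.t, "m": self.m, "v": self.v, "lr": self.lr}

    def load_state_dict(self, state: dict) -> None:
        self.t = state["t"]
        self.m = [np.array(m) for m in state["m"]]
        self.v = [np.array(v) for v in state["v"]]
        self.lr = float(state["lr"])
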