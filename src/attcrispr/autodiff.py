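"""Minimal reverse-mode automatic differentiation on numpy arrays.

This is the numerical core used by every trainable component of the
package: a :class:`Tensor` wrapping a float64 ``numpy.ndarray`` together
with a dynamically built computation graph, plus the handful of
primitives the architectures need (broadcast arithmetic, matmul,
2-D convolution, pooling reductions, sigmoid/tanh/ReLU/softplus,
row-softmax) and an Adam optimizer.

Everything is double precision and single-threaded numpy, which makes
training bit-reproducible for a fixed seed on a fixed platform.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "concatenate",
    "stack_rows",
    "conv2d",
    "softmax",
    "dropout",
    "Adam",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape``, undoing numpy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum over leading axes that were added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    # sum over axes that were size-1 in the original
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A node in the computation graph.

    Parameters are created with ``requires_grad=True``; everything built
    from them tracks gradients automatically.
    """

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        parents: tuple["Tensor", ...] = (),
        backward: Callable[[np.ndarray], None] | None = None,
    ) -> None:
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self._parents = parents
        self._backward = backward
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)

    # ------------------------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- graph construction helpers ------------------------------------
    def _accum(self, grad: np.ndarray) -> None:
        grad = np.asarray(grad, dtype=np.float64)
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad = self.grad + grad

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this node through the graph."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
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
        if grad is None:
            grad = np.ones_like(self.data)
        self._accum(grad)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic ----------------------------------------------------
    def __add__(self, other) -> "Tensor":
        other = as_tensor(other)
        out_data = self.data + other.data

        def bw(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        return Tensor(out_data, parents=(self, other), backward=bw)

    __radd__ = __add__

    def __mul__(self, other) -> "Tensor":
        other = as_tensor(other)
        out_data = self.data * other.data

        def bw(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        return Tensor(out_data, parents=(self, other), backward=bw)

    __rmul__ = __mul__

    def __neg__(self) -> "Tensor":
        return self * (-1.0)

    def __sub__(self, other) -> "Tensor":
        return self + (-as_tensor(other))

    def __rsub__(self, other) -> "Tensor":
        return as_tensor(other) + (-self)

    def __truediv__(self, other) -> "Tensor":
        other = as_tensor(other)
        return self * other ** (-1.0)

    def __rtruediv__(self, other) -> "Tensor":
        return as_tensor(other) * self ** (-1.0)

    def __pow__(self, p: float) -> "Tensor":
        out_data = self.data ** p

        def bw(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accum(g * p * self.data ** (p - 1.0))

        return Tensor(out_data, parents=(self,), backward=bw)

    def __matmul__(self, other) -> "Tensor":
        other = as_tensor(other)
        out_data = self.data @ other.data

        def bw(g: np.ndarray) -> None:
            a, b = self.data, other.data
            if self.requires_grad:
                if b.ndim == 1:
                    ga = np.multiply.outer(g, b) if a.ndim > 1 else g * b
                else:
                    ga = g @ np.swapaxes(b, -1, -2)
                self._accum(_unbroadcast(np.asarray(ga), a.shape))
            if other.requires_grad:
                if a.ndim == 1:
                    gb = np.multiply.outer(a, g) if b.ndim > 1 else a * g
                else:
                    gb = np.swapaxes(a, -1, -2) @ g
                other._accum(_unbroadcast(np.asarray(gb), b.shape))

        return Tensor(out_data, parents=(self, other), backward=bw)

    # -- reductions ------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bw(g: np.ndarray) -> None:
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape).copy())

        return Tensor(out_data, parents=(self,), backward=bw)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis: int, keepdims: bool = False) -> "Tensor":
        out_data = self.data.max(axis=axis, keepdims=keepdims)

        def bw(g: np.ndarray) -> None:
            if not self.requires_grad:
                return
            gk = g if keepdims else np.expand_dims(g, axis)
            mk = self.data.max(axis=axis, keepdims=True)
            mask = (self.data == mk).astype(np.float64)
            mask /= mask.sum(axis=axis, keepdims=True)  # split ties evenly
            self._accum(mask * gk)

        return Tensor(out_data, parents=(self,), backward=bw)

    # -- shape ops -------------------------------------------------------
    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out_data = self.data.reshape(shape)
        orig = self.data.shape

        def bw(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accum(g.reshape(orig))

        return Tensor(out_data, parents=(self,), backward=bw)

    def transpose(self, axes: Sequence[int]) -> "Tensor":
        out_data = self.data.transpose(axes)
        inv = np.argsort(axes)

        def bw(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accum(g.transpose(inv))

        return Tensor(out_data, parents=(self,), backward=bw)

    def swapaxes(self, a: int, b: int) -> "Tensor":
        out_data = np.swapaxes(self.data, a, b)

        def bw(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accum(np.swapaxes(g, a, b))

        return Tensor(out_data, parents=(self,), backward=bw)

    def __getitem__(self, idx) -> "Tensor":
        out_data = self.data[idx]

        def bw(g: np.ndarray) -> None:
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accum(full)

        return Tensor(out_data, parents=(self,), backward=bw)

    # -- nonlinearities --------------------------------------------------
    def exp(self) -> "Tensor":
        out_data = np.exp(self.data)

        def bw(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accum(g * out_data)

        return Tensor(out_data, parents=(self,), backward=bw)

    def log(self) -> "Tensor":
        out_data = np.log(self.data)

        def bw(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accum(g / self.data)

        return Tensor(out_data, parents=(self,), backward=bw)

    def sigmoid(self) -> "Tensor":
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def bw(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accum(g * out_data * (1.0 - out_data))

        return Tensor(out_data, parents=(self,), backward=bw)

    def tanh(self) -> "Tensor":
        out_data = np.tanh(self.data)

        def bw(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accum(g * (1.0 - out_data**2))

        return Tensor(out_data, parents=(self,), backward=bw)

    def relu(self) -> "Tensor":
        out_data = np.maximum(self.data, 0.0)

        def bw(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accum(g * (self.data > 0.0))

        return Tensor(out_data, parents=(self,), backward=bw)

    def softplus(self) -> "Tensor":
        # numerically stable log(1+exp(x))
        out_data = np.logaddexp(0.0, self.data)

        def bw(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accum(g / (1.0 + np.exp(-self.data)))

        return Tensor(out_data, parents=(self,), backward=bw)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concatenate(tensors: Sequence[Tensor], axis: int) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g: np.ndarray) -> None:
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    return Tensor(out_data, parents=tuple(tensors), backward=bw)


def stack_rows(tensors: Sequence[Tensor]) -> Tensor:
    """Stack a sequence of (B, h) tensors into (B, len, h)."""
    expanded = [t.reshape(t.shape[0], 1, t.shape[1]) for t in tensors]
    return concatenate(expanded, axis=1)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Softmax along ``axis`` (max-shift trick; the shift is a constant)."""
    shift = Tensor(x.data.max(axis=axis, keepdims=True))
    e = (x - shift).exp()
    return e / e.sum(axis=axis, keepdims=True)


def dropout(x: Tensor, p: float, rng: np.random.Generator | None) -> Tensor:
    """Inverted dropout; identity when ``rng`` is None (inference)."""
    if rng is None or p <= 0.0:
        return x
    mask = (rng.random(x.shape) >= p).astype(np.float64) / (1.0 - p)
    return x * Tensor(mask)


def conv2d(
    x: Tensor,
    w: Tensor,
    b: Tensor | None,
    pad: tuple[tuple[int, int], tuple[int, int]],
    pad_mode: str = "edge",
    pad_value: float = 0.0,
) -> Tensor:
    """2-D cross-correlation with explicit padding.

    ``x``: (B, C, H, W); ``w``: (F, C, kh, kw); ``b``: (F,) or None.
    Output: (B, F, H', W') with H' = H + ph0 + ph1 - kh + 1 etc.
    ``pad_mode`` is "edge" (replicate borders, avoiding boundary-row
    artifacts on short sequence images) or "constant" with ``pad_value``
    ("zero" is an alias for constant 0).
    """
    (ph0, ph1), (pw0, pw1) = pad
    pads = ((0, 0), (0, 0), (ph0, ph1), (pw0, pw1))
    if pad_mode == "edge":
        xd = np.pad(x.data, pads, mode="edge")
    else:
        xd = np.pad(x.data, pads, mode="constant", constant_values=pad_value)
    kh, kw = w.data.shape[2], w.data.shape[3]
    windows = np.lib.stride_tricks.sliding_window_view(xd, (kh, kw), axis=(2, 3))
    # windows: (B, C, H', W', kh, kw)
    out_data = np.einsum("bcijhw,fchw->bfij", windows, w.data, optimize=True)
    if b is not None:
        out_data = out_data + b.data[None, :, None, None]

    parents = (x, w) if b is None else (x, w, b)

    def bw(g: np.ndarray) -> None:
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))
        if w.requires_grad:
            gw = np.einsum("bcijhw,bfij->fchw", windows, g, optimize=True)
            w._accum(gw)
        if x.requires_grad:
            gx_pad = np.zeros_like(xd)
            ho, wo = g.shape[2], g.shape[3]
            for dh in range(kh):
                for dw in range(kw):
                    gx_pad[:, :, dh : dh + ho, dw : dw + wo] += np.einsum(
                        "bfij,fc->bcij", g, w.data[:, :, dh, dw], optimize=True
                    )
            H, W = x.data.shape[2], x.data.shape[3]
            if pad_mode == "edge":
                # fold border gradients back onto the replicated edge cells
                if ph0:
                    gx_pad[:, :, ph0, :] += gx_pad[:, :, :ph0, :].sum(axis=2)
                if ph1:
                    gx_pad[:, :, ph0 + H - 1, :] += gx_pad[:, :, ph0 + H :, :].sum(axis=2)
                if pw0:
                    gx_pad[:, :, :, pw0] += gx_pad[:, :, :, :pw0].sum(axis=3)
                if pw1:
                    gx_pad[:, :, :, pw0 + W - 1] += gx_pad[:, :, :, pw0 + W :].sum(axis=3)
            x._accum(gx_pad[:, :, ph0 : ph0 + H, pw0 : pw0 + W])

    return Tensor(out_data, parents=parents, backward=bw)


class Adam:
    """Adam optimizer over a name->Tensor parameter mapping."""

    def __init__(
        self,
        params: dict[str, Tensor],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ) -> None:
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.b1 * self.m[k] + (1.0 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1.0 - self.b2) * g * g
            mhat = self.m[k] / (1.0 - self.b1**self.t)
            vhat = self.v[k] / (1.0 - self.b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)


def glorot_uniform(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)
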