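"""Minimal reverse-mode automatic differentiation over NumPy arrays.

The segmentation network, its losses and the optimizer all operate on
:class:`Tensor`, a thin wrapper around an ``ndarray`` that records the
operations applied to it. Calling :meth:`Tensor.backward` on a scalar
result walks the recorded graph in reverse topological order and
accumulates gradients into every tensor created with
``requires_grad=True``.

Design notes:

* Dense primitives that dominate runtime (2-D convolution, transposed
  convolution, max pooling, layer/batch normalisation, softmax) carry
  hand-written vector-Jacobian products so the graph stays shallow and
  the heavy lifting happens inside BLAS calls.
* Elementwise ops support full NumPy broadcasting; gradients are summed
  back down to the operand shape (:func:`_unbroadcast`).
* Arrays keep the dtype they came in with. Model parameters are float32;
  gradient-checking tests may run the same graph in float64.
"""

from __future__ import annotations

import math
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy.special import erf

__all__ = ["Tensor", "astensor", "concat", "no_grad"]

_SQRT2 = math.sqrt(2.0)
_INV_SQRT_2PI = 1.0 / math.sqrt(2.0 * math.pi)

_grad_enabled = True


class no_grad:
    """Context manager disabling graph construction (inference mode)."""

    def __enter__(self):
        global _grad_enabled
        self._prev = _grad_enabled
        _grad_enabled = False
        return self

    def __exit__(self, *exc):
        global _grad_enabled
        _grad_enabled = self._prev
        return False


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over broadcast axes so it matches ``shape``."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_vjp")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        _parents: tuple["Tensor", ...] = (),
        _vjp: Callable[[np.ndarray], tuple[np.ndarray | None, ...]] | None = None,
    ):
        self.data = np.asarray(data)
        if self.data.dtype.kind in "iub":
            self.data = self.data.astype(np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents = _parents if _grad_enabled else ()
        self._vjp = _vjp if _grad_enabled else None

    # -- introspection -------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return f"Tensor(shape={self.shape}, grad={self.requires_grad})"

    # -- graph construction -------------------------------------------
    @staticmethod
    def _make(data, parents: tuple["Tensor", ...], vjp) -> "Tensor":
        needs = _grad_enabled and any(p.requires_grad or p._parents for p in parents)
        if not needs:
            return Tensor(data)
        out = Tensor(data, _parents=parents, _vjp=vjp)
        return out

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this tensor (scalar unless ``grad`` given)."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
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
                if id(p) not in seen:
                    stack.append((p, False))
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=self.data.dtype)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad:
                node.grad = g if node.grad is None else node.grad + g
            if node._vjp is None:
                continue
            parent_grads = node._vjp(g)
            for p, pg in zip(node._parents, parent_grads):
                if pg is None:
                    continue
                if id(p) in grads:
                    grads[id(p)] = grads[id(p)] + pg
                else:
                    grads[id(p)] = pg

    # -- elementwise arithmetic ----------------------------------------
    def __add__(self, other) -> "Tensor":
        if isinstance(other, (int, float)):
            a, c = self, other
            return Tensor._make(a.data + c, (a,), lambda g: (g,))
        other = astensor(other)
        a, b = self, other
        out = Tensor._make(
            a.data + b.data,
            (a, b),
            lambda g: (_unbroadcast(g, a.shape), _unbroadcast(g, b.shape)),
        )
        return out

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        return Tensor._make(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other) -> "Tensor":
        if isinstance(other, (int, float)):
            return self + (-other)
        return self + (-astensor(other))

    def __rsub__(self, other) -> "Tensor":
        if isinstance(other, (int, float)):
            a, c = self, other
            return Tensor._make(c - a.data, (a,), lambda g: (-g,))
        return astensor(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        if isinstance(other, (int, float)):
            a, c = self, other
            return Tensor._make(a.data * c, (a,), lambda g: (g * c,))
        other = astensor(other)
        a, b = self, other
        return Tensor._make(
            a.data * b.data,
            (a, b),
            lambda g: (
                _unbroadcast(g * b.data, a.shape),
                _unbroadcast(g * a.data, b.shape),
            ),
        )

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        if isinstance(other, (int, float)):
            return self * (1.0 / other)
        other = astensor(other)
        a, b = self, other
        return Tensor._make(
            a.data / b.data,
            (a, b),
            lambda g: (
                _unbroadcast(g / b.data, a.shape),
                _unbroadcast(-g * a.data / (b.data * b.data), b.shape),
            ),
        )

    def __rtruediv__(self, other) -> "Tensor":
        return astensor(other) / self

    def __pow__(self, exponent: float) -> "Tensor":
        if not np.isscalar(exponent):
            raise TypeError("only scalar exponents supported")
        a = self
        return Tensor._make(
            a.data**exponent,
            (a,),
            lambda g: (g * exponent * a.data ** (exponent - 1),),
        )

    def __matmul__(self, other) -> "Tensor":
        other = astensor(other)
        a, b = self, other

        def vjp(g):
            ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
            gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
            return _unbroadcast(ga, a.shape), _unbroadcast(gb, b.shape)

        return Tensor._make(np.matmul(a.data, b.data), (a, b), vjp)

    # -- shape manipulation --------------------------------------------
    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        a = self
        return Tensor._make(
            a.data.reshape(shape), (a,), lambda g: (g.reshape(a.shape),)
        )

    def transpose(self, *axes) -> "Tensor":
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        a = self
        inv = tuple(np.argsort(axes))
        return Tensor._make(
            a.data.transpose(axes), (a,), lambda g: (g.transpose(inv),)
        )

    # -- reductions -----------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        a = self

        def vjp(g):
            if axis is None:
                return (np.broadcast_to(g, a.shape).copy(),)
            g2 = g if keepdims else np.expand_dims(g, axis)
            return (np.broadcast_to(g2, a.shape).copy(),)

        return Tensor._make(a.data.sum(axis=axis, keepdims=keepdims), (a,), vjp)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        a = self
        if axis is None:
            n = a.data.size
        else:
            ax = (axis,) if np.isscalar(axis) else tuple(axis)
            n = int(np.prod([a.shape[i] for i in ax]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- nonlinearities --------------------------------------------------
    def relu(self) -> "Tensor":
        a = self
        mask = a.data > 0
        return Tensor._make(a.data * mask, (a,), lambda g: (g * mask,))

    def sigmoid(self) -> "Tensor":
        a = self
        x = a.data
        e = np.exp(-np.abs(x))
        s = np.where(x >= 0, 1.0 / (1.0 + e), e / (1.0 + e))
        return Tensor._make(s, (a,), lambda g: (g * s * (1.0 - s),))

    def gelu(self) -> "Tensor":
        """Exact (erf-based) Gaussian error linear unit."""
        a = self
        x = a.data
        cdf = 0.5 * (1.0 + erf(x / _SQRT2))
        out = x * cdf

        def vjp(g):
            pdf = _INV_SQRT_2PI * np.exp(-0.5 * x * x)
            return (g * (cdf + x * pdf),)

        return Tensor._make(out, (a,), vjp)

    def exp(self) -> "Tensor":
        a = self
        e = np.exp(a.data)
        return Tensor._make(e, (a,), lambda g: (g * e,))

    def log(self) -> "Tensor":
        a = self
        return Tensor._make(np.log(a.data), (a,), lambda g: (g / a.data,))

    def sqrt(self) -> "Tensor":
        a = self
        s = np.sqrt(a.data)
        return Tensor._make(s, (a,), lambda g: (g * 0.5 / s,))

    def clamp(self, lo: float, hi: float) -> "Tensor":
        """Clip values; gradient passes only inside the interval."""
        a = self
        out = np.clip(a.data, lo, hi)
        mask = (a.data >= lo) & (a.data <= hi)
        return Tensor._make(out, (a,), lambda g: (g * mask,))

    def softmax(self, axis: int = -1) -> "Tensor":
        a = self
        shifted = a.data - a.data.max(axis=axis, keepdims=True)
        e = np.exp(shifted)
        s = e / e.sum(axis=axis, keepdims=True)

        def vjp(g):
            dot = (g * s).sum(axis=axis, keepdims=True)
            return (s * (g - dot),)

        return Tensor._make(s, (a,), vjp)

    # -- dense spatial primitives ----------------------------------------
    def conv2d(
        self,
        weight: "Tensor",
        bias: "Tensor | None" = None,
        stride: int = 1,
        padding: int = 0,
    ) -> "Tensor":
        """2-D cross-correlation, NCHW layout, weight (Cout, Cin, k, k)."""
        x, w = self, weight
        B, C, H, W = x.shape
        Cout, Cin, k, _ = w.shape
        if Cin != C:
            raise ValueError(f"conv2d channel mismatch: input {C}, weight expects {Cin}")
        s, p = stride, padding
        Ho = (H + 2 * p - k) // s + 1
        Wo = (W + 2 * p - k) // s + 1
        xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p))) if p else x.data
        cols = np.empty((B, C, k, k, Ho, Wo), dtype=x.dtype)
        for u in range(k):
            for v in range(k):
                cols[:, :, u, v] = xp[:, :, u : u + (Ho - 1) * s + 1 : s,
                                      v : v + (Wo - 1) * s + 1 : s]
        cols2 = cols.reshape(B, C * k * k, Ho * Wo)
        wmat = w.data.reshape(Cout, C * k * k)
        out = np.matmul(wmat, cols2).reshape(B, Cout, Ho, Wo)
        if bias is not None:
            out = out + bias.data.reshape(1, Cout, 1, 1)

        def vjp(g):
            gmat = g.reshape(B, Cout, Ho * Wo)
            gw = np.einsum("bop,bfp->of", gmat, cols2).reshape(w.shape)
            gcols = np.matmul(wmat.T, gmat).reshape(B, C, k, k, Ho, Wo)
            gxp = np.zeros_like(xp)
            for u in range(k):
                for v in range(k):
                    gxp[:, :, u : u + (Ho - 1) * s + 1 : s,
                        v : v + (Wo - 1) * s + 1 : s] += gcols[:, :, u, v]
            gx = gxp[:, :, p : p + H, p : p + W] if p else gxp
            gb = g.sum(axis=(0, 2, 3)) if bias is not None else None
            return (gx, gw, gb) if bias is not None else (gx, gw)

        parents = (x, w, bias) if bias is not None else (x, w)
        return Tensor._make(out, parents, vjp)

    def conv_transpose2d(self, weight: "Tensor", bias: "Tensor | None" = None) -> "Tensor":
        """Transposed convolution, kernel 2, stride 2 (learned 2x upsampling).

        Weight layout (Cin, Cout, 2, 2); each input pixel paints a 2x2
        output patch.
        """
        x, w = self, weight
        B, C, H, W = x.shape
        Cin, Cout, k, _ = w.shape
        if Cin != C:
            raise ValueError(f"conv_transpose2d channel mismatch: {C} vs {Cin}")
        tmp = np.einsum("bihw,iokl->bohwkl", x.data, w.data)
        out = tmp.transpose(0, 1, 2, 4, 3, 5).reshape(B, Cout, H * k, W * k)
        if bias is not None:
            out = out + bias.data.reshape(1, Cout, 1, 1)

        def vjp(g):
            gtmp = g.reshape(B, Cout, H, k, W, k).transpose(0, 1, 2, 4, 3, 5)
            gx = np.einsum("bohwkl,iokl->bihw", gtmp, w.data)
            gw = np.einsum("bihw,bohwkl->iokl", x.data, gtmp)
            gb = g.sum(axis=(0, 2, 3)) if bias is not None else None
            return (gx, gw, gb) if bias is not None else (gx, gw)

        parents = (x, w, bias) if bias is not None else (x, w)
        return Tensor._make(out, parents, vjp)

    def maxpool2d(self) -> "Tensor":
        """2x2 max pooling with stride 2 (spatial dims must be even)."""
        x = self
        B, C, H, W = x.shape
        if H % 2 or W % 2:
            raise ValueError("maxpool2d requires even spatial dimensions")
        r = x.data.reshape(B, C, H // 2, 2, W // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        windows = r.reshape(B, C, H // 2, W // 2, 4)
        idx = windows.argmax(axis=-1)
        out = np.take_along_axis(windows, idx[..., None], axis=-1)[..., 0]

        def vjp(g):
            gwin = np.zeros_like(windows)
            np.put_along_axis(gwin, idx[..., None], g[..., None], axis=-1)
            gx = (
                gwin.reshape(B, C, H // 2, W // 2, 2, 2)
                .transpose(0, 1, 2, 4, 3, 5)
                .reshape(B, C, H, W)
            )
            return (gx,)

        return Tensor._make(out, (x,), vjp)

    def resize_bilinear(self, out_h: int, out_w: int) -> "Tensor":
        """Bilinear resampling to (out_h, out_w), half-pixel centers."""
        x = self
        B, C, H, W = x.shape
        if (out_h, out_w) == (H, W):
            return x

        def grid(n_out, n_in):
            coords = (np.arange(n_out) + 0.5) * n_in / n_out - 0.5
            coords = np.clip(coords, 0, n_in - 1)
            lo = np.floor(coords).astype(np.intp)
            hi = np.minimum(lo + 1, n_in - 1)
            frac = coords - lo
            return lo, hi, frac

        y0, y1, fy = grid(out_h, H)
        x0, x1, fx = grid(out_w, W)
        fy = fy[:, None]
        fx = fx[None, :]
        w00 = (1 - fy) * (1 - fx)
        w01 = (1 - fy) * fx
        w10 = fy * (1 - fx)
        w11 = fy * fx
        d = x.data
        out = (
            d[:, :, y0[:, None], x0[None, :]] * w00
            + d[:, :, y0[:, None], x1[None, :]] * w01
            + d[:, :, y1[:, None], x0[None, :]] * w10
            + d[:, :, y1[:, None], x1[None, :]] * w11
        )

        def vjp(g):
            gx_ = np.zeros_like(d)
            for ws, ys, xs in ((w00, y0, x0), (w01, y0, x1), (w10, y1, x0), (w11, y1, x1)):
                np.add.at(gx_, (slice(None), slice(None), ys[:, None], xs[None, :]), g * ws)
            return (gx_,)

        return Tensor._make(out.astype(d.dtype), (x,), vjp)

    def layer_norm(self, weight: "Tensor", bias: "Tensor", eps: float = 1e-5) -> "Tensor":
        """Normalise over the last axis, then scale and shift."""
        x, g_, b_ = self, weight, bias
        mu = x.data.mean(axis=-1, keepdims=True)
        var = x.data.var(axis=-1, keepdims=True)
        invstd = 1.0 / np.sqrt(var + eps)
        xhat = (x.data - mu) * invstd
        out = xhat * g_.data + b_.data
        n = x.shape[-1]

        def vjp(g):
            gxhat = g * g_.data
            gx = (
                invstd
                / n
                * (
                    n * gxhat
                    - gxhat.sum(axis=-1, keepdims=True)
                    - xhat * (gxhat * xhat).sum(axis=-1, keepdims=True)
                )
            )
            red = tuple(range(g.ndim - 1))
            return gx, (g * xhat).sum(axis=red), g.sum(axis=red)

        return Tensor._make(out, (x, g_, b_), vjp)

    def batch_norm2d(
        self,
        weight: "Tensor",
        bias: "Tensor",
        mean: np.ndarray,
        var: np.ndarray,
        training: bool,
        eps: float = 1e-5,
    ) -> "Tensor":
        """Per-channel normalisation over (B, H, W).

        In training mode ``mean``/``var`` must be the batch statistics
        (the gradient flows through them); in eval mode they are stored
        running statistics treated as constants.
        """
        x, g_, b_ = self, weight, bias
        C = x.shape[1]
        m = mean.reshape(1, C, 1, 1)
        v = var.reshape(1, C, 1, 1)
        invstd = 1.0 / np.sqrt(v + eps)
        xhat = (x.data - m) * invstd
        out = xhat * g_.data.reshape(1, C, 1, 1) + b_.data.reshape(1, C, 1, 1)
        n = x.data.size // C

        def vjp(g):
            gxhat = g * g_.data.reshape(1, C, 1, 1)
            if training:
                gx = (
                    invstd
                    / n
                    * (
                        n * gxhat
                        - gxhat.sum(axis=(0, 2, 3), keepdims=True)
                        - xhat * (gxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
                    )
                )
            else:
                gx = gxhat * invstd
            return gx, (g * xhat).sum(axis=(0, 2, 3)), g.sum(axis=(0, 2, 3))

        return Tensor._make(out, (x, g_, b_), vjp)


def astensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [astensor(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def vjp(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor._make(data, tuple(tensors), vjp)
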