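"""Reverse-mode automatic differentiation on NumPy arrays.

A deliberately small engine: a :class:`Tensor` wraps a float32 ndarray and
records, for every operation, a closure that accumulates gradients into its
parents.  ``backward()`` runs the closures in reverse topological order.
Only the operations needed by the models and losses in this package are
provided; each primitive's gradient is exercised by finite-difference tests.

All arrays are kept in float32 (float64 only inside reductions where NumPy
chooses to accumulate); computation is single-threaded NumPy, so results are
bit-reproducible for a fixed seed.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = ["Tensor", "as_tensor"]

_DTYPE = np.float32


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # remove leading broadcast axes
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum over axes that were 1 in the original shape
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        _parents: Sequence["Tensor"] = (),
        _backward: Callable[[np.ndarray], None] | None = None,
    ):
        self.data = np.asarray(data, dtype=_DTYPE)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents = tuple(_parents)
        self._backward = _backward

    # ------------------------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # ------------------------------------------------------------------
    def backward(self) -> None:
        """Accumulate gradients of a scalar output into every parent."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: graphs are deep for long conv chains
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
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, grad: np.ndarray) -> None:
        grad = grad.astype(_DTYPE, copy=False)
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    # -- elementwise arithmetic ----------------------------------------
    def __add__(self, other) -> "Tensor":
        other = as_tensor(other)
        out = Tensor(
            self.data + other.data,
            requires_grad=self.requires_grad or other.requires_grad,
            _parents=(self, other),
        )

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.shape))

        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        out = Tensor(-self.data, requires_grad=self.requires_grad, _parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accum(-g)

        out._backward = bw
        return out

    def __sub__(self, other) -> "Tensor":
        return self + (-as_tensor(other))

    def __rsub__(self, other) -> "Tensor":
        return as_tensor(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = as_tensor(other)
        out = Tensor(
            self.data * other.data,
            requires_grad=self.requires_grad or other.requires_grad,
            _parents=(self, other),
        )

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape))

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        other = as_tensor(other)
        return self * other ** -1.0

    def __rtruediv__(self, other) -> "Tensor":
        return as_tensor(other) * self ** -1.0

    def __pow__(self, p: float) -> "Tensor":
        p = float(p)
        out = Tensor(self.data ** p, requires_grad=self.requires_grad, _parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g * p * self.data ** (p - 1.0))

        out._backward = bw
        return out

    def exp(self) -> "Tensor":
        out_data = np.exp(self.data)
        # capture the array, not the output tensor: a closure referencing
        # ``out`` would form a reference cycle and defer freeing whole
        # graphs to the cyclic collector
        out = Tensor(out_data, requires_grad=self.requires_grad, _parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g * out_data)

        out._backward = bw
        return out

    def log(self) -> "Tensor":
        out = Tensor(np.log(self.data), requires_grad=self.requires_grad, _parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g / self.data)

        out._backward = bw
        return out

    def sqrt(self) -> "Tensor":
        return self ** 0.5

    def elu(self, alpha: float = 1.0) -> "Tensor":
        pos = self.data > 0
        out_data = np.where(pos, self.data, alpha * (np.exp(np.minimum(self.data, 0.0)) - 1.0))
        out = Tensor(out_data, requires_grad=self.requires_grad, _parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g * np.where(pos, 1.0, out_data + alpha).astype(_DTYPE))

        out._backward = bw
        return out

    # -- reductions / shaping ------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(
            self.data.sum(axis=axis, keepdims=keepdims),
            requires_grad=self.requires_grad,
            _parents=(self,),
        )

        def bw(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.shape))
            else:
                if not keepdims:
                    axes = axis if isinstance(axis, tuple) else (axis,)
                    axes = tuple(a % self.ndim for a in axes)
                    g = np.expand_dims(g, axes)
                self._accum(np.broadcast_to(g, self.shape))

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else np.prod(
            [self.shape[a % self.ndim] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), requires_grad=self.requires_grad, _parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g.reshape(self.shape))

        out._backward = bw
        return out

    def transpose(self, *axes) -> "Tensor":
        axes = axes or None
        out = Tensor(self.data.transpose(axes), requires_grad=self.requires_grad, _parents=(self,))

        def bw(g):
            if self.requires_grad:
                inv = np.argsort(axes) if axes else None
                self._accum(g.transpose(inv))

        out._backward = bw
        return out

    @property
    def T(self) -> "Tensor":
        return self.transpose()

    def __getitem__(self, idx) -> "Tensor":
        out = Tensor(self.data[idx], requires_grad=self.requires_grad, _parents=(self,))

        def bw(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accum(full)

        out._backward = bw
        return out

    # -- linear algebra -------------------------------------------------
    def __matmul__(self, other) -> "Tensor":
        other = as_tensor(other)
        out = Tensor(
            self.data @ other.data,
            requires_grad=self.requires_grad or other.requires_grad,
            _parents=(self, other),
        )

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g @ np.swapaxes(other.data, -1, -2), self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(np.swapaxes(self.data, -1, -2) @ g, other.shape))

        out._backward = bw
        return out

    # -- composite helpers ---------------------------------------------
    def logsumexp(self, axis: int, keepdims: bool = False) -> "Tensor":
        m = self.data.max(axis=axis, keepdims=True)  # constant shift, zero net grad
        shifted = self - Tensor(m)
        out = shifted.exp().sum(axis=axis, keepdims=True).log() + Tensor(m)
        if not keepdims:
            out = out.reshape(tuple(s for i, s in enumerate(out.shape) if i != axis % self.ndim))
        return out

    def log_softmax(self, axis: int = -1) -> "Tensor":
        return self - self.logsumexp(axis=axis, keepdims=True)

    def softmax(self, axis: int = -1) -> "Tensor":
        return self.log_softmax(axis=axis).exp()


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# ----------------------------------------------------------------------
# Convolution primitives (time axis last).  Forward passes are einsums over
# sliding windows; input gradients are full correlations with flipped
# kernels, validated against finite differences in the test suite.
# ----------------------------------------------------------------------

def _same_pads(K: int) -> tuple[int, int]:
    left = (K - 1) // 2
    return left, K - 1 - left


def _rfft(a: np.ndarray, n: int) -> np.ndarray:
    from scipy import fft as sfft

    return sfft.rfft(a.astype(_DTYPE, copy=False), n=n, axis=-1)


def _phase(n_freqs: int, delay: int, N: int) -> np.ndarray:
    """Spectrum of a pure delay, in single precision."""
    return np.exp(-2j * np.pi * np.arange(n_freqs) * delay / N).astype(np.complex64)


def _irfft(A: np.ndarray, n: int) -> np.ndarray:
    from scipy import fft as sfft

    return sfft.irfft(A, n=n, axis=-1)


def conv_temporal(x: Tensor, w: Tensor) -> Tensor:
    """'same' temporal correlation: x (B,C,T), w (F,K) -> (B,F,C,T).

    out[b,f,c,t] = sum_k xpad[b,c,t+k] w[f,k] with asymmetric 'same'
    padding.  Computed by circular FFT correlation at size N >= T+K-1 (no
    wrap-around for the retained lags); the input/kernel/grad spectra are
    each computed once and shared between the forward pass and both
    gradients, so the cost stays near T log T instead of T*K.
    """
    from scipy import fft as sfft

    B, C, T = x.shape
    F, K = w.shape
    pl, pr = _same_pads(K)
    N = sfft.next_fast_len(T + K - 1, real=True)
    Xf = _rfft(x.data, N)                      # (B,C,Nf)
    Wf = _rfft(w.data, N)                      # (F,Nf)
    shift_rev = _phase(Xf.shape[-1], K - 1, N)  # reversal delay
    # correlation == convolution with the reversed kernel
    full = _irfft(Xf[:, None, :, :] * (np.conj(Wf) * shift_rev)[None, :, None, :], N)
    out_data = full[..., pr : pr + T].astype(_DTYPE)
    out = Tensor(out_data, requires_grad=x.requires_grad or w.requires_grad, _parents=(x, w))

    def bw(g):
        Gf = _rfft(g, N)                        # (B,F,C,Nf)
        if w.requires_grad:
            # gw[f,k] = sum_{b,c,t} xpad[b,c,t+k] g[b,f,c,t]; xpad spectrum is
            # the input spectrum delayed by the left pad
            shift_pad = _phase(Xf.shape[-1], pl, N)
            S = (np.conj(Gf) * (Xf * shift_pad)[:, None, :, :]).sum(axis=(0, 2))
            w._accum(_irfft(S, N)[..., :K])
        if x.requires_grad:
            # gxpad[b,c,s] = sum_{f,k} g[b,f,c,s-k] w[f,k]: plain convolution
            gxp = _irfft((Gf * Wf[None, :, None, :]).sum(axis=1), N)
            x._accum(gxp[:, :, pl : pl + T])

    out._backward = bw
    return out


def conv_depthwise_spatial(x: Tensor, w: Tensor) -> Tensor:
    """Depthwise spatial filter: x (B,F,C,T), w (F,D,C) -> (B,F*D,T)."""
    B, F, C, T = x.shape
    F2, D, C2 = w.shape
    if F2 != F or C2 != C:
        raise ValueError("weight shape incompatible with input")
    out_data = np.einsum("bfct,fdc->bfdt", x.data, w.data, optimize=True).reshape(B, F * D, T)
    out = Tensor(out_data, requires_grad=x.requires_grad or w.requires_grad, _parents=(x, w))

    def bw(g):
        g4 = g.reshape(B, F, D, T)
        if w.requires_grad:
            w._accum(np.einsum("bfct,bfdt->fdc", x.data, g4, optimize=True))
        if x.requires_grad:
            x._accum(np.einsum("bfdt,fdc->bfct", g4, w.data, optimize=True))

    out._backward = bw
    return out


def conv_depthwise_temporal(x: Tensor, w: Tensor) -> Tensor:
    """'same' per-channel temporal convolution: x (B,G,T), w (G,K) -> (B,G,T)."""
    B, G, T = x.shape
    G2, K = w.shape
    if G2 != G:
        raise ValueError("weight shape incompatible with input")
    from scipy import fft as sfft

    pl, pr = _same_pads(K)
    N = sfft.next_fast_len(T + K - 1, real=True)
    Xf = _rfft(x.data, N)                      # (B,G,Nf)
    Wf = _rfft(w.data, N)                      # (G,Nf)
    shift_rev = _phase(Xf.shape[-1], K - 1, N)
    full = _irfft(Xf * (np.conj(Wf) * shift_rev)[None], N)
    out_data = full[..., pr : pr + T].astype(_DTYPE)
    out = Tensor(out_data, requires_grad=x.requires_grad or w.requires_grad, _parents=(x, w))

    def bw(g):
        Gf = _rfft(g, N)
        if w.requires_grad:
            shift_pad = _phase(Xf.shape[-1], pl, N)
            S = (np.conj(Gf) * (Xf * shift_pad)).sum(axis=0)
            w._accum(_irfft(S, N)[..., :K])
        if x.requires_grad:
            gxp = _irfft(Gf * Wf[None], N)
            x._accum(gxp[:, :, pl : pl + T])

    out._backward = bw
    return out


def conv_pointwise(x: Tensor, w: Tensor) -> Tensor:
    """1x1 channel mixing: x (B,G,T), w (O,G) -> (B,O,T)."""
    out_data = np.einsum("bgt,og->bot", x.data, w.data, optimize=True)
    out = Tensor(out_data, requires_grad=x.requires_grad or w.requires_grad, _parents=(x, w))

    def bw(g):
        if w.requires_grad:
            w._accum(np.einsum("bgt,bot->og", x.data, g, optimize=True))
        if x.requires_grad:
            x._accum(np.einsum("bot,og->bgt", g, w.data, optimize=True))

    out._backward = bw
    return out


def batch_norm(
    x: Tensor, gamma: Tensor, beta: Tensor, axes: tuple[int, ...], eps: float
) -> tuple[Tensor, np.ndarray, np.ndarray]:
    """Training-mode batch normalization as one primitive (closed-form
    backward), normalizing over ``axes``.  ``gamma``/``beta`` must already be
    broadcast-shaped.  Returns (out, batch_mean, batch_var) so the caller can
    maintain running statistics."""
    mu = x.data.mean(axis=axes, keepdims=True)
    var = x.data.var(axis=axes, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    out_data = gamma.data * xhat + beta.data
    out = Tensor(
        out_data,
        requires_grad=x.requires_grad or gamma.requires_grad or beta.requires_grad,
        _parents=(x, gamma, beta),
    )

    def bw(g):
        if gamma.requires_grad:
            gamma._accum((g * xhat).sum(axis=axes, keepdims=True))
        if beta.requires_grad:
            beta._accum(g.sum(axis=axes, keepdims=True))
        if x.requires_grad:
            gm = g.mean(axis=axes, keepdims=True)
            gxm = (g * xhat).mean(axis=axes, keepdims=True)
            x._accum(gamma.data * inv * (g - gm - xhat * gxm))

    out._backward = bw
    return out, mu.squeeze(), var.squeeze()


def avg_pool_time(x: Tensor, width: int) -> Tensor:
    """Non-overlapping average pooling along the last axis (remainder cropped)."""
    *lead, T = x.shape
    n = T // width
    cropped = x[..., : n * width] if n * width != T else x
    return cropped.reshape(*lead, n, width).mean(axis=-1)


def concat(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    ts = list(tensors)
    out = Tensor(
        np.concatenate([t.data for t in ts], axis=axis),
        requires_grad=any(t.requires_grad for t in ts),
        _parents=ts,
    )
    sizes = [t.shape[axis] for t in ts]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, a, b in zip(ts, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accum(g[tuple(sl)])

    out._backward = bw
    return out
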