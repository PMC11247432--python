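"""Minimal reverse-mode autodiff engine and neural-network layers on numpy.

The models in this package are small fixed-topology CNNs operating on
(channels x time) EEG arrays, so a compact tape-based engine with exactly the
primitives they need is sufficient: broadcast arithmetic, matmul, pointwise
nonlinearities, reductions, 1-D (transposed) convolutions evaluated through
real FFTs, batch normalization, average pooling and dropout.

Convolutions use frequency-domain products (O(L log L) per map) because every
kernel in the architecture is long (64 taps) relative to typical CNN kernels;
direct sliding-window products would dominate the training budget on one CPU.

The floating dtype is switchable (`set_dtype` / `use_dtype`): float64 by
default so finite-difference gradient checks pass at tight tolerance, float32
inside the training loops where memory bandwidth is the binding resource.
"""

from __future__ import annotations

from contextlib import contextmanager

import numpy as np
from scipy.fft import next_fast_len

__all__ = [
    "set_dtype",
    "use_dtype",
    "Tensor",
    "Parameter",
    "Module",
    "Linear",
    "BatchNorm",
    "Dropout",
    "Adam",
    "concat",
    "conv1d",
    "conv_transpose1d",
    "dwconv1d",
    "spatial_filter",
    "avg_pool1d",
    "log_softmax",
    "gradcheck",
]


_DTYPE = np.float64


def set_dtype(dtype) -> None:
    """Set the floating dtype newly created Tensors use.

    float64 (the default) is kept for gradient checking and small exact
    computations; the training loops run under float32, which halves memory
    traffic — the binding resource for these convolutional workloads.
    """
    global _DTYPE
    _DTYPE = np.dtype(dtype).type


@contextmanager
def use_dtype(dtype):
    prev = _DTYPE
    set_dtype(dtype)
    try:
        yield
    finally:
        set_dtype(prev)


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
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
    """A node in the backward tape wrapping a floating ndarray."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=_DTYPE)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._prev: tuple[Tensor, ...] = ()

    # -- graph plumbing ----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=self.data.dtype)
            if self.grad.shape != self.data.shape:  # broadcast constant grads
                self.grad = np.broadcast_to(self.grad, self.data.shape).copy()
        else:
            self.grad += g

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; graphs can exceed the recursion limit
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad or p._prev for p in parents):
            out.requires_grad = True
            out._prev = tuple(parents)
            out._backward = backward
        return out

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        other = self._lift(other)

        def bwd(g):
            self._accum(_unbroadcast(g, self.shape))
            other._accum(_unbroadcast(g, other.shape))

        return self._make(self.data + other.data, (self, other), bwd)

    __radd__ = __add__

    def __neg__(self):
        def bwd(g):
            self._accum(-g)

        return self._make(-self.data, (self,), bwd)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)

        def bwd(g):
            self._accum(_unbroadcast(g * other.data, self.shape))
            other._accum(_unbroadcast(g * self.data, other.shape))

        return self._make(self.data * other.data, (self, other), bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)

        def bwd(g):
            self._accum(_unbroadcast(g / other.data, self.shape))
            other._accum(
                _unbroadcast(-g * self.data / other.data**2, other.shape)
            )

        return self._make(self.data / other.data, (self, other), bwd)

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def __pow__(self, p: float):
        def bwd(g):
            self._accum(g * p * self.data ** (p - 1))

        return self._make(self.data**p, (self,), bwd)

    def __matmul__(self, other):
        other = self._lift(other)

        def bwd(g):
            self._accum(g @ other.data.T)
            other._accum(self.data.T @ g)

        return self._make(self.data @ other.data, (self, other), bwd)

    # -- shape -------------------------------------------------------------
    def reshape(self, *shape):
        orig = self.shape

        def bwd(g):
            self._accum(g.reshape(orig))

        return self._make(self.data.reshape(*shape), (self,), bwd)

    def transpose(self, *axes):
        inv = np.argsort(axes)

        def bwd(g):
            self._accum(g.transpose(inv))

        return self._make(self.data.transpose(axes), (self,), bwd)

    def narrow(self, axis: int, start: int, length: int):
        """Slice `length` entries from `start` along `axis`."""
        idx = [slice(None)] * self.ndim
        idx[axis] = slice(start, start + length)
        idx = tuple(idx)

        def bwd(g):
            full = np.zeros_like(self.data)
            full[idx] = g
            self._accum(full)

        return self._make(self.data[idx].copy(), (self,), bwd)

    # -- pointwise ---------------------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def bwd(g):
            self._accum(g * out_data)

        return self._make(out_data, (self,), bwd)

    def log(self):
        def bwd(g):
            self._accum(g / self.data)

        return self._make(np.log(self.data), (self,), bwd)

    def tanh(self):
        out_data = np.tanh(self.data)

        def bwd(g):
            self._accum(g * (1.0 - out_data**2))

        return self._make(out_data, (self,), bwd)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def bwd(g):
            self._accum(g * out_data * (1.0 - out_data))

        return self._make(out_data, (self,), bwd)

    def relu(self):
        mask = self.data > 0

        def bwd(g):
            self._accum(g * mask)

        return self._make(self.data * mask, (self,), bwd)

    def leaky_relu(self, slope: float = 0.2):
        factor = np.where(self.data > 0, 1.0, slope)

        def bwd(g):
            self._accum(g * factor)

        return self._make(self.data * factor, (self,), bwd)

    def elu(self, alpha: float = 1.0):
        neg = self.data <= 0
        expm1 = alpha * np.expm1(np.minimum(self.data, 0.0))
        out_data = np.where(neg, expm1, self.data)

        def bwd(g):
            self._accum(g * np.where(neg, expm1 + alpha, 1.0))

        return self._make(out_data, (self,), bwd)

    # -- reductions --------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        orig = self.shape

        def bwd(g):
            if axis is None:
                self._accum(np.broadcast_to(g, orig).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, orig).copy())

        return self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), bwd)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def __repr__(self):
        return f"Tensor(shape={self.shape}, grad={'yes' if self.requires_grad else 'no'})"


class Parameter(Tensor):
    """A trainable Tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis))
    if any(t.requires_grad or t._prev for t in tensors):
        out.requires_grad = True
        out._prev = tuple(tensors)

        def bwd(g):
            for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
                t._accum(piece)

        out._backward = bwd
    return out


# ---------------------------------------------------------------------------
# FFT convolution primitives.
#
# conv1d computes the cross-correlation y[n,o,t] = sum_{i,k} xp[n,i,t+k] w[o,i,k]
# on the zero-padded input xp; conv_transpose1d the linear convolution
# y[n,o,s+k] += x[n,i,s] w[i,o,k].  Both are evaluated with rfft/irfft of
# length nfft >= (padded length), which makes circular wrap-around vanish for
# the retained output samples.
# ---------------------------------------------------------------------------


def _rfft(a: np.ndarray, nfft: int) -> np.ndarray:
    return np.fft.rfft(a, n=nfft, axis=-1)


def _irfft(a: np.ndarray, nfft: int, length: int) -> np.ndarray:
    return np.fft.irfft(a, n=nfft, axis=-1)[..., :length]


def _fmm(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Per-frequency matmul of spectra: (.., A, F) x (.., B, F) stacks.

    Contracts the middle axes with frequency as the batch dimension, i.e.
    out[x, y, f] = sum_k a[x, k, f] * b[k, y, f], evaluated as stacked BLAS
    matmuls (much faster than a naive einsum loop for complex data).
    """
    out = np.matmul(a.transpose(2, 0, 1), b.transpose(2, 0, 1))
    return out.transpose(1, 2, 0)


def conv1d(x: Tensor, w: Tensor, pad: tuple[int, int] = (0, 0)) -> Tensor:
    """Cross-correlate (N, Ci, L) with filters (Co, Ci, K); zero pad = (left, right)."""
    n_b, c_in, length = x.shape
    c_out, c_in_w, k = w.shape
    if c_in != c_in_w:
        raise ValueError(f"conv1d channel mismatch: input {c_in}, weight {c_in_w}")
    pl, pr = pad
    lp = length + pl + pr
    l_out = lp - k + 1
    if l_out < 1:
        raise ValueError("conv1d: kernel longer than padded input")
    nfft = next_fast_len(lp)
    xp = np.pad(x.data, ((0, 0), (0, 0), (pl, pr)))
    fx = _rfft(xp, nfft)
    fw = _rfft(w.data, nfft)
    y = _irfft(_fmm(fx, fw.conj().transpose(1, 0, 2)), nfft, l_out)

    out = Tensor(y)
    if x.requires_grad or x._prev or w.requires_grad or w._prev:
        out.requires_grad = True
        out._prev = (x, w)

        def bwd(g):
            fg = _rfft(g, nfft)
            # d xp = full convolution of g with w, then strip the padding
            dxp = _irfft(_fmm(fg, fw), nfft, lp)
            x._accum(dxp[:, :, pl : pl + length])
            dw = _irfft(_fmm(fg.conj().transpose(1, 0, 2), fx), nfft, k)
            w._accum(dw)

        out._backward = bwd
    return out


def conv_transpose1d(x: Tensor, w: Tensor) -> Tensor:
    """Transposed convolution, stride 1: (N, Ci, L) x (Ci, Co, K) -> (N, Co, L+K-1)."""
    n_b, c_in, length = x.shape
    c_in_w, c_out, k = w.shape
    if c_in != c_in_w:
        raise ValueError(
            f"conv_transpose1d channel mismatch: input {c_in}, weight {c_in_w}"
        )
    l_out = length + k - 1
    nfft = next_fast_len(l_out)
    fx = _rfft(x.data, nfft)
    fw = _rfft(w.data, nfft)
    y = _irfft(_fmm(fx, fw), nfft, l_out)

    out = Tensor(y)
    if x.requires_grad or x._prev or w.requires_grad or w._prev:
        out.requires_grad = True
        out._prev = (x, w)

        def bwd(g):
            fg = _rfft(g, nfft)
            dx = _irfft(_fmm(fg, fw.conj().transpose(1, 0, 2)), nfft, length)
            x._accum(dx)
            dw = _irfft(_fmm(fx.conj().transpose(1, 0, 2), fg), nfft, k)
            w._accum(dw)

        out._backward = bwd
    return out


def dwconv1d(x: Tensor, w: Tensor, pad: tuple[int, int] = (0, 0)) -> Tensor:
    """Depthwise cross-correlation: (N, C, L) with per-channel kernels (C, K)."""
    n_b, c, length = x.shape
    c_w, k = w.shape
    if c != c_w:
        raise ValueError(f"dwconv1d channel mismatch: input {c}, weight {c_w}")
    pl, pr = pad
    lp = length + pl + pr
    l_out = lp - k + 1
    nfft = next_fast_len(lp)
    xp = np.pad(x.data, ((0, 0), (0, 0), (pl, pr)))
    fx = _rfft(xp, nfft)
    fw = _rfft(w.data, nfft)
    y = _irfft(fx * fw.conj()[None], nfft, l_out)

    out = Tensor(y)
    if x.requires_grad or x._prev or w.requires_grad or w._prev:
        out.requires_grad = True
        out._prev = (x, w)

        def bwd(g):
            fg = _rfft(g, nfft)
            dxp = _irfft(fg * fw[None], nfft, lp)
            x._accum(dxp[:, :, pl : pl + length])
            dw = _irfft((fx * fg.conj()).sum(axis=0), nfft, k)
            w._accum(dw)

        out._backward = bwd
    return out


def spatial_filter(x: Tensor, w: Tensor) -> Tensor:
    """Depthwise spatial convolution with a full-height kernel.

    Collapses the electrode axis: (N, F, C, T) with weights (F, D, C) ->
    (N, F*D, T), where map f*D+d mixes the C electrodes of input map f.
    """
    n_b, f, c, t = x.shape
    f_w, d, c_w = w.shape
    if (f, c) != (f_w, c_w):
        raise ValueError(
            f"spatial_filter mismatch: input maps/channels {(f, c)}, weight {(f_w, c_w)}"
        )
    y = np.einsum("nfct,fdc->nfdt", x.data, w.data).reshape(n_b, f * d, t)

    out = Tensor(y)
    if x.requires_grad or x._prev or w.requires_grad or w._prev:
        out.requires_grad = True
        out._prev = (x, w)

        def bwd(g):
            gr = g.reshape(n_b, f, d, t)
            x._accum(np.einsum("nfdt,fdc->nfct", gr, w.data))
            w._accum(np.einsum("nfct,nfdt->fdc", x.data, gr))

        out._backward = bwd
    return out


def avg_pool1d(x: Tensor, k: int) -> Tensor:
    """Non-overlapping average pooling along time; trailing remainder dropped."""
    n_b, c, length = x.shape
    l_out = length // k
    y = x.data[:, :, : l_out * k].reshape(n_b, c, l_out, k).mean(axis=-1)

    out = Tensor(y)
    if x.requires_grad or x._prev:
        out.requires_grad = True
        out._prev = (x,)

        def bwd(g):
            dx = np.zeros_like(x.data)
            dx[:, :, : l_out * k] = np.repeat(g / k, k, axis=-1)
            x._accum(dx)

        out._backward = bwd
    return out


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    shift = x - np.max(x.data, axis=axis, keepdims=True)  # constant shift
    return shift - shift.exp().sum(axis=axis, keepdims=True).log()


# ---------------------------------------------------------------------------
# Modules
# ---------------------------------------------------------------------------


class Module:
    """Base class: parameter discovery, train/eval mode, state round-trip."""

    def __init__(self):
        self.training = True
        self._buffers: dict[str, np.ndarray] = {}

    def _children(self):
        for name, val in vars(self).items():
            if isinstance(val, Module):
                yield name, val
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield f"{name}.{i}", item

    def named_parameters(self, prefix: str = ""):
        for name, val in vars(self).items():
            if isinstance(val, Parameter):
                yield prefix + name, val
        for name, child in self._children():
            yield from child.named_parameters(prefix + name + ".")

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def train(self):
        self.training = True
        for _, child in self._children():
            child.train()
        return self

    def eval(self):
        self.training = False
        for _, child in self._children():
            child.eval()
        return self

    def state_dict(self, prefix: str = "") -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters(prefix)}
        state.update(
            {prefix + k: v.copy() for k, v in self._buffers.items()}
        )
        for name, child in self._children():
            state.update(child.state_dict(prefix + name + "."))
        return state

    def load_state_dict(self, state: dict[str, np.ndarray], prefix: str = ""):
        for name, p in self.named_parameters(prefix):
            p.data = np.asarray(state[name], dtype=p.data.dtype).reshape(p.shape)
        for k in self._buffers:
            self._buffers[k] = np.asarray(state[prefix + k], dtype=np.float64)  # stats stay double
        for name, child in self._children():
            child.load_state_dict(state, prefix + name + ".")

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _glorot(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, fan_out: int):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, bias: bool = True):
        super().__init__()
        self.weight = Parameter(_glorot(rng, (n_in, n_out), n_in, n_out))
        self.bias = Parameter(np.zeros(n_out)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        y = x @ self.weight
        return y if self.bias is None else y + self.bias


class BatchNorm(Module):
    """Batch normalization over all axes except the channel axis (axis 1)."""

    def __init__(self, n_features: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(n_features))
        self.beta = Parameter(np.zeros(n_features))
        self.momentum = momentum
        self.eps = eps
        self._buffers["running_mean"] = np.zeros(n_features)
        self._buffers["running_var"] = np.ones(n_features)

    def forward(self, x: Tensor) -> Tensor:
        axes = (0,) + tuple(range(2, x.ndim))
        shape = (1, x.shape[1]) + (1,) * (x.ndim - 2)
        if self.training:
            mu = x.data.mean(axis=axes)
            var = x.data.var(axis=axes)
            rm, rv = self._buffers["running_mean"], self._buffers["running_var"]
            self._buffers["running_mean"] = (1 - self.momentum) * rm + self.momentum * mu
            self._buffers["running_var"] = (1 - self.momentum) * rv + self.momentum * var
        else:
            mu = self._buffers["running_mean"]
            var = self._buffers["running_var"]

        ivar = 1.0 / np.sqrt(var + self.eps)
        gamma, beta = self.gamma, self.beta
        training = self.training
        # fold normalization and affine into y = a*x + b (fewer large temporaries)
        a = (gamma.data * ivar).reshape(shape)
        b = (beta.data - gamma.data * mu * ivar).reshape(shape)

        out = Tensor(a * x.data + b)
        if x.requires_grad or x._prev or gamma.requires_grad:
            out.requires_grad = True
            out._prev = (x, gamma, beta)

            def bwd(g):
                xhat = (x.data - mu.reshape(shape)) * ivar.reshape(shape)
                gamma._accum((g * xhat).sum(axis=axes))
                beta._accum(g.sum(axis=axes))
                dxhat = g * gamma.data.reshape(shape)
                if training:
                    # standard batch-norm backward through the batch statistics
                    dx = (
                        dxhat
                        - dxhat.mean(axis=axes, keepdims=True)
                        - xhat * (dxhat * xhat).mean(axis=axes, keepdims=True)
                    ) * ivar.reshape(shape)
                    x._accum(dx)
                else:
                    x._accum(dxhat * ivar.reshape(shape))

            out._backward = bwd
        return out


class Dropout(Module):
    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        self.p = p
        self.rng = rng

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0.0:
            return x
        keep = 1.0 - self.p
        draw_dtype = np.float32 if _DTYPE == np.float32 else np.float64
        mask = (self.rng.random(x.shape, dtype=draw_dtype) < keep) / np.array(
            keep, dtype=_DTYPE
        )
        return x * Tensor(mask)


class Adam:
    """Adam optimizer with the usual bias correction."""

    def __init__(self, params: list[Parameter], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g**2
            p.data -= self.lr * (self.m[i] / b1t) / (np.sqrt(self.v[i] / b2t) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None


def gradcheck(fn, tensors: list[Tensor], eps: float = 1e-6, rtol: float = 1e-4,
              atol: float = 1e-7) -> bool:
    """Compare analytic gradients of scalar `fn(*tensors)` to central differences."""
    for t in tensors:
        t.requires_grad = True
        t.grad = None
    out = fn(*tensors)
    out.backward()
    for t in tensors:
        num = np.zeros_like(t.data)
        flat = t.data.reshape(-1)
        numf = num.reshape(-1)
        for i in range(flat.size):
            orig = flat[i]
            flat[i] = orig + eps
            hi = fn(*tensors).item()
            flat[i] = orig - eps
            lo = fn(*tensors).item()
            flat[i] = orig
            numf[i] = (hi - lo) / (2 * eps)
        if not np.allclose(t.grad, num, rtol=rtol, atol=atol):
            return False
    return True
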