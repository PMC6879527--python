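"""Minimal reverse-mode automatic differentiation over NumPy arrays.

This is a deliberately small CPU toolkit providing exactly the pieces the
package's convolutional models need: dense float64 tensors, 3x3 "same"
convolution, 2x2 max pooling, nearest-neighbour upsampling, channel
concatenation, ReLU/sigmoid/log/power primitives, and an Adam optimizer.
Everything is deterministic given the NumPy generator used for weight
initialization and data shuffling; there is no global random state.
"""

from __future__ import annotations

import numpy as np

#: dtype of the training engine; plain-array loss evaluation elsewhere in the
#: package stays in float64
DTYPE = np.float32

__all__ = [
    "Tensor",
    "Parameter",
    "Module",
    "Conv2d",
    "Linear",
    "Adam",
    "concat",
    "as_tensor",
]


class Tensor:
    """A NumPy array plus the bookkeeping needed for backpropagation."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    # make NumPy defer to the reflected operators instead of broadcasting
    # elementwise over this object
    __array_ufunc__ = None
    __array_priority__ = 1000

    def __init__(self, data, requires_grad=False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=DTYPE)
        self.requires_grad = bool(requires_grad)
        self.grad = None
        self._parents = parents
        self._backward = backward

    # -- basic introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self):
        return float(self.data)

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- autograd engine -----------------------------------------------------
    def _accum(self, g):
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
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
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- elementwise arithmetic ----------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data + other.data,
                     self.requires_grad or other.requires_grad,
                     parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        out._backward = bw
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data * other.data,
                     self.requires_grad or other.requires_grad,
                     parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __truediv__(self, scalar):
        return self * (1.0 / float(scalar))

    def __pow__(self, exponent):
        e = float(exponent)
        out = Tensor(self.data ** e, self.requires_grad, parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g * e * self.data ** (e - 1.0))

        out._backward = bw
        return out

    # -- nonlinearities ------------------------------------------------------
    def relu(self):
        mask = self.data > 0
        out = Tensor(np.where(mask, self.data, 0.0), self.requires_grad,
                     parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g * mask)

        out._backward = bw
        return out

    def sigmoid(self):
        x = self.data
        s = np.empty_like(x)
        pos = x >= 0
        s[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
        ex = np.exp(x[~pos])
        s[~pos] = ex / (1.0 + ex)
        out = Tensor(s, self.requires_grad, parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g * s * (1.0 - s))

        out._backward = bw
        return out

    def log(self):
        out = Tensor(np.log(self.data), self.requires_grad, parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g / self.data)

        out._backward = bw
        return out

    def clip(self, lo, hi):
        """Clamp values; gradient is passed through only where not clamped."""
        mask = (self.data > lo) & (self.data < hi)
        out = Tensor(np.clip(self.data, lo, hi), self.requires_grad,
                     parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g * mask)

        out._backward = bw
        return out

    # -- reductions / shaping ------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                     self.requires_grad, parents=(self,))

        def bw(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy()
                            if np.ndim(g) else np.full_like(self.data, g))
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accum(np.broadcast_to(gg, self.data.shape).copy())

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims=False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) / n

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), self.requires_grad,
                     parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g.reshape(self.data.shape))

        out._backward = bw
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], self.requires_grad, parents=(self,))

        def bw(g):
            if self.requires_grad:
                if self.grad is None:
                    self.grad = np.zeros_like(self.data)
                np.add.at(self.grad, idx, g)

        out._backward = bw
        return out

    def matmul(self, other):
        other = as_tensor(other)
        out = Tensor(self.data @ other.data,
                     self.requires_grad or other.requires_grad,
                     parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(g @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ g)

        out._backward = bw
        return out

    # -- spatial primitives (NCHW layout) ------------------------------------
    def maxpool2(self):
        n, c, h, w = self.data.shape
        if h % 2 or w % 2:
            raise ValueError("maxpool2 requires even spatial dimensions")
        r = self.data.reshape(n, c, h // 2, 2, w // 2, 2)
        r = r.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h // 2, w // 2, 4)
        idx = r.argmax(axis=-1)
        out_data = np.take_along_axis(r, idx[..., None], axis=-1)[..., 0]
        out = Tensor(out_data, self.requires_grad, parents=(self,))

        def bw(g):
            if not self.requires_grad:
                return
            scat = np.zeros((n, c, h // 2, w // 2, 4))
            np.put_along_axis(scat, idx[..., None], g[..., None], axis=-1)
            scat = scat.reshape(n, c, h // 2, w // 2, 2, 2)
            scat = scat.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h, w)
            self._accum(scat)

        out._backward = bw
        return out

    def upsample2(self):
        """Nearest-neighbour 2x upsampling."""
        out_data = self.data.repeat(2, axis=2).repeat(2, axis=3)
        out = Tensor(out_data, self.requires_grad, parents=(self,))
        n, c, h, w = self.data.shape

        def bw(g):
            if self.requires_grad:
                self._accum(g.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5)))

        out._backward = bw
        return out


def as_tensor(x):
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(grad, shape):
    """Sum a gradient down to ``shape`` (inverse of NumPy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


def concat(a: Tensor, b: Tensor, axis: int = 1) -> Tensor:
    out = Tensor(np.concatenate([a.data, b.data], axis=axis),
                 a.requires_grad or b.requires_grad, parents=(a, b))
    na = a.data.shape[axis]

    def bw(g):
        ga, gb = np.split(g, [na], axis=axis)
        if a.requires_grad:
            a._accum(ga)
        if b.requires_grad:
            b._accum(gb)

    out._backward = bw
    return out


def conv2d(x: Tensor, w: Tensor, b: Tensor, pad: int) -> Tensor:
    """Stride-1 2D cross-correlation with symmetric zero padding.

    ``x`` is (N, C, H, W), ``w`` is (F, C, kh, kw), ``b`` is (F,).
    Internally computed channels-last as a sum of kh*kw offset matmuls,
    which avoids materializing an im2col matrix.
    """
    n, c, h, wd = x.data.shape
    f, cw, kh, kw = w.data.shape
    if c != cw:
        raise ValueError(f"conv2d channel mismatch: input {c} vs kernel {cw}")
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    xh = np.ascontiguousarray(np.moveaxis(xp, 1, -1))  # N, Hp, Wp, C
    h2 = h + 2 * pad - kh + 1
    w2 = wd + 2 * pad - kw + 1
    acc = np.zeros((n, h2, w2, f), dtype=DTYPE)
    for i in range(kh):
        for j in range(kw):
            acc += xh[:, i:i + h2, j:j + w2, :] @ w.data[:, :, i, j].T
    acc += b.data
    out = Tensor(np.moveaxis(acc, -1, 1),
                 x.requires_grad or w.requires_grad or b.requires_grad,
                 parents=(x, w, b))

    def bw(g):
        gh = np.ascontiguousarray(np.moveaxis(g, 1, -1))  # N, H2, W2, F
        gflat = gh.reshape(-1, f)
        if w.requires_grad:
            dw = np.empty_like(w.data)
            for i in range(kh):
                for j in range(kw):
                    patch = xh[:, i:i + h2, j:j + w2, :].reshape(-1, c)
                    dw[:, :, i, j] = gflat.T @ patch
            w._accum(dw)
        if b.requires_grad:
            b._accum(gflat.sum(axis=0))
        if x.requires_grad:
            dxh = np.zeros_like(xh)
            for i in range(kh):
                for j in range(kw):
                    dxh[:, i:i + h2, j:j + w2, :] += gh @ w.data[:, :, i, j]
            dxp = np.moveaxis(dxh, -1, 1)
            if pad:
                dxp = dxp[:, :, pad:-pad, pad:-pad]
            x._accum(np.ascontiguousarray(dxp))

    out._backward = bw
    return out


# --------------------------------------------------------------------------
# modules


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Base class with recursive parameter discovery by attribute name."""

    def named_parameters(self, prefix=""):
        out = []
        for name, value in vars(self).items():
            full = f"{prefix}{name}" if prefix else name
            if isinstance(value, Parameter):
                out.append((full, value))
            elif isinstance(value, Module):
                out.extend(value.named_parameters(full + "."))
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        out.extend(item.named_parameters(f"{full}.{i}."))
                    elif isinstance(item, Parameter):
                        out.append((f"{full}.{i}", item))
        return out

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def state_dict(self):
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state):
        params = dict(self.named_parameters())
        for name, array in state.items():
            if name not in params:
                raise KeyError(f"unknown parameter {name!r}")
            if params[name].data.shape != array.shape:
                raise ValueError(
                    f"shape mismatch for {name!r}: model "
                    f"{params[name].data.shape} vs stored {array.shape}")
            params[name].data = np.asarray(array, dtype=np.float64).copy()

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None


class Conv2d(Module):
    def __init__(self, in_ch, out_ch, kernel=3, rng=None):
        rng = rng if rng is not None else np.random.default_rng(0)
        fan_in = in_ch * kernel * kernel
        scale = np.sqrt(2.0 / fan_in)  # He init for ReLU nets
        self.w = Parameter(rng.normal(0.0, scale, (out_ch, in_ch, kernel, kernel)))
        self.b = Parameter(np.zeros(out_ch))
        self.pad = kernel // 2

    def __call__(self, x):
        return conv2d(x, self.w, self.b, self.pad)


class Linear(Module):
    def __init__(self, in_features, out_features, rng=None):
        rng = rng if rng is not None else np.random.default_rng(0)
        scale = np.sqrt(2.0 / in_features)
        self.w = Parameter(rng.normal(0.0, scale, (in_features, out_features)))
        self.b = Parameter(np.zeros(out_features))

    def __call__(self, x):
        return x.matmul(self.w) + self.b


class Adam:
    """Adam optimizer (Kingma & Ba) with bias correction."""

    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * p.grad
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * p.grad ** 2
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
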