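"""Minimal reverse-mode automatic differentiation on numpy arrays.

The package's trainable components (encoder-decoder segmenter, the CNN/MLP
feature extractors with cross-attention fusion, and the deep Cox risk
network) are small enough that a compact tape-based autodiff core is all
that is needed.  Every operator implements a closed-form vector-Jacobian
product; correctness is enforced by central-finite-difference gradient
checks in the test suite.

Only the operations the package uses are provided: elementwise arithmetic,
matmul, 3x3 same-padding convolution (im2col), 2x2 max-pooling, nearest
2x upsampling, channel concatenation, relu/sigmoid/exp/log, reductions and
log-sum-exp.  All tensors are float64 for reproducibility across BLAS
builds.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Adam", "he_init", "glorot_init"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape`, inverting numpy broadcasting."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A node in the computation graph: a value plus a backward closure."""

    __slots__ = ("value", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, value, requires_grad: bool = False):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- graph plumbing -------------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @staticmethod
    def _node(value, parents, backward) -> "Tensor":
        out = Tensor(value, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.value.shape

    def backward(self) -> None:
        """Accumulate gradients of self (summed to a scalar) into leaves."""
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
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.value)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.value)
        self.grad += g

    # -- arithmetic -----------------------------------------------------
    def __add__(self, other):
        o = self._lift(other)

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.value.shape))
            if o.requires_grad:
                o._accum(_unbroadcast(g, o.value.shape))

        return self._node(self.value + o.value, (self, o), bwd)

    __radd__ = __add__

    def __neg__(self):
        def bwd(g):
            if self.requires_grad:
                self._accum(-g)

        return self._node(-self.value, (self,), bwd)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        o = self._lift(other)

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * o.value, self.value.shape))
            if o.requires_grad:
                o._accum(_unbroadcast(g * self.value, o.value.shape))

        return self._node(self.value * o.value, (self, o), bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        o = self._lift(other)

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / o.value, self.value.shape))
            if o.requires_grad:
                o._accum(_unbroadcast(-g * self.value / o.value**2, o.value.shape))

        return self._node(self.value / o.value, (self, o), bwd)

    def __pow__(self, p: float):
        def bwd(g):
            if self.requires_grad:
                self._accum(g * p * self.value ** (p - 1))

        return self._node(self.value**p, (self,), bwd)

    def matmul(self, other):
        o = self._lift(other)

        def bwd(g):
            if self.requires_grad:
                self._accum(g @ o.value.T)
            if o.requires_grad:
                o._accum(self.value.T @ g)

        return self._node(self.value @ o.value, (self, o), bwd)

    __matmul__ = matmul

    # -- nonlinearities -------------------------------------------------
    def relu(self):
        mask = self.value > 0

        def bwd(g):
            if self.requires_grad:
                self._accum(g * mask)

        return self._node(self.value * mask, (self,), bwd)

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-np.clip(self.value, -500, 500)))

        def bwd(g):
            if self.requires_grad:
                self._accum(g * s * (1.0 - s))

        return self._node(s, (self,), bwd)

    def exp(self):
        e = np.exp(self.value)

        def bwd(g):
            if self.requires_grad:
                self._accum(g * e)

        return self._node(e, (self,), bwd)

    def log(self):
        def bwd(g):
            if self.requires_grad:
                self._accum(g / self.value)

        return self._node(np.log(self.value), (self,), bwd)

    # -- reductions / shaping -------------------------------------------
    def sum(self, axis=None, keepdims=False):
        def bwd(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.value.shape).copy())
            else:
                ge = g if keepdims else np.expand_dims(g, axis)
                self._accum(np.broadcast_to(ge, self.value.shape).copy())

        return self._node(self.value.sum(axis=axis, keepdims=keepdims), (self,), bwd)

    def mean(self, axis=None, keepdims=False):
        n = self.value.size if axis is None else self.value.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        old = self.value.shape

        def bwd(g):
            if self.requires_grad:
                self._accum(g.reshape(old))

        return self._node(self.value.reshape(*shape), (self,), bwd)

    def transpose(self, *axes):
        inv = np.argsort(axes)

        def bwd(g):
            if self.requires_grad:
                self._accum(g.transpose(*inv))

        return self._node(self.value.transpose(*axes), (self,), bwd)

    def logsumexp(self, axis: int, keepdims: bool = False):
        m = self.value.max(axis=axis, keepdims=True)
        e = np.exp(self.value - m)
        s = e.sum(axis=axis, keepdims=True)
        out = m + np.log(s)
        soft = e / s

        def bwd(g):
            if self.requires_grad:
                ge = g if keepdims else np.expand_dims(g, axis)
                self._accum(ge * soft)

        val = out if keepdims else np.squeeze(out, axis=axis)
        return self._node(val, (self,), bwd)

    def softmax(self, axis: int = -1):
        return (self - self.logsumexp(axis=axis, keepdims=True)).exp()

    @staticmethod
    def concat(tensors: list["Tensor"], axis: int):
        tensors = [Tensor._lift(t) for t in tensors]
        sizes = [t.value.shape[axis] for t in tensors]
        offsets = np.cumsum([0] + sizes)

        def bwd(g):
            for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
                if t.requires_grad:
                    sl = [slice(None)] * g.ndim
                    sl[axis] = slice(a, b)
                    t._accum(g[tuple(sl)])

        return Tensor._node(
            np.concatenate([t.value for t in tensors], axis=axis), tensors, bwd
        )

    def slice(self, key):
        def bwd(g):
            if self.requires_grad:
                full = np.zeros_like(self.value)
                full[key] = g
                self._accum(full)

        return self._node(self.value[key], (self,), bwd)

    # -- spatial ops (N, C, H, W) ---------------------------------------
    def conv2d(self, weight: "Tensor", bias: "Tensor"):
        """3x3 (or kxk) same-padding stride-1 convolution via im2col."""
        x, w = self.value, weight.value
        n, c, h, wd = x.shape
        f, _, kh, kw = w.shape
        ph, pw = kh // 2, kw // 2
        xp = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
        # cols: (n, h, w, c*kh*kw)
        win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n, h * wd, c * kh * kw)
        wflat = w.reshape(f, -1)
        out = cols @ wflat.T + bias.value  # (n, h*w, f)
        out = out.transpose(0, 2, 1).reshape(n, f, h, wd)

        def bwd(g):
            gflat = g.reshape(n, f, h * wd).transpose(0, 2, 1)  # (n, hw, f)
            if weight.requires_grad:
                gw = np.einsum("nif,nik->fk", gflat, cols).reshape(w.shape)
                weight._accum(gw)
            if bias.requires_grad:
                bias._accum(gflat.sum(axis=(0, 1)))
            if self.requires_grad:
                gcols = gflat @ wflat  # (n, hw, c*kh*kw)
                gcols = gcols.reshape(n, h, wd, c, kh, kw)
                gx = np.zeros((n, c, h + 2 * ph, wd + 2 * pw))
                for i in range(kh):
                    for j in range(kw):
                        gx[:, :, i : i + h, j : j + wd] += gcols[
                            :, :, :, :, i, j
                        ].transpose(0, 3, 1, 2)
                self._accum(gx[:, :, ph : ph + h, pw : pw + wd])

        return self._node(out, (self, weight, bias), bwd)

    def maxpool2(self):
        """2x2 max pooling, stride 2; spatial dims must be even."""
        n, c, h, w = self.value.shape
        xr = self.value.reshape(n, c, h // 2, 2, w // 2, 2)
        xr = xr.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h // 2, w // 2, 4)
        idx = xr.argmax(axis=-1)
        out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]

        def bwd(g):
            if not self.requires_grad:
                return
            gr = np.zeros((n, c, h // 2, w // 2, 4))
            np.put_along_axis(gr, idx[..., None], g[..., None], axis=-1)
            gr = gr.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
            self._accum(gr.reshape(n, c, h, w))

        return self._node(out, (self,), bwd)

    def upsample2(self):
        """Nearest-neighbour 2x upsampling."""
        out = self.value.repeat(2, axis=2).repeat(2, axis=3)
        n, c, h, w = self.value.shape

        def bwd(g):
            if self.requires_grad:
                gr = g.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5))
                self._accum(gr)

        return self._node(out, (self,), bwd)


# -- initialisation and optimisation ------------------------------------


def he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


def glorot_init(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    lim = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-lim, lim, size=(fan_in, fan_out))


class Adam:
    """Adam optimiser over a list of parameter Tensors."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
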