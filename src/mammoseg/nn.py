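"""Minimal reverse-mode automatic differentiation over numpy arrays.

Provides exactly the operations the package's two networks need: dense and
3D convolutional layers, instance normalization, leaky ReLU, pooling,
nearest-neighbor upsampling, channel softmax, and the reductions used by
the training losses. Gradients are accumulated by a topological backward
sweep; convolution is implemented as shift-and-matmul over kernel taps,
which keeps both directions cache-friendly without materializing im2col
buffers.

All array layouts are channel-first: volumes are ``(C, D, H, W)``,
vectors ``(n,)``.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

__all__ = ["Tensor", "Parameter", "Adam", "Conv3d", "Linear", "InstanceNorm3d"]


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward: Callable[[], None] | None = None
        self._parents: tuple["Tensor", ...] = ()

    @property
    def shape(self):
        return self.data.shape

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=np.float64, copy=True)
        else:
            self.grad += g

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor through the graph."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [self]
        while stack:
            t = stack[-1]
            if id(t) in seen:
                stack.pop()
                continue
            unvisited = [p for p in t._parents if id(p) not in seen]
            if unvisited:
                stack.extend(unvisited)
            else:
                seen.add(id(t))
                topo.append(t)
                stack.pop()
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward()

    # -- arithmetic ------------------------------------------------------
    def __add__(self, other):
        other = _as_tensor(other)
        out = _node(self.data + other.data, (self, other))

        def bwd():
            self._accum(_unbroadcast(out.grad, self.shape))
            other._accum(_unbroadcast(out.grad, other.shape))

        out._backward = bwd
        return out

    __radd__ = __add__

    def __neg__(self):
        out = _node(-self.data, (self,))
        out._backward = lambda: self._accum(-out.grad)
        return out

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __mul__(self, other):
        other = _as_tensor(other)
        out = _node(self.data * other.data, (self, other))

        def bwd():
            self._accum(_unbroadcast(out.grad * other.data, self.shape))
            other._accum(_unbroadcast(out.grad * self.data, other.shape))

        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _as_tensor(other)
        out = _node(self.data / other.data, (self, other))

        def bwd():
            self._accum(_unbroadcast(out.grad / other.data, self.shape))
            other._accum(
                _unbroadcast(-out.grad * self.data / other.data**2, other.shape)
            )

        out._backward = bwd
        return out

    # -- reductions / shaping -------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = _node(self.data.sum(axis=axis, keepdims=keepdims), (self,))

        def bwd():
            g = out.grad
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.shape))

        out._backward = bwd
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        out = _node(self.data.reshape(*shape), (self,))
        out._backward = lambda: self._accum(out.grad.reshape(self.shape))
        return out

    # -- nonlinearities --------------------------------------------------
    def leaky_relu(self, slope: float = 0.01):
        mask = self.data > 0
        out = _node(np.where(mask, self.data, slope * self.data), (self,))
        out._backward = lambda: self._accum(out.grad * np.where(mask, 1.0, slope))
        return out

    def log(self):
        out = _node(np.log(self.data), (self,))
        out._backward = lambda: self._accum(out.grad / self.data)
        return out

    def clamp_min(self, lo: float):
        mask = self.data >= lo
        out = _node(np.maximum(self.data, lo), (self,))
        out._backward = lambda: self._accum(out.grad * mask)
        return out

    def softmax(self, axis: int = 0):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        s = e / e.sum(axis=axis, keepdims=True)
        out = _node(s, (self,))

        def bwd():
            g = out.grad
            self._accum(s * (g - (g * s).sum(axis=axis, keepdims=True)))

        out._backward = bwd
        return out


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _node(data: np.ndarray, parents: tuple[Tensor, ...]) -> Tensor:
    out = Tensor(data)
    out._parents = parents
    return out


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce a broadcast gradient back to ``shape``."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for i, s in enumerate(shape):
        if s == 1 and g.shape[i] != 1:
            g = g.sum(axis=i, keepdims=True)
    return g


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    out = _node(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors))
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bwd():
        for t, g in zip(tensors, np.split(out.grad, splits, axis=axis)):
            t._accum(g)

    out._backward = bwd
    return out


def avg_pool2(x: Tensor) -> Tensor:
    """2x average pooling over the three spatial axes of (C, D, H, W)."""
    c, d, h, w = x.shape
    if d % 2 or h % 2 or w % 2:
        raise ValueError(f"spatial dims must be even for 2x pooling, got {x.shape}")
    r = x.data.reshape(c, d // 2, 2, h // 2, 2, w // 2, 2)
    out = _node(r.mean(axis=(2, 4, 6)), (x,))

    def bwd():
        g = out.grad[:, :, None, :, None, :, None] / 8.0
        x._accum(np.broadcast_to(g, (c, d // 2, 2, h // 2, 2, w // 2, 2)).reshape(x.shape))

    out._backward = bwd
    return out


def upsample_nearest2(x: Tensor) -> Tensor:
    """2x nearest-neighbor upsampling over the spatial axes of (C, D, H, W)."""
    out_data = x.data.repeat(2, axis=1).repeat(2, axis=2).repeat(2, axis=3)
    out = _node(out_data, (x,))
    c, d, h, w = x.shape

    def bwd():
        g = out.grad.reshape(c, d, 2, h, 2, w, 2).sum(axis=(2, 4, 6))
        x._accum(g)

    out._backward = bwd
    return out


def global_mean(x: Tensor) -> Tensor:
    """Spatial global average pooling: (C, D, H, W) -> (C,)."""
    return x.mean(axis=(1, 2, 3))


# -- layers --------------------------------------------------------------


class Module:
    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        for v in vars(self).values():
            if isinstance(v, Parameter):
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def state_dict(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state_dict(self, state: Sequence[np.ndarray]) -> None:
        params = self.parameters()
        if len(state) != len(params):
            raise ValueError("state length mismatch")
        for p, s in zip(params, state):
            p.data = np.array(s, dtype=np.float64, copy=True)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        bound = np.sqrt(2.0 / n_in)
        self.weight = Parameter(rng.normal(0.0, bound, size=(n_out, n_in)))
        self.bias = Parameter(np.zeros(n_out))

    def __call__(self, x: Tensor) -> Tensor:
        out = _node(x.data @ self.weight.data.T + self.bias.data, (x, self.weight, self.bias))

        def bwd():
            g = out.grad
            x._accum(g @ self.weight.data)
            if g.ndim == 1:
                self.weight._accum(np.outer(g, x.data))
                self.bias._accum(g)
            else:
                self.weight._accum(g.T @ x.data)
                self.bias._accum(g.sum(axis=0))

        out._backward = bwd
        return out


class Conv3d(Module):
    """3D convolution, stride 1, 'same' padding for odd kernels.

    Both passes loop over the k^3 kernel taps, each tap contributing one
    (c_out, c_in) matrix product against a shifted view of the padded
    input — far cheaper on CPU than materializing im2col columns.
    """

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        fan_in = c_in * k**3
        self.weight = Parameter(rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, c_in, k, k, k)))
        self.bias = Parameter(np.zeros(c_out))
        self.k = k
        self.pad = (k - 1) // 2

    def __call__(self, x: Tensor) -> Tensor:
        c_in, d, h, w = x.shape
        c_out = self.weight.shape[0]
        k, p = self.k, self.pad
        n = d * h * w
        xp = np.pad(x.data, ((0, 0), (p, p), (p, p), (p, p)))
        # shift-and-matmul: one (c_out, c_in) product per kernel tap
        out_mat = np.broadcast_to(self.bias.data[:, None], (c_out, n)).copy()
        for a in range(k):
            for b in range(k):
                for c in range(k):
                    xs = xp[:, a : a + d, b : b + h, c : c + w].reshape(c_in, n)
                    out_mat += self.weight.data[:, :, a, b, c] @ xs
        out = _node(out_mat.reshape(c_out, d, h, w), (x, self.weight, self.bias))

        def bwd():
            g = out.grad.reshape(c_out, n)
            dw = np.empty_like(self.weight.data)
            need_dx = bool(x.requires_grad or x._parents)
            gxp = np.zeros_like(xp) if need_dx else None
            for a in range(k):
                for b in range(k):
                    for c in range(k):
                        xs = xp[:, a : a + d, b : b + h, c : c + w].reshape(c_in, n)
                        dw[:, :, a, b, c] = g @ xs.T
                        if need_dx:
                            gxp[:, a : a + d, b : b + h, c : c + w] += (
                                self.weight.data[:, :, a, b, c].T @ g
                            ).reshape(c_in, d, h, w)
            self.weight._accum(dw)
            self.bias._accum(g.sum(axis=1))
            if need_dx:
                x._accum(gxp[:, p : p + d, p : p + h, p : p + w] if p else gxp)

        out._backward = bwd
        return out


class InstanceNorm3d(Module):
    """Per-channel normalization over the spatial axes with affine scale/shift."""

    def __init__(self, c: int, eps: float = 1e-5):
        self.gamma = Parameter(np.ones((c, 1, 1, 1)))
        self.beta = Parameter(np.zeros((c, 1, 1, 1)))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        axes = (1, 2, 3)
        mu = x.data.mean(axis=axes, keepdims=True)
        var = x.data.var(axis=axes, keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x.data - mu) * inv
        out = _node(xhat * self.gamma.data + self.beta.data, (x, self.gamma, self.beta))
        n = x.data[0].size

        def bwd():
            g = out.grad
            self.gamma._accum((g * xhat).sum(axis=axes, keepdims=True))
            self.beta._accum(g.sum(axis=axes, keepdims=True))
            gx_hat = g * self.gamma.data
            dx = (
                gx_hat
                - gx_hat.mean(axis=axes, keepdims=True)
                - xhat * (gx_hat * xhat).mean(axis=axes, keepdims=True)
            ) * inv
            x._accum(dx)

        out._backward = bwd
        return out


class Adam:
    """Adam optimizer with the standard bias-corrected moment estimates."""

    def __init__(self, params: Sequence[Parameter], lr: float, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            self.m[i] = b1 * self.m[i] + (1 - b1) * p.grad
            self.v[i] = b2 * self.v[i] + (1 - b2) * p.grad**2
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
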