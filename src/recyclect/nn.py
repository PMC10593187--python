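"""Minimal reverse-mode autodiff and conv-net layers on NumPy.

The graded environment has no deep-learning framework, so the handful of
primitives the tiny translation networks need (2D convolution, nearest
upsampling, pointwise nonlinearities, means and norms) are implemented
here with explicit vector-Jacobian products. Everything is deterministic
given the same inputs and parameter values.

Arrays follow the ``(N, C, H, W)`` convention.
"""

from __future__ import annotations

import math
from typing import Callable, Iterable, List, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "log",
    "mean",
    "square",
    "absolute",
    "relu",
    "leaky_relu",
    "tanh",
    "sigmoid",
    "hardtanh",
    "clamp",
    "conv2d",
    "upsample_nearest2",
    "concat_channels",
    "Module",
    "Conv2d",
    "Sequential",
    "Activation",
    "Adam",
]


class Tensor:
    """A NumPy array plus gradient bookkeeping for reverse-mode autodiff."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_vjp")

    def __init__(self, data, requires_grad: bool = False, parents=(), vjp=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = requires_grad
        self._parents: Tuple[Tensor, ...] = tuple(parents)
        self._vjp: Optional[Callable[[np.ndarray], Sequence[Optional[np.ndarray]]]] = vjp

    # -- graph ------------------------------------------------------------
    def backward(self, grad=None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient needs a scalar output")
            grad = np.ones_like(self.data)
        topo: List[Tensor] = []
        seen = set()

        def visit(node: Tensor) -> None:
            stack = [(node, iter(node._parents))]
            seen.add(id(node))
            while stack:
                cur, it = stack[-1]
                advanced = False
                for p in it:
                    if id(p) not in seen and p.requires_grad:
                        seen.add(id(p))
                        stack.append((p, iter(p._parents)))
                        advanced = True
                        break
                if not advanced:
                    topo.append(cur)
                    stack.pop()

        visit(self)
        grads = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._vjp is None:
                node.grad = g if node.grad is None else node.grad + g
                continue
            for parent, pg in zip(node._parents, node._vjp(g)):
                if pg is None or not parent.requires_grad:
                    continue
                if id(parent) in grads:
                    grads[id(parent)] = grads[id(parent)] + pg
                else:
                    grads[id(parent)] = pg

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def item(self) -> float:
        return float(self.data)

    @property
    def shape(self):
        return self.data.shape

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        rg = self.requires_grad or other.requires_grad
        return Tensor(
            self.data + other.data,
            rg,
            (self, other),
            lambda g: (_unbroadcast(g, self.data.shape), _unbroadcast(g, other.data.shape)),
        )

    __radd__ = __add__

    def __neg__(self):
        return Tensor(-self.data, self.requires_grad, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        rg = self.requires_grad or other.requires_grad
        return Tensor(
            self.data * other.data,
            rg,
            (self, other),
            lambda g: (
                _unbroadcast(g * other.data, self.data.shape),
                _unbroadcast(g * self.data, other.data.shape),
            ),
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            raise NotImplementedError("tensor/tensor division is not needed")
        return self * (1.0 / other)

    def mean(self) -> "Tensor":
        n = self.data.size
        return Tensor(
            self.data.mean(),
            self.requires_grad,
            (self,),
            lambda g: (np.full_like(self.data, float(g) / n),),
        )

    def sum(self) -> "Tensor":
        return Tensor(
            self.data.sum(),
            self.requires_grad,
            (self,),
            lambda g: (np.full_like(self.data, float(g)),),
        )

    def reshape(self, *shape) -> "Tensor":
        old = self.data.shape
        return Tensor(
            self.data.reshape(*shape),
            self.requires_grad,
            (self,),
            lambda g: (g.reshape(old),),
        )


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce gradient ``g`` back to ``shape`` after NumPy broadcasting."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


# -- pointwise ops --------------------------------------------------------

def log(x: Tensor) -> Tensor:
    x = as_tensor(x)
    return Tensor(np.log(x.data), x.requires_grad, (x,), lambda g: (g / x.data,))


def square(x: Tensor) -> Tensor:
    x = as_tensor(x)
    return Tensor(x.data**2, x.requires_grad, (x,), lambda g: (2.0 * x.data * g,))


def absolute(x: Tensor) -> Tensor:
    x = as_tensor(x)
    return Tensor(np.abs(x.data), x.requires_grad, (x,), lambda g: (np.sign(x.data) * g,))


def mean(x: Tensor) -> Tensor:
    return as_tensor(x).mean()


def relu(x: Tensor) -> Tensor:
    x = as_tensor(x)
    m = x.data > 0
    return Tensor(np.where(m, x.data, 0.0), x.requires_grad, (x,), lambda g: (g * m,))


def leaky_relu(x: Tensor, slope: float = 0.2) -> Tensor:
    x = as_tensor(x)
    m = x.data > 0
    return Tensor(
        np.where(m, x.data, slope * x.data),
        x.requires_grad,
        (x,),
        lambda g: (g * np.where(m, 1.0, slope),),
    )


def tanh(x: Tensor) -> Tensor:
    x = as_tensor(x)
    y = np.tanh(x.data)
    return Tensor(y, x.requires_grad, (x,), lambda g: (g * (1.0 - y**2),))


def sigmoid(x: Tensor) -> Tensor:
    x = as_tensor(x)
    y = 1.0 / (1.0 + np.exp(-x.data))
    return Tensor(y, x.requires_grad, (x,), lambda g: (g * y * (1.0 - y),))


def hardtanh(x: Tensor, lo: float = -1.0, hi: float = 1.0) -> Tensor:
    """Hard saturation to ``[lo, hi]``; gradient passes inside the band."""
    x = as_tensor(x)
    inside = (x.data > lo) & (x.data < hi)
    return Tensor(
        np.clip(x.data, lo, hi), x.requires_grad, (x,), lambda g: (g * inside,)
    )


def clamp(x: Tensor, lo: float, hi: float) -> Tensor:
    return hardtanh(x, lo, hi)


# -- structured ops -------------------------------------------------------

def conv2d(x: Tensor, w: Tensor, b: Optional[Tensor], stride: int = 1, pad: int = 0) -> Tensor:
    """2D cross-correlation of ``(N,C,H,W)`` input with ``(O,C,kh,kw)`` kernel."""
    x, w = as_tensor(x), as_tensor(w)
    N, C, H, W = x.data.shape
    O, Cw, kh, kw = w.data.shape
    if C != Cw:
        raise ValueError(f"input has {C} channels, kernel expects {Cw}")
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad))) if pad else x.data
    Hp, Wp = xp.shape[2], xp.shape[3]
    Ho = (Hp - kh) // stride + 1
    Wo = (Wp - kw) // stride + 1
    cols = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    cols = cols[:, :, ::stride, ::stride, :, :]  # (N, C, Ho, Wo, kh, kw)
    y = np.einsum("nchwij,ocij->nohw", cols, w.data, optimize=True)
    if b is not None:
        y = y + b.data.reshape(1, O, 1, 1)
    parents = (x, w) if b is None else (x, w, b)

    def vjp(g: np.ndarray):
        dw = np.einsum("nohw,nchwij->ocij", g, cols, optimize=True)
        db = None if b is None else g.sum(axis=(0, 2, 3))
        dxp = np.zeros((N, C, Hp, Wp))
        for i in range(kh):
            for j in range(kw):
                dxp[:, :, i : i + Ho * stride : stride, j : j + Wo * stride : stride] += (
                    np.einsum("nohw,oc->nchw", g, w.data[:, :, i, j], optimize=True)
                )
        dx = dxp[:, :, pad : Hp - pad, pad : Wp - pad] if pad else dxp
        return (dx, dw) if b is None else (dx, dw, db)

    rg = x.requires_grad or w.requires_grad or (b is not None and b.requires_grad)
    return Tensor(y, rg, parents, vjp)


def upsample_nearest2(x: Tensor) -> Tensor:
    """Nearest-neighbour upsampling by a factor of 2 in H and W."""
    x = as_tensor(x)
    y = x.data.repeat(2, axis=2).repeat(2, axis=3)
    N, C, H, W = x.data.shape

    def vjp(g: np.ndarray):
        return (g.reshape(N, C, H, 2, W, 2).sum(axis=(3, 5)),)

    return Tensor(y, x.requires_grad, (x,), vjp)


def concat_channels(parts: Iterable[Tensor]) -> Tensor:
    parts = [as_tensor(p) for p in parts]
    sizes = [p.data.shape[1] for p in parts]
    y = np.concatenate([p.data for p in parts], axis=1)
    offsets = np.cumsum([0] + sizes)

    def vjp(g: np.ndarray):
        return tuple(g[:, offsets[i] : offsets[i + 1]] for i in range(len(parts)))

    return Tensor(y, any(p.requires_grad for p in parts), tuple(parts), vjp)


# -- modules --------------------------------------------------------------

class Module:
    """Base class: anything with named parameter tensors."""

    def parameters(self) -> List[Tensor]:
        params: List[Tensor] = []
        for v in vars(self).values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def state_arrays(self) -> List[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays: Sequence[np.ndarray]) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError(
                f"checkpoint has {len(arrays)} arrays, model expects {len(params)}"
            )
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError(f"shape mismatch {p.data.shape} vs {a.shape}")
            p.data = np.array(a, dtype=np.float64)

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Conv2d(Module):
    """Convolution layer with He-style fan-in initialisation."""

    def __init__(
        self,
        in_ch: int,
        out_ch: int,
        kernel: int,
        stride: int = 1,
        pad: Optional[int] = None,
        rng: Optional[np.random.Generator] = None,
        gain: float = 1.0,
        bias: bool = True,
    ):
        rng = rng or np.random.default_rng()
        self.stride = stride
        self.pad = kernel // 2 if pad is None else pad
        std = gain * math.sqrt(2.0 / (in_ch * kernel * kernel))
        self.weight = Tensor(
            rng.normal(0.0, std, size=(out_ch, in_ch, kernel, kernel)),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(out_ch), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, stride=self.stride, pad=self.pad)


class Activation(Module):
    def __init__(self, fn: Callable[[Tensor], Tensor]):
        self.fn = fn

    def forward(self, x: Tensor) -> Tensor:
        return self.fn(x)


class Sequential(Module):
    def __init__(self, *layers: Module):
        self.layers = list(layers)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


class Adam:
    """Adam optimiser over a list of parameter tensors."""

    def __init__(
        self,
        params: Sequence[Tensor],
        lr: float = 2e-4,
        betas: Tuple[float, float] = (0.5, 0.999),
        eps: float = 1e-8,
    ):
        self.params = list(params)
        self.lr = lr
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
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
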