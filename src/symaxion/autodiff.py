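"""A small reverse-mode automatic-differentiation engine over numpy arrays.

Only the operations the classifier needs are implemented: broadcasting
arithmetic, (batched) matmul, shape ops, reductions, the usual nonlinearities,
softmax, 2-D and depthwise 2-D convolution via im2col, batch/layer
normalisation and a fused softmax cross-entropy.  Gradients are accumulated by
topological traversal of the recorded graph; every backward rule is verified
against central finite differences in the test suite.

Tensors keep whatever float dtype they are given (the network runs in float32,
gradient checks in float64).
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Parameter", "Module", "SGD"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._prev: tuple[Tensor, ...] = ()

    # -- graph bookkeeping -------------------------------------------------
    @staticmethod
    def _result(data, prev, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in prev):
            out.requires_grad = True
            out._prev = tuple(prev)
            out._backward = backward
        return out

    def _accum(self, g: np.ndarray) -> None:
        if self.requires_grad:
            self.grad = g if self.grad is None else self.grad + g

    def backward(self, grad=None) -> None:
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; graphs can be deep
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data) if grad is None else np.asarray(grad)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- basics ------------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._wrap(other)
        out_data = self.data + other.data

        def backward(g):
            self._accum(_unbroadcast(g, self.data.shape))
            other._accum(_unbroadcast(g, other.data.shape))

        return self._result(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            self._accum(-g)

        return self._result(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        out_data = self.data * other.data

        def backward(g):
            self._accum(_unbroadcast(g * other.data, self.data.shape))
            other._accum(_unbroadcast(g * self.data, other.data.shape))

        return self._result(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        out_data = self.data / other.data

        def backward(g):
            self._accum(_unbroadcast(g / other.data, self.data.shape))
            other._accum(_unbroadcast(-g * self.data / other.data**2, other.data.shape))

        return self._result(out_data, (self, other), backward)

    def __pow__(self, p: float):
        out_data = self.data**p

        def backward(g):
            self._accum(g * p * self.data ** (p - 1))

        return self._result(out_data, (self,), backward)

    def __matmul__(self, other):
        other = self._wrap(other)
        out_data = np.matmul(self.data, other.data)

        def backward(g):
            a, b = self.data, other.data
            ga = np.matmul(g, np.swapaxes(b, -1, -2)) if a.ndim > 1 else np.matmul(g, b.T)
            gb = np.matmul(np.swapaxes(a, -1, -2), g)
            self._accum(_unbroadcast(ga, a.shape))
            other._accum(_unbroadcast(gb, b.shape))

        return self._result(out_data, (self, other), backward)

    # -- shape ops ---------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.data.shape

        def backward(g):
            self._accum(g.reshape(orig))

        return self._result(self.data.reshape(shape), (self,), backward)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = tuple(np.argsort(axes))

        def backward(g):
            self._accum(g.transpose(inv))

        return self._result(self.data.transpose(axes), (self,), backward)

    # -- reductions --------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape).copy())

        return self._result(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- nonlinearities ----------------------------------------------------
    def relu(self):
        mask = self.data > 0

        def backward(g):
            self._accum(g * mask)

        return self._result(self.data * mask, (self,), backward)

    def sigmoid(self):
        x = self.data
        y = np.empty_like(x)
        pos = x >= 0
        y[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
        ex = np.exp(x[~pos])
        y[~pos] = ex / (1.0 + ex)

        def backward(g):
            self._accum(g * y * (1.0 - y))

        return self._result(y, (self,), backward)

    def exp(self):
        y = np.exp(self.data)

        def backward(g):
            self._accum(g * y)

        return self._result(y, (self,), backward)

    def log(self):
        def backward(g):
            self._accum(g / self.data)

        return self._result(np.log(self.data), (self,), backward)

    def softmax(self, axis: int = -1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        y = e / e.sum(axis=axis, keepdims=True)

        def backward(g):
            self._accum(y * (g - (g * y).sum(axis=axis, keepdims=True)))

        return self._result(y, (self,), backward)


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t._accum(piece)

    return Tensor._result(data, tuple(tensors), backward)


# --------------------------------------------------------------------------
# Convolutions (im2col)
# --------------------------------------------------------------------------

def _sliding(xp: np.ndarray, kh: int, kw: int, stride: int) -> np.ndarray:
    """View of shape (N, C, Ho, Wo, kh, kw) over a padded input."""
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    return win[:, :, ::stride, ::stride]


def _scatter_cols(gcols: np.ndarray, x_shape, kh, kw, stride, padding) -> np.ndarray:
    """Inverse of im2col: accumulate (N, Ho, Wo, C, kh, kw) grads into x."""
    n, c, h, w = x_shape
    hp, wp = h + 2 * padding, w + 2 * padding
    ho, wo = gcols.shape[1], gcols.shape[2]
    gx = np.zeros((n, c, hp, wp), dtype=gcols.dtype)
    for i in range(kh):
        for j in range(kw):
            gx[:, :, i : i + ho * stride : stride, j : j + wo * stride : stride] += (
                gcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
            )
    if padding:
        gx = gx[:, :, padding:-padding, padding:-padding]
    return gx


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, stride: int = 1, padding: int = 0) -> Tensor:
    """2-D convolution: x (N, C, H, W), w (O, C, kh, kw) -> (N, O, Ho, Wo)."""
    n, c, h, wd = x.data.shape
    o, cw, kh, kw = w.data.shape
    if cw != c:
        raise ValueError(f"channel mismatch: input {c}, weight {cw}")
    if kh == 1 and kw == 1 and padding == 0:
        xs = x.data[:, :, ::stride, ::stride]
        ho, wo = xs.shape[2], xs.shape[3]
        cols = xs.transpose(0, 2, 3, 1).reshape(-1, c)  # (N*Ho*Wo, C)
    else:
        xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
        win = _sliding(xp, kh, kw, stride)
        ho, wo = win.shape[2], win.shape[3]
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(-1, c * kh * kw)
    wmat = w.data.reshape(o, -1)
    out = cols @ wmat.T
    out = out.reshape(n, ho, wo, o).transpose(0, 3, 1, 2)
    if b is not None:
        out = out + b.data.reshape(1, o, 1, 1)

    def backward(g):
        gmat = g.transpose(0, 2, 3, 1).reshape(-1, o)
        if w.requires_grad:
            w._accum((gmat.T @ cols).reshape(w.data.shape))
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gcols = gmat @ wmat  # (N*Ho*Wo, C*kh*kw)
            if kh == 1 and kw == 1 and padding == 0:
                gxs = gcols.reshape(n, ho, wo, c).transpose(0, 3, 1, 2)
                if stride == 1:
                    x._accum(gxs)
                else:
                    gx = np.zeros_like(x.data)
                    gx[:, :, ::stride, ::stride] = gxs
                    x._accum(gx)
            else:
                gcols6 = gcols.reshape(n, ho, wo, c, kh, kw)
                x._accum(_scatter_cols(gcols6, x.data.shape, kh, kw, stride, padding))

    prev = (x, w) if b is None else (x, w, b)
    return Tensor._result(out, prev, backward)


def depthwise_conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, stride: int = 1, padding: int = 1) -> Tensor:
    """Depthwise convolution: x (N, C, H, W), w (C, kh, kw), one filter per channel."""
    n, c, h, wd = x.data.shape
    cw, kh, kw = w.data.shape
    if cw != c:
        raise ValueError(f"channel mismatch: input {c}, weight {cw}")
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    win = _sliding(xp, kh, kw, stride)  # (N, C, Ho, Wo, kh, kw)
    out = np.einsum("nchwij,cij->nchw", win, w.data, optimize=True)
    if b is not None:
        out = out + b.data.reshape(1, c, 1, 1)

    def backward(g):
        if w.requires_grad:
            w._accum(np.einsum("nchw,nchwij->cij", g, win, optimize=True))
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            ho, wo = g.shape[2], g.shape[3]
            hp, wp = h + 2 * padding, wd + 2 * padding
            gx = np.zeros((n, c, hp, wp), dtype=g.dtype)
            for i in range(kh):
                for j in range(kw):
                    gx[:, :, i : i + ho * stride : stride, j : j + wo * stride : stride] += (
                        g * w.data[:, i, j].reshape(1, c, 1, 1)
                    )
            if padding:
                gx = gx[:, :, padding:-padding, padding:-padding]
            x._accum(gx)

    prev = (x, w) if b is None else (x, w, b)
    return Tensor._result(out, prev, backward)


# --------------------------------------------------------------------------
# Normalisation and loss
# --------------------------------------------------------------------------

def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Layer normalisation over the last axis."""
    mu = x.data.mean(axis=-1, keepdims=True)
    var = x.data.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    out = gamma.data * xhat + beta.data

    def backward(g):
        if gamma.requires_grad:
            gamma._accum(_unbroadcast(g * xhat, gamma.data.shape))
        if beta.requires_grad:
            beta._accum(_unbroadcast(g, beta.data.shape))
        if x.requires_grad:
            gh = g * gamma.data
            m = x.data.shape[-1]
            gx = (
                gh - gh.mean(axis=-1, keepdims=True) - xhat * (gh * xhat).mean(axis=-1, keepdims=True)
            ) * inv
            del m
            x._accum(gx)

    return Tensor._result(out, (x, gamma, beta), backward)


def batch_norm2d(
    x: Tensor,
    gamma: Tensor,
    beta: Tensor,
    running_mean: np.ndarray,
    running_var: np.ndarray,
    training: bool,
    momentum: float = 0.1,
    eps: float = 1e-5,
) -> Tensor:
    """Batch normalisation over (N, H, W) per channel of an NCHW tensor.

    In training mode batch statistics are used and the running buffers are
    updated in place; in eval mode the op is the affine map defined by the
    running statistics.
    """
    gshape = (1, -1, 1, 1)
    if training:
        mu = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        running_mean *= 1.0 - momentum
        running_mean += momentum * mu
        running_var *= 1.0 - momentum
        running_var += momentum * var
    else:
        mu, var = running_mean, running_var
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu.reshape(gshape)) * inv.reshape(gshape)
    out = gamma.data.reshape(gshape) * xhat + beta.data.reshape(gshape)

    def backward(g):
        if gamma.requires_grad:
            gamma._accum((g * xhat).sum(axis=(0, 2, 3)))
        if beta.requires_grad:
            beta._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gh = g * gamma.data.reshape(gshape)
            if training:
                m = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
                mean_gh = gh.mean(axis=(0, 2, 3)).reshape(gshape)
                mean_ghx = (gh * xhat).mean(axis=(0, 2, 3)).reshape(gshape)
                gx = (gh - mean_gh - xhat * mean_ghx) * inv.reshape(gshape)
                del m
            else:
                gx = gh * inv.reshape(gshape)
            x._accum(gx)

    return Tensor._result(out, (x, gamma, beta), backward)


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean softmax cross-entropy; ``labels`` are integer class ids."""
    labels = np.asarray(labels)
    n = logits.data.shape[0]
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    lse = np.log(np.exp(z).sum(axis=1, keepdims=True))
    logp = z - lse
    loss = -logp[np.arange(n), labels].mean()

    def backward(g):
        p = np.exp(logp)
        p[np.arange(n), labels] -= 1.0
        logits._accum(g * p / n)

    return Tensor._result(np.asarray(loss), (logits,), backward)


# --------------------------------------------------------------------------
# Modules and optimiser
# --------------------------------------------------------------------------

class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data):
        super().__init__(np.asarray(data), requires_grad=True)


class Module:
    """Minimal module container: tracks parameters, children and train mode."""

    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_children", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._params[name] = value
        elif isinstance(value, Module):
            self._children[name] = value
        object.__setattr__(self, name, value)

    def parameters(self) -> list[Parameter]:
        out = list(self._params.values())
        for child in self._children.values():
            out.extend(child.parameters())
        return out

    def modules(self) -> list["Module"]:
        out = [self]
        for child in self._children.values():
            out.extend(child.modules())
        return out

    def train(self, mode: bool = True) -> "Module":
        for m in self.modules():
            object.__setattr__(m, "training", mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    # checkpointing ---------------------------------------------------------
    def state_arrays(self, prefix: str = "") -> dict[str, np.ndarray]:
        out = {prefix + name: p.data for name, p in self._params.items()}
        for key in ("running_mean", "running_var"):
            buf = getattr(self, key, None)
            if isinstance(buf, np.ndarray):
                out[prefix + key] = buf
        for cname, child in self._children.items():
            out.update(child.state_arrays(prefix + cname + "."))
        return out

    def load_state_arrays(self, arrays: dict[str, np.ndarray], prefix: str = "") -> None:
        for name, p in self._params.items():
            p.data = np.asarray(arrays[prefix + name])
        for key in ("running_mean", "running_var"):
            if isinstance(getattr(self, key, None), np.ndarray):
                object.__setattr__(self, key, np.asarray(arrays[prefix + key]))
        for cname, child in self._children.items():
            child.load_state_arrays(arrays, prefix + cname + ".")


class SGD:
    """Stochastic gradient descent with momentum and L2 weight decay.

    ``weight_decay`` adds ``wd * w`` to the gradient of every parameter with
    more than one dimension (biases and normalisation scales are exempt, the
    usual convention).  ``momentum = 0`` recovers plain SGD.
    """

    def __init__(
        self,
        params: list[Parameter],
        lr: float,
        weight_decay: float = 0.0,
        momentum: float = 0.0,
    ):
        self.params = params
        self.lr = lr
        self.weight_decay = weight_decay
        self.momentum = momentum
        self._velocity = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        for p, v in zip(self.params, self._velocity):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay and p.data.ndim > 1:
                g = g + self.weight_decay * p.data
            if self.momentum:
                v *= self.momentum
                v += g.astype(p.data.dtype)
                g = v
            p.data = p.data - self.lr * np.asarray(g, dtype=p.data.dtype)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
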