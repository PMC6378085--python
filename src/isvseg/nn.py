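"""Small reverse-mode automatic-differentiation core and neural-network layers.

Everything runs on NumPy float64 arrays. The graph is built dynamically:
each operation returns a :class:`Tensor` holding the forward value, the
parent tensors and a closure that scatters the output gradient back to the
parents. ``Tensor.backward()`` runs a topological sort and accumulates
gradients. Only the operations the segmentation network needs are provided
(3x3 / 1x1 convolution, 2x2 stride-2 transposed convolution, 2x2 max
pooling, batch normalization, ReLU, sigmoid, log, clamp, elementwise
arithmetic, channel concatenation and reductions).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "Parameter",
    "Module",
    "Conv2d",
    "ConvTranspose2d",
    "BatchNorm2d",
    "SGD",
    "Adam",
    "relu",
    "sigmoid",
    "log",
    "clamp",
    "concat",
    "maxpool2x2",
]


# ---------------------------------------------------------------------------
# Tensor and autodiff machinery
# ---------------------------------------------------------------------------

class Tensor:
    """An n-d array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    # make `ndarray <op> Tensor` defer to the reflected Tensor operators
    __array_ufunc__ = None

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        out.requires_grad = any(p.requires_grad for p in parents)
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def _accumulate(self, g):
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar")
            grad = np.ones_like(self.data)
        # topological order via iterative DFS
        topo: list[Tensor] = []
        visited: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in visited:
                    stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = _as_tensor(other)

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.data.shape))

        return Tensor._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            if self.requires_grad:
                self._accumulate(-g)

        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __mul__(self, other):
        other = _as_tensor(other)

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        return Tensor._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, scalar):
        return self * (1.0 / float(scalar))

    def sum(self):
        def backward(g):
            self._accumulate(np.full_like(self.data, float(g)))

        return Tensor._make(self.data.sum(), (self,), backward)

    def mean(self):
        return self.sum() / self.data.size

    def reshape(self, *shape):
        old = self.data.shape

        def backward(g):
            self._accumulate(g.reshape(old))

        return Tensor._make(self.data.reshape(*shape), (self,), backward)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(g, shape):
    """Sum gradient ``g`` down to ``shape`` (inverse of NumPy broadcasting)."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


# ---------------------------------------------------------------------------
# Pointwise functions
# ---------------------------------------------------------------------------

def relu(x: Tensor) -> Tensor:
    mask = x.data > 0

    def backward(g):
        x._accumulate(g * mask)

    return Tensor._make(np.where(mask, x.data, 0.0), (x,), backward)


def sigmoid(x: Tensor) -> Tensor:
    y = 1.0 / (1.0 + np.exp(-np.clip(x.data, -500.0, 500.0)))

    def backward(g):
        x._accumulate(g * y * (1.0 - y))

    return Tensor._make(y, (x,), backward)


def log(x: Tensor) -> Tensor:
    def backward(g):
        x._accumulate(g / x.data)

    return Tensor._make(np.log(x.data), (x,), backward)


def clamp(x: Tensor, lo: float, hi: float) -> Tensor:
    """Clip to [lo, hi]; gradient passes only where the input is interior."""
    inside = (x.data >= lo) & (x.data <= hi)

    def backward(g):
        x._accumulate(g * inside)

    return Tensor._make(np.clip(x.data, lo, hi), (x,), backward)


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(a, b)
                t._accumulate(g[tuple(idx)])

    return Tensor._make(
        np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), backward
    )


def maxpool2x2(x: Tensor) -> Tensor:
    """2x2 max pooling with stride 2 over (N, C, H, W); ties go to the
    first window element in row-major order."""
    n, c, h, w = x.data.shape
    if h % 2 or w % 2:
        raise ValueError(f"maxpool2x2 needs even spatial size, got {h}x{w}")
    win = x.data.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    win = win.reshape(n, c, h // 2, w // 2, 4)
    idx = win.argmax(axis=-1)
    out = np.take_along_axis(win, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        onehot = (idx[..., None] == np.arange(4)).astype(np.float64)
        gwin = g[..., None] * onehot
        gwin = gwin.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        x._accumulate(gwin.reshape(n, c, h, w))

    return Tensor._make(out, (x,), backward)


# ---------------------------------------------------------------------------
# Convolutions
# ---------------------------------------------------------------------------

def _im2col(xp, k):
    """(N, C, Hp, Wp) padded input -> (N*Ho*Wo, C*k*k) patch matrix."""
    view = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    # view: (N, C, Ho, Wo, k, k)
    n, c, ho, wo = view.shape[:4]
    cols = view.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * k * k)
    return np.ascontiguousarray(cols), (n, ho, wo)


def conv2d(x: Tensor, w: Tensor, b: Tensor | None, padding: int) -> Tensor:
    """Stride-1 2-D convolution (cross-correlation) over (N, C, H, W)."""
    k = w.data.shape[2]
    p = padding
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p))) if p else x.data
    cols, (n, ho, wo) = _im2col(xp, k)
    o = w.data.shape[0]
    wflat = w.data.reshape(o, -1)
    out = cols @ wflat.T
    if b is not None:
        out += b.data
    out = out.reshape(n, ho, wo, o).transpose(0, 3, 1, 2)
    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        gflat = g.transpose(0, 2, 3, 1).reshape(-1, o)
        if w.requires_grad:
            w._accumulate((gflat.T @ cols).reshape(w.data.shape))
        if b is not None and b.requires_grad:
            b._accumulate(gflat.sum(axis=0))
        if x.requires_grad:
            gcols = gflat @ wflat  # (N*Ho*Wo, C*k*k)
            c = x.data.shape[1]
            gcols = gcols.reshape(n, ho, wo, c, k, k).transpose(0, 3, 1, 2, 4, 5)
            gxp = np.zeros_like(xp)
            for di in range(k):
                for dj in range(k):
                    gxp[:, :, di:di + ho, dj:dj + wo] += gcols[:, :, :, :, di, dj]
            x._accumulate(gxp[:, :, p:p + x.data.shape[2], p:p + x.data.shape[3]]
                          if p else gxp)

    return Tensor._make(out, parents, backward)


def conv_transpose2x2(x: Tensor, w: Tensor, b: Tensor | None) -> Tensor:
    """2x2 transposed convolution with stride 2; doubles spatial size.

    Weight layout is (C_in, C_out, 2, 2): each input pixel deposits a
    weighted 2x2 block into the output.
    """
    n, c, h, wd = x.data.shape
    o = w.data.shape[1]
    out6 = np.einsum("nchw,coab->nohawb", x.data, w.data, optimize=True)
    out = out6.reshape(n, o, 2 * h, 2 * wd)
    if b is not None:
        out = out + b.data[None, :, None, None]
    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        g6 = g.reshape(n, o, h, 2, wd, 2)
        if w.requires_grad:
            w._accumulate(np.einsum("nchw,nohawb->coab", x.data, g6, optimize=True))
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            x._accumulate(np.einsum("coab,nohawb->nchw", w.data, g6, optimize=True))

    return Tensor._make(out, parents, backward)


# ---------------------------------------------------------------------------
# Modules
# ---------------------------------------------------------------------------

class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Base class: registers parameters/submodules by attribute assignment."""

    def __init__(self):
        object.__setattr__(self, "_parameters", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._parameters[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def named_parameters(self, prefix: str = ""):
        for name, p in self._parameters.items():
            yield prefix + name, p
        for name, m in self._modules.items():
            yield from m.named_parameters(prefix + name + ".")

    def modules(self):
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def train(self, mode: bool = True):
        for m in self.modules():
            object.__setattr__(m, "training", mode)
        return self

    def eval(self):
        return self.train(False)

    def state_dict(self) -> dict:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, m in self._modules.items():
            for k, v in m._buffers_dict().items():
                state[name + "." + k] = v
        state.update(self._buffers_dict())
        return state

    def _buffers_dict(self) -> dict:
        out = {}
        for attr in ("running_mean", "running_var"):
            if hasattr(self, attr):
                out[attr] = getattr(self, attr).copy()
        for name, m in self._modules.items():
            for k, v in m._buffers_dict().items():
                out[name + "." + k] = v
        return out

    def load_state_dict(self, state: dict):
        params = dict(self.named_parameters())
        for key, value in state.items():
            if key in params:
                params[key].data = np.asarray(value, dtype=np.float64).copy()
            else:
                obj = self
                *path, attr = key.split(".")
                for part in path:
                    obj = obj._modules[part]
                if not hasattr(obj, attr):
                    raise KeyError(f"unknown state entry {key!r}")
                setattr(obj, attr, np.asarray(value, dtype=np.float64).copy())

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, padding: int = 0,
                 bias: bool = True):
        super().__init__()
        self.in_ch, self.out_ch = in_ch, out_ch
        self.kernel, self.padding = kernel, padding
        self.weight = Parameter(np.zeros((out_ch, in_ch, kernel, kernel)))
        self.bias = Parameter(np.zeros(out_ch)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, self.padding)


class ConvTranspose2d(Module):
    """2x2 stride-2 transposed convolution (the only geometry used here)."""

    def __init__(self, in_ch: int, out_ch: int, bias: bool = True):
        super().__init__()
        self.in_ch, self.out_ch = in_ch, out_ch
        self.weight = Parameter(np.zeros((in_ch, out_ch, 2, 2)))
        self.bias = Parameter(np.zeros(out_ch)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        return conv_transpose2x2(x, self.weight, self.bias)


class BatchNorm2d(Module):
    """Batch normalization over (N, H, W) per channel.

    Training mode normalizes with batch statistics and updates exponential
    running averages; evaluation mode uses the running averages, making the
    forward pass deterministic and batch-independent.
    """

    def __init__(self, num_features: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.num_features = num_features
        self.eps = eps
        self.momentum = momentum
        self.weight = Parameter(np.ones(num_features))
        self.bias = Parameter(np.zeros(num_features))
        self.running_mean = np.zeros(num_features)
        self.running_var = np.ones(num_features)

    def __call__(self, x: Tensor) -> Tensor:
        gamma, beta = self.weight, self.bias
        if self.training:
            axes = (0, 2, 3)
            m = x.data.mean(axis=axes)
            v = x.data.var(axis=axes)
            cnt = x.data.size / x.data.shape[1]
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * m
            unbiased = v * cnt / max(cnt - 1, 1)
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * unbiased
            inv = 1.0 / np.sqrt(v + self.eps)
            xhat = (x.data - m[None, :, None, None]) * inv[None, :, None, None]
            out = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]

            def backward(g):
                if gamma.requires_grad:
                    gamma._accumulate((g * xhat).sum(axis=axes))
                if beta.requires_grad:
                    beta._accumulate(g.sum(axis=axes))
                if x.requires_grad:
                    gxh = g * gamma.data[None, :, None, None]
                    t1 = gxh.mean(axis=axes)[None, :, None, None]
                    t2 = (gxh * xhat).mean(axis=axes)[None, :, None, None]
                    x._accumulate(inv[None, :, None, None] * (gxh - t1 - xhat * t2))

            return Tensor._make(out, (x, gamma, beta), backward)

        inv = 1.0 / np.sqrt(self.running_var + self.eps)
        xhat = (x.data - self.running_mean[None, :, None, None]) * inv[None, :, None, None]
        out = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]

        def backward(g):
            if gamma.requires_grad:
                gamma._accumulate((g * xhat).sum(axis=(0, 2, 3)))
            if beta.requires_grad:
                beta._accumulate(g.sum(axis=(0, 2, 3)))
            if x.requires_grad:
                x._accumulate(g * (gamma.data * inv)[None, :, None, None])

        return Tensor._make(out, (x, gamma, beta), backward)


# ---------------------------------------------------------------------------
# Optimizer
# ---------------------------------------------------------------------------

class SGD:
    """Stochastic gradient descent with classical momentum and L2 weight decay.

    Weight decay enters through the gradient (``g + wd * w``), the standard
    L2 contract, so reported loss values never include the penalty.
    """

    def __init__(self, params: list[Parameter], lr: float, momentum: float = 0.9,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self._velocity = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        for p, v in zip(self.params, self._velocity):
            if p.grad is None:
                continue
            g = p.grad + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data -= self.lr * v

    def zero_grad(self):
        for p in self.params:
            p.grad = None


class Adam:
    """Adam with decoupled-free (classical) L2 weight decay through the
    gradient; useful when a small step budget must fit a model tightly."""

    def __init__(self, params: list[Parameter], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.betas = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]
        self._t = 0

    def step(self):
        b1, b2 = self.betas
        self._t += 1
        c1 = 1.0 - b1 ** self._t
        c2 = 1.0 - b2 ** self._t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad + self.weight_decay * p.data
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * g * g
            p.data -= self.lr * (m / c1) / (np.sqrt(v / c2) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
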