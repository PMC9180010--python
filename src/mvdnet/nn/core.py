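"""Minimal NumPy layer library with explicit backward passes.

Only the operators the segmentation network needs are implemented:
2-D convolution (strided / dilated / grouped, hence depthwise and 1-D
asymmetric kernels), batch normalization, PReLU, sigmoid, 2x bilinear
upsampling, 2x2 average pooling, and channel-mean squeezing.  Every
layer caches what its backward pass needs during ``forward`` and
returns the input gradient from ``backward`` while accumulating
parameter gradients in place.

All arithmetic is float64.  Convolutions are evaluated by looping over
the (at most nine) kernel taps and contracting with ``einsum``, which
keeps memory flat and is fast for the small kernels used here; the
backward data pass scatter-adds through the same strided views.
"""

from __future__ import annotations

import numpy as np

from ..errors import InvalidInputError, InvalidSpecError

__all__ = [
    "Parameter",
    "Module",
    "ModuleList",
    "Sequential",
    "Conv2d",
    "BatchNorm2d",
    "PReLU",
    "Sigmoid",
    "UpsampleBilinear2x",
    "AvgPool2x2",
    "ChannelMean",
    "kaiming_normal",
]


class Parameter:
    """A trainable array together with its accumulated gradient."""

    __slots__ = ("data", "grad")

    def __init__(self, data: np.ndarray):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = np.zeros_like(self.data)

    @property
    def size(self) -> int:
        return self.data.size


def kaiming_normal(rng: np.random.Generator, shape, fan_in: int, a: float = 0.25) -> np.ndarray:
    """He-style normal init for layers followed by PReLU(a)."""
    std = np.sqrt(2.0 / ((1.0 + a * a) * fan_in))
    return rng.normal(0.0, std, size=shape)


class Module:
    """Base class; children and parameters register on attribute assignment."""

    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_children", {})
        object.__setattr__(self, "_buffers", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._params[name] = value
        elif isinstance(value, Module):
            self._children[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name: str, value: np.ndarray) -> None:
        self._buffers[name] = np.asarray(value, dtype=np.float64)
        object.__setattr__(self, name, self._buffers[name])

    def _set_buffer(self, name: str, value: np.ndarray) -> None:
        self._buffers[name] = np.asarray(value, dtype=np.float64)
        object.__setattr__(self, name, self._buffers[name])

    # -- traversal ----------------------------------------------------
    def named_parameters(self, prefix: str = ""):
        for k, p in self._params.items():
            yield prefix + k, p
        for k, c in self._children.items():
            yield from c.named_parameters(prefix + k + ".")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = ""):
        for k, b in self._buffers.items():
            yield prefix + k, b
        for k, c in self._children.items():
            yield from c.named_buffers(prefix + k + ".")

    def modules(self):
        yield self
        for c in self._children.values():
            yield from c.modules()

    # -- state --------------------------------------------------------
    def train(self, flag: bool = True):
        for m in self.modules():
            object.__setattr__(m, "training", flag)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad[...] = 0.0

    def num_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def state_dict(self) -> dict:
        out = {}
        for k, p in self.named_parameters():
            out["param:" + k] = p.data.copy()
        for k, b in self.named_buffers():
            out["buffer:" + k] = b.copy()
        return out

    def load_state_dict(self, state: dict) -> None:
        params = dict(self.named_parameters())
        for key, arr in state.items():
            kind, _, name = key.partition(":")
            if kind == "param":
                if name not in params:
                    raise KeyError(f"unknown parameter {name!r} in state dict")
                if params[name].data.shape != arr.shape:
                    raise InvalidInputError(
                        f"shape mismatch for {name}: {params[name].data.shape} vs {arr.shape}"
                    )
                params[name].data[...] = arr
            elif kind == "buffer":
                mod, attr = self._locate_buffer(name)
                mod._set_buffer(attr, arr)
            else:
                raise KeyError(f"malformed state key {key!r}")

    def _locate_buffer(self, dotted: str):
        mod = self
        parts = dotted.split(".")
        for p in parts[:-1]:
            mod = mod._children[p]
        if parts[-1] not in mod._buffers:
            raise KeyError(f"unknown buffer {dotted!r}")
        return mod, parts[-1]

    # subclasses implement forward/backward
    def forward(self, x):  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, grad_out):  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class ModuleList(Module):
    def __init__(self, mods=()):
        super().__init__()
        self._list = []
        for m in mods:
            self.append(m)

    def append(self, mod: Module):
        self._children[str(len(self._list))] = mod
        self._list.append(mod)

    def __iter__(self):
        return iter(self._list)

    def __len__(self):
        return len(self._list)

    def __getitem__(self, i):
        return self._list[i]


class Sequential(ModuleList):
    def forward(self, x):
        for m in self:
            x = m(x)
        return x

    def backward(self, grad_out):
        for m in reversed(self._list):
            grad_out = m.backward(grad_out)
        return grad_out


class Conv2d(Module):
    """2-D convolution with stride, dilation and groups.

    ``padding`` defaults to the amount that preserves spatial size at
    stride 1 (i.e. ``dilation * (k - 1) / 2`` per axis for odd kernels).
    """

    def __init__(self, in_channels, out_channels, kernel_size, *, stride=1,
                 dilation=1, groups=1, bias=False, padding=None,
                 rng: np.random.Generator | None = None):
        super().__init__()
        kh, kw = kernel_size if isinstance(kernel_size, tuple) else (kernel_size, kernel_size)
        if in_channels % groups or out_channels % groups:
            raise InvalidSpecError("channels must divide groups")
        self.in_channels, self.out_channels = in_channels, out_channels
        self.kh, self.kw = kh, kw
        self.stride, self.dilation, self.groups = stride, dilation, groups
        if padding is None:
            padding = (dilation * (kh - 1) // 2, dilation * (kw - 1) // 2)
        self.ph, self.pw = padding
        rng = rng or np.random.default_rng(0)
        fan_in = in_channels // groups * kh * kw
        self.weight = Parameter(
            kaiming_normal(rng, (out_channels, in_channels // groups, kh, kw), fan_in)
        )
        self.bias = Parameter(np.zeros(out_channels)) if bias else None
        self._x = None

    def _geometry(self, H, W):
        Hp, Wp = H + 2 * self.ph, W + 2 * self.pw
        eh = self.dilation * (self.kh - 1) + 1
        ew = self.dilation * (self.kw - 1) + 1
        if Hp < eh or Wp < ew:
            raise InvalidInputError(
                f"spatial size {H}x{W} smaller than effective kernel extent {eh}x{ew}"
            )
        Ho = (Hp - eh) // self.stride + 1
        Wo = (Wp - ew) // self.stride + 1
        return Hp, Wp, Ho, Wo

    def forward(self, x):
        N, C, H, W = x.shape
        if C != self.in_channels:
            raise InvalidInputError(f"expected {self.in_channels} channels, got {C}")
        Hp, Wp, Ho, Wo = self._geometry(H, W)
        xp = np.pad(x, ((0, 0), (0, 0), (self.ph, self.ph), (self.pw, self.pw)))
        G = self.groups
        xg = xp.reshape(N, G, C // G, Hp, Wp)
        wg = self.weight.data.reshape(G, self.out_channels // G, C // G, self.kh, self.kw)
        out = np.zeros((N, G, self.out_channels // G, Ho, Wo))
        s, d = self.stride, self.dilation
        for i in range(self.kh):
            for j in range(self.kw):
                xs = xg[:, :, :,
                        i * d: i * d + s * (Ho - 1) + 1: s,
                        j * d: j * d + s * (Wo - 1) + 1: s]
                out += np.einsum("gok,ngkhw->ngohw", wg[:, :, :, i, j], xs, optimize=True)
        out = out.reshape(N, self.out_channels, Ho, Wo)
        if self.bias is not None:
            out += self.bias.data[:, None, None]
        if self.training:
            self._x = x
            self._shape = (Hp, Wp, Ho, Wo)
        return out

    def backward(self, grad_out):
        x = self._x
        N, C, H, W = x.shape
        Hp, Wp, Ho, Wo = self._shape
        G, s, d = self.groups, self.stride, self.dilation
        xp = np.pad(x, ((0, 0), (0, 0), (self.ph, self.ph), (self.pw, self.pw)))
        xg = xp.reshape(N, G, C // G, Hp, Wp)
        wg = self.weight.data.reshape(G, self.out_channels // G, C // G, self.kh, self.kw)
        go = grad_out.reshape(N, G, self.out_channels // G, Ho, Wo)
        gw = np.zeros_like(wg)
        gxp = np.zeros((N, G, C // G, Hp, Wp))
        for i in range(self.kh):
            for j in range(self.kw):
                hs = slice(i * d, i * d + s * (Ho - 1) + 1, s)
                ws = slice(j * d, j * d + s * (Wo - 1) + 1, s)
                xs = xg[:, :, :, hs, ws]
                gw[:, :, :, i, j] += np.einsum("ngohw,ngkhw->gok", go, xs, optimize=True)
                gxp[:, :, :, hs, ws] += np.einsum("gok,ngohw->ngkhw", wg[:, :, :, i, j], go,
                                                  optimize=True)
        self.weight.grad += gw.reshape(self.weight.data.shape)
        if self.bias is not None:
            self.bias.grad += grad_out.sum(axis=(0, 2, 3))
        gx = gxp.reshape(N, C, Hp, Wp)
        if self.ph or self.pw:
            gx = gx[:, :, self.ph: Hp - self.ph, self.pw: Wp - self.pw]
        return gx


class BatchNorm2d(Module):
    """Batch normalization with affine transform.

    Normalizes with biased batch variance; running statistics use the
    unbiased estimate and momentum 0.1 (eps defaults to 1e-3).
    """

    def __init__(self, channels, *, eps=1e-3, momentum=0.1):
        super().__init__()
        self.channels, self.eps, self.momentum = channels, eps, momentum
        self.weight = Parameter(np.ones(channels))
        self.bias = Parameter(np.zeros(channels))
        self.register_buffer("running_mean", np.zeros(channels))
        self.register_buffer("running_var", np.ones(channels))
        self._cache = None

    def forward(self, x):
        if self.training:
            axes = (0, 2, 3)
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            n = x.shape[0] * x.shape[2] * x.shape[3]
            unbiased = var * n / max(n - 1, 1)
            self.running_mean *= 1 - self.momentum
            self.running_mean += self.momentum * mean
            self.running_var *= 1 - self.momentum
            self.running_var += self.momentum * unbiased
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[:, None, None]) * inv_std[:, None, None]
        out = self.weight.data[:, None, None] * xhat + self.bias.data[:, None, None]
        if self.training:
            self._cache = (xhat, inv_std)
        return out

    def backward(self, grad_out):
        xhat, inv_std = self._cache
        axes = (0, 2, 3)
        n = grad_out.shape[0] * grad_out.shape[2] * grad_out.shape[3]
        self.weight.grad += (grad_out * xhat).sum(axis=axes)
        self.bias.grad += grad_out.sum(axis=axes)
        g = grad_out * self.weight.data[:, None, None]
        gm = g.mean(axis=axes)
        gxm = (g * xhat).mean(axis=axes)
        gx = (g - gm[:, None, None] - xhat * gxm[:, None, None]) * inv_std[:, None, None]
        return gx


class PReLU(Module):
    """Per-channel parametric ReLU, slope initialized at 0.25."""

    def __init__(self, channels, init=0.25):
        super().__init__()
        self.channels = channels
        self.weight = Parameter(np.full(channels, init))
        self._x = None

    def forward(self, x):
        a = self.weight.data[:, None, None]
        out = np.where(x > 0, x, a * x)
        if self.training:
            self._x = x
        return out

    def backward(self, grad_out):
        x = self._x
        a = self.weight.data[:, None, None]
        self.weight.grad += (grad_out * np.minimum(x, 0.0)).sum(axis=(0, 2, 3))
        return grad_out * np.where(x > 0, 1.0, a)


class Sigmoid(Module):
    def __init__(self):
        super().__init__()
        self._y = None

    def forward(self, x):
        y = 1.0 / (1.0 + np.exp(-x))
        if self.training:
            self._y = y
        return y

    def backward(self, grad_out):
        y = self._y
        return grad_out * y * (1.0 - y)


_UP2_CACHE: dict[int, np.ndarray] = {}


def _up2_matrix(n: int) -> np.ndarray:
    """Dense (2n x n) 1-D bilinear interpolation matrix (half-pixel centers)."""
    U = _UP2_CACHE.get(n)
    if U is None:
        U = np.zeros((2 * n, n))
        for i in range(2 * n):
            src = (i + 0.5) / 2.0 - 0.5
            i0 = int(np.floor(src))
            f = src - i0
            lo = min(max(i0, 0), n - 1)
            hi = min(max(i0 + 1, 0), n - 1)
            U[i, lo] += 1.0 - f
            U[i, hi] += f
        _UP2_CACHE[n] = U
    return U


class UpsampleBilinear2x(Module):
    """Separable 2x bilinear upsampling (half-pixel-center convention).

    A fixed linear operator: backward is its exact transpose and infers
    the source size from the gradient shape, so one instance may be
    applied at several scales within a single forward pass.
    """

    def __init__(self):
        super().__init__()

    def forward(self, x):
        N, C, H, W = x.shape
        Uh, Uw = _up2_matrix(H), _up2_matrix(W)
        y = np.einsum("ph,nchw->ncpw", Uh, x, optimize=True)
        y = np.einsum("qw,ncpw->ncpq", Uw, y, optimize=True)
        return y

    def backward(self, grad_out):
        H, W = grad_out.shape[2] // 2, grad_out.shape[3] // 2
        Uh, Uw = _up2_matrix(H), _up2_matrix(W)
        g = np.einsum("qw,ncpq->ncpw", Uw, grad_out, optimize=True)
        return np.einsum("ph,ncpw->nchw", Uh, g, optimize=True)


class AvgPool2x2(Module):
    """Average pooling with kernel = stride = 2 (even sizes only)."""

    def __init__(self):
        super().__init__()

    def forward(self, x):
        N, C, H, W = x.shape
        if H % 2 or W % 2:
            raise InvalidInputError("AvgPool2x2 needs even spatial sizes")
        return x.reshape(N, C, H // 2, 2, W // 2, 2).mean(axis=(3, 5))

    def backward(self, grad_out):
        g = np.repeat(np.repeat(grad_out, 2, axis=2), 2, axis=3)
        return g / 4.0


class ChannelMean(Module):
    """Squeeze the channel axis to a single map by averaging."""

    def __init__(self):
        super().__init__()
        self._c = None

    def forward(self, x):
        if self.training:
            self._c = x.shape[1]
        return x.mean(axis=1, keepdims=True)

    def backward(self, grad_out):
        c = self._c
        return np.broadcast_to(grad_out / c, (grad_out.shape[0], c) + grad_out.shape[2:]).copy()
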