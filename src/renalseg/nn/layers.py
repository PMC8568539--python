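"""NumPy layers with hand-written forward/backward passes (NCHW layout)."""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Module",
    "Conv2d",
    "ConvTranspose2x2",
    "BatchNorm2d",
    "MaxPool2x2",
    "ReLU",
    "Sigmoid",
    "softmax_channels",
]


class Param:
    """A trainable tensor with an accumulated gradient."""

    __slots__ = ("data", "grad")

    def __init__(self, data: np.ndarray):
        self.data = np.asarray(data)
        self.grad = np.zeros_like(self.data)

    @property
    def shape(self):
        return self.data.shape

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Module:
    """Base class: recursive parameter discovery, state dicts, train/eval mode.

    Sub-modules and :class:`Param` attributes (including those inside plain
    lists) are found by walking ``__dict__``, in attribute order, which makes
    parameter naming deterministic.
    """

    def __init__(self):
        self.training = True

    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(value, Param):
                yield key, value
            elif isinstance(value, Module):
                yield from value.named_parameters(prefix=f"{key}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(prefix=f"{key}.{i}.")
                    elif isinstance(item, Param):
                        yield f"{key}.{i}", item

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def modules(self):
        yield self
        for value in vars(self).values():
            if isinstance(value, Module):
                yield from value.modules()
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        yield from item.modules()

    def num_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def train(self) -> None:
        for m in self.modules():
            m.training = True

    def eval(self) -> None:
        for m in self.modules():
            m.training = False

    # -- persistence ---------------------------------------------------
    def _named_buffers(self, prefix: str = ""):
        for name, value in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(value, Module):
                yield from value._named_buffers(prefix=f"{key}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item._named_buffers(prefix=f"{key}.{i}.")
            elif isinstance(value, np.ndarray) and name.startswith("running_"):
                yield key, value

    def state_dict(self) -> dict:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        state.update({name: buf.copy() for name, buf in self._named_buffers()})
        return state

    def load_state_dict(self, state: dict) -> None:
        params = dict(self.named_parameters())
        buffers = dict(self._named_buffers())
        for name, value in state.items():
            if name in params:
                if params[name].data.shape != value.shape:
                    raise ValueError(
                        f"shape mismatch for {name!r}: model "
                        f"{params[name].data.shape} vs checkpoint {value.shape}"
                    )
                params[name].data[...] = value
            elif name in buffers:
                buffers[name][...] = value
            else:
                raise KeyError(f"unexpected key in state dict: {name!r}")
        missing = (set(params) | set(buffers)) - set(state)
        if missing:
            raise KeyError(f"missing keys in state dict: {sorted(missing)}")


def _he_init(rng: np.random.Generator, shape, fan_in: int, dtype) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(dtype)


class Conv2d(Module):
    """2-D convolution (cross-correlation), stride 1, zero 'same' padding.

    Feature sizes are preserved for odd kernel sizes, matching the
    zero-filled convolutions used throughout the network.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, dtype=np.float32):
        super().__init__()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        fan_in = in_channels * kernel_size * kernel_size
        self.weight = Param(_he_init(rng, (out_channels, in_channels,
                                           kernel_size, kernel_size), fan_in, dtype))
        self.bias = Param(np.zeros(out_channels, dtype=dtype))
        self._cols = None

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        k = self.kernel_size
        p = k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        cols = np.empty((n, c, k, k, h, w), dtype=x.dtype)
        for i in range(k):
            for j in range(k):
                cols[:, :, i, j] = xp[:, :, i:i + h, j:j + w]
        return cols

    def forward(self, x: np.ndarray) -> np.ndarray:
        cols = self._im2col(x)
        self._cols = cols
        y = np.tensordot(self.weight.data, cols, axes=([1, 2, 3], [1, 2, 3]))
        y = np.moveaxis(y, 0, 1)  # (O,N,H,W) -> (N,O,H,W)
        return y + self.bias.data[None, :, None, None]

    def backward(self, gy: np.ndarray) -> np.ndarray:
        cols = self._cols
        self.bias.grad += gy.sum(axis=(0, 2, 3))
        self.weight.grad += np.tensordot(gy, cols, axes=([0, 2, 3], [0, 4, 5]))
        # (C,k,k,N,H,W)
        dcols = np.tensordot(self.weight.data, gy, axes=(0, 1))
        n, _, h, w = gy.shape
        k = self.kernel_size
        p = k // 2
        dxp = np.zeros((n, self.in_channels, h + 2 * p, w + 2 * p), dtype=gy.dtype)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i:i + h, j:j + w] += np.moveaxis(dcols[:, i, j], 0, 1)
        self._cols = None
        if p:
            return dxp[:, :, p:-p, p:-p]
        return dxp


class ConvTranspose2x2(Module):
    """Transposed convolution with 2x2 kernel and stride 2 (doubles H and W)."""

    def __init__(self, in_channels: int, out_channels: int,
                 rng: np.random.Generator, dtype=np.float32):
        super().__init__()
        self.in_channels = in_channels
        self.out_channels = out_channels
        # weight[c_in, c_out, i, j]
        self.weight = Param(_he_init(rng, (in_channels, out_channels, 2, 2),
                                     in_channels, dtype))
        self.bias = Param(np.zeros(out_channels, dtype=dtype))
        self._x = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        n, c, h, w = x.shape
        y = np.empty((n, self.out_channels, 2 * h, 2 * w), dtype=x.dtype)
        for i in range(2):
            for j in range(2):
                y[:, :, i::2, j::2] = np.einsum(
                    "nchw,co->nohw", x, self.weight.data[:, :, i, j])
        return y + self.bias.data[None, :, None, None]

    def backward(self, gy: np.ndarray) -> np.ndarray:
        x = self._x
        self.bias.grad += gy.sum(axis=(0, 2, 3))
        gx = np.zeros_like(x)
        for i in range(2):
            for j in range(2):
                g = gy[:, :, i::2, j::2]
                self.weight.grad[:, :, i, j] += np.einsum("nchw,nohw->co", x, g)
                gx += np.einsum("nohw,co->nchw", g, self.weight.data[:, :, i, j])
        self._x = None
        return gx


class BatchNorm2d(Module):
    """Per-channel batch normalisation; batch statistics during training,
    running averages at evaluation time."""

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1,
                 dtype=np.float32):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.gamma = Param(np.ones(channels, dtype=dtype))
        self.beta = Param(np.zeros(channels, dtype=dtype))
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        if self.training:
            axes = (0, 2, 3)
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = x.shape[0] * x.shape[2] * x.shape[3]
            self.running_mean += self.momentum * (mean - self.running_mean)
            unbiased = var * m / max(m - 1, 1)
            self.running_var += self.momentum * (unbiased - self.running_var)
        else:
            mean = self.running_mean
            var = self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv_std[None, :, None, None]
        if self.training:
            self._cache = (xhat, inv_std)
        return self.gamma.data[None, :, None, None] * xhat \
            + self.beta.data[None, :, None, None]

    def backward(self, gy: np.ndarray) -> np.ndarray:
        xhat, inv_std = self._cache
        self._cache = None
        axes = (0, 2, 3)
        m = gy.shape[0] * gy.shape[2] * gy.shape[3]
        self.beta.grad += gy.sum(axis=axes)
        self.gamma.grad += (gy * xhat).sum(axis=axes)
        gxhat = gy * self.gamma.data[None, :, None, None]
        gsum = gxhat.sum(axis=axes, keepdims=True)
        gdot = (gxhat * xhat).sum(axis=axes, keepdims=True)
        return inv_std[None, :, None, None] * (gxhat - gsum / m - xhat * gdot / m)


class MaxPool2x2(Module):
    """2x2 max pooling, stride 2; gradient routed to the first arg-max."""

    def __init__(self):
        super().__init__()
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2)
        flat = xr.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h // 2, w // 2, 4)
        idx = flat.argmax(axis=-1)
        self._cache = (idx, x.shape)
        return np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]

    def backward(self, gy: np.ndarray) -> np.ndarray:
        idx, shape = self._cache
        self._cache = None
        n, c, h, w = shape
        gflat = np.zeros((n, c, h // 2, w // 2, 4), dtype=gy.dtype)
        np.put_along_axis(gflat, idx[..., None], gy[..., None], axis=-1)
        gx = gflat.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return gx.reshape(shape)


class ReLU(Module):
    def __init__(self):
        super().__init__()
        self._mask = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(x.dtype)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        mask = self._mask
        self._mask = None
        return np.where(mask, gy, 0.0).astype(gy.dtype)


class Sigmoid(Module):
    def __init__(self):
        super().__init__()
        self._y = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        # numerically stable logistic
        y = np.empty_like(x)
        pos = x >= 0
        y[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
        ex = np.exp(x[~pos])
        y[~pos] = ex / (1.0 + ex)
        self._y = y
        return y

    def backward(self, gy: np.ndarray) -> np.ndarray:
        y = self._y
        self._y = None
        return gy * y * (1.0 - y)


def softmax_channels(z: np.ndarray) -> np.ndarray:
    """Softmax over the channel axis of an NCHW tensor."""
    zs = z - z.max(axis=1, keepdims=True)
    e = np.exp(zs)
    return e / e.sum(axis=1, keepdims=True)


def softmax_channels_backward(probs: np.ndarray, gprobs: np.ndarray) -> np.ndarray:
    """Gradient through :func:`softmax_channels` given d loss / d probs."""
    dot = (gprobs * probs).sum(axis=1, keepdims=True)
    return probs * (gprobs - dot)
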