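"""Neural-network module system (layers, parameter traversal, state dicts)."""
from __future__ import annotations

from collections import OrderedDict

import numpy as np

from .tensor import Parameter
from . import functional as F

__all__ = [
    "Module", "Sequential", "Conv3d", "DepthwiseConv2d", "BatchNorm3d",
    "ChannelScaleNorm", "ReLU", "GELU", "Identity",
]


class Module:
    """Base class: tracks parameters/submodules, train/eval mode, state."""

    def __init__(self):
        object.__setattr__(self, "_parameters", OrderedDict())
        object.__setattr__(self, "_modules", OrderedDict())
        object.__setattr__(self, "_buffers", OrderedDict())
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._parameters[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def __delattr__(self, name):
        self._parameters.pop(name, None)
        self._modules.pop(name, None)
        self._buffers.pop(name, None)
        object.__delattr__(self, name)

    def register_buffer(self, name, value):
        self._buffers[name] = np.asarray(value)
        object.__setattr__(self, name, self._buffers[name])

    def modules(self):
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def named_parameters(self, prefix=""):
        for n, p in self._parameters.items():
            yield prefix + n, p
        for mn, m in self._modules.items():
            yield from m.named_parameters(prefix + mn + ".")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def num_parameters(self) -> int:
        """Total trainable parameter count."""
        return sum(p.size for p in self.parameters())

    def train(self, mode: bool = True):
        object.__setattr__(self, "training", mode)
        for m in self._modules.values():
            m.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    # -- serialization --------------------------------------------------------
    def state_dict(self, prefix=""):
        out = {}
        for n, p in self._parameters.items():
            out[prefix + n] = p.data
        for n, b in self._buffers.items():
            out[prefix + n] = b
        for mn, m in self._modules.items():
            out.update(m.state_dict(prefix + mn + "."))
        return out

    def load_state_dict(self, state):
        own = self.state_dict()
        missing = set(own) - set(state)
        if missing:
            raise KeyError(f"missing keys in state dict: {sorted(missing)[:5]}")
        self._load(state, "")

    def _load(self, state, prefix):
        for n, p in self._parameters.items():
            p.data = np.asarray(state[prefix + n], dtype=p.data.dtype).reshape(p.shape)
        for n in self._buffers:
            arr = np.asarray(state[prefix + n])
            self._buffers[n][...] = arr
        for mn, m in self._modules.items():
            m._load(state, prefix + mn + ".")

    def __call__(self, *args, **kw):
        return self.forward(*args, **kw)


class Sequential(Module):
    def __init__(self, *layers):
        super().__init__()
        self.layers = list(layers)
        for i, layer in enumerate(layers):
            self._modules[str(i)] = layer

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x

    def __iter__(self):
        return iter(self.layers)


def _he_init(rng, shape, fan_in):
    std = np.sqrt(2.0 / fan_in)
    return (rng.standard_normal(shape) * std).astype(np.float32)


class Conv3d(Module):
    def __init__(self, cin, cout, kernel=3, stride=1, padding=None,
                 bias=True, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.cin, self.cout, self.kernel = cin, cout, kernel
        self.stride = stride
        self.padding = kernel // 2 if padding is None else padding
        fan_in = cin * kernel ** 3
        self.weight = Parameter(
            _he_init(rng, (cout, cin, kernel, kernel, kernel), fan_in))
        self.bias = Parameter(np.zeros(cout, dtype=np.float32)) if bias else None

    def forward(self, x):
        return F.conv3d(x, self.weight, self.bias,
                        stride=self.stride, padding=self.padding)


class DepthwiseConv2d(Module):
    """Per-channel 2D convolution; kernel may be rectangular (e.g. 1x7)."""

    def __init__(self, channels, kernel, bias=True, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng()
        kh, kw = kernel if isinstance(kernel, tuple) else (kernel, kernel)
        self.channels, self.kh, self.kw = channels, kh, kw
        fan_in = kh * kw
        self.weight = Parameter(_he_init(rng, (channels, kh, kw), fan_in))
        self.bias = Parameter(np.zeros(channels, dtype=np.float32)) if bias else None

    def forward(self, x):
        return F.conv2d_depthwise(x, self.weight, self.bias,
                                  padding=(self.kh // 2, self.kw // 2))


class BatchNorm3d(Module):
    def __init__(self, channels, eps=1e-5, momentum=0.1):
        super().__init__()
        self.channels, self.eps, self.momentum = channels, eps, momentum
        self.weight = Parameter(np.ones(channels, dtype=np.float32))
        self.bias = Parameter(np.zeros(channels, dtype=np.float32))
        self.register_buffer("running_mean", np.zeros(channels, np.float32))
        self.register_buffer("running_var", np.ones(channels, np.float32))

    def forward(self, x, relu=False):
        if self.training:
            out, (mean, var) = F.batch_norm(x, self.weight, self.bias,
                                            self.eps, relu=relu)
            m = self.momentum
            self.running_mean *= 1 - m
            self.running_mean += m * mean
            self.running_var *= 1 - m
            self.running_var += m * var
            return out
        return F.batch_norm(x, self.weight, self.bias, self.eps,
                            stats=(self.running_mean, self.running_var),
                            relu=relu)


class ChannelScaleNorm(Module):
    """Instance normalization over spatial axes with a per-channel scale.

    Used inside the attention blocks; normalizes each (sample, channel)
    slice to zero mean / unit variance and applies a learnable gain only.
    """

    def __init__(self, channels, eps=1e-5):
        super().__init__()
        self.channels, self.eps = channels, eps
        self.weight = Parameter(np.ones(channels, dtype=np.float32))

    def forward(self, x):
        axes = tuple(range(2, x.ndim))
        shape = (1, self.channels) + (1,) * (x.ndim - 2)
        mu = x.mean(axis=axes, keepdims=True)
        xc = x - mu
        v = (xc * xc).mean(axis=axes, keepdims=True)
        return xc * (v + self.eps) ** -0.5 * self.weight.reshape(shape)


class ReLU(Module):
    def forward(self, x):
        return x.relu()


class GELU(Module):
    def forward(self, x):
        return x.gelu()


class Identity(Module):
    def forward(self, x):
        return x
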