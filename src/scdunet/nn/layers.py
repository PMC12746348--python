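"""Trainable layers on top of the autodiff engine.

Initialisation is Kaiming-uniform and fully seeded: every layer draws its
weights from a ``numpy.random.Generator`` supplied at construction, so a
network built twice from the same seed is bit-identical.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, conv2d, conv_transpose2d

__all__ = ["Module", "Conv2d", "ConvTranspose2d", "Linear", "BatchNorm2d", "Sequential"]


def _kaiming_uniform(rng: np.random.Generator, shape, fan_in: int, dtype) -> np.ndarray:
    # gain sqrt(2) for ReLU networks -> bound sqrt(6 / fan_in)
    bound = np.sqrt(6.0 / fan_in)
    return rng.uniform(-bound, bound, size=shape).astype(dtype)


class Module:
    """Base class: parameter discovery, train/eval mode, state dict."""

    def __init__(self):
        self.training = True

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError

    def children(self):
        for value in self.__dict__.values():
            if isinstance(value, Module):
                yield value
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        yield item

    def parameters(self):
        for value in self.__dict__.values():
            if isinstance(value, Tensor) and value.requires_grad:
                yield value
        for child in self.children():
            yield from child.parameters()

    def train(self):
        self.training = True
        for child in self.children():
            child.train()
        return self

    def eval(self):
        self.training = False
        for child in self.children():
            child.eval()
        return self

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    # -- flat state dict (includes non-trainable buffers) ------------------

    def _named_arrays(self, prefix=""):
        for name, value in self.__dict__.items():
            key = f"{prefix}{name}"
            if isinstance(value, Tensor):
                yield key, value
            elif isinstance(value, np.ndarray):
                yield key, value
            elif isinstance(value, Module):
                yield from value._named_arrays(f"{key}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item._named_arrays(f"{key}.{i}.")

    def state_dict(self) -> dict:
        return {k: (v.data if isinstance(v, Tensor) else v).copy()
                for k, v in self._named_arrays()}

    def load_state_dict(self, state: dict) -> None:
        own = dict(self._named_arrays())
        missing = set(own) - set(state)
        if missing:
            raise KeyError(f"state dict missing keys: {sorted(missing)}")
        for key, value in own.items():
            arr = np.asarray(state[key])
            if isinstance(value, Tensor):
                value.data = arr.astype(value.data.dtype).reshape(value.data.shape)
            else:
                # plain ndarray buffer: re-assign on the owning module
                obj = self
                parts = key.split(".")
                for part in parts[:-1]:
                    obj = obj[int(part)] if part.isdigit() else getattr(obj, part)
                setattr(obj, parts[-1], arr.astype(value.dtype).reshape(value.shape))


class Conv2d(Module):
    def __init__(self, in_channels, out_channels, kernel_size, *, stride=1,
                 dilation=1, padding=0, bias=True, rng=None, dtype=np.float32):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        self.stride = stride
        self.dilation = dilation
        self.padding = padding
        fan_in = in_channels * kernel_size * kernel_size
        self.weight = Tensor(_kaiming_uniform(
            rng, (out_channels, in_channels, kernel_size, kernel_size), fan_in, dtype),
            requires_grad=True)
        if bias:
            bound = 1.0 / np.sqrt(fan_in)
            self.bias = Tensor(rng.uniform(-bound, bound, out_channels).astype(dtype),
                               requires_grad=True)
        else:
            self.bias = None

    def forward(self, x):
        return conv2d(x, self.weight, self.bias, stride=self.stride,
                      dilation=self.dilation, padding=self.padding)


class ConvTranspose2d(Module):
    """Kernel-2 / stride-2 transposed convolution (2x upsampling)."""

    def __init__(self, in_channels, out_channels, *, rng=None, dtype=np.float32):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        fan_in = in_channels * 4
        self.weight = Tensor(_kaiming_uniform(
            rng, (in_channels, out_channels, 2, 2), fan_in, dtype), requires_grad=True)
        bound = 1.0 / np.sqrt(fan_in)
        self.bias = Tensor(rng.uniform(-bound, bound, out_channels).astype(dtype),
                           requires_grad=True)

    def forward(self, x):
        return conv_transpose2d(x, self.weight, self.bias)


class Linear(Module):
    def __init__(self, in_features, out_features, *, rng=None, dtype=np.float32):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        self.weight = Tensor(_kaiming_uniform(
            rng, (in_features, out_features), in_features, dtype), requires_grad=True)
        bound = 1.0 / np.sqrt(in_features)
        self.bias = Tensor(rng.uniform(-bound, bound, out_features).astype(dtype),
                           requires_grad=True)

    def forward(self, x):
        return x @ self.weight + self.bias


class BatchNorm2d(Module):
    """Batch normalisation over (B, H, W) per channel, with running stats."""

    def __init__(self, num_features, *, eps=1e-5, momentum=0.1, dtype=np.float32):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.gamma = Tensor(np.ones(num_features, dtype=dtype), requires_grad=True)
        self.beta = Tensor(np.zeros(num_features, dtype=dtype), requires_grad=True)
        self.running_mean = np.zeros(num_features, dtype=dtype)
        self.running_var = np.ones(num_features, dtype=dtype)

    def forward(self, x):
        if self.training:
            mean = x.mean(axis=(0, 2, 3), keepdims=True)
            centred = x - mean
            var = (centred * centred).mean(axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean
                                 + m * mean.data.reshape(-1)).astype(self.running_mean.dtype)
            n = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
            unbiased = var.data.reshape(-1) * (n / max(n - 1, 1))
            self.running_var = ((1 - m) * self.running_var
                                + m * unbiased).astype(self.running_var.dtype)
            inv = (var + self.eps) ** -0.5
            xhat = centred * inv
        else:
            mean = self.running_mean[None, :, None, None]
            inv = 1.0 / np.sqrt(self.running_var + self.eps)
            xhat = (x - mean) * inv[None, :, None, None]
        g = self.gamma.reshape(1, -1, 1, 1)
        b = self.beta.reshape(1, -1, 1, 1)
        return xhat * g + b


class Sequential(Module):
    def __init__(self, *modules):
        super().__init__()
        self.items = list(modules)

    def forward(self, x):
        for m in self.items:
            x = m(x)
        return x

    def __iter__(self):
        return iter(self.items)

    def __getitem__(self, i):
        return self.items[i]
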