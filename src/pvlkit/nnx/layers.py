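"""Neural-network layers built on the autograd tensor.

Follows the familiar module protocol: parameters are `Tensor`s with
`requires_grad=True`, `train()` / `eval()` toggle batch-norm behaviour,
and `state_dict()` / `load_state_dict()` round-trip through plain
name → ndarray mappings (JSON-serializable after `.tolist()`).
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, conv3d

__all__ = ["Module", "Conv3d", "BatchNorm3d", "Linear", "ReLU", "Sequential"]


class Module:
    """Base class: parameter/buffer registry with recursive traversal."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._buffers: dict[str, np.ndarray] = {}
        self._modules: dict[str, "Module"] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        object.__setattr__(self, name, value)

    def register_parameter(self, name: str, value: Tensor) -> Tensor:
        value.requires_grad = True
        value.name = name
        self._params[name] = value
        object.__setattr__(self, name, value)
        return value

    def register_buffer(self, name: str, value: np.ndarray) -> np.ndarray:
        self._buffers[name] = value
        object.__setattr__(self, name, value)
        return value

    def parameters(self) -> list[Tensor]:
        out = list(self._params.values())
        for m in self._modules.values():
            out.extend(m.parameters())
        return out

    def named_parameters(self, prefix: str = "") -> dict[str, Tensor]:
        out = {prefix + k: v for k, v in self._params.items()}
        for name, m in self._modules.items():
            out.update(m.named_parameters(prefix + name + "."))
        return out

    def named_buffers(self, prefix: str = "") -> dict[str, np.ndarray]:
        out = {prefix + k: v for k, v in self._buffers.items()}
        for name, m in self._modules.items():
            out.update(m.named_buffers(prefix + name + "."))
        return out

    def train(self, mode: bool = True) -> "Module":
        self.training = mode
        for m in self._modules.values():
            m.train(mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        out = {k: v.data.copy() for k, v in self.named_parameters().items()}
        out.update({k: v.copy() for k, v in self.named_buffers().items()})
        return out

    def load_state_dict(self, state: dict[str, np.ndarray],
                        strict: bool = True) -> None:
        params = self.named_parameters()
        buffers = self.named_buffers()
        for key, value in state.items():
            value = np.asarray(value, dtype=np.float32)
            if key in params:
                if params[key].data.shape != value.shape:
                    raise ValueError(f"shape mismatch for {key}")
                params[key].data = value.copy()
            elif key in buffers:
                buffers[key][...] = value
            elif strict:
                raise KeyError(f"unexpected key {key!r} in state dict")
        if strict:
            missing = (set(params) | set(buffers)) - set(state)
            if missing:
                raise KeyError(f"missing keys in state dict: {sorted(missing)}")

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Conv3d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel_size: int = 3,
                 stride=1, padding=0, bias: bool = False, *,
                 rng: np.random.Generator):
        super().__init__()
        k = (kernel_size,) * 3 if isinstance(kernel_size, int) else tuple(kernel_size)
        self.stride = (stride,) * 3 if isinstance(stride, int) else tuple(stride)
        self.padding = (padding,) * 3 if isinstance(padding, int) else tuple(padding)
        fan_in = in_channels * int(np.prod(k))
        # He-normal init for ReLU networks
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                       size=(out_channels, in_channels) + k)
        self.register_parameter("weight", Tensor(w))
        self.bias = None
        if bias:
            self.register_parameter("bias", Tensor(np.zeros(out_channels)))

    def forward(self, x: Tensor) -> Tensor:
        return conv3d(x, self.weight, self.bias, self.stride, self.padding)


class BatchNorm3d(Module):
    """Batch normalization over (N, D, H, W) per channel, with running stats."""

    def __init__(self, num_features: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.register_parameter("gamma", Tensor(np.ones(num_features)))
        self.register_parameter("beta", Tensor(np.zeros(num_features)))
        self.register_buffer("running_mean",
                             np.zeros(num_features, dtype=np.float32))
        self.register_buffer("running_var", np.ones(num_features, dtype=np.float32))

    def forward(self, x: Tensor) -> Tensor:
        axes = (0, 2, 3, 4)
        shape = (1, -1, 1, 1, 1)
        if self.training:
            mu = x.mean(axis=axes, keepdims=True)
            xc = x - mu
            var = (xc * xc).mean(axis=axes, keepdims=True)
            n = x.data.size / x.shape[1]
            self.running_mean *= 1 - self.momentum
            self.running_mean += self.momentum * mu.data.reshape(-1)
            self.running_var *= 1 - self.momentum
            unbiased = var.data.reshape(-1) * (n / max(n - 1, 1))
            self.running_var += self.momentum * unbiased
            inv = (var + self.eps) ** -0.5
            xhat = xc * inv
        else:
            xhat = (x - self.running_mean.reshape(shape)) * (
                1.0 / np.sqrt(self.running_var + self.eps)).reshape(shape)
        return xhat * self.gamma.reshape(shape) + self.beta.reshape(shape)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, *,
                 rng: np.random.Generator):
        super().__init__()
        bound = np.sqrt(1.0 / in_features)
        w = rng.uniform(-bound, bound, size=(in_features, out_features))
        b = rng.uniform(-bound, bound, size=out_features)
        self.register_parameter("weight", Tensor(w))
        self.register_parameter("bias", Tensor(b))

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class Sequential(Module):
    def __init__(self, *modules: Module):
        super().__init__()
        self.items = list(modules)
        for i, m in enumerate(modules):
            self._modules[str(i)] = m

    def forward(self, x: Tensor) -> Tensor:
        for m in self.items:
            x = m(x)
        return x
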