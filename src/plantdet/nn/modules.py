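"""Layer modules (conv / norm / linear) with parameter registration.

Every module records the shapes of its last forward call so the profiler
can derive MAC counts from a single traced run.
"""
from __future__ import annotations

import numpy as np

from . import functional as F
from .tensor import Tensor

__all__ = ["Module", "Conv2d", "BatchNorm2d", "ReLU", "Sigmoid",
           "MaxPool2d", "Linear", "Sequential", "Identity"]


class Module:
    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._modules: dict[str, Module] = {}
        self.training = True
        self.last_in_shape = None
        self.last_out_shape = None

    def __setattr__(self, name, value):
        if isinstance(value, Tensor) and value.requires_grad:
            self.__dict__.setdefault("_params", {})[name] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        object.__setattr__(self, name, value)

    def parameters(self):
        for p in self._params.values():
            yield p
        for m in self._modules.values():
            yield from m.parameters()

    def named_modules(self, prefix: str = ""):
        yield prefix or "root", self
        for name, m in self._modules.items():
            yield from m.named_modules(f"{prefix}.{name}" if prefix else name)

    def train(self, mode: bool = True):
        self.training = mode
        for m in self._modules.values():
            m.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def num_params(self) -> int:
        return sum(p.size for p in self.parameters())

    def forward(self, x):  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, x):
        self.last_in_shape = tuple(x.shape)
        out = self.forward(x)
        self.last_out_shape = tuple(out.shape)
        return out

    def state_dict(self, prefix: str = ""):
        out = {}
        for name, p in self._params.items():
            out[prefix + name] = p.data.copy()
        for name, m in self._modules.items():
            out.update(m.state_dict(prefix + name + "."))
        return out

    def load_state_dict(self, state: dict, prefix: str = ""):
        for name, p in self._params.items():
            p.data[...] = state[prefix + name]
        for name, m in self._modules.items():
            m.load_state_dict(state, prefix + name + ".")


class Conv2d(Module):
    def __init__(self, in_channels, out_channels, kernel_size, stride=1,
                 padding=0, groups=1, bias=False, rng=None):
        super().__init__()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.stride = stride
        self.padding = padding
        self.groups = groups
        rng = rng or np.random.default_rng(0)
        fan_in = (in_channels // groups) * kernel_size * kernel_size
        std = np.sqrt(2.0 / fan_in)
        w = rng.normal(0.0, std, size=(out_channels, in_channels // groups,
                                       kernel_size, kernel_size))
        self.weight = Tensor(w, requires_grad=True)
        self.bias = Tensor(np.zeros(out_channels), requires_grad=True) if bias else None

    def forward(self, x):
        return F.conv2d(x, self.weight, self.bias, stride=self.stride,
                        padding=self.padding, groups=self.groups)


class BatchNorm2d(Module):
    def __init__(self, num_features, eps: float = 1e-5, momentum: float = 0.1,
                 use_batch_stats_in_eval: bool = False):
        super().__init__()
        self.num_features = num_features
        self.eps = eps
        self.momentum = momentum
        # when set, eval-mode forward normalizes by the current input's
        # statistics (useful for small-batch detection training where
        # running averages are unrepresentative); running stats are
        # still tracked either way
        self.use_batch_stats_in_eval = use_batch_stats_in_eval
        self.weight = Tensor(np.ones(num_features), requires_grad=True)
        self.bias = Tensor(np.zeros(num_features), requires_grad=True)
        self.running_mean = np.zeros(num_features, dtype=np.float32)
        self.running_var = np.ones(num_features, dtype=np.float32)

    def forward(self, x):
        if self.training or self.use_batch_stats_in_eval:
            out, mu, var = F.batch_norm(x, self.weight, self.bias, eps=self.eps)
            if self.training:
                m = self.momentum
                self.running_mean = ((1 - m) * self.running_mean + m * mu).astype(np.float32)
                self.running_var = ((1 - m) * self.running_var + m * var).astype(np.float32)
            return out
        out, _, _ = F.batch_norm(x, self.weight, self.bias,
                                 mean=self.running_mean, var=self.running_var,
                                 eps=self.eps)
        return out

    def state_dict(self, prefix: str = ""):
        out = super().state_dict(prefix)
        out[prefix + "running_mean"] = self.running_mean.copy()
        out[prefix + "running_var"] = self.running_var.copy()
        return out

    def load_state_dict(self, state: dict, prefix: str = ""):
        super().load_state_dict(state, prefix)
        self.running_mean[...] = state[prefix + "running_mean"]
        self.running_var[...] = state[prefix + "running_var"]


class ReLU(Module):
    def forward(self, x):
        return x.relu()


class Sigmoid(Module):
    def forward(self, x):
        return x.sigmoid()


class MaxPool2d(Module):
    def __init__(self, kernel_size=3, stride=2, padding=1):
        super().__init__()
        self.kernel_size = kernel_size
        self.stride = stride
        self.padding = padding

    def forward(self, x):
        return F.max_pool2d(x, self.kernel_size, self.stride, self.padding)


class Linear(Module):
    def __init__(self, in_features, out_features, rng=None):
        super().__init__()
        self.in_features = in_features
        self.out_features = out_features
        rng = rng or np.random.default_rng(0)
        std = np.sqrt(2.0 / in_features)
        self.weight = Tensor(rng.normal(0.0, std, size=(out_features, in_features)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_features), requires_grad=True)

    def forward(self, x):
        return x @ self.weight.transpose((1, 0)) + self.bias


class Identity(Module):
    def forward(self, x):
        return x


class Sequential(Module):
    def __init__(self, *layers):
        super().__init__()
        self.layers = list(layers)
        for i, layer in enumerate(layers):
            setattr(self, f"m{i}", layer)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x

    def __iter__(self):
        return iter(self.layers)

    def __len__(self):
        return len(self.layers)
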