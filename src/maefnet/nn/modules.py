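"""Layer/module abstractions over the autodiff core.

Mirrors the usual CNN-framework surface (Module, Conv2d, BatchNorm2d,
Sequential, squeeze-excitation, inverted residual) so the network definition
reads like the field's standard code.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from . import core
from .core import Tensor

# module-level RNG used for weight init; reseed via seed_init()
_init_rng = np.random.default_rng(0)


def seed_init(seed: int) -> None:
    """Reseed the weight-initialization RNG (call before building a model)."""
    global _init_rng
    _init_rng = np.random.default_rng(seed)


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    def __init__(self):
        self.training = True

    def parameters(self) -> Iterator[Parameter]:
        for v in vars(self).values():
            if isinstance(v, Parameter):
                yield v
            elif isinstance(v, Module):
                yield from v.parameters()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield from item.parameters()

    def modules(self) -> Iterator["Module"]:
        yield self
        for v in vars(self).values():
            if isinstance(v, Module):
                yield from v.modules()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield from item.modules()

    def train(self, mode: bool = True) -> "Module":
        for m in self.modules():
            m.training = mode
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    # -- flat state dict of numpy arrays (for checkpointing) ----------------
    def state_dict(self, prefix: str = "") -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for name, v in vars(self).items():
            if isinstance(v, Parameter):
                out[prefix + name] = v.data.copy()
            elif isinstance(v, np.ndarray) and name.startswith("running_"):
                out[prefix + name] = v.copy()
            elif isinstance(v, Module):
                out.update(v.state_dict(prefix + name + "."))
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        out.update(item.state_dict(f"{prefix}{name}.{i}."))
        return out

    def load_state_dict(self, state: dict[str, np.ndarray],
                        prefix: str = "") -> None:
        for name, v in vars(self).items():
            if isinstance(v, Parameter):
                v.data = np.asarray(state[prefix + name], dtype=np.float32)
            elif isinstance(v, np.ndarray) and name.startswith("running_"):
                v[...] = state[prefix + name]
            elif isinstance(v, Module):
                v.load_state_dict(state, prefix + name + ".")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        item.load_state_dict(state, f"{prefix}{name}.{i}.")

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int = 1,
                 padding: int = 0, groups: int = 1, bias: bool = False):
        super().__init__()
        self.stride, self.padding, self.groups = stride, padding, groups
        fan_out = out_ch * kernel * kernel // groups
        std = float(np.sqrt(2.0 / fan_out))
        shape = (out_ch, in_ch // groups, kernel, kernel)
        self.weight = Parameter(
            _init_rng.normal(0.0, std, size=shape).astype(np.float32))
        self.bias = Parameter(np.zeros(out_ch, np.float32)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return core.conv2d(x, self.weight, self.bias, self.stride,
                           self.padding, self.groups)


class BatchNorm2d(Module):
    def __init__(self, ch: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.weight = Parameter(np.ones(ch, np.float32))
        self.bias = Parameter(np.zeros(ch, np.float32))
        self.running_mean = np.zeros(ch, np.float32)
        self.running_var = np.ones(ch, np.float32)

    def forward(self, x: Tensor) -> Tensor:
        return core.batch_norm(x, self.weight, self.bias, self.running_mean,
                               self.running_var, self.training, self.momentum,
                               self.eps)


class ReLU(Module):
    def forward(self, x):
        return core.relu(x)


class Hardswish(Module):
    def forward(self, x):
        return core.hardswish(x)


class ConvBNAct(Sequential):
    """conv -> batch norm -> activation, the standard convolutional block."""

    def __init__(self, in_ch, out_ch, kernel=3, stride=1, groups=1,
                 act: str = "relu"):
        layers = [
            Conv2d(in_ch, out_ch, kernel, stride, padding=kernel // 2,
                   groups=groups),
            BatchNorm2d(out_ch),
        ]
        if act == "relu":
            layers.append(ReLU())
        elif act == "hardswish":
            layers.append(Hardswish())
        elif act != "none":
            raise ValueError(f"unknown activation {act!r}")
        super().__init__(*layers)


def _make_divisible(v: float, divisor: int = 8) -> int:
    new_v = max(divisor, int(v + divisor / 2) // divisor * divisor)
    if new_v < 0.9 * v:
        new_v += divisor
    return new_v


class SqueezeExcite(Module):
    """Channel gating: global pool -> 1x1 reduce (ReLU) -> 1x1 expand
    (hard sigmoid) -> scale."""

    def __init__(self, ch: int, squeeze_ch: int):
        super().__init__()
        self.fc1 = Conv2d(ch, squeeze_ch, 1, bias=True)
        self.fc2 = Conv2d(squeeze_ch, ch, 1, bias=True)

    def forward(self, x: Tensor) -> Tensor:
        s = core.mean(x, (2, 3), keepdims=True)
        s = core.relu(self.fc1(s))
        s = core.hardsigmoid(self.fc2(s))
        return core.mul(x, s)


class InvertedResidual(Module):
    """MobileNetV3 building block: 1x1 expand, depthwise, optional SE,
    1x1 project, residual when stride 1 and channels match."""

    def __init__(self, in_ch: int, exp_ch: int, out_ch: int, kernel: int,
                 stride: int, use_se: bool, act: str):
        super().__init__()
        self.use_res = stride == 1 and in_ch == out_ch
        layers: list[Module] = []
        if exp_ch != in_ch:
            layers.append(ConvBNAct(in_ch, exp_ch, kernel=1, act=act))
        layers.append(ConvBNAct(exp_ch, exp_ch, kernel=kernel, stride=stride,
                                groups=exp_ch, act=act))
        if use_se:
            layers.append(SqueezeExcite(exp_ch, _make_divisible(exp_ch // 4)))
        layers.append(ConvBNAct(exp_ch, out_ch, kernel=1, act="none"))
        self.block = Sequential(*layers)

    def forward(self, x: Tensor) -> Tensor:
        out = self.block(x)
        if self.use_res:
            out = core.add(out, x)
        return out


def count_parameters(module: Module, trainable_only: bool = True) -> int:
    """Total number of parameter elements in a module tree."""
    return sum(int(p.data.size) for p in module.parameters()
               if p.requires_grad or not trainable_only)


class SGD:
    """SGD with momentum and decoupled-in-gradient weight decay
    (v = m*v + g + wd*p; p -= lr*v)."""

    def __init__(self, params, lr: float, momentum: float = 0.0,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.lr, self.momentum, self.weight_decay = lr, momentum, weight_decay
        self._buf = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        for p, buf in zip(self.params, self._buf):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            buf *= self.momentum
            buf += g
            p.data -= self.lr * buf

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
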