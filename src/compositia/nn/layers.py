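"""Layer modules built on the autograd engine.

Parameters are held as `Tensor`s with `requires_grad=True`; `Module`
walks its attribute tree to collect them, to toggle train/eval mode and
to serialize weights into flat name->array dicts.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, batchnorm2d, conv2d, conv_transpose2x


class Module:
    training: bool = True

    def parameters(self):
        params = []
        for child in self._children():
            params.extend(child.parameters())
        for v in vars(self).values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
        return params

    def _children(self):
        out = []
        for v in vars(self).values():
            if isinstance(v, Module):
                out.append(v)
            elif isinstance(v, (list, tuple)):
                out.extend(c for c in v if isinstance(c, Module))
        return out

    def train(self, mode: bool = True):
        self.training = mode
        for child in self._children():
            child.train(mode)
        return self

    def eval(self):
        return self.train(False)

    # -- weight (de)serialization ---------------------------------------
    def state_dict(self, prefix=""):
        state = {}
        for name, v in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(v, Tensor) and v.requires_grad:
                state[key] = v.data
            elif isinstance(v, np.ndarray):
                state[key] = v
            elif isinstance(v, Module):
                state.update(v.state_dict(prefix=key + "."))
            elif isinstance(v, (list, tuple)):
                for i, c in enumerate(v):
                    if isinstance(c, Module):
                        state.update(c.state_dict(prefix=f"{key}.{i}."))
        return state

    def load_state_dict(self, state, prefix=""):
        for name, v in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(v, Tensor) and v.requires_grad:
                v.data[...] = state[key]
            elif isinstance(v, np.ndarray):
                v[...] = state[key]
            elif isinstance(v, Module):
                v.load_state_dict(state, prefix=key + ".")
            elif isinstance(v, (list, tuple)):
                for i, c in enumerate(v):
                    if isinstance(c, Module):
                        c.load_state_dict(state, prefix=f"{key}.{i}.")

    def __call__(self, x):
        return self.forward(x)


class Conv2d(Module):
    """Same-padding stride-1 convolution with He-normal init."""

    def __init__(self, in_ch: int, out_ch: int, k: int, rng: np.random.Generator, bias: bool = True):
        fan_in = in_ch * k * k
        std = np.sqrt(2.0 / fan_in)
        self.weight = Tensor(rng.normal(0.0, std, size=(out_ch, in_ch, k, k)), requires_grad=True)
        self.bias = Tensor(np.zeros(out_ch), requires_grad=True) if bias else None

    def forward(self, x):
        return conv2d(x, self.weight, self.bias)


class ConvTranspose2x(Module):
    """Stride-2 transposed convolution with a 2x2 kernel (doubles H and W)."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator):
        std = np.sqrt(2.0 / (in_ch * 4))
        self.weight = Tensor(rng.normal(0.0, std, size=(in_ch, out_ch, 2, 2)), requires_grad=True)
        self.bias = Tensor(np.zeros(out_ch), requires_grad=True)

    def forward(self, x):
        return conv_transpose2x(x, self.weight, self.bias)


class BatchNorm2d(Module):
    def __init__(self, num_ch: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(num_ch), requires_grad=True)
        self.beta = Tensor(np.zeros(num_ch), requires_grad=True)
        self.running_mean = np.zeros(num_ch, dtype=np.float32)
        self.running_var = np.ones(num_ch, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x):
        return batchnorm2d(x, self.gamma, self.beta, self.running_mean, self.running_var,
                           training=self.training, momentum=self.momentum, eps=self.eps)


class ConvBNReLU(Module):
    def __init__(self, in_ch: int, out_ch: int, k: int, rng: np.random.Generator):
        self.conv = Conv2d(in_ch, out_ch, k, rng)
        self.bn = BatchNorm2d(out_ch)

    def forward(self, x):
        return self.bn(self.conv(x)).relu()
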