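"""Neural-network layers built on the autograd engine.

All parameters are float64 Tensors with fan-in-scaled random initialization
from a caller-supplied numpy Generator, so a model is fully reproducible
from its seed.
"""

from __future__ import annotations

from typing import Dict, Iterable, List

import numpy as np

from .autograd import Tensor, concat, conv1d, max_pool1d


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Minimal layer base: named parameters + train/eval mode flag."""

    def __init__(self):
        self.training = True

    def parameters(self) -> List[Parameter]:
        out = []
        for v in self.__dict__.values():
            if isinstance(v, Parameter):
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.parameters())
        return out

    def set_training(self, flag: bool) -> None:
        self.training = flag
        for v in self.__dict__.values():
            if isinstance(v, Module):
                v.set_training(flag)
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        item.set_training(flag)

    # state dicts hold plain numpy arrays for checkpointing
    def state_arrays(self, prefix: str = "") -> Dict[str, np.ndarray]:
        out = {}
        for name, v in self.__dict__.items():
            key = f"{prefix}{name}"
            if isinstance(v, Parameter):
                out[key] = v.data
            elif isinstance(v, Module):
                out.update(v.state_arrays(prefix=key + "."))
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        out.update(item.state_arrays(prefix=f"{key}.{i}."))
            elif isinstance(v, np.ndarray):
                out[key] = v
        return out

    def load_state_arrays(self, state: Dict[str, np.ndarray], prefix: str = "") -> None:
        for name, v in self.__dict__.items():
            key = f"{prefix}{name}"
            if isinstance(v, Parameter):
                v.data = np.array(state[key], dtype=np.float64)
            elif isinstance(v, Module):
                v.load_state_arrays(state, prefix=key + ".")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        item.load_state_arrays(state, prefix=f"{key}.{i}.")
            elif isinstance(v, np.ndarray):
                self.__dict__[name] = np.array(state[key], dtype=np.float64)


def _fan_in_normal(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / max(fan_in, 1)), size=shape)


class Dense(Module):
    def __init__(self, rng: np.random.Generator, n_in: int, n_out: int):
        super().__init__()
        self.weight = Parameter(_fan_in_normal(rng, (n_in, n_out), n_in))
        self.bias = Parameter(np.zeros(n_out))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Conv1d(Module):
    """Same-padding 1-D convolution over (B, C, L) inputs."""

    def __init__(self, rng: np.random.Generator, c_in: int, c_out: int, kernel: int):
        super().__init__()
        self.kernel = kernel
        self.weight = Parameter(_fan_in_normal(rng, (c_out, c_in, kernel), c_in * kernel))
        self.bias = Parameter(np.zeros(c_out))

    def __call__(self, x: Tensor) -> Tensor:
        return conv1d(x, self.weight, self.bias, padding=(self.kernel - 1) // 2)


class BatchNorm1d(Module):
    """Per-channel batch normalization over (B, C, L).

    Training uses batch statistics (and updates exponential running
    estimates); evaluation uses the frozen running statistics, keeping
    inference deterministic.
    """

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        if self.training:
            mean = x.mean(axis=(0, 2), keepdims=True)
            centered = x - mean
            var = centered.pow_const(2.0).mean(axis=(0, 2), keepdims=True)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean.data.reshape(-1))
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var.data.reshape(-1))
            inv = (var + self.eps).pow_const(-0.5)
            xhat = centered * inv
        else:
            mean = self.running_mean[None, :, None]
            inv = 1.0 / np.sqrt(self.running_var + self.eps)
            xhat = (x - Tensor(mean)) * Tensor(inv[None, :, None])
        return xhat * self.gamma.reshape(1, -1, 1) + self.beta.reshape(1, -1, 1)


class LSTMDirection(Module):
    """One direction of an LSTM over (B, T, C); returns the final hidden state."""

    def __init__(self, rng: np.random.Generator, c_in: int, hidden: int, reverse: bool):
        super().__init__()
        self.hidden = hidden
        self.reverse = reverse
        self.wx = Parameter(_fan_in_normal(rng, (c_in, 4 * hidden), c_in))
        self.wh = Parameter(_fan_in_normal(rng, (hidden, 4 * hidden), hidden))
        b = np.zeros(4 * hidden)
        b[hidden:2 * hidden] = 1.0  # forget-gate bias
        self.bias = Parameter(b)

    def __call__(self, x: Tensor) -> Tensor:
        B, T, _ = x.data.shape
        H = self.hidden
        h = Tensor(np.zeros((B, H)))
        c = Tensor(np.zeros((B, H)))
        order = range(T - 1, -1, -1) if self.reverse else range(T)
        for t in order:
            xt = x[(slice(None), t, slice(None))]
            z = xt @ self.wx + h @ self.wh + self.bias
            i = z[(slice(None), slice(0, H))].sigmoid()
            f = z[(slice(None), slice(H, 2 * H))].sigmoid()
            g = z[(slice(None), slice(2 * H, 3 * H))].tanh()
            o = z[(slice(None), slice(3 * H, 4 * H))].sigmoid()
            c = f * c + i * g
            h = o * c.tanh()
        return h


class BiLSTM(Module):
    """Bi-directional LSTM; output = concatenated final states (2*hidden)."""

    def __init__(self, rng: np.random.Generator, c_in: int, hidden: int):
        super().__init__()
        self.fwd = LSTMDirection(rng, c_in, hidden, reverse=False)
        self.bwd = LSTMDirection(rng, c_in, hidden, reverse=True)

    def __call__(self, x: Tensor) -> Tensor:
        return concat([self.fwd(x), self.bwd(x)], axis=1)


class Adam:
    """Adam optimizer with bias correction (the training default)."""

    def __init__(self, params: Iterable[Parameter], lr: float = 1e-5,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * p.grad
            self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * p.grad ** 2
            mhat = self.m[i] / b1t
            vhat = self.v[i] / b2t
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)


__all__ = [
    "Parameter", "Module", "Dense", "Conv1d", "BatchNorm1d", "BiLSTM",
    "LSTMDirection", "Adam", "Tensor", "concat", "max_pool1d",
]
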