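"""Stateful layers and the Adam optimizer built on the autograd primitives."""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import Tensor

__all__ = ["Module", "Conv3d", "BatchNorm3d", "ConvBlock", "Adam"]


class Module:
    """Base class: parameter registry plus train/eval mode propagation."""

    def __init__(self):
        self.training = True

    def children(self) -> list["Module"]:
        out = []
        for v in self.__dict__.values():
            if isinstance(v, Module):
                out.append(v)
            elif isinstance(v, (list, tuple)):
                out.extend(m for m in v if isinstance(m, Module))
            elif isinstance(v, dict):
                out.extend(m for m in v.values() if isinstance(m, Module))
        return out

    def parameters(self) -> list[Tensor]:
        params = [v for v in self.__dict__.values()
                  if isinstance(v, Tensor) and v.requires_grad]
        for child in self.children():
            params.extend(child.parameters())
        return params

    def named_state(self, prefix: str = "") -> dict[str, np.ndarray]:
        """All arrays needed to restore the module (params + running stats)."""
        state: dict[str, np.ndarray] = {}
        for name, v in self.__dict__.items():
            if isinstance(v, Tensor):
                state[prefix + name] = v.data
            elif isinstance(v, dict) and name == "running":
                for k, arr in v.items():
                    state[f"{prefix}running.{k}"] = arr
        for name, v in self.__dict__.items():
            if isinstance(v, Module):
                state.update(v.named_state(f"{prefix}{name}."))
            elif isinstance(v, (list, tuple)):
                for i, m in enumerate(v):
                    if isinstance(m, Module):
                        state.update(m.named_state(f"{prefix}{name}.{i}."))
            elif isinstance(v, dict) and name != "running":
                for k, m in v.items():
                    if isinstance(m, Module):
                        state.update(m.named_state(f"{prefix}{name}.{k}."))
        return state

    def load_state(self, state: dict[str, np.ndarray], prefix: str = "") -> None:
        for name, v in list(self.__dict__.items()):
            if isinstance(v, Tensor) and prefix + name in state:
                v.data = np.asarray(state[prefix + name], dtype=np.float32).copy()
            elif isinstance(v, dict) and name == "running":
                for k in v:
                    v[k] = np.asarray(state[f"{prefix}running.{k}"]).copy()
        for name, v in self.__dict__.items():
            if isinstance(v, Module):
                v.load_state(state, f"{prefix}{name}.")
            elif isinstance(v, (list, tuple)):
                for i, m in enumerate(v):
                    if isinstance(m, Module):
                        m.load_state(state, f"{prefix}{name}.{i}.")
            elif isinstance(v, dict) and name != "running":
                for k, m in v.items():
                    if isinstance(m, Module):
                        m.load_state(state, f"{prefix}{name}.{k}.")

    def train(self) -> "Module":
        self.training = True
        for c in self.children():
            c.train()
        return self

    def eval(self) -> "Module":
        self.training = False
        for c in self.children():
            c.eval()
        return self

    def freeze(self) -> "Module":
        for p in self.parameters():
            p.requires_grad = False
        return self


class Conv3d(Module):
    """3D convolution (stride 1, 'same' padding), Kaiming-initialized."""

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator):
        super().__init__()
        self.cin, self.cout, self.k = cin, cout, k
        fan_in = cin * k ** 3
        std = np.sqrt(2.0 / fan_in)
        self.weight = Tensor(rng.normal(0.0, std, (fan_in, cout)), requires_grad=True)
        self.bias = Tensor(np.zeros(cout), requires_grad=True)

    def __call__(self, x: Tensor, pad: int | None = None) -> Tensor:
        return ag.conv3d(x, self.weight, self.bias, self.k, pad)

    def n_params(self) -> int:
        return self.weight.data.size + self.bias.data.size


class BatchNorm3d(Module):
    def __init__(self, c: int):
        super().__init__()
        self.gamma = Tensor(np.ones(c), requires_grad=True)
        self.beta = Tensor(np.zeros(c), requires_grad=True)
        self.running = {"mean": np.zeros(c, np.float32), "var": np.ones(c, np.float32)}

    def __call__(self, x: Tensor) -> Tensor:
        return ag.batch_norm(x, self.gamma, self.beta, self.running, self.training)

    def n_params(self) -> int:
        return self.gamma.data.size + self.beta.data.size


class ConvBlock(Module):
    """(conv 3x3x3 -> batchnorm -> ReLU) x n_convs."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator, n_convs: int = 1):
        super().__init__()
        self.layers = []
        for i in range(n_convs):
            self.layers.append(Conv3d(cin if i == 0 else cout, cout, 3, rng))
            self.layers.append(BatchNorm3d(cout))

    def __call__(self, x: Tensor, pad: int | None = None) -> Tensor:
        for conv, bn in zip(self.layers[0::2], self.layers[1::2]):
            x = ag.relu(bn(conv(x, pad)))
        return x

    def n_params(self) -> int:
        return sum(layer.n_params() for layer in self.layers)


class Adam:
    """Adam with a mutable learning rate (for the halving schedule)."""

    def __init__(self, params: list[Tensor], lr: float = 0.004,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / b1t
            vhat = self.v[i] / b2t
            p.data -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(np.float32)
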