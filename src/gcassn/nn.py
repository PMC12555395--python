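"""Layers, loss and optimizer for the point-cloud segmentation network.

Thin torch-like conventions (``Module`` tree, ``train()``/``eval()`` modes,
``parameters()``) so the model code reads the way point-set networks are
usually written.  All math runs through :mod:`gcassn.autodiff`.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, as_tensor, log_softmax, relu

__all__ = [
    "Module", "Linear", "BatchNorm", "Dropout", "Sequential", "ReLU",
    "SGD", "cross_entropy", "relu",
]


class Module:
    """Base class; children and parameters are discovered from attributes."""

    def __init__(self):
        self.training = True

    def modules(self):
        yield self
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield from v.modules()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield from item.modules()

    def named_parameters(self, prefix: str = ""):
        for name, v in self.__dict__.items():
            path = f"{prefix}{name}"
            if isinstance(v, Tensor) and v.requires_grad:
                yield path, v
            elif isinstance(v, Module):
                yield from v.named_parameters(f"{path}.")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{path}.{i}.")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = ""):
        for name, v in self.__dict__.items():
            path = f"{prefix}{name}"
            if isinstance(v, Tensor) and not v.requires_grad:
                yield path, v
            elif isinstance(v, Module):
                yield from v.named_buffers(f"{path}.")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        yield from item.named_buffers(f"{path}.{i}.")

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def n_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def state_dict(self) -> dict[str, np.ndarray]:
        d = {k: v.data.copy() for k, v in self.named_parameters()}
        d.update({k: v.data.copy() for k, v in self.named_buffers()})
        return d

    def load_state_dict(self, d: dict[str, np.ndarray]):
        own = dict(self.named_parameters())
        own.update(dict(self.named_buffers()))
        missing = set(own) ^ set(d)
        if missing:
            raise KeyError(f"state dict mismatch: {sorted(missing)}")
        for k, v in own.items():
            arr = np.asarray(d[k], dtype=np.float64)
            if arr.shape != v.data.shape:
                raise ValueError(f"shape mismatch for {k}")
            v.data = arr.copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Linear(Module):
    """Shared point-wise affine map (a 1x1 convolution over points)."""

    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator,
                 bias: bool = True):
        super().__init__()
        self.in_features = in_features
        self.out_features = out_features
        # He fan-in initialization; every layer here feeds a ReLU or a softmax
        scale = np.sqrt(2.0 / in_features)
        self.weight = Tensor(rng.normal(0.0, scale, (in_features, out_features)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_features), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = as_tensor(x) @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class BatchNorm(Module):
    """Per-channel normalization over every leading axis.

    During training the statistics come from the current batch of points and
    running averages are updated; in eval mode the stored running statistics
    are used, which makes evaluation deterministic.
    """

    def __init__(self, n_features: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.momentum = momentum
        self.eps = eps
        self.gamma = Tensor(np.ones(n_features), requires_grad=True)
        self.beta = Tensor(np.zeros(n_features), requires_grad=True)
        self.running_mean = Tensor(np.zeros(n_features))
        self.running_var = Tensor(np.ones(n_features))

    def forward(self, x: Tensor) -> Tensor:
        x = as_tensor(x)
        axes = tuple(range(x.ndim - 1))
        if self.training:
            mean = x.mean(axis=axes, keepdims=True)
            var = ((x - mean) ** 2.0).mean(axis=axes, keepdims=True)
            m = self.momentum
            self.running_mean.data = (1 - m) * self.running_mean.data \
                + m * mean.data.reshape(-1)
            self.running_var.data = (1 - m) * self.running_var.data \
                + m * var.data.reshape(-1)
            xhat = (x - mean) * ((var + self.eps) ** -0.5)
        else:
            xhat = (x - self.running_mean) * \
                as_tensor((self.running_var.data + self.eps) ** -0.5)
        return xhat * self.gamma + self.beta


class Dropout(Module):
    def __init__(self, p: float = 0.5):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.p = p
        self.rng = np.random.default_rng(0)

    def reseed(self, seed: int):
        self.rng = np.random.default_rng(seed)

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0.0:
            return as_tensor(x)
        keep = 1.0 - self.p
        mask = (self.rng.random(x.shape) < keep) / keep
        return as_tensor(x) * Tensor(mask)


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return relu(x)


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean per-point cross-entropy; ``labels`` index the last logit axis."""
    logp = log_softmax(logits, axis=-1)
    labels = np.asarray(labels)
    onehot = np.zeros(logits.shape)
    np.put_along_axis(onehot, labels[..., None], 1.0, axis=-1)
    return -(logp * Tensor(onehot)).sum() * (1.0 / labels.size)


class SGD:
    """Stochastic gradient descent with classical momentum and L2 weight decay.

    Update: ``v <- mu*v + (g + wd*p); p <- p - lr*v``.
    """

    def __init__(self, params, lr: float, momentum: float = 0.9,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self._velocity = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        for p, v in zip(self.params, self._velocity):
            if p.grad is None:
                continue
            g = p.grad + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data -= self.lr * v

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()
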