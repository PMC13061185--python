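"""Layers and optimization on top of the autodiff core.

Weight initialization is truncated normal (sigma=0.02, clipped at two sigma)
for projections, zeros for biases, normalization offsets and GRN parameters,
all drawn from an explicit numpy Generator so a model is a pure function of
(config, seed).
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, conv2d


def trunc_normal(rng: np.random.Generator, shape, std: float = 0.02) -> np.ndarray:
    x = rng.normal(0.0, std, size=shape)
    return np.clip(x, -2.0 * std, 2.0 * std).astype(np.float32)


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=np.float32), requires_grad=True)


class Module:
    """Lightweight container with recursive parameter discovery."""

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def named_parameters(self, prefix: str = ""):
        out = []

        def visit(name, val):
            if isinstance(val, Parameter):
                out.append((name, val))
            elif isinstance(val, Module):
                out.extend(val.named_parameters(prefix=name + "."))
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    visit(f"{name}.{i}", item)

        for key, val in vars(self).items():
            visit(f"{prefix}{key}", val)
        return out

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        extra = set(state) - set(own)
        if missing or extra:
            raise ValueError(f"state dict mismatch: missing={sorted(missing)}, extra={sorted(extra)}")
        for k, p in own.items():
            if p.data.shape != state[k].shape:
                raise ValueError(f"shape mismatch for {k}: {p.data.shape} vs {state[k].shape}")
            p.data = state[k].astype(np.float32).copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator,
                 bias: bool = True):
        self.weight = Parameter(trunc_normal(rng, (out_features, in_features)))
        self.bias = Parameter(np.zeros(out_features)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        lead = x.shape[:-1]
        flat = x.reshape((-1, x.shape[-1]))
        out = flat @ self.weight.transpose(1, 0)
        if self.bias is not None:
            out = out + self.bias
        return out.reshape(lead + (self.weight.shape[0],))


class LayerNorm(Module):
    """Normalization over the trailing feature axis (tokens) with affine params."""

    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc / (var + self.eps).sqrt() * self.gamma + self.beta


class ChannelLayerNorm(Module):
    """LayerNorm over the channel axis of an NCHW map (batch-independent)."""

    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=1, keepdims=True)
        g = self.gamma.reshape(1, -1, 1, 1)
        b = self.beta.reshape(1, -1, 1, 1)
        return xc / (var + self.eps).sqrt() * g + b


class Conv2d(Module):
    """Convolution layers carry the main signal path, so their init is
    fan-in scaled (He) rather than the 0.02 used for residual projections."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator,
                 stride: int = 1, padding: int = 0, depthwise: bool = False,
                 bias: bool = True):
        if depthwise and in_ch != out_ch:
            raise ValueError("depthwise convolution requires in_ch == out_ch")
        wshape = (out_ch, 1, kernel, kernel) if depthwise else (out_ch, in_ch, kernel, kernel)
        fan_in = kernel * kernel * (1 if depthwise else in_ch)
        self.weight = Parameter(trunc_normal(rng, wshape, std=float(np.sqrt(2.0 / fan_in))))
        self.bias = Parameter(np.zeros(out_ch)) if bias else None
        self.stride, self.padding, self.depthwise = stride, padding, depthwise

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, stride=self.stride,
                      padding=self.padding, depthwise=self.depthwise)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    # subtracting the detached max leaves value and gradient of softmax unchanged
    m = Tensor(x.data.max(axis=axis, keepdims=True))
    e = (x - m).exp()
    return e / e.sum(axis=axis, keepdims=True)


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    m = Tensor(x.data.max(axis=axis, keepdims=True))
    z = x - m
    return z - z.exp().sum(axis=axis, keepdims=True).log()


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    n, k = logits.shape
    onehot = np.zeros((n, k), dtype=np.float32)
    onehot[np.arange(n), labels] = 1.0
    return -(log_softmax(logits) * Tensor(onehot)).sum() * (1.0 / n)


class Adam:
    """Adam with L2 weight decay folded into the gradient."""

    def __init__(self, params: list[Parameter], lr: float = 1e-5,
                 betas=(0.9, 0.999), eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = list(params)
        self.lr, self.betas, self.eps, self.weight_decay = lr, betas, eps, weight_decay
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
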