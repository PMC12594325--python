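"""Layer primitives and the AdamW optimizer used by the classifier.

Initialisation: He (fan-in) scaled normal weights, zero biases, unit
LayerNorm gains, zero GRN affine parameters (so GRN starts as the identity).
He scaling keeps activations O(1) so the GELU nonlinearities are active from
the first step — at the desk-scale training lengths this package targets
there is no budget to grow tiny (e.g. 0.02-std) weights into a useful
operating range.  Every layer takes a ``numpy.random.Generator`` so model
construction is exactly reproducible from a seed.
"""

from __future__ import annotations

import numpy as np

from ._autodiff import Tensor, conv2d, depthwise_conv2d

__all__ = ["Module", "Conv2d", "DepthwiseConv2d", "Linear",
           "LayerNormChannels", "GRN", "AdamW", "cosine_lr"]


class Module:
    """Base class: recursive parameter discovery and state (de)serialisation."""

    def named_parameters(self, prefix: str = ""):
        def walk(key, val, out):
            if isinstance(val, Tensor):
                if val.requires_grad:
                    out.append((key, val))
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    walk(f"{key}.{i}", item, out)
            elif hasattr(val, "named_parameters") and callable(val.named_parameters):
                out.extend(val.named_parameters(prefix=key + "."))

        out: list = []
        for name, val in vars(self).items():
            walk(f"{prefix}{name}", val, out)
        return out

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.parameters()))

    def state_dict(self) -> dict:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict) -> None:
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        extra = set(state) - set(own)
        if missing or extra:
            raise ValueError(f"state mismatch: missing={sorted(missing)} extra={sorted(extra)}")
        for name, p in own.items():
            arr = np.asarray(state[name], dtype=np.float64)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {name}: {arr.shape} vs {p.data.shape}")
            p.data = arr.copy()


def _param(rng: np.random.Generator, shape, fan_in: int) -> Tensor:
    std = np.sqrt(2.0 / fan_in)
    return Tensor(rng.normal(0.0, std, size=shape), requires_grad=True)


class Conv2d(Module):
    def __init__(self, cin: int, cout: int, k: int, stride: int = 1,
                 padding: int = 0, bias: bool = True, *, rng: np.random.Generator):
        self.stride = stride
        self.padding = padding
        self.weight = _param(rng, (cout, cin, k, k), fan_in=cin * k * k)
        self.bias = Tensor(np.zeros(cout), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, stride=self.stride, padding=self.padding)


class DepthwiseConv2d(Module):
    def __init__(self, channels: int, k: int, padding: int = 0, bias: bool = True,
                 *, rng: np.random.Generator):
        self.padding = padding
        self.weight = _param(rng, (channels, k, k), fan_in=k * k)
        self.bias = Tensor(np.zeros(channels), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        return depthwise_conv2d(x, self.weight, self.bias, padding=self.padding)


class Linear(Module):
    def __init__(self, cin: int, cout: int, bias: bool = True, *, rng: np.random.Generator):
        self.weight = _param(rng, (cin, cout), fan_in=cin)
        self.bias = Tensor(np.zeros(cout), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class LayerNormChannels(Module):
    """LayerNorm over the channel axis of an NCHW tensor (per spatial site)."""

    def __init__(self, channels: int, eps: float = 1e-6):
        self.eps = eps
        self.gamma = Tensor(np.ones((1, channels, 1, 1)), requires_grad=True)
        self.beta = Tensor(np.zeros((1, channels, 1, 1)), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=1, keepdims=True)
        return self.gamma * (xc / (var + self.eps).sqrt()) + self.beta


class GRN(Module):
    """Global Response Normalization (the V2 addition to the ConvNeXt block).

    Gx = ||x||_2 over space per channel; Nx = Gx / (mean_c Gx + eps);
    y = gamma * (x * Nx) + beta + x.  gamma = beta = 0 at init => identity.
    """

    def __init__(self, channels: int, eps: float = 1e-6):
        self.eps = eps
        self.gamma = Tensor(np.zeros((1, channels, 1, 1)), requires_grad=True)
        self.beta = Tensor(np.zeros((1, channels, 1, 1)), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        gx = ((x * x).sum(axis=(2, 3), keepdims=True) + self.eps).sqrt()
        nx = gx / (gx.mean(axis=1, keepdims=True) + self.eps)
        return self.gamma * (x * nx) + self.beta + x


class AdamW:
    """Decoupled-weight-decay Adam over a list of parameter Tensors."""

    def __init__(self, params, lr: float = 1e-4, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 1e-5):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / bc1
            vhat = self.v[i] / bc2
            p.data -= self.lr * (mhat / (np.sqrt(vhat) + self.eps)
                                 + self.weight_decay * p.data)


def cosine_lr(initial_lr: float, epoch: int, total_epochs: int) -> float:
    """Cosine annealing from ``initial_lr`` down to exactly 0 at the final epoch."""
    if total_epochs <= 1:
        return initial_lr
    return initial_lr * 0.5 * (1.0 + np.cos(np.pi * epoch / (total_epochs - 1)))
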