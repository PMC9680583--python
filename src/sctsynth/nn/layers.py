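"""Trainable layers: convolution, instance normalisation and small MLPs.

Weights are initialised from N(0, 0.02) as is conventional for this family
of translation networks; instance-norm affine parameters start at identity.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor
from . import ops


class Module:
    """Minimal parameter container with named-parameter traversal."""

    def parameters(self) -> dict:
        out = {}
        for name, val in vars(self).items():
            if isinstance(val, Tensor) and val.requires_grad:
                out[name] = val
            elif isinstance(val, Module):
                for sub, p in val.parameters().items():
                    out[f"{name}.{sub}"] = p
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        for sub, p in item.parameters().items():
                            out[f"{name}.{i}.{sub}"] = p
        return out

    def state_dict(self) -> dict:
        return {k: v.data.copy() for k, v in self.parameters().items()}

    def load_state_dict(self, state: dict) -> None:
        params = self.parameters()
        if set(params) != set(state):
            missing = set(params) ^ set(state)
            raise KeyError(f"parameter name mismatch: {sorted(missing)}")
        for k, v in params.items():
            arr = np.asarray(state[k], dtype=v.data.dtype)
            if arr.shape != v.data.shape:
                raise ValueError(f"shape mismatch for {k}")
            v.data = arr.copy()

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters().values())


class Conv2d(Module):
    """Convolution with symmetric padding (zeros or reflect) applied inside."""

    def __init__(self, in_ch: int, out_ch: int, k: int, stride: int = 1,
                 pad: int = 0, pad_mode: str = "constant", *, rng: np.random.Generator):
        self.w = Tensor(rng.normal(0.0, 0.02, size=(out_ch, in_ch, k, k)
                                   ).astype(np.float32), requires_grad=True)
        self.b = Tensor(np.zeros(out_ch, dtype=np.float32), requires_grad=True)
        self.stride = stride
        self.pad = pad
        self.pad_mode = pad_mode

    def __call__(self, x: Tensor) -> Tensor:
        if self.pad:
            x = ops.pad2d(x, self.pad, mode=self.pad_mode)
        return ops.conv2d(x, self.w, self.b, stride=self.stride)


class InstanceNorm2d(Module):
    """Per-sample, per-channel normalisation over the spatial axes."""

    def __init__(self, ch: int, eps: float = 1e-5):
        self.gamma = Tensor(np.ones((1, ch, 1, 1), dtype=np.float32),
                            requires_grad=True)
        self.beta = Tensor(np.zeros((1, ch, 1, 1), dtype=np.float32),
                           requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        return ops.instance_norm(x, self.gamma, self.beta, self.eps)


class MLPHead(Module):
    """Two-layer projection head mapping a (S, C) feature matrix to unit-norm
    (S, out_dim) embeddings: Linear -> LeakyReLU -> Linear -> L2-normalise.

    The leaky nonlinearity plus a small constant hidden-bias initialisation
    guarantee a nonzero pre-normalisation vector for every input — including
    the exactly-zero feature vectors a ReLU encoder produces at some spatial
    locations — so embeddings are genuinely unit-norm everywhere.  A residual
    epsilon guard keeps the normalisation NaN-free regardless."""

    def __init__(self, in_dim: int, hidden_dim: int, out_dim: int, *,
                 rng: np.random.Generator, eps: float = 1e-20):
        self.w1 = Tensor(rng.normal(0.0, 0.02, size=(in_dim, hidden_dim)
                                    ).astype(np.float32), requires_grad=True)
        self.b1 = Tensor(np.full(hidden_dim, 0.01, dtype=np.float32),
                         requires_grad=True)
        self.w2 = Tensor(rng.normal(0.0, 0.02, size=(hidden_dim, out_dim)
                                    ).astype(np.float32), requires_grad=True)
        self.b2 = Tensor(np.zeros(out_dim, dtype=np.float32), requires_grad=True)
        self.eps = eps

    def __call__(self, feats: Tensor) -> Tensor:
        h = (feats @ self.w1 + self.b1).leaky_relu(0.2)
        z = h @ self.w2 + self.b2
        norm_sq = (z * z).sum(axis=1, keepdims=True)
        return z * ((norm_sq + self.eps) ** -0.5)
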