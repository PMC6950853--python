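"""Minimal dense-network engine with explicit reverse-mode gradients.

The generators and discriminators here are small fully connected networks
(at most a few thousand parameters), so the package carries its own NumPy
layer stack rather than a deep-learning framework: dense layers, batch
normalization, leaky-ReLU, residual blocks, and Adam.

Design: ``forward(x, training)`` returns ``(output, tape)`` where the tape
holds everything the backward pass needs; ``backward(tape, grad_out)``
accumulates parameter gradients in place and returns the gradient with
respect to the input. Because tapes are externalized, a network can be
applied several times within one optimization step (as the cycle and
identity terms require) and gradients from every use accumulate correctly.
Analytic gradients are validated against finite differences in the test
suite.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Dense",
    "BatchNorm",
    "LeakyReLU",
    "Residual",
    "Sequential",
    "Adam",
]


class Layer:
    """Base class: parameterless layers inherit the empty containers."""

    def params(self) -> dict[str, np.ndarray]:
        return {}

    def grads(self) -> dict[str, np.ndarray]:
        return {}

    def buffers(self) -> dict[str, np.ndarray]:
        """Non-trained state (e.g. batch-norm running statistics)."""
        return {}

    def zero_grads(self) -> None:
        for g in self.grads().values():
            g[...] = 0.0

    def forward(self, x: np.ndarray, training: bool):  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, tape, gy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Dense(Layer):
    """Affine map x @ W + b.

    Default initialization is fan-in-scaled Gaussian; ``init="identity"``
    starts a square layer as the exact identity map (used by generators so
    they begin as the identity transformation).
    """

    def __init__(
        self, n_in: int, n_out: int, rng: np.random.Generator, init: str = "gaussian"
    ):
        if init == "identity":
            if n_in != n_out:
                raise ValueError("identity init requires a square layer")
            self.W = np.eye(n_in)
        elif init == "gaussian":
            self.W = rng.normal(0.0, 1.0 / np.sqrt(n_in), size=(n_in, n_out))
        else:
            raise ValueError(f"unknown init {init!r}")
        self.b = np.zeros(n_out)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)

    def params(self):
        return {"W": self.W, "b": self.b}

    def grads(self):
        return {"W": self.gW, "b": self.gb}

    def forward(self, x, training):
        return x @ self.W + self.b, x

    def backward(self, tape, gy):
        x = tape
        self.gW += x.T @ gy
        self.gb += gy.sum(axis=0)
        return gy @ self.W.T


class BatchNorm(Layer):
    """Batch normalization over the batch axis.

    Training mode normalizes with batch statistics and updates exponential
    running averages; inference mode uses the frozen running statistics, so
    trained networks are deterministic functions at inference.
    """

    def __init__(
        self, n: int, momentum: float = 0.1, eps: float = 1e-5, init_gamma: float = 1.0
    ):
        self.gamma = np.full(n, float(init_gamma))
        self.beta = np.zeros(n)
        self.running_mean = np.zeros(n)
        self.running_var = np.ones(n)
        self.momentum = momentum
        self.eps = eps
        self.ggamma = np.zeros_like(self.gamma)
        self.gbeta = np.zeros_like(self.beta)

    def params(self):
        return {"gamma": self.gamma, "beta": self.beta}

    def grads(self):
        return {"gamma": self.ggamma, "beta": self.gbeta}

    def buffers(self):
        return {"running_mean": self.running_mean, "running_var": self.running_var}

    def forward(self, x, training):
        if training:
            mu = x.mean(axis=0)
            var = x.var(axis=0)
            self.running_mean += self.momentum * (mu - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mu = self.running_mean
            var = self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv_std
        return self.gamma * xhat + self.beta, (xhat, inv_std, training)

    def backward(self, tape, gy):
        xhat, inv_std, training = tape
        self.ggamma += (gy * xhat).sum(axis=0)
        self.gbeta += gy.sum(axis=0)
        gxhat = gy * self.gamma
        if not training:
            return gxhat * inv_std
        # batch statistics couple every sample in the batch
        return inv_std * (
            gxhat
            - gxhat.mean(axis=0)
            - xhat * (gxhat * xhat).mean(axis=0)
        )


class LeakyReLU(Layer):
    def __init__(self, alpha: float = 0.1):
        self.alpha = alpha

    def forward(self, x, training):
        pos = x >= 0
        return np.where(pos, x, self.alpha * x), pos

    def backward(self, tape, gy):
        pos = tape
        return np.where(pos, gy, self.alpha * gy)


class _Composite(Layer):
    """Shared parameter/tape plumbing for layers that contain layers."""

    def __init__(self, layers: list[Layer]):
        self.layers = list(layers)

    def _collect(self, getter) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for i, layer in enumerate(self.layers):
            for k, v in getter(layer).items():
                out[f"{i}.{k}"] = v
        return out

    def params(self):
        return self._collect(lambda l: l.params())

    def grads(self):
        return self._collect(lambda l: l.grads())

    def buffers(self):
        return self._collect(lambda l: l.buffers())

    def _forward_chain(self, x, training):
        tapes = []
        for layer in self.layers:
            x, tape = layer.forward(x, training)
            tapes.append(tape)
        return x, tapes

    def _backward_chain(self, tapes, gy):
        for layer, tape in zip(reversed(self.layers), reversed(tapes)):
            gy = layer.backward(tape, gy)
        return gy


class Residual(_Composite):
    """Skip connection: output = inner(x) + x."""

    def forward(self, x, training):
        h, tapes = self._forward_chain(x, training)
        return h + x, tapes

    def backward(self, tapes, gy):
        return self._backward_chain(tapes, gy) + gy


class Sequential(_Composite):
    """A chain of layers; the network container used for G, F, D_X, D_Y."""

    def forward(self, x, training):
        return self._forward_chain(x, training)

    def backward(self, tapes, gy):
        return self._backward_chain(tapes, gy)

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Inference-mode forward pass (frozen batch-norm statistics)."""
        y, _ = self.forward(np.asarray(x, dtype=float), training=False)
        return y

    def n_params(self) -> int:
        return int(sum(p.size for p in self.params().values()))

    def state(self) -> dict[str, np.ndarray]:
        """All arrays (parameters + buffers) keyed for checkpointing."""
        out = {f"param.{k}": v for k, v in self.params().items()}
        out.update({f"buffer.{k}": v for k, v in self.buffers().items()})
        return out

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        own = self.state()
        missing = set(own) - set(state)
        if missing:
            raise KeyError(f"checkpoint is missing arrays: {sorted(missing)}")
        for k, arr in own.items():
            src = np.asarray(state[k], dtype=float)
            if src.shape != arr.shape:
                raise ValueError(f"shape mismatch for {k}: {src.shape} vs {arr.shape}")
            arr[...] = src


class Adam(Layer):
    """Adam optimizer over one network's parameters (in-place updates)."""

    def __init__(
        self,
        net: Sequential | Residual,
        lr: float = 1e-4,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        self.net = net
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(p) for k, p in net.params().items()}
        self.v = {k: np.zeros_like(p) for k, p in net.params().items()}

    def step(self) -> None:
        self.t += 1
        b1c = 1.0 - self.beta1 ** self.t
        b2c = 1.0 - self.beta2 ** self.t
        grads = self.net.grads()
        for k, p in self.net.params().items():
            g = grads[k]
            m = self.m[k]
            v = self.v[k]
            m += (1.0 - self.beta1) * (g - m)
            v += (1.0 - self.beta2) * (g * g - v)
            p -= self.lr * (m / b1c) / (np.sqrt(v / b2c) + self.eps)
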