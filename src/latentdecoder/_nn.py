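"""Minimal feed-forward engine: linear layers (optionally masked), activations,
losses and optimizers, all in NumPy.

Only what the package's models need is implemented: dense / sparse (masked)
linear layers without bias, the four activations, squared-error and
binary-cross-entropy losses, Adam for weights and momentum SGD for
representation rows.  Weights are stored ``(out_dim, in_dim)``; a forward pass
on a batch ``h`` of shape ``(B, in_dim)`` computes ``act(h @ W.T)``.
"""

from __future__ import annotations

import numpy as np

from .errors import ShapeError

ACTIVATIONS = ("none", "rectifier", "leaky-rectifier", "sigmoid")
LOSSES = ("squared-error", "binary-cross-entropy")


def _activate(pre: np.ndarray, activation: str, slope: float) -> np.ndarray:
    if activation == "none":
        return pre
    if activation == "rectifier":
        return np.maximum(pre, 0.0)
    if activation == "leaky-rectifier":
        return np.where(pre > 0.0, pre, slope * pre)
    if activation == "sigmoid":
        # clip to keep exp finite; saturated anyway
        return 1.0 / (1.0 + np.exp(-np.clip(pre, -60.0, 60.0)))
    raise ValueError(f"unknown activation {activation!r}")


def _activation_grad(pre: np.ndarray, out: np.ndarray, activation: str, slope: float) -> np.ndarray:
    if activation == "none":
        return np.ones_like(pre)
    if activation == "rectifier":
        return (pre > 0.0).astype(pre.dtype)
    if activation == "leaky-rectifier":
        return np.where(pre > 0.0, 1.0, slope)
    if activation == "sigmoid":
        return out * (1.0 - out)
    raise ValueError(f"unknown activation {activation!r}")


class LinearLayer:
    """A bias-free linear layer with optional binary sparsity mask.

    The mask is applied multiplicatively to the weights; masked entries stay
    exactly zero through initialization, gradients and optimizer updates, so
    they are never trainable parameters.
    """

    def __init__(
        self,
        in_dim: int,
        out_dim: int,
        activation: str = "none",
        slope: float = 0.1,
        mask: np.ndarray | None = None,
        rng: np.random.Generator | None = None,
    ):
        if activation not in ACTIVATIONS:
            raise ValueError(f"unknown activation {activation!r}")
        self.in_dim = int(in_dim)
        self.out_dim = int(out_dim)
        self.activation = activation
        self.slope = float(slope)
        if mask is not None:
            mask = np.asarray(mask, dtype=np.float64)
            if mask.shape != (self.out_dim, self.in_dim):
                raise ShapeError(
                    f"mask shape {mask.shape} != (out_dim, in_dim) = "
                    f"({self.out_dim}, {self.in_dim})"
                )
        self.mask = mask
        rng = rng if rng is not None else np.random.default_rng()
        bound = 1.0 / np.sqrt(self.in_dim)
        self.W = rng.uniform(-bound, bound, size=(self.out_dim, self.in_dim))
        if self.mask is not None:
            self.W *= self.mask
        self.gW: np.ndarray | None = None
        self._in: np.ndarray | None = None
        self._pre: np.ndarray | None = None
        self._out: np.ndarray | None = None

    @property
    def n_weight_params(self) -> int:
        if self.mask is None:
            return self.in_dim * self.out_dim
        return int(np.count_nonzero(self.mask))

    def forward(self, h: np.ndarray, cache: bool = True) -> np.ndarray:
        if h.ndim != 2 or h.shape[1] != self.in_dim:
            raise ShapeError(f"input shape {h.shape} incompatible with in_dim {self.in_dim}")
        pre = h @ self.W.T
        out = _activate(pre, self.activation, self.slope)
        if cache:
            self._in, self._pre, self._out = h, pre, out
        return out

    def backward(self, g_out: np.ndarray) -> np.ndarray:
        """Backprop ``dL/d(out)`` -> stores ``self.gW`` and returns ``dL/d(in)``."""
        g_pre = g_out * _activation_grad(self._pre, self._out, self.activation, self.slope)
        gW = g_pre.T @ self._in
        if self.mask is not None:
            gW *= self.mask
        self.gW = gW
        return g_pre @ self.W


class Network:
    """An ordered stack of :class:`LinearLayer` with a loss attached."""

    def __init__(self, layers: list[LinearLayer], loss: str = "squared-error"):
        if loss not in LOSSES:
            raise ValueError(f"unknown loss {loss!r}")
        for a, b in zip(layers, layers[1:]):
            if a.out_dim != b.in_dim:
                raise ShapeError(f"layer dims do not chain: {a.out_dim} -> {b.in_dim}")
        self.layers = layers
        self.loss = loss

    @property
    def in_dim(self) -> int:
        return self.layers[0].in_dim

    @property
    def out_dim(self) -> int:
        return self.layers[-1].out_dim

    def forward(self, h: np.ndarray, cache: bool = True) -> np.ndarray:
        for layer in self.layers:
            h = layer.forward(h, cache=cache)
        return h

    def backward(self, g_out: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            g_out = layer.backward(g_out)
        return g_out

    def loss_and_grad(self, y_hat: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
        return loss_and_grad(self.loss, y_hat, y)

    def weight_arrays(self) -> list[np.ndarray]:
        return [layer.W for layer in self.layers]


def loss_and_grad(loss: str, y_hat: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Loss value and its gradient w.r.t. ``y_hat``.

    Convention: sum over output dimensions, mean over the batch (so the loss
    is a per-sample quantity independent of batch size).  Under this scaling
    the representation gradients are O(1) per sample and the published
    benchmark learning rates are effective; Adam is invariant to the overall
    loss scale, so the weight updates do not depend on this choice.
    """
    if y_hat.shape != y.shape:
        raise ShapeError(f"prediction shape {y_hat.shape} != target shape {y.shape}")
    B = y.shape[0]
    if loss == "squared-error":
        r = y_hat - y
        return float(np.sum(r * r) / B), (2.0 / B) * r
    if loss == "binary-cross-entropy":
        p = np.clip(y_hat, 1e-12, 1.0 - 1e-12)
        val = float(-np.sum(y * np.log(p) + (1.0 - y) * np.log1p(-p)) / B)
        grad = (p - y) / (p * (1.0 - p)) / B
        return val, grad
    raise ValueError(f"unknown loss {loss!r}")


class Adam:
    """Adam with decoupled-from-nothing (classic, gradient-added) weight decay,
    one state slot per layer."""

    def __init__(
        self,
        layers: list[LinearLayer],
        lr: float,
        weight_decay: float = 0.0,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        self.layers = layers
        self.lr = float(lr)
        self.weight_decay = float(weight_decay)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(l.W) for l in layers]
        self.v = [np.zeros_like(l.W) for l in layers]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1**self.t
        bias2 = 1.0 - b2**self.t
        for layer, m, v in zip(self.layers, self.m, self.v):
            g = layer.gW
            if self.weight_decay:
                g = g + self.weight_decay * layer.W
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * (g * g)
            update = (m / bias1) / (np.sqrt(v / bias2) + self.eps)
            if layer.mask is not None:
                update *= layer.mask
            layer.W -= self.lr * update


class RowMomentumSGD:
    """Momentum SGD over the rows of a parameter matrix (the representation
    table); each call updates only the rows in ``idx``.

    With ``nonneg=True`` the update is projected gradient descent onto the
    non-negative orthant: entries clipped to zero also have their velocity
    zeroed (the standard projected-momentum rule, so momentum cannot keep
    pressing into the boundary).
    """

    def __init__(self, values: np.ndarray, lr: float, momentum: float = 0.0,
                 nonneg: bool = False):
        self.values = values
        self.lr = float(lr)
        self.momentum = float(momentum)
        self.nonneg = nonneg
        self.velocity = np.zeros_like(values)

    def step(self, idx: np.ndarray, grad_rows: np.ndarray) -> None:
        v = self.momentum * self.velocity[idx] + grad_rows if self.momentum else grad_rows
        new = self.values[idx] - self.lr * v
        if self.nonneg:
            clipped = new < 0.0
            new[clipped] = 0.0
            v = np.where(clipped, 0.0, v)
        self.velocity[idx] = v
        self.values[idx] = new
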