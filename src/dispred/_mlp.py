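"""Minimal multilayer-perceptron engine: dense layers, ReLU, Adam.

Forward/backward passes are written directly in numpy.  The engine is
deliberately small — just what the disentangling autoencoder and the
supervised network need: seeded He initialisation, cached activations for
backprop, and a textbook Adam update.  All arithmetic is float64 so repeated
runs on the same machine are bit-identical.
"""

from __future__ import annotations

import numpy as np

__all__ = ["MLP", "Adam"]


class _Dense:
    """One affine layer.  Gradients accumulate into ``gW``/``gb``."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        # He initialisation suits the ReLU hidden stack.
        scale = np.sqrt(2.0 / n_in)
        self.W = rng.normal(0.0, scale, size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        self.gW += self._x.T @ grad_out
        self.gb += grad_out.sum(axis=0)
        return grad_out @ self.W.T


class MLP:
    """Stack of dense layers with ReLU on every hidden layer, linear output.

    Parameters
    ----------
    widths
        Layer widths including input and output, e.g. ``(500, 512, 256, 80)``
        builds a 3-layer network.
    rng
        Source of initialisation randomness; pass a seeded generator for
        reproducible training.
    """

    def __init__(self, widths: tuple[int, ...], rng: np.random.Generator):
        if len(widths) < 2:
            raise ValueError("need at least an input and an output width")
        if any(w <= 0 for w in widths):
            raise ValueError(f"widths must be positive, got {widths}")
        self.widths = tuple(int(w) for w in widths)
        self.layers = [
            _Dense(a, b, rng) for a, b in zip(self.widths[:-1], self.widths[1:])
        ]
        self._relu_masks: list[np.ndarray] = []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._relu_masks = []
        h = x
        last = len(self.layers) - 1
        for i, layer in enumerate(self.layers):
            h = layer.forward(h)
            if i < last:
                mask = h > 0
                self._relu_masks.append(mask)
                h = h * mask
        return h

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        """Propagate ``dL/d(output)`` back to the input, accumulating grads."""
        g = grad_out
        last = len(self.layers) - 1
        for i in range(last, -1, -1):
            if i < last:
                g = g * self._relu_masks[i]
            g = self.layers[i].backward(g)
        return g

    def zero_grad(self) -> None:
        for layer in self.layers:
            layer.gW[:] = 0.0
            layer.gb[:] = 0.0

    @property
    def parameters(self) -> list[np.ndarray]:
        out: list[np.ndarray] = []
        for layer in self.layers:
            out.extend([layer.W, layer.b])
        return out

    @property
    def gradients(self) -> list[np.ndarray]:
        out: list[np.ndarray] = []
        for layer in self.layers:
            out.extend([layer.gW, layer.gb])
        return out

    def get_state(self) -> list[np.ndarray]:
        return [p.copy() for p in self.parameters]

    def set_state(self, state: list[np.ndarray]) -> None:
        for p, s in zip(self.parameters, state, strict=True):
            p[:] = s


class Adam:
    """Adam with the standard bias-corrected moment estimates."""

    def __init__(
        self,
        params: list[np.ndarray],
        grads: list[np.ndarray],
        lr: float = 5e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        self.params = params
        self.grads = grads
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for p, g, m, v in zip(self.params, self.grads, self.m, self.v):
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * g * g
            p -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
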