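"""Adam optimizer and reduce-on-plateau learning-rate schedule."""

from __future__ import annotations

import numpy as np

from .layers import Layer


class Adam:
    """Adam over a list of layers' parameters.

    beta1/beta2 default to the usual 0.9 / 0.999 first/second-moment decays.
    """

    def __init__(self, layers: list[Layer], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.layers = [l for l in layers if l.params]
        self.lr = float(lr)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self._m = [{k: np.zeros_like(v) for k, v in l.params.items()} for l in self.layers]
        self._v = [{k: np.zeros_like(v) for k, v in l.params.items()} for l in self.layers]

    def zero_grad(self) -> None:
        for layer in self.layers:
            layer.zero_grad()

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for layer, m, v in zip(self.layers, self._m, self._v):
            for k, p in layer.params.items():
                g = layer.grads[k]
                m[k] = b1 * m[k] + (1 - b1) * g
                v[k] = b2 * v[k] + (1 - b2) * g * g
                p -= self.lr * (m[k] / bc1) / (np.sqrt(v[k] / bc2) + self.eps)


class ReduceLROnPlateau:
    """Halve the learning rate when a monitored loss stops improving.

    The rate is halved once the loss has failed to improve (strictly
    decrease) for ``patience`` consecutive epochs, and is never reduced
    below ``floor``.  The counter resets after each reduction.
    """

    def __init__(self, optimizer: Adam, patience: int, floor: float,
                 factor: float = 0.5) -> None:
        if patience < 1:
            raise ValueError("patience must be >= 1")
        self.optimizer = optimizer
        self.patience = patience
        self.floor = float(floor)
        self.factor = factor
        self.best = np.inf
        self.bad_epochs = 0

    def step(self, loss: float) -> bool:
        """Record an epoch's monitored loss; return True if the lr was reduced."""
        if loss < self.best:
            self.best = loss
            self.bad_epochs = 0
            return False
        self.bad_epochs += 1
        if self.bad_epochs >= self.patience:
            self.optimizer.lr = max(self.optimizer.lr * self.factor, self.floor)
            self.bad_epochs = 0
            return True
        return False
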