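"""AdamW optimizer and cosine-annealing-with-warm-restarts schedule."""

from __future__ import annotations

import numpy as np


class AdamW:
    """Adam with decoupled weight decay."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 1e-4) -> None:
        self.params = params
        self.lr = lr
        self.betas = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.betas
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for k, p in self.params.items():
            g = grads[k]
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * (g * g)
            m_hat = self.m[k] / bc1
            v_hat = self.v[k] / bc2
            p -= self.lr * (m_hat / (np.sqrt(v_hat) + self.eps)
                            + self.weight_decay * p)


class CosineWarmRestarts:
    """SGDR schedule: lr anneals over each cycle and resets to lr0.

    Cycle i has length t0 * mult**i epochs; within a cycle,
    lr = eta_min + (lr0 - eta_min) * (1 + cos(pi * t_cur / t_i)) / 2.
    """

    def __init__(self, lr0: float, t0: int = 10, mult: int = 2,
                 eta_min: float = 0.0) -> None:
        if lr0 <= 0 or t0 < 1 or mult < 1:
            raise ValueError("invalid schedule parameters")
        self.lr0 = lr0
        self.t0 = t0
        self.mult = mult
        self.eta_min = eta_min

    def lr_at(self, epoch: int) -> float:
        t_cur, t_i = epoch, self.t0
        while t_cur >= t_i:
            t_cur -= t_i
            t_i *= self.mult
        return self.eta_min + 0.5 * (self.lr0 - self.eta_min) * (
            1.0 + np.cos(np.pi * t_cur / t_i))
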