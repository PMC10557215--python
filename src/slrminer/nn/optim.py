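"""Adam optimiser with linear warm-up, updating parameters in registration order."""

from __future__ import annotations

import numpy as np

from .autograd import DTYPE, Tensor


class Adam:
    def __init__(self, params: dict[str, Tensor], lr: float = 5e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 warmup_steps: int = 50, clip: float = 5.0):
        self.names = sorted(params)
        self.params = [params[n] for n in self.names]
        self.lr, self.betas, self.eps = lr, betas, eps
        self.warmup_steps, self.clip = warmup_steps, clip
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        scale = min(1.0, self.t / max(1, self.warmup_steps))
        lr = self.lr * scale
        if self.clip > 0:
            total = 0.0
            for p in self.params:
                if p.grad is not None:
                    total += float((p.grad.astype(np.float64) ** 2).sum())
            norm = np.sqrt(total)
            gscale = 1.0 if norm <= self.clip else self.clip / (norm + 1e-12)
        else:
            gscale = 1.0
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad * gscale
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p.data = (p.data - lr * mhat / (np.sqrt(vhat) + self.eps)).astype(DTYPE)
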