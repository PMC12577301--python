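"""Adam optimizer with coupled L2 weight decay.

Weight decay is applied the classic way — added to the gradient before the
adaptive moment updates (as in ``torch.optim.Adam(weight_decay=...)``), not
decoupled as in AdamW.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Adam"]


class Adam:
    def __init__(self, model, lr: float = 3e-3, weight_decay: float = 2e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8) -> None:
        if lr <= 0 or weight_decay < 0:
            raise ValueError("lr must be positive and weight_decay non-negative")
        self.model = model
        self.lr, self.wd = float(lr), float(weight_decay)
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m = [{k: np.zeros_like(v) for k, v in layer.params.items()} for layer in model.layers]
        self._v = [{k: np.zeros_like(v) for k, v in layer.params.items()} for layer in model.layers]

    def effective_grad(self, layer_idx: int, name: str) -> np.ndarray:
        """Gradient with the L2 penalty term wd * w added (pre-moment update)."""
        layer = self.model.layers[layer_idx]
        return layer.grads[name] + self.wd * layer.params[name]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for i, layer in enumerate(self.model.layers):
            for name in layer.params:
                g = self.effective_grad(i, name)
                m = self._m[i][name]
                v = self._v[i][name]
                m *= self.b1
                m += (1 - self.b1) * g
                v *= self.b2
                v += (1 - self.b2) * g * g
                layer.params[name] -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
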