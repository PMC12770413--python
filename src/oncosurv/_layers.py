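"""Small trainable building blocks shared by the learning modules."""

from __future__ import annotations

import numpy as np

from ._nn import Tensor, glorot_init

__all__ = ["MLP"]

_ACTS = {
    "relu": lambda t: t.relu(),
    "sigmoid": lambda t: t.sigmoid(),
    "linear": lambda t: t,
}


class MLP:
    """Fully connected network with per-layer weights and biases.

    `sizes` gives (input, hidden..., output) widths.  Hidden layers use
    `hidden_activation`; the last layer uses `output_activation`.  Inverted
    dropout (train-time only) is applied after each hidden activation.
    """

    def __init__(
        self,
        sizes: tuple[int, ...],
        hidden_activation: str = "relu",
        output_activation: str = "linear",
        dropout: float = 0.0,
        seed: int = 0,
    ):
        if len(sizes) < 2:
            raise ValueError("MLP needs at least input and output sizes")
        rng = np.random.default_rng(seed)
        self.sizes = tuple(sizes)
        self.hidden_activation = hidden_activation
        self.output_activation = output_activation
        self.dropout = dropout
        self.weights = [
            Tensor(glorot_init(rng, a, b), requires_grad=True)
            for a, b in zip(sizes[:-1], sizes[1:])
        ]
        self.biases = [
            Tensor(np.zeros(b), requires_grad=True) for b in sizes[1:]
        ]

    @property
    def params(self) -> list[Tensor]:
        out = []
        for w, b in zip(self.weights, self.biases):
            out.extend([w, b])
        return out

    def forward(
        self,
        x,
        train: bool = False,
        rng: np.random.Generator | None = None,
    ) -> Tensor:
        h = x if isinstance(x, Tensor) else Tensor(np.atleast_2d(x))
        n_layers = len(self.weights)
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            h = h @ w + b
            act = self.output_activation if i == n_layers - 1 else self.hidden_activation
            h = _ACTS[act](h)
            if train and self.dropout > 0 and i < n_layers - 1:
                keep = (rng.uniform(size=h.shape) >= self.dropout) / (1 - self.dropout)
                h = h * Tensor(keep)
        return h

    def __call__(self, x, **kw) -> Tensor:
        return self.forward(x, **kw)

    def get_params(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.params]

    def set_params(self, values: list[np.ndarray]) -> None:
        for p, v in zip(self.params, values):
            p.value = np.asarray(v, dtype=np.float64).copy()
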