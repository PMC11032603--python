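"""Global-pooling probability head.

Reduces an (m x n) base interaction probability map to a scalar pair
probability:

    Q    = ReLU(p_map - mean(p_map) - gamma * var(p_map))     elementwise
    p_Q  = sum(Q) / (sum(sign(Q)) + 1)
    p    = 1 / (1 + exp(-eta * (p_Q - p0)))

gamma and eta are the head's only two trainable scalars; p0 is a
hyperparameter in [0, 1]. Since Q >= 0, sign(Q) is an indicator and the
denominator counts the strictly-positive entries plus one, so p_Q is always
finite. var() is the population (divide-by-N) variance. Adding a constant to
every map entry leaves p unchanged.
"""

from __future__ import annotations

import numpy as np

from .nn import Module, Tensor


class ProbabilityHead(Module):
    """Trainable head; gamma starts at 0 and eta at 1 (a neutral shifted-mean
    logistic) unless a checkpoint overrides them."""

    def __init__(self, p0: float = 0.5, dtype=np.float32):
        super().__init__()
        if not 0.0 <= p0 <= 1.0:
            raise ValueError(f"p0 must be in [0,1], got {p0}")
        self.p0 = p0
        self.gamma = Tensor(np.zeros((), dtype=dtype), requires_grad=True)
        self.eta = Tensor(np.ones((), dtype=dtype), requires_grad=True)

    def __call__(self, p_map: Tensor) -> Tensor:
        """p_map (B, m, n) -> pair probabilities (B,)."""
        if p_map.size == 0:
            raise ValueError("empty probability map")
        mu = p_map.mean(axis=(1, 2), keepdims=True)
        centered = p_map - mu
        var = (centered * centered).mean(axis=(1, 2), keepdims=True)
        q = (p_map - mu - self.gamma * var).relu()
        # sign(Q) is 0/1 and piecewise constant: zero gradient, so the
        # denominator enters the graph as a constant per sample
        denom = (q.data > 0).sum(axis=(1, 2)).astype(p_map.dtype) + 1.0
        p_q = q.sum(axis=(1, 2)) * Tensor(1.0 / denom)
        return (self.eta * (p_q - self.p0)).sigmoid()


def pair_probability(p_map: np.ndarray, gamma: float = 0.0, eta: float = 1.0,
                     p0: float = 0.5) -> float:
    """Scalar reference evaluation of the pooling formula on one map."""
    p_map = np.asarray(p_map, dtype=np.float64)
    if p_map.size == 0:
        raise ValueError("empty probability map")
    q = np.maximum(p_map - p_map.mean() - gamma * p_map.var(), 0.0)
    p_q = q.sum() / ((q > 0).sum() + 1.0)
    return float(1.0 / (1.0 + np.exp(-eta * (p_q - p0))))
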