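"""Convolutional scorer: contact map -> base interaction probability map.

Four stride-1 "same" convolutions with square ks x ks kernels, each followed
by batch normalization; ReLU after the first three, a logistic activation
after the fourth. Channels halve per layer, 2*d1 -> d1 -> d1/2 -> d1/4 -> 1,
so the output squeezes to an (m x n) map of per-base-pair probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import BatchNorm2d, Conv2d, Module, Tensor


@dataclass(frozen=True)
class CnnConfig:
    d1: int = 256
    ks: int = 9

    def __post_init__(self) -> None:
        if self.ks % 2 == 0:
            raise ValueError(f"ks must be odd, got {self.ks}")
        if self.d1 % 4:
            raise ValueError(f"d1 must be divisible by 4, got {self.d1}")

    @property
    def channels(self) -> tuple[int, ...]:
        return (2 * self.d1, self.d1, self.d1 // 2, self.d1 // 4, 1)


class ContactCnn(Module):
    def __init__(self, config: CnnConfig, rng: np.random.Generator, dtype=np.float32):
        super().__init__()
        self.config = config
        ch = config.channels
        self.convs = [Conv2d(ch[i], ch[i + 1], config.ks, rng, dtype) for i in range(4)]
        self.norms = [BatchNorm2d(ch[i + 1], dtype) for i in range(4)]

    def __call__(self, contact_map: Tensor) -> Tensor:
        """contact_map (B, m, n, 2*d1) channels-last -> probability map (B, m, n)."""
        if contact_map.shape[-1] != 2 * self.config.d1:
            raise ValueError(
                f"expected {2 * self.config.d1} channels, got {contact_map.shape[-1]}")
        x = contact_map
        for i in range(3):
            x = self.norms[i](self.convs[i](x)).relu()
        x = self.norms[3](self.convs[3](x)).sigmoid()
        b, m, n, _ = x.shape
        return x.reshape(b, m, n)


def score_map(contact_map: np.ndarray, cnn: ContactCnn) -> np.ndarray:
    """Score one channel-first (2*d1, m, n) contact map in inference mode."""
    was_training = cnn.training
    cnn.eval()
    try:
        nhwc = np.ascontiguousarray(np.asarray(contact_map).transpose(1, 2, 0))
        return cnn(Tensor(nhwc[None])).data[0]
    finally:
        if was_training:
            cnn.train()


def cnn_parameter_count(config: CnnConfig) -> int:
    """Closed-form trainable-parameter count of the conv module."""
    ch = config.channels
    conv = sum(ch[i] * ch[i + 1] * config.ks ** 2 + ch[i + 1] for i in range(4))
    bn = sum(2 * ch[i + 1] for i in range(4))
    return conv + bn
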