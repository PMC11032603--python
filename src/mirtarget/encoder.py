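"""Shared sequence encoder: embedding + sinusoidal positions + transformer.

One weight set serves both the miRNA branch and the candidate-target-site
branch: a pair is encoded by calling the same encoder twice. The encoder
maps an integer-encoded, zero-padded sequence to a per-base feature matrix
of width ``d1`` via

    X  = Embed(codes)                       (l x d0)
    T  = TransformerEncoder(X + P_X)        (l x d0)
    T' = Dropout(ReLU(T W + b))             (l x d1)

with the standard 0-based sinusoidal positional encoding P_X.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Dropout, Embedding, Linear, Module, Tensor, TransformerEncoderLayer

N_TOKENS = 5  # four bases plus the padding symbol


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class EncoderConfig:
    """Widths and depths of the shared encoder.

    d0: embedding / transformer model width; nl: encoder layers; nh:
    attention heads; p_dropout: dropout fraction (0 in the reference
    setting); d1: width after the transform module. The feedforward width
    is fixed at 2*d0.
    """

    d0: int = 512
    nl: int = 6
    nh: int = 1
    p_dropout: float = 0.0
    d1: int = 256

    @property
    def ff_dim(self) -> int:
        return 2 * self.d0

    def __post_init__(self) -> None:
        if self.d0 % 2:
            raise ConfigError(f"d0 must be even, got {self.d0}")
        if self.d0 % self.nh:
            raise ConfigError(f"d0={self.d0} not divisible by nh={self.nh}")
        if self.d1 % 4:
            raise ConfigError(f"d1 must be divisible by 4 for the conv channel halvings, got {self.d1}")
        if not 0.0 <= self.p_dropout <= 1.0:
            raise ConfigError(f"p_dropout must be in [0,1], got {self.p_dropout}")


def positional_encoding(length: int, d0: int) -> np.ndarray:
    """Sinusoidal positional encoding, 0-based in position and frequency.

    PE[p, 2j] = sin(p / 10000^(2j/d0)), PE[p, 2j+1] = cos(p / 10000^(2j/d0)).
    """
    if d0 % 2:
        raise ConfigError(f"d0 must be even, got {d0}")
    if length < 1:
        raise ConfigError(f"length must be >= 1, got {length}")
    pos = np.arange(length, dtype=np.float64)[:, None]
    freq = np.exp(-np.log(10000.0) * (2.0 * np.arange(d0 // 2)) / d0)[None, :]
    pe = np.empty((length, d0), dtype=np.float64)
    pe[:, 0::2] = np.sin(pos * freq)
    pe[:, 1::2] = np.cos(pos * freq)
    return pe


class SequenceEncoder(Module):
    """Embedding + positional encoding + transformer stack + transform module."""

    def __init__(self, config: EncoderConfig, rng: np.random.Generator, dtype=np.float32):
        super().__init__()
        self.config = config
        self.embed = Embedding(N_TOKENS, config.d0, rng, dtype)
        self.layers = [
            TransformerEncoderLayer(config.d0, config.nh, config.ff_dim,
                                    config.p_dropout, rng, dtype)
            for _ in range(config.nl)
        ]
        self.transform = Linear(config.d0, config.d1, rng, dtype)
        self.drop = Dropout(config.p_dropout, rng)
        self.dtype = dtype
        self._pe_cache: dict[int, np.ndarray] = {}

    def _pe(self, length: int) -> Tensor:
        if length not in self._pe_cache:
            self._pe_cache[length] = positional_encoding(length, self.config.d0).astype(self.dtype)
        return Tensor(self._pe_cache[length])

    def __call__(self, codes: np.ndarray) -> Tensor:
        """codes: int array (batch, length) -> representation (batch, length, d1)."""
        codes = np.asarray(codes)
        if codes.ndim == 1:
            codes = codes[None, :]
        if codes.min() < 0 or codes.max() >= N_TOKENS:
            raise ValueError("sequence codes must lie in {0..4}")
        x = self.embed(codes) + self._pe(codes.shape[1])
        for layer in self.layers:
            x = layer(x)
        return self.drop(self.transform(x).relu())


def encode_representation(codes: np.ndarray, encoder: SequenceEncoder) -> np.ndarray:
    """Inference-mode representation of one encoded sequence: (length, d1)."""
    was_training = encoder.training
    encoder.eval()
    try:
        out = encoder(np.asarray(codes)[None, :]).data[0]
    finally:
        if was_training:
            encoder.train()
    return out
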