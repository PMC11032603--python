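"""Full model assembly: shared encoder -> contact map -> CNN -> pooling head.

The ``full`` profile reproduces the reference hyperparameters (d0=512,
nl=6, nh=1, d1=256, ks=9, p0=0.5, p_dropout=0) at 26,691,717 trainable
parameters; the ``reduced`` profile is a CPU-scale configuration for tests
and examples.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np

from .convnet import CnnConfig, ContactCnn, cnn_parameter_count
from .encoder import EncoderConfig, SequenceEncoder
from .fusion import build_contact_map_batch
from .nn import Module, Tensor
from .prob_head import ProbabilityHead
from .seqio import RnaSequence, encode_sequence


@dataclass(frozen=True)
class ModelConfig:
    d0: int = 512
    nl: int = 6
    nh: int = 1
    d1: int = 256
    ks: int = 9
    p0: float = 0.5
    p_dropout: float = 0.0
    #: padded input lengths; miRNAs are ~22 nt and CTS windows at most 3x22
    mirna_pad: int = 30
    cts_pad: int = 90

    @property
    def encoder(self) -> EncoderConfig:
        return EncoderConfig(d0=self.d0, nl=self.nl, nh=self.nh,
                             p_dropout=self.p_dropout, d1=self.d1)

    @property
    def cnn(self) -> CnnConfig:
        return CnnConfig(d1=self.d1, ks=self.ks)

    @classmethod
    def full(cls, **overrides) -> "ModelConfig":
        return cls(**overrides)

    @classmethod
    def reduced(cls, **overrides) -> "ModelConfig":
        """CPU-scale profile: narrower widths, smaller conv kernel, and pads
        tight around the 22-nt miRNAs / 66-nt sites the generator emits."""
        base = dict(d0=64, nl=2, nh=1, d1=32, ks=5, mirna_pad=24, cts_pad=66)
        base.update(overrides)
        return cls(**base)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(**d)


class TargetModel(Module):
    """End-to-end miRNA / candidate-target-site interaction model."""

    def __init__(self, config: ModelConfig, seed: int = 1234, dtype=np.float32):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.config = config
        self.encoder = SequenceEncoder(config.encoder, rng, dtype)
        self.cnn = ContactCnn(config.cnn, rng, dtype)
        self.head = ProbabilityHead(config.p0, dtype)
        self.seed = seed

    def forward(self, mirna_codes: np.ndarray, cts_codes: np.ndarray
                ) -> tuple[Tensor, Tensor]:
        """Batched forward pass.

        mirna_codes (B, m), cts_codes (B, n) -> (probabilities (B,),
        probability maps (B, m, n)). The same encoder weights serve both
        branches.
        """
        t1 = self.encoder(mirna_codes)
        t2 = self.encoder(cts_codes)
        contact = build_contact_map_batch(t1, t2)
        p_map = self.cnn(contact)
        p = self.head(p_map)
        return p, p_map

    __call__ = forward

    def encode_pair(self, mirna: RnaSequence | str, cts: RnaSequence | str
                    ) -> tuple[np.ndarray, np.ndarray]:
        return (encode_sequence(mirna, self.config.mirna_pad),
                encode_sequence(cts, self.config.cts_pad))

    def predict_batch(self, pairs: list[tuple[RnaSequence | str, RnaSequence | str]],
                      batch_size: int = 32, return_maps: bool = False):
        """Inference over sequence pairs; returns probs (and maps if asked)."""
        was_training = self.training
        self.eval()
        probs: list[np.ndarray] = []
        maps: list[np.ndarray] = []
        try:
            for a in range(0, len(pairs), batch_size):
                chunk = pairs[a:a + batch_size]
                m = np.stack([self.encode_pair(mi, ct)[0] for mi, ct in chunk])
                c = np.stack([self.encode_pair(mi, ct)[1] for mi, ct in chunk])
                p, pm = self.forward(m, c)
                probs.append(p.data.copy())
                if return_maps:
                    maps.append(pm.data.copy())
        finally:
            if was_training:
                self.train()
        out = np.concatenate(probs) if probs else np.empty(0)
        if return_maps:
            return out, (np.concatenate(maps) if maps else np.empty((0, 0, 0)))
        return out


def encoder_parameter_count(cfg: EncoderConfig) -> int:
    """Closed-form count of the shared encoder branch (embedding through
    transform module)."""
    d0, ff = cfg.d0, cfg.ff_dim
    per_layer = (3 * d0 * d0 + 3 * d0        # fused QKV projection
                 + d0 * d0 + d0              # attention output projection
                 + d0 * ff + ff              # feedforward in
                 + ff * d0 + d0              # feedforward out
                 + 2 * (2 * d0))             # two layer norms
    return 5 * d0 + cfg.nl * per_layer + (d0 * cfg.d1 + cfg.d1)


def count_parameters(config: ModelConfig) -> int:
    """Closed-form total trainable-parameter count of the full model."""
    return encoder_parameter_count(config.encoder) + cnn_parameter_count(config.cnn) + 2
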