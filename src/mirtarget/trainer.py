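"""Training loop, checkpointing and parameter accounting.

Training minimizes binary cross entropy on the head's pair probability with
Adam, evaluates the validation set once per epoch, and keeps the checkpoint
with the highest composite score (sum of the six ratio metrics). When the
validation set contains a single class the score is undefined; selection
then falls back to accuracy and a warning is logged.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .metrics import MetricsReport, evaluate
from .model import ModelConfig, TargetModel, count_parameters
from .nn import Adam, Tensor
from .seqio import LabeledPair, RnaSequence

logger = logging.getLogger(__name__)

_BCE_EPS = 1e-7


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 40
    batch_size: int = 32
    learning_rate: float = 1e-4
    rng_seed: int = 1234

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")


@dataclass
class Checkpoint:
    """Best-epoch snapshot: weights + config + its validation report."""

    model_config: ModelConfig
    weights: dict[str, np.ndarray]
    val_report: MetricsReport | None
    epoch: int

    def build_model(self) -> TargetModel:
        model = TargetModel(self.model_config, seed=0)
        model.load_state_dict(self.weights)
        model.eval()
        return model

    def save(self, path: str | Path) -> None:
        meta = {
            "model_config": self.model_config.to_dict(),
            "epoch": self.epoch,
            "val_report": None if self.val_report is None else self.val_report.as_dict(),
        }
        with open(path, "wb") as fh:
            np.savez(fh, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                     **{f"w/{k}": v for k, v in self.weights.items()})

    @classmethod
    def load(cls, path: str | Path) -> "Checkpoint":
        with np.load(path) as archive:
            meta = json.loads(bytes(archive["__meta__"]).decode())
            weights = {k[2:]: archive[k] for k in archive.files if k.startswith("w/")}
        report = meta["val_report"]
        if report is not None:
            report.pop("score", None)
            report = MetricsReport(**report)
        return cls(model_config=ModelConfig.from_dict(meta["model_config"]),
                   weights=weights, val_report=report, epoch=meta["epoch"])


def _encode_pairs(pairs: Sequence[LabeledPair], config: ModelConfig
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    from .seqio import encode_sequence
    m = np.stack([encode_sequence(p.mirna, config.mirna_pad) for p in pairs])
    c = np.stack([encode_sequence(p.site, config.cts_pad) for p in pairs])
    y = np.array([p.label for p in pairs], dtype=np.float64)
    return m, c, y


def bce_loss(p: Tensor, y: np.ndarray) -> Tensor:
    """Binary cross entropy on probabilities, clipped for log stability."""
    y = Tensor(np.asarray(y, dtype=p.dtype))
    pc = p * (1.0 - 2.0 * _BCE_EPS) + _BCE_EPS
    return -(y * pc.log() + (1.0 - y) * (1.0 - pc).log()).mean()


def predict_pair(mirna: RnaSequence | str, cts: RnaSequence | str,
                 ckpt_or_model: "Checkpoint | TargetModel"
                 ) -> tuple[float, np.ndarray]:
    """Inference on one pair: (probability, base interaction probability map)."""
    model = ckpt_or_model.build_model() if isinstance(ckpt_or_model, Checkpoint) else ckpt_or_model
    probs, maps = model.predict_batch([(mirna, cts)], return_maps=True)
    return float(probs[0]), maps[0]


def _validation_key(report: MetricsReport) -> float:
    if report.score is not None:
        return report.score
    logger.warning("validation score undefined (a confusion ratio is NA); selecting by accuracy")
    return report.accuracy if report.accuracy is not None else float("-inf")


def train(train_pairs: Sequence[LabeledPair], val_pairs: Sequence[LabeledPair],
          model_config: ModelConfig | None = None,
          train_config: TrainConfig | None = None,
          log_path: str | Path | None = None) -> Checkpoint:
    """Train the full model and return the best-validation-score checkpoint."""
    if not train_pairs or not val_pairs:
        raise ValueError("train and validation sets must be nonempty")
    model_config = model_config or ModelConfig.full()
    train_config = train_config or TrainConfig()
    model = TargetModel(model_config, seed=train_config.rng_seed)
    optimizer = Adam(model.parameters(), lr=train_config.learning_rate)
    # distinct stream from the weight-init rng, still derived from the seed
    shuffle_rng = np.random.default_rng([train_config.rng_seed, 1])

    mir, cts, y = _encode_pairs(train_pairs, model_config)
    val_labels = [p.label for p in val_pairs]
    n = len(train_pairs)
    bs = train_config.batch_size

    best: Checkpoint | None = None
    best_key = float("-inf")
    log_lines = ["epoch\tmean_train_loss\tval_score\tval_accuracy"]

    for epoch in range(1, train_config.epochs + 1):
        model.train()
        order = shuffle_rng.permutation(n)
        losses = []
        for a in range(0, n, bs):
            idx = order[a:a + bs]
            optimizer.zero_grad()
            p, _ = model.forward(mir[idx], cts[idx])
            loss = bce_loss(p, y[idx])
            loss.backward()
            optimizer.step()
            losses.append(loss.item())

        model.eval()
        val_probs = model.predict_batch([(p.mirna, p.site) for p in val_pairs],
                                        batch_size=bs)
        report = evaluate(val_labels, val_probs)
        key = _validation_key(report)
        log_lines.append(
            f"{epoch}\t{np.mean(losses):.6f}\t"
            f"{'NA' if report.score is None else f'{report.score:.6f}'}\t"
            f"{'NA' if report.accuracy is None else f'{report.accuracy:.6f}'}")
        logger.info("epoch %d: loss %.5f, val %s", epoch, float(np.mean(losses)),
                    "NA" if report.score is None else f"score {report.score:.4f}")
        if key > best_key:
            best_key = key
            best = Checkpoint(model_config=model_config, weights=model.state_dict(),
                              val_report=report, epoch=epoch)

    if log_path is not None:
        Path(log_path).write_text("\n".join(log_lines) + "\n")
    assert best is not None
    return best


def epoch_losses(lines_path: str | Path) -> list[float]:
    """Parse mean train losses back out of a training log."""
    rows = Path(lines_path).read_text().strip().splitlines()[1:]
    return [float(r.split("\t")[1]) for r in rows]


__all__ = [
    "TrainConfig", "Checkpoint", "train", "predict_pair", "bce_loss",
    "count_parameters", "epoch_losses",
]
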