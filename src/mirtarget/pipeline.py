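"""Transcript-level decision procedure and probability-map export.

A miRNA targets a transcript when the scanner finds at least one candidate
target site and the maximum pair probability over all sites (p_max) reaches
0.5. With no candidate sites the pair is called non-interacting outright.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .cts_scan import CtsWindow, find_cts
from .metrics import MetricsReport, average_reports, evaluate
from .model import TargetModel
from .seqio import RnaSequence
from .trainer import Checkpoint

INTERACTION_THRESHOLD = 0.5


@dataclass(frozen=True)
class TranscriptPrediction:
    interaction: bool
    p_max: float | None
    per_window: tuple[tuple[CtsWindow, float], ...]
    n_c: int

    @property
    def best_windows(self) -> tuple[CtsWindow, ...]:
        """All windows attaining p_max (ties reported together)."""
        if self.p_max is None:
            return ()
        return tuple(w for w, p in self.per_window if p == self.p_max)


def _as_model(ckpt_or_model: Checkpoint | TargetModel) -> TargetModel:
    return ckpt_or_model.build_model() if isinstance(ckpt_or_model, Checkpoint) else ckpt_or_model


def predict_transcript(mirna: RnaSequence | str, transcript: RnaSequence | str,
                       ckpt_or_model: Checkpoint | TargetModel,
                       max_distance: int = 4, batch_size: int = 32
                       ) -> TranscriptPrediction:
    """Scan, score every candidate window, and threshold p_max."""
    model = _as_model(ckpt_or_model)
    windows = find_cts(mirna, transcript, max_distance=max_distance)
    if not windows:
        return TranscriptPrediction(interaction=False, p_max=None, per_window=(), n_c=0)
    probs = model.predict_batch([(mirna, w.cts_seq) for w in windows],
                                batch_size=batch_size)
    per_window = tuple(zip(windows, (float(p) for p in probs)))
    p_max = float(max(probs))
    return TranscriptPrediction(
        interaction=p_max >= INTERACTION_THRESHOLD, p_max=p_max,
        per_window=per_window, n_c=len(windows))


def predict_transcript_table(mirnas: dict[str, RnaSequence],
                             transcripts: dict[str, RnaSequence],
                             pairs: Sequence[tuple[str, str]],
                             ckpt_or_model: Checkpoint | TargetModel,
                             max_distance: int = 4) -> pd.DataFrame:
    """Batch transcript-level prediction over (mirna_id, transcript_id) pairs."""
    model = _as_model(ckpt_or_model)
    rows = []
    for mid, tid in pairs:
        pred = predict_transcript(mirnas[mid], transcripts[tid], model,
                                  max_distance=max_distance)
        best = pred.best_windows[0] if pred.best_windows else None
        rows.append({
            "mirna_id": mid, "transcript_id": tid, "n_c": pred.n_c,
            "p_max": np.nan if pred.p_max is None else pred.p_max,
            "interaction": int(pred.interaction),
            "best_cts_start": np.nan if best is None else best.cts_start,
            "best_cts_end": np.nan if best is None else best.cts_end,
        })
    return pd.DataFrame(rows)


def evaluate_transcript_sets(predictions: Sequence[Sequence[float]],
                             labels: Sequence[Sequence[int]]) -> MetricsReport:
    """Per-set reports averaged with the unweighted mean (ten-set layout)."""
    reports = [evaluate(l, p) for l, p in zip(labels, predictions)]
    return average_reports(reports)


def export_pmap(mirna: RnaSequence | str, cts: RnaSequence | str,
                ckpt_or_model: Checkpoint | TargetModel,
                tsv_path: str | Path | None = None,
                image_path: str | Path | None = None) -> np.ndarray:
    """Compute and optionally export a base interaction probability map.

    The TSV stores the (m x n) matrix with miRNA positions (5'->3') as rows
    and CTS positions as columns, to six decimals; the optional image is a
    heat map of the same matrix.
    """
    model = _as_model(ckpt_or_model)
    probs, maps = model.predict_batch([(mirna, cts)], return_maps=True)
    p_map = maps[0]
    if tsv_path is not None:
        np.savetxt(tsv_path, p_map, delimiter="\t", fmt="%.6f")
    if image_path is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(8, 3.2))
        im = ax.imshow(p_map, aspect="auto", cmap="viridis", vmin=0.0, vmax=1.0)
        ax.set_xlabel("CTS position (arranged)")
        ax.set_ylabel("miRNA position (5'->3')")
        ax.set_title(f"base interaction probability map (p = {float(probs[0]):.3f})")
        fig.colorbar(im, ax=ax, label="probability")
        fig.tight_layout()
        fig.savefig(image_path, dpi=120)
        plt.close(fig)
    return p_map
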