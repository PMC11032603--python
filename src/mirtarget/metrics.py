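"""Binary-classification metrics and the composite model-selection score.

Metrics are stored as fractions in [0, 1]; tables display percentages
(rounded half-up to two decimals). The composite score is the plain sum of
the six confusion-matrix metrics (accuracy, sensitivity, specificity, PPV,
NPV, F1) as fractions, so a perfect classifier scores 6. A ratio whose
denominator is zero (e.g. PPV on an all-negative test set) is reported as
None / "NA", never silently as 0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, fields
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

RATIO_METRICS = ("accuracy", "sensitivity", "specificity", "ppv", "npv", "f1")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricsReport:
    accuracy: float | None = None
    sensitivity: float | None = None
    specificity: float | None = None
    ppv: float | None = None
    npv: float | None = None
    f1: float | None = None
    auc: float | None = None
    aupr: float | None = None

    @property
    def score(self) -> float | None:
        """Sum of the six ratio metrics (fractions); None if any is NA."""
        vals = [getattr(self, m) for m in RATIO_METRICS]
        if any(v is None for v in vals):
            return None
        return float(sum(vals))

    def as_dict(self, percent: bool = False) -> dict:
        out = {}
        for f in fields(self):
            v = getattr(self, f.name)
            if v is not None and percent and f.name in RATIO_METRICS:
                v = float(percent_display(v))
            out[f.name] = v
        out["score"] = self.score
        return out


def confusion(labels: Sequence[int], probs: Sequence[float],
              threshold: float = 0.5) -> ConfusionCounts:
    """Count TP/FP/TN/FN; a probability >= threshold predicts positive."""
    labels = np.asarray(labels)
    probs = np.asarray(probs, dtype=float)
    if labels.shape != probs.shape or labels.size == 0:
        raise ValueError("labels and probs must be equal-length and nonempty")
    pred = probs >= threshold
    pos = labels == 1
    return ConfusionCounts(
        tp=int(np.sum(pred & pos)),
        fp=int(np.sum(pred & ~pos)),
        tn=int(np.sum(~pred & ~pos)),
        fn=int(np.sum(~pred & pos)),
    )


def _ratio(num: int, den: int) -> float | None:
    return None if den == 0 else num / den


def compute_metrics(c: ConfusionCounts) -> MetricsReport:
    """The six ratio metrics from confusion counts."""
    return MetricsReport(
        accuracy=_ratio(c.tp + c.tn, c.total),
        sensitivity=_ratio(c.tp, c.tp + c.fn),
        specificity=_ratio(c.tn, c.tn + c.fp),
        ppv=_ratio(c.tp, c.tp + c.fp),
        npv=_ratio(c.tn, c.tn + c.fn),
        f1=_ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn),
    )


def curve_metrics(labels: Sequence[int], probs: Sequence[float]
                  ) -> tuple[float | None, float | None]:
    """(AUC, AUPR); None when only one class is present."""
    labels = np.asarray(labels)
    if len(set(labels.tolist())) < 2:
        return None, None
    return (float(roc_auc_score(labels, probs)),
            float(average_precision_score(labels, probs)))


def evaluate(labels: Sequence[int], probs: Sequence[float],
             threshold: float = 0.5) -> MetricsReport:
    """Full report: confusion-matrix metrics plus ROC/PR areas."""
    report = compute_metrics(confusion(labels, probs, threshold))
    auc, aupr = curve_metrics(labels, probs)
    return MetricsReport(**{**{m: getattr(report, m) for m in RATIO_METRICS},
                            "auc": auc, "aupr": aupr})


def average_reports(reports: Sequence[MetricsReport]) -> MetricsReport:
    """Unweighted arithmetic mean per metric across test-set reports.

    A metric is averaged only if defined in every report; otherwise None.
    """
    if not reports:
        raise ValueError("no reports to average")
    values = {}
    for f in fields(MetricsReport):
        vals = [getattr(r, f.name) for r in reports]
        values[f.name] = None if any(v is None for v in vals) else float(np.mean(vals))
    return MetricsReport(**values)


def percent_display(fraction: float, places: int = 2) -> Decimal:
    """Half-up rounding of a fraction to a printed percentage."""
    return Decimal(fraction * 100).quantize(Decimal(10) ** -places, rounding=ROUND_HALF_UP)


def format_report(report: MetricsReport) -> str:
    parts = []
    for m in RATIO_METRICS:
        v = getattr(report, m)
        parts.append(f"{m}={percent_display(v)}%" if v is not None else f"{m}=NA")
    for m in ("auc", "aupr"):
        v = getattr(report, m)
        parts.append(f"{m}={v:.4f}" if v is not None else f"{m}=NA")
    s = report.score
    parts.append(f"score={s:.4f}" if s is not None else "score=NA")
    return "  ".join(parts)


def write_report(report: MetricsReport, path: str | Path, fmt: str = "tsv",
                 header_lines: Sequence[str] = ()) -> None:
    path = Path(path)
    d = report.as_dict(percent=True)
    if fmt == "json":
        path.write_text(json.dumps(d, indent=2) + "\n")
        return
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        keys = list(d)
        fh.write("\t".join(keys) + "\n")
        fh.write("\t".join("NA" if d[k] is None else f"{d[k]:.4f}" for k in keys) + "\n")
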