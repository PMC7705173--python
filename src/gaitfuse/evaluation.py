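"""Decision-stream scoring: accuracy, per-class recall/precision/F1, confusion.

"Sample-by-sample" metrics are computed over the decision windows (the
100 Hz prediction stream), which is where predictions exist. Per-class recall
doubles as the recognition rate of each gait phase. Macro averages are
unweighted means over classes present in the ground truth (the common
convention for imbalanced gait classes); frequency-weighted averages are
available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fusion import ConfusionMatrix, estimate_confusion

__all__ = ["MetricsReport", "score", "compare_conditions", "metrics_from_confusion"]


@dataclass
class MetricsReport:
    accuracy: float
    recall: dict[str, float]
    precision: dict[str, float]
    f1: dict[str, float]
    support: dict[str, int]
    macro_recall: float
    macro_precision: float
    macro_f1: float
    confusion: ConfusionMatrix
    n_windows: int
    classes: tuple[str, ...]
    chance_level: float
    average: str = "macro"
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "recall": self.recall,
            "precision": self.precision,
            "f1": self.f1,
            "support": self.support,
            "macro_recall": self.macro_recall,
            "macro_precision": self.macro_precision,
            "macro_f1": self.macro_f1,
            "confusion_counts": self.confusion.counts.tolist(),
            "n_windows": self.n_windows,
            "classes": list(self.classes),
            "chance_level": self.chance_level,
            "average": self.average,
        }


def metrics_from_confusion(cm: ConfusionMatrix, average: str = "macro") -> MetricsReport:
    """All scalar metrics recomputed from a confusion matrix."""
    counts = cm.counts.astype(np.float64)
    n = counts.sum()
    if n == 0:
        raise ValueError("cannot score an empty label sequence")
    row_sums = counts.sum(axis=1)   # per-class true counts
    col_sums = counts.sum(axis=0)   # per-class predicted counts
    diag = np.diag(counts)
    with np.errstate(invalid="ignore", divide="ignore"):
        rec = np.where(row_sums > 0, diag / row_sums, np.nan)
        prec = np.where(col_sums > 0, diag / col_sums, np.nan)
        f1 = np.where(
            np.nan_to_num(rec + prec) > 0, 2 * rec * prec / (rec + prec), np.nan
        )
    # absent classes (no true samples) stay NaN and are excluded from macro means
    present = row_sums > 0
    if average == "macro":
        mrec = float(np.nanmean(rec[present]))
        mprec = float(np.nanmean(prec[present]))
        mf1 = float(np.nanmean(f1[present]))
    elif average == "weighted":
        w = row_sums[present] / row_sums[present].sum()
        mrec = float(np.nansum(rec[present] * w))
        mprec = float(np.nansum(prec[present] * w))
        mf1 = float(np.nansum(f1[present] * w))
    else:
        raise ValueError("average must be 'macro' or 'weighted'")
    classes = cm.classes
    return MetricsReport(
        accuracy=float(diag.sum() / n),
        recall={c: float(rec[i]) for i, c in enumerate(classes)},
        precision={c: float(prec[i]) for i, c in enumerate(classes)},
        f1={c: float(f1[i]) for i, c in enumerate(classes)},
        support={c: int(row_sums[i]) for i, c in enumerate(classes)},
        macro_recall=mrec, macro_precision=mprec, macro_f1=mf1,
        confusion=cm, n_windows=int(n), classes=classes,
        chance_level=1.0 / len(classes), average=average,
    )


def score(true_labels, predicted_labels, classes: tuple[str, ...],
          average: str = "macro") -> MetricsReport:
    """Score an aligned pair of label-code sequences over a class set."""
    t = np.asarray(true_labels)
    if t.size == 0:
        raise ValueError("cannot score an empty label sequence")
    cm = estimate_confusion(t, predicted_labels, classes)
    return metrics_from_confusion(cm, average=average)


def compare_conditions(
    reports: dict[tuple[str, str, object], MetricsReport]
) -> pd.DataFrame:
    """Long-format table over (decoder, regime, level) condition grids.

    ``reports`` maps ``(decoder, regime, level)`` to a MetricsReport. All
    reports sharing a (regime, class-set) pair must describe the same test
    windows. Rows: decoder, regime, level, metric, value — with per-class
    recognition rates (recall) as ``recall_<CLASS>`` entries.
    """
    sizes: dict[tuple[str, int], int] = {}
    rows = []
    for (decoder, regime, level), rep in reports.items():
        key = (regime, len(rep.classes))
        if key in sizes and sizes[key] != rep.n_windows:
            raise ValueError("conditions within a regime must share the same test windows")
        sizes[key] = rep.n_windows
        base = {"decoder": decoder, "regime": regime, "level": level}
        rows.append({**base, "metric": "accuracy", "value": rep.accuracy})
        rows.append({**base, "metric": "macro_recall", "value": rep.macro_recall})
        rows.append({**base, "metric": "macro_precision", "value": rep.macro_precision})
        rows.append({**base, "metric": "macro_f1", "value": rep.macro_f1})
        for c in rep.classes:
            rows.append({**base, "metric": f"recall_{c}", "value": rep.recall[c]})
    return pd.DataFrame(rows, columns=["decoder", "regime", "level", "metric", "value"])
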