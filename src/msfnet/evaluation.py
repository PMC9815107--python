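"""Confusion matrix and classification metrics.

Convention (fixed in every output): **rows are true classes, columns are
predicted classes**; the diagonal counts correct predictions and the trace
over the total is the overall accuracy.  Per class ``c``:

* precision = TP / (TP + FP)
* recall    = TP / (TP + FN)
* one-vs-rest accuracy = (TP + TN) / total

A zero denominator yields 0 together with an ``undefined`` flag rather than
NaN.  Internally all metrics are fractions; multiply by 100 for display.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import ValidationError


@dataclass(frozen=True)
class ConfusionMatrix:
    counts: np.ndarray                   # (K, K) int, rows=true, cols=predicted
    classes: Tuple[str, ...]

    def __post_init__(self):
        c = np.asarray(self.counts)
        if c.ndim != 2 or c.shape[0] != c.shape[1] or c.shape[0] < 1:
            raise ValidationError(f"counts must be square K×K, got {c.shape}")
        if np.any(c < 0):
            raise ValidationError("counts must be nonnegative")
        if c.sum() < 1:
            raise ValidationError("confusion matrix is empty")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.counts) / self.total)

    def per_class(self, c: int) -> Tuple[int, int, int, int]:
        """(TP, FP, FN, TN) for class index ``c``."""
        tp = int(self.counts[c, c])
        fp = int(self.counts[:, c].sum() - tp)
        fn = int(self.counts[c, :].sum() - tp)
        tn = self.total - tp - fp - fn
        return tp, fp, fn, tn

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.classes), columns=list(self.classes))

    def to_csv(self, path: str) -> None:
        self.to_frame().to_csv(path, index_label="true\\predicted")

    def plot(self, path: Optional[str] = None, normalize: bool = False):
        """Render the matrix as a heatmap (row-normalized when asked)."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        m = self.counts.astype(float)
        if normalize:
            rows = m.sum(axis=1, keepdims=True)
            m = np.divide(m, rows, out=np.zeros_like(m), where=rows > 0)
        fig, ax = plt.subplots(figsize=(1.2 * len(self.classes) + 2,) * 2)
        im = ax.imshow(m, cmap="Blues")
        ax.set_xticks(range(len(self.classes)), self.classes, rotation=45, ha="right")
        ax.set_yticks(range(len(self.classes)), self.classes)
        ax.set_xlabel("predicted class")
        ax.set_ylabel("true class")
        for i in range(len(self.classes)):
            for j in range(len(self.classes)):
                val = f"{m[i, j]:.2f}" if normalize else f"{int(m[i, j])}"
                ax.text(j, i, val, ha="center", va="center", fontsize=8)
        fig.colorbar(im, ax=ax, shrink=0.8)
        fig.tight_layout()
        if path:
            fig.savefig(path, dpi=120)
            plt.close(fig)
            return None
        return fig


def confusion_matrix(
    y_true: Sequence[int],
    y_pred: Sequence[int],
    classes: Sequence[str],
) -> ConfusionMatrix:
    """Count matrix with counts[i, j] = #{true == i and predicted == j}."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape or y_true.ndim != 1:
        raise ValidationError("label vectors must be 1-D and of equal length")
    k = len(classes)
    if y_true.size and (y_true.min() < 0 or y_true.max() >= k):
        raise ValidationError(f"true labels out of range [0, {k})")
    if y_pred.size and (y_pred.min() < 0 or y_pred.max() >= k):
        raise ValidationError(f"predicted labels out of range [0, {k})")
    counts = np.zeros((k, k), dtype=int)
    np.add.at(counts, (y_true, y_pred), 1)
    return ConfusionMatrix(counts, tuple(classes))


def metrics(cm: ConfusionMatrix) -> pd.DataFrame:
    """Per-class precision/recall/one-vs-rest accuracy plus an overall row.

    Columns: class, precision, recall, ovr_accuracy, support, undefined
    (True where a zero denominator forced the 0 sentinel).  The final row
    ("overall") carries the overall accuracy in every rate column.
    """
    rows = []
    for c, name in enumerate(cm.classes):
        tp, fp, fn, tn = cm.per_class(c)
        undefined = False

        def rate(num: int, den: int) -> float:
            nonlocal undefined
            if den == 0:
                undefined = True
                return 0.0
            return num / den

        rows.append(
            dict(
                label=name,
                precision=rate(tp, tp + fp),
                recall=rate(tp, tp + fn),
                ovr_accuracy=(tp + tn) / cm.total,
                support=tp + fn,
                undefined=undefined,
            )
        )
    rows.append(
        dict(
            label="overall",
            precision=cm.accuracy,
            recall=cm.accuracy,
            ovr_accuracy=cm.accuracy,
            support=cm.total,
            undefined=False,
        )
    )
    return pd.DataFrame(rows)


def micro_average(cm: ConfusionMatrix) -> Tuple[float, float]:
    """(micro-precision, micro-recall) — both equal accuracy for single-label
    multiclass data, a useful internal consistency check."""
    tps = fps = fns = 0
    for c in range(len(cm.classes)):
        tp, fp, fn, _ = cm.per_class(c)
        tps, fps, fns = tps + tp, fps + fp, fns + fn
    return tps / (tps + fps), tps / (tps + fns)
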