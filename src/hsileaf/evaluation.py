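"""Confusion matrices and the four classification metrics.

Overall accuracy, macro-averaged precision, macro F1, and Cohen's kappa
(chance-corrected agreement, (p_o - p_e) / (1 - p_e) with the expected
agreement p_e from the row x column marginals).  "Precision" is
macro-averaged by default, consistent with macro F1; micro averaging is
available via ``metrics(cm, average="micro")``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)


@dataclass
class ConfusionMatrix:
    """C x C counts; rows are truth, columns are prediction."""

    counts: np.ndarray
    class_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("counts must be square")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def row_normalized(self) -> np.ndarray:
        """Rows sum to 1: per-class recall / omission structure."""
        s = self.counts.sum(axis=1, keepdims=True)
        return np.divide(self.counts, s, out=np.zeros_like(self.counts, float),
                         where=s > 0)

    def col_normalized(self) -> np.ndarray:
        """Columns sum to 1: per-class precision / commission structure."""
        s = self.counts.sum(axis=0, keepdims=True)
        return np.divide(self.counts, s, out=np.zeros_like(self.counts, float),
                         where=s > 0)

    def to_csv(self, path) -> None:
        import pandas as pd

        names = self.class_names or [str(i) for i in range(len(self.counts))]
        pd.DataFrame(self.counts, index=names, columns=names).to_csv(path)


def confusion(
    truth, pred, n_classes: int, class_names: list[str] | None = None
) -> ConfusionMatrix:
    """Tally a confusion matrix from parallel label sequences."""
    t = np.asarray(truth, dtype=int)
    p = np.asarray(pred, dtype=int)
    if t.shape != p.shape or t.ndim != 1:
        raise ValueError("truth and pred must be equal-length 1-D sequences")
    if len(t) and (t.min() < 0 or p.min() < 0 or
                   t.max() >= n_classes or p.max() >= n_classes):
        raise ValueError(f"labels must lie in [0, {n_classes})")
    counts = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(counts, (t, p), 1)
    return ConfusionMatrix(counts, class_names)


@dataclass
class EvalReport:
    """OA, macro precision, macro F1, kappa, and per-class TPRs."""

    oa: float
    macro_precision: float
    macro_f1: float
    kappa: float
    per_class_tpr: np.ndarray = field(default_factory=lambda: np.array([]))

    def to_json_dict(self) -> dict:
        return {
            "oa": self.oa,
            "macro_precision": self.macro_precision,
            "macro_f1": self.macro_f1,
            "kappa": self.kappa,
            "per_class_tpr": [round(float(x), 4) for x in self.per_class_tpr],
        }


def metrics(cm: ConfusionMatrix, average: str = "macro") -> EvalReport:
    """Compute the evaluation report from a confusion matrix.

    Per-class precision for an empty prediction column is 0 (logged);
    F1 for a class with zero precision + recall is 0.  Kappa for the
    degenerate p_e = 1 case (all mass in one truth/prediction pair) is
    defined as 0.
    """
    c = cm.counts.astype(np.float64)
    total = c.sum()
    if total <= 0:
        raise ValueError("empty confusion matrix")
    diag = np.diag(c)
    row = c.sum(axis=1)
    col = c.sum(axis=0)

    oa = float(diag.sum() / total)
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(col > 0, diag / np.maximum(col, 1e-300), 0.0)
        recall = np.where(row > 0, diag / np.maximum(row, 1e-300), 0.0)
    if (col == 0).any():
        logger.info("classes never predicted: %s", np.flatnonzero(col == 0))
    pr = precision + recall
    f1 = np.where(pr > 0, 2 * precision * recall / np.maximum(pr, 1e-300), 0.0)

    if average == "micro":
        macro_precision = oa  # micro precision == OA for single-label tasks
    elif average == "macro":
        macro_precision = float(precision.mean())
    else:
        raise ValueError(f"unknown average '{average}'")

    p_o = oa
    p_e = float((row * col).sum() / total**2)
    if p_e >= 1.0 - 1e-15:
        logger.info("degenerate marginals (p_e = 1); kappa set to 0")
        kappa = 0.0
    else:
        kappa = (p_o - p_e) / (1.0 - p_e)
    tpr = np.where(row > 0, diag / np.maximum(row, 1e-300), 0.0)
    return EvalReport(oa, macro_precision, float(f1.mean()), float(kappa), tpr)
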