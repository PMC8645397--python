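"""Detection and segmentation metrics against ground truth.

Confusion-matrix statistics (sensitivity, specificity, accuracy), the
Dice overlap coefficient, and ROC/AUC are computed voxelwise against
ground-truth binary masks.  Undefined quantities (empty denominators,
two empty masks) are reported explicitly as ``None`` rather than being
silently replaced with 0, which would corrupt comparisons.

The ROC is built over all distinct score thresholds in descending order;
ties are grouped so that the trapezoidal AUC equals the Mann-Whitney
statistic Pr(score+ > score-) + 0.5 * Pr(equal).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import KurticaError, ShapeMismatchError
from .preprocess import Mask3D

__all__ = [
    "ConfusionCounts",
    "ROCResult",
    "confusion_metrics",
    "dice",
    "roc_auc",
    "compare_runs",
]


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class ROCResult:
    thresholds: np.ndarray  # descending
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def _as_bool(m) -> np.ndarray:
    if isinstance(m, Mask3D):
        return m.data
    return np.asarray(m).astype(bool)


def confusion_metrics(
    pred, truth
) -> tuple[ConfusionCounts, float | None, float | None, float | None]:
    """Voxelwise confusion counts and (sensitivity, specificity, accuracy).

    sensitivity = tp / (tp + fn); specificity = tn / (tn + fp);
    accuracy = (tp + tn) / total.  A metric with an empty denominator is
    returned as ``None`` (undefined).
    """
    p, t = _as_bool(pred), _as_bool(truth)
    if p.shape != t.shape:
        raise ShapeMismatchError(f"shape mismatch: pred {p.shape} vs truth {t.shape}")
    tp = int(np.sum(p & t))
    fp = int(np.sum(p & ~t))
    fn = int(np.sum(~p & t))
    tn = int(np.sum(~p & ~t))
    counts = ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)
    sens = tp / (tp + fn) if (tp + fn) > 0 else None
    spec = tn / (tn + fp) if (tn + fp) > 0 else None
    acc = (tp + tn) / counts.total if counts.total > 0 else None
    return counts, sens, spec, acc


def dice(pred, truth) -> float | None:
    """Dice overlap 2|A ∩ B| / (|A| + |B|); ``None`` when both masks are empty."""
    p, t = _as_bool(pred), _as_bool(truth)
    if p.shape != t.shape:
        raise ShapeMismatchError(f"shape mismatch: pred {p.shape} vs truth {t.shape}")
    denom = int(p.sum()) + int(t.sum())
    if denom == 0:
        return None
    return 2.0 * int(np.sum(p & t)) / denom


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> ROCResult:
    """ROC curve over all distinct thresholds and trapezoidal AUC.

    Equal scores are grouped into a single operating point, which makes
    the trapezoidal area identical to the tie-corrected Mann-Whitney
    probability that a random positive outscores a random negative.
    """
    scores = np.asarray(scores, dtype=np.float64).ravel()
    labels = np.asarray(labels).ravel().astype(bool)
    if scores.shape != labels.shape:
        raise ShapeMismatchError("scores and labels must have equal length")
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise KurticaError("roc_auc requires both classes present")
    order = np.argsort(-scores, kind="stable")
    s_sorted, l_sorted = scores[order], labels[order]
    # collapse runs of equal scores into single operating points
    distinct = np.nonzero(np.diff(s_sorted))[0]  # last index of each run but the final
    cut = np.concatenate([distinct, [s_sorted.size - 1]])
    cum_tp = np.cumsum(l_sorted)[cut]
    cum_fp = np.cumsum(~l_sorted)[cut]
    tpr = np.concatenate([[0.0], cum_tp / n_pos])
    fpr = np.concatenate([[0.0], cum_fp / n_neg])
    thresholds = np.concatenate([[np.inf], s_sorted[cut]])
    auc = float(np.trapezoid(tpr, fpr))
    return ROCResult(thresholds=thresholds, fpr=fpr, tpr=tpr, auc=auc)


def compare_runs(run_a: dict, run_b: dict) -> pd.DataFrame:
    """Side-by-side metric table: metric, value_a, value_b, difference."""
    if not run_a or not run_b:
        raise KurticaError("metric bundles must be non-empty")
    missing_a = sorted(set(run_b) - set(run_a))
    missing_b = sorted(set(run_a) - set(run_b))
    if missing_a or missing_b:
        raise KurticaError(
            f"metric keys differ; missing from a: {missing_a}; missing from b: {missing_b}"
        )
    keys = sorted(run_a)
    rows = []
    for k in keys:
        va, vb = run_a[k], run_b[k]
        diff = (va - vb) if (va is not None and vb is not None) else None
        rows.append({"metric": k, "value_a": va, "value_b": vb, "difference": diff})
    return pd.DataFrame(rows)
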