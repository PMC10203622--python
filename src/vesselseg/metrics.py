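"""Pixel-level segmentation metrics: confusion counts, SE/SP/ACC/F1, ROC/AUC.

Definitions (per-pixel, at a stated threshold):

    SE  = TP / (TP + FN)          SP  = TN / (TN + FP)
    ACC = (TP + TN) / total       F1  = 2 TP / (2 TP + FP + FN)

AUC is the area under the ROC curve traced by sweeping the threshold,
equal to the normalised Mann-Whitney U statistic.  When a field-of-view
mask is supplied, pixels outside it are excluded from all counts.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from sklearn import metrics as skmetrics

__all__ = ["MetricsReport", "confusion_metrics", "roc_auc", "pooled_metrics", "plot_roc"]


@dataclass
class MetricsReport:
    tp: int
    fp: int
    fn: int
    tn: int
    se: float
    sp: float
    acc: float
    f1: float
    auc: float
    threshold: float

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def _flatten(pred, mask, fov):
    pred = np.asarray(pred, dtype=np.float64).ravel()
    mask = np.asarray(mask).ravel()
    if pred.shape != mask.shape:
        raise ValueError("pred and mask must have the same number of pixels")
    if fov is not None:
        fov = np.asarray(fov).ravel().astype(bool)
        if fov.shape != mask.shape:
            raise ValueError("fov shape must match mask")
        pred, mask = pred[fov], mask[fov]
    if pred.size == 0:
        raise ValueError("empty evaluation region")
    return pred, mask.astype(np.int64)


def _ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator); returning NaN", RuntimeWarning)
        return float("nan")
    return num / den


def confusion_metrics(
    pred,
    mask,
    threshold: float = 0.5,
    fov=None,
    auc: bool = True,
) -> MetricsReport:
    """Threshold a probability map and score it against a binary mask.

    Pixels with ``pred >= threshold`` count as vessel.  ``auc=False`` skips
    the ROC computation (useful for single-class degenerate inputs).
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must be in (0, 1)")
    p, y = _flatten(pred, mask, fov)
    pos = p >= threshold
    tp = int(np.sum(pos & (y == 1)))
    fp = int(np.sum(pos & (y == 0)))
    fn = int(np.sum(~pos & (y == 1)))
    tn = int(np.sum(~pos & (y == 0)))
    auc_val = float("nan")
    if auc and y.min() != y.max():
        auc_val = float(skmetrics.roc_auc_score(y, p))
    elif auc:
        warnings.warn("AUC undefined for single-class ground truth; returning NaN", RuntimeWarning)
    return MetricsReport(
        tp=tp,
        fp=fp,
        fn=fn,
        tn=tn,
        se=_ratio(tp, tp + fn, "SE"),
        sp=_ratio(tn, tn + fp, "SP"),
        acc=_ratio(tp + tn, tp + fp + fn + tn, "ACC"),
        f1=_ratio(2 * tp, 2 * tp + fp + fn, "F1"),
        auc=auc_val,
        threshold=threshold,
    )


def roc_auc(pred, mask, fov=None) -> tuple[np.ndarray, float]:
    """ROC curve (as an array of (fpr, tpr) rows) and its area."""
    p, y = _flatten(pred, mask, fov)
    if y.min() == y.max():
        raise ValueError("ROC requires both classes in the ground truth")
    fpr, tpr, _ = skmetrics.roc_curve(y, p)
    return np.column_stack([fpr, tpr]), float(skmetrics.auc(fpr, tpr))


def pooled_metrics(
    preds: list,
    masks: list,
    threshold: float = 0.5,
    fovs: list | None = None,
) -> MetricsReport:
    """Dataset-level metrics: pool all pixels across images, then score once."""
    if fovs is None:
        fovs = [None] * len(preds)
    parts = [_flatten(p, m, f) for p, m, f in zip(preds, masks, fovs)]
    pred = np.concatenate([p for p, _ in parts])
    mask = np.concatenate([y for _, y in parts])
    return confusion_metrics(pred, mask, threshold=threshold)


def plot_roc(curve: np.ndarray, auc_value: float, path: str | Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(curve[:, 0], curve[:, 1], label=f"AUC = {auc_value:.4f}")
    ax.plot([0, 1], [0, 1], "k--", linewidth=0.8)
    ax.set_xlabel("False positive rate")
    ax.set_ylabel("True positive rate")
    ax.legend(loc="lower right")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
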