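"""Evaluation panel for imbalanced binary methylation prediction.

Threshold metrics (ACC, F1, MCC, TNR, TPR) are computed from the confusion
matrix at the strict > 0.5 rule (a probability of exactly 0.5 predicts
unmethylated).  AUC is the Mann-Whitney probability of correct ranking (ties
counted one half); PRC is average precision (step-wise, no trapezoid
interpolation) — the conservative, imbalance-robust pairing for a dataset
where methylated sites are the ~1:9 minority.

Zero-denominator conventions: F1 = 0 when precision + recall = 0; MCC = 0
when any confusion-matrix marginal is 0; AUC/PRC are NaN (with a warning)
when only one class is present.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

__all__ = ["MetricsReport", "confusion", "metrics"]

DEFAULT_THRESHOLD = 0.5


@dataclass
class MetricsReport:
    acc: float
    auc: float
    prc: float
    f1: float
    mcc: float
    tnr: float
    tpr: float
    tp: int
    fp: int
    tn: int
    fn: int
    n: int
    threshold: float = DEFAULT_THRESHOLD

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    def __str__(self) -> str:
        return ("ACC={acc:.4f} AUC={auc:.4f} PRC={prc:.4f} F1={f1:.4f} "
                "MCC={mcc:.4f} TNR={tnr:.4f} TPR={tpr:.4f} (n={n})"
                ).format(**self.to_dict())


def _validate(labels, probs):
    labels = np.asarray(labels, dtype=np.float64).ravel()
    probs = np.asarray(probs, dtype=np.float64).ravel()
    if labels.shape != probs.shape:
        raise ValueError(f"labels ({labels.shape}) and probabilities "
                         f"({probs.shape}) differ in length")
    if not np.isin(labels, [0.0, 1.0]).all():
        raise ValueError("labels must be binary (0/1)")
    if np.isnan(probs).any():
        raise ValueError("probabilities contain NaN")
    return labels, probs


def confusion(labels, probs, threshold: float = DEFAULT_THRESHOLD):
    """Confusion counts (tp, fp, tn, fn) under prediction = prob > threshold."""
    labels, probs = _validate(labels, probs)
    pred = probs > threshold
    pos = labels == 1.0
    tp = int(np.sum(pred & pos))
    fp = int(np.sum(pred & ~pos))
    tn = int(np.sum(~pred & ~pos))
    fn = int(np.sum(~pred & pos))
    return tp, fp, tn, fn


def metrics(labels, probs, threshold: float = DEFAULT_THRESHOLD) -> MetricsReport:
    """Full metric panel: ACC, AUC, PRC, F1, MCC, TNR, TPR + counts."""
    labels, probs = _validate(labels, probs)
    tp, fp, tn, fn = confusion(labels, probs, threshold)
    n = tp + fp + tn + fn
    if n == 0:
        raise ValueError("empty input")
    acc = (tp + tn) / n
    tpr = tp / (tp + fn) if tp + fn else 0.0
    tnr = tn / (tn + fp) if tn + fp else 0.0
    precision = tp / (tp + fp) if tp + fp else 0.0
    f1 = (2 * precision * tpr / (precision + tpr)) if precision + tpr else 0.0
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = ((tp * tn - fp * fn) / np.sqrt(denom)) if denom else 0.0
    if len(np.unique(labels)) < 2:
        warnings.warn("only one class present; AUC and PRC are undefined")
        auc = prc = float("nan")
    else:
        auc = float(roc_auc_score(labels, probs))
        prc = float(average_precision_score(labels, probs))
    return MetricsReport(acc=acc, auc=auc, prc=prc, f1=float(f1),
                         mcc=float(mcc), tnr=tnr, tpr=tpr,
                         tp=tp, fp=fp, tn=tn, fn=fn, n=n,
                         threshold=threshold)
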