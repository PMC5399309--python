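"""Binary-classifier performance metrics.

The ten-metric suite used to validate segment-level CSB classification:
sensitivity (TPR), specificity (TNR), PPV, NPV, balanced accuracy
(BAC = (TPR+TNR)/2), ROC-AUC, FNR, FPR, mean misclassification error
(MMCE = (FP+FN)/total) and balanced error rate (BER = (FNR+FPR)/2), plus
Cohen's chance-corrected kappa with a large-sample Wald interval.

Metrics with a zero denominator are reported as ``None`` (absent), never
coerced to 0.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
from scipy import stats
from sklearn.metrics import roc_auc_score

__all__ = ["ConfusionMatrix", "MetricSet", "confusion_metrics", "cohens_kappa", "roc_auc"]


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 counts: rows truth, columns prediction (tp = true positive)."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self):
        for f in fields(self):
            v = getattr(self, f.name)
            if v < 0 or v != int(v):
                raise ValueError(f"{f.name} must be a non-negative integer")
        if self.total < 1:
            raise ValueError("confusion matrix must contain at least one observation")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    @classmethod
    def from_labels(cls, y_true, y_pred) -> "ConfusionMatrix":
        y_true = np.asarray(y_true, dtype=bool)
        y_pred = np.asarray(y_pred, dtype=bool)
        if y_true.shape != y_pred.shape:
            raise ValueError("y_true and y_pred must have equal length")
        return cls(
            tp=int(np.sum(y_true & y_pred)),
            fn=int(np.sum(y_true & ~y_pred)),
            fp=int(np.sum(~y_true & y_pred)),
            tn=int(np.sum(~y_true & ~y_pred)),
        )


@dataclass(frozen=True)
class MetricSet:
    """The performance suite; absent (undefined) entries are ``None``."""

    tpr: float | None
    tnr: float | None
    ppv: float | None
    npv: float | None
    bac: float | None
    fnr: float | None
    fpr: float | None
    mmce: float | None
    ber: float | None
    auc: float | None = None
    kappa: float | None = None
    kappa_ci: tuple[float, float] | None = None

    def as_dict(self) -> dict:
        d = {f.name: getattr(self, f.name) for f in fields(self)}
        if d["kappa_ci"] is not None:
            d["kappa_ci"] = list(d["kappa_ci"])
        return d


def _ratio(num: int, den: int) -> float | None:
    return num / den if den > 0 else None


def confusion_metrics(m: ConfusionMatrix, auc: float | None = None) -> MetricSet:
    """Compute the metric suite from 2x2 counts.

    ``auc`` may be supplied (from :func:`roc_auc` on scores) since it is
    not a function of the thresholded counts.  Kappa is attached via
    :func:`cohens_kappa` by callers that want it.
    """
    tpr = _ratio(m.tp, m.tp + m.fn)
    tnr = _ratio(m.tn, m.tn + m.fp)
    ppv = _ratio(m.tp, m.tp + m.fp)
    npv = _ratio(m.tn, m.tn + m.fn)
    fnr = None if tpr is None else 1.0 - tpr
    fpr = None if tnr is None else 1.0 - tnr
    bac = None if (tpr is None or tnr is None) else (tpr + tnr) / 2.0
    ber = None if (fnr is None or fpr is None) else (fnr + fpr) / 2.0
    mmce = (m.fp + m.fn) / m.total
    return MetricSet(
        tpr=tpr, tnr=tnr, ppv=ppv, npv=npv, bac=bac,
        fnr=fnr, fpr=fpr, mmce=mmce, ber=ber, auc=auc,
    )


def cohens_kappa(
    m: ConfusionMatrix, ci_level: float = 0.95
) -> tuple[float | None, tuple[float, float] | None]:
    """Chance-corrected agreement between predicted and true labels.

    kappa = (p_o - p_e) / (1 - p_e) with observed agreement
    p_o = (tp+tn)/n and expected agreement p_e from the marginal products.
    The confidence interval uses the classical large-sample standard error
    sqrt(p_o (1-p_o) / (n (1-p_e)^2)) with normal quantiles.  Degenerate
    marginals (p_e = 1) make kappa undefined -> ``(None, None)``.
    """
    n = m.total
    po = (m.tp + m.tn) / n
    pe = ((m.tp + m.fn) * (m.tp + m.fp) + (m.fp + m.tn) * (m.fn + m.tn)) / n**2
    if abs(1.0 - pe) < 1e-12:
        return None, None
    kappa = (po - pe) / (1.0 - pe)
    se = np.sqrt(po * (1.0 - po) / (n * (1.0 - pe) ** 2))
    z = stats.norm.ppf(0.5 + ci_level / 2.0)
    return float(kappa), (float(kappa - z * se), float(kappa + z * se))


def roc_auc(scores, labels) -> float | None:
    """Rank-based (Mann-Whitney) area under the ROC curve; ties count 1/2.

    Returns ``None`` when only one class is present.
    """
    labels = np.asarray(labels, dtype=bool)
    scores = np.asarray(scores, dtype=float)
    if labels.all() or (~labels).all():
        return None
    return float(roc_auc_score(labels, scores))
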