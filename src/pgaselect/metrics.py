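"""Confusion matrices and the six screening-test metrics.

Reported metrics are sensitivity, specificity, positive/negative percent
agreement (PPA = tp/(tp+fp), NPA = tn/(tn+fn), i.e. predictive-value-style
agreement with the reference eFI classification), accuracy, and F1 (harmonic
mean of PPA and sensitivity).  All are reported on the percentage scale.

The positive class is an explicit parameter: swapping it exchanges
sensitivity with specificity and PPA with NPA, which lets users reproduce
either class convention for the agreement columns.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricsReport:
    """Six metrics on the 0–100 scale; NaN marks an undefined metric."""

    sensitivity: float
    specificity: float
    ppa: float
    npa: float
    accuracy: float
    f1: float
    positive_class: int = 1

    def as_dict(self) -> dict[str, float]:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppa": self.ppa,
            "npa": self.npa,
            "accuracy": self.accuracy,
            "f1": self.f1,
        }

    def rounded(self, ndigits: int = 1) -> dict[str, float]:
        return {k: round(v, ndigits) for k, v in self.as_dict().items()}


def confusion(y_true, y_pred, positive_class: int = 1) -> ConfusionMatrix:
    """Tally the confusion matrix of two equal-length 0/1 vectors."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape or y_true.ndim != 1:
        raise ValueError(
            f"y_true and y_pred must be 1-D and equal length, got {y_true.shape} vs {y_pred.shape}"
        )
    for name, vec in (("y_true", y_true), ("y_pred", y_pred)):
        bad = set(np.unique(vec)) - {0, 1}
        if bad:
            raise ValueError(f"{name} must contain only 0/1, found {sorted(bad)}")
    pos_t = y_true == positive_class
    pos_p = y_pred == positive_class
    return ConfusionMatrix(
        tp=int(np.sum(pos_t & pos_p)),
        fp=int(np.sum(~pos_t & pos_p)),
        tn=int(np.sum(~pos_t & ~pos_p)),
        fn=int(np.sum(pos_t & ~pos_p)),
    )


def _ratio(num: int, den: int) -> float:
    return 100.0 * num / den if den > 0 else float("nan")


def compute_metrics(cm: ConfusionMatrix, positive_class: int = 1) -> MetricsReport:
    """Derive the six screening metrics from confusion counts.

    A metric whose denominator is empty (e.g. sensitivity with no actual
    positives) is reported as NaN, never as zero.
    """
    if cm.n == 0:
        raise ValueError("cannot compute metrics from an all-zero confusion matrix")
    sensitivity = _ratio(cm.tp, cm.tp + cm.fn)
    specificity = _ratio(cm.tn, cm.tn + cm.fp)
    ppa = _ratio(cm.tp, cm.tp + cm.fp)
    npa = _ratio(cm.tn, cm.tn + cm.fn)
    accuracy = _ratio(cm.tp + cm.tn, cm.n)
    if math.isnan(ppa) or math.isnan(sensitivity) or (ppa + sensitivity) == 0:
        f1 = float("nan")
    else:
        f1 = 2.0 * ppa * sensitivity / (ppa + sensitivity)
    return MetricsReport(
        sensitivity=sensitivity,
        specificity=specificity,
        ppa=ppa,
        npa=npa,
        accuracy=accuracy,
        f1=f1,
        positive_class=positive_class,
    )


def score_predictions(y_true, y_pred, positive_class: int = 1) -> MetricsReport:
    """Convenience: :func:`confusion` followed by :func:`compute_metrics`."""
    return compute_metrics(confusion(y_true, y_pred, positive_class), positive_class)


def fraction_score(y_true, y_pred, metric: str = "accuracy", positive_class: int = 1) -> float:
    """A single metric on the 0–1 scale, used as GA fold fitness."""
    report = score_predictions(y_true, y_pred, positive_class)
    value = getattr(report, metric)
    return 0.0 if math.isnan(value) else value / 100.0
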