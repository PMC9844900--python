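"""Scoring and calibration diagnostics.

Besides the standard classification scores (accuracy, cross-entropy,
weighted precision/recall/f1) this module provides the mean predicted
probability error ("proba-loss")

    delta_p = 1 - mean_i phat(y = y_true(x_i) | x_i),

computable whenever ground-truth labels are known, and binary reliability
diagnostics: a ten-bin calibration curve and the area between the curve and
the diagonal ("area-deviation", zero for perfect calibration).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import (
    accuracy_score,
    f1_score,
    log_loss,
    precision_score,
    recall_score,
)

__all__ = [
    "CalibrationReport",
    "proba_loss",
    "classification_scores",
    "calibration_curve",
    "area_deviation",
]

_LOGLOSS_EPS = 1e-15


@dataclass
class CalibrationReport:
    """Binned reliability curve of a binary probabilistic classifier.

    Only occupied bins carry curve points; ``mean_predicted`` and
    ``empirical_fraction`` are aligned with ``counts > 0`` bins.
    """

    bin_edges: np.ndarray
    mean_predicted: np.ndarray
    empirical_fraction: np.ndarray
    counts: np.ndarray

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "mean_predicted": self.mean_predicted,
            "empirical_fraction": self.empirical_fraction,
            "count": self.counts[self.counts > 0],
        })


def _align_probs(prob_vectors, true_labels, classes):
    P = np.asarray(prob_vectors, dtype=float)
    true_labels = list(true_labels)
    if P.shape[0] != len(true_labels):
        raise ValueError(
            f"{P.shape[0]} probability vectors for {len(true_labels)} labels"
        )
    index = {c: j for j, c in enumerate(classes)}
    missing = sorted({str(t) for t in true_labels if t not in index})
    if missing:
        raise ValueError(f"true labels {missing} not among classes {list(classes)}")
    cols = np.array([index[t] for t in true_labels])
    return P, cols


def proba_loss(prob_vectors, true_labels, classes=None) -> float:
    """Mean predicted probability error ``1 - mean p(true class)`` in [0, 1].

    ``classes`` gives the column order of ``prob_vectors``; defaults to the
    sorted unique true labels.
    """
    if classes is None:
        classes = sorted(set(true_labels))
    P, cols = _align_probs(prob_vectors, true_labels, classes)
    return float(1.0 - P[np.arange(len(cols)), cols].mean())


def classification_scores(pred_labels, prob_vectors, true_labels, classes=None) -> dict:
    """Accuracy, log-loss and weighted f1/precision/recall.

    Per-class precision, recall and f1 are averaged with weights given by
    the true class frequencies; log-loss clips probabilities at 1e-15.
    """
    if classes is None:
        classes = sorted(set(true_labels))
    pred_labels = list(pred_labels)
    true_labels = list(true_labels)
    if len(pred_labels) != len(true_labels):
        raise ValueError("pred_labels and true_labels differ in length")
    P, _ = _align_probs(prob_vectors, true_labels, classes)
    P = np.clip(P, _LOGLOSS_EPS, 1.0)
    P = P / P.sum(axis=1, keepdims=True)
    return {
        "accuracy": float(accuracy_score(true_labels, pred_labels)),
        "log_loss": float(log_loss(true_labels, P, labels=list(classes))),
        "f1": float(f1_score(true_labels, pred_labels, labels=list(classes),
                             average="weighted", zero_division=0)),
        "precision": float(precision_score(true_labels, pred_labels,
                                           labels=list(classes),
                                           average="weighted", zero_division=0)),
        "recall": float(recall_score(true_labels, pred_labels,
                                     labels=list(classes),
                                     average="weighted", zero_division=0)),
    }


def calibration_curve(prob_class1, true_binary, n_bins: int = 10) -> CalibrationReport:
    """Reliability curve: per-bin mean predicted probability of class 1
    versus the empirical class-1 fraction, over equal-width bins on [0, 1].
    """
    p = np.asarray(prob_class1, dtype=float)
    t = np.asarray(true_binary)
    if p.shape != t.shape or p.ndim != 1:
        raise ValueError("prob_class1 and true_binary must be equal-length 1-D")
    uniq = np.unique(t)
    if uniq.size > 2 or not np.all(np.isin(uniq, [0, 1])):
        raise ValueError("true_binary must contain only 0/1 indicators")
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    # right-closed last bin so p = 1 lands in bin n_bins - 1
    idx = np.minimum(np.digitize(p, edges[1:-1]), n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    occupied = counts > 0
    sums_p = np.bincount(idx, weights=p, minlength=n_bins)
    sums_t = np.bincount(idx, weights=t.astype(float), minlength=n_bins)
    return CalibrationReport(
        bin_edges=edges,
        mean_predicted=sums_p[occupied] / counts[occupied],
        empirical_fraction=sums_t[occupied] / counts[occupied],
        counts=counts,
    )


def area_deviation(report: CalibrationReport) -> float:
    """Area between the reliability curve and the diagonal reference line.

    Trapezoidal integral of ``|empirical - predicted|`` over the
    mean-predicted axis across occupied-bin points; zero iff the curve lies
    on the diagonal.  A single occupied bin has zero width, hence area zero.
    """
    x = np.asarray(report.mean_predicted, dtype=float)
    y = np.asarray(report.empirical_fraction, dtype=float)
    if x.size == 0:
        raise ValueError("calibration curve has no occupied bins")
    order = np.argsort(x)
    return float(np.trapezoid(np.abs(y[order] - x[order]), x[order]))
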