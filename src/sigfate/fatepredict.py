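"""Predicting fate from signaling features and full histories.

The central question: does the full signaling history carry more
information about fate than the signaling integral alone? Tools:

* a Bayesian threshold classifier per feature — because fate is
  monotone in each signaling feature, the optimal (Bayes) decision rule
  is a single threshold, found by exhaustive scan over the midpoints of
  consecutive sorted values;
* the quadrant confusion matrix formed by a fate-score threshold and a
  feature threshold;
* generic classifiers on the raw history vector (a no-hidden-layer
  sigmoid network, i.e. logistic regression, and a quadratic-kernel
  SVM), evaluated with stratified 5-fold cross-validation;
* decoder-based mutual information computed from a confusion matrix,
  which is zero at chance.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegressionCV
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

logger = logging.getLogger(__name__)

POSITIVE = "amnion"
NEGATIVE = "pluripotent"

__all__ = [
    "ThresholdClassifier",
    "bayes_threshold",
    "quadrant_confusion",
    "history_classifier",
    "decoder_mutual_information",
]


@dataclass
class ThresholdClassifier:
    """Optimal single-threshold fate classifier for one signaling feature.

    Orientation is fixed: values strictly above the threshold predict
    amnion (all four signaling features increase with differentiation).
    ``confusion`` is the 2x2 percent matrix [[TP, FN], [FP, TN]].
    """

    feature: str
    threshold: float
    accuracy: float
    confusion: np.ndarray = field(repr=False)

    def predict(self, values):
        values = np.asarray(values, dtype=float)
        return np.where(values > self.threshold, POSITIVE, NEGATIVE)


def _as_binary(labels):
    labels = np.asarray(labels)
    if labels.dtype.kind in "bif":
        return labels.astype(bool)
    return labels == POSITIVE


def bayes_threshold(values, labels, feature: str = "feature") -> ThresholdClassifier:
    """Exhaustive-scan optimal threshold maximizing accuracy.

    Candidate thresholds are the midpoints between consecutive sorted
    unique values, plus one below the minimum and one above the maximum
    (predict-all-amnion / predict-none). Accuracy is piecewise constant
    between observed values, so this scan is exact. Ties are broken by
    returning the midpoint of the widest optimal interval (preferring
    finite intervals); this reproduces a brute-force scan.
    """
    values = np.asarray(values, dtype=float)
    y = _as_binary(labels)
    if y.all() or not y.any():
        raise ValueError("both classes must be present")
    uniq = np.unique(values)
    # interval k = (uniq[k-1], uniq[k]); intervals 0 and len(uniq) are half-open
    edges_lo = np.concatenate([[uniq[0] - 1.0], uniq])
    edges_hi = np.concatenate([uniq, [uniq[-1] + 1.0]])
    # threshold in interval k => predicted positive iff value >= uniq[k]
    # accuracy(k) = (#pos with v >= uniq[k]) + (#neg with v < uniq[k])
    order = np.argsort(values, kind="stable")
    y_sorted = y[order]
    v_sorted = values[order]
    starts = np.searchsorted(v_sorted, uniq, side="left")
    cum_pos = np.concatenate([[0], np.cumsum(y_sorted)])
    cum_neg = np.concatenate([[0], np.cumsum(~y_sorted)])
    total_pos = cum_pos[-1]
    n = len(values)
    ks = np.concatenate([starts, [n]])  # cut positions incl. all-negative rule
    correct = (total_pos - cum_pos[ks]) + cum_neg[ks]
    acc = correct / n
    best = acc.max()
    optimal = np.flatnonzero(np.isclose(acc, best))
    widths = edges_hi[optimal] - edges_lo[optimal]
    interior = (optimal > 0) & (optimal < len(uniq))
    pick = optimal[interior][np.argmax(widths[interior])] if interior.any() else optimal[np.argmax(widths)]
    threshold = 0.5 * (edges_lo[pick] + edges_hi[pick])
    pred = values > threshold
    conf = 100.0 * np.array(
        [[(pred & y).sum(), (~pred & y).sum()],
         [(pred & ~y).sum(), (~pred & ~y).sum()]]
    ) / n
    return ThresholdClassifier(feature=feature, threshold=float(threshold),
                               accuracy=float(best), confusion=conf)


def quadrant_confusion(fate_scores, feature_values, feature_threshold,
                       score_threshold: float = 0.0) -> dict:
    """Percent of cells in the four quadrants of the score-feature plane.

    Correct assignments sit in the top-right (amnion by both score and
    feature) and bottom-left (pluripotent by both) quadrants; the
    quadrant percentages are exactly the confusion matrix of the feature
    threshold classifier against the score labels.
    """
    s = np.asarray(fate_scores, dtype=float)
    f = np.asarray(feature_values, dtype=float)
    if not (np.isfinite(feature_threshold) and np.isfinite(score_threshold)):
        raise ValueError("thresholds must be finite")
    hi_s, hi_f = s > score_threshold, f > feature_threshold
    n = len(s)
    pct = lambda m: 100.0 * m.sum() / n
    return {
        "top_right": pct(hi_s & hi_f),
        "top_left": pct(hi_s & ~hi_f),
        "bottom_left": pct(~hi_s & ~hi_f),
        "bottom_right": pct(~hi_s & hi_f),
    }


def _make_model(model: str, seed: int):
    # the regularization strength a raw history vector needs depends
    # sharply on dimensionality and noise, so C is chosen by internal
    # cross-validation on each training split (deterministic folds)
    if model == "linear_sigmoid":
        # a neural network without hidden layers and sigmoid output unit
        # is logistic regression on the raw history vector
        return LogisticRegressionCV(Cs=np.logspace(-4, 2, 7), cv=3, max_iter=5000)
    if model == "svm_quadratic":
        # coef0=1: inhomogeneous quadratic kernel (includes linear terms)
        return GridSearchCV(
            SVC(kernel="poly", degree=2, coef0=1.0, random_state=seed),
            {"C": [1e-2, 1e-1, 1.0, 10.0]}, cv=3)
    raise ValueError(f"unknown model {model!r}")


def history_classifier(histories, labels, model: str = "linear_sigmoid",
                       folds: int = 5, seed: int = 0) -> dict:
    """Cross-validated fate prediction from the full history vector.

    Stratified k-fold CV; each fold standardizes timepoints on its
    training split. Returns overall CV accuracy and the pooled percent
    confusion matrix [[TP, FN], [FP, TN]].
    """
    X = np.asarray(histories, dtype=float)
    y = _as_binary(labels)
    counts = np.bincount(y.astype(int), minlength=2)
    if counts.min() < 2 * folds:
        raise ValueError("need at least 2 cells per class per fold")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    pred = np.zeros_like(y)
    for train, test in skf.split(X, y):
        scaler = StandardScaler().fit(X[train])
        clf = _make_model(model, seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", FutureWarning)
            clf.fit(scaler.transform(X[train]), y[train])
        pred[test] = clf.predict(scaler.transform(X[test])).astype(bool)
    n = len(y)
    conf = 100.0 * np.array(
        [[(pred & y).sum(), (~pred & y).sum()],
         [(pred & ~y).sum(), (~pred & ~y).sum()]]
    ) / n
    return {
        "model": model,
        "cv_accuracy": float((pred == y).mean()),
        "confusion": conf,
        "folds": folds,
        "seed": seed,
    }


def decoder_mutual_information(confusion) -> float:
    """Mutual information (bits) between true fate and predicted fate.

    I = H(fate) - H(fate | prediction), computed from the joint
    frequencies of a 2x2 confusion matrix (percent or counts; it is
    normalized internally). Zero for chance performance, 1 bit for a
    perfect balanced classifier.
    """
    P = np.asarray(confusion, dtype=float)
    if P.shape != (2, 2) or (P < 0).any() or P.sum() <= 0:
        raise ValueError("confusion must be a nonnegative 2x2 matrix")
    # reorder [[TP, FN], [FP, TN]] into the joint over (prediction, truth)
    joint = np.array([[P[0, 0], P[1, 0]], [P[0, 1], P[1, 1]]]) / P.sum()

    def xlogx(p):
        out = np.zeros_like(p)
        m = p > 0
        out[m] = p[m] * np.log2(p[m])
        return out

    p_true = joint.sum(axis=0)
    p_pred = joint.sum(axis=1)
    h_true = -xlogx(p_true).sum()
    h_joint = -xlogx(joint).sum()
    h_pred = -xlogx(p_pred).sum()
    return float(h_true + h_pred - h_joint)
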