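"""ROC analysis over TTROI, Youden cutoff selection and video classification.

The video-level diagnosis thresholds the TTROI statistic: a video is called
cancer iff its TTROI is at least the cutoff (closed inequality, so a cutoff
equal to the smallest positive observed TTROI behaves sensibly).  Candidate
cutoffs are the unique observed TTROI values plus +∞; the AUC is the
trapezoidal area of the resulting step ROC, which equals the tie-corrected
Mann–Whitney statistic U/(n₁n₂).  The "best" cutoff maximises Youden's
J = sensitivity + specificity − 1, with ties broken toward the smallest
threshold (favouring sensitivity, i.e. a low negative likelihood ratio).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_array, check_is_fitted, column_or_1d

__all__ = ["RocResult", "roc_points", "best_cutoff", "classify_video",
           "TTROIClassifier"]


@dataclass(frozen=True)
class RocResult:
    """ROC over the candidate cutoffs (ascending; last is +∞).

    ``sens_at[i]`` and ``fpr_at[i]`` are the sensitivity and 1 − specificity
    of the rule "positive iff TTROI ≥ thresholds[i]"; both are non-increasing
    in the threshold.  ``best_cutoff`` maximises Youden's J.
    """

    thresholds: np.ndarray
    sens_at: np.ndarray
    fpr_at: np.ndarray
    auc: float
    best_cutoff: float
    j_at_best: float


def _as_binary(truths, pos_label) -> np.ndarray:
    arr = np.asarray(truths)
    if arr.dtype.kind == "b":
        return arr
    if arr.dtype.kind in "iuf":
        return arr.astype(float) == 1.0
    return arr == pos_label


def roc_points(ttroi, truths, pos_label="cancer") -> RocResult:
    """Exact ROC of the TTROI ≥ threshold rule.

    ``truths`` may be booleans, 0/1, or labels compared against
    ``pos_label``.  Requires at least one positive and one negative video.
    """
    tt = column_or_1d(np.asarray(ttroi, dtype=float))
    y = _as_binary(truths, pos_label)
    if y.size != tt.size:
        raise ValueError("ttroi and truths differ in length")
    if y.all() or not y.any():
        raise ValueError("ROC undefined: truths contain a single class")
    thresholds = np.append(np.unique(tt), np.inf)
    pos = np.sort(tt[y])
    neg = np.sort(tt[~y])
    sens = 1.0 - np.searchsorted(pos, thresholds, side="left") / pos.size
    fpr = 1.0 - np.searchsorted(neg, thresholds, side="left") / neg.size
    # thresholds ascend → (fpr, sens) walks from (1,1) down to (0,0)
    auc = float(np.trapezoid(sens[::-1], fpr[::-1]))
    j = sens - fpr
    best = int(np.flatnonzero(j >= j.max() - 1e-12)[0])
    return RocResult(
        thresholds=thresholds,
        sens_at=sens,
        fpr_at=fpr,
        auc=auc,
        best_cutoff=float(thresholds[best]),
        j_at_best=float(j[best]),
    )


def best_cutoff(roc: RocResult) -> float:
    """The Youden-optimal candidate cutoff (ties → smallest threshold)."""
    return roc.best_cutoff


def classify_video(ttroi_s, cutoff_s: float = 1.0, pos_label="cancer",
                   neg_label="non_cancer"):
    """Binary video diagnosis: positive iff TTROI ≥ cutoff (closed).

    Accepts a scalar TTROI, an array of them, or a :class:`~ttroi.roi.VideoSummary`.
    """
    if cutoff_s < 0:
        raise ValueError("cutoff_s must be non-negative")
    ttroi_s = getattr(ttroi_s, "ttroi_s", ttroi_s)
    arr = np.asarray(ttroi_s, dtype=float)
    out = np.where(arr >= cutoff_s, pos_label, neg_label)
    return out[()] if arr.ndim == 0 else out


class TTROIClassifier(ClassifierMixin, BaseEstimator):
    """Threshold classifier on the TTROI statistic.

    ``fit`` takes per-video TTROI values (shape ``(n,)`` or ``(n, 1)``) and
    binary truths.  With ``cutoff="auto"`` the cutoff is selected on the
    training videos by maximising Youden's J over the observed TTROI values;
    a numeric ``cutoff`` fixes the threshold (e.g. the 1-s operating point)
    while still fitting the ROC for reference.

    Attributes
    ----------
    classes_ : ndarray of shape (2,)
        Sorted class labels seen in ``y``.
    cutoff_ : float
        The operating threshold: videos with TTROI ≥ ``cutoff_`` are called
        positive.
    auc_ : float
        Trapezoidal AUC of the training ROC.
    roc_ : RocResult
        The full training ROC.

    Examples
    --------
    >>> clf = TTROIClassifier(cutoff="auto")
    >>> clf.fit([[0.], [0.], [5.], [47.]], ["non_cancer"] * 2 + ["cancer"] * 2)
    TTROIClassifier()
    >>> float(clf.cutoff_)
    5.0
    >>> list(clf.predict([[0.5], [12.0]]))
    ['non_cancer', 'cancer']
    """

    def __init__(self, cutoff: float | str = "auto", pos_label=None):
        self.cutoff = cutoff
        self.pos_label = pos_label

    def _check_X(self, X) -> np.ndarray:
        X = check_array(X, ensure_2d=False, dtype=float)
        if X.ndim == 2:
            if X.shape[1] != 1:
                raise ValueError("TTROI input must have a single feature")
            X = X[:, 0]
        return X

    def fit(self, X, y) -> "TTROIClassifier":
        tt = self._check_X(X)
        y = column_or_1d(np.asarray(y))
        if y.size != tt.size:
            raise ValueError("X and y differ in length")
        self.classes_ = np.unique(y)
        if self.classes_.size != 2:
            raise ValueError(
                f"expected exactly 2 classes, got {self.classes_.size}"
            )
        if self.pos_label is not None:
            pos = self.pos_label
            if pos not in self.classes_:
                raise ValueError(f"pos_label {pos!r} not present in y")
        elif "cancer" in self.classes_:
            pos = "cancer"
        else:
            pos = self.classes_[1]
        self.pos_label_ = pos
        self.neg_label_ = self.classes_[self.classes_ != pos][0]
        self.roc_ = roc_points(tt, y == pos, pos_label=True)
        self.auc_ = self.roc_.auc
        self.cutoff_ = (
            self.roc_.best_cutoff if self.cutoff == "auto" else float(self.cutoff)
        )
        if self.cutoff != "auto" and self.cutoff_ < 0:
            raise ValueError("cutoff must be non-negative")
        self.n_features_in_ = 1
        return self

    def decision_function(self, X) -> np.ndarray:
        check_is_fitted(self)
        return self._check_X(X) - self.cutoff_

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self)
        positive = self.decision_function(X) >= 0
        return np.where(positive, self.pos_label_, self.neg_label_)
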