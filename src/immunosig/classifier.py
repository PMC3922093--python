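"""Below-median count classifier over a probe signature, with ROC analysis.

A sample's score is the number of signature probes whose value lies
strictly below the probe's reference median — by default the median of
all *other* samples (leave-one-out), with a pooled-median mode for
sensitivity analysis.  A sample is called metastatic when its count
exceeds a half-integer cutoff θ (equivalently, at least ⌈θ⌉ probes are
below their medians; the published operating point is θ = 8.5, i.e. at
least 9 of 14).  The cutoff is chosen on the ROC curve by Youden's J
unless fixed by the caller; the AUC uses the Mann-Whitney identity with
ties counted one half.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .errors import ValidationError

MODES = ("loo", "pooled")


def default_positive_label(classes):
    """Prefer the study's positive class name when present."""
    classes = list(classes)
    return "metastatic" if "metastatic" in classes else classes[-1]


def below_median_counts(
    expr: pd.DataFrame, signature_probes, mode: str = "loo"
) -> pd.Series:
    """Per-sample count of signature probes strictly below their reference median.

    ``expr`` is probes x samples.  mode='loo' (default) takes, for each
    sample, each probe's median over all other samples; mode='pooled'
    uses the median over all samples.  Values equal to the median do not
    count (strict inequality), so a constant matrix yields all zeros.
    """
    if mode not in MODES:
        raise ValidationError(f"mode must be one of {MODES}")
    signature_probes = list(signature_probes)
    missing = [p for p in signature_probes if p not in expr.index]
    if missing:
        raise ValidationError(f"signature probes missing from matrix: {missing}")
    if expr.shape[1] < 3:
        raise ValidationError("below_median_counts requires at least 3 samples")
    values = expr.loc[signature_probes].to_numpy(dtype=float)
    n = values.shape[1]
    if mode == "pooled":
        ref = np.median(values, axis=1, keepdims=True)
        counts = (values < ref).sum(axis=0)
    else:
        counts = np.empty(n, dtype=int)
        mask = np.ones(n, dtype=bool)
        for i in range(n):
            mask[i] = False
            ref = np.median(values[:, mask], axis=1)
            counts[i] = int((values[:, i] < ref).sum())
            mask[i] = True
    return pd.Series(counts, index=expr.columns, name="below_median_count")


def classify(counts, cutoff: float) -> np.ndarray:
    """Label a sample metastatic iff its count exceeds the cutoff θ.

    With a half-integer θ this is "count >= ceil(θ)"; e.g. θ = 8.5
    calls a sample positive when at least 9 probes are below median.
    """
    return np.asarray(counts, dtype=float) > cutoff


@dataclass
class RocResult:
    """ROC sweep over half-integer cutoffs on below-median counts."""

    thresholds: np.ndarray
    fpr: np.ndarray  # 1 - specificity per threshold
    tpr: np.ndarray  # sensitivity per threshold
    auc: float
    cutoff: float  # Youden-optimal threshold (ties -> higher specificity)
    sensitivity: float  # at the selected cutoff
    specificity: float

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"threshold": self.thresholds, "fpr": self.fpr, "tpr": self.tpr}
        )


def roc_analysis(counts, true_labels, positive_label=None) -> RocResult:
    """ROC points, Mann-Whitney AUC and Youden-optimal cutoff.

    Thresholds sweep the half-integers bracketing the observed count
    range.  AUC counts concordant (positive, negative) pairs with ties
    worth one half.  The selected cutoff maximizes J = sensitivity +
    specificity - 1; ties are broken toward the higher threshold
    (higher specificity).
    """
    counts = np.asarray(counts, dtype=float)
    labels = np.asarray(true_labels)
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValidationError("roc_analysis requires both classes present")
    if positive_label is None:
        positive_label = default_positive_label(classes)
    pos = counts[labels == positive_label]
    neg = counts[labels != positive_label]
    if pos.size == 0 or neg.size == 0:
        raise ValidationError("roc_analysis requires both classes present")

    greater = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    auc = (greater + 0.5 * ties) / (pos.size * neg.size)

    lo = np.floor(counts.min()) - 0.5
    hi = np.floor(counts.max()) + 0.5
    thresholds = np.arange(lo, hi + 1.0)
    tpr = np.array([(pos > t).mean() for t in thresholds])
    fpr = np.array([(neg > t).mean() for t in thresholds])
    j = tpr - fpr
    best = np.flatnonzero(j == j.max())[-1]  # last index = highest threshold
    return RocResult(
        thresholds=thresholds,
        fpr=fpr,
        tpr=tpr,
        auc=float(auc),
        cutoff=float(thresholds[best]),
        sensitivity=float(tpr[best]),
        specificity=float(1.0 - fpr[best]),
    )


class BelowMedianCountClassifier(ClassifierMixin, BaseEstimator):
    """sklearn-style wrapper around the below-median count rule.

    ``X`` is samples x signature-probes (sklearn orientation).  ``fit``
    computes training counts (leave-one-out or pooled medians), runs
    the ROC analysis against ``y`` and selects the cutoff (Youden's J,
    unless ``cutoff`` fixes it); ``predict`` scores new samples against
    the pooled training medians.

    Attributes: ``medians_``, ``counts_``, ``cutoff_``, ``roc_``, ``auc_``.
    """

    def __init__(self, mode: str = "loo", cutoff: float | None = None,
                 positive_label=None):
        self.mode = mode
        self.cutoff = cutoff
        self.positive_label = positive_label

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValidationError("X must be samples x probes aligned with y")
        expr = pd.DataFrame(
            X.T,
            index=[f"f{j}" for j in range(X.shape[1])],
            columns=[f"s{i}" for i in range(X.shape[0])],
        )
        self.medians_ = np.median(X, axis=0)
        self.counts_ = below_median_counts(expr, expr.index, mode=self.mode).to_numpy()
        self.roc_ = roc_analysis(self.counts_, y, self.positive_label)
        self.auc_ = self.roc_.auc
        self.cutoff_ = float(self.cutoff) if self.cutoff is not None else self.roc_.cutoff
        classes = np.unique(y)
        pos = (
            self.positive_label
            if self.positive_label is not None
            else default_positive_label(classes)
        )
        self.classes_ = classes
        self.positive_label_ = pos
        self.n_features_in_ = X.shape[1]
        return self

    def decision_function(self, X):
        check_is_fitted(self, "medians_")
        X = np.asarray(X, dtype=float)
        return (X < self.medians_).sum(axis=1).astype(float)

    def predict(self, X):
        counts = self.decision_function(X)
        positive = classify(counts, self.cutoff_)
        negative = self.classes_[self.classes_ != self.positive_label_][0]
        return np.where(positive, self.positive_label_, negative)
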