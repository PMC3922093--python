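"""Bootstrap recursive-SVM (R-SVM) multivariate feature selection.

Recursive SVM ranks features by their contribution to the separating
direction of a linear maximum-margin classifier, f_j = w_j (m_j+ - m_j-)
with w the fitted weight vector and m_j± the class means of feature j,
and retrains on shrinking feature sets along a geometric ladder.  A
bootstrap wrapper repeats the recursion on stratified resamples (with
out-of-bag samples as the held-out set), saves the features retained at
the reporting level of each step, and aggregates selection counts; the
union of features selected at least once is the candidate signature.

This multivariate scheme recovers marker sets whose members separate
the classes collectively even when no single member survives a
univariate screen — the regime the heterogeneous synthetic cohorts in
:mod:`immunosig.datasets` are built to exercise.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.svm import SVC

from .errors import ConfigError, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class RsvmConfig:
    """Bootstrap R-SVM parameters (defaults follow the published run:
    100 bootstrap steps, best 42 probes saved per step)."""

    n_bootstrap: int = 100
    keep_per_step: int = 42
    ladder: tuple[int, ...] | None = None  # default: geometric halving
    svm_cost: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_bootstrap < 1:
            raise ConfigError("n_bootstrap must be >= 1")
        if self.keep_per_step < 1:
            raise ConfigError("keep_per_step must be >= 1")
        if self.svm_cost <= 0:
            raise ConfigError("svm_cost must be > 0")
        if self.ladder is not None:
            if len(self.ladder) == 0 or any(
                b >= a for a, b in zip(self.ladder, self.ladder[1:])
            ):
                raise ConfigError("ladder must be non-empty and strictly decreasing")
            if self.ladder[-1] < 1:
                raise ConfigError("ladder levels must be >= 1")


@dataclass
class SelectionResult:
    """Aggregated bootstrap selection: counts, signature, error ladder."""

    selection_count: pd.Series  # probe -> times saved
    signature_probes: list[str] = field(default_factory=list)
    cv_error_by_level: dict[int, float] = field(default_factory=dict)


def make_ladder(n_features: int, keep_per_step: int) -> tuple[int, ...]:
    """Geometric halving from all features to <= keep, with keep inserted."""
    levels = [n_features]
    while levels[-1] > keep_per_step:
        levels.append(max(1, math.ceil(levels[-1] / 2)))
    levels.append(min(keep_per_step, n_features))
    return tuple(sorted(set(levels), reverse=True))


def _fit_svm(X: np.ndarray, y01: np.ndarray, cost: float) -> SVC:
    model = SVC(kernel="linear", C=cost)
    model.fit(X, y01)
    return model


def svm_feature_scores(X, y, cost: float = 1.0) -> np.ndarray:
    """Per-feature class-separation contribution f_j = w_j (m_j+ - m_j-).

    ``X`` is samples x features; ``y`` any two-class labeling.  The score
    is invariant to negating a feature (both factors flip sign) and zero
    for a feature identical in the two classes.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValidationError("svm_feature_scores requires exactly two classes")
    if X.ndim != 2 or X.shape[1] < 1:
        raise ValidationError("X must be samples x features with >= 1 feature")
    model = _fit_svm(X, (y == classes[1]).astype(int), cost)
    w = model.coef_[0]
    m_pos = X[y == classes[1]].mean(axis=0)
    m_neg = X[y == classes[0]].mean(axis=0)
    return w * (m_pos - m_neg)


def _top_features(scores: np.ndarray, feats: np.ndarray, k: int) -> np.ndarray:
    """Top-k features by score; ties broken by feature order (stable)."""
    order = np.argsort(-scores, kind="stable")
    return np.sort(feats[order[:k]])


@dataclass
class LadderLevel:
    n_features: int
    features: np.ndarray  # indices into the full feature set
    error: float  # misclassification rate on the held-out samples


def rsvm_ladder(
    X, y, ladder, train_idx, test_idx, cost: float = 1.0
) -> list[LadderLevel]:
    """One recursive-SVM descent: retrain, rank, shrink along ``ladder``.

    At each level the SVM is refit on the training samples restricted to
    the retained features, the held-out error recorded, and the next
    level's features chosen as the top scorers of the current fit.
    Deterministic given inputs.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    train_idx = np.asarray(train_idx, dtype=int)
    test_idx = np.asarray(test_idx, dtype=int)
    if test_idx.size == 0:
        raise ValidationError("test index set must be non-empty")
    if np.intersect1d(np.unique(train_idx), test_idx).size:
        raise ValidationError("train and test index sets must be disjoint")
    classes = np.unique(y[train_idx])
    if classes.size != 2:
        raise ValidationError("training labels must contain two classes")

    y01 = (y == classes[1]).astype(int)
    feats = np.arange(X.shape[1])
    levels: list[LadderLevel] = []
    model = _fit_svm(X[np.ix_(train_idx, feats)], y01[train_idx], cost)
    for level in ladder:
        if level < feats.size:
            w = model.coef_[0]
            m_pos = X[np.ix_(train_idx[y01[train_idx] == 1], feats)].mean(axis=0)
            m_neg = X[np.ix_(train_idx[y01[train_idx] == 0], feats)].mean(axis=0)
            feats = _top_features(w * (m_pos - m_neg), feats, level)
            model = _fit_svm(X[np.ix_(train_idx, feats)], y01[train_idx], cost)
        pred = model.predict(X[np.ix_(test_idx, feats)])
        error = float(np.mean(pred != y01[test_idx]))
        levels.append(LadderLevel(feats.size, feats.copy(), error))
    return levels


class BootstrapRSVM(SelectorMixin, BaseEstimator):
    """Bootstrap-aggregated recursive-SVM feature selector.

    Parameters mirror :class:`RsvmConfig`.  ``fit`` draws stratified
    bootstrap resamples (out-of-bag samples held out), runs the
    recursive descent on each, and counts how often every feature is
    saved at the reporting level (``keep_per_step``).  Features selected
    at least once form the signature (``get_support``).

    Attributes
    ----------
    selection_count_ : ndarray, bootstrap steps in which each feature was saved
    signature_mask_ : boolean ndarray, selection_count_ >= 1
    cv_error_by_level_ : dict, ladder level -> mean out-of-bag error
    """

    def __init__(
        self,
        n_bootstrap: int = 100,
        keep_per_step: int = 42,
        ladder: tuple[int, ...] | None = None,
        svm_cost: float = 1.0,
        random_state: int = 0,
    ):
        self.n_bootstrap = n_bootstrap
        self.keep_per_step = keep_per_step
        self.ladder = ladder
        self.svm_cost = svm_cost
        self.random_state = random_state

    def fit(self, X, y):
        config = RsvmConfig(
            n_bootstrap=self.n_bootstrap,
            keep_per_step=self.keep_per_step,
            ladder=tuple(self.ladder) if self.ladder is not None else None,
            svm_cost=self.svm_cost,
            seed=self.random_state,
        )
        config.validate()
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        classes, counts = np.unique(y, return_counts=True)
        if classes.size != 2:
            raise ValidationError("BootstrapRSVM requires exactly two classes")
        if counts.min() < 4:
            raise ValidationError("both classes need at least 4 samples")
        n_samples, n_features = X.shape
        ladder = config.ladder or make_ladder(n_features, config.keep_per_step)
        report_level = min(ladder, key=lambda lv: (abs(lv - config.keep_per_step), lv))

        rng = np.random.default_rng(config.seed)
        class_idx = [np.flatnonzero(y == c) for c in classes]
        selection = np.zeros(n_features, dtype=int)
        errors: dict[int, list[float]] = {lv: [] for lv in ladder}
        for _ in range(config.n_bootstrap):
            while True:  # redraw if out-of-bag set is empty
                train = np.concatenate(
                    [rng.choice(idx, idx.size, replace=True) for idx in class_idx]
                )
                oob = np.setdiff1d(np.arange(n_samples), train)
                if oob.size:
                    break
                logger.info("empty out-of-bag set; redrawing bootstrap sample")
            levels = rsvm_ladder(X, y, ladder, train, oob, config.svm_cost)
            for lv in levels:
                errors[lv.n_features].append(lv.error)
                if lv.n_features == report_level:
                    selection[lv.features] += 1

        self.classes_ = classes
        self.ladder_ = tuple(ladder)
        self.report_level_ = int(report_level)
        self.selection_count_ = selection
        self.signature_mask_ = selection >= 1
        self.cv_error_by_level_ = {
            lv: float(np.mean(errs)) for lv, errs in errors.items()
        }
        self.n_features_in_ = n_features
        return self

    def _get_support_mask(self):
        return self.signature_mask_


def bootstrap_select(
    expr: pd.DataFrame, labels, config: RsvmConfig | None = None
) -> SelectionResult:
    """Run bootstrap R-SVM on a probes x samples expression matrix."""
    if config is None:
        config = RsvmConfig()
    config.validate()
    selector = BootstrapRSVM(
        n_bootstrap=config.n_bootstrap,
        keep_per_step=config.keep_per_step,
        ladder=config.ladder,
        svm_cost=config.svm_cost,
        random_state=config.seed,
    )
    selector.fit(expr.to_numpy(dtype=float).T, np.asarray(labels))
    counts = pd.Series(selector.selection_count_, index=expr.index, name="selection_count")
    return SelectionResult(
        selection_count=counts,
        signature_probes=list(expr.index[selector.signature_mask_]),
        cv_error_by_level=selector.cv_error_by_level_,
    )
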