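"""Normalization, univariate differential-expression screen, projections.

Raw array intensities are put on a variance-stabilized scale by a
per-array robust affine calibration (median/MAD matching) followed by a
generalized-log transform glog(x) = arsinh(x/c).  For microarray-like
noise — additive at low intensity, multiplicative at high intensity —
the arsinh interpolates between a linear and a logarithmic scale, and
the crossover ``c`` is estimated as the ratio of the additive noise
scale to the multiplicative coefficient of variation.

The differential screen is a per-probe Welch two-sample t-test with
Benjamini-Hochberg control, flagging probes that pass the conventional
double threshold (|fold change| beyond 2 and q below 0.05).  On the
heterogeneous cohorts this package targets, the screen is expected to
come up empty — the signature is a multivariate object.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA

from .errors import ValidationError

_MAD_TO_SD = 1.4826


def glog(x, c: float):
    """Generalized log: arsinh(x / c).  glog(0) = 0 for any c > 0."""
    if c <= 0:
        raise ValidationError("glog scale c must be > 0")
    return np.arcsinh(np.asarray(x, dtype=float) / c)


def _column_med_mad(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    med = np.median(values, axis=0)
    mad = np.median(np.abs(values - med), axis=0) * _MAD_TO_SD
    return med, mad


def calibrate_arrays(values: np.ndarray) -> np.ndarray:
    """Affine-match every array (column) to common median/MAD targets."""
    med, mad = _column_med_mad(values)
    m_ref = np.median(med)
    s_ref = np.median(mad[mad > 0]) if np.any(mad > 0) else 1.0
    scale = np.ones_like(mad)
    nz = mad > 0
    scale[nz] = s_ref / mad[nz]
    return (values - med) * scale + m_ref


def estimate_glog_scale(values: np.ndarray) -> float:
    """Estimate the glog crossover c = sigma_additive / cv_multiplicative.

    Per-probe across-array SDs estimate the noise: their typical value
    among low-intensity probes gives the additive scale, and the typical
    SD/mean among high-intensity probes gives the multiplicative CV.
    """
    mu = values.mean(axis=1)
    sd = values.std(axis=1, ddof=1)
    lo, hi = np.quantile(mu, [0.2, 0.8])
    sigma_a = np.median(sd[mu <= lo])
    top = (mu >= hi) & (mu > 0)
    cv = np.median(sd[top] / mu[top]) if np.any(top) else 0.0
    if not np.isfinite(sigma_a) or not np.isfinite(cv) or sigma_a <= 0 or cv <= 0:
        fallback = np.median(np.abs(values - np.median(values))) * _MAD_TO_SD
        return float(fallback) if fallback > 0 else 1.0
    return float(sigma_a / cv)


def normalize(raw: pd.DataFrame, c: float | None = None) -> pd.DataFrame:
    """Calibrate arrays and apply the generalized-log transform.

    Parameters
    ----------
    raw : DataFrame, probes x samples, non-negative intensities.
    c : glog crossover scale; estimated from the data when ``None``.

    The transform is strictly increasing, so within-array rank order is
    preserved; all outputs are finite.
    """
    _check_matrix(raw)
    if raw.shape[1] < 2:
        raise ValidationError("normalize requires at least 2 samples")
    values = raw.to_numpy(dtype=float)
    if np.any(values < 0):
        raise ValidationError("raw intensities must be non-negative")
    calibrated = calibrate_arrays(values)
    if c is None:
        c = estimate_glog_scale(calibrated)
    out = pd.DataFrame(glog(calibrated, c), index=raw.index, columns=raw.columns)
    out.attrs["glog_scale"] = float(c)
    return out


class GlogNormalizer(TransformerMixin, BaseEstimator):
    """Array calibration + generalized-log transform as an sklearn transformer.

    Follows the sklearn orientation (rows = arrays/samples, columns =
    probes).  ``fit`` freezes the calibration targets and the glog scale
    on the training arrays; ``transform`` calibrates each new array with
    its own median/MAD against those targets.
    """

    def __init__(self, c: float | None = None):
        self.c = c

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 2:
            raise ValidationError("GlogNormalizer requires a 2-D matrix with >= 2 arrays")
        if np.any(X < 0):
            raise ValidationError("raw intensities must be non-negative")
        med, mad = _column_med_mad(X.T)  # per-array stats
        self.median_ = float(np.median(med))
        self.scale_ = float(np.median(mad[mad > 0])) if np.any(mad > 0) else 1.0
        calibrated = calibrate_arrays(X.T)
        self.c_ = float(self.c) if self.c is not None else estimate_glog_scale(calibrated)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        med = np.median(X, axis=1, keepdims=True)
        mad = np.median(np.abs(X - med), axis=1, keepdims=True) * _MAD_TO_SD
        scale = np.ones_like(mad)
        nz = mad > 0
        scale[nz] = self.scale_ / mad[nz]
        return glog((X - med) * scale + self.median_, self.c_)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values.

    q_(i) = min_{j >= i} m * p_(j) / j over the p-value ranking, capped
    at 1; order-preserving in the inputs.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValidationError("pvalues must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def differential_screen(
    expr: pd.DataFrame,
    labels,
    positive_label: str | None = None,
    fc_threshold: float = 2.0,
    q_threshold: float = 0.05,
    log_base: float = 2.0,
) -> pd.DataFrame:
    """Per-probe Welch t-test with BH correction and a fold-change screen.

    ``labels`` is a two-class labeling aligned with the sample columns.
    The mean difference is positive class minus negative class on the
    transformed scale; the fold change is the ratio of anti-transformed
    group means, treating the transformed scale as log with ``log_base``.
    A probe is flagged when q < ``q_threshold`` and the fold change is
    beyond ``fc_threshold`` in either direction.
    """
    _check_matrix(expr)
    labels = np.asarray(labels)
    if labels.shape[0] != expr.shape[1]:
        raise ValidationError("labels must align with the sample columns")
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValidationError("differential_screen requires exactly two classes")
    if positive_label is None:
        from .classifier import default_positive_label

        positive_label = default_positive_label(classes)
    elif positive_label not in classes:
        raise ValidationError(f"positive_label {positive_label!r} not present")
    pos = expr.loc[:, labels == positive_label].to_numpy(dtype=float)
    neg = expr.loc[:, labels != positive_label].to_numpy(dtype=float)
    if pos.shape[1] < 2 or neg.shape[1] < 2:
        raise ValidationError("both classes need at least 2 samples")

    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(pos, neg, axis=1, equal_var=False)
    degenerate = ~np.isfinite(p)
    if np.any(degenerate):
        warnings.warn(
            f"{int(degenerate.sum())} probe(s) with zero variance in both groups; "
            "p set to 1",
            RuntimeWarning,
            stacklevel=2,
        )
        t = np.where(degenerate, 0.0, t)
        p = np.where(degenerate, 1.0, p)

    mean_diff = pos.mean(axis=1) - neg.mean(axis=1)
    fold_change = (log_base ** pos.mean(axis=1)) / (log_base ** neg.mean(axis=1))
    q = bh_adjust(p)
    flagged = (q < q_threshold) & (
        (fold_change > fc_threshold) | (fold_change < 1.0 / fc_threshold)
    )
    return pd.DataFrame(
        {
            "mean_diff": mean_diff,
            "fold_change": fold_change,
            "t": t,
            "pvalue": p,
            "qvalue": q,
            "flagged": flagged,
        },
        index=expr.index,
    )


@dataclass
class ProjectionResult:
    """Sample ordering, linkage and 2-D principal-component coordinates."""

    sample_order: list[str]
    linkage_matrix: np.ndarray
    pc_coordinates: pd.DataFrame  # samples x (PC1, PC2)
    retained_probes: list[str]
    standardized: pd.DataFrame | None = None  # row-standardized probe subset


def project_and_cluster(expr: pd.DataFrame, probes=None) -> ProjectionResult:
    """Row-standardize a probe subset, then cluster and project the samples.

    Rows are centered and scaled to unit variance (zero-variance rows are
    dropped with a warning); samples are ordered by average-linkage
    Euclidean agglomeration and projected on the first two principal
    components.
    """
    _check_matrix(expr)
    sub = expr if probes is None else expr.loc[list(probes)]
    if sub.shape[0] == 0:
        raise ValidationError("probe subset must be non-empty")
    values = sub.to_numpy(dtype=float)
    sd = values.std(axis=1, ddof=0)
    keep = sd > 0
    if not np.all(keep):
        warnings.warn(
            f"dropping {int((~keep).sum())} zero-variance probe(s) before clustering",
            RuntimeWarning,
            stacklevel=2,
        )
    if not np.any(keep):
        raise ValidationError("no probe with positive variance")
    values = values[keep]
    standardized = (values - values.mean(axis=1, keepdims=True)) / values.std(
        axis=1, keepdims=True, ddof=0
    )
    samples = standardized.T  # samples x probes
    link = linkage(samples, method="average", metric="euclidean")
    order = [sub.columns[i] for i in leaves_list(link)]
    n_comp = min(2, samples.shape[0], samples.shape[1])
    coords = PCA(n_components=n_comp).fit_transform(samples)
    if n_comp < 2:  # degenerate: pad the second axis with zeros
        coords = np.column_stack([coords, np.zeros(len(coords))])
    pc = pd.DataFrame(coords[:, :2], index=sub.columns, columns=["PC1", "PC2"])
    return ProjectionResult(
        sample_order=order,
        linkage_matrix=link,
        pc_coordinates=pc,
        retained_probes=list(sub.index[keep]),
        standardized=pd.DataFrame(
            standardized, index=sub.index[keep], columns=sub.columns
        ),
    )


def _check_matrix(df: pd.DataFrame) -> None:
    if df.index.has_duplicates or df.columns.has_duplicates:
        raise ValidationError("probe and sample identifiers must be unique")
    if any(not str(i) for i in df.index) or any(not str(c) for c in df.columns):
        raise ValidationError("probe and sample identifiers must be non-empty")
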