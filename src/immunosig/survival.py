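"""Kaplan-Meier estimation and Mantel-Cox log-rank comparison.

Disease-free time runs from surgery to confirmed distant metastasis
(event = 1) or to last follow-up (censored, event = 0).  The survival
curve is the product-limit estimator S(t) = prod_{t_j <= t} (1 - d_j/r_j)
over distinct event times; two predicted strata are compared with the
Mantel-Cox log-rank test (chi-square, 1 df).  Events precede
censorings at tied times (the standard convention).  Estimation and
testing are delegated to lifelines behind this module's surface.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

from .errors import ValidationError


@dataclass
class KMCurve:
    """A fitted product-limit curve on its event-time grid."""

    timeline: np.ndarray
    survival: np.ndarray  # S(t) at each timeline point
    at_risk: np.ndarray
    label: str = ""

    def survival_at(self, t: float) -> float:
        """Step-function value S(t) (right-continuous)."""
        idx = np.searchsorted(self.timeline, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.timeline,
                "at_risk": self.at_risk,
                "survival": self.survival,
            }
        )


def _check_surv(times, events) -> tuple[np.ndarray, np.ndarray]:
    times = np.asarray(times, dtype=float)
    events = np.asarray(events)
    if times.size == 0:
        raise ValidationError("survival data must be non-empty")
    if np.any(~np.isfinite(times)) or np.any(times <= 0):
        raise ValidationError("survival times must be positive and finite")
    if not np.isin(events, (0, 1)).all():
        raise ValidationError("event flags must be 0 or 1")
    return times, events.astype(int)


def km_fit(times, events, label: str = "") -> KMCurve:
    """Product-limit (Kaplan-Meier) estimate of disease-free survival."""
    times, events = _check_surv(times, events)
    kmf = KaplanMeierFitter()
    kmf.fit(times, events, label=label or "KM")
    timeline = kmf.survival_function_.index.to_numpy(dtype=float)
    survival = kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float)
    at_risk = (
        kmf.event_table["at_risk"].reindex(kmf.survival_function_.index).to_numpy()
    )
    keep = timeline > 0  # drop the S(0)=1 anchor row lifelines prepends
    return KMCurve(
        timeline=timeline[keep],
        survival=survival[keep],
        at_risk=at_risk[keep],
        label=label,
    )


def km_by_group(times, events, groups) -> dict[str, KMCurve]:
    """One product-limit curve per stratum."""
    times, events = _check_surv(times, events)
    groups = np.asarray(groups)
    return {
        str(g): km_fit(times[groups == g], events[groups == g], label=str(g))
        for g in pd.unique(groups)
    }


def logrank_test(times_a, events_a, times_b, events_b) -> tuple[float, float]:
    """Mantel-Cox log-rank statistic and two-sided chi-square p (1 df)."""
    times_a, events_a = _check_surv(times_a, events_a)
    times_b, events_b = _check_surv(times_b, events_b)
    if events_a.sum() + events_b.sum() == 0:
        raise ValidationError("log-rank test undefined without any event")
    res = _ll_logrank(times_a, times_b, event_observed_A=events_a,
                      event_observed_B=events_b)
    return float(res.test_statistic), float(res.p_value)


def logrank_by_group(times, events, groups) -> tuple[float, float]:
    """Log-rank test between exactly two strata given as a group vector."""
    groups = np.asarray(groups)
    levels = pd.unique(groups)
    if levels.size != 2:
        raise ValidationError("logrank_by_group requires exactly two groups")
    times = np.asarray(times, dtype=float)
    events = np.asarray(events)
    a, b = (groups == levels[0]), (groups == levels[1])
    return logrank_test(times[a], events[a], times[b], events[b])
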