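"""Time-to-event estimators: Kaplan-Meier curves and marginal Cox models.

Both delegate to lifelines.  The marginal Cox fit is a single-covariate
proportional-hazards partial-likelihood fit with Efron tie handling; when
inverse-probability weights are supplied a robust sandwich variance is used
for the confidence interval, as required for valid IPW inference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter

__all__ = ["KmCurve", "WeightedCoxResult", "km_estimator", "marginal_cox_hr"]


@dataclass
class KmCurve:
    event_times: np.ndarray  # ascending distinct event times
    survival: np.ndarray  # S(t) at each event time, non-increasing
    at_risk: np.ndarray  # (weighted) number at risk just before each time
    events: np.ndarray  # (weighted) events at each time

    def survival_at(self, t: float) -> float:
        """Step-function evaluation of S(t)."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass
class WeightedCoxResult:
    hr: float
    ci_low: float
    ci_high: float
    log_hr_se: float
    n_events: int
    weighted: bool

    def __post_init__(self) -> None:
        if not self.ci_low <= self.hr <= self.ci_high:
            raise ValueError("confidence interval must bracket the hazard ratio")


def km_estimator(times, events, weights=None) -> KmCurve:
    """Product-limit survival estimate.

    ``events`` True marks an observed event, False right-censoring; the
    weighted variant scales both the at-risk and event counts.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if len(times) != len(events):
        raise ValueError("times and events must have equal length")
    if np.any(times < 0):
        raise ValueError("times must be non-negative")
    if weights is not None:
        weights = np.asarray(weights, dtype=float)
        if np.any(weights <= 0):
            raise ValueError("weights must be positive")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events, weights=weights)
    table = kmf.event_table
    observed = table[table["observed"] > 0]
    event_times = observed.index.to_numpy(dtype=float)
    sf = kmf.survival_function_.iloc[:, 0]
    survival = np.array([float(sf.loc[t]) for t in observed.index])
    return KmCurve(
        event_times=event_times,
        survival=survival,
        at_risk=observed["at_risk"].to_numpy(dtype=float),
        events=observed["observed"].to_numpy(dtype=float),
    )


def marginal_cox_hr(times, events, group, weights=None, alpha: float = 0.05) -> WeightedCoxResult:
    """Marginal hazard ratio of ``group`` (True vs False) for the event.

    Efron approximation for ties; with weights, lifelines' robust
    (sandwich) variance supplies the standard error.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    group = np.asarray(group, dtype=bool)
    if not events.any():
        raise ValueError("no events observed")
    if not (events & group).any() or not (events & ~group).any():
        raise ValueError("each group needs at least one event")
    df = pd.DataFrame({"time": times, "event": events.astype(int), "group": group.astype(float)})
    weighted = weights is not None
    fit_kwargs: dict = {}
    if weighted:
        w = np.asarray(weights, dtype=float)
        if np.any(w <= 0):
            raise ValueError("weights must be positive")
        df["w"] = w
        fit_kwargs.update(weights_col="w", robust=True)
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(df, duration_col="time", event_col="event", **fit_kwargs)
    beta = float(cph.params_["group"])
    se = float(cph.standard_errors_["group"])
    from scipy.stats import norm

    z = norm.ppf(1 - alpha / 2)
    return WeightedCoxResult(
        hr=float(np.exp(beta)),
        ci_low=float(np.exp(beta - z * se)),
        ci_high=float(np.exp(beta + z * se)),
        log_hr_se=se,
        n_events=int(events.sum()),
        weighted=weighted,
    )
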