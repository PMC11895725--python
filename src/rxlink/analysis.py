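"""Top-level study analysis: balance, propensity weighting, follow-up hazards.

``StudyAnalysis`` is the model object for the analytic core of the study:
given the assembled cohort covariate table (one row per member with
fill_status) and follow-up outcomes (time to first visit with the
prescribing provider, censored administratively), ``fit()`` produces a
``StudyResults`` carrying the covariate-balance report, the fitted
propensity model with held-out AUROC, unweighted and IPW-weighted marginal
hazard ratios with confidence intervals, and the per-group Kaplan-Meier
curves.  ``summary()`` renders the headline numbers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .balance import SmdReport, balance_table
from .config import PropensityConfig
from .propensity import FillPropensityModel, FillPropensityResults
from .survival import KmCurve, WeightedCoxResult, km_estimator, marginal_cox_hr

__all__ = ["StudyAnalysis", "StudyResults"]


@dataclass
class StudyResults:
    n: int
    n_filled: int
    balance: SmdReport
    propensity: FillPropensityResults
    hr_unweighted: WeightedCoxResult
    hr_weighted: WeightedCoxResult
    km_filled: KmCurve
    km_not_filled: KmCurve
    weights: np.ndarray = field(repr=False, default=None)

    @property
    def fill_rate(self) -> float:
        return self.n_filled / self.n

    def summary(self) -> str:
        b = self.balance.flagged()
        u, w = self.hr_unweighted, self.hr_weighted
        lines = [
            "Prescription-fill study analysis",
            "================================",
            f"cohort size                 {self.n}",
            f"filled within cutoff        {self.n_filled} ({100 * self.fill_rate:.1f}%)",
            f"covariates with SMD > 0.10  {len(b)}: {', '.join(b) if b else '-'}",
            f"propensity model AUROC      {self.propensity.test_auroc:.3f}",
            f"marginal HR (follow-up)     {u.hr:.3f} (95% CI {u.ci_low:.3f}-{u.ci_high:.3f})",
            f"IPW-weighted HR             {w.hr:.3f} (95% CI {w.ci_low:.3f}-{w.ci_high:.3f})",
        ]
        return "\n".join(lines)


class StudyAnalysis:
    """Balance + propensity + weighted survival analysis of fill status.

    Parameters
    ----------
    cohort_rows : DataFrame with fill_status and the contextual covariates
    followup_time : days to first follow-up visit or censoring, per row
    followup_event : True when the visit was observed
    propensity_config : split/CV/seed/clipping settings
    """

    def __init__(
        self,
        cohort_rows: pd.DataFrame,
        followup_time,
        followup_event,
        propensity_config: PropensityConfig | None = None,
    ):
        self.rows = cohort_rows.reset_index(drop=True)
        self.time = np.asarray(followup_time, dtype=float)
        self.event = np.asarray(followup_event, dtype=bool)
        if not (len(self.rows) == len(self.time) == len(self.event)):
            raise ValueError("cohort rows and outcome vectors must align")
        self.propensity_config = propensity_config or PropensityConfig()

    def fit(self) -> StudyResults:
        fill = self.rows["fill_status"].astype(bool).to_numpy()
        balance = balance_table(self.rows)
        ps_model = FillPropensityModel.from_dataframe(self.rows, config=self.propensity_config)
        ps_res = ps_model.fit()
        weights = ps_res.weights(fill)
        hr_u = marginal_cox_hr(self.time, self.event, fill)
        hr_w = marginal_cox_hr(self.time, self.event, fill, weights=weights)
        km_f = km_estimator(self.time[fill], self.event[fill])
        km_n = km_estimator(self.time[~fill], self.event[~fill])
        return StudyResults(
            n=len(self.rows),
            n_filled=int(fill.sum()),
            balance=balance,
            propensity=ps_res,
            hr_unweighted=hr_u,
            hr_weighted=hr_w,
            km_filled=km_f,
            km_not_filled=km_n,
            weights=weights,
        )
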