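"""Regularized-logistic propensity model for prescription filling.

The probability of filling the index prescription is modelled with an
L1-penalized (LASSO) logistic regression on the contextual covariates.
Following the study design this package supports, the data are split 9:1
into training and test sets, the penalty is chosen by 5-fold
cross-validated deviance on the training split, discrimination is reported
as the held-out AUROC, and the fitted model's predicted probabilities serve
as propensity scores for inverse-probability weighting.

`FillPropensityModel` / `FillPropensityResults` follow the model/results
convention: construct the model from a covariate DataFrame and labels, call
``fit()``, read estimates and diagnostics off the results object.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegressionCV
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.preprocessing import StandardScaler

from .config import PropensityConfig

__all__ = ["FillPropensityModel", "FillPropensityResults", "auroc", "ipw_weights"]

# reference levels dropped during one-hot encoding
CATEGORICAL_REFERENCES = {
    "sex": "Female",
    "race_ethnicity": "NH White",
    "payer": "Private",
    "provider_type": "Physician",
    "prescriber_specialty": "Primary care",
    "clinic_type": "Primary care",
    "phq9_severity": "Not taken",
}
NUMERIC = ["age", "bmi", "adi_state_rank", "n_rx_at_index", "n_rx_in_year"]
BOOLEAN = [
    "dx_depression",
    "dx_anxiety",
    "dx_adhd",
    "dx_headache",
    "ssri",
    "wcv_prior_year",
    "wcv_index_year",
    "outpatient_prior_year",
    "inpatient_prior_year",
    "ed_prior_year",
]


def auroc(scores, labels) -> float:
    """Probability a random positive outscores a random negative (ties 1/2)."""
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or not labels.any():
        raise ValueError("both classes must be present")
    return float(roc_auc_score(labels.astype(int), np.asarray(scores, dtype=float)))


def ipw_weights(ps, fill_status, clip_bounds: tuple[float, float] = (0.01, 0.99)) -> np.ndarray:
    """ATE inverse-probability weights: 1/ps for fillers, 1/(1-ps) otherwise.

    Propensity scores are clipped to ``clip_bounds`` first to bound the
    weights.
    """
    ps = np.asarray(ps, dtype=float)
    if np.any(ps < 0) or np.any(ps > 1):
        raise ValueError("propensity scores must lie in [0, 1]")
    lo, hi = clip_bounds
    ps = np.clip(ps, lo, hi)
    fill = np.asarray(fill_status, dtype=bool)
    return np.where(fill, 1.0 / ps, 1.0 / (1.0 - ps))


def encode_features(rows: pd.DataFrame) -> pd.DataFrame:
    """Design matrix: numerics (BMI median-imputed with a missingness
    indicator), 0/1 flags, and one-hot categoricals against declared
    reference levels."""
    cols: dict[str, np.ndarray] = {}
    for name in NUMERIC:
        v = rows[name].astype(float)
        if name == "bmi":
            cols["bmi_missing"] = v.isna().astype(float).to_numpy()
            v = v.fillna(v.median())
        cols[name] = v.to_numpy()
    for name in BOOLEAN:
        cols[name] = rows[name].astype(bool).astype(float).to_numpy()
    for name, ref in CATEGORICAL_REFERENCES.items():
        levels = sorted(set(rows[name].astype(str)) - {ref})
        for lv in levels:
            key = f"{name}[{lv}]"
            cols[key] = (rows[name].astype(str) == lv).astype(float).to_numpy()
    return pd.DataFrame(cols, index=rows.index)


@dataclass
class FillPropensityResults:
    params: pd.Series  # coefficients on the standardized scale, incl. intercept
    penalty_value: float  # lambda = 1 / C at the CV optimum
    cv_folds: int
    train_fraction: float
    seed: int
    test_auroc: float
    propensity_scores: pd.Series  # clipped predicted P(fill) for every row
    model: "FillPropensityModel" = field(repr=False, default=None)

    def weights(self, fill_status) -> np.ndarray:
        return ipw_weights(self.propensity_scores.to_numpy(), fill_status, self.model.config.ps_clip)

    def summary(self) -> str:
        lines = [
            "Fill propensity model (L1 logistic, CV-selected penalty)",
            f"  n = {len(self.propensity_scores)}, folds = {self.cv_folds}, "
            f"train fraction = {self.train_fraction}",
            f"  lambda = {self.penalty_value:.4g}",
            f"  held-out AUROC = {self.test_auroc:.3f}",
            "  nonzero coefficients (standardized scale):",
        ]
        nz = self.params[self.params.abs() > 1e-10].sort_values(key=np.abs, ascending=False)
        for name, val in nz.items():
            lines.append(f"    {name:<32s} {val:+.4f}")
        return "\n".join(lines)


class FillPropensityModel:
    """LASSO propensity model for fill status.

    Parameters
    ----------
    exog : DataFrame of raw covariates (the 22 contextual variables)
    endog : boolean fill labels
    config : PropensityConfig (folds, train fraction, seed, PS clipping)
    """

    def __init__(self, exog: pd.DataFrame, endog, config: PropensityConfig | None = None):
        self.config = config or PropensityConfig()
        self.config.validate()
        self.exog = exog.reset_index(drop=True)
        self.endog = np.asarray(endog, dtype=bool)
        if len(self.exog) != len(self.endog):
            raise ValueError("exog and endog lengths differ")
        if len(self.exog) < 50:
            raise ValueError("need at least 50 rows to fit the propensity model")
        if self.endog.all() or not self.endog.any():
            raise ValueError("both fill-status classes must be present")

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, label_col: str = "fill_status", config: PropensityConfig | None = None
    ) -> "FillPropensityModel":
        covars = [c for c in df.columns if c not in (label_col, "patient_id", "rx_id")]
        return cls(df[covars], df[label_col], config=config)

    def fit(self) -> FillPropensityResults:
        cfg = self.config
        x = encode_features(self.exog)
        y = self.endog.astype(int)
        idx = np.arange(len(y))
        train_idx, test_idx = train_test_split(
            idx,
            test_size=1.0 - cfg.train_fraction,
            stratify=y,
            random_state=cfg.seed,
        )
        scaler = StandardScaler()
        # constant columns scale to zero variance; sklearn leaves them at 0
        x_train = scaler.fit_transform(x.iloc[train_idx])
        x_test = scaler.transform(x.iloc[test_idx])
        clf = LogisticRegressionCV(
            Cs=np.logspace(-3, 2, 25),
            cv=StratifiedKFold(cfg.cv_folds, shuffle=True, random_state=cfg.seed),
            penalty="l1",
            solver="liblinear",
            scoring="neg_log_loss",
            max_iter=1000,
            random_state=cfg.seed,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", FutureWarning)
            clf.fit(x_train, y[train_idx])
        test_scores = clf.predict_proba(x_test)[:, 1]
        test_auroc = auroc(test_scores, y[test_idx].astype(bool))
        ps_all = clf.predict_proba(scaler.transform(x))[:, 1]
        lo, hi = cfg.ps_clip
        ps_all = np.clip(ps_all, lo, hi)
        params = pd.Series(
            np.concatenate([[clf.intercept_[0]], clf.coef_[0]]),
            index=["intercept"] + list(x.columns),
        )
        return FillPropensityResults(
            params=params,
            penalty_value=float(1.0 / clf.C_[0]),
            cv_folds=cfg.cv_folds,
            train_fraction=cfg.train_fraction,
            seed=cfg.seed,
            test_auroc=test_auroc,
            propensity_scores=pd.Series(ps_all, index=self.exog.index, name="propensity"),
            model=self,
        )
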