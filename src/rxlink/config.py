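"""Configuration objects for the synthetic generator and the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import yaml


class ConfigurationError(ValueError):
    """A configuration field failed validation; the message names the field."""


# Log-odds contributions to the probability of filling the index
# prescription.  Directions follow the observed imbalances: anxiety
# diagnoses, SSRI prescriptions, prior well-child visits and primary-care
# clinics raise the fill probability; public insurance / self-pay, male sex,
# neighbourhood deprivation and higher BMI lower it.  The intercept is left
# None and calibrated at generation time so the marginal fill rate hits
# 1 - nonfill_rate_target.
DEFAULT_FILL_COEFFICIENTS: dict[str, float] = {
    "intercept": None,  # type: ignore[dict-item]
    "anxiety": 1.8,
    "ssri": 1.1,
    "wcv_prior_year": 1.0,
    "clinic_primary_care": 1.0,
    "payer_public": -0.9,
    "payer_selfpay": -1.0,
    "male": -0.4,
    "adi_state_rank": -0.14,
    "bmi": -0.05,
}

# Log hazard-ratio contributions of covariates to the follow-up visit
# hazard.  Empty by default (the follow-up hazard then depends only on fill
# status); the confounded scenario shares covariates between the fill and
# follow-up models so that inverse-probability weighting has bias to remove.
CONFOUNDED_FOLLOWUP_LOG_HRS: dict[str, float] = {
    "anxiety": 0.5,
    "wcv_prior_year": 0.45,
    "payer_public": -0.35,
}


@dataclass
class DelayMixture:
    """Fill-delay model among true fillers: a point mass at day 0 plus a
    shifted geometric tail.

    p_same_day       probability the fill happens the day of the encounter
    p_within_week    target cumulative fraction filled within 7 days
                     (a calibration anchor; generation uses tail_rate)
    tail_rate        geometric success rate for delays >= 1 day
    """

    p_same_day: float = 0.812
    p_within_week: float = 0.913
    tail_rate: float = 0.104

    def validate(self) -> None:
        for name in ("p_same_day", "p_within_week"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"delay_mixture.{name} must be in [0,1], got {v}")
        if not 0.0 < self.tail_rate <= 1.0:
            raise ConfigurationError(
                f"delay_mixture.tail_rate must be in (0,1], got {self.tail_rate}"
            )


@dataclass
class SimConfig:
    """Parameters of the synthetic study population.

    Defaults emulate the structure of a pediatric new-user psychotropic
    cohort: one index prescription per patient written at an outpatient
    encounter during the study year, a covariate-dependent fill process with
    marginal fill rate ~0.778, heavy same-day mass in the fill delay, and an
    exponential follow-up-visit process with true fill-vs-nonfill hazard
    ratio 1.5 censored at 90 days.
    """

    n_patients: int = 2000
    seed: int = 20210101
    study_year: int = 2021
    capture_year: int = 2022

    fill_model_coefficients: dict[str, float | None] = field(
        default_factory=lambda: dict(DEFAULT_FILL_COEFFICIENTS)
    )
    delay_mixture: DelayMixture = field(default_factory=DelayMixture)
    nonfill_rate_target: float = 0.222
    decoy_dispensing_rate: float = 0.10
    coverage_miss_rate: float = 0.03
    followup_log_hr: float = 0.4054651081081644  # log(1.5)
    followup_covariate_log_hrs: dict[str, float] = field(default_factory=dict)
    baseline_followup_hazard: float = 0.007  # events per day
    censor_days: int = 90
    washout_days: int = 365

    # Fractions of patients carrying the two exclusion conditions the cohort
    # filters must detect: a psychotropic prescription or fill inside the
    # washout window, and absence of any capture-year encounter.
    prior_use_rate: float = 0.10
    missed_capture_rate: float = 0.10

    multi_prescription: bool = False  # reserved; single index rx per patient

    def validate(self) -> None:
        if self.n_patients <= 0:
            raise ConfigurationError(f"n_patients must be positive, got {self.n_patients}")
        for name in (
            "nonfill_rate_target",
            "decoy_dispensing_rate",
            "coverage_miss_rate",
            "prior_use_rate",
            "missed_capture_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0,1], got {v}")
        if self.baseline_followup_hazard <= 0:
            raise ConfigurationError(
                f"baseline_followup_hazard must be positive, got {self.baseline_followup_hazard}"
            )
        for name in ("censor_days", "washout_days"):
            v = getattr(self, name)
            if int(v) < 1:
                raise ConfigurationError(f"{name} must be a positive integer, got {v}")
        if isinstance(self.delay_mixture, dict):
            self.delay_mixture = DelayMixture(**self.delay_mixture)
        self.delay_mixture.validate()
        if "intercept" not in self.fill_model_coefficients:
            raise ConfigurationError("fill_model_coefficients must include 'intercept'")

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "SimConfig":
        cfg = cls(**d)
        cfg.validate()
        return cfg


@dataclass
class PropensityConfig:
    cv_folds: int = 5
    train_fraction: float = 0.9
    seed: int = 0
    ps_clip: tuple[float, float] = (0.01, 0.99)

    def validate(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ConfigurationError(
                f"train_fraction must be in (0,1), got {self.train_fraction}"
            )
        if self.cv_folds < 2:
            raise ConfigurationError(f"cv_folds must be >= 2, got {self.cv_folds}")
        lo, hi = self.ps_clip
        if not 0.0 < lo < hi < 1.0:
            raise ConfigurationError(f"ps_clip must satisfy 0 < low < high < 1, got {self.ps_clip}")


@dataclass
class PipelineConfig:
    """End-to-end run configuration (simulate -> link -> ... -> report)."""

    out_dir: str = "rxlink_run"
    input_dir: str | None = None  # read tables here instead of simulating
    simulate: SimConfig | None = field(default_factory=SimConfig)

    cutoff_days: int = 30
    search_horizon_days: int = 365
    washout_days: int = 365
    followup_censor_days: int = 90
    phq9_lookback_days: int = 14
    propensity: PropensityConfig = field(default_factory=PropensityConfig)
    make_plots: bool = False

    def validate(self) -> None:
        for name in (
            "cutoff_days",
            "search_horizon_days",
            "washout_days",
            "followup_censor_days",
            "phq9_lookback_days",
        ):
            if int(getattr(self, name)) < 1:
                raise ConfigurationError(f"{name} must be a positive integer")
        if self.cutoff_days > self.search_horizon_days:
            raise ConfigurationError("cutoff_days must not exceed search_horizon_days")
        if self.input_dir is None and self.simulate is None:
            raise ConfigurationError("either input_dir or a simulate block is required")
        if isinstance(self.simulate, dict):
            self.simulate = SimConfig.from_dict(self.simulate)
        if isinstance(self.propensity, dict):
            self.propensity = PropensityConfig(**self.propensity)
        if self.simulate is not None:
            self.simulate.validate()
        self.propensity.validate()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        cfg.validate()
        return cfg
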