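import numpy as np
import pandas as pd
import pytest
from pandas.testing import assert_frame_equal
from scipy.special import logit
from scipy.stats import binom

from rxlink import SimConfig, generate_population, read_fixture, write_fixture
from rxlink.balance import smd_binary
from rxlink.config import ConfigurationError
from rxlink.synth import SimPopulation, TABLE_NAMES


def test_same_config_same_tables():
    cfg = SimConfig(n_patients=200, seed=123)
    a = generate_population(cfg)
    b = generate_population(SimConfig(n_patients=200, seed=123))
    for name in TABLE_NAMES:
        assert_frame_equal(getattr(a, name), getattr(b, name))


def test_tables_internally_consistent(small_population):
    pop = small_population
    pids = set(pop.patients["patient_id"])
    encs = set(pop.encounters["encounter_id"])
    assert set(pop.prescriptions["patient_id"]) <= pids
    assert set(pop.prescriptions["encounter_id"]) <= encs
    assert len(pop.truth) == len(pop.prescriptions)
    # recorded (non-decoy) dispensings never precede their prescription
    rx_date = dict(zip(pop.prescriptions["patient_id"], pop.prescriptions["rx_date"]))
    recorded = pop.truth[pop.truth["recorded"]]
    fills = pop.dispensings.merge(
        recorded[["patient_id", "index_date", "true_delay"]], on="patient_id"
    )
    same_drug = fills[fills["fill_date"] == fills["index_date"] + fills["true_delay"].astype(int)]
    assert (same_drug["fill_date"] >= same_drug["index_date"]).all()


def test_no_noise_config_gives_one_matchable_dispensing_per_rx(clean_population):
    pop = clean_population
    # nonfill target 0 -> everyone fills; no misses, no decoys
    cfg = SimConfig(
        n_patients=150,
        seed=5,
        nonfill_rate_target=0.0,
        coverage_miss_rate=0.0,
        decoy_dispensing_rate=0.0,
        prior_use_rate=0.0,
    )
    pop = generate_population(cfg)
    assert pop.truth["true_fill"].all()
    after = pop.dispensings.merge(pop.prescriptions[["patient_id", "rx_date"]], on="patient_id")
    matchable = after[after["fill_date"] >= after["rx_date"]]
    assert matchable.groupby("patient_id").size().eq(1).all()
    assert len(matchable.groupby("patient_id")) == 150


def test_flat_model_hits_configured_fill_rate():
    """With zero coefficients and intercept logit(0.778), the empirical fill
    fraction is a Binomial(n, 0.778) draw; assert inside its exact 99.9% CI."""
    n = 5000
    coeffs = {"intercept": float(logit(0.778))}
    cfg = SimConfig(n_patients=n, seed=9, fill_model_coefficients=coeffs)
    pop = generate_population(cfg)
    k = int(pop.truth["true_fill"].sum())
    lo, hi = binom.ppf([0.0005, 0.9995], n, 0.778)
    assert lo <= k <= hi


def test_delay_mixture_calibration():
    cfg = SimConfig(n_patients=4000, seed=21)
    pop = generate_population(cfg)
    d = pop.truth.loc[pop.truth["true_fill"], "true_delay"].astype(int)
    p0 = (d == 0).mean()
    target = cfg.delay_mixture.p_same_day
    se = np.sqrt(target * (1 - target) / len(d))
    assert abs(p0 - target) < 4 * se
    # within-a-week mass lands near its calibration anchor
    assert abs((d <= 7).mean() - cfg.delay_mixture.p_within_week) < 0.03


def test_nonzero_coefficients_produce_imbalance():
    """Covariates that enter the fill model separate fillers from
    non-fillers by more than the 0.10 SMD convention at n=2000."""
    cfg = SimConfig(n_patients=2000, seed=33)
    pop = generate_population(cfg)
    t = pop.truth
    g1, g2 = t[t["true_fill"]], t[~t["true_fill"]]
    for col in ("dx_anxiety", "ssri", "wcv_prior_year"):
        smd = smd_binary(int(g1[col].sum()), len(g1), int(g2[col].sum()), len(g2))
        assert smd > 0.10, col


def test_fixture_round_trip(tmp_path, small_population):
    manifest = write_fixture(small_population, tmp_path)
    assert set(TABLE_NAMES) <= set(manifest)
    back = read_fixture(tmp_path)
    for name in TABLE_NAMES:
        assert_frame_equal(
            getattr(small_population, name).reset_index(drop=True),
            getattr(back, name).reset_index(drop=True),
            check_dtype=False,
        )
    assert back.config == small_population.config


def test_empty_population_writes_headers_only(tmp_path, small_population):
    empty = SimPopulation(
        **{name: getattr(small_population, name).head(0) for name in TABLE_NAMES},
        config=small_population.config,
    )
    manifest = write_fixture(empty, tmp_path)
    for name in TABLE_NAMES:
        df = pd.read_csv(manifest[name])
        assert len(df) == 0 and len(df.columns) > 0


@pytest.mark.parametrize(
    "field,value",
    [
        ("n_patients", 0),
        ("nonfill_rate_target", 1.5),
        ("coverage_miss_rate", -0.1),
        ("baseline_followup_hazard", 0.0),
        ("censor_days", 0),
    ],
)
def test_invalid_config_names_field(field, value):
    cfg = SimConfig(**{field: value})
    with pytest.raises(ConfigurationError, match=field):
        cfg.validate()


def test_unknown_coefficient_name_rejected():
    cfg = SimConfig(
        n_patients=60, fill_model_coefficients={"intercept": 0.0, "not_a_covariate": 1.0}
    )
    with pytest.raises(ConfigurationError, match="not_a_covariate"):
        generate_population(cfg)
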