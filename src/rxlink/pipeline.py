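"""End-to-end orchestration: simulate -> link -> cohort -> covariates ->
balance -> propensity/outcomes -> report.

Every stage's outputs are written before the next stage begins, and a run
manifest records the configuration hash and seeds, so a run is auditable
and byte-reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io, synth
from .analysis import StudyAnalysis, StudyResults
from .cohort import build_cohort
from .config import ConfigurationError, PipelineConfig
from .covariates import build_covariate_table
from .dates import year_interval
from .linkage import apply_fill_cutoff, days_to_fill_ecdf, match_fills
from .vocabulary import bundled_vocabulary

logger = logging.getLogger("rxlink")

__all__ = ["run_pipeline", "compute_followup"]


def compute_followup(
    cohort: pd.DataFrame, encounters: pd.DataFrame, censor_days: int = 90
) -> tuple[np.ndarray, np.ndarray]:
    """Days to the first encounter with the prescribing provider strictly
    after the index date, administratively censored at ``censor_days``."""
    enc = encounters.copy()
    enc["patient_id"] = enc["patient_id"].astype(str)
    enc["provider_id"] = enc["provider_id"].astype(str)
    by_patient = {pid: g for pid, g in enc.groupby("patient_id")}
    times, events = [], []
    for m in cohort.itertuples(index=False):
        g = by_patient.get(str(m.patient_id))
        t, e = censor_days, False
        if g is not None:
            sub = g[
                (g["provider_id"] == str(m.prescriber_id))
                & (g["date"] > int(m.index_date))
                & (g["date"] <= int(m.index_date) + censor_days)
            ]
            if len(sub):
                t, e = int(sub["date"].min()) - int(m.index_date), True
        times.append(t)
        events.append(e)
    return np.asarray(times, dtype=float), np.asarray(events, dtype=bool)


def _fill_summary(links: pd.DataFrame, cutoff_days: int) -> dict:
    matched = links.dropna(subset=["days_to_fill"])
    n = len(links)
    n_filled = int(links["filled_within_cutoff"].sum())
    out = {
        "n_prescriptions": n,
        "n_filled_within_cutoff": n_filled,
        "pct_filled_within_cutoff": round(100.0 * n_filled / n, 1) if n else None,
        "cutoff_days": cutoff_days,
    }
    if len(matched):
        d = matched["days_to_fill"].astype(int)
        out["pct_same_day_among_matched"] = round(100.0 * float((d == 0).mean()), 1)
        out["pct_within_7_among_matched"] = round(100.0 * float((d <= 7).mean()), 1)
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full study pipeline; returns the report bundle."""
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    # --- stage: inputs ----------------------------------------------------
    if config.input_dir is not None:
        in_dir = Path(config.input_dir)
        if not in_dir.exists():
            raise ConfigurationError(f"input_dir does not exist: {in_dir}")
        pop = synth.read_fixture(in_dir)
        sim_cfg = pop.config
        logger.info("loaded tables from %s", in_dir)
    else:
        sim_cfg = config.simulate
        pop = synth.generate_population(sim_cfg)
        synth.write_fixture(pop, out_dir / "tables")
        logger.info("simulated %d patients (seed %d)", sim_cfg.n_patients, sim_cfg.seed)
    study_year = sim_cfg.study_year if sim_cfg is not None else 2021
    capture_year = sim_cfg.capture_year if sim_cfg is not None else study_year + 1
    vocab = bundled_vocabulary()

    # --- stage: linkage ---------------------------------------------------
    result = match_fills(
        pop.prescriptions, pop.dispensings, vocab, search_horizon_days=config.search_horizon_days
    )
    result = apply_fill_cutoff(result, config.cutoff_days)
    links = result.to_frame()
    io.write_table(links, "links", out_dir)
    days_to_fill_ecdf(result).to_csv(out_dir / "days_to_fill_ecdf.csv", index=False)
    logger.info("linkage: %s", result.diagnostics)

    # --- stage: cohort ----------------------------------------------------
    cohort_frame, attrition = build_cohort(
        pop.prescriptions,
        pop.dispensings,
        pop.patients,
        pop.encounters,
        study_window=year_interval(study_year),
        capture_window=year_interval(capture_year),
        washout_days=config.washout_days,
        vocab=vocab,
    )
    io.write_table(cohort_frame, "cohort", out_dir)
    attrition.to_frame().to_csv(out_dir / "attrition.csv", index=False)
    if not len(cohort_frame):
        raise RuntimeError("cohort stage produced no members")

    # --- stage: covariates ------------------------------------------------
    covar = build_covariate_table(
        cohort_frame,
        pop.patients,
        pop.encounters,
        pop.diagnoses,
        pop.phq9,
        pop.prescriptions,
        links,
        vocab,
        index_year=study_year,
        phq9_lookback_days=config.phq9_lookback_days,
    )
    io.write_table(covar, "covariates", out_dir)

    # --- stage: analysis --------------------------------------------------
    fu_time, fu_event = compute_followup(cohort_frame, pop.encounters, config.followup_censor_days)
    study = StudyAnalysis(
        covar.drop(columns=["patient_id", "rx_id"]),
        fu_time,
        fu_event,
        propensity_config=config.propensity,
    )
    results = study.fit()
    _write_analysis(results, out_dir)
    if config.make_plots:
        from .linkage import time_to_fill_curve
        from .plotting import plot_followup_km, plot_time_to_fill

        ttf = time_to_fill_curve(result, observation_end_days=config.search_horizon_days)
        plot_time_to_fill(ttf, out_dir / "time_to_fill.png")
        plot_followup_km(results.km_filled, results.km_not_filled, out_dir / "followup_km.png")

    # --- report -----------------------------------------------------------
    cohort_links = links[links["rx_id"].isin(set(cohort_frame["rx_id"].astype(str)))]
    report = {
        "n_cohort": results.n,
        "fill_summary": _fill_summary(cohort_links, config.cutoff_days),
        "auroc": round(results.propensity.test_auroc, 3),
        "hr_unweighted": {
            "hr": round(results.hr_unweighted.hr, 3),
            "ci": [round(results.hr_unweighted.ci_low, 3), round(results.hr_unweighted.ci_high, 3)],
        },
        "hr_weighted": {
            "hr": round(results.hr_weighted.hr, 3),
            "ci": [round(results.hr_weighted.ci_low, 3), round(results.hr_weighted.ci_high, 3)],
        },
        "imbalanced_covariates": results.balance.flagged(),
        "attrition": attrition.stages,
    }
    with open(out_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)

    cfg_yaml = yaml.safe_dump(
        {
            "pipeline": {
                k: v
                for k, v in vars(config).items()
                if not hasattr(v, "__dict__") or isinstance(v, (int, float, str))
            },
            "simulate": sim_cfg.to_dict() if sim_cfg is not None else None,
        },
        sort_keys=True,
    )
    io.write_manifest(
        {
            "config_sha256": hashlib.sha256(cfg_yaml.encode()).hexdigest(),
            "sim_seed": str(sim_cfg.seed) if sim_cfg is not None else "",
            "propensity_seed": str(config.propensity.seed),
            "report": str(out_dir / "report.json"),
        },
        out_dir,
    )
    report["results"] = results
    return report


def _write_analysis(results: StudyResults, out_dir: Path) -> None:
    results.balance.to_frame().to_csv(out_dir / "balance.csv", index=False)
    results.propensity.params.rename("coefficient").to_csv(out_dir / "coefficients.csv")
    pd.DataFrame(
        {"propensity": results.propensity.propensity_scores, "weight": results.weights}
    ).to_csv(out_dir / "ps_weights.csv", index=False)
    for name, curve in (("km_filled", results.km_filled), ("km_not_filled", results.km_not_filled)):
        pd.DataFrame(
            {
                "time": curve.event_times,
                "survival": curve.survival,
                "at_risk": curve.at_risk,
                "events": curve.events,
            }
        ).to_csv(out_dir / f"{name}.csv", index=False)
    with open(out_dir / "summary.txt", "w") as fh:
        fh.write(results.summary() + "\n")
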