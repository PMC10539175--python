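"""Synthetic umbilical cord blood transplant cohorts.

The clinical dataset the analysis was designed for is not publicly
deposited, so this module generates cohorts with the same statistical
structure: a mixed paediatric/adult recipient population (about half older
than 16 years), a log-normal per-kg CD34+ dose distribution calibrated to
the published percentile anchors (minimum/5th/10th/25th percentiles of
roughly 0.17/0.60/0.83/1.28 x 1e5 cells/kg), a dose-dependent recovery
hazard following an explicit scenario curve, a small competing hazard of
death before recovery (about 10 deaths per 619 recipients), and
administrative censoring.

Recovery times are drawn from the proportional-hazards model
``h(t | d) = h0(t) * r(d)`` with a Weibull baseline h0 and scenario curve
r, via inverse-transform sampling; death before recovery is an independent
exponential competing event; the first event wins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .scenarios import ScenarioCurve, scenario_relative_hazard

__all__ = [
    "SimulationConfig",
    "simulate_cohort",
    "write_cohort",
    "read_cohort",
    "COHORT_COLUMNS",
    "EVENT_TYPES",
]

COHORT_COLUMNS = [
    "patient_id",
    "sex",
    "age_years",
    "body_weight_kg",
    "lean_body_mass_kg",
    "cd34_total",
    "time_days",
    "event",
    "tbi_flag",
    "mtx_flag",
]

EVENT_TYPES = ("recovered", "died_before_recovery", "censored")

#: Default scenario: hazard rises with per-kg dose and saturates at 1.5
#: above 3 x 1e5 cells/kg, staying at 0.5 at the low-dose end -- the
#: no-threshold shape the clinical analysis recovered.
DEFAULT_SCENARIO = ScenarioCurve(kind="plateau", d0=3.0, low_level=0.5, high_level=1.5)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic cohort generator.

    Dose parameters are on the natural-log scale of the per-kg dose in
    units of 1e5 cells/kg; the defaults reproduce the published percentile
    anchors of the study cohort.  ``baseline_shape``/``baseline_scale``
    parameterise the Weibull time-to-recovery baseline in days (median
    ~19 days at relative hazard 1).  ``death_rate`` is the constant
    competing hazard of death before recovery per day.
    """

    n: int = 619
    seed: int = 0
    dose_lognormal_mu: float = 0.773
    dose_lognormal_sigma: float = 0.781
    adult_fraction: float = 0.5
    adult_weight_mean: float = 62.0
    adult_weight_sd: float = 11.0
    lbm_fraction_m: float = 0.80
    lbm_fraction_f: float = 0.72
    lbm_fraction_sd: float = 0.05
    bv_ml_per_kg_lbm: float = 80.0
    baseline_shape: float = 4.0
    baseline_scale: float = 20.823
    death_rate: float = 0.00085
    censor_day: float = 60.0
    tbi_prob: float = 0.15
    mtx_prob: float = 0.25
    scenario: ScenarioCurve = field(default_factory=lambda: DEFAULT_SCENARIO)
    dose_metric_for_scenario: str = "per_bw"

    def validate(self) -> None:
        if self.n < 2:
            raise ValueError("n must be >= 2")
        if self.dose_lognormal_sigma <= 0:
            raise ValueError("dose_lognormal_sigma must be > 0")
        if self.censor_day <= 0:
            raise ValueError("censor_day must be > 0")
        if not (0 <= self.adult_fraction <= 1):
            raise ValueError("adult_fraction must be in [0, 1]")
        if self.baseline_shape <= 0 or self.baseline_scale <= 0:
            raise ValueError("baseline_shape and baseline_scale must be > 0")
        if self.death_rate < 0:
            raise ValueError("death_rate must be >= 0")
        if self.dose_metric_for_scenario not in ("abs", "per_bw", "per_bv"):
            raise ValueError(
                "dose_metric_for_scenario must be one of 'abs', 'per_bw', 'per_bv'"
            )


def simulate_cohort(config: SimulationConfig) -> pd.DataFrame:
    """Generate a synthetic cohort of ``config.n`` recipients.

    Returns a DataFrame with the canonical cohort columns.  Identical
    config (including seed) yields identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n

    sex = np.where(rng.random(n) < 0.5, "M", "F")
    adult = rng.random(n) < config.adult_fraction
    age = np.where(
        adult, rng.uniform(17.0, 60.0, n), rng.uniform(1.0, 16.0, n)
    ).round(1)

    child_mean = 8.0 + 2.5 * age
    weight = np.where(
        adult,
        rng.normal(config.adult_weight_mean, config.adult_weight_sd, n),
        child_mean * np.exp(rng.normal(0.0, 0.13, n)),
    )
    weight = np.clip(weight, 6.0, None).round(1)

    lbm_frac = np.where(sex == "M", config.lbm_fraction_m, config.lbm_fraction_f)
    lbm_frac = np.clip(lbm_frac + rng.normal(0.0, config.lbm_fraction_sd, n), 0.45, 0.95)
    lbm = (lbm_frac * weight).round(1)

    # Per-kg dose in 1e5 cells/kg; absolute count follows from weight.
    dose_per_kg = np.exp(
        rng.normal(config.dose_lognormal_mu, config.dose_lognormal_sigma, n)
    )
    cd34_total = np.maximum(1, np.rint(dose_per_kg * 1e5 * weight)).astype(np.int64)
    dose_per_kg = cd34_total / weight / 1e5  # recompute after rounding

    blood_volume_l = config.bv_ml_per_kg_lbm * lbm / 1000.0
    dose_per_bv = cd34_total / blood_volume_l / 1e7

    scenario_dose = {
        "abs": cd34_total.astype(float),
        "per_bw": dose_per_kg,
        "per_bv": dose_per_bv,
    }[config.dose_metric_for_scenario]

    if config.scenario.kind == "threshold" and config.scenario.d0 is not None:
        if config.scenario.d0 <= scenario_dose.min():
            warnings.warn(
                "threshold d0 lies at or below the minimum simulated dose; "
                "the threshold is unexercised",
                stacklevel=2,
            )

    r = scenario_relative_hazard(config.scenario, scenario_dose)

    # Inverse-transform: S(t|d) = exp(-r(d) * (t/scale)^shape).
    e_rec = rng.exponential(1.0, n)
    with np.errstate(divide="ignore"):
        t_rec = np.where(
            r > 0,
            config.baseline_scale * np.power(e_rec / np.where(r > 0, r, 1.0),
                                             1.0 / config.baseline_shape),
            np.inf,
        )
    t_death = (
        rng.exponential(1.0 / config.death_rate, n)
        if config.death_rate > 0
        else np.full(n, np.inf)
    )

    # First event wins; observed times are whole posttransplant days.
    event = np.full(n, "censored", dtype=object)
    time_days = np.full(n, float(config.censor_day))
    rec_first = (t_rec <= t_death) & (t_rec < config.censor_day)
    death_first = (t_death < t_rec) & (t_death < config.censor_day)
    event[rec_first] = "recovered"
    event[death_first] = "died_before_recovery"
    time_days[rec_first] = np.maximum(1.0, np.ceil(t_rec[rec_first]))
    time_days[death_first] = np.maximum(1.0, np.ceil(t_death[death_first]))
    time_days = np.minimum(time_days, config.censor_day)

    return pd.DataFrame(
        {
            "patient_id": [f"P{i + 1:04d}" for i in range(n)],
            "sex": sex,
            "age_years": age,
            "body_weight_kg": weight,
            "lean_body_mass_kg": lbm,
            "cd34_total": cd34_total,
            "time_days": time_days,
            "event": event,
            "tbi_flag": rng.random(n) < config.tbi_prob,
            "mtx_flag": rng.random(n) < config.mtx_prob,
        }
    )


def _validate_cohort(df: pd.DataFrame) -> None:
    bad_event = set(df["event"].unique()) - set(EVENT_TYPES)
    if bad_event:
        raise ValueError(f"unknown event value(s): {sorted(bad_event)}")
    bad_sex = set(df["sex"].unique()) - {"M", "F"}
    if bad_sex:
        raise ValueError(f"unknown sex value(s): {sorted(bad_sex)}")
    if (df["lean_body_mass_kg"] > df["body_weight_kg"]).any():
        bad = df.index[df["lean_body_mass_kg"] > df["body_weight_kg"]].tolist()
        raise ValueError(f"lean_body_mass_kg exceeds body_weight_kg in rows {bad[:5]}")
    if (df["time_days"] <= 0).any():
        raise ValueError("time_days must be > 0")
    if (df["body_weight_kg"] <= 0).any() or (df["lean_body_mass_kg"] <= 0).any():
        raise ValueError("body_weight_kg and lean_body_mass_kg must be > 0")


def write_cohort(rows: pd.DataFrame, path) -> None:
    """Write a cohort table to CSV with the canonical column order."""
    missing = [c for c in COHORT_COLUMNS if c not in rows.columns]
    if missing:
        raise ValueError(f"cohort is missing column(s): {missing}")
    rows[COHORT_COLUMNS].to_csv(path, index=False)


def read_cohort(path) -> pd.DataFrame:
    """Read and validate a cohort CSV (exact schema, lossless round trip)."""
    df = pd.read_csv(path, dtype={"patient_id": str})
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    extra = [c for c in df.columns if c not in COHORT_COLUMNS]
    if missing or extra:
        raise ValueError(
            f"cohort CSV schema mismatch: missing columns {missing}, "
            f"unexpected columns {extra}"
        )
    df = df[COHORT_COLUMNS]
    df["cd34_total"] = df["cd34_total"].astype(np.int64)
    df["tbi_flag"] = df["tbi_flag"].astype(bool)
    df["mtx_flag"] = df["mtx_flag"].astype(bool)
    _validate_cohort(df)
    return df
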