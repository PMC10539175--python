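"""CD34+ dose expressions, blood-volume estimation and sampling-noise math.

Three expressions of graft CD34+ cell dose are computed for each recipient:
the absolute count, the count per kg of body weight (reported in units of
1e5 cells/kg) and the count per litre of estimated blood volume (reported
in units of 1e7 cells/L).  Blood volume tracks lean body mass (LBM) far
better than total body weight, which is the motivation for the
per-blood-volume normalisation; by default it is estimated as a constant
80 mL per kg of LBM, with the Nadler height-weight formula available as an
alternative.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "GraftDose",
    "BloodVolumeEstimate",
    "estimate_blood_volume",
    "compute_dose_metrics",
    "lbm_bw_strata",
    "hsc_poisson_variation",
    "add_dose_columns",
    "DOSE_METRICS",
]

# Reporting scales: doses are expressed in 1e5 cells/kg and 1e7 cells/L.
PER_KG_SCALE = 1e5
PER_BV_SCALE = 1e7

DOSE_METRICS = ("abs", "per_bw", "per_bv")

# Column names used when a cohort table is annotated with dose metrics.
DOSE_COLUMNS = {
    "abs": "cd34_total",
    "per_bw": "dose_per_kg_1e5",
    "per_bv": "dose_per_bv_1e7",
}


@dataclass(frozen=True)
class BloodVolumeEstimate:
    litres: float
    method: str  # "per_lbm" | "nadler"
    coefficient: float | None = None  # mL per kg LBM, for per_lbm


@dataclass(frozen=True)
class GraftDose:
    abs_cd34: float
    dose_per_kg: float  # 1e5 cells / kg
    dose_per_bv: float  # 1e7 cells / L
    log2_abs: float
    log2_per_kg: float
    log2_per_bv: float


def estimate_blood_volume(
    sex: str,
    lean_body_mass_kg: float | None = None,
    body_weight_kg: float | None = None,
    height_m: float | None = None,
    method: str = "per_lbm",
    coefficient: float = 80.0,
) -> BloodVolumeEstimate:
    """Estimate recipient blood volume in litres.

    ``per_lbm`` uses a constant ``coefficient`` mL per kg of lean body
    mass (default 80 mL/kg).  ``nadler`` uses the classic sex-specific
    Nadler height-weight formula and requires ``height_m`` and
    ``body_weight_kg``.
    """
    if sex not in ("M", "F"):
        raise ValueError(f"sex must be 'M' or 'F', got {sex!r}")
    if method == "per_lbm":
        if lean_body_mass_kg is None or lean_body_mass_kg <= 0:
            raise ValueError("lean_body_mass_kg must be > 0 for method='per_lbm'")
        if coefficient <= 0:
            raise ValueError("coefficient must be > 0")
        litres = coefficient * lean_body_mass_kg / 1000.0
        return BloodVolumeEstimate(litres=litres, method="per_lbm", coefficient=coefficient)
    if method == "nadler":
        if height_m is None or body_weight_kg is None:
            raise ValueError("method='nadler' requires height_m and body_weight_kg")
        if height_m <= 0 or body_weight_kg <= 0:
            raise ValueError("height_m and body_weight_kg must be > 0")
        if sex == "M":
            litres = 0.3669 * height_m**3 + 0.03219 * body_weight_kg + 0.6041
        else:
            litres = 0.3561 * height_m**3 + 0.03308 * body_weight_kg + 0.1833
        return BloodVolumeEstimate(litres=litres, method="nadler", coefficient=None)
    raise ValueError(f"unknown blood-volume method {method!r}")


def compute_dose_metrics(
    abs_cd34: float, body_weight_kg: float, blood_volume_l: float
) -> GraftDose:
    """Compute the three CD34+ dose expressions for one recipient.

    dose_per_kg = abs_cd34 / body_weight_kg / 1e5 (units 1e5 cells/kg);
    dose_per_bv = abs_cd34 / blood_volume_l / 1e7 (units 1e7 cells/L).
    """
    if abs_cd34 <= 0:
        raise ValueError("abs_cd34 must be > 0")
    if body_weight_kg <= 0:
        raise ValueError("body_weight_kg must be > 0")
    if blood_volume_l <= 0:
        raise ValueError("blood_volume_l must be > 0")
    per_kg = abs_cd34 / body_weight_kg / PER_KG_SCALE
    per_bv = abs_cd34 / blood_volume_l / PER_BV_SCALE
    return GraftDose(
        abs_cd34=abs_cd34,
        dose_per_kg=per_kg,
        dose_per_bv=per_bv,
        log2_abs=math.log2(abs_cd34),
        log2_per_kg=math.log2(per_kg),
        log2_per_bv=math.log2(per_bv),
    )


def lbm_bw_strata(
    cohort: pd.DataFrame, low_pct: float = 15.0, high_pct: float = 85.0
) -> pd.Series:
    """Label each recipient 'extreme' or 'normal' by their LBM/BW ratio.

    'Extreme' means the ratio of lean body mass to body weight falls
    strictly below the cohort's ``low_pct`` percentile or strictly above
    its ``high_pct`` percentile; everything else is 'normal'.
    """
    if len(cohort) == 0:
        raise ValueError("cohort must be non-empty")
    if not (0 < low_pct < high_pct < 100):
        raise ValueError("need 0 < low_pct < high_pct < 100")
    ratio = (
        cohort["lean_body_mass_kg"].to_numpy(float)
        / cohort["body_weight_kg"].to_numpy(float)
    )
    lo = np.percentile(ratio, low_pct)
    hi = np.percentile(ratio, high_pct)
    extreme = (ratio < lo) | (ratio > hi)
    if np.ptp(ratio) == 0:
        warnings.warn(
            "LBM/BW ratio is constant across the cohort; all rows labelled 'normal'",
            stacklevel=2,
        )
        extreme[:] = False
    return pd.Series(
        np.where(extreme, "extreme", "normal"), index=cohort.index, name="lbm_bw_stratum"
    )


def hsc_poisson_variation(cd34_count: float, hsc_per_cd34: float) -> dict:
    """Poisson sampling noise in the number of true HSCs in a graft.

    With ``lambda = cd34_count * hsc_per_cd34`` expected HSCs, the relative
    fluctuation is 1/sqrt(lambda); returns the coefficient of variation and
    the three-standard-deviation relative width, both in percent.  E.g. a
    graft of 40e5 CD34+ cells at 1 HSC per 5000 CD34+ cells carries
    lambda = 800, a ~10% three-sigma fluctuation in its HSC content.
    """
    if cd34_count <= 0:
        raise ValueError("cd34_count must be > 0")
    if not (0 < hsc_per_cd34 <= 1):
        raise ValueError("hsc_per_cd34 must be in (0, 1]")
    lam = cd34_count * hsc_per_cd34
    if lam == 0:
        raise ValueError("expected HSC count is zero; variation undefined")
    return {
        "lambda": lam,
        "cv_pct": 100.0 / math.sqrt(lam),
        "three_sigma_pct": 300.0 / math.sqrt(lam),
    }


def add_dose_columns(
    cohort: pd.DataFrame,
    bv_method: str = "per_lbm",
    bv_coefficient: float = 80.0,
) -> pd.DataFrame:
    """Annotate a cohort table with blood volume, dose metrics and strata.

    Adds columns ``blood_volume_l``, ``dose_per_kg_1e5``, ``dose_per_bv_1e7``
    and ``lbm_bw_stratum``; returns a new DataFrame.
    """
    out = cohort.copy()
    if bv_method != "per_lbm":
        raise ValueError("cohort annotation supports only the per-LBM estimator")
    out["blood_volume_l"] = bv_coefficient * out["lean_body_mass_kg"] / 1000.0
    out["dose_per_kg_1e5"] = out["cd34_total"] / out["body_weight_kg"] / PER_KG_SCALE
    out["dose_per_bv_1e7"] = out["cd34_total"] / out["blood_volume_l"] / PER_BV_SCALE
    out["lbm_bw_stratum"] = lbm_bw_strata(out)
    return out
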