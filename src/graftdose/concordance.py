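"""Concordance of dose metrics with granulocyte recovery.

Two endpoints are assessed for each of the three dose expressions, overall
and within lean-body-mass/body-weight strata:

* ``interval`` -- Harrell's C between the dose (higher dose should mean
  earlier recovery) and the censored time to recovery, using all
  recipients; deaths before recovery count as censoring at death time.
* ``day21``    -- AUROC of a univariate logistic model for recovery within
  21 days, excluding recipients who died before recovery.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dose import DOSE_COLUMNS, add_dose_columns

__all__ = [
    "ConcordanceEstimate",
    "harrell_c",
    "day21_labels",
    "logistic_concordance",
    "concordance_table",
]


@dataclass(frozen=True)
class ConcordanceEstimate:
    value: float
    n_pairs: int
    n_tied: int
    endpoint: str  # "interval" | "day21"


def harrell_c(time, event, score) -> ConcordanceEstimate:
    """Harrell's concordance index for censored recovery times.

    Orientation: a higher score should predict a *shorter* time to
    recovery.  A pair is permissible when the member with the shorter
    time had an observed recovery (or, at equal times, exactly one of the
    two recovered -- the other is known to be event-free at that time).
    Tied event times contribute no pair; tied scores earn half credit.
    """
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=bool)
    s = np.asarray(score, dtype=float)
    if not (len(t) == len(e) == len(s)):
        raise ValueError("time, event and score must have equal length")
    if e.sum() < 1:
        raise ValueError("need at least one observed recovery")

    conc = disc = tied = 0
    n = len(t)
    chunk = max(1, 10_000_000 // max(n, 1))
    for start in range(0, n, chunk):
        sl = slice(start, min(start + chunk, n))
        ti, ei, si = t[sl][:, None], e[sl][:, None], s[sl][:, None]
        perm = ei & ((ti < t[None, :]) | ((ti == t[None, :]) & ~e[None, :]))
        conc += int((perm & (si > s[None, :])).sum())
        disc += int((perm & (si < s[None, :])).sum())
        tied += int((perm & (si == s[None, :])).sum())
    n_pairs = conc + disc + tied
    if n_pairs == 0:
        raise ValueError("no permissible pairs; concordance undefined")
    return ConcordanceEstimate(
        value=(conc + 0.5 * tied) / n_pairs,
        n_pairs=n_pairs,
        n_tied=tied,
        endpoint="interval",
    )


def day21_labels(cohort: pd.DataFrame):
    """Binary recovery-by-day-21 labels and the inclusion mask.

    Label 1 iff the recipient recovered on or before day 21.  Recipients
    who died before recovery are excluded (mask False); recipients
    censored alive without recovery are labelled 0.
    """
    mask = cohort["event"] != "died_before_recovery"
    labels = (
        (cohort["event"] == "recovered") & (cohort["time_days"] <= 21)
    ).astype(int)
    return labels[mask], mask


def logistic_concordance(labels, dose) -> ConcordanceEstimate:
    """AUROC of a univariate logistic model for the day-21 endpoint.

    Fits intercept + slope on the dose by maximum likelihood; the reported
    concordance is the Mann-Whitney AUROC of the fitted probabilities,
    which for a monotone single-covariate model coincides with the rank
    AUROC of the dose itself (up to orientation of the fitted slope).
    """
    import statsmodels.api as sm
    from sklearn.metrics import roc_auc_score

    y = np.asarray(labels, dtype=int)
    x = np.asarray(dose, dtype=float)
    if y.min() == y.max():
        raise ValueError("both outcome classes must be present")

    probs = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, sm.add_constant(x)).fit(disp=0, maxiter=200)
            probs = res.predict(sm.add_constant(x))
            if not np.all(np.isfinite(res.params)):
                probs = None
        except Exception:
            probs = None
    if probs is None:
        warnings.warn(
            "logistic fit did not converge (separation?); using rank AUROC of dose",
            stacklevel=2,
        )
        probs = x

    auc = float(roc_auc_score(y, probs))

    # cross-class tied-dose pairs, for the estimate's bookkeeping
    df = pd.DataFrame({"x": x, "y": y})
    counts = df.groupby("x")["y"].agg(["sum", "count"])
    n_tied = int((counts["sum"] * (counts["count"] - counts["sum"])).sum())
    n1 = int(y.sum())
    return ConcordanceEstimate(
        value=auc, n_pairs=n1 * (len(y) - n1), n_tied=n_tied, endpoint="day21"
    )


def concordance_table(cohort: pd.DataFrame) -> pd.DataFrame:
    """Concordance of each dose metric with recovery, overall and by stratum.

    Returns a tidy table with one row per (metric, stratum, endpoint):
    3 metrics x {all, extreme, normal} x {interval, day21}.  Cells whose
    estimate is undefined (e.g. an empty stratum) hold NaN.
    """
    if "lbm_bw_stratum" not in cohort.columns:
        cohort = add_dose_columns(cohort)
    strata = {
        "all": np.ones(len(cohort), dtype=bool),
        "extreme": (cohort["lbm_bw_stratum"] == "extreme").to_numpy(),
        "normal": (cohort["lbm_bw_stratum"] == "normal").to_numpy(),
    }
    rows = []
    for metric, col in DOSE_COLUMNS.items():
        dose = cohort[col].to_numpy(float)
        for stratum, sel in strata.items():
            sub = cohort[sel]
            d = dose[sel]
            # interval endpoint: all rows, deaths censored at death time
            try:
                est = harrell_c(
                    sub["time_days"], sub["event"] == "recovered", d
                )
                rows.append((metric, stratum, "interval", len(sub), est.value))
            except ValueError:
                rows.append((metric, stratum, "interval", len(sub), np.nan))
            # day-21 endpoint: deaths excluded
            try:
                labels, mask = day21_labels(sub)
                est = logistic_concordance(labels, d[mask.to_numpy()])
                rows.append((metric, stratum, "day21", int(mask.sum()), est.value))
            except ValueError:
                rows.append((metric, stratum, "day21", int(mask.sum()) if len(sub) else 0, np.nan))
    return pd.DataFrame(
        rows, columns=["metric", "stratum", "endpoint", "n", "concordance"]
    )
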