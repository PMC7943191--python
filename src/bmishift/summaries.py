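"""Survey-weighted stratum summaries and inclusion filtering.

A stratum is one study x sex x 10-year age band. Each gets a weighted mean
BMI, a (design-effect-free) standard error, and weighted prevalences of
underweight (BMI < 18.5), obesity (BMI >= 30) and severe obesity (BMI >= 35).
Strata enter the probit regression only if they have at least 25 participants,
a standard 10-year age band within 20-79 years, and an outcome prevalence
strictly between 0 and 1 (the probit transform is undefined at the
boundaries); filtering is applied per outcome.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .constants import AGE_BANDS, OUTCOMES

logger = logging.getLogger(__name__)

SUMMARY_COLUMNS = [
    "study_id",
    "region",
    "sex",
    "age_group",
    "year",
    "n",
    "mean_bmi",
    "se_mean",
    "prev_underweight",
    "prev_obesity",
    "prev_severe_obesity",
]


def _check_inputs(values: np.ndarray, weights: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if values.size == 0:
        raise ValueError("empty input")
    if values.shape != weights.shape:
        raise ValueError("values and weights must have equal length")
    if np.any(weights <= 0) or not np.all(np.isfinite(weights)):
        raise ValueError("weights must be positive and finite")
    return values, weights


def weighted_mean(values, weights) -> float:
    """Weighted mean sum(w x)/sum(w); invariant to rescaling the weights."""
    values, weights = _check_inputs(values, weights)
    return float(np.average(values, weights=weights))


def weighted_prevalence(values, weights, threshold: float, tail: str) -> float:
    """Weighted fraction below (strict) or at-or-above a BMI threshold.

    A value exactly at the threshold counts only in ``at_or_above``, matching
    the closed lower bounds of the obesity cutoffs and the strict upper bound
    of the underweight cutoff.
    """
    values, weights = _check_inputs(values, weights)
    if tail == "below":
        ind = values < threshold
    elif tail == "at_or_above":
        ind = values >= threshold
    else:
        raise ValueError(f"tail must be 'below' or 'at_or_above', got {tail!r}")
    return float(np.average(ind, weights=weights))


def _weighted_se_mean(values: np.ndarray, weights: np.ndarray) -> float:
    # weighted SD / sqrt(n); no design-effect correction
    m = np.average(values, weights=weights)
    var = np.average((values - m) ** 2, weights=weights)
    return float(np.sqrt(var / len(values)))


def summarise_study(microdata: pd.DataFrame) -> pd.DataFrame:
    """One summary row per sex x age band present in a study's microdata.

    Expects the microdata columns ``study_id, region, sex, age_group, year,
    bmi, weight``; empty strata simply yield no row.
    """
    required = {"study_id", "region", "sex", "age_group", "year", "bmi", "weight"}
    missing = required - set(microdata.columns)
    if missing:
        raise ValueError(f"microdata missing columns: {sorted(missing)}")
    rows = []
    for (study, sex, age), grp in microdata.groupby(
        ["study_id", "sex", "age_group"], sort=True, observed=True
    ):
        bmi = grp["bmi"].to_numpy(float)
        w = grp["weight"].to_numpy(float)
        if bmi.size == 0:  # pragma: no cover - groupby drops empty groups
            logger.info("empty stratum %s/%s/%s omitted", study, sex, age)
            continue
        row = {
            "study_id": study,
            "region": grp["region"].iloc[0],
            "sex": sex,
            "age_group": age,
            "year": int(grp["year"].iloc[0]),
            "n": int(bmi.size),
            "mean_bmi": weighted_mean(bmi, w),
            "se_mean": _weighted_se_mean(bmi, w),
        }
        for outcome, (threshold, tail) in OUTCOMES.items():
            row[f"prev_{outcome}"] = weighted_prevalence(bmi, w, threshold, tail)
        rows.append(row)
    return pd.DataFrame(rows, columns=SUMMARY_COLUMNS)


def summarise_stratum_arrays(bmi: np.ndarray, weights: np.ndarray) -> dict[str, float]:
    """Summary statistics for one stratum given raw arrays (no labels).

    Fast path used by the simulation pipeline to avoid materialising microdata
    frames; numerically identical to :func:`summarise_study` on one stratum.
    """
    out = {
        "n": int(len(bmi)),
        "mean_bmi": weighted_mean(bmi, weights),
        "se_mean": _weighted_se_mean(np.asarray(bmi, float), np.asarray(weights, float)),
    }
    for outcome, (threshold, tail) in OUTCOMES.items():
        out[f"prev_{outcome}"] = weighted_prevalence(bmi, weights, threshold, tail)
    return out


def apply_inclusion_filters(
    summaries: pd.DataFrame, outcome: str, min_n: int = 25
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the stratum inclusion rules for one outcome.

    Rules, in fixed precedence (one logged reason per dropped row):

    1. ``non_standard_age_band`` — age band not one of the six 10-year bands
       spanning 20-79;
    2. ``n<25`` — fewer than ``min_n`` participants;
    3. ``boundary_prevalence`` — outcome prevalence exactly 0 or 1, which the
       probit transform cannot represent.

    Returns the included table and an exclusion log. Filtering is total and
    idempotent.
    """
    if outcome not in OUTCOMES:
        raise ValueError(f"unknown outcome: {outcome!r}")
    prev_col = f"prev_{outcome}"
    summaries = summaries.reset_index(drop=True)
    band_ok = summaries["age_group"].isin(AGE_BANDS)
    n_ok = summaries["n"] >= min_n
    p = summaries[prev_col]
    prev_ok = (p > 0.0) & (p < 1.0)

    reason = np.where(
        ~band_ok,
        "non_standard_age_band",
        np.where(~n_ok, f"n<{min_n}", np.where(~prev_ok, "boundary_prevalence", "")),
    )
    excluded = reason != ""
    log = summaries.loc[excluded, ["study_id", "sex", "age_group", "year"]].copy()
    log["outcome"] = outcome
    log["reason"] = reason[excluded]
    included = summaries.loc[~excluded].reset_index(drop=True)
    return included, log.reset_index(drop=True)
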