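"""Counterfactual decomposition of 1985->2016 prevalence change.

The fitted probit model predicts prevalence from mean BMI and year (with age
and region structure). The total change in a stratum is the prediction at the
2016 mean and year 2016 minus the prediction at the 1985 mean and year 1985.
Holding the year terms at 1985 while moving the mean to its 2016 value yields
the change attributable to the mean-BMI shift alone; the remainder — carried
by the model's year terms — reflects change in the shape of the BMI
distribution relative to its mean. The two parts sum to the total exactly, at
every stratum and after age aggregation.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .constants import BROAD_BANDS, OUTCOMES, REGIONS, standard_population_weights
from .model import CoefficientTable, predict_prevalence

RESULT_COLUMNS = [
    "region",
    "sex",
    "band",
    "outcome",
    "total_change_pp",
    "mean_contribution_pp",
    "shape_residual_pp",
]


def decompose_stratum(
    coef: CoefficientTable,
    trajectory_row: Mapping,
    year_start: int = 1985,
    year_end: int = 2016,
) -> dict:
    """Shift/shape split of the prevalence change for one region x sex x age band.

    ``trajectory_row`` must carry ``region, sex, age_group, mean_1985,
    mean_2016``. All changes are in percentage points; the shape residual is
    defined as total minus mean contribution, so additivity is exact.
    """
    region = trajectory_row["region"]
    age = trajectory_row["age_group"]
    if trajectory_row.get("sex", coef.sex) != coef.sex:
        raise ValueError(
            f"trajectory sex {trajectory_row['sex']!r} does not match model sex {coef.sex!r}"
        )
    m0 = float(trajectory_row[f"mean_{year_start}"])
    m1 = float(trajectory_row[f"mean_{year_end}"])
    p_start = predict_prevalence(coef, m0, age, region, year_start)
    p_end = predict_prevalence(coef, m1, age, region, year_end)
    p_counterfactual = predict_prevalence(coef, m1, age, region, year_start)
    total = 100.0 * (p_end - p_start)
    mean_part = 100.0 * (p_counterfactual - p_start)
    return {
        "region": region,
        "sex": coef.sex,
        "band": age,
        "outcome": coef.outcome,
        "total_change_pp": total,
        "mean_contribution_pp": mean_part,
        "shape_residual_pp": total - mean_part,
    }


def percent_explained(
    total_change_pp: float, mean_contribution_pp: float, min_abs_change: float = 1.0
) -> float:
    """Share (%) of the total change explained by the mean shift.

    Reported only when the total change is at least ``min_abs_change``
    percentage points in magnitude (default 1.0); smaller changes are too
    small for the split to be epidemiologically meaningful and return NaN.
    """
    if abs(total_change_pp) < min_abs_change:
        return float("nan")
    return 100.0 * mean_contribution_pp / total_change_pp


def aggregate_age_bands(
    results: pd.DataFrame, weights: Mapping[str, float] | None = None
) -> pd.DataFrame:
    """Aggregate 10-year-band results into the broad bands 20-49 and 50-79.

    Each component (total, mean contribution, shape residual) is the
    standard-population weighted average of the constituent band values, so
    additivity survives aggregation exactly. Every constituent band must be
    present for every region x sex x outcome.
    """
    if weights is None:
        weights = standard_population_weights()
    rows = []
    for (region, sex, outcome), grp in results.groupby(
        ["region", "sex", "outcome"], sort=True, observed=True
    ):
        by_band = grp.set_index("band")
        for broad, bands in BROAD_BANDS.items():
            missing = [b for b in bands if b not in by_band.index]
            if missing:
                raise ValueError(
                    f"missing age band(s) {missing} for ({region}, {sex}, {outcome})"
                )
            w = np.array([weights[b] for b in bands])
            w = w / w.sum()
            row = {"region": region, "sex": sex, "band": broad, "outcome": outcome}
            for col in ("total_change_pp", "mean_contribution_pp", "shape_residual_pp"):
                row[col] = float(w @ by_band.loc[list(bands), col].to_numpy())
            rows.append(row)
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def run_decomposition(
    coefs: Mapping[tuple[str, str], CoefficientTable],
    trajectories: pd.DataFrame,
    weights: Mapping[str, float] | None = None,
    min_abs_change: float = 1.0,
    include_detail: bool = False,
    year_start: int = 1985,
    year_end: int = 2016,
) -> pd.DataFrame:
    """Decompose every region x sex x outcome and aggregate to broad bands.

    ``coefs`` maps ``(sex, outcome)`` to a fitted coefficient table;
    ``trajectories`` is the mean-BMI endpoint table (one row per region x sex
    x 10-year band). Returns broad-band rows (108 for the full grid), plus the
    10-year detail when ``include_detail``; each row carries
    ``percent_explained`` (NaN when the total change is below the relevance
    threshold).
    """
    detail_rows = []
    for (sex, outcome), coef in sorted(coefs.items()):
        if coef.sex != sex or coef.outcome != outcome:
            raise ValueError(f"coefficient table mismatched with key {(sex, outcome)}")
        traj = trajectories[trajectories["sex"] == sex]
        for _, row in traj.iterrows():
            detail_rows.append(
                decompose_stratum(coef, row, year_start=year_start, year_end=year_end)
            )
    detail = pd.DataFrame(detail_rows, columns=RESULT_COLUMNS)
    broad = aggregate_age_bands(detail, weights=weights)
    out = pd.concat([broad, detail], ignore_index=True) if include_detail else broad
    out["percent_explained"] = [
        percent_explained(t, m, min_abs_change)
        for t, m in zip(out["total_change_pp"], out["mean_contribution_pp"])
    ]
    order = {r: i for i, r in enumerate(REGIONS)}
    out = out.sort_values(
        ["outcome", "sex", "region", "band"],
        key=lambda s: s.map(order) if s.name == "region" else s,
        kind="stable",
    ).reset_index(drop=True)
    return out
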