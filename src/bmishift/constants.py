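"""Region, sex, age-band and outcome vocabularies shared across the package.

The nine world regions and the six 10-year adult age bands follow the
convention of the NCD Risk Factor Collaboration pooled analyses of
cardiometabolic risk factors.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

REGIONS: tuple[str, ...] = (
    "Central and Eastern Europe",
    "Central Asia, the Middle East, and North Africa",
    "East and Southeast Asia",
    "High-income Asia Pacific",
    "High-income Western",
    "Latin America and the Caribbean",
    "Oceania",
    "South Asia",
    "Sub-Saharan Africa",
)

SEXES: tuple[str, ...] = ("female", "male")

AGE_BANDS: tuple[str, ...] = ("20-29", "30-39", "40-49", "50-59", "60-69", "70-79")

BROAD_BANDS: dict[str, tuple[str, ...]] = {
    "20-49": ("20-29", "30-39", "40-49"),
    "50-79": ("50-59", "60-69", "70-79"),
}

YEAR_MIN = 1985
YEAR_MAX = 2019

UNDERWEIGHT_THRESHOLD = 18.5  # kg/m^2, strict below
OBESITY_THRESHOLD = 30.0  # kg/m^2, at or above
SEVERE_OBESITY_THRESHOLD = 35.0  # kg/m^2, at or above

#: outcome name -> (BMI threshold in kg/m^2, tail)
OUTCOMES: dict[str, tuple[float, str]] = {
    "underweight": (UNDERWEIGHT_THRESHOLD, "below"),
    "obesity": (OBESITY_THRESHOLD, "at_or_above"),
    "severe_obesity": (SEVERE_OBESITY_THRESHOLD, "at_or_above"),
}

# WHO World Standard population (Ahmad et al. 2001), 5-year shares summed into
# 10-year bands, in percent of the full standard population.
WHO_STANDARD_10YR_PCT: dict[str, float] = {
    "20-29": 16.15,  # 8.22 + 7.93
    "30-39": 14.76,  # 7.61 + 7.15
    "40-49": 12.63,  # 6.59 + 6.04
    "50-59": 9.92,   # 5.37 + 4.55
    "60-69": 6.68,   # 3.72 + 2.96
    "70-79": 3.73,   # 2.21 + 1.52
}


def standard_population_weights(path: str | Path | None = None) -> dict[str, float]:
    """Age-band weights normalised within each broad band (20-49 and 50-79).

    Parameters
    ----------
    path
        Optional CSV with columns ``age_band, weight`` overriding the embedded
        WHO World Standard shares. Weights need not be pre-normalised.

    Returns
    -------
    dict mapping each 10-year band to its weight; weights sum to 1 within
    each broad band.
    """
    if path is None:
        raw = dict(WHO_STANDARD_10YR_PCT)
    else:
        tab = pd.read_csv(path)
        missing = {"age_band", "weight"} - set(tab.columns)
        if missing:
            raise ValueError(f"weight table missing columns: {sorted(missing)}")
        raw = dict(zip(tab["age_band"].astype(str), tab["weight"].astype(float)))
    out: dict[str, float] = {}
    for broad, bands in BROAD_BANDS.items():
        absent = [b for b in bands if b not in raw]
        if absent:
            raise ValueError(f"weight table missing age bands {absent} for {broad}")
        total = sum(raw[b] for b in bands)
        if total <= 0 or any(raw[b] <= 0 for b in bands):
            raise ValueError(f"weights must be positive within band {broad}")
        for b in bands:
            out[b] = raw[b] / total
    return out
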