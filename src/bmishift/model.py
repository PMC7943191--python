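"""Probit-scale regression of stratum prevalence on population mean BMI.

For each sex x outcome, probit-transformed stratum prevalence is regressed on
centred mean BMI, age band, region and calendar year, with pairwise
interactions mean-BMI x age, mean-BMI x region, age x region, age x year and
year x region. Probit-transformed prevalence is approximately linear in the
population mean when the distribution translates at fixed shape (exactly
linear for a normal population), which is what makes the linear model a good
description and the year terms a probe of residual shape change.

Age and region use treatment (reference-level) coding; predictions are
invariant to the reference choice because every interaction group spans the
same column space under any coding.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .constants import AGE_BANDS, OUTCOMES, REGIONS

__all__ = [
    "ModelSpec",
    "CoefficientTable",
    "SingularFitError",
    "probit",
    "inverse_probit",
    "term_names",
    "build_design",
    "fit_model",
    "predict_prevalence",
    "save_coefficients",
    "load_coefficients",
    "regional_prevalence_profile",
    "unit_bmi_relative_change",
]


class SingularFitError(RuntimeError):
    """Design matrix is rank deficient after dropping empty columns."""


def probit(p):
    """Inverse standard-normal CDF of a proportion in the open interval (0, 1)."""
    arr = np.asarray(p, dtype=float)
    if np.any(arr <= 0.0) or np.any(arr >= 1.0):
        raise ValueError("probit requires 0 < p < 1; boundary strata must be filtered")
    out = stats.norm.ppf(arr)
    return float(out) if np.isscalar(p) else out


def inverse_probit(z):
    """Standard-normal CDF; inverse of :func:`probit`."""
    arr = np.asarray(z, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("inverse_probit requires finite input")
    out = stats.norm.cdf(arr)
    return float(out) if np.isscalar(z) else out


@dataclass(frozen=True)
class ModelSpec:
    """Coding and centring choices for one sex x outcome regression."""

    outcome: str
    sex: str
    reference_region: str = REGIONS[0]
    reference_age: str = AGE_BANDS[0]
    year_origin: int = 1985
    bmi_center: float = 25.0
    weighted: bool = False  # inverse-variance weights from delta-method var of probit(p)

    def __post_init__(self) -> None:
        if self.outcome not in OUTCOMES:
            raise ValueError(f"unknown outcome: {self.outcome!r}")
        if self.reference_region not in REGIONS:
            raise ValueError(f"unknown reference region: {self.reference_region!r}")
        if self.reference_age not in AGE_BANDS:
            raise ValueError(f"unknown reference age band: {self.reference_age!r}")

    @property
    def nonref_ages(self) -> list[str]:
        return [a for a in AGE_BANDS if a != self.reference_age]

    @property
    def nonref_regions(self) -> list[str]:
        return [r for r in REGIONS if r != self.reference_region]


def term_names(spec: ModelSpec) -> list[str]:
    """Deterministic column order of the full design (82 terms)."""
    ages, regions = spec.nonref_ages, spec.nonref_regions
    terms = ["intercept", "mean_bmi"]
    terms += [f"age[{a}]" for a in ages]
    terms += [f"region[{r}]" for r in regions]
    terms += ["year"]
    terms += [f"mean_bmi:age[{a}]" for a in ages]
    terms += [f"mean_bmi:region[{r}]" for r in regions]
    terms += [f"age[{a}]:region[{r}]" for a in ages for r in regions]
    terms += [f"age[{a}]:year" for a in ages]
    terms += [f"year:region[{r}]" for r in regions]
    return terms


def _design_matrix(
    region: np.ndarray, age: np.ndarray, year: np.ndarray, mean_bmi: np.ndarray, spec: ModelSpec
) -> np.ndarray:
    unknown_r = set(region) - set(REGIONS)
    if unknown_r:
        raise ValueError(f"unknown region level(s): {sorted(unknown_r)}")
    unknown_a = set(age) - set(AGE_BANDS)
    if unknown_a:
        raise ValueError(f"unknown age band(s): {sorted(unknown_a)}")
    b = mean_bmi.astype(float) - spec.bmi_center
    t = year.astype(float) - spec.year_origin
    a_ind = [(age == a).astype(float) for a in spec.nonref_ages]
    r_ind = [(region == r).astype(float) for r in spec.nonref_regions]
    cols = [np.ones(len(b)), b]
    cols += a_ind + r_ind + [t]
    cols += [b * ai for ai in a_ind]
    cols += [b * ri for ri in r_ind]
    cols += [ai * ri for ai in a_ind for ri in r_ind]
    cols += [ai * t for ai in a_ind]
    cols += [t * ri for ri in r_ind]
    return np.column_stack(cols)


def build_design(summaries: pd.DataFrame, spec: ModelSpec):
    """Design matrix and probit response for an included stratum-summary table.

    Returns ``(X, y, terms)`` with deterministic column order. The table must
    already have passed :func:`~bmishift.summaries.apply_inclusion_filters`
    for ``spec.outcome`` (boundary prevalences raise).
    """
    X = _design_matrix(
        summaries["region"].to_numpy(),
        summaries["age_group"].to_numpy(),
        summaries["year"].to_numpy(),
        summaries["mean_bmi"].to_numpy(),
        spec,
    )
    y = probit(summaries[f"prev_{spec.outcome}"].to_numpy(float))
    return X, y, term_names(spec)


@dataclass
class CoefficientTable:
    """Fitted terms of one probit-scale regression plus fit diagnostics."""

    outcome: str
    sex: str
    reference_region: str
    reference_age: str
    year_origin: int
    bmi_center: float
    estimates: pd.Series  # indexed by the full term list; dropped terms carry 0.0
    dropped: tuple[str, ...] = ()
    r_squared: float = np.nan
    n_obs: int = 0
    df_resid: int = 0

    def spec(self) -> ModelSpec:
        return ModelSpec(
            outcome=self.outcome,
            sex=self.sex,
            reference_region=self.reference_region,
            reference_age=self.reference_age,
            year_origin=self.year_origin,
            bmi_center=self.bmi_center,
        )


def _collinear_terms(X: np.ndarray, terms: list[str]) -> list[str]:
    # QR with column pivoting: columns whose R diagonal collapses are the culprits
    from scipy.linalg import qr

    _, R, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    bad = piv[np.where(diag < tol)[0]] if diag.size else []
    return [terms[i] for i in bad]


def fit_model(summaries: pd.DataFrame, spec: ModelSpec) -> CoefficientTable:
    """Least-squares fit of probit prevalence on the full interaction design.

    Columns that are identically zero for the supplied table (absent levels)
    are dropped and recorded; a genuinely rank-deficient design raises
    :class:`SingularFitError` naming the collinear terms. With
    ``spec.weighted`` the fit is inverse-variance weighted using the
    delta-method variance of the probit-transformed prevalence,
    p(1-p) / (n phi(z)^2).
    """
    X, y, terms = build_design(summaries, spec)
    keep = np.ptp(X, axis=0) != 0
    keep[0] = True  # intercept
    dropped = tuple(t for t, k in zip(terms, keep) if not k)
    Xk = X[:, keep]
    kept_terms = [t for t, k in zip(terms, keep) if k]
    if Xk.shape[0] < Xk.shape[1]:
        raise SingularFitError(
            f"{Xk.shape[0]} strata cannot identify {Xk.shape[1]} terms"
        )
    if np.linalg.matrix_rank(Xk) < Xk.shape[1]:
        raise SingularFitError(
            "design is rank deficient; collinear terms: "
            + ", ".join(_collinear_terms(Xk, kept_terms))
        )
    if spec.weighted:
        p = summaries[f"prev_{spec.outcome}"].to_numpy(float)
        n = summaries["n"].to_numpy(float)
        var = p * (1.0 - p) / (n * stats.norm.pdf(y) ** 2)
        res = sm.WLS(y, Xk, weights=1.0 / var).fit()
    else:
        res = sm.OLS(y, Xk).fit()
    if np.ptp(y) == 0:
        warnings.warn("constant probit response; R^2 reported as 0", stacklevel=2)
        r2 = 0.0
    else:
        r2 = float(res.rsquared)
    estimates = pd.Series(0.0, index=terms, name="estimate")
    estimates[kept_terms] = res.params
    return CoefficientTable(
        outcome=spec.outcome,
        sex=spec.sex,
        reference_region=spec.reference_region,
        reference_age=spec.reference_age,
        year_origin=spec.year_origin,
        bmi_center=spec.bmi_center,
        estimates=estimates,
        dropped=dropped,
        r_squared=r2,
        n_obs=int(Xk.shape[0]),
        df_resid=int(res.df_resid),
    )


def linear_predictor(
    coef: CoefficientTable, mean_bmi: float, age_group: str, region: str, year: float
) -> float:
    """Probit-scale prediction for one covariate combination."""
    spec = coef.spec()
    x = _design_matrix(
        np.array([region]), np.array([age_group]), np.array([float(year)]),
        np.array([float(mean_bmi)]), spec,
    )
    return float((x @ coef.estimates.to_numpy())[0])


def predict_prevalence(
    coef: CoefficientTable, mean_bmi: float, age_group: str, region: str, year: float
) -> float:
    """Predicted prevalence (proportion) at the given mean BMI and covariates."""
    return inverse_probit(linear_predictor(coef, mean_bmi, age_group, region, year))


# ---------------------------------------------------------------------------
# worked-example helpers
# ---------------------------------------------------------------------------

def regional_prevalence_profile(
    coef: CoefficientTable, mean_bmi: float, age_group: str, year: float
) -> pd.Series:
    """Predicted prevalence by region at a common mean BMI, age band and year.

    The max-min of this profile (x100) is the regional spread in percentage
    points at that mean level.
    """
    return pd.Series(
        {r: predict_prevalence(coef, mean_bmi, age_group, r, year) for r in REGIONS},
        name=coef.outcome,
    )


def unit_bmi_relative_change(
    coef: CoefficientTable, mean_bmi: float, age_group: str, region: str, year: float
) -> float:
    """Relative change (%) in predicted prevalence for a 1 kg/m^2 rise in mean BMI."""
    p0 = predict_prevalence(coef, mean_bmi, age_group, region, year)
    p1 = predict_prevalence(coef, mean_bmi + 1.0, age_group, region, year)
    return 100.0 * (p1 - p0) / p0


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

_HEADER_FIELDS = [
    "outcome",
    "sex",
    "reference_region",
    "reference_age",
    "year_origin",
    "bmi_center",
    "r_squared",
    "n_obs",
    "df_resid",
    "dropped",
]


def save_coefficients(coef: CoefficientTable, path) -> None:
    """Write a coefficient table as CSV with a commented header block."""
    with open(path, "w") as fh:
        for name in _HEADER_FIELDS:
            value = getattr(coef, name) if name != "dropped" else ";".join(coef.dropped)
            fh.write(f"# {name}: {value}\n")
        coef.estimates.rename_axis("term").to_csv(fh)


def load_coefficients(path) -> CoefficientTable:
    """Read a coefficient CSV written by :func:`save_coefficients`.

    Missing terms raise; unknown extra terms are ignored with a warning, so a
    hand-edited or externally supplied table can still be used as long as it
    covers the full design.
    """
    header: dict[str, str] = {}
    body = io.StringIO()
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                key, _, value = line[1:].partition(":")
                header[key.strip()] = value.strip()
            else:
                body.write(line)
    body.seek(0)
    table = pd.read_csv(body)
    if not {"term", "estimate"} <= set(table.columns):
        raise ValueError("coefficient file must have 'term' and 'estimate' columns")
    spec = ModelSpec(
        outcome=header.get("outcome", ""),
        sex=header.get("sex", ""),
        reference_region=header.get("reference_region", REGIONS[0]),
        reference_age=header.get("reference_age", AGE_BANDS[0]),
        year_origin=int(header.get("year_origin", 1985)),
        bmi_center=float(header.get("bmi_center", 25.0)),
    )
    expected = term_names(spec)
    got = pd.Series(
        table["estimate"].to_numpy(float), index=table["term"].astype(str), name="estimate"
    )
    missing = [t for t in expected if t not in got.index]
    if missing:
        raise ValueError(f"coefficient file missing terms: {missing}")
    extra = [t for t in got.index if t not in expected]
    if extra:
        warnings.warn(f"ignoring unknown terms: {extra}", stacklevel=2)
    estimates = got.reindex(expected)
    estimates.index.name = None
    if not np.all(np.isfinite(estimates.to_numpy())):
        raise ValueError("non-finite estimates in coefficient file")
    dropped = tuple(t for t in header.get("dropped", "").split(";") if t)
    return CoefficientTable(
        outcome=spec.outcome,
        sex=spec.sex,
        reference_region=spec.reference_region,
        reference_age=spec.reference_age,
        year_origin=spec.year_origin,
        bmi_center=spec.bmi_center,
        estimates=estimates,
        dropped=dropped,
        r_squared=float(header.get("r_squared", "nan")),
        n_obs=int(header.get("n_obs", 0)),
        df_resid=int(header.get("df_resid", 0)),
    )
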