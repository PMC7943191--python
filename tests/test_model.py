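"""Probit link, design construction, fitting, prediction, persistence."""

import dataclasses
import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from bmishift import (
    AGE_BANDS,
    REGIONS,
    ModelSpec,
    SingularFitError,
    apply_inclusion_filters,
    build_design,
    fit_model,
    inverse_probit,
    load_coefficients,
    predict_prevalence,
    probit,
    save_coefficients,
    term_names,
)
from conftest import noiseless_strata, normal_params


class TestLink:
    def test_probit_examples(self):
        assert probit(0.5) == pytest.approx(0.0, abs=1e-12)
        assert probit(0.975) == pytest.approx(1.959964, abs=1e-6)
        assert inverse_probit(0.0) == pytest.approx(0.5, abs=1e-12)
        assert inverse_probit(-1.625) == pytest.approx(0.052081, abs=1e-6)

    @pytest.mark.parametrize("p", [0.01, 0.3, 0.9])
    def test_round_trip_identity(self, p):
        assert inverse_probit(probit(p)) == pytest.approx(p, abs=1e-12)

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.1, 1.1])
    def test_probit_domain(self, bad):
        with pytest.raises(ValueError):
            probit(bad)

    def test_inverse_probit_requires_finite(self):
        with pytest.raises(ValueError):
            inverse_probit(np.inf)


def closed_form_strata(n_strata: int = 200) -> pd.DataFrame:
    """Noiseless strata from normal BMI populations, sigma 4, means over 20-30."""
    means = np.linspace(20.0, 30.0, n_strata)
    return noiseless_strata(normal_params(m) for m in means)


class TestDesign:
    def test_full_design_has_82_terms(self):
        spec = ModelSpec(outcome="obesity", sex="female")
        assert len(term_names(spec)) == 82

    def test_reference_level_collapse(self):
        # single region/age/year at the references: only intercept and the
        # centred mean-BMI column vary
        strata = closed_form_strata(10)
        spec = ModelSpec(
            outcome="underweight", sex="female",
            reference_region="South Asia", reference_age="50-59",
        )
        X, y, terms = build_design(strata, spec)
        nonzero = [t for t, col in zip(terms, X.T) if np.ptp(col) != 0 or col[0] != 0]
        assert nonzero == ["intercept", "mean_bmi"]
        assert len(y) == 10

    def test_centering(self):
        strata = noiseless_strata([normal_params(25.0)])
        X, _, terms = build_design(strata, ModelSpec(outcome="underweight", sex="female"))
        assert X[0, terms.index("mean_bmi")] == pytest.approx(0.0, abs=1e-12)

    def test_unknown_level_rejected(self):
        strata = closed_form_strata(5)
        strata.loc[0, "region"] = "Atlantis"
        with pytest.raises(ValueError, match="Atlantis"):
            build_design(strata, ModelSpec(outcome="underweight", sex="female"))


class TestClosedFormRecovery:
    """For normal BMI with common sigma, probit prevalence is exactly linear in
    the mean with slope -1/sigma (underweight) or +1/sigma (obesity)."""

    @pytest.mark.parametrize(
        "outcome,expected_slope",
        [("underweight", -0.25), ("obesity", 0.25), ("severe_obesity", 0.25)],
    )
    def test_slope(self, outcome, expected_slope):
        spec = ModelSpec(
            outcome=outcome, sex="female",
            reference_region="South Asia", reference_age="50-59",
        )
        coef = fit_model(closed_form_strata(), spec)
        assert coef.estimates["mean_bmi"] == pytest.approx(expected_slope, abs=1e-6)
        assert coef.r_squared > 1 - 1e-10

    def test_predictions_match_analytic_prevalence(self):
        spec = ModelSpec(
            outcome="underweight", sex="female",
            reference_region="South Asia", reference_age="50-59",
        )
        coef = fit_model(closed_form_strata(), spec)
        p = predict_prevalence(coef, 25.0, "50-59", "South Asia", 1985)
        assert p == pytest.approx(0.052081, abs=1e-6)
        for m in (21.0, 24.0, 29.0):
            assert predict_prevalence(coef, m, "50-59", "South Asia", 1985) == pytest.approx(
                stats.norm.cdf((18.5 - m) / 4.0), abs=1e-6
            )

    def test_obesity_prediction_monotone_in_mean(self):
        spec = ModelSpec(
            outcome="obesity", sex="female",
            reference_region="South Asia", reference_age="50-59",
        )
        coef = fit_model(closed_form_strata(), spec)
        grid = np.linspace(20.0, 35.0, 40)
        preds = [predict_prevalence(coef, m, "50-59", "South Asia", 1985) for m in grid]
        assert np.all(np.diff(preds) > 0)


@pytest.fixture(scope="module")
def grid_fit(fixture_data):
    summaries, _ = fixture_data
    females = summaries[summaries["sex"] == "female"]
    included, _ = apply_inclusion_filters(females, "obesity")
    spec = ModelSpec(outcome="obesity", sex="female")
    return included, fit_model(included, spec)


class TestFitOnFullGrid:
    def test_no_terms_dropped_on_full_grid(self, grid_fit):
        _, coef = grid_fit
        assert coef.dropped == ()
        assert len(coef.estimates) == 82
        assert np.all(np.isfinite(coef.estimates))

    def test_coding_invariance_of_predictions(self, grid_fit):
        included, coef = grid_fit
        alt = fit_model(
            included,
            ModelSpec(
                outcome="obesity", sex="female",
                reference_region=REGIONS[5], reference_age=AGE_BANDS[3],
            ),
        )
        for region in (REGIONS[0], REGIONS[5], REGIONS[8]):
            for mean in (23.0, 27.5):
                a = predict_prevalence(coef, mean, "30-39", region, 2010)
                b = predict_prevalence(alt, mean, "30-39", region, 2010)
                assert a == pytest.approx(b, abs=1e-10)

    def test_weighted_fit_close_to_unweighted_on_clean_data(self):
        spec = ModelSpec(
            outcome="underweight", sex="female", weighted=True,
            reference_region="South Asia", reference_age="50-59",
        )
        coef = fit_model(closed_form_strata(), spec)
        assert coef.estimates["mean_bmi"] == pytest.approx(-0.25, abs=1e-6)

    def test_too_few_rows_rejected(self, fixture_data):
        summaries, _ = fixture_data
        few = summaries[summaries["sex"] == "female"].head(8)
        with pytest.raises(SingularFitError):
            fit_model(few, ModelSpec(outcome="obesity", sex="female"))

    def test_constant_response_gives_zero_r2(self):
        strata = closed_form_strata(30)
        strata["prev_underweight"] = 0.1
        spec = ModelSpec(
            outcome="underweight", sex="female",
            reference_region="South Asia", reference_age="50-59",
        )
        with pytest.warns(UserWarning, match="constant"):
            coef = fit_model(strata, spec)
        assert coef.r_squared == 0.0


class TestMeanMedianCorrelation:
    def test_high_correlation_for_moderate_skew(self):
        # mean and median track each other closely for |shape| <= 3
        rng = np.random.default_rng(0)
        means, medians = [], []
        for _ in range(300):
            loc = rng.uniform(18, 32)
            scale = rng.uniform(2.5, 6)
            shape = rng.uniform(-3, 3)
            delta = shape / np.sqrt(1 + shape**2)
            means.append(loc + scale * delta * np.sqrt(2 / np.pi))
            medians.append(stats.skewnorm.ppf(0.5, shape, loc=loc, scale=scale))
        assert np.corrcoef(means, medians)[0, 1] >= 0.98


class TestPersistence:
    @pytest.fixture()
    def coef(self):
        spec = ModelSpec(
            outcome="underweight", sex="female",
            reference_region="South Asia", reference_age="50-59",
        )
        return fit_model(closed_form_strata(50), spec)

    def test_round_trip(self, coef, tmp_path):
        path = tmp_path / "coef.csv"
        save_coefficients(coef, path)
        loaded = load_coefficients(path)
        pd.testing.assert_series_equal(loaded.estimates, coef.estimates)
        assert loaded.outcome == coef.outcome
        assert loaded.sex == coef.sex
        assert loaded.r_squared == pytest.approx(coef.r_squared)
        assert loaded.dropped == coef.dropped

    def test_missing_term_rejected(self, coef, tmp_path):
        path = tmp_path / "coef.csv"
        save_coefficients(coef, path)
        text = path.read_text().replace("mean_bmi,", "renamed_term,", 1)
        path.write_text(text)
        with pytest.raises(ValueError, match="missing terms"):
            load_coefficients(path)

    def test_extra_term_warns_and_is_ignored(self, coef, tmp_path):
        path = tmp_path / "coef.csv"
        save_coefficients(coef, path)
        with open(path, "a") as fh:
            fh.write("mystery_term,0.123\n")
        with pytest.warns(UserWarning, match="mystery_term"):
            loaded = load_coefficients(path)
        assert "mystery_term" not in loaded.estimates.index
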