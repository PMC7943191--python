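import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from bmishift import ScenarioConfig, StratumParams, make_fixtures
from bmishift.synthetic import analytic_summary

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow], deadline=None
)
settings.load_profile("ci")


def normal_params(mean: float, scale: float = 4.0, **kw) -> StratumParams:
    """Normal (shape 0) stratum centred on ``mean``; location equals the mean."""
    defaults = dict(
        region="South Asia", sex="female", age_group="50-59", year=1985,
        location=mean, scale=scale, shape=0.0,
    )
    defaults.update(kw)
    return StratumParams(**defaults)


def noiseless_strata(params_iter, n: int = 10_000) -> pd.DataFrame:
    """Stratum-summary table with exact (analytic) means and prevalences."""
    return pd.DataFrame(
        [analytic_summary(p, n=n, study_id=f"S{i}") for i, p in enumerate(params_iter)]
    )


@pytest.fixture(scope="session")
def fixture_data():
    """Miniature mixed-scenario dataset: (stratum summaries, trajectories)."""
    return make_fixtures(seed=0)


@pytest.fixture(scope="session")
def tiny_scenario():
    """Smallest scenario that exercises the full pipeline without the heavy
    boundary-prevalence filtering that makes severe-obesity fits degenerate."""
    return ScenarioConfig.pure_shift(
        seed=0,
        years=(1985, 1993, 2001, 2009, 2016),
        studies_per_region_year=1,
        participants_per_stratum=10_000,
    )
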