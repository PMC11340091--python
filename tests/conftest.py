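import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mirsurv import SimulationConfig, SurvivalOutcome, simulate_cohort
from mirsurv.pipeline import cohort_analysis_inputs

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def toy_outcome():
    """10 patients, one binary covariate, mixed events; no ties."""
    time = np.array([2.0, 3.5, 5.0, 6.5, 8.0, 9.5, 11.0, 12.5, 14.0, 15.5])
    event = np.array([1, 1, 0, 1, 1, 0, 1, 0, 1, 0])
    x = np.array([1.0, 1, 0, 1, 0, 1, 0, 0, 1, 0])
    return SurvivalOutcome(time, event), x


@pytest.fixture(scope="session")
def signal_cohort():
    """Moderate-size cohort with five prognostic miRNAs."""
    cfg = SimulationConfig(seed=11, n_patients=250, n_mirnas=300,
                           zero_fraction=0.5, low_quality_fraction=0.1)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def signal_blocks(signal_cohort):
    blocks, outcome, expr = cohort_analysis_inputs(signal_cohort)
    return blocks, outcome, expr


def random_survival(rng, n, scale=30.0, event_frac=0.35):
    """Null survival data helper (no covariate association)."""
    t = np.maximum(rng.weibull(1.2, n) * scale, 1e-2)
    e = (rng.random(n) < event_frac).astype(int)
    return SurvivalOutcome(t, e)
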