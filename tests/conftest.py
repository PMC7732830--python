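import matplotlib
import pytest
from hypothesis import HealthCheck, settings

matplotlib.use("Agg")

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

from painbalance import datagen  # noqa: E402


@pytest.fixture(scope="session")
def small_cohort():
    """A 20-subject cohort under the default generative conditions."""
    cfg = datagen.CohortConfig(n_subjects=20, seed=101)
    subjects, trials, calibration = datagen.simulate_cohort(cfg)
    return cfg, subjects, trials, calibration
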