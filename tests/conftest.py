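import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

#: The nine per-species acute toxicity geometric means (µg/L) driving the SSD.
ACUTE_VALUES = [0.72, 2.0, 3.0, 12, 16, 25.5, 88, 331, 363]


@pytest.fixture(scope="session")
def acute_values():
    return list(ACUTE_VALUES)


@pytest.fixture(scope="session")
def acute_ssd(acute_values):
    """Model-averaged SSD over all seven candidate families (session-wide:
    the mixture fits are the expensive part)."""
    from ecorisk import fit_all, model_average

    return model_average(fit_all(acute_values, "all", seed=0))


@pytest.fixture(scope="session")
def skeletonema():
    from ecorisk import load_packaged_fixture

    return load_packaged_fixture("table1_skeletonema")


@pytest.fixture(scope="session")
def tigriopus():
    from ecorisk import load_packaged_fixture

    return load_packaged_fixture("table2_tigriopus")
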