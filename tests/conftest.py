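import pytest
from hypothesis import HealthCheck, settings

import msnt

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def thresholds():
    return msnt.PhaseThresholds()


@pytest.fixture(scope="session")
def small_panel(synthetic_panel):
    """First 1000 synthetic estimates, bounds included."""
    return synthetic_panel.estimates[:1000]


@pytest.fixture(scope="session")
def recovery_config():
    """Reference study conditions at 400 countries per intended phase."""
    return msnt.reference_config(n_per_phase=(400,) * 5)


@pytest.fixture(scope="session")
def synthetic_panel(recovery_config):
    return msnt.generate_panel(recovery_config, seed=20)


@pytest.fixture(scope="session")
def synthetic_assignments(synthetic_panel):
    return msnt.classify_panel(synthetic_panel.estimates)


def make_estimate(mmr, sbr, nmr, country="X", year=2000, halfwidth=0.0):
    """Estimate with symmetric relative bounds; halfwidth=0 collapses them."""
    return msnt.CountryYearEstimate(
        country_id=country, year=year, mmr=mmr, sbr=sbr, nmr=nmr,
        mmr_lower=mmr * (1 - halfwidth), mmr_upper=mmr * (1 + halfwidth),
        sbr_lower=sbr * (1 - halfwidth), sbr_upper=sbr * (1 + halfwidth),
        nmr_lower=nmr * (1 - halfwidth), nmr_upper=nmr * (1 + halfwidth))
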