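import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from digimat.catalog import CountryRecord, default_catalog
from digimat.index import build_profiles
from digimat.simulate import SyntheticConfig, generate

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def catalog():
    return default_catalog()


@pytest.fixture(scope="session")
def complete_dataset(catalog):
    """80 synthetic countries with no missingness: every downstream stage
    sees complete cases."""
    cfg = SyntheticConfig(
        n_countries=80,
        missing_rates={s: 0.0 for s in catalog.subcomponents},
        seed=11,
    )
    return generate(cfg, catalog)


@pytest.fixture(scope="session")
def complete_profiles(complete_dataset, catalog):
    return build_profiles(complete_dataset.records, catalog)


@pytest.fixture
def make_record(catalog):
    """Factory for a complete country record with optional blanked indicators."""

    def _make(country_id="X", region="European", value=50.0, blank=(), **kwargs):
        raw = {i: float(value) for i in catalog.indicator_ids}
        for i in blank:
            raw[i] = None
        return CountryRecord(country_id=country_id, region=region, raw_indicators=raw, **kwargs)

    return _make
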