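import pytest

from desertmap import RegionSpec, ThresholdPolicy, generate_region


@pytest.fixture(scope="session")
def policy():
    return ThresholdPolicy()


@pytest.fixture(scope="session")
def small_region():
    """A mixed region exercising every verdict category and all three
    urbanicity classes, with low-vehicle overrides planted."""
    spec = RegionSpec(
        n_urban=8, n_suburban=8, n_rural=8,
        planted_desert_fraction=0.25,
        low_access_only_fraction=0.15,
        no_income_fraction=0.05,
        zero_pop_fraction=0.05,
        low_vehicle_fraction=0.2,
        seed=42,
    )
    return generate_region(spec)
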