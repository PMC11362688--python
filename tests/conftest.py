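import numpy as np
import pytest

import uhcd


@pytest.fixture(scope="session")
def registry():
    return uhcd.default_registry()


@pytest.fixture(scope="session")
def default_sim(registry):
    """Default 687-district scenario with subgroups, latents and indices.

    Session-scoped: tests must not mutate these records (copy first).
    """
    cfg = uhcd.SimulationConfig(seed=7)
    records, latent = uhcd.simulate_districts(cfg, registry, return_latent=True)
    uhcd.simulate_subgroups(records, cfg, registry)
    results = uhcd.compute_indices(records, registry)
    return cfg, records, latent, results


@pytest.fixture(scope="session")
def small_sim(registry):
    """Small scenario (6 states x 8 districts) for cheap tests."""
    cfg = uhcd.SimulationConfig(n_states=6, districts_per_state=8, seed=3)
    records = uhcd.simulate_districts(cfg, registry)
    uhcd.simulate_subgroups(records, cfg, registry)
    return cfg, records


@pytest.fixture
def toy_record(registry):
    """Every indicator at 50 (oriented) except both cancer screens at 0.5."""
    values = {}
    for ind in registry.indicators:
        oriented = 0.5 if ind.id in ("cervical_screening", "breast_screening") else 50.0
        values[ind.id] = 100.0 - oriented if ind.orientation == "adverse_incidence" else oriented
    return uhcd.DistrictRecord(district_id="toy", state_id="S", values=values)


def constant_record(registry, value, district_id="d", state_id="s"):
    """Record whose every oriented indicator equals `value`."""
    values = {}
    for ind in registry.indicators:
        values[ind.id] = (
            100.0 - value if ind.orientation == "adverse_incidence" else value
        )
    return uhcd.DistrictRecord(district_id=district_id, state_id=state_id, values=values)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
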