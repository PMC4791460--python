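import numpy as np
import pytest

from alcatrack import simulate as sim


@pytest.fixture(scope="session")
def small_cohort():
    """In-memory synthetic cohort, small enough for repeated use."""
    cfg = sim.SimConfig(seed=11, n_birds=6, trips_per_bird=2.0, trips_per_bird_sd=0.5)
    _, data = sim.gen_cohort(cfg)
    return cfg, data


@pytest.fixture(scope="session")
def route_families():
    """Two clearly separated route families (12 + 37 members)."""
    paths, labels = sim.gen_route_families(2, [12, 37], jitter_m=1000.0, seed=3,
                                           separation_m=10_000.0)
    return paths, labels


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
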