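import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import linkmap as lm

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=30)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_sim():
    """Moderate simulated dataset with truth, shared across tests."""
    cfg = lm.SimulationConfig(
        n_families=50, n_progeny_per_family=40, p=40, seed=7,
    )
    data, truth, theta = lm.simulate_dataset(cfg)
    return cfg, data, truth, theta


@pytest.fixture(scope="session")
def small_results(small_sim):
    _, data, _, _ = small_sim
    return lm.RecombinationMapModel(data).fit()


@pytest.fixture
def toy_map():
    return lm.MarkerMap(pd.DataFrame({
        "chrom": ["1", "1", "1"],
        "marker_id": ["m1", "m2", "m3"],
        "bp": [100, 200, 300],
    }))


def make_family(sire, progeny, sire_id="s1"):
    sire = np.asarray(sire, dtype=float)
    progeny = np.asarray(progeny, dtype=float)
    ids = [f"p{i}" for i in range(progeny.shape[0])]
    return lm.Family(sire_id, sire, ids, progeny)


@pytest.fixture
def make_dataset(toy_map):
    def _make(sire, progeny):
        return lm.HalfSibDataset(toy_map, [make_family(sire, progeny)])
    return _make
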