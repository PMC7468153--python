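import numpy as np
import pandas as pd
import pytest

from lakebiogeo import geometry, synth


@pytest.fixture(scope="session")
def small_world():
    """A 217-lake, 300-taxon labelled world shared by read-only tests."""
    return synth.generate_world(synth.WorldConfig(n_taxa=300, seed=11))


@pytest.fixture(scope="session")
def small_matrix(small_world):
    lakes = small_world.lakes
    return geometry.distance_matrix(
        lakes["lake_id"], lakes["lat"].to_numpy(), lakes["lon"].to_numpy()
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def brute_force_mean_pairwise(dm, ids):
    """O(n^2) double-loop oracle for the mean pairwise distance."""
    ids = list(ids)
    total, npairs = 0.0, 0
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            a, b = dm.indices([ids[i]])[0], dm.indices([ids[j]])[0]
            total += dm.values[a, b]
            npairs += 1
    return total / npairs


def toy_lakes(coords, **env):
    """Quick lake metadata frame from [(id, lat, lon, altitude), ...]."""
    df = pd.DataFrame(coords, columns=["lake_id", "lat", "lon", "altitude_m"])
    df["pH"] = env.get("pH", 7.0)
    df["conductivity_uScm"] = env.get("conductivity_uScm", 250.0)
    df["temperature_C"] = env.get("temperature_C", 15.0)
    return df
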