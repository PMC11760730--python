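import numpy as np
import pandas as pd
import pytest

from avalanchekit import raster_io, synthetic


def make_neurons(spec):
    """Neuron table from {id: (population, layer, ncd, ei)}."""
    return pd.DataFrame(
        [
            {"id": i, "population": p, "layer": lay, "ncd": ncd, "ei": ei}
            for i, (p, lay, ncd, ei) in spec.items()
        ]
    ).set_index("id")


@pytest.fixture
def tiny_neurons():
    return make_neurons(
        {
            0: ("IT5B", "L5B", 0.6, "excitatory"),
            1: ("IT5B", "L5B", 0.65, "excitatory"),
            2: ("IT6", "L6", 0.9, "excitatory"),
            3: ("SOM2/3", "L2/3", 0.2, "inhibitory"),
            4: ("IT2/3", "L2/3", 0.15, "excitatory"),
        }
    )


@pytest.fixture
def tiny_raster(tiny_neurons):
    return raster_io.SpikeRaster(
        times=np.array([0.5, 1.2, 3.7]),
        neuron_ids=np.array([0, 1, 0]),
        neurons=tiny_neurons,
        t_start=0.0,
        t_stop=4.0,
    )


@pytest.fixture(scope="session")
def default_session():
    """One full-scale 60 s synthetic session (shared across tests)."""
    cfg = synthetic.SessionConfig()
    raster, schedule = synthetic.generate_session(cfg, seed=1)
    return cfg, raster, schedule


@pytest.fixture(scope="session")
def default_binned(default_session):
    _, raster, _ = default_session
    return raster_io.bin_spikes(raster, bin_width=1.0)


@pytest.fixture(scope="session")
def irregular_session():
    """Irregular-only session: IT5B/IT6 background with gaps, no patterns."""
    cfg = synthetic.SessionConfig(
        duration_ms=30_000.0, include_patterns=()
    )
    raster, schedule = synthetic.generate_session(cfg, seed=7)
    return cfg, raster, schedule
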