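import numpy as np
import pytest

from lmspeed.io import DENSE_PROTOCOL, Protocol
from lmspeed.pipeline import RunConfig, run_pipeline
from lmspeed.synth import ArchetypeParams, simulate_cell


@pytest.fixture(scope="session")
def pipeline_result():
    """The default 114-cell synthetic study, run end to end once (seed 1)."""
    return run_pipeline(RunConfig(seed=1))


@pytest.fixture(scope="session")
def archetype_cells():
    """One high-SNR cell per archetype on the dense protocol, 10 sweeps."""
    specs = {
        "directional": ArchetypeParams(archetype="directional", pd=20.0),
        "dir_to_omni": ArchetypeParams(archetype="dir_to_omni", pd=350.0,
                                       kappa_decay=0.25),
        "bidirectional": ArchetypeParams(archetype="bidirectional", pd=65.0),
        "omnidirectional": ArchetypeParams(archetype="omnidirectional", kappa0=0.0),
        "unmodulated": ArchetypeParams(archetype="unmodulated", peak_gain=0.0),
    }
    out = {}
    for i, (name, params) in enumerate(specs.items()):
        rec, truth = simulate_cell(params, DENSE_PROTOCOL, n_sweeps=10, seed=7,
                                   cell_id=name, cell_index=i)
        out[name] = (rec, truth)
    return out


@pytest.fixture()
def single_speed_protocol():
    """A one-speed protocol for cheap targeted simulations."""
    return Protocol(name="dense", speeds=(32.0,), sf_range=(0.0155, 0.25),
                    tf_range=(1.0, 16.0), n_sweeps=10)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
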