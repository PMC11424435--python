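import numpy as np
import pytest

from measeg import ElectrodeLayout, SpikeTrains, SynthConfig, grid_layout
from measeg.synth import generate_spike_trains


@pytest.fixture(scope="session")
def layout():
    """Default 120-electrode, four-compartment quadrant layout."""
    return grid_layout()


@pytest.fixture(scope="session")
def small_layout():
    """Hand-built 6-electrode layout: two compartments, one unassigned."""
    ids = ("a1", "a2", "a3", "b1", "b2", "u1")
    pos = np.array([
        [0.0, 0.0], [200.0, 0.0], [0.0, 200.0],
        [1000.0, 0.0], [1200.0, 0.0], [600.0, 600.0],
    ])
    comps = ("C1", "C1", "C1", "C2", "C2", "unassigned")
    return ElectrodeLayout(ids, pos, comps)


@pytest.fixture(scope="session")
def synth_session(layout):
    """One moderately-coupled synthetic recording shared across tests."""
    cfg = SynthConfig(duration_s=120.0, seed=11, n_events=15, p_couple=0.5)
    trains, truth = generate_spike_trains(cfg, layout)
    return trains, truth, cfg


def poisson_trains(n_electrodes, rate, duration, seed, prefix="e"):
    """Independent homogeneous Poisson spike trains (test helper)."""
    rng = np.random.default_rng(seed)
    trains = {}
    for k in range(n_electrodes):
        n = rng.poisson(rate * duration)
        trains[f"{prefix}{k:03d}"] = np.sort(rng.uniform(0, duration, n))
    return SpikeTrains(trains, duration_s=duration)
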