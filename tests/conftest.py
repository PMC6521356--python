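import numpy as np
import pytest

import her4jakstat as h


@pytest.fixture(scope="session")
def canonical_net():
    return h.build_canonical_network()


@pytest.fixture(scope="session")
def full_net():
    return h.build_full_network()


@pytest.fixture(scope="session")
def baseline_traj(full_net):
    """Full model at 20 nM NRG on a moderately fine grid (shared, read-only)."""
    return h.run_timecourse(full_net, 20.0, output_step=0.02)


@pytest.fixture(scope="session")
def dose_series_trajs(full_net):
    """Full-model trajectories at the three assay doses (10/20/50 nM)."""
    protocol = h.DoseProtocol([10.0, 20.0, 50.0], output_step=0.02)
    return h.run_dose_series(full_net, protocol)


def make_trajectory(times, profiles, dose=0.0):
    """Assemble a synthetic Trajectory from {species_id: concentration array}."""
    times = np.asarray(times, dtype=float)
    ids = list(profiles)
    conc = np.vstack([np.asarray(profiles[s], dtype=float) for s in ids])
    return h.Trajectory(times, conc, ids, dose, {})
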