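import numpy as np
import pytest

from perfsource.acquisition import acquire_series
from perfsource.fixtures import make_fixture
from perfsource.phantom import SpinEnsemble, build_forest, seed_spins
from perfsource.recon import reconstruct_source_maps, separate_echoes


def make_moving_ensemble(r0s, velocities, compartment=0, m0=None):
    """Hand-built ensemble: spins at ``r0s`` moving with constant
    ``velocities`` forever (single-interval trajectories)."""
    r0 = np.atleast_2d(np.asarray(r0s, dtype=float))
    vel = np.atleast_2d(np.asarray(velocities, dtype=float))
    n = r0.shape[0]
    return SpinEnsemble(
        r0=r0,
        compartment=np.full(n, compartment, dtype=np.int8),
        tree_index=np.zeros(n, dtype=int),
        m0=np.ones(n) if m0 is None else np.asarray(m0, dtype=float),
        bp_t=np.zeros((n, 1)),
        bp_p=r0[:, None, :].copy(),
        vel=vel[:, None, :].copy(),
    )


def make_static_ensemble(r0s, compartment=2):
    r0 = np.atleast_2d(np.asarray(r0s, dtype=float))
    return make_moving_ensemble(r0, np.zeros_like(r0), compartment=compartment)


@pytest.fixture(scope="session")
def y_tree():
    spec, protocol = make_fixture("y_tree", seed=0)
    ensemble = seed_spins(build_forest(spec), spec)
    return spec, protocol, ensemble


@pytest.fixture(scope="session")
def y_tree_maps(y_tree):
    spec, protocol, ensemble = y_tree
    signal = acquire_series(ensemble, protocol)
    stim = separate_echoes(signal)
    maps = reconstruct_source_maps(stim, protocol)
    return signal, stim, maps
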