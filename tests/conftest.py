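"""Shared fixtures: small assemblies and short cached trajectories."""

import numpy as np
import pytest

from ringmotor import synthetic_topology as topo
from ringmotor.energetics import ForceFieldParams, make_active_potentials
from ringmotor.engine import SwitchProtocol, run_protocol


@pytest.fixture(scope="session")
def params():
    return ForceFieldParams()


@pytest.fixture(scope="session")
def ss_assembly():
    return topo.build_ssdna_scenario(seed=11)


@pytest.fixture(scope="session")
def fork_assembly():
    return topo.build_fork_scenario(seed=11)


@pytest.fixture(scope="session")
def nuc_assembly():
    return topo.build_nucleosome_scenario(shl_start=-7.0, seed=11)


@pytest.fixture(scope="session")
def ss_active(ss_assembly, params):
    return make_active_potentials(ss_assembly.states[0], params, ss_assembly)


@pytest.fixture(scope="session")
def short_ss_traj(ss_assembly, params):
    """A short 3-state run used by metric and serialization tests."""
    return run_protocol(
        ss_assembly,
        SwitchProtocol(sequence=(1, 2, 3), interval=1500),
        seed=5,
        params=params,
        subsample=30,
        relax_steps=500,
    )


@pytest.fixture(scope="session")
def short_fork_traj(fork_assembly, params):
    return run_protocol(
        fork_assembly,
        SwitchProtocol(sequence=(1, 2), interval=1500),
        seed=5,
        params=params,
        subsample=30,
        relax_steps=500,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
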