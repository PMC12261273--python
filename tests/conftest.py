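import numpy as np
import pytest

from aptadyn import FixtureSpec, make_hairpin_system, simulate_trajectory


@pytest.fixture(scope="session")
def default_system():
    """4-bp stem, 4-nt loop, 10-nt 3' tail — the standard study system."""
    return make_hairpin_system()


@pytest.fixture(scope="session")
def default_traj(default_system):
    spec = FixtureSpec(n_frames=120, seed=11)
    return simulate_trajectory(default_system, spec)


@pytest.fixture(scope="session")
def quiet_system_traj():
    """Nearly static hairpin(+tail): ideal geometry with negligible jitter."""
    spec = FixtureSpec(
        n_frames=40, sigma_stem=0.02, sigma_tail=0.02, tail_reorient_deg=0.5, seed=2
    )
    system = make_hairpin_system(spec)
    return system, simulate_trajectory(system, spec)


@pytest.fixture(scope="session")
def hairpin_only_system():
    """12-residue hairpin, no tail (for spacer / clustering constructions)."""
    spec = FixtureSpec(n_stem=4, n_loop=4, n_tail=0)
    return make_hairpin_system(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
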