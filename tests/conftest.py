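import numpy as np
import pytest

from tubudyn.io import ResidueSelection, Topology, default_selection
from tubudyn.synthetic import DimerParams, simulate_dimer


@pytest.fixture(scope="session")
def selection() -> ResidueSelection:
    return default_selection()


@pytest.fixture(scope="session")
def small_dimer():
    """A short synthetic dimer run plus its ground-truth manifest."""
    params = DimerParams(n_frames=300, seed=42, run_id="fixture_run")
    return simulate_dimer(params)


@pytest.fixture(scope="session")
def quiet_dimer():
    """A dimer with no jitter and frozen loop, for exact-geometry tests."""
    params = DimerParams(
        n_frames=50,
        seed=7,
        jitter_sd=0.0,
        loop_occupancy_a=1.0,
        loop_switch_rate=0.0,
        run_id="quiet_run",
    )
    return simulate_dimer(params)


def toy_topology(positions, resids=None, chains=None, elements=None, names=None):
    """Minimal topology helper for hand-built frames."""
    n = len(positions)
    resids = np.arange(1, n + 1) if resids is None else np.asarray(resids)
    chains = np.array(["A"] * n) if chains is None else np.asarray(chains)
    elements = np.array(["C"] * n) if elements is None else np.asarray(elements)
    names = np.array(["CA"] * n) if names is None else np.asarray(names)
    roles = {}
    for c in chains:
        if c not in roles:
            roles[c] = "TUBA" if not roles else "TUBB"
    return Topology(
        ids=np.arange(1, n + 1),
        names=names,
        elements=elements,
        resids=resids,
        resnames=np.array(["GLY"] * n),
        chain_ids=chains,
        roles=roles,
    )
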