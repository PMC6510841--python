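import numpy as np
import pytest

from acmodes import (
    RunConfig,
    StimulusSpec,
    build_connections,
    build_layout,
    canonicalize,
    couple,
    decompose,
    make_fixture,
    solve_modes,
)
from acmodes.experiments import run_default


@pytest.fixture(scope="session")
def layout():
    return build_layout()


@pytest.fixture(scope="session")
def default_conn(layout):
    return build_connections(layout)


@pytest.fixture(scope="session")
def default_run():
    """One full default simulation, shared across the suite."""
    return run_default()


@pytest.fixture(scope="session")
def mini():
    """Miniature relay + 2-cortical-field system solved end to end."""
    lay, conn = make_fixture(3, 4, seed=3)
    system = canonicalize(conn)
    spectrum = decompose(system)
    cfg = RunConfig()
    stim = StimulusSpec.centered(lay)
    _, traj = solve_modes(spectrum, stim, cfg.time_grid())
    traj = couple(spectrum, traj)
    return dict(layout=lay, conn=conn, system=system, spectrum=spectrum,
                traj=traj, cfg=cfg, stim=stim)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
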