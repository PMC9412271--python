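import warnings

import numpy as np
import pytest

from scrim import (
    AugmentedState,
    DataBundle,
    FitConfig,
    OccData,
    SCRData,
    ScenarioConfig,
    StateSpace,
    TelemetryData,
    TrapArray,
    run_fit,
    simulate_dataset,
)
from scrim.types import CAMERA, LIVE_TRAP

warnings.filterwarnings("ignore", message=".*ArviZ.*")


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def toy_space():
    return StateSpace(0.0, 4.0, 0.0, 4.0)


@pytest.fixture
def toy_traps():
    return TrapArray(coords=[[1.0, 1.0], [2.0, 2.5]], kind=LIVE_TRAP, effort=[2, 3])


@pytest.fixture
def toy_cameras():
    return TrapArray(coords=[[3.0, 1.0], [1.5, 3.0]], kind=CAMERA, effort=[2, 2])


@pytest.fixture
def toy_scr():
    return SCRData(y=[[1, 0], [0, 2]])


@pytest.fixture
def toy_occ():
    return OccData(y=[1, 2])


@pytest.fixture
def toy_bundle(toy_space, toy_traps, toy_cameras, toy_scr, toy_occ):
    tel = TelemetryData(
        fixes=[[[1.1, 1.2], [1.3, 0.9], [0.8, 1.0]]],
        links=[0],
    )
    return DataBundle(
        traps=toy_traps,
        scr=toy_scr,
        space=toy_space,
        cameras=toy_cameras,
        occ=toy_occ,
        telemetry=tel,
    )


def make_toy_state(rng, M=5, n_obs=2, space=None, **kw):
    space = space or StateSpace(0.0, 4.0, 0.0, 4.0)
    z = np.ones(M, dtype=int)
    z[n_obs:] = rng.random(M - n_obs) < 0.5
    defaults = dict(psi=0.4, lam0_trap=0.3, lam0_cam=0.4, sigma=0.8)
    defaults.update(kw)
    return AugmentedState(z=z, s=space.sample(M, rng), n_obs=n_obs, **defaults)


@pytest.fixture
def toy_state(rng):
    return make_toy_state(rng)


@pytest.fixture(scope="session")
def case_scenario():
    """Case-study emulation scenario with calibrated rates (session-cached)."""
    return ScenarioConfig(seed=1)


@pytest.fixture(scope="session")
def sim_bundle(case_scenario):
    """One simulated case-study-like dataset plus its truth record."""
    return simulate_dataset(case_scenario, seed=7)


@pytest.fixture(scope="session")
def fitted_chains(sim_bundle):
    """A short but usable SCR-Occ-Tel fit of :func:`sim_bundle` (session-cached)."""
    bundle, _ = sim_bundle
    cfg = FitConfig(n_chains=2, n_iter=1500, n_burn=500, seed=11)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return cfg, run_fit(bundle, cfg)
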