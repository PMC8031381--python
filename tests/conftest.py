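from functools import lru_cache

import numpy as np
import pytest

from rowerchain.dynamics import Trajectory, simulate
from rowerchain.experiments import reduced_preset
from rowerchain.geometry import ChainSpec, build_chain


@pytest.fixture(scope="session")
def default_spec() -> ChainSpec:
    return ChainSpec()


@pytest.fixture(scope="session")
def default_chain(default_spec):
    return build_chain(default_spec)


@pytest.fixture(scope="session")
def tiny_spec() -> ChainSpec:
    """Small chain for integration tests that loop in Python."""
    return ChainSpec(n_rowers=6, group_size=3)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def trajectory_from_phases(phases: np.ndarray, times: np.ndarray) -> Trajectory:
    """Build a synthetic trajectory realising the given (S, N) phase matrix."""
    spec = ChainSpec(n_rowers=phases.shape[1])
    config = build_chain(spec)
    a = spec.amplitude
    phi = np.mod(phases, 2 * np.pi)
    forward = phi <= np.pi
    u = np.where(forward, a * (phi / np.pi - 0.5), a * (0.5 - (phi - np.pi) / np.pi))
    sigma = np.where(forward, 1, -1).astype(np.int8)
    return Trajectory(times=times, track_coords=u, trap_signs=sigma, seed=None,
                      config=config, dt_cycles=1e-2, engine="synthetic")


@pytest.fixture(scope="session")
def synthetic_trajectory_factory():
    """Factory for trajectories that hold a fixed square-wave profile."""

    def make(k: int, amplitude: float, n_rowers: int = 60,
             n_cycles: int = 100) -> Trajectory:
        i = np.arange(n_rowers)
        dphi = amplitude * np.sign(np.cos(2 * np.pi * k * i / n_rowers))
        phi0 = np.concatenate([[0.0], np.cumsum(dphi)[:-1]])
        times = np.arange(0.0, n_cycles + 1e-9, 0.5)
        # all rowers advance together; the profile is constant in time
        phases = phi0[None, :] + 2 * np.pi * times[:, None]
        return trajectory_from_phases(phases, times)

    return make


# ---------------------------------------------------------------------------
# Reduced-scale simulation ensembles, shared between the acceptance tests and
# the snapshot-stride stability check. Memoised so the cost (about a minute
# per ensemble) is paid once per session.
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def reduced_ensemble(d_x: float = 0.0, decouple: bool = False,
                     n_cycles: float | None = None) -> tuple:
    preset = reduced_preset()
    spec = preset["spec"].with_(mechanism="spacing", d_x=d_x)
    return tuple(
        simulate(spec, n_cycles=n_cycles or preset["n_cycles"],
                 dt_cycles=preset["dt_cycles"], seed=seed, engine="fast",
                 decouple_groups=decouple)
        for seed in range(preset["n_runs"])
    )


@pytest.fixture(scope="session")
def chevron_bearing_trajectories():
    """Stochastic runs at intermediate extra spacing (chevron-rich)."""
    return reduced_ensemble(d_x=16.0)


@pytest.fixture(scope="session")
def uniform_chain_trajectories():
    """Runs at d_x = 0; longer, because the softest profile mode relaxes
    slowly from random initial conditions."""
    return reduced_ensemble(d_x=0.0, n_cycles=1000)


@pytest.fixture(scope="session")
def decoupled_group_trajectories():
    """Runs with inter-group mobility zeroed (fully decoupled limit)."""
    return reduced_ensemble(d_x=0.0, decouple=True)
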