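"""Driving, switching, calibration and Brownian integration of the chain.

Each rower is a bead confined to its track, pulled toward a trap vertex at
``sigma * (A/2 + x_s)`` by an attractive power-law potential ``k |x - x_r|^alpha``.
When the bead crosses the switch point ``A/2`` the trap flips sign
(geometric switch), producing phase-free oscillations.

Positions follow an overdamped Langevin equation with configuration-
dependent mobility and correlated Gaussian noise of covariance
``2 kT M dt`` (Ermak-McCammon style; the mobility-divergence drift vanishes
here because beads are confined to fixed-height tracks and the divergence
of the projected far-field mobility is negligible). The deterministic
drift uses a Heun predictor-corrector on the trap force (mobility is
evaluated once per step), and switch overshoot is redistributed at the
turning point scaled by the post-turn/pre-turn speed ratio; both
corrections keep the discretisation bias of the oscillation period well
below one time step, which plain explicit Euler does not achieve.

Two integration engines exist: a compiled kernel ("fast") and a pure NumPy
reference ("reference"). Both consume the same random-number stream, so
they produce matching trajectories up to floating-point reordering.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, IntegrationError
from .geometry import ChainConfig, ChainSpec, build_chain
from .hydrodynamics import MobilityMatrix, projected_mobility, self_mobility

__all__ = [
    "RowerState",
    "Trajectory",
    "driving_force",
    "switch_update",
    "calibrate_trap_strength",
    "thermal_energy",
    "thermal_step",
    "step",
    "simulate",
]

#: Default integration step, in units of the oscillation cycle.
DEFAULT_DT_CYCLES = 2e-3
#: Default run length in cycles.
DEFAULT_N_CYCLES = 2000
#: Default interval between stored samples, in cycles.
DEFAULT_SAMPLE_CYCLES = 0.1

_NOISE_CHUNK = 8192  # steps of pre-generated noise per kernel call


@dataclass
class RowerState:
    """Instantaneous chain state: track coordinates and trap orientations."""

    track_coord: np.ndarray  # (N,) float, relative to track center
    trap_sign: np.ndarray  # (N,) +-1

    def copy(self) -> "RowerState":
        return RowerState(self.track_coord.copy(), self.trap_sign.copy())


@dataclass
class Trajectory:
    """Sampled states of one seeded run."""

    times: np.ndarray  # (S,) in cycle units
    track_coords: np.ndarray  # (S, N)
    trap_signs: np.ndarray  # (S, N) int8
    seed: int | None
    config: ChainConfig
    dt_cycles: float
    engine: str

    @property
    def n_rowers(self) -> int:
        return self.track_coords.shape[1]

    @property
    def n_cycles(self) -> float:
        return float(self.times[-1])

    def phases(self) -> np.ndarray:
        """(S, N) geometric phases, each rower normalised by its own amplitude."""
        from .phase_analysis import geometric_phase

        return geometric_phase(
            self.track_coords, self.trap_signs,
            self.config.per_rower_amplitude[None, :],
        )


def driving_force(u, sigma, amplitude, strength, exponent, switch_offset):
    """Signed force along the track from the attractive power-law trap.

    The trap vertex sits at ``sigma * (amplitude/2 + switch_offset)``; the
    force has magnitude ``exponent * strength * r**(exponent-1)`` at distance
    ``r`` from the vertex and points toward it. Vectorised.
    """
    u = np.asarray(u, dtype=float)
    sigma = np.asarray(sigma)
    vertex = sigma * (amplitude / 2.0 + switch_offset)
    rv = vertex - u
    r = np.abs(rv)
    if np.any(r == 0.0):
        raise ValueError("bead exactly at trap vertex: force undefined")
    f = np.sign(rv) * exponent * strength * r ** (exponent - 1.0)
    return float(f) if f.ndim == 0 else f


def switch_update(u, sigma, amplitude):
    """Flip the trap sign for rowers that crossed their switch point A/2."""
    u = np.asarray(u, dtype=float)
    sigma = np.asarray(sigma)
    out = np.where(sigma * u >= np.asarray(amplitude) / 2.0, -sigma, sigma)
    return out if out.ndim else out[()]


def calibrate_trap_strength(drag: float, amplitude: float, switch_offset: float,
                            exponent: float, target_period: float) -> float:
    """Trap strength giving an isolated noise-free rower the target period.

    From the overdamped half-stroke time
    ``T/2 = (drag / (alpha k)) * integral_{x_s}^{A+x_s} r^(1-alpha) dr``:

    ``k = 2 * drag * ((A+x_s)^(2-alpha) - x_s^(2-alpha)) / (alpha (2-alpha) T)``

    (for alpha = 1/2 this is ``(8 drag / (3 T)) ((A+x_s)^1.5 - x_s^1.5)``).
    """
    if min(drag, amplitude, switch_offset, target_period) <= 0:
        raise ValueError("drag, amplitude, switch_offset, target_period must be positive")
    if not 0.0 < exponent <= 1.0:
        raise ValueError("exponent must be in (0, 1]")
    p = 2.0 - exponent
    span = (amplitude + switch_offset) ** p - switch_offset ** p
    return 2.0 * drag * span / (exponent * p * target_period)


def thermal_energy(spec: ChainSpec, trap_strength: float | None = None) -> float:
    """Thermal energy kT implied by the dimensionless noise level.

    Defined as ``noise_level`` times the driving-potential drop over one
    half stroke, ``k [(A+x_s)^alpha - x_s^alpha]``, evaluated for the
    unmodified rower. Single point of change if an alternative noise
    normalisation is preferred.
    """
    if trap_strength is None:
        trap_strength = calibrate_trap_strength(
            spec.drag, spec.amplitude, spec.switch_offset,
            spec.force_exponent, spec.target_period,
        )
    a, xs, al = spec.amplitude, spec.switch_offset, spec.force_exponent
    delta_e = trap_strength * ((a + xs) ** al - xs ** al)
    return spec.noise_level * delta_e


def thermal_step(mobility: MobilityMatrix, k_t: float, dt: float,
                 rng: np.random.Generator | None = None,
                 normals: np.ndarray | None = None) -> np.ndarray:
    """Correlated Gaussian displacement with covariance 2 kT M dt.

    ``normals`` may supply the standard-normal draws explicitly (used to
    keep the two integration engines on one random stream).
    """
    n = mobility.entries.shape[0]
    if k_t == 0.0:
        return np.zeros(n)
    if dt <= 0:
        raise ValueError("dt must be positive")
    z = rng.standard_normal(n) if normals is None else np.asarray(normals, dtype=float)
    chol = mobility.cholesky()
    return math.sqrt(2.0 * k_t * dt) * (chol @ z)


def _group_mask(config: ChainConfig) -> np.ndarray:
    g = np.arange(config.n_rowers) // config.spec.group_size
    return g[:, None] == g[None, :]


def turn_speed_ratio(config: ChainConfig) -> np.ndarray:
    """Per-rower ratio of post-turn to pre-turn speed at the switch point.

    Just after the switch the bead sits at distance ``A + x_s`` from the new
    vertex versus ``x_s`` from the old one, so for force exponent alpha the
    speed ratio is ``((A + x_s)/x_s)**(alpha - 1)``. Overshoot past the
    switch point is redistributed by this factor, locating the turning
    event to second order in dt.
    """
    spec = config.spec
    a, xs = config.per_rower_amplitude, config.per_rower_switch_offset
    return ((a + xs) / xs) ** (spec.force_exponent - 1.0)


def step(state: RowerState, config: ChainConfig, k_t: float, dt: float,
         rng: np.random.Generator | None = None,
         normals: np.ndarray | None = None,
         decouple_groups: bool = False) -> RowerState:
    """One Heun-drift Euler-Maruyama step plus the geometric switch (reference path)."""
    spec = config.spec
    mob = projected_mobility(config, state.track_coord)
    m = mob.entries
    if decouple_groups:
        m = np.where(_group_mask(config), m, 0.0)
        mob = MobilityMatrix(entries=m, positions=mob.positions, viscosity=mob.viscosity)

    def trap_forces(u):
        return driving_force(
            u, state.trap_sign,
            config.per_rower_amplitude, config.per_rower_trap_strength,
            spec.force_exponent, config.per_rower_switch_offset,
        )

    f0 = trap_forces(state.track_coord)
    u_pred = state.track_coord + dt * (m @ f0)
    f1 = trap_forces(u_pred)
    u = state.track_coord + 0.5 * dt * (m @ (f0 + f1))
    if k_t > 0.0:
        u = u + thermal_step(mob, k_t, dt, rng=rng, normals=normals)
    limit = config.per_rower_amplitude / 2.0 + config.per_rower_switch_offset
    if np.any(np.abs(u) > limit):
        raise IntegrationError(
            "bead moved past the trap vertex; reduce the time step"
        )
    half = config.per_rower_amplitude / 2.0
    crossed = state.trap_sign * u >= half
    overshoot = state.trap_sign * u - half
    ratio = turn_speed_ratio(config)
    u = np.where(crossed, state.trap_sign * (half - overshoot * ratio), u)
    sigma = np.where(crossed, -state.trap_sign, state.trap_sign)
    # a single step must never arm an immediate second switch
    assert not np.any(sigma * u >= half)
    return RowerState(track_coord=u, trap_sign=sigma)


def _initial_state(config: ChainConfig, rng: np.random.Generator) -> RowerState:
    half = config.per_rower_amplitude / 2.0
    u0 = rng.uniform(-half, half)
    sigma0 = rng.integers(0, 2, size=config.n_rowers) * 2 - 1
    return RowerState(track_coord=u0, trap_sign=sigma0.astype(np.int64))


def simulate(spec: ChainSpec,
             n_cycles: float = DEFAULT_N_CYCLES,
             dt_cycles: float = DEFAULT_DT_CYCLES,
             seed: int | None = None,
             sample_cycles: float = DEFAULT_SAMPLE_CYCLES,
             engine: str = "fast",
             decouple_groups: bool = False,
             initial_state: RowerState | None = None) -> Trajectory:
    """Run one seeded simulation of the chain.

    Initial track coordinates are uniform on (-A_i/2, A_i/2) and trap signs
    uniform on {-1, +1}, both drawn from ``seed``. States are stored every
    ``sample_cycles``. Fully reproducible from ``(spec, seed)`` for a fixed
    engine. ``decouple_groups`` zeroes the mobility between different
    ``group_size`` blocks (used to probe the fully decoupled limit).
    """
    if n_cycles <= 0 or dt_cycles <= 0:
        raise ConfigurationError("n_cycles and dt_cycles must be positive")
    if decouple_groups and spec.n_rowers % spec.group_size != 0:
        raise ConfigurationError("decouple_groups requires n_rowers divisible by group_size")

    config = build_chain(spec)
    n = spec.n_rowers
    n_steps = int(round(n_cycles / dt_cycles))
    stride = max(1, int(round(sample_cycles / dt_cycles)))
    dt = dt_cycles * spec.target_period
    k_t = thermal_energy(spec)

    rng = np.random.default_rng(seed)
    state = initial_state.copy() if initial_state is not None else _initial_state(config, rng)

    n_samples = n_steps // stride + 1
    u_out = np.empty((n_samples, n))
    s_out = np.empty((n_samples, n), dtype=np.int8)
    u_out[0] = state.track_coord
    s_out[0] = state.trap_sign

    if engine == "fast":
        _run_fast(state, config, k_t, dt, n_steps, stride, rng,
                  decouple_groups, u_out, s_out)
    elif engine == "reference":
        _run_reference(state, config, k_t, dt, n_steps, stride, rng,
                       decouple_groups, u_out, s_out)
    else:
        raise ConfigurationError(f"unknown engine {engine!r}")

    times = np.arange(n_samples) * stride * dt_cycles
    return Trajectory(times=times, track_coords=u_out, trap_signs=s_out,
                      seed=seed, config=config, dt_cycles=dt_cycles, engine=engine)


def _run_reference(state, config, k_t, dt, n_steps, stride, rng,
                   decouple_groups, u_out, s_out):
    n = config.n_rowers
    done = 0
    while done < n_steps:
        chunk = min(_NOISE_CHUNK, n_steps - done)
        normals = rng.standard_normal((chunk, n)) if k_t > 0.0 else None
        for i in range(chunk):
            state_new = step(state, config, k_t, dt,
                             normals=None if normals is None else normals[i],
                             decouple_groups=decouple_groups)
            state = state_new
            g = done + i + 1
            if g % stride == 0:
                u_out[g // stride] = state.track_coord
                s_out[g // stride] = state.trap_sign
        done += chunk


def _run_fast(state, config, k_t, dt, n_steps, stride, rng,
              decouple_groups, u_out, s_out):
    from ._kernels import run_steps

    spec = config.spec
    n = config.n_rowers
    u = state.track_coord.astype(np.float64)
    sigma = state.trap_sign.astype(np.float64)
    group = (np.arange(n) // spec.group_size if decouple_groups
             else np.full(n, -1)).astype(np.int64)
    pref = 1.0 / (8.0 * math.pi * spec.viscosity)
    mob_diag = self_mobility(spec.viscosity, spec.bead_radius)

    done = 0
    while done < n_steps:
        chunk = min(_NOISE_CHUNK, n_steps - done)
        noise = (rng.standard_normal((chunk, n)) if k_t > 0.0
                 else np.empty((0, n)))
        code = run_steps(
            u, sigma, done, chunk, stride,
            config.track_centers[:, 0].copy(),
            config.track_direction[0], config.track_direction[1],
            spec.height, config.ring_length,
            config.per_rower_amplitude, config.per_rower_trap_strength,
            config.per_rower_switch_offset, spec.force_exponent,
            pref, mob_diag, k_t, dt, noise, group, turn_speed_ratio(config),
            u_out, s_out,
        )
        if code == 1:
            raise IntegrationError("bead moved past the trap vertex; reduce the time step")
        done += chunk

    state.track_coord = u
    state.trap_sign = sigma.astype(np.int64)
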