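"""Chain geometry: rower tracks on a periodic ring and the three control mechanisms.

A chain is a ring of N "rowers": beads driven back and forth along straight,
parallel 1-D tracks. Tracks lie in the plane z = h above a no-slip wall at
z = 0 and are tilted by ``tilt_angle`` off the x axis; track centers are
spaced along x. Exactly one of three control mechanisms may modify the
uniform chain:

``spacing``
    every ``group_size``-th gap is widened by ``d_x`` (reduced coupling
    between groups),
``amplitude``
    every ``group_size``-th rower has its oscillation amplitude changed by
    ``a_x`` with the trap strength recalibrated so its period is unchanged,
``frequency``
    every ``group_size``-th rower has its trap strength scaled by ``f_x``
    (detuning its intrinsic frequency).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigurationError

__all__ = [
    "Mechanism",
    "ChainSpec",
    "ChainConfig",
    "build_chain",
    "minimum_image",
    "drag_coefficient",
]


class Mechanism(str, enum.Enum):
    """Which control mechanism modifies the uniform chain."""

    NONE = "none"
    SPACING = "spacing"
    AMPLITUDE = "amplitude"
    FREQUENCY = "frequency"


def drag_coefficient(viscosity: float, bead_radius: float) -> float:
    """Stokes drag 6*pi*eta*a of a single bead."""
    return 6.0 * math.pi * viscosity * bead_radius


@dataclass(frozen=True)
class ChainSpec:
    """Full specification of a rower chain before geometry is realised.

    Lengths are in units of your choice; defaults take the bead radius as
    the unit of length (``bead_radius = 1``) and seconds as the unit of
    time. ``noise_level`` is the dimensionless ratio of the thermal energy
    to the driving-potential drop per half stroke.
    """

    n_rowers: int = 60
    bead_radius: float = 1.0
    spacing: float = 7.0
    height: float = 3.0
    amplitude: float = 30.0
    tilt_angle: float = math.pi / 4
    switch_offset: float = 2.5
    force_exponent: float = 0.5
    target_period: float = 2.0
    noise_level: float = 3.7e-5
    viscosity: float = 1.0
    mechanism: Mechanism = Mechanism.NONE
    group_size: int = 10
    d_x: float = 0.0
    a_x: float = 0.0
    f_x: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "mechanism", Mechanism(self.mechanism))
        self.validate()

    def validate(self) -> None:
        if self.n_rowers <= 0:
            raise ConfigurationError("n_rowers must be positive")
        if self.bead_radius <= 0:
            raise ConfigurationError("bead_radius must be positive")
        if self.amplitude <= 0:
            raise ConfigurationError("amplitude must be positive")
        if self.height <= self.bead_radius:
            raise ConfigurationError("height must exceed bead_radius (bead must clear the wall)")
        if self.switch_offset <= 0:
            raise ConfigurationError("switch_offset must be positive")
        if not 0.0 < self.force_exponent <= 1.0:
            raise ConfigurationError("force_exponent must be in (0, 1]")
        if self.target_period <= 0:
            raise ConfigurationError("target_period must be positive")
        if self.viscosity <= 0:
            raise ConfigurationError("viscosity must be positive")
        if self.noise_level < 0:
            raise ConfigurationError("noise_level must be non-negative")
        if self.mechanism is not Mechanism.NONE:
            if self.group_size <= 0:
                raise ConfigurationError("group_size must be positive")
            if self.n_rowers % self.group_size != 0:
                raise ConfigurationError(
                    f"n_rowers ({self.n_rowers}) must be divisible by "
                    f"group_size ({self.group_size})"
                )
        if self.mechanism is Mechanism.SPACING and self.d_x < 0:
            raise ConfigurationError("d_x must be >= 0 (only reduced coupling is considered)")
        if self.mechanism is Mechanism.AMPLITUDE and self.amplitude + self.a_x <= 0:
            raise ConfigurationError("amplitude + a_x must be positive")
        if self.mechanism is Mechanism.FREQUENCY and self.f_x <= 0:
            raise ConfigurationError("f_x must be positive")

    @property
    def drag(self) -> float:
        return drag_coefficient(self.viscosity, self.bead_radius)

    def with_(self, **changes) -> "ChainSpec":
        """Return a copy with the given fields replaced (re-validated)."""
        return replace(self, **changes)


@dataclass(frozen=True)
class ChainConfig:
    """Realised chain geometry and per-rower dynamical parameters."""

    spec: ChainSpec
    track_centers: np.ndarray  # (N, 3) points (x_i, 0, h)
    track_direction: np.ndarray  # unit 3-vector shared by all tracks
    ring_length: float
    per_rower_amplitude: np.ndarray  # (N,)
    per_rower_trap_strength: np.ndarray  # (N,)
    per_rower_switch_offset: np.ndarray  # (N,)
    modified_indices: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    @property
    def n_rowers(self) -> int:
        return self.spec.n_rowers

    def bead_positions(self, track_coords: np.ndarray) -> np.ndarray:
        """3-D bead positions for per-rower track coordinates ``u``."""
        u = np.asarray(track_coords, dtype=float)
        return self.track_centers + u[:, None] * self.track_direction[None, :]

    def gaps(self) -> np.ndarray:
        """Consecutive x-gaps around the ring, including the wrap gap."""
        x = self.track_centers[:, 0]
        inner = np.diff(x)
        wrap = self.ring_length - x[-1] + x[0]
        return np.concatenate([inner, [wrap]])


def minimum_image(dx, ring_length: float):
    """Wrap an x-separation into the primary interval (-L/2, L/2].

    Accepts scalars or arrays. The upper boundary is inclusive so the map
    is single-valued at |dx| = L/2.
    """
    if ring_length <= 0:
        raise ConfigurationError("ring_length must be positive")
    r = np.mod(dx, ring_length)
    r = np.where(r > 0.5 * ring_length, r - ring_length, r)
    return float(r) if np.isscalar(dx) else r


def build_chain(spec: ChainSpec) -> ChainConfig:
    """Lay out tracks on the ring and apply the selected control mechanism.

    Modified rowers (amplitude/frequency) and widened gaps (spacing) occur
    every ``group_size`` rowers, anchored at index 0; on a ring the anchor
    choice is unobservable.
    """
    from .dynamics import calibrate_trap_strength  # deferred: dynamics imports geometry

    spec.validate()
    n = spec.n_rowers
    d = spec.spacing
    idx = np.arange(n)

    k_base = calibrate_trap_strength(
        spec.drag, spec.amplitude, spec.switch_offset,
        spec.force_exponent, spec.target_period,
    )

    amplitudes = np.full(n, spec.amplitude)
    strengths = np.full(n, k_base)
    offsets = np.full(n, spec.switch_offset)
    modified = np.array([], dtype=int)

    if spec.mechanism is Mechanism.SPACING:
        x = idx * d + (idx // spec.group_size) * spec.d_x
        ring_length = n * d + (n // spec.group_size) * spec.d_x
    else:
        x = idx * d
        ring_length = n * d
        if spec.mechanism is Mechanism.AMPLITUDE:
            modified = idx[idx % spec.group_size == 0]
            a_mod = spec.amplitude + spec.a_x
            amplitudes[modified] = a_mod
            # period is maintained: recalibrate the trap for the new amplitude
            strengths[modified] = calibrate_trap_strength(
                spec.drag, a_mod, spec.switch_offset,
                spec.force_exponent, spec.target_period,
            )
        elif spec.mechanism is Mechanism.FREQUENCY:
            modified = idx[idx % spec.group_size == 0]
            strengths[modified] = spec.f_x * k_base

    centers = np.zeros((n, 3))
    centers[:, 0] = x
    centers[:, 2] = spec.height
    direction = np.array([math.cos(spec.tilt_angle), math.sin(spec.tilt_angle), 0.0])

    return ChainConfig(
        spec=spec,
        track_centers=centers,
        track_direction=direction,
        ring_length=float(ring_length),
        per_rower_amplitude=amplitudes,
        per_rower_trap_strength=strengths,
        per_rower_switch_offset=offsets,
        modified_indices=modified,
    )
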