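"""Wall-corrected pairwise mobility and its projection onto the 1-D tracks.

The Green's function of Stokes flow bounded by a plane no-slip wall at z = 0
is the free-space Stokeslet plus an image system (image Stokeslet, Stokes
doublet, source doublet). Pair mobilities use the point-force expression;
the self-mobility is the bulk Stokes value 1/(6*pi*eta*a) — beads stay at a
fixed height and a constant diagonal shift does not change the coupling
structure. A Faxen-style wall correction to the diagonal can be enabled via
``self_mobility(..., wall_correction=True)`` for comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import NumericalError
from .geometry import ChainConfig, minimum_image

__all__ = [
    "oseen_block",
    "blake_block",
    "self_mobility",
    "projected_pair_mobility",
    "projected_mobility",
    "MobilityMatrix",
]


def oseen_block(r_vec: np.ndarray, viscosity: float) -> np.ndarray:
    """Free-space Oseen tensor G(r) = (I + rr/|r|^2) / (8*pi*eta*|r|)."""
    r_vec = np.asarray(r_vec, dtype=float)
    r = np.linalg.norm(r_vec)
    if r == 0.0:
        raise ValueError("Oseen tensor is singular at zero separation")
    rr = np.outer(r_vec, r_vec) / r**2
    return (np.eye(3) + rr) / (8.0 * math.pi * viscosity * r)


def blake_block(source: np.ndarray, field: np.ndarray, viscosity: float) -> np.ndarray:
    """Wall Green's function: velocity at ``field`` from a unit force at ``source``.

    Both points must lie strictly above the wall z = 0. Vanishes as the
    field point approaches the wall (no-slip) and reduces to the Oseen
    tensor when the wall is removed.
    """
    source = np.asarray(source, dtype=float)
    field = np.asarray(field, dtype=float)
    h = source[2]
    if h <= 0.0 or field[2] < 0.0:
        raise ValueError("points must lie above the wall z = 0")
    if np.array_equal(source, field):
        raise ValueError("source and field points must be distinct")

    image = source.copy()
    image[2] = -h
    r = field - source
    R = field - image
    Rn = np.linalg.norm(R)

    G = oseen_block(r, viscosity) - oseen_block(R, viscosity)

    # image-system corrections: 2h*beta_j*[h*D - SD] with beta = (1, 1, -1)
    pref = 1.0 / (8.0 * math.pi * viscosity)
    corr = np.zeros((3, 3))
    for i in range(3):
        for j in range(3):
            beta = 1.0 if j < 2 else -1.0
            d_ij = 1.0 if i == j else 0.0
            doublet = d_ij / Rn**3 - 3.0 * R[i] * R[j] / Rn**5
            term = (
                h * doublet
                + ((1.0 if i == 2 else 0.0) * R[j]
                   - d_ij * R[2]
                   - (1.0 if j == 2 else 0.0) * R[i]) / Rn**3
                + 3.0 * R[i] * R[2] * R[j] / Rn**5
            )
            corr[i, j] = 2.0 * h * beta * term * pref
    return G + corr


def self_mobility(viscosity: float, bead_radius: float, height: float | None = None,
                  wall_correction: bool = False) -> float:
    """Translational self-mobility of one bead.

    Default is the bulk Stokes value. With ``wall_correction`` the leading
    wall-parallel Faxen correction 1 - 9a/(16h) is applied.
    """
    m0 = 1.0 / (6.0 * math.pi * viscosity * bead_radius)
    if wall_correction:
        if height is None or height <= bead_radius:
            raise ValueError("wall correction requires height > bead_radius")
        m0 *= 1.0 - 9.0 * bead_radius / (16.0 * height)
    return m0


def projected_pair_mobility(dx, dy, height: float, t_x: float, t_y: float,
                            viscosity: float):
    """Track-projected wall mobility t.G(r).t for beads at equal height.

    Closed form of the full tensor contraction for in-plane separations
    (dx, dy, 0) and an in-plane track direction (t_x, t_y, 0); used both
    directly and as the reference for the compiled kernel. Vectorised over
    ``dx``/``dy``.
    """
    dx = np.asarray(dx, dtype=float)
    dy = np.asarray(dy, dtype=float)
    r2 = dx * dx + dy * dy
    r = np.sqrt(r2)
    R2 = r2 + 4.0 * height * height
    R = np.sqrt(R2)
    rt = dx * t_x + dy * t_y  # r.t == R.t (track is in-plane)
    pref = 1.0 / (8.0 * math.pi * viscosity)
    g = (
        1.0 / r + rt * rt / (r2 * r)
        - 1.0 / R - rt * rt / (R2 * R)
        - 2.0 * height * height * (1.0 / (R2 * R) - 3.0 * rt * rt / (R2 * R2 * R))
    )
    return pref * g


@dataclass(frozen=True)
class MobilityMatrix:
    """Symmetric positive-definite N x N track-projected mobility."""

    entries: np.ndarray
    positions: np.ndarray
    viscosity: float

    def cholesky(self) -> np.ndarray:
        try:
            return np.linalg.cholesky(self.entries)
        except np.linalg.LinAlgError as exc:
            raise NumericalError(
                "projected mobility matrix is not positive definite"
            ) from exc


def projected_mobility(config: ChainConfig, track_coords: np.ndarray,
                       viscosity: float | None = None) -> MobilityMatrix:
    """N x N coupling matrix for the chain at the given track coordinates.

    Off-diagonal entries are the wall Green's function projected onto the
    (shared) track direction, with the minimum-image convention applied to
    the x-separation. The diagonal is the self-mobility.
    """
    eta = config.spec.viscosity if viscosity is None else viscosity
    pos = config.bead_positions(track_coords)
    n = pos.shape[0]
    tx, ty = config.track_direction[0], config.track_direction[1]

    dx = minimum_image(pos[None, :, 0] - pos[:, None, 0], config.ring_length)
    dy = pos[None, :, 1] - pos[:, None, 1]
    with np.errstate(divide="ignore", invalid="ignore"):
        m = projected_pair_mobility(dx, dy, config.spec.height, tx, ty, eta)
    np.fill_diagonal(m, self_mobility(eta, config.spec.bead_radius))
    m = 0.5 * (m + m.T)
    if not np.all(np.isfinite(m)):
        raise NumericalError("non-finite entries in projected mobility (bead overlap?)")
    return MobilityMatrix(entries=m, positions=pos, viscosity=eta)
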