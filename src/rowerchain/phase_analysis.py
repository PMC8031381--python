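"""From trajectories to phases, phase-difference profiles and chevron counts.

A rower's geometric phase maps (track coordinate, trap sign) onto [0, 2*pi):
0 at the start of the forward stroke, pi at the switch, advancing 2*pi per
beat. The spatial profile of neighbour phase differences is Fourier-analysed;
a "chevron" is a sign reversal of the neighbour phase difference, and on a
ring reversals come in pairs (one wedge up, one wedge down). The dominant
retained Fourier mode of the profile counts the chevron pairs, with modes
spanning fewer than three rowers discarded and a coefficient threshold below
which the profile is considered structureless.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dynamics import Trajectory
from .errors import ConfigurationError

__all__ = [
    "CHEVRON_THRESHOLD",
    "mode_cutoff",
    "geometric_phase",
    "wrap_phase",
    "PhaseProfile",
    "phase_profile",
    "fourier_coefficients",
    "ChevronDetection",
    "detect_chevrons",
    "run_chevron_count",
]

#: Coefficient threshold below which a profile carries no chevron; this is
#: the per-pair phase difference from one disruption every 40 rowers,
#: 2*pi/40 ~ 0.15, an implausibly weak feature in chains of 60.
CHEVRON_THRESHOLD = 0.15


def mode_cutoff(n_rowers: int) -> int:
    """Largest retained Fourier mode index: modes with N/(2k) <= 3 are dropped.

    For N = 60 this keeps k < 10, i.e. k_max = 9.
    """
    if n_rowers < 7:
        raise ConfigurationError("chain too short for any retained Fourier mode")
    return (n_rowers - 1) // 6


def geometric_phase(u, sigma, amplitude):
    """Phase in [0, 2*pi) from track coordinate and trap sign.

    Forward stroke (sigma=+1): phi = pi (u + A/2) / A; return stroke:
    phi = pi + pi (A/2 - u) / A. Coordinates beyond +-A/2 (noise overshoot
    just before the switch fires) are clamped. Vectorised.
    """
    u = np.asarray(u, dtype=float)
    sigma = np.asarray(sigma)
    amplitude = np.asarray(amplitude, dtype=float)
    half = amplitude / 2.0
    uc = np.clip(u, -half, half)
    phi = np.where(
        sigma > 0,
        np.pi * (uc + half) / amplitude,
        np.pi + np.pi * (half - uc) / amplitude,
    )
    phi = np.mod(phi, 2.0 * np.pi)
    return float(phi) if phi.ndim == 0 else phi


def wrap_phase(dphi):
    """Wrap phase differences into (-pi, pi]."""
    w = np.mod(-np.asarray(dphi, dtype=float) + np.pi, 2.0 * np.pi)
    out = -(w - np.pi)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class PhaseProfile:
    """Neighbour phase differences around the ring at one instant."""

    values: np.ndarray  # (N,) wrapped to (-pi, pi]; values[i] = phi_{i+1} - phi_i
    snapshot_time: float = float("nan")  # cycle units

    @property
    def n_rowers(self) -> int:
        return self.values.shape[0]

    def closure_defect(self) -> float:
        """Distance of sum(values) from the nearest multiple of 2*pi."""
        s = float(np.sum(self.values))
        return abs(s - 2.0 * np.pi * round(s / (2.0 * np.pi)))


def phase_profile(traj: Trajectory, t: float) -> PhaseProfile:
    """Profile of wrapped neighbour phase differences at the sample nearest ``t``."""
    if not traj.times[0] <= t <= traj.times[-1]:
        raise ConfigurationError(f"snapshot time {t} outside trajectory")
    s = int(np.argmin(np.abs(traj.times - t)))
    phi = traj.phases()[s]
    dphi = wrap_phase(np.roll(phi, -1) - phi)
    return PhaseProfile(values=dphi, snapshot_time=float(traj.times[s]))


def fourier_coefficients(profile: PhaseProfile, k_max: int | None = None) -> np.ndarray:
    """Amplitudes c_k, k = 1..k_max, of the spatial Fourier modes of the profile.

    Normalised by 2/N so that a pure cosine of amplitude s gives c_k = s
    (and a square wave of amplitude s gives (4/pi) s at its fundamental).
    """
    n = profile.n_rowers
    if k_max is None:
        k_max = mode_cutoff(n)
    if n < 2 * k_max:
        raise ConfigurationError("k_max too large for profile length")
    spectrum = np.fft.fft(profile.values)
    return 2.0 / n * np.abs(spectrum[1:k_max + 1])


@dataclass(frozen=True)
class ChevronDetection:
    """Outcome of chevron detection on one phase-profile snapshot."""

    coefficients: np.ndarray  # c_1..c_{k_max}
    dominant_mode: int  # argmax_k c_k (1-based)
    chevron_count: int  # 0 if below threshold, else dominant_mode
    above_threshold: bool


def detect_chevrons(coefficients: np.ndarray,
                    threshold: float = CHEVRON_THRESHOLD) -> ChevronDetection:
    """Count chevron pairs from the retained Fourier coefficients.

    If every coefficient is below ``threshold`` the profile is considered
    structureless (count 0); otherwise the dominant mode index is the
    number of wedge pairs.
    """
    c = np.asarray(coefficients, dtype=float)
    dominant = int(np.argmax(c)) + 1
    above = bool(c.max() >= threshold)
    return ChevronDetection(
        coefficients=c,
        dominant_mode=dominant,
        chevron_count=dominant if above else 0,
        above_threshold=above,
    )


def run_chevron_count(traj: Trajectory,
                      threshold: float = CHEVRON_THRESHOLD,
                      window_fraction: float = 0.05,
                      snapshot_cycles: float = 1.0) -> int:
    """Chevron count of one run: modal detection over late-time snapshots.

    Snapshots are taken every ``snapshot_cycles`` within the final
    ``window_fraction`` of the run; the modal count is returned, ties broken
    toward the count seen at the latest snapshot.
    """
    t_end = traj.times[-1]
    t_start = t_end * (1.0 - window_fraction)
    snaps = np.arange(np.ceil(t_start / snapshot_cycles) * snapshot_cycles,
                      t_end + 1e-9, snapshot_cycles)
    if snaps.size == 0:
        raise ConfigurationError("burn-in window leaves no snapshots; run too short")
    counts = []
    for t in snaps:
        prof = phase_profile(traj, t)
        det = detect_chevrons(fourier_coefficients(prof), threshold=threshold)
        counts.append(det.chevron_count)
    counts = np.asarray(counts)
    values, freq = np.unique(counts, return_counts=True)
    best = freq.max()
    tied = set(values[freq == best].tolist())
    for c in reversed(counts.tolist()):  # latest snapshot wins ties
        if c in tied:
            return int(c)
    raise AssertionError("unreachable")
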