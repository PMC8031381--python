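"""Binomial modelling of chevron occurrence across repeated simulations.

Each run contributes a chevron count; with ``n_sites`` available chevron
slots per chain (3 for six disruption points, since reversals pair up on a
ring) and ``n_runs`` runs, the chevron probability is the total count over
``n_sites * n_runs``. An exact two-tailed binomial test against 0.5
classifies each condition as showing no preference, a reduced chance of
chevrons, or an enhanced one.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AssumptionViolationError, ConfigurationError

__all__ = [
    "ALPHA",
    "max_chevrons_per_chain",
    "ChevronSurvey",
    "Preference",
    "PreferenceResult",
    "p_chevron",
    "binomial_test",
    "classify_preference",
    "chevron_histogram",
]

#: Significance level of the two-tailed preference test.
ALPHA = 0.05


def max_chevrons_per_chain(n_disruption_points: int) -> int:
    """Maximum chevrons per chain given the pairing constraint on a ring.

    Periodic boundaries force sign reversals of the neighbour phase
    difference to occur in pairs, so six disruption points allow at most 3.
    """
    if n_disruption_points < 0:
        raise ConfigurationError("n_disruption_points must be non-negative")
    return n_disruption_points // 2


class Preference(str, enum.Enum):
    NO_PREFERENCE = "no_preference"
    REDUCED = "reduced"
    ENHANCED = "enhanced"


@dataclass(frozen=True)
class ChevronSurvey:
    """Chevron counts for the repeated runs of one control level."""

    counts: np.ndarray  # (n_runs,) int
    n_sites: int  # assumed maximum chevrons per chain (3, 4 or 6)
    mechanism: str = "none"
    control_value: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "counts", np.asarray(self.counts, dtype=int))
        if self.counts.size == 0:
            raise ConfigurationError("survey needs at least one run")
        if self.n_sites <= 0:
            raise ConfigurationError("n_sites must be positive")
        if np.any(self.counts < 0):
            raise ConfigurationError("chevron counts must be non-negative")

    @property
    def n_runs(self) -> int:
        return int(self.counts.size)

    @property
    def n_trials(self) -> int:
        return self.n_sites * self.n_runs

    def check_counts(self) -> None:
        bad = np.nonzero(self.counts > self.n_sites)[0]
        if bad.size:
            raise AssumptionViolationError(
                f"counts exceed n_sites={self.n_sites} in runs {bad.tolist()} "
                f"(values {self.counts[bad].tolist()})"
            )

    def bimodality_warning(self, mass: float = 0.25) -> bool:
        """True when both 0 and n_sites hold >= ``mass`` of the runs — the
        fixed-trials binomial assumption is then doubtful (frequency detuning)."""
        frac0 = np.mean(self.counts == 0)
        frac_max = np.mean(self.counts >= self.n_sites)
        return bool(frac0 >= mass and frac_max >= mass)


@dataclass(frozen=True)
class PreferenceResult:
    """Estimated chevron probability and its preference classification."""

    p_ch: float
    p_value: float
    preference: Preference
    n_successes: int = 0
    n_trials: int = 0
    warnings: tuple[str, ...] = field(default_factory=tuple)


def p_chevron(survey: ChevronSurvey) -> float:
    """Total observed chevrons over the total possible chevron occurrences."""
    survey.check_counts()
    return float(survey.counts.sum()) / survey.n_trials


def binomial_test(successes: int, trials: int, p0: float = 0.5) -> float:
    """Exact two-tailed binomial p-value (minimum-likelihood method).

    Sums the Binomial(trials, p0) probabilities of every outcome no more
    probable than the observed one.
    """
    if not 0 <= successes <= trials:
        raise ConfigurationError("need 0 <= successes <= trials")
    return float(stats.binomtest(successes, trials, p0, alternative="two-sided").pvalue)


def classify_preference(survey: ChevronSurvey, alpha: float = ALPHA) -> PreferenceResult:
    """Exact two-tailed test of the chevron proportion against 0.5."""
    p_ch = p_chevron(survey)
    k = int(survey.counts.sum())
    n = survey.n_trials
    p_value = binomial_test(k, n, 0.5)
    if p_value > alpha:
        pref = Preference.NO_PREFERENCE
    elif p_ch < 0.5:
        pref = Preference.REDUCED
    else:
        pref = Preference.ENHANCED
    warnings = ("bimodal_counts",) if survey.bimodality_warning() else ()
    return PreferenceResult(p_ch=p_ch, p_value=p_value, preference=pref,
                           n_successes=k, n_trials=n, warnings=warnings)


def chevron_histogram(survey: ChevronSurvey) -> pd.DataFrame:
    """Observed count frequencies next to the no-preference reference.

    Columns: ``count``, ``observed`` and ``reference`` — the latter being
    ``n_runs * Binomial(n_sites, 0.5)`` expected frequencies.
    """
    survey.check_counts()
    ks = np.arange(survey.n_sites + 1)
    observed = np.array([(survey.counts == k).sum() for k in ks])
    reference = survey.n_runs * stats.binom.pmf(ks, survey.n_sites, 0.5)
    return pd.DataFrame({"count": ks, "observed": observed, "reference": reference})
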