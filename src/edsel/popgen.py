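"""Mutation-limited fixation race between a direct substitution and
editing-enhancing mutations.

In a low-polymorphism population (Ne*mu << 1) adaptation waits for the
next beneficial mutation to arise and fix.  For a strongly selected
mutation (4*Ne*s >> 1) the expected waiting time is 1/(4*Ne*s*mu), so
when a single direct A->G change (rate mu1, benefit s1) competes with M
editing-enhancing context mutations (each rate mu2, benefit s2), the
editing path wins the race with probability
M*mu2*s2 / (mu1*s1 + M*mu2*s2).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)


class WeakSelectionWarning(UserWarning):
    """4*Ne*s is not >> 1; the waiting-time formula is out of its regime."""


@dataclass(frozen=True)
class FixationParams:
    mu1: float  # rate of the direct A->G mutation
    s1: float  # selection coefficient of the direct mutation
    mu2: float  # per-site rate of an editing-enhancing mutation
    s2: float  # its selection coefficient
    M: int = 1  # number of editing-enhancing target sites
    Ne: float = 1e4  # effective population size

    def __post_init__(self):
        if min(self.mu1, self.s1, self.s2, self.Ne) <= 0 or self.mu2 < 0 or self.M < 0:
            raise ValueError("rates, selection coefficients and Ne must be positive")


def _check_strong_selection(Ne: float, s: float) -> None:
    if 4.0 * Ne * s < 10.0:
        warnings.warn(
            f"4*Ne*s = {4 * Ne * s:.3g} < 10: strong-selection assumption violated",
            WeakSelectionWarning,
            stacklevel=3,
        )


def fixation_time(Ne: float, s: float, mu: float) -> float:
    """Expected generations until a new strongly beneficial mutation fixes,
    1 / (4 * Ne * s * mu)."""
    if min(Ne, s, mu) <= 0:
        raise ValueError("Ne, s and mu must be positive")
    _check_strong_selection(Ne, s)
    return 1.0 / (4.0 * Ne * s * mu)


def first_fixation_probability(params: FixationParams) -> float:
    """Probability the editing-enhancing path fixes first:
    M*mu2*s2 / (mu1*s1 + M*mu2*s2)."""
    _check_strong_selection(params.Ne, params.s1)
    direct = params.mu1 * params.s1
    editing = params.M * params.mu2 * params.s2
    if direct + editing == 0:
        raise ValueError("both competing fluxes are zero")
    return editing / (direct + editing)


def race_monte_carlo(
    params: FixationParams, n_reps: int = 100_000, seed: int | None = None
) -> float:
    """Empirical first-arrival probability via competing exponential clocks.

    The direct and editing paths fire at rates proportional to mu*s
    (origination-and-fixation flux); returns the fraction of replicates
    the editing path wins.  Agrees with the closed form within Monte
    Carlo error.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rate_d = params.mu1 * params.s1
    rate_e = params.M * params.mu2 * params.s2
    if rate_e == 0:
        return 0.0
    rng = np.random.default_rng(seed)
    t_d = rng.exponential(1.0 / rate_d, size=n_reps)
    t_e = rng.exponential(1.0 / rate_e, size=n_reps)
    return float(np.mean(t_e < t_d))
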