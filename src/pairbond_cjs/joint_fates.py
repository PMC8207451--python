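"""Bivariate-Bernoulli fate distributions for pair-bonded animals.

A mated male-female pair has four possible outcomes at each survival or
recapture step: both succeed, only the female does, only the male does, or
neither does.  The joint distribution is parameterized by the two marginal
probabilities and a linear correlation coefficient; the admissible
correlation range is the Frechet-Hoeffding band for two Bernoulli
marginals, conveniently written in terms of the odds ratio and odds
product of the marginals.

When a pair is temporarily separated (``together=False``) the correlation
term vanishes and the members' fates are independent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

__all__ = [
    "MarginalPair",
    "CorrelationBounds",
    "JointFateDistribution",
    "STATE_LABELS",
    "odds_product",
    "odds_ratio",
    "correlation_bounds",
    "joint_fate_distribution",
    "survival_transition_matrix",
    "recapture_emission_matrix",
]

#: Pair states, in the order used by every 4-vector and matrix in this module.
STATE_LABELS = ("both", "female_only", "male_only", "neither")

#: Correlations this far outside the admissible band are clamped to the
#: boundary instead of raising; grid endpoints like gamma=1.0 must not fail
#: from floating-point rounding.
BOUND_TOL = 1e-10


class MarginalPair(NamedTuple):
    """Marginal success probabilities for the female and male of a pair."""

    prob_female: float
    prob_male: float


class CorrelationBounds(NamedTuple):
    """Admissible linear-correlation interval for two Bernoulli marginals."""

    lower: float
    upper: float

    def contains(self, corr: float, tol: float = BOUND_TOL) -> bool:
        return self.lower - tol <= corr <= self.upper + tol

    def clamp(self, corr: float, tol: float = BOUND_TOL) -> float:
        """Clamp a correlation within ``tol`` of a boundary onto it.

        Raises :class:`ValueError` when ``corr`` is genuinely outside the
        admissible interval.
        """
        if not self.contains(corr, tol):
            raise ValueError(
                f"correlation {corr} outside the admissible interval "
                f"[{self.lower:.6g}, {self.upper:.6g}] for these marginals"
            )
        return min(max(corr, self.lower), self.upper)


@dataclass(frozen=True)
class JointFateDistribution:
    """Probabilities of the four pair outcomes of one survival/recapture step."""

    both: float
    female_only: float
    male_only: float
    neither: float

    def as_array(self) -> np.ndarray:
        return np.array([self.both, self.female_only, self.male_only, self.neither])


def _as_pair(m) -> MarginalPair:
    pf, pm = m
    return MarginalPair(float(pf), float(pm))


def _require_interior(m: MarginalPair) -> None:
    for label, value in (("female", m.prob_female), ("male", m.prob_male)):
        if not 0.0 < value < 1.0:
            raise ValueError(
                f"{label} marginal probability {value} must lie strictly in (0, 1)"
            )


def odds_product(m) -> float:
    """Product of the marginal odds, odds(pF) * odds(pM).

    Its square root gives the magnitude of the most negative admissible
    correlation (capped at 1).
    """
    m = _as_pair(m)
    _require_interior(m)
    pf, pm = m
    return (pf / (1.0 - pf)) * (pm / (1.0 - pm))


def odds_ratio(m) -> float:
    """Ratio of the marginal odds, odds(pF) / odds(pM)."""
    m = _as_pair(m)
    _require_interior(m)
    pf, pm = m
    return (pf / (1.0 - pf)) / (pm / (1.0 - pm))


def correlation_bounds(m) -> CorrelationBounds:
    """Frechet-Hoeffding correlation bounds for two Bernoulli marginals.

    lower = -min(sqrt(OP), 1/sqrt(OP)) and upper = min(sqrt(OR), 1/sqrt(OR));
    the upper bound equals 1 exactly when the two marginals coincide.
    """
    m = _as_pair(m)
    _require_interior(m)
    sqrt_op = math.sqrt(odds_product(m))
    sqrt_or = math.sqrt(odds_ratio(m))
    return CorrelationBounds(
        lower=-min(sqrt_op, 1.0 / sqrt_op),
        upper=min(sqrt_or, 1.0 / sqrt_or),
    )


def joint_fate_distribution(m, corr: float, together=True) -> JointFateDistribution:
    """Joint outcome distribution for one pair step.

    ``P(both) = together * corr * sigma_F * sigma_M + pF * pM`` with the
    remaining cells fixed by the marginals.  A separated pair
    (``together`` falsy) has independent fates regardless of ``corr``.
    Degenerate marginals (0 or 1) have zero standard deviation, so the
    correlation term vanishes and the independence product is returned.
    """
    m = _as_pair(m)
    pf, pm = m
    if not (0.0 <= pf <= 1.0 and 0.0 <= pm <= 1.0):
        raise ValueError(f"marginals {m} must lie in [0, 1]")
    interior = 0.0 < pf < 1.0 and 0.0 < pm < 1.0
    if together and interior:
        corr = correlation_bounds(m).clamp(float(corr))
        sigma_f = math.sqrt(pf * (1.0 - pf))
        sigma_m = math.sqrt(pm * (1.0 - pm))
        both = corr * sigma_f * sigma_m + pf * pm
    else:
        both = pf * pm
    female_only = pf - both
    male_only = pm - both
    neither = 1.0 - both - female_only - male_only
    # Exact-boundary correlations can leave cells at -1e-17; snap to zero.
    cells = [both, female_only, male_only, neither]
    cells = [0.0 if -1e-12 < c < 0.0 else c for c in cells]
    return JointFateDistribution(*cells)


def _pair_state_matrix(m: MarginalPair, corr: float, together) -> np.ndarray:
    top = joint_fate_distribution(m, corr, together).as_array()
    pf, pm = m
    return np.array(
        [
            top,
            [0.0, pf, 0.0, 1.0 - pf],
            [0.0, 0.0, pm, 1.0 - pm],
            [0.0, 0.0, 0.0, 1.0],
        ]
    )


def survival_transition_matrix(m, gamma: float, together=True) -> np.ndarray:
    """4x4 multinomial transition matrix of the pair survival process.

    Rows index the pair state at the start of the interval, columns the
    state at its end, both in :data:`STATE_LABELS` order.  Only an intact
    pair (row ``both``) carries the correlation; a lone survivor follows an
    independent Bernoulli survival draw, and death is absorbing.
    """
    return _pair_state_matrix(_as_pair(m), gamma, together)


def recapture_emission_matrix(m, rho: float, together=True) -> np.ndarray:
    """4x4 multinomial emission matrix of the pair recapture process.

    Rows index the alive state of the pair at the sampling occasion,
    columns the observed capture outcome, in :data:`STATE_LABELS` order.
    Structurally identical to the survival transition with (pF, pM, rho).
    """
    return _pair_state_matrix(_as_pair(m), rho, together)
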