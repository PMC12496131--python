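"""ACMG/AMP likelihood points for a given prior probability of pathogenicity.

The ACMG/AMP framework grades evidence as supporting, moderate, strong or
very strong, with likelihood-ratio (LR) points that scale exponentially:
if X is the very-strong point, the lower levels are X^(1/2), X^(1/4) and
X^(1/8), and the benign points are the reciprocals.  X itself is pinned down
by the combining rules: each rule lists a minimal combination of evidence
whose combined LR is X raised to the sum of the evidence weights
(supporting = 1/8, moderate = 1/4, strong = 1/2, very strong = 1), and the
posterior probability of pathogenicity implied by that combined LR under the
prior must clear a floor (0.99 for Pathogenic rules, 0.90 for Likely
Pathogenic rules).

Because two of the fourteen P/LP rules are internally inconsistent at any
single X, the very-strong point is defined as the smallest LR satisfying at
least 13 of the 14 posterior criteria.  At the widely used prior of 0.1 this
yields 350; at 0.0441 it yields 1131.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "CombiningRule",
    "EvidenceScale",
    "enumerate_combining_rules",
    "posterior_probability",
    "criteria_satisfied",
    "very_strong_threshold",
    "likelihood_points",
    "evidence_scale_for_prior",
]

#: Posterior-probability floor for Pathogenic combining rules.
POSTERIOR_FLOOR_PATHOGENIC = 0.99
#: Posterior-probability floor for Likely Pathogenic combining rules.
POSTERIOR_FLOOR_LIKELY_PATHOGENIC = 0.90

#: Number of criteria (out of 14) that must be satisfied by the very-strong point.
MIN_CRITERIA_SATISFIED = 13


@dataclass(frozen=True)
class CombiningRule:
    """One ACMG/AMP combining rule at its minimal satisfying combination.

    ``exponent`` is the sum of evidence weights of the minimal combination,
    so the combined LR of the rule is ``X ** exponent`` for a very-strong
    candidate ``X``.  ``posterior_floor`` is the posterior probability the
    combined LR must reach under the prior.
    """

    name: str
    exponent: float
    posterior_floor: float


# The 8 Pathogenic and 6 Likely Pathogenic combining rules, in the order of
# the original ACMG/AMP guidelines, each at its minimal satisfying count.
# Weights: very strong = 1, strong = 1/2, moderate = 1/4, supporting = 1/8.
_RULES: tuple[CombiningRule, ...] = (
    # Pathogenic
    CombiningRule("P_i_a", 1 + 1 / 2, POSTERIOR_FLOOR_PATHOGENIC),      # VS + St
    CombiningRule("P_i_b", 1 + 2 / 4, POSTERIOR_FLOOR_PATHOGENIC),      # VS + 2M
    CombiningRule("P_i_c", 1 + 1 / 4 + 1 / 8, POSTERIOR_FLOOR_PATHOGENIC),  # VS + M + Su
    CombiningRule("P_i_d", 1 + 2 / 8, POSTERIOR_FLOOR_PATHOGENIC),      # VS + 2Su
    CombiningRule("P_ii", 2 / 2, POSTERIOR_FLOOR_PATHOGENIC),           # 2St
    CombiningRule("P_iii_a", 1 / 2 + 3 / 4, POSTERIOR_FLOOR_PATHOGENIC),    # St + 3M
    CombiningRule("P_iii_b", 1 / 2 + 2 / 4 + 2 / 8, POSTERIOR_FLOOR_PATHOGENIC),  # St + 2M + 2Su
    CombiningRule("P_iii_c", 1 / 2 + 1 / 4 + 4 / 8, POSTERIOR_FLOOR_PATHOGENIC),  # St + M + 4Su
    # Likely pathogenic
    CombiningRule("LP_i", 1 + 1 / 4, POSTERIOR_FLOOR_LIKELY_PATHOGENIC),    # VS + M
    CombiningRule("LP_ii", 1 / 2 + 1 / 4, POSTERIOR_FLOOR_LIKELY_PATHOGENIC),   # St + M
    CombiningRule("LP_iii", 1 / 2 + 2 / 8, POSTERIOR_FLOOR_LIKELY_PATHOGENIC),  # St + 2Su
    CombiningRule("LP_iv", 3 / 4, POSTERIOR_FLOOR_LIKELY_PATHOGENIC),       # 3M
    CombiningRule("LP_v", 2 / 4 + 2 / 8, POSTERIOR_FLOOR_LIKELY_PATHOGENIC),    # 2M + 2Su
    CombiningRule("LP_vi", 1 / 4 + 4 / 8, POSTERIOR_FLOOR_LIKELY_PATHOGENIC),   # M + 4Su
)


@dataclass(frozen=True)
class EvidenceScale:
    """The eight LR evidence points implied by a very-strong point ``X``.

    Pathogenic points are X, X^(1/2), X^(1/4), X^(1/8); benign points are
    their reciprocals.  ``prior`` records the prior the scale was derived
    under.
    """

    prior: float
    very_strong: float
    strong: float
    moderate: float
    supporting: float
    benign_supporting: float
    benign_moderate: float
    benign_strong: float
    benign_very_strong: float

    def pathogenic_points(self) -> list[tuple[str, float]]:
        """(level, LR point) pairs, strongest first."""
        return [
            ("pathogenic_very_strong", self.very_strong),
            ("pathogenic_strong", self.strong),
            ("pathogenic_moderate", self.moderate),
            ("pathogenic_supporting", self.supporting),
        ]

    def benign_points(self) -> list[tuple[str, float]]:
        """(level, LR point) pairs, strongest first."""
        return [
            ("benign_very_strong", self.benign_very_strong),
            ("benign_strong", self.benign_strong),
            ("benign_moderate", self.benign_moderate),
            ("benign_supporting", self.benign_supporting),
        ]

    def to_dict(self) -> dict[str, float]:
        return {
            "prior": self.prior,
            "pathogenic_very_strong": self.very_strong,
            "pathogenic_strong": self.strong,
            "pathogenic_moderate": self.moderate,
            "pathogenic_supporting": self.supporting,
            "benign_supporting": self.benign_supporting,
            "benign_moderate": self.benign_moderate,
            "benign_strong": self.benign_strong,
            "benign_very_strong": self.benign_very_strong,
        }


def enumerate_combining_rules() -> list[CombiningRule]:
    """Return the 14 P/LP combining rules in a fixed, documented order.

    Order: the 8 Pathogenic rules (P_i_a..P_i_d, P_ii, P_iii_a..P_iii_c)
    followed by the 6 Likely Pathogenic rules (LP_i..LP_vi).
    """
    return list(_RULES)


def _check_prior(prior: float) -> None:
    if not (0.0 < prior < 1.0) or not math.isfinite(prior):
        raise ValueError(f"prior must lie strictly in (0, 1); got {prior!r}")


def posterior_probability(combined_lr: float, prior: float) -> float:
    """Posterior probability of pathogenicity from a combined LR and a prior.

    Standard odds update: posterior = LR*pi / (LR*pi + 1 - pi).
    """
    if not math.isfinite(combined_lr) or combined_lr <= 0:
        raise ValueError(f"combined_lr must be a finite positive number; got {combined_lr!r}")
    _check_prior(prior)
    return combined_lr * prior / (combined_lr * prior + 1.0 - prior)


def criteria_satisfied(x: float, prior: float) -> int:
    """Count the combining-rule posterior criteria satisfied by candidate ``x``.

    A rule is satisfied when ``posterior_probability(x ** exponent, prior)``
    reaches its posterior floor.  Monotone non-decreasing in ``x``.
    """
    if not math.isfinite(x) or x <= 1.0:
        raise ValueError(f"candidate very-strong LR must exceed 1; got {x!r}")
    _check_prior(prior)
    return sum(
        posterior_probability(x**rule.exponent, prior) >= rule.posterior_floor
        for rule in _RULES
    )


def very_strong_threshold(prior: float, rounding: str = "floor") -> float:
    """Smallest LR satisfying at least 13 of the 14 posterior criteria.

    The continuous infimum is found by bisection (relative tolerance well
    below 1e-6) and reported at integer resolution.  ``rounding`` selects the
    integer convention: ``"floor"`` (default), ``"nearest"``, or ``"none"``
    to return the continuous solution.  Strictly decreasing in ``prior``.
    """
    _check_prior(prior)
    if rounding not in ("floor", "nearest", "none"):
        raise ValueError(f"unknown rounding convention {rounding!r}")

    lo = 1.0 + 1e-12
    hi = 2.0
    while criteria_satisfied(hi, prior) < MIN_CRITERIA_SATISFIED:
        hi *= 2.0
        if hi > 1e15:  # pragma: no cover - unreachable for priors in (0, 1)
            raise RuntimeError("bisection bracket expansion failed")
    # invariant: count(lo) < 13 <= count(hi)
    for _ in range(200):
        if hi - lo <= 1e-12 * hi:
            break
        mid = 0.5 * (lo + hi)
        if criteria_satisfied(mid, prior) >= MIN_CRITERIA_SATISFIED:
            hi = mid
        else:
            lo = mid
    if rounding == "none":
        return hi
    if rounding == "nearest":
        return float(round(hi))
    # floor; the 1e-9 guard absorbs bisection round-off when the continuous
    # solution sits exactly on an integer
    return float(math.floor(hi + 1e-9))


def likelihood_points(x: float, prior: float) -> EvidenceScale:
    """Derive the full evidence scale from a very-strong point ``x``.

    Lower pathogenic levels are the square roots down the ladder
    (strong = x^(1/2), moderate = x^(1/4), supporting = x^(1/8)); benign
    points are the reciprocals of the pathogenic points.
    """
    if not math.isfinite(x) or x <= 1.0:
        raise ValueError(f"very-strong LR point must exceed 1; got {x!r}")
    _check_prior(prior)
    strong = x ** (1 / 2)
    moderate = x ** (1 / 4)
    supporting = x ** (1 / 8)
    return EvidenceScale(
        prior=prior,
        very_strong=x,
        strong=strong,
        moderate=moderate,
        supporting=supporting,
        benign_supporting=1.0 / supporting,
        benign_moderate=1.0 / moderate,
        benign_strong=1.0 / strong,
        benign_very_strong=1.0 / x,
    )


def evidence_scale_for_prior(prior: float, rounding: str = "floor") -> EvidenceScale:
    """Convenience: threshold search followed by the exponent ladder."""
    return likelihood_points(very_strong_threshold(prior, rounding=rounding), prior)
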