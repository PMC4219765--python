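"""Stochastic social-interaction perturbation of the daily energy balance.

The social environment nudges an individual's intake and expenditure away
from their personal routine.  The perturbation is the product of two
factors: *social proximity* ``alpha_s`` in [0, 1] (how strongly the
individual is coupled to the people around them) and *social influence*
``epsilon`` in kcal/day (the magnitude of the energetic difference those
people induce).  The signed product ``sign * alpha_s * epsilon`` — the
*social interaction* — enters the daily energy balance as a single term.

Three experimental cases:

* ``fixed_proximity`` (case i): alpha_s fixed (typically 0.5), epsilon a
  deterministic sweep value in [20, 150] kcal/day.
* ``fixed_influence`` (case ii): epsilon fixed (typically 50 kcal/day),
  alpha_s a sweep value in [0, 1].
* ``random`` (case iii): each day alpha_s ~ U(0, 1), epsilon ~ U(0, 300)
  and the sign is +/- with equal probability (zero mean).

The +/-300 kcal/day magnitude cap mirrors the range of daily
intake-expenditure gaps seen in FAO energy distributions, roughly 10-20%
of a typical daily intake.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "EPSILON_MAX_KCAL",
    "SocialParams",
    "social_term",
    "perturbed_balance",
]

#: Upper bound of the social-influence magnitude, kcal/day.
EPSILON_MAX_KCAL = 300.0

_CASES = ("off", "fixed_proximity", "fixed_influence", "random")
_SIGNS = {"positive": 1.0, "negative": -1.0}


@dataclass(frozen=True)
class SocialParams:
    """Configuration of the social-interaction term."""

    case: str = "off"
    alpha_s: float = 0.5
    epsilon_kcal: float = 50.0
    sign_policy: str = "positive"

    def __post_init__(self) -> None:
        if self.case not in _CASES:
            raise ValueError(f"case must be one of {_CASES}, got {self.case!r}")
        if not 0.0 <= self.alpha_s <= 1.0:
            raise ValueError(f"alpha_s must lie in [0, 1], got {self.alpha_s}")
        if not 0.0 <= self.epsilon_kcal <= EPSILON_MAX_KCAL:
            raise ValueError(
                f"epsilon_kcal must lie in [0, {EPSILON_MAX_KCAL:g}], got {self.epsilon_kcal}"
            )
        if self.sign_policy not in ("positive", "negative", "random"):
            raise ValueError(
                f"sign_policy must be 'positive', 'negative' or 'random', got {self.sign_policy!r}"
            )


def _draw_sign(policy: str, rng: np.random.Generator) -> float:
    if policy == "random":
        return 1.0 if rng.random() < 0.5 else -1.0
    return _SIGNS[policy]


def social_term(params: SocialParams, rng: np.random.Generator) -> float:
    """One day's signed social interaction, kcal/day.

    Case ``off`` returns 0.  Cases i/ii use the configured alpha_s and
    epsilon with the configured sign (deterministic unless the sign policy
    is random).  Case iii redraws proximity, influence and sign
    independently every day.
    """
    if params.case == "off":
        return 0.0
    if params.case == "random":
        alpha = rng.uniform(0.0, 1.0)
        eps = rng.uniform(0.0, EPSILON_MAX_KCAL)
        sign = 1.0 if rng.random() < 0.5 else -1.0
        return sign * alpha * eps
    sign = _draw_sign(params.sign_policy, rng)
    return sign * params.alpha_s * params.epsilon_kcal


def perturbed_balance(i_ind: float, e_ind: float, term: float) -> float:
    """Effective daily imbalance: (I_ind - E_ind) + social term, kcal/day.

    The net social energetic difference enters the balance once, as a
    single signed term; the individual intake and expenditure series are
    left untouched (the trajectory records the term in its own column).
    """
    return (i_ind - e_ind) + term
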