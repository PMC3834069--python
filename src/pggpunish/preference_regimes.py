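"""Selfish versus disadvantageous-inequity-averse (DIA) preferences.

Two parameter-free satisfaction predicates:

* A purely self-regarding agent is satisfied when her own P&L did not
  decrease across the transition she just experienced.
* A DIA agent dislikes exactly two situations — contributing at least as
  much as her group fellows while earning strictly less, or contributing
  strictly more while earning no more.  She is satisfied otherwise; there
  is no aversion to advantageous inequity.

Each preference pins down a range of punishment propensities.  Solving the
selfish predicate on the one-deviator transition (one agent lowers her
contribution by ``d`` against a homogeneous group) gives the largest
propensity a selfish deviator still tolerates,
``(1 - r/N) / ((N-1) e)`` — strictly below the bifurcation threshold, so
selfish preferences can never carry the population over the bifurcation.
Solving the DIA predicate for a cooperator facing a lone defector gives
the smallest propensity DIA agents require, ``1/((N-1)e - 1)`` with strict
inequality — exactly the bifurcation threshold, so DIA preferences demand
punishment strong enough to make coordination stable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Tuple

from .game_core import GameConfig

__all__ = [
    "PreferenceSpec",
    "selfish_satisfied",
    "dia_satisfied",
    "alpha_preference_bounds",
]


@dataclass(frozen=True)
class PreferenceSpec:
    """Label of a supported preference type (predicates are parameter-free)."""

    kind: Literal["selfish", "dia"]

    def __post_init__(self):
        if self.kind not in ("selfish", "dia"):
            raise ValueError(f"unsupported preference kind {self.kind!r}")


def selfish_satisfied(pl_now: float, pl_prev: float) -> bool:
    """A purely self-regarding agent accepts a transition iff her own P&L
    did not decrease."""
    return pl_now >= pl_prev


def dia_satisfied(
    c_i: float, c_others_mean: float, pl_i: float, pl_others_mean: float
) -> bool:
    """Satisfaction of a disadvantageous-inequity-averse agent.

    True iff at least one of

    1. she contributes less than her group fellows' average,
    2. she earns strictly more than their average P&L,
    3. she contributes no more than them and earns no less.

    This is the negation of the two dislike cases (equal-or-higher
    contribution with strictly smaller payoff; strictly higher contribution
    with smaller-or-equal payoff).
    """
    return (
        c_i < c_others_mean
        or pl_i > pl_others_mean
        or (c_i <= c_others_mean and pl_i >= pl_others_mean)
    )


def alpha_preference_bounds(config: GameConfig) -> Tuple[float, float]:
    """(selfish_sup, dia_inf): the propensity ranges the two preferences imply.

    ``selfish_sup = (1 - r/N) / ((N-1) e)`` — the largest common propensity
    at which a lone downward deviation still weakly raises the deviator's
    own next-period P&L (her saving ``(1 - r/N)|dc|`` at least offsets the
    punishment ``(N-1) e alpha |dc|`` she receives).

    ``dia_inf = 1/((N-1)e - 1)`` — above this (strictly), a cooperator
    facing a lone defector earns at least the defector's P&L, so the DIA
    dislike conditions never trigger.

    For every valid configuration ``selfish_sup < dia_inf``: selfish
    preferences keep punishment below the bifurcation, DIA preferences
    push it above.
    """
    N, e, r = config.N, config.e, config.r
    selfish_sup = (1.0 - r / N) / ((N - 1) * e)
    dia_inf = 1.0 / ((N - 1) * e - 1.0)
    return selfish_sup, dia_inf
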