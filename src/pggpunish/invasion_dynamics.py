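"""Invasion analysis: DIA punishers against selfish non-punishers.

Two internally homogeneous groups play one mixed public goods game with
cross-group punishment: ``n_selfish`` self-regarding agents at a common
norm contribution (punishment propensity ``alpha_selfish``, by default 0)
and ``n_dia`` disadvantageous-inequity-averse agents whose contribution
deviates from that norm by ``+-delta`` — negatively with probability
``p_neg`` each period, positively otherwise (propensity ``alpha_dia``,
by default the coordination optimum ``2/(N(e-1))`` of the total
population).

Per-capita P&L differences (DIA minus selfish) in the two branches — the
pool return cancels in the difference:

    D(-) = delta * (1 - alpha_selfish * (e * n_selfish - n_dia))
    D(+) = delta * (-1 + alpha_dia * (e * n_dia - n_selfish))

so the expected per-period success is ``p_neg*D(-) + (1-p_neg)*D(+)``,
antisymmetric between the two viewpoints.  The smallest deviation
probability at which the DIA group gains in expectation is

    p_min = max(0, -D(+) / (D(-) - D(+)))        (when D(-) > D(+)).

With non-punishing selfish residents, ``D(-) > 0`` always: a lone DIA
deviator already invades for ``p > p_min``, and once the DIA group reaches
half the population ``D(+) >= 0`` too (``p_min = 0``) — the selfish group
can no longer win a single period and is eventually absorbed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .game_core import GameConfig, Profile, payoffs
from .replicator_dynamics import viability_floor

__all__ = [
    "CompetitionSpec",
    "branch_success",
    "expected_success",
    "p_min",
    "takeover_probability",
    "survival_floor_contribution",
    "mixed_profile_branch_success",
]


@dataclass(frozen=True)
class CompetitionSpec:
    """Two-group competition setup; group sizes, propensities, deviation."""

    n_selfish: int
    n_dia: int
    alpha_selfish: float
    alpha_dia: float
    delta: float
    p_neg: float
    config: GameConfig
    base_contribution: float = 10.0

    def __post_init__(self):
        if self.n_selfish + self.n_dia < 2:
            raise ValueError("total population must be at least 2")
        if self.n_selfish < 0 or self.n_dia < 0:
            raise ValueError("group sizes must be non-negative")
        if self.delta <= 0:
            raise ValueError("deviation magnitude delta must be positive")
        if not 0.0 <= self.p_neg <= 1.0:
            raise ValueError("p_neg must be a probability")
        if self.alpha_selfish < 0 or self.alpha_dia < 0:
            raise ValueError("propensities must be non-negative")
        if self.base_contribution < viability_floor(self.config):
            raise ValueError(
                "base contribution lies below the viability floor "
                f"{viability_floor(self.config)}"
            )


def branch_success(sign: str, spec: CompetitionSpec) -> float:
    """Per-capita P&L difference (DIA minus selfish) for one deviation branch.

    ``sign`` is ``"-"`` (DIA group deviates ``-delta``) or ``"+"``.
    Closed form; validated against explicit mixed-profile payoff
    evaluation (:func:`mixed_profile_branch_success`).
    """
    d, e = spec.delta, spec.config.e
    if sign == "-":
        return d * (1.0 - spec.alpha_selfish * (e * spec.n_selfish - spec.n_dia))
    if sign == "+":
        return d * (-1.0 + spec.alpha_dia * (e * spec.n_dia - spec.n_selfish))
    raise ValueError(f"sign must be '-' or '+', got {sign!r}")


def mixed_profile_branch_success(sign: str, spec: CompetitionSpec) -> float:
    """Oracle route: build the explicit mixed profile, run the payoff engine
    and difference the per-capita P&L of the two groups.

    Uses a one-off game configuration of size ``n_selfish + n_dia`` (the
    whole population plays one PGG with cross-group punishment).
    """
    n_total = spec.n_selfish + spec.n_dia
    r_mixed = spec.config.per_capita_return * n_total
    cfg = GameConfig(
        N=n_total,
        r=r_mixed,
        e=spec.config.e,
        E=max(spec.config.E, spec.base_contribution + spec.delta),
        c_m=0.0,
    )
    shift = spec.delta if sign == "+" else -spec.delta
    if sign not in ("-", "+"):
        raise ValueError(f"sign must be '-' or '+', got {sign!r}")
    c = np.concatenate(
        [
            np.full(spec.n_selfish, spec.base_contribution),
            np.full(spec.n_dia, spec.base_contribution + shift),
        ]
    )
    a = np.concatenate(
        [
            np.full(spec.n_selfish, spec.alpha_selfish),
            np.full(spec.n_dia, spec.alpha_dia),
        ]
    )
    res = payoffs(Profile(contributions=c, alphas=a), cfg)
    pl_selfish = res.pl[: spec.n_selfish].mean() if spec.n_selfish else 0.0
    pl_dia = res.pl[spec.n_selfish:].mean() if spec.n_dia else 0.0
    return float(pl_dia - pl_selfish)


def expected_success(spec: CompetitionSpec) -> float:
    """Expected per-period per-capita success of the DIA group:
    ``p_neg * D(-) + (1 - p_neg) * D(+)``.  The selfish group's viewpoint
    is exactly the negative."""
    return spec.p_neg * branch_success("-", spec) + (1.0 - spec.p_neg) * branch_success(
        "+", spec
    )


def p_min(spec: CompetitionSpec) -> Optional[float]:
    """Smallest negative-deviation probability with positive expected success.

    Returns 0 when the positive branch already favors the DIA group
    (invasion at any p), ``None`` when neither branch does (no invasion),
    and raises on the degenerate case ``D(-) == D(+)`` where no threshold
    is defined.
    """
    d_minus = branch_success("-", spec)
    d_plus = branch_success("+", spec)
    if d_plus >= 0.0:
        return 0.0
    if math.isclose(d_minus, d_plus, rel_tol=0.0, abs_tol=1e-12):
        raise ValueError("degenerate branches D(-) == D(+): threshold undefined")
    if d_minus <= 0.0:
        return None  # DIA group loses both branches: no invasion
    return max(0.0, -d_plus / (d_minus - d_plus))


def takeover_probability(
    spec: CompetitionSpec,
    replicates: int,
    seed: int,
    max_periods: int = 100_000,
    rederive_alpha_dia: bool = True,
) -> float:
    """Monte-Carlo probability that the DIA group absorbs the population.

    Birth-death dynamics: each period the deviation sign is drawn
    (negative with ``p_neg``), the per-capita branch success is computed at
    the current group sizes, and the group with strictly higher per-capita
    P&L converts one member of the other (ties change nothing).  The DIA
    propensity is re-derived each period as the coordination optimum
    ``2/(N_total (e-1))`` of the whole population when
    ``rederive_alpha_dia`` is set.  Absorption: either group extinct.
    Replicates not absorbed within ``max_periods`` count as failures.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rng = np.random.default_rng(seed)
    n_total = spec.n_selfish + spec.n_dia
    e = spec.config.e
    wins = 0
    for _ in range(replicates):
        n_dia = spec.n_dia
        n_selfish = spec.n_selfish
        for _ in range(max_periods):
            if n_dia == 0 or n_selfish == 0:
                break
            alpha_dia = (
                2.0 / (n_total * (e - 1.0)) if rederive_alpha_dia else spec.alpha_dia
            )
            cur = replace(
                spec, n_dia=n_dia, n_selfish=n_selfish, alpha_dia=alpha_dia
            )
            sign = "-" if rng.random() < spec.p_neg else "+"
            d = branch_success(sign, cur)
            if d > 0:
                n_dia += 1
                n_selfish -= 1
            elif d < 0:
                n_dia -= 1
                n_selfish += 1
        if n_selfish == 0 and n_dia > 0:
            wins += 1
    return wins / replicates


def survival_floor_contribution(config: GameConfig, formula: str = "consumption") -> float:
    """Minimum average contribution keeping the population viable.

    Default reconstruction ``c_m / (r - 1)``; the ``"per_capita"`` variant
    ``N * c_m / r`` is selectable.  Raises for ``r <= 1`` (no sustainable
    contribution exists).
    """
    return viability_floor(config, formula)  # shares the replicator module's switch
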