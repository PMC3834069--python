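"""One-shot public goods game (PGG) with altruistic punishment.

The stage game: ``N`` players each receive an endowment of ``E`` monetary
units (MU) and contribute ``c_i in [0, E]`` to a common pool.  The pool is
multiplied by ``r`` and redistributed equally, so each contributed MU
returns ``r/N`` per capita — a social dilemma whenever ``1 < r < N``.  In a
second stage every player may punish group mates who contributed *less*
than herself: spending one MU on punishment deducts ``e`` MU from the
target.  Punishment expenditure follows a linear norm: a punisher with
propensity ``alpha`` spends ``alpha * (c_i - c_j)`` MU on a target whose
contribution falls short of her own by ``c_i - c_j``.  Higher contributors
are never punished.

Fitness is relative: an agent's evolutionary success within the group is
the sum of her profit-and-loss (P&L) differences against every other group
member, which makes relative fitness exactly zero-sum inside a group.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "GameConfig",
    "Profile",
    "PayoffResult",
    "punishment_expenditure",
    "payoffs",
    "deviation_relative_payoff",
]


@dataclass(frozen=True)
class GameConfig:
    """Parameterization of the punishment PGG.

    Parameters
    ----------
    N : int
        Group size (players per game), ``N >= 2``.
    r : float
        Return per invested MU of the common pool (MU/MU).  The
        social-dilemma condition ``1 < r < N`` must hold: the total return
        exceeds the investment while the per-capita return ``r/N`` stays
        below one.
    e : float
        Punishment efficiency: MU of harm inflicted per MU spent on
        punishment, ``e > 1`` (punishment hurts the target more than the
        punisher).
    E : float
        Per-period endowment in MU (contributions live in ``[0, E]``).
    c_m : float
        Minimum consumption per period in MU (subsistence cost); induces
        the viability floor on sustainable average contributions.
    """

    N: int
    r: float
    e: float
    E: float = 20.0
    c_m: float = 0.0

    def __post_init__(self) -> None:
        if self.N < 2:
            raise ValueError(f"group size N must be >= 2, got {self.N}")
        if not self.r > 1:
            raise ValueError(
                f"social dilemma requires total return r > 1, got r={self.r}"
            )
        if not self.r < self.N:
            raise ValueError(
                "social dilemma requires per-capita return r/N < 1, "
                f"got r={self.r}, N={self.N}"
            )
        if not self.e > 1:
            raise ValueError(f"punishment efficiency must satisfy e > 1, got {self.e}")
        if self.E < 0:
            raise ValueError(f"endowment E must be >= 0, got {self.E}")
        if self.c_m < 0:
            raise ValueError(f"subsistence cost c_m must be >= 0, got {self.c_m}")

    @property
    def per_capita_return(self) -> float:
        """Marginal per-capita return ``r/N`` of one contributed MU."""
        return self.r / self.N


@dataclass(frozen=True)
class Profile:
    """A group's strategy profile: contributions and punishment propensities.

    ``contributions[i]`` is player *i*'s contribution in MU; ``alphas[i]``
    her propensity to punish (MU spent per MU of negative deviation of a
    target below her own contribution).
    """

    contributions: np.ndarray
    alphas: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "contributions", np.asarray(self.contributions, dtype=float)
        )
        object.__setattr__(self, "alphas", np.asarray(self.alphas, dtype=float))
        if self.contributions.ndim != 1 or self.alphas.ndim != 1:
            raise ValueError("contributions and alphas must be 1-d vectors")
        if self.contributions.shape != self.alphas.shape:
            raise ValueError(
                "contributions and alphas must have equal length, got "
                f"{self.contributions.shape} vs {self.alphas.shape}"
            )
        if np.any(self.alphas < 0):
            raise ValueError("punishment propensities must be non-negative")

    def validate(self, config: GameConfig) -> None:
        if len(self.contributions) != config.N:
            raise ValueError(
                f"profile length {len(self.contributions)} does not match N={config.N}"
            )
        if np.any(self.contributions < 0) or np.any(self.contributions > config.E):
            raise ValueError(
                f"contributions must lie in [0, {config.E}] MU"
            )


@dataclass(frozen=True)
class PayoffResult:
    """Per-agent P&L, pairwise punishment expenditures and relative fitness.

    ``spent[i, j]`` is what player *i* spends punishing player *j* (MU);
    the harm suffered by *j* from *i* is ``e * spent[i, j]``.  ``fitness``
    is the pairwise-difference relative fitness and sums to zero over the
    group by construction.
    """

    pl: np.ndarray
    spent: np.ndarray
    fitness: np.ndarray


def punishment_expenditure(c_punisher, c_target, alpha):
    """MU a punisher spends on a target under the linear punishment norm.

    Returns ``alpha * max(c_punisher - c_target, 0)``: only negative
    deviators (targets contributing strictly less than the punisher) are
    punished; punishment of higher contributors is excluded.  The harm the
    target suffers is ``e`` times the returned expenditure.

    Accepts scalars or broadcastable arrays.
    """
    alpha = np.asarray(alpha, dtype=float)
    if np.any(alpha < 0):
        raise ValueError("propensity to punish alpha must be >= 0")
    out = alpha * np.maximum(np.asarray(c_punisher, float) - np.asarray(c_target, float), 0.0)
    return float(out) if out.ndim == 0 else out


def payoffs(profile: Profile, config: GameConfig) -> PayoffResult:
    """Stage-game P&L and relative fitness of every player in a group.

    P&L of player *i*::

        pl_i = -c_i + (r/N) * sum_k c_k
               - e * sum_{j!=i} alpha_j * max(c_j - c_i, 0)   # harm received
               -     sum_{j!=i} alpha_i * max(c_i - c_j, 0)   # punishment spent

    Relative fitness ``u_i = sum_{j!=i} (pl_i - pl_j) = N*pl_i - sum_j pl_j``
    is exactly zero-sum over the group.
    """
    profile.validate(config)
    c = profile.contributions
    a = profile.alphas
    pool_share = config.r / config.N * c.sum()

    # spent[i, j]: i punishes j when c_i > c_j
    deficit = np.maximum(c[:, None] - c[None, :], 0.0)
    spent = a[:, None] * deficit
    np.fill_diagonal(spent, 0.0)

    harm_received = config.e * spent.sum(axis=0)
    spent_total = spent.sum(axis=1)
    pl = -c + pool_share - harm_received - spent_total
    fitness = config.N * pl - pl.sum()
    return PayoffResult(pl=pl, spent=spent, fitness=fitness)


def deviation_relative_payoff(dc, alpha, config: GameConfig):
    """Relative fitness change of a lone deviator against a homogeneous norm.

    One agent shifts her contribution by ``dc`` (signed MU) away from a
    group norm played by all ``N - 1`` others, everyone sharing the common
    punishment propensity ``alpha``.  The change of her relative fitness is
    piecewise linear::

        dc < 0:  (N-1) * |dc| * (1 - alpha * ((N-1) * e - 1))
        dc > 0: -(N-1) *  dc  * (1 + alpha * (N - 1 - e))
        dc = 0:  0

    The slope of the downward branch changes sign exactly at the
    bifurcation propensity ``1 / ((N-1) * e - 1)``: below it, defection
    pays; above it, any deviation loses.  Accepts scalar or array ``dc``
    and ``alpha``.
    """
    dc = np.asarray(dc, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    if np.any(alpha < 0):
        raise ValueError("propensity to punish alpha must be >= 0")
    n1 = config.N - 1
    down = n1 * (-dc) * (1.0 - alpha * (n1 * config.e - 1.0))
    up = -n1 * dc * (1.0 + alpha * (n1 - config.e))
    out = np.where(dc < 0, down, np.where(dc > 0, up, 0.0))
    return float(out) if out.ndim == 0 else out
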