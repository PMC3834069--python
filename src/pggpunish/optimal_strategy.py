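"""Subjective expected utility and optimal punishment propensities.

An agent chooses her contribution ``c`` to maximize her *evolutionary*
expected utility: the expectation, under her first-order belief about the
others' contributions, of her relative fitness in the group — everyone
sharing the common punishment norm ``alpha``.  Writing ``mean`` for the
believed mean contribution, ``t_plus(c) = E[max(X-c,0)]``,
``t_minus(c) = E[max(c-X,0)]`` and ``D = E[max(X-Y,0)]`` (X, Y independent
draws from the belief):

    U(c) = (N-1) * [ -c + mean
                     - e*alpha*(N-1)*t_plus(c)    # punishment received
                     - alpha*(N-1)*t_minus(c)     # punishment spent
                     + e*alpha*t_minus(c)         # others' harm, relative
                     + alpha*t_plus(c)            # others' spending, relative
                     + (e+1)*alpha*(N-2)*D ]      # punishment among others

The last term does not depend on ``c`` and never moves the argmax; it is
included in reported utility values for completeness.

Setting the first-order condition ``dU/dc = 0`` at a contribution whose
believed survival is ``s_bar = P(X > c)`` and solving for the propensity
gives the closed form

    alpha_star(s_bar) = 1 / [ s_bar*(N-2)*(e+1) + e - N + 1 ].

Two special values organize the whole analysis:

* ``alpha_star(1) = 1/((N-1)e - 1)`` — the *bifurcation* propensity at
  which downward deviation stops paying,
* ``alpha_star(1/2) = 2/(N(e-1))`` — the *coordination* propensity, the
  unique alpha that makes deviation losses symmetric in +-dc, sustaining
  coordination on the believed median contribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .beliefs import BeliefDistribution
from .game_core import GameConfig

__all__ = [
    "OptimalityReport",
    "expected_utility",
    "best_contribution",
    "alpha_star",
    "alpha_thresholds",
]

#: |dU/dc| below which a stationary point is accepted (MU per MU).
FOC_TOLERANCE = 1e-6


@dataclass(frozen=True)
class OptimalityReport:
    """Result of maximizing expected utility over the contribution range.

    ``foc_residual`` is the smallest-magnitude element of the numerical
    sub-differential at the optimum (0 when the left and right derivatives
    bracket zero, as happens at belief atoms); ``soc_value`` is a central
    second difference, non-positive by concavity.  ``boundary`` flags
    optima pinned at 0 or E.
    """

    c_star: float
    utility_at_optimum: float
    foc_residual: float
    soc_value: float
    alpha_used: float
    s_bar_at_optimum: float
    boundary: bool


def expected_utility(
    c: float,
    alpha: float,
    q: BeliefDistribution,
    config: GameConfig,
    include_cross_term: bool = True,
) -> float:
    """Evolutionary expected utility of contributing ``c`` under belief ``q``.

    ``include_cross_term`` toggles the c-independent punishment-among-others
    term ``(e+1)*alpha*(N-2)*D``; dropping it shifts the utility level but
    never the argmax.
    """
    if not 0.0 <= c <= config.E:
        raise ValueError(f"contribution {c} outside [0, {config.E}]")
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    N, e = config.N, config.e
    t_plus, t_minus = q.partial_expectations(c)
    inner = (
        -c
        + q.mean()
        - e * alpha * (N - 1) * t_plus
        - alpha * (N - 1) * t_minus
        + e * alpha * t_minus
        + alpha * t_plus
    )
    if include_cross_term:
        inner += (e + 1.0) * alpha * (N - 2) * q.pairwise_positive_expectation()
    return (N - 1) * inner


def _grid_argmax(alpha, q, config, n_points=401):
    cs = np.linspace(0.0, config.E, n_points)
    us = np.array([expected_utility(c, alpha, q, config) for c in cs])
    return cs, us, int(np.argmax(us))


def best_contribution(
    alpha: float,
    q: BeliefDistribution,
    config: GameConfig,
    n_grid: int = 401,
) -> OptimalityReport:
    """Maximize expected utility over ``[0, E]``.

    Coarse grid search (default step E/400) followed by golden-section
    refinement in the bracketing interval; derivative-free because the
    survival function of a grid belief is a step function.  Boundary
    optima are reported with ``boundary=True``, not raised.
    """
    cs, us, k = _grid_argmax(alpha, q, config, n_grid)
    lo = cs[max(k - 1, 0)]
    hi = cs[min(k + 1, len(cs) - 1)]
    if hi > lo:
        res = optimize.minimize_scalar(
            lambda c: -expected_utility(c, alpha, q, config),
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": 1e-10},
        )
        c_star = float(res.x)
        if expected_utility(c_star, alpha, q, config) < us[k]:
            c_star = float(cs[k])
    else:
        c_star = float(cs[k])

    u_star = expected_utility(c_star, alpha, q, config)
    boundary = c_star <= 1e-9 or c_star >= config.E - 1e-9

    h = max(config.E * 1e-7, 1e-9)
    lo_c = max(c_star - h, 0.0)
    hi_c = min(c_star + h, config.E)
    u_lo = expected_utility(lo_c, alpha, q, config)
    u_hi = expected_utility(hi_c, alpha, q, config)
    d_left = (u_star - u_lo) / (c_star - lo_c) if c_star > lo_c else np.nan
    d_right = (u_hi - u_star) / (hi_c - c_star) if hi_c > c_star else np.nan
    if boundary:
        foc = 0.0
    elif d_left >= -FOC_TOLERANCE and d_right <= FOC_TOLERANCE:
        # zero is in the sub-differential [d_right, d_left]: optimality certified
        foc = 0.0
    else:
        foc = float(min(abs(d_left), abs(d_right)))
    if np.isnan(d_left) or np.isnan(d_right):
        soc = 0.0
    else:
        soc = float((d_right - d_left) / h)

    return OptimalityReport(
        c_star=c_star,
        utility_at_optimum=float(u_star),
        foc_residual=foc,
        soc_value=min(soc, 0.0) if abs(soc) < 1e-6 else soc,
        alpha_used=float(alpha),
        s_bar_at_optimum=q.survival(c_star),
        boundary=boundary,
    )


def alpha_star(s_bar: float, config: GameConfig) -> float:
    """Propensity making a contribution with believed survival ``s_bar``
    a stationary point of expected utility.

    Closed form ``1 / [s_bar*(N-2)*(e+1) + e - N + 1]``.  When the
    denominator is non-positive (possible for ``e < N - 1`` with small
    ``s_bar``) no finite propensity stabilizes that contribution level and
    a :class:`ValueError` is raised.
    """
    if not 0.0 <= s_bar <= 1.0:
        raise ValueError(f"s_bar must be a probability, got {s_bar}")
    N, e = config.N, config.e
    denom = s_bar * (N - 2) * (e + 1.0) + e - N + 1.0
    if denom <= 0:
        raise ValueError(
            "no finite optimal propensity: denominator "
            f"{denom} <= 0 for s_bar={s_bar}, N={N}, e={e}"
        )
    return 1.0 / denom


def alpha_thresholds(config: GameConfig) -> tuple[float, float]:
    """(bifurcation, coordination) propensities for a game configuration.

    ``alpha_bifurcation = 1/((N-1)e - 1) = alpha_star(1)`` separates the
    defection and coordination regimes; ``alpha_coordination =
    2/(N(e-1)) = alpha_star(1/2)`` is the evolutionarily optimal propensity
    sustaining coordination on the believed median.  The coordination value
    strictly exceeds the bifurcation value except at N = 2, where the two
    formulas coincide; both decrease in N and e.
    """
    N, e = config.N, config.e
    return 1.0 / ((N - 1) * e - 1.0), 2.0 / (N * (e - 1.0))
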