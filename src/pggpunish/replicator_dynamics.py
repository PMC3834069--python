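"""Replicator dynamics of contribution deviations and punishment propensities.

The population is a frequency measure over a discretized strategy grid;
each strategy is a pair ``(dc, alpha)``: a signed contribution deviation
(MU) from the group norm and a propensity to punish.  The payoff of a
strategy is the relative-fitness change of a lone deviator playing it
against the norm (:func:`~pggpunish.game_core.deviation_relative_payoff`).

The norm is fixed at the *initial* frequency-weighted median of the
contribution marginal — the Black's-theorem coordination point: with
efficient punishment, the utility-maximizing contribution is the median of
the believed distribution, and beliefs do not update in the one-shot
(strong-mixing) setting.  A deviator below the norm is punished by the
others at the population-mean propensity; a deviator above the norm spends
her own.

Two regimes, separated by the bifurcation propensity
``1/((N-1)e - 1)``:

* *defection* (``alpha`` at or below the threshold): downward deviation
  gains relative fitness, the population slides to the viability floor —
  the smallest mean contribution whose net return covers the subsistence
  cost, ``c_floor = c_m / (r - 1)``;
* *coordination* (``alpha`` above it): every deviation loses and the
  population concentrates at the initial median contribution.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import List, Literal

import numpy as np
import pandas as pd

from .game_core import GameConfig, deviation_relative_payoff

__all__ = [
    "PopulationState",
    "make_grid_state",
    "strategy_success",
    "evolve",
    "classify_regime",
    "viability_floor",
    "trajectory_frame",
]


@dataclass(frozen=True)
class PopulationState:
    """Frequencies over a strategy grid at one instant.

    ``dc[i]`` and ``alpha[i]`` define grid strategy *i*; ``freq`` holds the
    frequency measure (non-negative, sums to one); ``c_norm`` is the
    absolute contribution the population's norm corresponds to, so the
    contribution played by strategy *i* is ``c_norm + dc[i]``.
    """

    dc: np.ndarray
    alpha: np.ndarray
    freq: np.ndarray
    c_norm: float
    time: float = 0.0

    def __post_init__(self):
        for name in ("dc", "alpha", "freq"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), float))
        if not (self.dc.shape == self.alpha.shape == self.freq.shape):
            raise ValueError("dc, alpha, freq must share one shape")
        if np.any(self.freq < 0):
            raise ValueError("frequencies must be non-negative")
        if abs(self.freq.sum() - 1.0) > 1e-10:
            raise ValueError(f"frequencies must sum to 1, got {self.freq.sum()!r}")

    @property
    def mean_dc(self) -> float:
        return float(self.freq @ self.dc)

    @property
    def mean_alpha(self) -> float:
        return float(self.freq @ self.alpha)

    @property
    def var_dc(self) -> float:
        m = self.mean_dc
        return float(self.freq @ (self.dc - m) ** 2)

    @property
    def mean_contribution(self) -> float:
        return self.c_norm + self.mean_dc

    def median_dc(self) -> float:
        """Frequency-weighted median of the dc marginal (smallest value
        whose cumulative frequency reaches 1/2)."""
        order = np.argsort(self.dc, kind="stable")
        cum = np.cumsum(self.freq[order])
        idx = int(np.searchsorted(cum, 0.5 - 1e-12, side="left"))
        return float(self.dc[order][min(idx, len(cum) - 1)])


def make_grid_state(
    config: GameConfig,
    alpha: float,
    c_norm: float = 10.0,
    n_points: int = 101,
    freq=None,
    floor_formula: Literal["consumption", "per_capita"] = "consumption",
) -> PopulationState:
    """Population on a contribution grid from the viability floor to E,
    all strategies sharing punishment propensity ``alpha``.

    ``freq`` defaults to uniform; pass an array to start from a skewed
    distribution.
    """
    floor = viability_floor(config, floor_formula)
    cs = np.linspace(floor, config.E, n_points)
    dc = cs - c_norm
    alphas = np.full(n_points, float(alpha))
    if freq is None:
        freq = np.full(n_points, 1.0 / n_points)
    else:
        freq = np.asarray(freq, float)
        freq = freq / freq.sum()
    return PopulationState(dc=dc, alpha=alphas, freq=freq, c_norm=c_norm)


def viability_floor(
    config: GameConfig,
    formula: Literal["consumption", "per_capita"] = "consumption",
) -> float:
    """Minimum sustainable average contribution.

    Default ``c_m / (r - 1)``: the homogeneous contribution whose net
    payoff ``(r - 1) * c`` covers the subsistence cost.  The alternative
    ``N * c_m / r`` treats the floor as the pool size whose per-capita
    share pays ``c_m``.
    """
    if config.r <= 1:
        raise ValueError("no sustainable contribution exists for r <= 1")
    if formula == "consumption":
        return config.c_m / (config.r - 1.0)
    if formula == "per_capita":
        return config.N * config.c_m / config.r
    raise ValueError(f"unknown floor formula {formula!r}")


def _payoffs_against_norm(state: PopulationState, config: GameConfig) -> np.ndarray:
    """Per-strategy payoff: lone deviator by ``dc - dc_ref`` against the norm.

    The norm reference is the initial median of the dc marginal; callers
    inside :func:`evolve` pass the frozen reference via ``state.c_norm``
    bookkeeping — here the reference is the state's own median, which
    :func:`evolve` keeps fixed by construction of the kernel it uses.
    """
    dc_ref = state.median_dc()
    return _payoffs_vs_reference(state, config, dc_ref)


def _payoffs_vs_reference(
    state: PopulationState, config: GameConfig, dc_ref: float
) -> np.ndarray:
    d = state.dc - dc_ref
    alpha_bar = state.mean_alpha
    # below the norm: punished at the population-mean propensity;
    # above it: the deviator spends at her own propensity
    alpha_eff = np.where(d < 0, alpha_bar, state.alpha)
    return deviation_relative_payoff(d, alpha_eff, config)


def strategy_success(strategy, state: PopulationState, config: GameConfig) -> float:
    """Success ``sigma(s) = u(s, nu) - u_bar(nu)`` of a grid strategy.

    ``strategy`` is a ``(dc, alpha)`` pair present on the grid.  The
    frequency-weighted mean success over the grid is exactly zero.
    """
    dc_s, alpha_s = strategy
    match = (np.abs(state.dc - dc_s) < 1e-12) & (np.abs(state.alpha - alpha_s) < 1e-12)
    if not np.any(match):
        raise ValueError(f"strategy {strategy!r} not on the population grid")
    u = _payoffs_against_norm(state, config)
    u_bar = float(state.freq @ u)
    return float(u[np.argmax(match)] - u_bar)


def _mutation_matrix(dc: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian diffusion kernel on the dc grid, column-normalized so mass
    leaving a strategy is redistributed over feasible grid points only
    (reflection at the grid bounds by renormalization)."""
    k = np.exp(-((dc[:, None] - dc[None, :]) ** 2) / (2.0 * sigma**2))
    return k / k.sum(axis=0, keepdims=True)


def evolve(
    state: PopulationState,
    config: GameConfig,
    dt: float,
    steps: int,
    mutation_sigma: float = 0.0,
    mutation_rate: float = 0.01,
    seed: int | None = None,
    record_every: int = 1,
) -> List[PopulationState]:
    """Iterate the discretized replicator equation.

    Explicit Euler on normalized frequencies:
    ``nu <- nu * (1 + dt * sigma(s))`` with renormalization each step; the
    payoff kernel is the lone-deviator relative fitness against the norm,
    whose reference point (the initial median of the dc marginal) is fixed
    at the start.  When ``mutation_sigma > 0``, a fraction
    ``mutation_rate`` of the mass diffuses each step through a Gaussian
    kernel reflected at the grid bounds (a deterministic convolution, so
    the trajectory is reproducible regardless of ``seed``; the argument is
    accepted for interface stability).

    Raises a step-size error when ``dt`` is large enough to drive a
    frequency negative.  Returns the recorded trajectory, initial state
    first.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if steps < 0:
        raise ValueError("steps must be >= 0")

    dc_ref = state.median_dc()  # Black's-theorem norm, frozen for the run
    freq = state.freq.copy()
    kernel = (
        _mutation_matrix(state.dc, mutation_sigma) if mutation_sigma > 0 else None
    )

    traj = [state]
    current = state
    for step in range(1, steps + 1):
        u = _payoffs_vs_reference(current, config, dc_ref)
        u_bar = float(freq @ u)
        sigma_s = u - u_bar
        growth = 1.0 + dt * sigma_s
        if np.any((growth < 0) & (freq > 0)):
            raise ValueError(
                f"time step dt={dt} too large: a frequency would turn negative "
                f"(max |success| = {np.abs(sigma_s).max():.3g}); reduce dt below "
                f"{1.0 / np.abs(sigma_s).max():.3g}"
            )
        freq = freq * growth
        if kernel is not None:
            freq = (1.0 - mutation_rate) * freq + mutation_rate * (kernel @ freq)
        freq = freq / freq.sum()
        current = replace(current, freq=freq, time=state.time + step * dt)
        if step % record_every == 0 or step == steps:
            traj.append(current)
    return traj


def classify_regime(alpha: float, config: GameConfig) -> str:
    """Label the evolutionary regime of a common punishment propensity.

    ``"defection"`` when ``alpha <= 1/((N-1)e - 1)`` (attractor: viability
    floor), ``"coordination"`` above it (attractor: the initial population
    median contribution).  The boundary itself counts as defection, since
    coordination requires the strict inequality.
    """
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    threshold = 1.0 / ((config.N - 1) * config.e - 1.0)
    return "defection" if alpha <= threshold else "coordination"


def trajectory_frame(traj: List[PopulationState]) -> pd.DataFrame:
    """Summarize an :func:`evolve` trajectory as (t, mean_dc, mean_alpha,
    var_dc, mean_contribution) rows."""
    return pd.DataFrame(
        {
            "t": [s.time for s in traj],
            "mean_dc": [s.mean_dc for s in traj],
            "mean_alpha": [s.mean_alpha for s in traj],
            "var_dc": [s.var_dc for s in traj],
            "mean_contribution": [s.mean_contribution for s in traj],
        }
    )
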