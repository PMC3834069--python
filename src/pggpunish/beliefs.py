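"""First-order beliefs over group mates' contributions.

An agent's subjective probability measure over the contribution another
group member will make.  Contributions in the lab are integer MU on
``[0, E]``, so the canonical representation is a discrete grid of atoms;
continuous uniform and truncated-normal families are provided for the
analytical oracles (their survival functions are smooth, which the
closed-form punishment-propensity results presume).

Summary functionals exposed here feed the expected-utility model:

* ``survival(c) = P(X > c)`` — the survival function (strict inequality),
* mean and median (smallest support value with CDF >= 1/2),
* the partial expectations ``E[max(X - c, 0)]`` and ``E[max(c - X, 0)]``
  entering the expected punishment-received / punishment-spent terms,
* ``E[max(X - Y, 0)]`` for independent X, Y — punishment among the others.
"""

from __future__ import annotations

from typing import Tuple

import numpy as np
from scipy import integrate, stats

__all__ = [
    "BeliefDistribution",
    "GridBelief",
    "UniformBelief",
    "TruncatedNormalBelief",
    "point_mass",
    "uniform_grid",
    "survival",
    "belief_summary",
    "partial_expectations",
]


class BeliefDistribution:
    """Abstract first-order belief.  Subclasses implement the functionals."""

    def survival(self, c: float) -> float:
        """P(X > c), strict inequality; non-increasing in ``c``."""
        raise NotImplementedError

    def mean(self) -> float:
        raise NotImplementedError

    def median(self) -> float:
        raise NotImplementedError

    def partial_expectations(self, c: float) -> Tuple[float, float]:
        """(E[max(X-c,0)], E[max(c-X,0)]); their difference is mean - c."""
        raise NotImplementedError

    def pairwise_positive_expectation(self) -> float:
        """E[max(X - Y, 0)] for independent X, Y with this distribution."""
        raise NotImplementedError


class GridBelief(BeliefDistribution):
    """Belief with finitely many atoms on a contribution grid.

    Weights must be non-negative and sum to one (tolerance 1e-12).
    """

    def __init__(self, support, probs):
        support = np.asarray(support, dtype=float)
        probs = np.asarray(probs, dtype=float)
        if support.ndim != 1 or support.size == 0:
            raise ValueError("belief support must be a non-empty 1-d grid")
        if support.shape != probs.shape:
            raise ValueError("support and probs must have equal length")
        if np.any(probs < 0):
            raise ValueError("belief weights must be non-negative")
        if abs(probs.sum() - 1.0) > 1e-12:
            raise ValueError(f"belief weights must sum to 1, got {probs.sum()!r}")
        order = np.argsort(support)
        self.support = support[order]
        self.probs = probs[order]
        self._cdf = np.cumsum(self.probs)
        self._D: float | None = None

    def survival(self, c: float) -> float:
        # strict: mass strictly above c
        idx = np.searchsorted(self.support, c, side="right")
        return float(self.probs[idx:].sum())

    def mean(self) -> float:
        return float(self.support @ self.probs)

    def median(self) -> float:
        # smallest support value m with P(X <= m) >= 1/2
        idx = int(np.searchsorted(self._cdf, 0.5 - 1e-15, side="left"))
        return float(self.support[min(idx, len(self.support) - 1)])

    def partial_expectations(self, c: float) -> Tuple[float, float]:
        d = self.support - c
        t_plus = float(self.probs @ np.maximum(d, 0.0))
        t_minus = float(self.probs @ np.maximum(-d, 0.0))
        return t_plus, t_minus

    def pairwise_positive_expectation(self) -> float:
        if self._D is None:
            diff = np.maximum(self.support[:, None] - self.support[None, :], 0.0)
            self._D = float(self.probs @ diff @ self.probs)
        return self._D


class UniformBelief(BeliefDistribution):
    """Continuous uniform belief on ``[low, high]`` (closed forms throughout)."""

    def __init__(self, low: float, high: float):
        if not high > low:
            raise ValueError("uniform belief requires high > low")
        self.low = float(low)
        self.high = float(high)

    def survival(self, c: float) -> float:
        return float(np.clip((self.high - c) / (self.high - self.low), 0.0, 1.0))

    def mean(self) -> float:
        return 0.5 * (self.low + self.high)

    def median(self) -> float:
        return self.mean()

    def inverse_survival(self, s: float) -> float:
        """Contribution level whose survival equals ``s`` (0 <= s <= 1)."""
        if not 0.0 <= s <= 1.0:
            raise ValueError("survival level must lie in [0, 1]")
        return self.high - s * (self.high - self.low)

    def partial_expectations(self, c: float) -> Tuple[float, float]:
        a, b = self.low, self.high
        if c <= a:
            t_plus = self.mean() - c
        elif c >= b:
            t_plus = 0.0
        else:
            t_plus = (b - c) ** 2 / (2.0 * (b - a))
        t_minus = t_plus - (self.mean() - c)
        return float(t_plus), float(max(t_minus, 0.0))

    def pairwise_positive_expectation(self) -> float:
        return (self.high - self.low) / 6.0


class TruncatedNormalBelief(BeliefDistribution):
    """Normal(mu, sigma) truncated to ``[low, high]``.

    Partial expectations use the identity ``E[max(X-c,0)] = int_c^b S(x) dx``
    evaluated by quadrature; the pairwise term uses
    ``E|X-Y| = 2 int F(x)(1-F(x)) dx``.
    """

    def __init__(self, mu: float, sigma: float, low: float, high: float):
        if sigma <= 0:
            raise ValueError("sigma must be positive")
        if not high > low:
            raise ValueError("truncation requires high > low")
        self.low, self.high = float(low), float(high)
        a, b = (low - mu) / sigma, (high - mu) / sigma
        self._dist = stats.truncnorm(a, b, loc=mu, scale=sigma)
        self._D: float | None = None

    def survival(self, c: float) -> float:
        return float(self._dist.sf(c))

    def mean(self) -> float:
        return float(self._dist.mean())

    def median(self) -> float:
        return float(self._dist.median())

    def partial_expectations(self, c: float) -> Tuple[float, float]:
        if c >= self.high:
            t_plus = 0.0
        else:
            lo = max(c, self.low)
            t_plus, _ = integrate.quad(self._dist.sf, lo, self.high, limit=200)
            if c < self.low:
                t_plus += self.low - c
        t_minus = t_plus - (self.mean() - c)
        return float(t_plus), float(max(t_minus, 0.0))

    def pairwise_positive_expectation(self) -> float:
        if self._D is None:
            f = lambda x: self._dist.cdf(x) * self._dist.sf(x)
            val, _ = integrate.quad(f, self.low, self.high, limit=200)
            self._D = float(val)  # = E|X-Y| / 2
        return self._D


def point_mass(value: float) -> GridBelief:
    """Degenerate belief: the other's contribution is known exactly."""
    return GridBelief([value], [1.0])


def uniform_grid(low: float = 0.0, high: float = 20.0, step: float = 1.0) -> GridBelief:
    """Equal-weight belief over the integer-like grid low, low+step, ..., high."""
    support = np.arange(low, high + step / 2, step)
    return GridBelief(support, np.full(support.size, 1.0 / support.size))


# -- functional facade ------------------------------------------------------

def survival(q: BeliefDistribution, c: float) -> float:
    """P(contribution > c) under belief ``q`` (strict inequality)."""
    return q.survival(c)


def belief_summary(q: BeliefDistribution) -> Tuple[float, float]:
    """(mean, median) of the belief."""
    return q.mean(), q.median()


def partial_expectations(q: BeliefDistribution, c: float) -> Tuple[float, float]:
    """(E[max(X-c,0)], E[max(c-X,0)]) under belief ``q``."""
    return q.partial_expectations(c)
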