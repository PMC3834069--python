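"""Synthetic PGG-with-punishment experiment generator.

Emulates the lab design the estimation pipeline expects: subjects endowed
with 20 MU play a two-stage public goods game in groups of ``N`` for
several periods (6–10 in the cited designs).  Stage one: simultaneous
contributions; stage two: subjects see their group mates' contributions
and may punish negative deviators.  In the *stranger* treatment group
compositions are re-drawn uniformly at random every period; in the
*partner* treatment they are fixed.

The generator's behavioral rule is the linear punishment norm itself: for
every ordered within-group pair whose deviation ``d = c_punisher -
c_target`` is positive, the expenditure is ``clamp(alpha_true * d + noise,
0, cap)``.  Higher contributors are never punished.  Contributions are
drawn i.i.d. from a truncated normal (default mean 10, sd 5 on [0, 20],
rounded to integer MU) — a stand-in for the real contribution
distributions, whose moments are not published.  The defaults are the
study conditions: ``alpha_true = 0.25`` (the coordination optimum at
N = 4, e = 3), additive truncated-normal noise with sigma = 0.5 MU.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from .game_core import GameConfig

__all__ = ["SyntheticSpec", "generate_experiment", "default_config"]


def default_config() -> GameConfig:
    """The cited experiments' parameterization: groups of 4, per-capita
    return 0.4 (r = 1.6), punishment efficiency 3, endowment 20 MU."""
    return GameConfig(N=4, r=1.6, e=3.0, E=20.0, c_m=0.0)


@dataclass(frozen=True)
class SyntheticSpec:
    """Design of one synthetic experiment."""

    n_subjects: int = 24
    periods: int = 10
    treatment: str = "stranger"
    alpha_true: float = 0.25
    contribution_model: str = "truncated_normal"
    contribution_mean: float = 10.0
    contribution_sd: float = 5.0
    integer_contributions: bool = True
    noise_model: str = "additive-truncated-normal"
    noise_sigma: float = 0.5
    expenditure_cap: Optional[float] = None
    seed: int = 0
    config: GameConfig = field(default_factory=default_config)

    def __post_init__(self):
        if self.n_subjects % self.config.N != 0:
            raise ValueError(
                f"n_subjects={self.n_subjects} not divisible by group size "
                f"{self.config.N}"
            )
        if self.periods < 1:
            raise ValueError("periods must be >= 1")
        if self.alpha_true < 0:
            raise ValueError("alpha_true must be >= 0")
        if self.treatment not in ("stranger", "partner"):
            raise ValueError(f"unknown treatment {self.treatment!r}")
        if self.contribution_model not in ("truncated_normal", "uniform", "point"):
            raise ValueError(f"unknown contribution model {self.contribution_model!r}")
        if self.noise_model not in (
            "none",
            "additive-truncated-normal",
            "multiplicative-lognormal",
        ):
            raise ValueError(f"unknown noise model {self.noise_model!r}")
        if self.noise_model != "none" and self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.expenditure_cap is not None and self.expenditure_cap < 0:
            raise ValueError("expenditure cap must be >= 0")


def _draw_contributions(spec: SyntheticSpec, rng, size: int) -> np.ndarray:
    E = spec.config.E
    if spec.contribution_model == "truncated_normal":
        c = rng.normal(spec.contribution_mean, spec.contribution_sd, size=size * 3)
        c = c[(c >= 0) & (c <= E)]
        while len(c) < size:  # top up on unlucky truncation
            extra = rng.normal(spec.contribution_mean, spec.contribution_sd, size=size)
            c = np.concatenate([c, extra[(extra >= 0) & (extra <= E)]])
        c = c[:size]
    elif spec.contribution_model == "uniform":
        c = rng.uniform(0.0, E, size=size)
    else:  # point
        c = np.full(size, spec.contribution_mean)
    if spec.integer_contributions:
        c = np.round(c)
    return np.clip(c, 0.0, E)


def generate_experiment(spec: SyntheticSpec) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Generate (contributions, punishments) record tables.

    Contributions: one row per subject and period with columns
    ``session, period, group, subject, contribution``.  Punishments: one
    row per ordered within-group pair with positive deviation, columns
    ``session, period, group, punisher, target, expenditure`` —
    non-punished pairs with positive deviation appear with expenditure 0
    (they are observed decisions).  Fully reproducible from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    N = spec.config.N
    n_groups = spec.n_subjects // N
    subjects = np.array([f"s{i:03d}" for i in range(spec.n_subjects)])

    fixed_assignment = rng.permutation(spec.n_subjects)
    contrib_rows = []
    punish_rows = []
    for period in range(1, spec.periods + 1):
        if spec.treatment == "stranger" or period == 1:
            assignment = (
                rng.permutation(spec.n_subjects)
                if spec.treatment == "stranger"
                else fixed_assignment
            )
        contributions = _draw_contributions(spec, rng, spec.n_subjects)
        for g in range(n_groups):
            members = assignment[g * N : (g + 1) * N]
            group_id = f"g{g:02d}"
            cs = contributions[members]
            for m, c in zip(members, cs):
                contrib_rows.append(
                    {
                        "session": "synthetic",
                        "period": period,
                        "group": group_id,
                        "subject": subjects[m],
                        "contribution": float(c),
                    }
                )
            for i in range(N):
                for j in range(N):
                    if i == j:
                        continue
                    d = cs[i] - cs[j]
                    if d <= 0:
                        continue  # only negative deviators are punished
                    base = spec.alpha_true * d
                    if spec.noise_model == "additive-truncated-normal":
                        expend = base + rng.normal(0.0, spec.noise_sigma)
                    elif spec.noise_model == "multiplicative-lognormal":
                        expend = base * rng.lognormal(0.0, spec.noise_sigma)
                    else:
                        expend = base
                    expend = max(expend, 0.0)
                    if spec.expenditure_cap is not None:
                        expend = min(expend, spec.expenditure_cap)
                    punish_rows.append(
                        {
                            "session": "synthetic",
                            "period": period,
                            "group": group_id,
                            "punisher": subjects[members[i]],
                            "target": subjects[members[j]],
                            "expenditure": float(expend),
                        }
                    )

    contributions_df = pd.DataFrame(contrib_rows)
    punishments_df = pd.DataFrame(
        punish_rows,
        columns=["session", "period", "group", "punisher", "target", "expenditure"],
    )
    return contributions_df, punishments_df
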