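"""Recovering the propensity to punish from experiment records.

Each pairwise punishment decision in a PGG-with-punishment experiment in
which the punisher contributed strictly more than the target yields one
realization of the propensity to punish:

    alpha_hat = expenditure / (c_punisher - c_target).

Pairs with zero or negative deviation are excluded (punishment of equal or
higher contributors — "anomalous punishment" — is outside the linear
norm); pairs with positive deviation and zero expenditure are genuine
non-punishment decisions and enter as realizations of 0.

Summary statistics follow the empirical workflow the model is tested
against: the sample median of the realizations, its bootstrap standard
error, bootstrap-t confidence intervals (each outer resample studentized
by a nested inner-bootstrap standard error), a two-sample
Kolmogorov–Smirnov check that the period-1 realizations look like the full
sample (stationarity of the punishment norm over the session), and the
binned punishment curve: mean expenditure against pairwise deviation with
its origin-constrained least-squares slope.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PunishmentRecord",
    "AlphaEstimate",
    "alpha_realizations",
    "median_se_ci",
    "ks_first_period_vs_all",
    "punishment_curve",
    "records_frame",
]

PUNISHMENT_COLUMNS = [
    "session",
    "period",
    "group",
    "punisher",
    "target",
    "c_punisher",
    "c_target",
    "expenditure",
]


@dataclass(frozen=True)
class PunishmentRecord:
    """One pairwise punishment decision with both contributions attached."""

    session: str
    period: int
    group: str
    punisher: str
    target: str
    c_punisher: float
    c_target: float
    expenditure: float

    def __post_init__(self):
        if self.punisher == self.target:
            raise ValueError(
                f"punisher and target coincide ({self.punisher!r}) in "
                f"session={self.session} period={self.period}"
            )
        if self.expenditure < 0:
            raise ValueError(
                f"negative expenditure {self.expenditure} for punisher "
                f"{self.punisher!r} in period {self.period}"
            )
        if self.period < 1:
            raise ValueError(f"period must be >= 1, got {self.period}")


@dataclass(frozen=True)
class AlphaEstimate:
    """Median propensity to punish with bootstrap uncertainty."""

    realizations: np.ndarray
    median: float
    se_median: float
    ci_low: float
    ci_high: float
    level: float
    n_used: int
    n_excluded: int


def records_frame(records: Iterable) -> pd.DataFrame:
    """Normalize a record list / DataFrame to the punishment-record schema."""
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        df = pd.DataFrame([vars(r) if not isinstance(r, dict) else r for r in records])
    missing = [c for c in PUNISHMENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"punishment records lack columns {missing}")
    return df


def alpha_realizations(
    records,
    include_zero_expenditure: bool = True,
) -> Tuple[np.ndarray, pd.DataFrame]:
    """Propensity realizations ``expenditure / (c_punisher - c_target)``.

    Only records with a strictly positive deviation produce realizations;
    the rest are returned in the exclusion log with a reason column.
    ``include_zero_expenditure=False`` additionally drops observed
    non-punishment (expenditure 0) pairs — a sensitivity switch, not the
    default: non-punishment is a decision too.

    Returns ``(realizations, exclusion_log)``; the log keeps the original
    row order and indices.
    """
    df = records_frame(records)
    if (df["expenditure"] < 0).any():
        bad = df.index[df["expenditure"] < 0][0]
        raise ValueError(f"negative expenditure at row {bad}")
    deviation = df["c_punisher"] - df["c_target"]

    reasons = pd.Series(pd.NA, index=df.index, dtype="string")
    reasons[deviation <= 0] = "non-positive deviation"
    if not include_zero_expenditure:
        zero = (deviation > 0) & (df["expenditure"] == 0)
        reasons[zero] = "zero expenditure (excluded by switch)"
    excluded = df.loc[reasons.notna()].assign(reason=reasons[reasons.notna()])

    kept = reasons.isna()
    values = (df.loc[kept, "expenditure"] / deviation[kept]).to_numpy(dtype=float)
    return values, excluded


def _bootstrap_medians(values: np.ndarray, n_boot: int, rng) -> np.ndarray:
    idx = rng.integers(0, len(values), size=(n_boot, len(values)))
    return np.median(values[idx], axis=1)


def median_se_ci(
    realizations: Sequence[float],
    level: float = 0.95,
    b_outer: int = 10_000,
    b_inner: int = 200,
    seed: int = 0,
    n_excluded: int = 0,
    studentization: str = "inner-bootstrap",
) -> AlphaEstimate:
    """Sample median with bootstrap SE and bootstrap-t confidence interval.

    The point estimate is the ordinary sample median (even sizes: mean of
    the two central order statistics).  ``b_outer`` resamples give the SE;
    the bootstrap-t interval studentizes each outer resample's median by a
    per-resample SE from either ``b_inner`` nested resamples
    (``studentization="inner-bootstrap"``) or a delete-one jackknife
    (``"jackknife"``), then inverts the percentile-t pivot.  Degenerate
    resamples with zero spread contribute a studentized value of 0, so a
    constant sample returns a degenerate interval at the median.
    """
    values = np.asarray(realizations, dtype=float)
    if values.ndim != 1 or len(values) < 2:
        raise ValueError("need at least two realizations")
    if not 0.0 < level < 1.0:
        raise ValueError("confidence level must lie in (0, 1)")
    if studentization not in ("inner-bootstrap", "jackknife"):
        raise ValueError(f"unknown studentization {studentization!r}")

    rng = np.random.default_rng(seed)
    n = len(values)
    med = float(np.median(values))

    outer_idx = rng.integers(0, n, size=(b_outer, n))
    outer_samples = values[outer_idx]
    outer_medians = np.median(outer_samples, axis=1)
    se = float(outer_medians.std(ddof=1))

    # per-resample SE for studentization, chunked to bound memory
    inner_se = np.empty(b_outer)
    chunk = max(1, int(2_000_000 // max(n * b_inner, 1)))
    for start in range(0, b_outer, chunk):
        block = outer_samples[start : start + chunk]  # (m, n)
        if studentization == "inner-bootstrap":
            m = block.shape[0]
            ii = rng.integers(0, n, size=(m, b_inner, n))
            meds = np.median(
                np.take_along_axis(block[:, None, :], ii, axis=2), axis=2
            )
            inner_se[start : start + chunk] = meds.std(axis=1, ddof=1)
        else:  # delete-one jackknife of the median
            m, _ = block.shape
            srt = np.sort(block, axis=1)
            jack = np.empty((m, n))
            for j in range(n):
                keep = np.delete(srt, j, axis=1)
                jack[:, j] = np.median(keep, axis=1)
            inner_se[start : start + chunk] = np.sqrt(
                (n - 1) / n * ((jack - jack.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
            )

    with np.errstate(divide="ignore", invalid="ignore"):
        t_stats = np.where(inner_se > 0, (outer_medians - med) / inner_se, 0.0)
    a = (1.0 - level) / 2.0
    t_lo, t_hi = np.quantile(t_stats, [a, 1.0 - a])
    ci_low = med - t_hi * se
    ci_high = med - t_lo * se

    return AlphaEstimate(
        realizations=values,
        median=med,
        se_median=se,
        ci_low=float(min(ci_low, med)),
        ci_high=float(max(ci_high, med)),
        level=level,
        n_used=n,
        n_excluded=n_excluded,
    )


def ks_first_period_vs_all(records) -> Tuple[float, float]:
    """Two-sample KS test: period-1 realizations against the full sample.

    A non-rejection supports treating the punishment norm as stationary
    over the session.  Discrete MU data produce ties; the plain ECDF
    sup-distance with the asymptotic p-value is used, which is
    conservative under ties (and the period-1 subset being contained in
    the full sample adds further conservatism — documented, deliberate
    mirroring of the empirical procedure).
    """
    df = records_frame(records)
    all_values, _ = alpha_realizations(df)
    first_values, _ = alpha_realizations(df[df["period"] == 1])
    if len(first_values) == 0 or len(all_values) == 0:
        raise ValueError("empty subset after deviation filtering")
    stat, p = stats.ks_2samp(first_values, all_values, method="asymp")
    return float(stat), float(p)


def punishment_curve(
    records,
    bin_width: float = 1.0,
) -> Tuple[pd.DataFrame, float, pd.DataFrame]:
    """Binned punishment curve and origin-constrained slope.

    Bins the positive pairwise deviations ``c_punisher - c_target`` with
    the given width and reports per-bin mean expenditure, its standard
    error (NaN when a bin holds fewer than 2 records) and count — empty
    bins appear with count 0.  The slope is least squares of expenditure
    on deviation through the origin, ``sum(d*s)/sum(d^2)``.  Also returns
    the deviation frequency histogram (all pairwise deviations, positive
    and otherwise).

    Returns ``(curve, slope, deviation_histogram)``.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    df = records_frame(records)
    deviation = (df["c_punisher"] - df["c_target"]).to_numpy(dtype=float)
    spend = df["expenditure"].to_numpy(dtype=float)

    pos = deviation > 0
    d, s = deviation[pos], spend[pos]
    slope = float((d @ s) / (d @ d)) if len(d) else float("nan")

    if len(d):
        n_bins = int(np.ceil(d.max() / bin_width))
        edges = np.arange(0.0, (n_bins + 1) * bin_width, bin_width)
        which = np.clip(np.digitize(d, edges) - 1, 0, n_bins - 1)
        rows = []
        for b in range(n_bins):
            in_bin = which == b
            cnt = int(in_bin.sum())
            rows.append(
                {
                    "bin_low": edges[b],
                    "bin_high": edges[b + 1],
                    "mean_expenditure": float(s[in_bin].mean()) if cnt else np.nan,
                    "se_expenditure": float(s[in_bin].std(ddof=1) / np.sqrt(cnt))
                    if cnt > 1
                    else np.nan,
                    "count": cnt,
                }
            )
        curve = pd.DataFrame(rows)
    else:
        curve = pd.DataFrame(
            columns=["bin_low", "bin_high", "mean_expenditure", "se_expenditure", "count"]
        )

    hist = (
        pd.Series(deviation).value_counts().sort_index().rename("count").reset_index()
    )
    hist.columns = ["deviation", "count"]
    hist["relative_frequency"] = hist["count"] / hist["count"].sum()
    return curve, slope, hist
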