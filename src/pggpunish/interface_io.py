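"""CSV/JSON readers and writers, validation, pipeline composition, manifests.

File conventions: comma-separated UTF-8 CSV with a header row and "."
decimals.  Two tables describe an experiment:

* contributions: ``session, period, group, subject, contribution``
* punishments:   ``session, period, group, punisher, target, expenditure``

``read_records`` validates types, ranges and referential integrity
(punisher and target must appear in the same session/period/group of the
contributions table) and joins the contributions onto each punishment row,
yielding the estimation pipeline's record schema.  ``run_pipeline``
composes generate → estimate → thresholds into the end-to-end synthetic
reproduction of the empirical analysis.  Every CLI run writes a manifest
(command, config snapshot, seed, timestamps, outputs, package version)
sufficient to reproduce it.
"""

from __future__ import annotations

import datetime as _dt
import json
import logging
from dataclasses import asdict
from pathlib import Path
from typing import Optional, Tuple

import pandas as pd
import yaml

from . import __version__
from .estimation_pipeline import alpha_realizations, median_se_ci
from .game_core import GameConfig
from .optimal_strategy import alpha_thresholds
from .replicator_dynamics import classify_regime
from .synthetic_data import SyntheticSpec, generate_experiment

__all__ = [
    "read_records",
    "write_records",
    "attach_contributions",
    "load_game_config",
    "run_pipeline",
    "write_manifest",
]

logger = logging.getLogger("pggpunish")

CONTRIBUTION_COLUMNS = ["session", "period", "group", "subject", "contribution"]
RAW_PUNISHMENT_COLUMNS = ["session", "period", "group", "punisher", "target", "expenditure"]
_KEY = ["session", "period", "group"]


def load_game_config(path) -> GameConfig:
    """Read a flat key-value config file (YAML: N, r, e, E, c_m)."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    known = {k: raw[k] for k in ("N", "r", "e", "E", "c_m") if k in raw}
    if "N" not in known or "r" not in known or "e" not in known:
        raise ValueError(f"config file {path} must define at least N, r and e")
    known["N"] = int(known["N"])
    return GameConfig(**known)


def _require_columns(df: pd.DataFrame, columns, what: str, path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{what} table {path} is missing columns {missing}")


def read_records(
    contributions_path,
    punishments_path,
    config: Optional[GameConfig] = None,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Load and validate the two record tables.

    Returns ``(contributions, punishments)`` where the punishments table
    carries the joined ``c_punisher`` / ``c_target`` columns.  Violations
    (missing columns, out-of-range contributions, orphan punishment rows)
    raise descriptive errors naming the offending rows.  An empty
    punishment table is valid — no punishment was observed.
    """
    contrib = pd.read_csv(contributions_path)
    punish = pd.read_csv(punishments_path)
    _require_columns(contrib, CONTRIBUTION_COLUMNS, "contributions", contributions_path)
    _require_columns(punish, RAW_PUNISHMENT_COLUMNS, "punishments", punishments_path)

    if config is not None:
        bad = contrib[
            (contrib["contribution"] < 0) | (contrib["contribution"] > config.E)
        ]
        if len(bad):
            raise ValueError(
                f"contributions outside [0, {config.E}] at rows "
                f"{bad.index.tolist()[:10]}"
            )
    if (punish["expenditure"] < 0).any():
        rows = punish.index[punish["expenditure"] < 0].tolist()[:10]
        raise ValueError(f"negative expenditures at rows {rows}")
    same = punish["punisher"] == punish["target"]
    if same.any():
        raise ValueError(
            f"punisher equals target at rows {punish.index[same].tolist()[:10]}"
        )

    joined = attach_contributions(contrib, punish)
    logger.info(
        "read %d contribution rows, %d punishment rows", len(contrib), len(joined)
    )
    return contrib, joined


def attach_contributions(
    contributions: pd.DataFrame, punishments: pd.DataFrame
) -> pd.DataFrame:
    """Join punisher/target contributions onto punishment rows.

    Raises a referential-integrity error naming the first offending rows
    when a punisher or target has no contribution entry in the same
    session/period/group.
    """
    if punishments.empty:
        out = punishments.copy()
        out["c_punisher"] = pd.Series(dtype=float)
        out["c_target"] = pd.Series(dtype=float)
        return out
    lookup = contributions.set_index(_KEY + ["subject"])["contribution"]
    out = punishments.copy()
    for role, col in (("punisher", "c_punisher"), ("target", "c_target")):
        keys = pd.MultiIndex.from_frame(out[_KEY + [role]])
        try:
            out[col] = lookup.reindex(keys).to_numpy()
        except Exception as exc:  # duplicated contribution entries
            raise ValueError(f"ambiguous contribution entries: {exc}") from exc
        orphan = out[col].isna()
        if orphan.any():
            rows = out.index[orphan].tolist()[:10]
            raise ValueError(
                f"punishment rows whose {role} has no contribution entry in the "
                f"same session/period/group: rows {rows}"
            )
    return out


def write_records(
    contributions: pd.DataFrame,
    punishments: pd.DataFrame,
    out_dir,
) -> Tuple[Path, Path]:
    """Write the two tables as CSV; returns their paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    c_path = out / "contributions.csv"
    p_path = out / "punishments.csv"
    contributions.to_csv(c_path, index=False)
    punishments[RAW_PUNISHMENT_COLUMNS].to_csv(p_path, index=False)
    return c_path, p_path


def run_pipeline(
    spec: SyntheticSpec,
    level: float = 0.95,
    b_outer: int = 2000,
    b_inner: int = 50,
    seed: Optional[int] = None,
    out_dir=None,
) -> dict:
    """End-to-end synthetic reproduction of the empirical analysis.

    Generates an experiment, recovers the propensity-to-punish median with
    its bootstrap-t interval, computes the configuration's bifurcation and
    coordination propensities, classifies the regime of the estimated
    median and reports its distance to the coordination optimum (the
    model's prediction for lab behavior).
    """
    seed = spec.seed if seed is None else seed
    contributions, punishments = generate_experiment(spec)
    joined = attach_contributions(contributions, punishments)
    values, excluded = alpha_realizations(joined)
    estimate = median_se_ci(
        values,
        level=level,
        b_outer=b_outer,
        b_inner=b_inner,
        seed=seed,
        n_excluded=len(excluded),
    )
    bifurcation, coordination = alpha_thresholds(spec.config)
    report = {
        "n_records": int(len(joined)),
        "n_used": estimate.n_used,
        "n_excluded": estimate.n_excluded,
        "alpha_median": estimate.median,
        "se_median": estimate.se_median,
        "ci_low": estimate.ci_low,
        "ci_high": estimate.ci_high,
        "level": level,
        "alpha_bifurcation": bifurcation,
        "alpha_coordination": coordination,
        "regime_of_median": classify_regime(estimate.median, spec.config),
        "abs_gap_to_coordination": abs(estimate.median - coordination),
        "ci_covers_coordination": bool(
            estimate.ci_low <= coordination <= estimate.ci_high
        ),
        "alpha_true": spec.alpha_true,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_records(contributions, punishments, out)
        with open(out / "estimate.json", "w", encoding="utf-8") as fh:
            json.dump(report, fh, indent=2)
    logger.info(
        "pipeline: median=%.4f, coordination=%.4f, regime=%s",
        report["alpha_median"],
        report["alpha_coordination"],
        report["regime_of_median"],
    )
    return report


def write_manifest(
    command: str,
    seed: Optional[int],
    outputs,
    out_path,
    config: Optional[GameConfig] = None,
    extra: Optional[dict] = None,
) -> Path:
    """Write a reproduction manifest next to a CLI run's outputs."""
    manifest = {
        "command": command,
        "package_version": __version__,
        "seed": seed,
        "config": asdict(config) if config is not None else None,
        "timestamp_utc": _dt.datetime.now(_dt.timezone.utc).isoformat(),
        "outputs": [str(p) for p in outputs],
    }
    if extra:
        manifest.update(extra)
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    with open(out_path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2)
    return out_path
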