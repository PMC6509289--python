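"""Longitudinal region-summary tables and baseline normalisation.

Tables are plain pandas DataFrames with columns ``animal_id``, ``group``,
``day``, ``value`` and optionally ``measure`` (e.g. ``mean_bp``,
``volume_mm3``).  Each (animal_id, measure, day) appears once and every
animal belongs to exactly one group.
"""

from __future__ import annotations

from typing import Iterable

import pandas as pd

from .exceptions import DataError, MissingBaselineError, ZeroBaselineError

__all__ = ["validate_longitudinal", "normalize_longitudinal"]

REQUIRED_COLUMNS = ("animal_id", "group", "day", "value")


def validate_longitudinal(table: pd.DataFrame) -> pd.DataFrame:
    """Check table schema and invariants; returns the table unchanged."""
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise DataError(f"longitudinal table missing columns: {missing}")
    keys = ["animal_id", "day"] + (["measure"] if "measure" in table.columns else [])
    if table.duplicated(subset=keys).any():
        raise DataError("duplicate (animal_id, day) records in longitudinal table")
    n_groups = table.groupby("animal_id")["group"].nunique()
    if (n_groups > 1).any():
        bad = n_groups[n_groups > 1].index.tolist()
        raise DataError(f"animals assigned to multiple groups: {bad}")
    if table["value"].isna().any():
        raise DataError("longitudinal table contains missing values")
    return table


def normalize_longitudinal(
    table: pd.DataFrame, baseline_day=30, mode: str = "ratio"
) -> pd.DataFrame:
    """Normalise each animal's trajectory to its own baseline-day value.

    ``ratio`` mode divides every value by the animal's baseline value
    (baseline rows become exactly 1); ``difference`` subtracts it
    (baseline rows become exactly 0).  Normalisation is per animal and,
    when a ``measure`` column is present, per measure.
    """
    if mode not in ("ratio", "difference"):
        raise DataError(f"unknown normalisation mode {mode!r}")
    validate_longitudinal(table)
    keys = ["animal_id"] + (["measure"] if "measure" in table.columns else [])
    out = table.copy()
    base = table[table["day"] == baseline_day].set_index(keys)["value"]
    if base.empty and len(table):
        raise MissingBaselineError(f"no records at baseline day {baseline_day}")
    idx = pd.MultiIndex.from_frame(out[keys]) if len(keys) > 1 else out[keys[0]]
    try:
        baseline_values = base.loc[idx].to_numpy()
    except KeyError as exc:
        raise MissingBaselineError(
            f"animal(s) lack a baseline-day ({baseline_day}) record: {exc}"
        ) from exc
    if mode == "ratio":
        if (baseline_values == 0).any():
            raise ZeroBaselineError("ratio normalisation with a zero baseline value")
        out["value"] = out["value"].to_numpy() / baseline_values
        out.loc[out["day"] == baseline_day, "value"] = 1.0
    else:
        out["value"] = out["value"].to_numpy() - baseline_values
        out.loc[out["day"] == baseline_day, "value"] = 0.0
    return out
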