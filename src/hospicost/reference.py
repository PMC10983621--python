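"""Loaders for the packaged reference constants of the national costing study.

These are the *published* aggregate results — unit costs per activity center
and care level, pharmaceutical shares, and the bottom-up financing tables
(per-admission costs, frequency profiles, inpatient counts, printed row and
level totals, and the outpatient line). They are shipped for lookup,
comparison and table reproduction; they are never inputs to the costing
computation itself.

Monetary columns are parsed as :class:`decimal.Decimal` so that reproducing
printed column sums is exact, not merely close in binary floating point.
"""

from __future__ import annotations

from decimal import Decimal
from functools import lru_cache
from importlib import resources

import pandas as pd

__all__ = [
    "reference_unit_costs",
    "reference_unit_cost",
    "reference_pharma_shares",
    "financing_activity_rows",
    "financing_ancillary_rows",
    "financing_levels",
    "financing_outpatient",
]

_MONEY_COLS = {
    "unit_cost_no_dep",
    "unit_cost_with_dep",
    "cost_per_admission",
    "unit_cost",
    "printed_total",
    "printed_level_total",
    "frequency_pct",
    "pharma_share",
}


@lru_cache(maxsize=None)
def _load(name: str) -> pd.DataFrame:
    path = resources.files("hospicost.data") / name
    with resources.as_file(path) as p:
        df = pd.read_csv(p, dtype=str)
    for col in df.columns:
        if col in _MONEY_COLS:
            df[col] = df[col].map(Decimal)
        elif col in {"total_inpatients", "inpatient_count", "units_per_inpatient",
                     "total_consultations"}:
            df[col] = df[col].astype(int)
    return df


def reference_unit_costs() -> pd.DataFrame:
    """Published unit costs per activity center, aggregated by care level."""
    return _load("reference_unit_costs.csv").copy()


def reference_unit_cost(
    activity_code: str, level: str, with_depreciation: bool = True
) -> Decimal:
    """Look up one published unit cost (USD per output unit)."""
    df = _load("reference_unit_costs.csv")
    row = df[(df.activity_code == activity_code) & (df.level == level)]
    if row.empty:
        raise KeyError(f"no reference unit cost for ({activity_code}, {level})")
    col = "unit_cost_with_dep" if with_depreciation else "unit_cost_no_dep"
    return row.iloc[0][col]


def reference_pharma_shares() -> pd.DataFrame:
    """Published share of pharmaceuticals in the unit cost, per activity."""
    return _load("reference_pharma_shares.csv").copy()


def financing_activity_rows(level: str | None = None) -> pd.DataFrame:
    """Inpatient-activity rows of the published financing tables."""
    df = _load("financing_activity_rows.csv")
    return (df if level is None else df[df.level == level]).copy()


def financing_ancillary_rows(level: str | None = None) -> pd.DataFrame:
    """Laboratory/radiology ancillary rows of the published financing tables."""
    df = _load("financing_ancillary_rows.csv")
    return (df if level is None else df[df.level == level]).copy()


def financing_levels() -> pd.DataFrame:
    """Per-level projected inpatient totals and printed level totals."""
    return _load("financing_levels.csv").copy()


def financing_outpatient() -> pd.Series:
    """The published all-levels outpatient consultation line."""
    return _load("financing_outpatient.csv").iloc[0].copy()
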