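"""Unit costs per final center, harmonized aggregation across hospitals, the
pharmaceutical-share decomposition, and the cross-hospital dispersion report.

A final center's unit cost is its full (direct + allocated) cost divided by
its yearly activity volume, computed both without the capital component
("without depreciation") and with it. Centers sharing the same harmonized
activity-center code are aggregated — within a hospital and then across
hospitals of the same care level — as the volume-weighted mean
``sum(cost) / sum(volume)``, i.e. the cost of producing one unit at that
level, not the unweighted mean of per-hospital ratios.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .ledger import HospitalLedger
from .stepdown import CascadeResult

log = logging.getLogger(__name__)

__all__ = [
    "UnitCostRecord",
    "PharmaShare",
    "compute_unit_costs",
    "aggregate_by_code",
    "pharmaceutical_share",
    "dispersion_report",
    "unit_costs_frame",
]


@dataclass(frozen=True)
class UnitCostRecord:
    """Cost per output unit for one activity center (or a level aggregate)."""

    hospital_id: str  # or "aggregate"
    level: str
    activity_code: str
    unit: str
    volume: float
    full_cost_no_dep: float
    full_cost_with_dep: float
    pharma_cost: float = 0.0
    flagged: bool = False  # zero volume with positive cost: cost undefined

    @property
    def unit_cost_no_dep(self) -> float:
        return self.full_cost_no_dep / self.volume if self.volume > 0 else math.nan

    @property
    def unit_cost_with_dep(self) -> float:
        return self.full_cost_with_dep / self.volume if self.volume > 0 else math.nan


@dataclass(frozen=True)
class PharmaShare:
    activity_code: str
    share: float  # fraction of the unit cost attributable to pharmaceuticals

    def __post_init__(self) -> None:
        if not -1e-12 <= self.share <= 1 + 1e-12:
            raise ValueError(f"pharmaceutical share {self.share} outside [0, 1]")


def compute_unit_costs(
    result: CascadeResult,
    ledger: HospitalLedger,
) -> list[UnitCostRecord]:
    """Per final center: full cost / volume, with and without depreciation.

    Zero-volume centers with positive cost yield a flagged record (NaN unit
    cost) rather than a division error; they are excluded from aggregation.
    Centers sharing an activity code within the hospital are merged first
    (their costs and volumes add).
    """
    volumes = {a.center_id: a.volume for a in ledger.activities}
    merged: dict[str, UnitCostRecord] = {}
    for center_id, vec in result.final_costs.items():
        center = ledger.center(center_id)
        rec, cap, pharma = float(vec[0]), float(vec[1]), float(vec[2])
        volume = float(volumes.get(center_id, 0.0))
        code = center.code_l2
        prev = merged.get(code)
        if prev is None:
            merged[code] = UnitCostRecord(
                hospital_id=ledger.hospital_id,
                level=ledger.level,
                activity_code=code,
                unit=center.output_unit,
                volume=volume,
                full_cost_no_dep=rec,
                full_cost_with_dep=rec + cap,
                pharma_cost=pharma,
            )
        else:
            merged[code] = UnitCostRecord(
                hospital_id=prev.hospital_id,
                level=prev.level,
                activity_code=code,
                unit=prev.unit,
                volume=prev.volume + volume,
                full_cost_no_dep=prev.full_cost_no_dep + rec,
                full_cost_with_dep=prev.full_cost_with_dep + rec + cap,
                pharma_cost=prev.pharma_cost + pharma,
            )
    records = []
    for code, r in merged.items():
        if r.volume <= 0 and r.full_cost_with_dep > 0:
            log.warning(
                "W-ZERO-VOLUME hospital %s activity %s: cost %.2f with no output; "
                "unit cost undefined, excluded from aggregation",
                r.hospital_id,
                code,
                r.full_cost_with_dep,
            )
            r = UnitCostRecord(
                r.hospital_id, r.level, code, r.unit, 0.0,
                r.full_cost_no_dep, r.full_cost_with_dep, r.pharma_cost,
                flagged=True,
            )
        records.append(r)
    return sorted(records, key=lambda r: r.activity_code)


def aggregate_by_code(
    records: Iterable[UnitCostRecord],
    level: str,
    weighted: bool = True,
) -> list[UnitCostRecord]:
    """Aggregate per-hospital records of one care level per activity code.

    The default is the volume-weighted mean ``sum(full cost) / sum(volume)``
    across hospitals; ``weighted=False`` gives the unweighted mean of
    per-hospital unit costs for sensitivity analysis. Flagged (zero-volume)
    records are excluded.
    """
    usable = [r for r in records if r.level == level and not r.flagged and r.volume > 0]
    out: list[UnitCostRecord] = []
    by_code: dict[str, list[UnitCostRecord]] = {}
    for r in usable:
        by_code.setdefault(r.activity_code, []).append(r)
    for code in sorted(by_code):
        group = by_code[code]
        volume = sum(r.volume for r in group)
        if weighted:
            no_dep = sum(r.full_cost_no_dep for r in group)
            with_dep = sum(r.full_cost_with_dep for r in group)
            pharma = sum(r.pharma_cost for r in group)
        else:
            # mean of per-hospital ratios, rescaled onto the pooled volume
            mean_no = sum(r.unit_cost_no_dep for r in group) / len(group)
            mean_with = sum(r.unit_cost_with_dep for r in group) / len(group)
            mean_ph = sum(r.pharma_cost / r.volume for r in group) / len(group)
            no_dep, with_dep, pharma = (
                mean_no * volume,
                mean_with * volume,
                mean_ph * volume,
            )
        out.append(
            UnitCostRecord(
                hospital_id="aggregate",
                level=level,
                activity_code=code,
                unit=group[0].unit,
                volume=volume,
                full_cost_no_dep=no_dep,
                full_cost_with_dep=with_dep,
                pharma_cost=pharma,
            )
        )
    return out


def pharmaceutical_share(
    result: CascadeResult, ledger: HospitalLedger
) -> list[PharmaShare]:
    """Fraction of each activity center's full cost that is pharmaceutical.

    The pharmaceutical component (direct drug lines plus drug cost received
    through allocated flows, e.g. from the pharmacy store) is cascaded in
    parallel with the recurrent component, so the share is simply its ratio
    to the full (with-depreciation) cost.
    """
    shares = []
    for r in compute_unit_costs(result, ledger):
        full = r.full_cost_with_dep
        if full > 0:
            shares.append(PharmaShare(r.activity_code, min(r.pharma_cost / full, 1.0)))
    return shares


def dispersion_report(records: Iterable[UnitCostRecord]) -> pd.DataFrame:
    """Within-level min / median / max of per-hospital unit costs per code.

    Mirrors the min-max framing used to surface cross-hospital efficiency
    spreads (the same inpatient day costing several times more in one
    hospital than another at the same level of care).
    """
    rows = [
        {
            "level": r.level,
            "activity_code": r.activity_code,
            "hospital_id": r.hospital_id,
            "unit_cost_no_dep": r.unit_cost_no_dep,
            "unit_cost_with_dep": r.unit_cost_with_dep,
        }
        for r in records
        if not r.flagged and r.volume > 0
    ]
    if not rows:
        return pd.DataFrame(
            columns=["level", "activity_code", "n_hospitals", "min", "median", "max"]
        )
    df = pd.DataFrame(rows)
    out = (
        df.groupby(["level", "activity_code"], sort=True)["unit_cost_with_dep"]
        .agg(n_hospitals="count", min="min", median="median", max="max")
        .reset_index()
    )
    return out


def unit_costs_frame(records: Sequence[UnitCostRecord]) -> pd.DataFrame:
    """Tabular view matching the unit_costs.csv output schema."""
    return pd.DataFrame(
        [
            {
                "hospital_id": r.hospital_id,
                "level": r.level,
                "activity_code": r.activity_code,
                "unit": r.unit,
                "volume": r.volume,
                "unit_cost_no_dep": r.unit_cost_no_dep,
                "unit_cost_with_dep": r.unit_cost_with_dep,
                "pharma_share": (r.pharma_cost / r.full_cost_with_dep)
                if r.full_cost_with_dep > 0
                else 0.0,
                "flagged": r.flagged,
            }
            for r in records
        ]
    )
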