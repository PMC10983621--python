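"""Synthetic multi-hospital ledgers with exact ground truth.

The generator works *backwards*: it first draws each final center's target
full cost, capital share and activity volume (around the published per-level
unit-cost magnitudes, with a configurable cross-hospital dispersion emulating
the efficiency spread observed between real hospitals), then fabricates
overhead/support direct costs, staff assignments, capital inventories and
allocation keys whose step-down cascade reproduces those targets by
construction. Ground truth is therefore exact, and running the pipeline on a
generated ledger must recover the target unit costs to floating-point
precision — the sharpest possible end-to-end test.

The construction exploits a closed form: if every source distributes its
final-center portion with proportions equal to each final's share of the
total allocated cost, the cascade delivers exactly that allocated amount to
each final, regardless of how overhead cost is routed through support
centers on the way.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .depreciation import DepreciationPolicy, annuity_factor
from .ledger import (
    ActivityRecord,
    CapitalAsset,
    CostCenter,
    ExpenditureLine,
    HospitalLedger,
    KeyMeasurement,
    StaffAssignment,
    MARKET,
    write_ledger,
)
from .reference import reference_pharma_shares, reference_unit_costs
from .stepdown import GENERAL_UNIT_VARIABLES

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "AdmissionsTrend",
    "generate_hospital",
    "generate_sample",
    "generate_admissions_series",
    "write_sample",
]

CARE_LEVELS = ("provincial", "regional", "teaching")

#: Sample shape of the national study: 10 provincial, 11 regional, 18 teaching.
FULL_SAMPLE_SHAPE = {"provincial": 10, "regional": 11, "teaching": 18}

# Final-center roster: activity code -> output unit, in generation order.
_FINAL_ROSTER = (
    ("surgery_hospitalization", "hospitalization_day"),
    ("medicine_hospitalization", "hospitalization_day"),
    ("maternity", "hospitalization_day"),
    ("pediatrics", "hospitalization_day"),
    ("icu", "hospitalization_day"),
    ("outpatient_consultation", "consultation"),
    ("laboratory", "unit_B"),
    ("radiology", "unit_Z"),
    ("emergency", "consultation"),
    ("operating_theater", "unit_K"),
    ("hemodialysis", "hemodialysis_session"),
    ("psychiatry", "hospitalization_day"),
    ("neonatology", "hospitalization_day"),
    ("oncology", "hospitalization_day"),
)

# Typical yearly output volumes per unit type (midpoint of the sampling range).
_VOLUME_SCALE = {
    "hospitalization_day": 8000.0,
    "consultation": 20000.0,
    "emergency_visit": 15000.0,
    "unit_B": 400000.0,
    "unit_K": 60000.0,
    "unit_Z": 150000.0,
    "hemodialysis_session": 6000.0,
}

_OVERHEAD_ROLES = (
    "directorate",
    "reception",
    "human_resources",
    "cleaning",
    "informatics",
    "space_maintenance",
    "billing",
    "statistics",
)
_SUPPORT_ROLES = (
    "pharmacy_store",
    "laundry",
    "catering",
    "equipment_maintenance",
    "supply_stores",
    "gardening",
)


@dataclass(frozen=True)
class SyntheticSpec:
    """Study-shape parameters of the synthetic hospital sample.

    Defaults mirror the national sample scaled down (two hospitals per care
    level instead of 10/11/18) with six final centers, four overhead and
    three support centers per hospital; ``overhead_share`` is the fraction of
    recurrent cost held by overhead/support centers before allocation,
    ``capital_share`` the capital fraction of full cost, and ``dispersion``
    the log-scale cross-hospital spread of unit costs around the published
    per-level magnitudes.
    """

    n_hospitals: Mapping[str, int] = field(
        default_factory=lambda: {"provincial": 2, "regional": 2, "teaching": 2}
    )
    n_overhead: int = 4
    n_support: int = 3
    n_final: int = 6
    overhead_share: float = 0.35
    capital_share: float = 0.15
    dispersion: float = 0.25
    unit_cost_ranges: Mapping[tuple[str, str], tuple[float, float]] | None = None
    market_salaries: Mapping[str, float] = field(
        default_factory=lambda: {"nurse": 48000.0}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.overhead_share < 1:
            raise ValueError("overhead_share must be in [0, 1)")
        if not 0 <= self.capital_share < 1:
            raise ValueError("capital_share must be in [0, 1)")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.n_final < 1 or self.n_final > len(_FINAL_ROSTER):
            raise ValueError(f"n_final must be in [1, {len(_FINAL_ROSTER)}]")


@dataclass
class GroundTruth:
    """Exact per-final-center targets the pipeline must recover."""

    hospital_id: str
    level: str
    # center_id -> {activity_code, volume, full_recurrent, capital,
    #               unit_cost_no_dep, unit_cost_with_dep}
    finals: dict[str, dict]

    def to_json(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class AdmissionsTrend:
    """Linear admissions trend with optional shock years (pandemic dips)."""

    level: str
    intercept: float  # admissions at year 0 of the centered scale
    slope: float  # admissions per year
    noise_sd: float = 0.0


def _hospital_rng(seed: int, level: str, index: int) -> np.random.Generator:
    # one independent stream per hospital, reproducible from (seed, level, index)
    ss = np.random.SeedSequence(seed, spawn_key=(CARE_LEVELS.index(level), index))
    return np.random.default_rng(ss)


def generate_hospital(
    spec: SyntheticSpec, level: str, index: int
) -> tuple[HospitalLedger, GroundTruth]:
    """Fabricate one hospital ledger whose cascade output is known exactly."""
    if level not in CARE_LEVELS:
        raise ValueError(f"unknown care level {level!r}")
    rng = _hospital_rng(spec.seed, level, index)
    hid = f"{level[:4]}-{index:02d}"
    ref = reference_unit_costs()
    pharma_ref = {
        r.activity_code: float(r.pharma_share)
        for r in reference_pharma_shares().itertuples()
    }

    centers: list[CostCenter] = []
    expenditures: list[ExpenditureLine] = []
    staff: list[StaffAssignment] = []
    assets: list[CapitalAsset] = []
    keys: list[KeyMeasurement] = []
    activities: list[ActivityRecord] = []
    truth_finals: dict[str, dict] = {}

    # --- final centers: draw targets -------------------------------------
    roster = _FINAL_ROSTER[: spec.n_final]
    final_ids, allocated, direct_rec, capital = [], {}, {}, {}
    for j, (code, unit) in enumerate(roster):
        cid = f"{hid}-F{j}"
        final_ids.append(cid)
        row = ref[(ref.activity_code == code) & (ref.level == level)]
        base_uc = float(row.iloc[0]["unit_cost_with_dep"])
        if spec.unit_cost_ranges and (code, level) in spec.unit_cost_ranges:
            lo, hi = spec.unit_cost_ranges[(code, level)]
            base_uc = rng.uniform(lo, hi)
        target_uc = base_uc * float(np.exp(rng.normal(0.0, spec.dispersion)))
        volume = _VOLUME_SCALE[unit] * rng.uniform(0.5, 1.5)
        full_with_dep = target_uc * volume
        cap = spec.capital_share * full_with_dep
        rec = full_with_dep - cap
        allocated[cid] = spec.overhead_share * rec
        direct_rec[cid] = rec - allocated[cid]
        capital[cid] = cap
        centers.append(
            CostCenter(cid, hid, code.replace("_", " "), "final",
                       code_l1=f"U{j}", code_l2=code, output_unit=unit)
        )
        activities.append(ActivityRecord(cid, unit, volume))
        truth_finals[cid] = {
            "activity_code": code,
            "volume": volume,
            "full_recurrent": rec,
            "capital": cap,
            "unit_cost_no_dep": rec / volume,
            "unit_cost_with_dep": target_uc,
        }

    total_allocated = sum(allocated.values())
    final_weights = (
        {cid: allocated[cid] / total_allocated for cid in final_ids}
        if total_allocated > 0
        else {}
    )

    # --- capital inventory: assets placed at finals, EAC == target capital
    policy = DepreciationPolicy()
    for cid in final_ids:
        cap = capital[cid]
        if cap <= 0:
            continue
        eq, bd = 0.7 * cap, 0.3 * cap
        assets.append(CapitalAsset(cid, "equipment",
                                   eq * annuity_factor(10, policy.interest_rate), 1))
        assets.append(CapitalAsset(cid, "building",
                                   bd * annuity_factor(25, policy.interest_rate), 1))

    # --- overhead / support centers --------------------------------------
    over_roles = list(_OVERHEAD_ROLES[: spec.n_overhead])
    supp_roles = list(_SUPPORT_ROLES[: spec.n_support])
    source_ids, source_roles = [], {}
    for j, role in enumerate(over_roles):
        cid = f"{hid}-O{j}"
        source_ids.append(cid)
        source_roles[cid] = role
        centers.append(CostCenter(cid, hid, role.replace("_", " "), "overhead",
                                  code_l1=role))
    supp_ids = []
    for j, role in enumerate(supp_roles):
        cid = f"{hid}-S{j}"
        source_ids.append(cid)
        supp_ids.append(cid)
        source_roles[cid] = role
        centers.append(CostCenter(cid, hid, role.replace("_", " "), "support",
                                  code_l1=role))

    if total_allocated > 0 and source_ids:
        weights = rng.dirichlet(np.full(len(source_ids), 4.0))
        src_direct = {cid: total_allocated * w for cid, w in zip(source_ids, weights)}
    else:
        src_direct = {cid: 0.0 for cid in source_ids}

    beta = 0.3 if supp_ids else 0.0  # overhead fraction routed via supports
    for cid in source_ids:
        role = source_roles[cid]
        variable = GENERAL_UNIT_VARIABLES[role]
        scale = rng.uniform(50.0, 500.0)
        is_overhead = cid.split("-")[-1].startswith("O")
        if is_overhead and supp_ids:
            sweights = rng.dirichlet(np.full(len(supp_ids), 2.0))
            for sid, w in zip(supp_ids, sweights):
                keys.append(KeyMeasurement(cid, variable, sid, beta * w * scale))
        frac_final = (1.0 - beta) if (is_overhead and supp_ids) else 1.0
        for fid in final_ids:
            keys.append(
                KeyMeasurement(cid, variable, fid,
                               frac_final * final_weights.get(fid, 0.0) * scale)
            )

    # --- expenditure lines and staff ------------------------------------
    for cid in source_ids:
        d = src_direct[cid]
        if d <= 0:
            continue
        if source_roles[cid] == "pharmacy_store":
            expenditures.append(ExpenditureLine(cid, "pharmaceuticals", d))
        else:
            expenditures.append(ExpenditureLine(cid, "personnel", 0.5 * d))
            expenditures.append(ExpenditureLine(cid, "other", d - 0.5 * d))

    # a physician shared between the two largest finals exercises FTE splits
    shared_budget = 0.0
    if len(final_ids) >= 2:
        f0, f1 = final_ids[0], final_ids[1]
        shared_budget = 0.1 * min(direct_rec[f0], direct_rec[f1])
        if shared_budget > 0:
            staff.append(
                StaffAssignment(f"{hid}-md-shared", 2 * shared_budget, "physician",
                               ((f0, 0.5), (f1, 0.5)))
            )
    volunteer_salary = spec.market_salaries.get("nurse", 0.0)
    for j, cid in enumerate(final_ids):
        d = direct_rec[cid]
        personnel = 0.4 * d
        if j in (0, 1):
            personnel -= shared_budget
        if j == 0 and 0 < volunteer_salary < personnel:
            staff.append(
                StaffAssignment(f"{hid}-volunteer-nurse", MARKET, "nurse",
                               ((cid, 1.0),))
            )
            personnel -= volunteer_salary
        if personnel > 0:
            staff.append(
                StaffAssignment(f"{hid}-staff-{j}", personnel, "mixed", ((cid, 1.0),))
            )
        code = truth_finals[cid]["activity_code"]
        pharma = min(0.5 * pharma_ref.get(code, 0.1), 0.4) * d
        supplies = 0.15 * d
        other = d - 0.4 * d - pharma - supplies
        expenditures.append(ExpenditureLine(cid, "pharmaceuticals", pharma))
        expenditures.append(ExpenditureLine(cid, "medical_supplies", supplies))
        expenditures.append(ExpenditureLine(cid, "other", other))

    ledger = HospitalLedger(
        hospital_id=hid,
        level=level,
        region=f"region-{index}",
        currency="USD",
        centers=tuple(centers),
        expenditures=tuple(expenditures),
        staff=tuple(staff),
        assets=tuple(assets),
        keys=tuple(keys),
        activities=tuple(activities),
    )
    ledger.validate()
    return ledger, GroundTruth(hid, level, truth_finals)


def generate_sample(spec: SyntheticSpec) -> list[tuple[HospitalLedger, GroundTruth]]:
    """All hospitals of the spec, ordered by level then index."""
    out = []
    for level in CARE_LEVELS:
        for index in range(spec.n_hospitals.get(level, 0)):
            out.append(generate_hospital(spec, level, index))
    return out


def generate_admissions_series(
    trend: AdmissionsTrend,
    years: Sequence[int],
    shock_years: frozenset[int] | set[int] = frozenset(),
    shock_factor: float = 0.6,
    seed: int = 0,
):
    """Linear admissions series with Gaussian noise and shock-year dips."""
    from .financing import AdmissionsSeries

    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(97,)))
    year0 = min(years)
    obs = []
    for y in years:
        value = trend.intercept + trend.slope * (y - year0)
        if trend.noise_sd > 0:
            value += rng.normal(0.0, trend.noise_sd)
        if y in shock_years:
            value *= shock_factor
        obs.append((int(y), max(float(value), 0.0)))
    return AdmissionsSeries(trend.level, tuple(obs))


def write_sample(spec: SyntheticSpec, out_dir: str | Path) -> list[Path]:
    """Write every generated ledger as a CSV file set plus ground_truth.json."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    truths = {}
    for ledger, truth in generate_sample(spec):
        hdir = out_dir / ledger.hospital_id
        write_ledger(ledger, hdir)
        truths[ledger.hospital_id] = truth.to_json()
        paths.append(hdir)
    (out_dir / "ground_truth.json").write_text(
        json.dumps(truths, indent=2, sort_keys=True)
    )
    return paths
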