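"""Domain model and CSV I/O for one hospital's cost-accounting ledger.

A hospital is modeled as a set of *cost centers* — overhead (administration),
support (intermediate services such as laundry, catering or the pharmacy
store) and final (patient-facing) centers — together with the recurrent
expenditure lines booked to each center, the capital asset inventory, staff
assignments (full-time-equivalent fractions across centers), allocation-key
measurements used by the step-down cascade, and the yearly activity volumes of
final centers.

Final centers carry a two-level code: level 1 identifies the physical unit,
level 2 the harmonized *activity center* (e.g. every surgical ward maps to
``surgery_hospitalization``) so unit costs can be compared across hospitals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "CENTER_CATEGORIES",
    "OUTPUT_UNITS",
    "ACTIVITY_CENTERS",
    "KEY_VARIABLES",
    "MARKET",
    "CostCenter",
    "ExpenditureLine",
    "StaffAssignment",
    "CapitalAsset",
    "KeyMeasurement",
    "ActivityRecord",
    "HospitalLedger",
    "LedgerValidationError",
    "load_ledger",
    "write_ledger",
    "impute_staff_costs",
    "assemble_direct_costs",
    "convert_currency",
]

CENTER_CATEGORIES = ("overhead", "support", "final")

CARE_LEVELS = ("provincial", "regional", "teaching")

#: Output units of final centers. ``unit_B`` / ``unit_K`` / ``unit_Z`` are the
#: virtual laboratory / surgical / radiology units of the Moroccan general
#: nomenclature of procedures (complexity-weighted volumes).
OUTPUT_UNITS = (
    "hospitalization_day",
    "consultation",
    "emergency_visit",
    "unit_B",
    "unit_K",
    "unit_Z",
    "hemodialysis_session",
    "none",
)

#: The 14 harmonized activity-center groups (level-2 codes) final centers
#: aggregate into for cross-hospital comparison.
ACTIVITY_CENTERS = (
    "surgery_hospitalization",
    "medicine_hospitalization",
    "maternity",
    "neonatology",
    "pediatrics",
    "psychiatry",
    "icu",
    "emergency",
    "outpatient_consultation",
    "radiology",
    "laboratory",
    "operating_theater",
    "hemodialysis",
    "oncology",
)

#: Allocation-key variables of the nationally validated distribution keys
#: (EFT = equivalent full-time staffing).
KEY_VARIABLES = (
    "EFT",
    "EFT_medical",
    "EFT_nurse",
    "n_patients",
    "total_expenditure",
    "received_store_amount",
    "m2",
    "n_computers",
    "laundry_kg",
    "n_meals",
    "n_maintenance_interventions",
    "n_pharmacy_items",
    "n_patients_plus_HR",
)

EXPENDITURE_CATEGORIES = (
    "personnel",
    "pharmaceuticals",
    "medical_supplies",
    "utilities",
    "maintenance",
    "catering",
    "other",
)

ASSET_CLASSES = ("equipment", "informatics_transport", "building")

#: Sentinel salary for volunteer / contract staff whose cost is imputed from
#: the market salary of a similar position.
MARKET = "MARKET"


class LedgerValidationError(ValueError):
    """Aggregated validation failure: carries every violation found."""

    def __init__(self, errors: Sequence[str]):
        self.errors = list(errors)
        super().__init__(
            "ledger validation failed with %d error(s):\n  - %s"
            % (len(self.errors), "\n  - ".join(self.errors))
        )


@dataclass(frozen=True)
class CostCenter:
    center_id: str
    hospital_id: str
    name: str
    category: str  # overhead | support | final
    code_l1: str = ""  # physical unit code
    code_l2: str = ""  # harmonized activity-center group (final centers)
    output_unit: str = "none"


@dataclass(frozen=True)
class ExpenditureLine:
    center_id: str
    item_category: str
    amount: float  # currency per year, >= 0


@dataclass(frozen=True)
class StaffAssignment:
    """One staff member's salary and its split across centers.

    ``gross_annual_salary`` is either a number or the :data:`MARKET` sentinel,
    in which case the salary of ``market_position`` is looked up in the
    configured market-salary table (volunteer imputation).
    """

    staff_id: str
    gross_annual_salary: float | str
    market_position: str
    splits: tuple[tuple[str, float], ...]  # (center_id, fte_fraction)


@dataclass(frozen=True)
class CapitalAsset:
    center_id: str
    asset_class: str
    purchase_price: float
    quantity: int = 1


@dataclass(frozen=True)
class KeyMeasurement:
    source_center_id: str
    variable: str
    target_center_id: str
    key_value: float


@dataclass(frozen=True)
class ActivityRecord:
    center_id: str
    unit: str
    volume: float


@dataclass(frozen=True)
class HospitalLedger:
    hospital_id: str
    level: str  # provincial | regional | teaching
    region: str = ""
    currency: str = "USD"
    centers: tuple[CostCenter, ...] = ()
    expenditures: tuple[ExpenditureLine, ...] = ()
    staff: tuple[StaffAssignment, ...] = ()
    assets: tuple[CapitalAsset, ...] = ()
    keys: tuple[KeyMeasurement, ...] = ()
    activities: tuple[ActivityRecord, ...] = ()

    def center(self, center_id: str) -> CostCenter:
        for c in self.centers:
            if c.center_id == center_id:
                return c
        raise KeyError(center_id)

    def centers_by_category(self, category: str) -> list[CostCenter]:
        return [c for c in self.centers if c.category == category]

    def validate(self) -> None:
        """Check every invariant; raise one aggregated error listing them all."""
        errors: list[str] = []
        ids = [c.center_id for c in self.centers]
        known = set(ids)
        if len(ids) != len(known):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            errors.append(f"duplicate center_id(s): {dupes}")
        if self.level not in CARE_LEVELS:
            errors.append(f"unknown care level {self.level!r}")

        finals = set()
        for c in self.centers:
            if c.category not in CENTER_CATEGORIES:
                errors.append(f"center {c.center_id}: unknown category {c.category!r}")
            if c.output_unit not in OUTPUT_UNITS:
                errors.append(
                    f"center {c.center_id}: unknown output unit {c.output_unit!r}"
                )
            if c.category == "final":
                finals.add(c.center_id)
                if c.output_unit == "none":
                    errors.append(
                        f"final center {c.center_id} must declare an output unit"
                    )
                if c.code_l2 not in ACTIVITY_CENTERS:
                    errors.append(
                        f"final center {c.center_id}: level-2 code {c.code_l2!r} is "
                        f"not a harmonized activity center"
                    )
            elif c.output_unit != "none":
                errors.append(
                    f"{c.category} center {c.center_id} must have output_unit=none"
                )
        if not finals:
            errors.append("ledger has no final cost center")

        for i, line in enumerate(self.expenditures):
            if line.center_id not in known:
                errors.append(
                    f"expenditures row {i}: unknown center {line.center_id!r}"
                )
            if line.item_category not in EXPENDITURE_CATEGORIES:
                errors.append(
                    f"expenditures row {i}: unknown item category "
                    f"{line.item_category!r}"
                )
            if not line.amount >= 0:
                errors.append(
                    f"expenditures row {i} ({line.center_id}): negative amount "
                    f"{line.amount} (refunds are not representable)"
                )

        for s in self.staff:
            total_fte = sum(f for _, f in s.splits)
            if total_fte > 1 + 1e-9:
                errors.append(
                    f"staff {s.staff_id}: FTE fractions sum to {total_fte:.4f} > 1"
                )
            for cid, f in s.splits:
                if cid not in known:
                    errors.append(f"staff {s.staff_id}: unknown center {cid!r}")
                if not 0 <= f <= 1:
                    errors.append(
                        f"staff {s.staff_id}: FTE fraction {f} outside [0, 1]"
                    )

        for i, a in enumerate(self.assets):
            if a.center_id not in known:
                errors.append(f"assets row {i}: unknown center {a.center_id!r}")
            if a.asset_class not in ASSET_CLASSES:
                errors.append(f"assets row {i}: unknown asset class {a.asset_class!r}")
            if not a.purchase_price > 0:
                errors.append(
                    f"assets row {i} ({a.center_id}): purchase price must be > 0"
                )
            if a.quantity < 1:
                errors.append(f"assets row {i} ({a.center_id}): quantity must be >= 1")

        seen_pairs = set()
        for i, k in enumerate(self.keys):
            if k.source_center_id not in known:
                errors.append(f"keys row {i}: unknown source {k.source_center_id!r}")
            if k.target_center_id not in known:
                errors.append(f"keys row {i}: unknown target {k.target_center_id!r}")
            if k.variable not in KEY_VARIABLES:
                errors.append(f"keys row {i}: unknown key variable {k.variable!r}")
            if not k.key_value >= 0:
                errors.append(f"keys row {i}: negative key value {k.key_value}")
            pair = (k.source_center_id, k.target_center_id)
            if pair in seen_pairs:
                errors.append(f"keys row {i}: duplicate (source, target) pair {pair}")
            seen_pairs.add(pair)

        for i, act in enumerate(self.activities):
            if act.center_id not in known:
                errors.append(f"activity row {i}: unknown center {act.center_id!r}")
            else:
                c = self.center(act.center_id)
                if c.category != "final":
                    errors.append(
                        f"activity row {i}: center {act.center_id} is not final"
                    )
                elif act.unit != c.output_unit:
                    errors.append(
                        f"activity row {i}: unit {act.unit!r} does not match "
                        f"center {act.center_id}'s output unit {c.output_unit!r}"
                    )
            if not act.volume >= 0:
                errors.append(f"activity row {i}: negative volume {act.volume}")

        if errors:
            raise LedgerValidationError(errors)


# ---------------------------------------------------------------------------
# CSV I/O
#
# One ledger = six CSV files in a directory (UTF-8, comma-separated, header
# row, "." decimal separator): cost_centers, expenditures, staff, assets,
# keys, activity — plus hospital.csv with the one-row hospital metadata.

LEDGER_FILES = {
    "hospital": ["hospital_id", "level", "region", "currency"],
    "cost_centers": [
        "hospital_id",
        "center_id",
        "name",
        "category",
        "code_l1",
        "code_l2",
        "output_unit",
    ],
    "expenditures": ["center_id", "item_category", "amount", "currency"],
    "staff": [
        "staff_id",
        "gross_annual_salary",
        "market_position",
        "center_id",
        "fte_fraction",
    ],
    "assets": ["center_id", "asset_class", "purchase_price", "quantity", "currency"],
    "keys": ["source_center_id", "variable", "target_center_id", "key_value"],
    "activity": ["center_id", "unit", "volume"],
}


def _read_csv(directory: Path, stem: str) -> pd.DataFrame:
    path = directory / f"{stem}.csv"
    if not path.exists():
        raise FileNotFoundError(f"missing ledger file: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in LEDGER_FILES[stem] if c not in df.columns]
    if missing:
        raise LedgerValidationError(
            [f"{path.name}: missing column(s) {missing} (found {list(df.columns)})"]
        )
    return df


def load_ledger(
    directory: str | Path,
    exchange_rate: float = 1.0,
    reporting_currency: str | None = None,
) -> HospitalLedger:
    """Read one hospital's CSV file set, validate, and convert currency.

    All monetary amounts are multiplied once by ``exchange_rate`` (source
    currency -> reporting currency); the returned ledger is tagged with
    ``reporting_currency`` so a second conversion is detectable.
    """
    directory = Path(directory)
    errors: list[str] = []

    hosp = _read_csv(directory, "hospital")
    if len(hosp) != 1:
        raise LedgerValidationError(
            [f"hospital.csv: expected exactly 1 row, found {len(hosp)}"]
        )
    meta = hosp.iloc[0]

    centers_df = _read_csv(directory, "cost_centers")
    centers = tuple(
        CostCenter(
            center_id=r.center_id,
            hospital_id=r.hospital_id,
            name=r.name,
            category=r.category,
            code_l1=r.code_l1,
            code_l2=r.code_l2,
            output_unit=r.output_unit or "none",
        )
        for r in centers_df.itertuples()
    )

    def _num(value: str, where: str) -> float:
        try:
            return float(value)
        except ValueError:
            errors.append(f"{where}: not a number: {value!r}")
            return 0.0

    exp_df = _read_csv(directory, "expenditures")
    expenditures = tuple(
        ExpenditureLine(
            center_id=r.center_id,
            item_category=r.item_category,
            amount=_num(r.amount, f"expenditures.csv row {i}"),
        )
        for i, r in enumerate(exp_df.itertuples())
    )

    staff_df = _read_csv(directory, "staff")
    staff = []
    for staff_id, grp in staff_df.groupby("staff_id", sort=False):
        salary_raw = grp.iloc[0].gross_annual_salary
        salary: float | str
        if salary_raw == MARKET:
            salary = MARKET
        else:
            salary = _num(salary_raw, f"staff.csv staff {staff_id}")
        staff.append(
            StaffAssignment(
                staff_id=str(staff_id),
                gross_annual_salary=salary,
                market_position=grp.iloc[0].market_position,
                splits=tuple(
                    (r.center_id, _num(r.fte_fraction, f"staff.csv staff {staff_id}"))
                    for r in grp.itertuples()
                ),
            )
        )

    assets_df = _read_csv(directory, "assets")
    assets = tuple(
        CapitalAsset(
            center_id=r.center_id,
            asset_class=r.asset_class,
            purchase_price=_num(r.purchase_price, f"assets.csv row {i}"),
            quantity=int(_num(r.quantity, f"assets.csv row {i}")),
        )
        for i, r in enumerate(assets_df.itertuples())
    )

    keys_df = _read_csv(directory, "keys")
    keys = tuple(
        KeyMeasurement(
            source_center_id=r.source_center_id,
            variable=r.variable,
            target_center_id=r.target_center_id,
            key_value=_num(r.key_value, f"keys.csv row {i}"),
        )
        for i, r in enumerate(keys_df.itertuples())
    )

    act_df = _read_csv(directory, "activity")
    activities = tuple(
        ActivityRecord(
            center_id=r.center_id,
            unit=r.unit,
            volume=_num(r.volume, f"activity.csv row {i}"),
        )
        for i, r in enumerate(act_df.itertuples())
    )

    if errors:
        raise LedgerValidationError(errors)

    ledger = HospitalLedger(
        hospital_id=meta.hospital_id,
        level=meta.level,
        region=meta.region,
        currency=meta.currency,
        centers=centers,
        expenditures=expenditures,
        staff=tuple(staff),
        assets=assets,
        keys=keys,
        activities=activities,
    )
    ledger.validate()
    if exchange_rate != 1.0 or (
        reporting_currency is not None and reporting_currency != ledger.currency
    ):
        ledger = convert_currency(
            ledger, exchange_rate, reporting_currency or ledger.currency
        )
    return ledger


def convert_currency(
    ledger: HospitalLedger, rate: float, to_currency: str
) -> HospitalLedger:
    """Multiply every monetary amount once by ``rate`` and retag the ledger."""
    if ledger.currency == to_currency and rate != 1.0:
        raise ValueError(
            f"ledger already in {to_currency}; refusing a second conversion"
        )
    return replace(
        ledger,
        currency=to_currency,
        expenditures=tuple(
            replace(e, amount=e.amount * rate) for e in ledger.expenditures
        ),
        staff=tuple(
            s
            if s.gross_annual_salary == MARKET
            else replace(s, gross_annual_salary=s.gross_annual_salary * rate)
            for s in ledger.staff
        ),
        assets=tuple(
            replace(a, purchase_price=a.purchase_price * rate) for a in ledger.assets
        ),
    )


def write_ledger(ledger: HospitalLedger, directory: str | Path) -> None:
    """Write the six-file CSV set; ``load_ledger`` round-trips it."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [
            {
                "hospital_id": ledger.hospital_id,
                "level": ledger.level,
                "region": ledger.region,
                "currency": ledger.currency,
            }
        ]
    ).to_csv(directory / "hospital.csv", index=False)
    pd.DataFrame(
        [
            {
                "hospital_id": c.hospital_id,
                "center_id": c.center_id,
                "name": c.name,
                "category": c.category,
                "code_l1": c.code_l1,
                "code_l2": c.code_l2,
                "output_unit": c.output_unit,
            }
            for c in ledger.centers
        ],
        columns=LEDGER_FILES["cost_centers"],
    ).to_csv(directory / "cost_centers.csv", index=False)
    pd.DataFrame(
        [
            {
                "center_id": e.center_id,
                "item_category": e.item_category,
                "amount": repr(float(e.amount)),
                "currency": ledger.currency,
            }
            for e in ledger.expenditures
        ],
        columns=LEDGER_FILES["expenditures"],
    ).to_csv(directory / "expenditures.csv", index=False)
    pd.DataFrame(
        [
            {
                "staff_id": s.staff_id,
                "gross_annual_salary": s.gross_annual_salary
                if s.gross_annual_salary == MARKET
                else repr(float(s.gross_annual_salary)),
                "market_position": s.market_position,
                "center_id": cid,
                "fte_fraction": repr(float(f)),
            }
            for s in ledger.staff
            for cid, f in s.splits
        ],
        columns=LEDGER_FILES["staff"],
    ).to_csv(directory / "staff.csv", index=False)
    pd.DataFrame(
        [
            {
                "center_id": a.center_id,
                "asset_class": a.asset_class,
                "purchase_price": repr(float(a.purchase_price)),
                "quantity": a.quantity,
                "currency": ledger.currency,
            }
            for a in ledger.assets
        ],
        columns=LEDGER_FILES["assets"],
    ).to_csv(directory / "assets.csv", index=False)
    pd.DataFrame(
        [
            {
                "source_center_id": k.source_center_id,
                "variable": k.variable,
                "target_center_id": k.target_center_id,
                "key_value": repr(float(k.key_value)),
            }
            for k in ledger.keys
        ],
        columns=LEDGER_FILES["keys"],
    ).to_csv(directory / "keys.csv", index=False)
    pd.DataFrame(
        [
            {"center_id": a.center_id, "unit": a.unit, "volume": repr(float(a.volume))}
            for a in ledger.activities
        ],
        columns=LEDGER_FILES["activity"],
    ).to_csv(directory / "activity.csv", index=False)


# ---------------------------------------------------------------------------
# Staff-cost imputation and direct-cost assembly


def impute_staff_costs(
    staff: Iterable[StaffAssignment],
    market_table: Mapping[str, float] | None = None,
) -> list[ExpenditureLine]:
    """Turn staff assignments into personnel expenditure lines.

    Each (staff, center) split becomes one line of ``salary * fte_fraction``.
    Volunteers (salary = :data:`MARKET`) are costed at the market salary of a
    similar position. Staff assigned less than a full FTE in total are allowed
    (part-time positions) but logged, so unbooked payroll is visible.
    """
    market_table = market_table or {}
    lines: list[ExpenditureLine] = []
    for s in staff:
        if s.gross_annual_salary == MARKET:
            try:
                salary = market_table[s.market_position]
            except KeyError:
                raise KeyError(
                    f"staff {s.staff_id}: no market salary for position "
                    f"{s.market_position!r}"
                ) from None
        else:
            salary = float(s.gross_annual_salary)
        total_fte = 0.0
        for center_id, fte in s.splits:
            lines.append(ExpenditureLine(center_id, "personnel", salary * fte))
            total_fte += fte
        if total_fte < 1 - 1e-9:
            log.warning(
                "W-FTE-UNASSIGNED staff %s: %.4f FTE unassigned",
                s.staff_id,
                1 - total_fte,
            )
    return lines


def assemble_direct_costs(
    ledger: HospitalLedger,
    depreciation: Mapping[str, float] | None = None,
    market_table: Mapping[str, float] | None = None,
) -> dict[str, tuple[float, float]]:
    """Per-center (recurrent, capital) direct costs before any allocation.

    Recurrent = booked expenditure lines + imputed staff lines; capital = the
    per-center equivalent annual cost (zero when running the without-
    depreciation variant, i.e. ``depreciation`` empty or None). Every center
    of the ledger appears in the result, including empty ones.
    """
    depreciation = depreciation or {}
    recurrent = {c.center_id: 0.0 for c in ledger.centers}
    for line in ledger.expenditures:
        recurrent[line.center_id] += line.amount
    for line in impute_staff_costs(ledger.staff, market_table):
        recurrent[line.center_id] += line.amount
    return {
        cid: (recurrent[cid], float(depreciation.get(cid, 0.0)))
        for cid in recurrent
    }


def direct_pharma_costs(ledger: HospitalLedger) -> dict[str, float]:
    """Per-center direct pharmaceutical expenditure (a component of recurrent)."""
    pharma = {c.center_id: 0.0 for c in ledger.centers}
    for line in ledger.expenditures:
        if line.item_category == "pharmaceuticals":
            pharma[line.center_id] += line.amount
    return pharma
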