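"""Bottom-up estimation of the financing size of a hospital network.

The chain: project national admissions to the target year with an ordinary
least-squares linear trend (pandemic shock years excluded), split ("ventilate")
the projected total over activity types using the frequency profile observed
in the hospital sample, multiply each activity's admission count by its cost
per admission, add ancillary laboratory (B units) and radiology (Z units)
consumption per inpatient, and sum levels plus the outpatient line into the
grand total.

Money is handled in exact decimal arithmetic: level totals are exact sums of
their components, invariant to summation order, and quantized to two decimals
only at report time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "AdmissionsSeries",
    "FrequencyProfile",
    "PerAdmissionCost",
    "AncillaryConsumption",
    "FinancingEstimate",
    "project_admissions",
    "ventilate_admissions",
    "estimate_level_financing",
    "estimate_outpatient_financing",
    "total_financing",
]

CENT = Decimal("0.01")


def _dec(x) -> Decimal:
    return x if isinstance(x, Decimal) else Decimal(str(x))


@dataclass(frozen=True)
class AdmissionsSeries:
    """Yearly national admissions for one care level."""

    level: str
    observations: tuple[tuple[int, float], ...]  # (year, admissions)

    def __post_init__(self) -> None:
        years = [y for y, _ in self.observations]
        if len(set(years)) != len(years):
            raise ValueError("duplicate years in admissions series")
        if any(a < 0 for _, a in self.observations):
            raise ValueError("admissions counts must be >= 0")


@dataclass(frozen=True)
class FrequencyProfile:
    """Share of total admissions per activity type for one care level."""

    level: str
    shares: Mapping[str, float]

    def __post_init__(self) -> None:
        total = sum(float(s) for s in self.shares.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(
                f"frequency shares must sum to 1 (got {total!r}) for level "
                f"{self.level}"
            )
        if any(float(s) < 0 for s in self.shares.values()):
            raise ValueError("frequency shares must be >= 0")


@dataclass(frozen=True)
class PerAdmissionCost:
    level: str
    activity_code: str
    cost_per_admission: Decimal


@dataclass(frozen=True)
class AncillaryConsumption:
    """Average ancillary units consumed per inpatient, and their unit cost."""

    activity_code: str  # laboratory (unit B) or radiology (unit Z)
    unit_cost: Decimal
    units_per_inpatient: float


@dataclass(frozen=True)
class FinancingEstimate:
    """Per-activity and total financing requirement of one care level."""

    level: str
    activity_totals: Mapping[str, Decimal]
    ancillary_totals: Mapping[str, Decimal] = field(default_factory=dict)
    admission_counts: Mapping[str, int] = field(default_factory=dict)

    @property
    def level_total(self) -> Decimal:
        return sum(self.activity_totals.values(), Decimal(0)) + sum(
            self.ancillary_totals.values(), Decimal(0)
        )

    def quantized(self) -> Decimal:
        return self.level_total.quantize(CENT)


def project_admissions(
    series: AdmissionsSeries,
    target_year: int,
    excluded_years: Iterable[int] = (2020, 2021),
) -> int:
    """OLS linear-trend projection of admissions, shock years excluded.

    Years in ``excluded_years`` (by default the two pandemic years, when
    hospital use collapsed) are dropped before fitting; at least three
    observations must remain. The prediction is rounded to the nearest
    integer and floored at zero.
    """
    excluded = set(excluded_years)
    pts = [(y, a) for y, a in series.observations if y not in excluded]
    if len(pts) < 3:
        raise ValueError(
            f"need >= 3 usable observations to fit a trend, have {len(pts)}"
        )
    years = np.array([y for y, _ in pts], dtype=float)
    adm = np.array([a for _, a in pts], dtype=float)
    # center years for numerical stability of the normal equations
    slope, intercept = np.polyfit(years - years.mean(), adm, 1)
    pred = intercept + slope * (target_year - years.mean())
    return max(int(np.floor(pred + 0.5)), 0)


def ventilate_admissions(
    total: int, profile: FrequencyProfile
) -> dict[str, int]:
    """Largest-remainder apportionment of ``total`` admissions by shares.

    Each activity gets the floor of its exact quota; the leftover admissions
    go one-by-one to the largest fractional remainders (ties broken by
    profile order), so the counts always sum exactly to ``total``.
    """
    codes = list(profile.shares)
    quotas = {c: float(profile.shares[c]) * total for c in codes}
    counts = {c: int(np.floor(quotas[c])) for c in codes}
    leftover = total - sum(counts.values())
    remainders = sorted(
        codes, key=lambda c: (-(quotas[c] - counts[c]), codes.index(c))
    )
    for c in remainders[:leftover]:
        counts[c] += 1
    assert sum(counts.values()) == total
    return counts


def estimate_level_financing(
    level: str,
    total_admissions: int,
    profile: FrequencyProfile,
    costs: Mapping[str, Decimal | float],
    ancillary: Iterable[AncillaryConsumption] = (),
    admission_counts: Mapping[str, int] | None = None,
    row_totals: Mapping[str, Decimal] | None = None,
) -> FinancingEstimate:
    """Financing requirement of one care level.

    Per-activity total = cost per admission x ventilated admission count;
    each ancillary total = units consumed per inpatient x unit cost x total
    admissions; the level total is their exact decimal sum.

    ``admission_counts`` overrides the largest-remainder ventilation with
    externally given counts (e.g. a published table's printed counts).
    ``row_totals`` switches to reproduction mode: the given per-row totals
    (as printed in a published table, where unit costs were rounded after the
    row totals were computed) are taken as-is and only the column sum is
    recomputed.
    """
    if admission_counts is None:
        counts = ventilate_admissions(total_admissions, profile)
    else:
        counts = dict(admission_counts)
    missing = [c for c in counts if c not in costs and
               (row_totals is None or c not in row_totals)]
    if missing:
        raise KeyError(
            f"no per-admission cost for activity {missing[0]!r} at level {level}"
        )

    activity_totals: dict[str, Decimal] = {}
    for code, n in counts.items():
        if row_totals is not None and code in row_totals:
            activity_totals[code] = _dec(row_totals[code])
        else:
            activity_totals[code] = _dec(costs[code]) * n

    ancillary_totals: dict[str, Decimal] = {}
    for a in ancillary:
        if row_totals is not None and a.activity_code in row_totals:
            ancillary_totals[a.activity_code] = _dec(row_totals[a.activity_code])
        else:
            ancillary_totals[a.activity_code] = (
                _dec(a.unit_cost) * _dec(a.units_per_inpatient) * total_admissions
            )
    return FinancingEstimate(level, activity_totals, ancillary_totals, counts)


def estimate_outpatient_financing(
    aggregate_unit_cost: Decimal | float, total_consultations: int
) -> Decimal:
    """All-levels outpatient requirement: unit cost x consultation count."""
    if _dec(aggregate_unit_cost) < 0 or total_consultations < 0:
        raise ValueError("outpatient inputs must be >= 0")
    return _dec(aggregate_unit_cost) * total_consultations


def total_financing(
    subtotals: Mapping[str, Decimal], outpatient: Decimal
) -> Decimal:
    """Grand total over the three care levels plus the outpatient line."""
    missing = [l for l in ("provincial", "regional", "teaching") if l not in subtotals]
    if missing:
        raise KeyError(f"missing level subtotal(s): {missing}")
    return sum((_dec(v) for v in subtotals.values()), Decimal(0)) + _dec(outpatient)


# ---------------------------------------------------------------------------
# Published-table reproduction helpers


def published_level_estimate(level: str) -> FinancingEstimate:
    """Rebuild one care level's financing table from the packaged inputs.

    Uses the printed per-row totals (reproduction mode) because the published
    rows were computed from unrounded unit costs; the level total is then the
    exact decimal column sum.
    """
    from . import reference

    act = reference.financing_activity_rows(level)
    anc = reference.financing_ancillary_rows(level)
    meta = reference.financing_levels()
    total = int(meta.loc[meta.level == level, "total_inpatients"].iloc[0])
    shares = {
        r.activity_code: float(r.frequency_pct) / 100.0 for r in act.itertuples()
    }
    # published provincial/regional tables omit oncology; renormalize for the
    # engine's profile invariant while keeping the printed counts authoritative
    share_sum = sum(shares.values())
    profile = FrequencyProfile(level, {c: s / share_sum for c, s in shares.items()})
    return estimate_level_financing(
        level,
        total,
        profile,
        costs={r.activity_code: r.cost_per_admission for r in act.itertuples()},
        ancillary=[
            AncillaryConsumption(r.activity_code, r.unit_cost, r.units_per_inpatient)
            for r in anc.itertuples()
        ],
        admission_counts={r.activity_code: r.inpatient_count for r in act.itertuples()},
        row_totals={
            **{r.activity_code: r.printed_total for r in act.itertuples()},
            **{r.activity_code: r.printed_total for r in anc.itertuples()},
        },
    )


def published_grand_total() -> Decimal:
    """Grand total from the packaged printed level subtotals + outpatient line."""
    from . import reference

    meta = reference.financing_levels()
    subtotals = {
        r.level: r.printed_level_total for r in meta.itertuples()
    }
    outpatient = reference.financing_outpatient()["printed_total"]
    return total_financing(subtotals, outpatient)
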