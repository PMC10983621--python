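"""Step-down ("cascading, without iteration") allocation of overhead and
support costs onto final cost centers.

Centers are processed in a fixed cascade order — overhead first, then support
services, then final centers. Each non-final center's accumulated balance
(its direct cost plus everything received from earlier centers) is distributed
over strictly *later* centers in proportion to its allocation key, then zeroed.
Nothing ever flows back to an already-processed center, so the flow system is
triangular and the grand total is conserved exactly.

Costs are cascaded as parallel components (recurrent, capital, and the
pharmaceutical sub-component of recurrent) in a single pass, so the
with-depreciation and without-depreciation totals and the pharmaceutical
share all emerge from one allocation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .ledger import HospitalLedger

__all__ = [
    "COMPONENTS",
    "GENERAL_UNIT_VARIABLES",
    "AllocationMatrix",
    "CascadeResult",
    "UndistributableCenterError",
    "build_allocation_matrix",
    "default_cascade_order",
    "stepdown_allocate",
    "oracle_solve",
]

#: Parallel cost components carried through the cascade.
COMPONENTS = ("recurrent", "capital", "pharma")

#: Nationally validated allocation variables per general (overhead/support)
#: unit, keyed by the role slug stored in a center's level-1 code. Listed in
#: the canonical sequence also used for the default cascade order.
GENERAL_UNIT_VARIABLES: dict[str, str] = {
    "directorate": "EFT",
    "medical_services_admin": "EFT_medical",
    "nursing_services_admin": "EFT_nurse",
    "reception": "n_patients",
    "financial_services": "total_expenditure",
    "accounting": "total_expenditure",
    "billing": "n_patients",
    "supply_stores": "received_store_amount",
    "statistics": "n_patients",
    "human_resources": "EFT",
    "space_maintenance": "m2",
    "cleaning": "m2",
    "informatics": "n_computers",
    "laundry": "laundry_kg",
    "catering": "n_meals",
    "equipment_maintenance": "n_maintenance_interventions",
    "gardening": "m2",
    "pharmacy_store": "n_pharmacy_items",
    "electricity": "m2",
    "water": "n_patients_plus_HR",
}


class UndistributableCenterError(ValueError):
    """A source center holds cost but its eligible key values sum to zero."""


@dataclass(frozen=True)
class AllocationMatrix:
    """Per-source distribution proportions over strictly-later centers."""

    order: tuple[str, ...]  # every center, overhead/support before finals
    sources: tuple[str, ...]  # the non-final centers, in cascade order
    proportions: Mapping[str, Mapping[str, float]]  # source -> target -> share

    def __post_init__(self) -> None:
        pos = {cid: i for i, cid in enumerate(self.order)}
        for src, row in self.proportions.items():
            if not row:
                continue
            total = sum(row.values())
            if abs(total - 1.0) > 1e-12:
                raise ValueError(
                    f"source {src}: proportions sum to {total!r}, not 1"
                )
            for tgt, p in row.items():
                if p < 0:
                    raise ValueError(f"source {src}: negative proportion to {tgt}")
                if pos[tgt] <= pos[src]:
                    raise ValueError(
                        f"source {src}: backflow to {tgt} (not later in the cascade)"
                    )


@dataclass
class CascadeResult:
    """Outcome of one cascade pass.

    ``final_costs`` maps each final center to its full-cost component vector
    (recurrent, capital, pharma); ``inflows`` is the audit trail of
    source -> target flows; ``residuals`` records each processed source's
    post-distribution balance (always zero by construction).
    """

    order: tuple[str, ...]
    components: tuple[str, ...]
    final_costs: dict[str, np.ndarray]
    inflows: dict[str, dict[str, np.ndarray]]
    residuals: dict[str, float]

    def full_cost(self, center_id: str, with_depreciation: bool = True) -> float:
        v = self.final_costs[center_id]
        rec, cap = v[0], v[1]
        return float(rec + cap) if with_depreciation else float(rec)

    def pharma_cost(self, center_id: str) -> float:
        return float(self.final_costs[center_id][2])

    @property
    def total_full_cost(self) -> float:
        return float(sum(v[0] + v[1] for v in self.final_costs.values()))


def default_cascade_order(
    ledger: HospitalLedger, direct: Mapping[str, tuple] | None = None
) -> list[str]:
    """Canonical cascade order for a ledger.

    Overhead centers follow the canonical general-unit sequence (directorate
    first, pharmacy logistics last; unrecognized roles keep ledger order after
    the recognized ones), support centers come next in descending direct
    recurrent cost, and final centers close the cascade. Step-down without
    iteration is order-dependent, so the order used is recorded in the run
    manifest.
    """
    roles = list(GENERAL_UNIT_VARIABLES)

    def overhead_rank(c) -> tuple:
        role = c.code_l1
        return (0, roles.index(role)) if role in roles else (1, 0)

    overhead = sorted(ledger.centers_by_category("overhead"), key=overhead_rank)
    support = ledger.centers_by_category("support")
    if direct:
        support = sorted(
            support, key=lambda c: -float(direct[c.center_id][0])
        )
    finals = ledger.centers_by_category("final")
    return [c.center_id for c in overhead + support + finals]


def build_allocation_matrix(
    ledger: HospitalLedger,
    order: Sequence[str],
    direct: Mapping[str, tuple] | None = None,
    uniform_fallback: bool = False,
) -> AllocationMatrix:
    """Turn key measurements into cascade proportions.

    For each non-final source, proportions are its key values over the
    eligible targets (strictly later in ``order``), renormalized after
    dropping earlier-or-self targets. Sources whose general-unit role
    prescribes the ``total_expenditure`` variable and that carry no explicit
    key rows fall back to the targets' direct recurrent costs (computed
    *before* allocation — the cascade is not iterated). A source with
    positive direct cost but zero eligible key mass is an error, unless
    ``uniform_fallback`` spreads it uniformly over later final centers.
    """
    order = list(order)
    pos = {cid: i for i, cid in enumerate(order)}
    center_ids = {c.center_id for c in ledger.centers}
    if set(order) != center_ids or len(order) != len(center_ids):
        raise ValueError("cascade order must contain every center exactly once")
    categories = {c.center_id: c.category for c in ledger.centers}
    first_final = min(
        (pos[cid] for cid, cat in categories.items() if cat == "final"),
        default=len(order),
    )
    for cid, cat in categories.items():
        if cat != "final" and pos[cid] >= first_final:
            raise ValueError(
                f"{cat} center {cid} ordered after a final center"
            )

    keys_by_source: dict[str, list] = {}
    for k in ledger.keys:
        keys_by_source.setdefault(k.source_center_id, []).append(k)

    sources = tuple(cid for cid in order if categories[cid] != "final")
    proportions: dict[str, dict[str, float]] = {}
    for src in sources:
        rows = keys_by_source.get(src, [])
        center = ledger.center(src)
        role_variable = GENERAL_UNIT_VARIABLES.get(center.code_l1)
        if rows:
            variables = {k.variable for k in rows}
            if len(variables) > 1:
                raise ValueError(
                    f"source {src}: mixed key variables {sorted(variables)}"
                )
            variable = variables.pop()
            if role_variable is not None and variable != role_variable:
                raise ValueError(
                    f"source {src} ({center.code_l1}): key variable {variable!r} "
                    f"contradicts the prescribed {role_variable!r}"
                )
            raw = {
                k.target_center_id: k.key_value
                for k in rows
                if pos[k.target_center_id] > pos[src]
            }
        elif role_variable == "total_expenditure" and direct is not None:
            raw = {
                cid: float(direct[cid][0])
                for cid in order
                if pos[cid] > pos[src]
            }
        else:
            raw = {}

        total = sum(raw.values())
        if total > 0:
            proportions[src] = {t: v / total for t, v in raw.items() if v > 0}
        else:
            src_cost = float(direct[src][0]) + float(direct[src][1]) if direct else None
            if src_cost is None or src_cost > 0:
                if uniform_fallback:
                    later_finals = [
                        cid
                        for cid in order
                        if pos[cid] > pos[src] and categories[cid] == "final"
                    ]
                    proportions[src] = {
                        t: 1.0 / len(later_finals) for t in later_finals
                    }
                else:
                    raise UndistributableCenterError(
                        f"center {src} has cost to distribute but no positive "
                        f"eligible key values (set uniform_fallback to spread "
                        f"it over final centers)"
                    )
            else:
                proportions[src] = {}  # zero cost, nothing to distribute
    return AllocationMatrix(tuple(order), sources, proportions)


def _as_vector(value, k: int) -> np.ndarray:
    v = np.atleast_1d(np.asarray(value, dtype=float))
    out = np.zeros(k)
    out[: v.size] = v
    return out


def stepdown_allocate(
    direct: Mapping[str, tuple],
    matrix: AllocationMatrix,
    order: Sequence[str] | None = None,
    components: Sequence[str] = COMPONENTS,
) -> CascadeResult:
    """Run the sequential cascade.

    ``direct`` maps every center to its direct-cost component tuple
    (recurrent[, capital[, pharma]]); shorter tuples are zero-padded. All
    components are distributed by the same proportions in one pass. The grand
    total over final centers equals the sum of all direct costs (checked to
    1e-9 relative).
    """
    order = tuple(order) if order is not None else matrix.order
    if set(order) != set(matrix.order):
        raise ValueError("order and allocation matrix cover different centers")
    pos = {cid: i for i, cid in enumerate(order)}
    k = len(components)
    balances = {cid: _as_vector(direct.get(cid, 0.0), k) for cid in order}
    if any(np.any(b < 0) for b in balances.values()):
        raise ValueError("direct costs must be nonnegative")
    grand_direct = float(sum(b.sum() for b in balances.values()))

    inflows: dict[str, dict[str, np.ndarray]] = {cid: {} for cid in order}
    residuals: dict[str, float] = {}
    for src in matrix.sources:
        bal = balances[src]
        for tgt, p in matrix.proportions.get(src, {}).items():
            if pos[tgt] <= pos[src]:
                raise ValueError(f"cascade ordering violation: {src} -> {tgt}")
            flow = bal * p
            balances[tgt] = balances[tgt] + flow
            inflows[tgt][src] = flow
        if matrix.proportions.get(src) or not bal.any():
            balances[src] = np.zeros(k)
        residuals[src] = float(balances[src].sum())

    finals = [cid for cid in order if cid not in set(matrix.sources)]
    final_costs = {cid: balances[cid] for cid in finals}
    grand_final = float(sum(v.sum() for v in final_costs.values()))
    scale = max(abs(grand_direct), 1.0)
    if abs(grand_final - grand_direct) > 1e-9 * scale:
        raise AssertionError(
            f"cascade lost cost: finals {grand_final!r} vs direct {grand_direct!r}"
        )
    return CascadeResult(tuple(order), tuple(components), final_costs, inflows, residuals)


def oracle_solve(
    direct: Mapping[str, tuple],
    matrix: AllocationMatrix,
    order: Sequence[str] | None = None,
    components: Sequence[str] = COMPONENTS,
) -> dict[str, np.ndarray]:
    """Final-center full costs by dense triangular solve (verification path).

    The cascade is the linear system ``b = d + Aᵀ b`` with A strictly upper
    triangular in cascade order; solving it directly must agree with the
    sequential pass to 1e-9 relative. Intended for instances of at most ~50
    centers.
    """
    order = tuple(order) if order is not None else matrix.order
    n, k = len(order), len(components)
    pos = {cid: i for i, cid in enumerate(order)}
    A = np.zeros((n, n))
    for src, row in matrix.proportions.items():
        for tgt, p in row.items():
            A[pos[src], pos[tgt]] = p
    d = np.zeros((n, k))
    for cid, value in direct.items():
        d[pos[cid]] = _as_vector(value, k)
    b = np.linalg.solve(np.eye(n) - A.T, d)
    sources = set(matrix.sources)
    return {cid: b[pos[cid]] for cid in order if cid not in sources}
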