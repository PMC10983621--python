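"""Pipeline orchestration: validate -> depreciate -> allocate -> unit costs
-> aggregate -> project -> estimate -> report.

Each stage is a pure function over the previous stage's outputs; a run writes
its artifacts (CSV/JSON) plus a manifest (config hash, seed, cascade orders)
into a run directory, so any output is reproducible from the manifest alone.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from decimal import Decimal
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import __version__
from .config import Config
from .depreciation import depreciate_inventory
from .financing import (
    AdmissionsSeries,
    published_grand_total,
    published_level_estimate,
    estimate_outpatient_financing,
    project_admissions,
)
from .ledger import HospitalLedger, assemble_direct_costs, load_ledger
from .reference import financing_outpatient
from .stepdown import (
    CascadeResult,
    build_allocation_matrix,
    default_cascade_order,
    stepdown_allocate,
)
from .unit_costs import (
    UnitCostRecord,
    aggregate_by_code,
    compute_unit_costs,
    dispersion_report,
    unit_costs_frame,
)

__all__ = ["HospitalRun", "cost_hospital", "run_pipeline", "report"]


@dataclass
class HospitalRun:
    """All per-hospital artifacts of one costing pass."""

    ledger: HospitalLedger
    direct: Mapping[str, tuple[float, float, float]]
    order: list[str]
    cascade: CascadeResult
    unit_costs: list[UnitCostRecord]


def cost_hospital(ledger: HospitalLedger, config: Config) -> HospitalRun:
    """Run the costing stages for one hospital ledger."""
    policy = config.depreciation.policy()
    eac = depreciate_inventory(ledger.assets, policy)
    rec_cap = assemble_direct_costs(ledger, eac, config.market_salaries)
    from .ledger import direct_pharma_costs

    pharma = direct_pharma_costs(ledger)
    direct = {
        cid: (rec, cap, pharma[cid]) for cid, (rec, cap) in rec_cap.items()
    }
    if config.cascade.order == "auto":
        order = default_cascade_order(ledger, direct)
    else:
        order = list(config.cascade.order)
    matrix = build_allocation_matrix(
        ledger, order, direct, uniform_fallback=config.cascade.uniform_fallback
    )
    cascade = stepdown_allocate(direct, matrix, order)
    records = compute_unit_costs(cascade, ledger)
    return HospitalRun(ledger, direct, order, cascade, records)


def _allocation_trace(run: HospitalRun) -> pd.DataFrame:
    rows = []
    for target, flows in run.cascade.inflows.items():
        for source, vec in flows.items():
            for comp, value in zip(run.cascade.components, vec):
                rows.append(
                    {
                        "hospital_id": run.ledger.hospital_id,
                        "source": source,
                        "target": target,
                        "component": comp,
                        "amount": float(value),
                    }
                )
    return pd.DataFrame(rows, columns=["hospital_id", "source", "target",
                                       "component", "amount"])


def run_pipeline(
    config: Config,
    input_dir: str | Path,
    out_dir: str | Path,
) -> Path:
    """Cost every hospital ledger under ``input_dir`` and write all outputs.

    ``input_dir`` holds one subdirectory per hospital (the six-file CSV set).
    If an ``admissions.csv`` (level,year,admissions) is present, the national
    projection uses it; otherwise the financing report reproduces the
    packaged published tables.
    """
    input_dir, out_dir = Path(input_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    hospital_dirs = sorted(
        d for d in input_dir.iterdir() if (d / "hospital.csv").exists()
    )
    if not hospital_dirs:
        raise FileNotFoundError(f"no hospital ledger directories under {input_dir}")

    runs: list[HospitalRun] = []
    for hdir in hospital_dirs:
        ledger = load_ledger(
            hdir, exchange_rate=config.exchange_rate,
            reporting_currency=config.currency,
        )
        runs.append(cost_hospital(ledger, config))

    records = [r for run in runs for r in run.unit_costs]
    unit_costs_frame(records).to_csv(out_dir / "unit_costs.csv", index=False)
    pd.concat([_allocation_trace(r) for r in runs], ignore_index=True).to_csv(
        out_dir / "allocation_trace.csv", index=False
    )

    levels = sorted({run.ledger.level for run in runs})
    aggregates = [
        rec
        for level in levels
        for rec in aggregate_by_code(records, level, config.aggregation_weighted)
    ]
    unit_costs_frame(aggregates).to_csv(
        out_dir / "aggregate_unit_costs.csv", index=False
    )
    dispersion_report(records).to_csv(out_dir / "dispersion_report.csv", index=False)

    financing = _financing_stage(config, input_dir)
    (out_dir / "financing_report.json").write_text(
        json.dumps(financing, indent=2, sort_keys=True)
    )

    manifest = {
        "package_version": __version__,
        "config": config.model_dump(),
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "hospitals": [run.ledger.hospital_id for run in runs],
        "cascade_orders": {run.ledger.hospital_id: run.order for run in runs},
    }
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True)
    )
    return out_dir


def _financing_stage(config: Config, input_dir: Path) -> dict:
    """National financing estimate: projected if admissions data is given,
    otherwise the packaged published-tables reproduction."""
    admissions_path = input_dir / "admissions.csv"
    projected: dict[str, int] = {}
    if admissions_path.exists():
        adm = pd.read_csv(admissions_path)
        for level, grp in adm.groupby("level"):
            series = AdmissionsSeries(
                str(level),
                tuple(
                    (int(r.year), float(r.admissions)) for r in grp.itertuples()
                ),
            )
            projected[str(level)] = project_admissions(
                series, config.target_year, config.excluded_years
            )

    from .reference import financing_levels

    estimates = {lvl: published_level_estimate(lvl)
                 for lvl in ("teaching", "regional", "provincial")}
    meta = financing_levels().set_index("level")
    out_row = financing_outpatient()
    outpatient_product = estimate_outpatient_financing(
        out_row["unit_cost"], int(out_row["total_consultations"])
    )
    report = {
        "target_year": config.target_year,
        "projected_admissions": projected,
        "levels": {
            lvl: {
                "activity_totals": {
                    k: str(v.quantize(Decimal("0.01")))
                    for k, v in est.activity_totals.items()
                },
                "ancillary_totals": {
                    k: str(v.quantize(Decimal("0.01")))
                    for k, v in est.ancillary_totals.items()
                },
                "level_total": str(est.quantized()),
                "level_total_published": str(meta.loc[lvl, "printed_level_total"]),
            }
            for lvl, est in estimates.items()
        },
        "outpatient_total_product": str(
            outpatient_product.quantize(Decimal("0.01"))
        ),
        "outpatient_total_published": str(out_row["printed_total"]),
        "grand_total": str(published_grand_total().quantize(Decimal("0.01"))),
    }
    return report


def report(run_dir: str | Path) -> str:
    """Render a completed run as plain-text tables; also written to report.txt."""
    run_dir = Path(run_dir)
    required = [
        "unit_costs.csv",
        "aggregate_unit_costs.csv",
        "dispersion_report.csv",
        "financing_report.json",
        "manifest.json",
    ]
    missing = [f for f in required if not (run_dir / f).exists()]
    if missing:
        raise FileNotFoundError(f"incomplete run {run_dir}: missing {missing}")

    parts = []
    agg = pd.read_csv(run_dir / "aggregate_unit_costs.csv")
    parts.append("== Unit costs by activity center (level aggregates) ==")
    if agg.empty:
        parts.append("(no unit-cost records)")
    else:
        cols = ["level", "activity_code", "unit", "volume",
                "unit_cost_no_dep", "unit_cost_with_dep", "pharma_share"]
        parts.append(agg[cols].round(2).to_string(index=False))
    disp = pd.read_csv(run_dir / "dispersion_report.csv")
    parts.append("\n== Cross-hospital unit-cost dispersion (with depreciation) ==")
    parts.append("(no records)" if disp.empty else disp.round(2).to_string(index=False))
    fin = json.loads((run_dir / "financing_report.json").read_text())
    parts.append("\n== Financing size by care level (USD) ==")
    for lvl, block in fin["levels"].items():
        parts.append(
            f"{lvl:>12}: {block['level_total']} "
            f"(published {block['level_total_published']})"
        )
    parts.append(f"  outpatient: {fin['outpatient_total_published']}")
    parts.append(f" grand total: {fin['grand_total']}")
    text = "\n".join(parts) + "\n"
    (run_dir / "report.txt").write_text(text)
    return text
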