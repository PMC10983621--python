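"""Unit-cost computation, volume-weighted aggregation, pharma shares,
dispersion, and the packaged national reference constants."""

from decimal import Decimal

import numpy as np
import pytest

from hospicost.reference import (
    reference_pharma_shares,
    reference_unit_cost,
)
from hospicost.stepdown import CascadeResult
from hospicost.unit_costs import (
    UnitCostRecord,
    aggregate_by_code,
    compute_unit_costs,
    dispersion_report,
    pharmaceutical_share,
)


def make_result(final_costs):
    return CascadeResult(
        order=tuple(final_costs),
        components=("recurrent", "capital", "pharma"),
        final_costs={cid: np.asarray(v, dtype=float)
                     for cid, v in final_costs.items()},
        inflows={},
        residuals={},
    )


def make_record(hospital, code, cost_no, cost_with, volume, level="provincial"):
    return UnitCostRecord(hospital, level, code, "hospitalization_day",
                          volume, cost_no, cost_with)


class TestComputeUnitCosts:
    def test_with_and_without_depreciation(self, tiny_ledger):
        # full cost 230 of which capital 30, over 10 days
        result = make_result({"F1": (200.0, 30.0, 0.0), "F2": (40.0, 0.0, 0.0)})
        records = {r.activity_code: r for r in compute_unit_costs(result, tiny_ledger)}
        surgery = records["surgery_hospitalization"]
        assert surgery.unit_cost_no_dep == pytest.approx(20.0)
        assert surgery.unit_cost_with_dep == pytest.approx(23.0)
        # component additivity: the gap is exactly capital / volume
        assert (surgery.unit_cost_with_dep - surgery.unit_cost_no_dep
                ) == pytest.approx(30.0 / 10.0)

    def test_zero_volume_flagged_not_divided(self, tiny_ledger):
        from dataclasses import replace
        from hospicost.ledger import ActivityRecord

        ledger = replace(
            tiny_ledger,
            activities=(
                ActivityRecord("F1", "hospitalization_day", 0.0),
                ActivityRecord("F2", "hospitalization_day", 20.0),
            ),
        )
        result = make_result({"F1": (500.0, 0.0, 0.0), "F2": (40.0, 0.0, 0.0)})
        records = {r.activity_code: r for r in compute_unit_costs(result, ledger)}
        flagged = records["surgery_hospitalization"]
        assert flagged.flagged and np.isnan(flagged.unit_cost_with_dep)
        assert aggregate_by_code(list(records.values()), "provincial") == [
            a for a in aggregate_by_code(list(records.values()), "provincial")
            if a.activity_code == "medicine_hospitalization"
        ]

    def test_same_code_centers_merge_within_hospital(self, tiny_ledger):
        from dataclasses import replace
        from hospicost.ledger import ActivityRecord, CostCenter

        # second surgery ward: costs {600, 400}, days {10, 10} -> 50/day
        ledger = replace(
            tiny_ledger,
            centers=tiny_ledger.centers + (
                CostCenter("F3", "h1", "surgery 2", "final", "U2",
                           "surgery_hospitalization", "hospitalization_day"),
            ),
            activities=tiny_ledger.activities + (
                ActivityRecord("F3", "hospitalization_day", 10.0),
            ),
        )
        result = make_result({"F1": (600.0, 0.0, 0.0), "F3": (400.0, 0.0, 0.0),
                              "F2": (40.0, 0.0, 0.0)})
        records = {r.activity_code: r for r in compute_unit_costs(result, ledger)}
        assert records["surgery_hospitalization"].unit_cost_no_dep == pytest.approx(
            50.0
        )


class TestAggregation:
    def test_volume_weighted_not_mean_of_ratios(self):
        # (100, 10) and (600, 30): pooled 700/40 = 17.5; mean of ratios = 15
        records = [
            make_record("h1", "icu", 100.0, 100.0, 10.0),
            make_record("h2", "icu", 600.0, 600.0, 30.0),
        ]
        agg = aggregate_by_code(records, "provincial")[0]
        assert agg.unit_cost_with_dep == pytest.approx(17.5)
        unweighted = aggregate_by_code(records, "provincial", weighted=False)[0]
        assert unweighted.unit_cost_with_dep == pytest.approx(15.0)

    def test_equal_volumes_match_either_convention(self):
        records = [
            make_record("h1", "icu", 100.0, 100.0, 10.0),
            make_record("h2", "icu", 300.0, 300.0, 10.0),
        ]
        assert aggregate_by_code(records, "provincial")[0].unit_cost_with_dep == (
            pytest.approx(20.0)
        )

    def test_single_hospital_is_identity(self):
        records = [make_record("h1", "icu", 120.0, 150.0, 10.0)]
        agg = aggregate_by_code(records, "provincial")[0]
        assert agg.unit_cost_no_dep == pytest.approx(12.0)
        assert agg.unit_cost_with_dep == pytest.approx(15.0)
        assert aggregate_by_code([], "provincial") == []

    @pytest.mark.parametrize("seed", [0, 1])
    def test_weighted_aggregate_matches_ratio_oracle(self, seed):
        rng = np.random.default_rng(seed)
        records = [
            make_record(f"h{i}", "icu", float(c := rng.uniform(50, 500)),
                        c * 1.2, float(rng.uniform(5, 50)))
            for i in range(8)
        ]
        agg = aggregate_by_code(records, "provincial")[0]
        oracle = sum(r.full_cost_with_dep for r in records) / sum(
            r.volume for r in records
        )
        assert agg.unit_cost_with_dep == pytest.approx(oracle, rel=1e-12)


class TestPharmaShare:
    def test_all_pharma_center_has_share_one(self, tiny_ledger):
        result = make_result({"F1": (100.0, 0.0, 100.0), "F2": (40.0, 0.0, 0.0)})
        shares = {s.activity_code: s.share
                  for s in pharmaceutical_share(result, tiny_ledger)}
        assert shares["surgery_hospitalization"] == pytest.approx(1.0)
        assert shares["medicine_hospitalization"] == 0.0

    def test_ratio_of_components(self, tiny_ledger):
        result = make_result({"F1": (69.0, 31.0, 31.0), "F2": (40.0, 0.0, 0.0)})
        shares = {s.activity_code: s.share
                  for s in pharmaceutical_share(result, tiny_ledger)}
        assert shares["surgery_hospitalization"] == pytest.approx(0.31)

    def test_pharma_conserved_through_cascade(self, tiny_ledger):
        from hospicost.stepdown import build_allocation_matrix, stepdown_allocate

        direct = {"O1": (100.0, 0.0, 0.0), "S1": (60.0, 0.0, 60.0),
                  "F1": (80.0, 0.0, 50.0), "F2": (40.0, 0.0, 0.0)}
        order = ["O1", "S1", "F1", "F2"]
        matrix = build_allocation_matrix(tiny_ledger, order, direct)
        result = stepdown_allocate(direct, matrix, order)
        total_pharma = sum(result.pharma_cost(c) for c in ("F1", "F2"))
        assert total_pharma == pytest.approx(110.0, rel=1e-12)


class TestDispersion:
    def test_min_max_of_provincial_surgery_spread(self):
        # the published provincial surgery inpatient-day range: 29 to 154 USD
        records = [
            make_record(f"h{i}", "surgery_hospitalization", c * 10, c * 10, 10.0)
            for i, c in enumerate((29.0, 80.0, 154.0))
        ]
        rep = dispersion_report(records)
        row = rep.iloc[0]
        assert (row["min"], row["max"]) == (29.0, 154.0)
        assert row["median"] == 80.0

    def test_single_hospital_min_equals_max(self):
        rep = dispersion_report([make_record("h1", "icu", 100.0, 120.0, 10.0)])
        assert rep.iloc[0]["min"] == rep.iloc[0]["max"] == 12.0

    def test_matches_order_statistics_oracle(self):
        rng = np.random.default_rng(1)
        costs = rng.uniform(100, 2000, size=10)
        records = [
            make_record(f"h{i}", "icu", float(c), float(c), 10.0)
            for i, c in enumerate(costs)
        ]
        rep = dispersion_report(records).iloc[0]
        unit = costs / 10.0
        assert rep["min"] == pytest.approx(unit.min())
        assert rep["max"] == pytest.approx(unit.max())
        assert rep["median"] == pytest.approx(float(np.median(unit)))


class TestReferenceConstants:
    def test_icu_teaching_unit_cost_lookup(self):
        assert reference_unit_cost("icu", "teaching") == Decimal("453.94")
        assert reference_unit_cost("icu", "teaching", with_depreciation=False) == (
            Decimal("394.83")
        )

    def test_pharma_share_lookups(self):
        shares = {
            r.activity_code: r.pharma_share
            for r in reference_pharma_shares().itertuples()
        }
        assert shares["oncology"] == Decimal("0.56")
        assert shares["psychiatry"] == Decimal("0.03")

    def test_depreciation_never_lowers_reference_unit_costs(self):
        from hospicost.reference import reference_unit_costs

        df = reference_unit_costs()
        assert (df.unit_cost_with_dep >= df.unit_cost_no_dep).all()
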