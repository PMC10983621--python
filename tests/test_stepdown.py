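"""Cascade allocation: matrix construction, conservation, oracle agreement."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hospicost.stepdown import (
    AllocationMatrix,
    UndistributableCenterError,
    build_allocation_matrix,
    default_cascade_order,
    oracle_solve,
    stepdown_allocate,
)

from conftest import random_cascade_instance


class TestMatrixConstruction:
    def test_laundry_keys_become_proportions(self, tiny_ledger):
        order = ["O1", "S1", "F1", "F2"]
        matrix = build_allocation_matrix(tiny_ledger, order)
        assert matrix.proportions["S1"] == pytest.approx({"F1": 0.75, "F2": 0.25})

    def test_earlier_targets_excluded_and_renormalized(self, tiny_ledger):
        from dataclasses import replace
        from hospicost.ledger import KeyMeasurement

        # S1's keys now also point at O1, which sits earlier in the cascade
        ledger = replace(
            tiny_ledger,
            keys=tiny_ledger.keys + (KeyMeasurement("S1", "laundry_kg", "O1", 99.0),),
        )
        matrix = build_allocation_matrix(ledger, ["O1", "S1", "F1", "F2"])
        assert matrix.proportions["S1"] == pytest.approx({"F1": 0.75, "F2": 0.25})

    def test_single_eligible_target_gets_everything(self, tiny_ledger):
        from dataclasses import replace
        from hospicost.ledger import KeyMeasurement

        ledger = replace(
            tiny_ledger,
            keys=(
                KeyMeasurement("O1", "m2", "F1", 7.0),
                KeyMeasurement("S1", "laundry_kg", "F1", 3.0),
            ),
        )
        matrix = build_allocation_matrix(ledger, ["O1", "S1", "F1", "F2"])
        assert matrix.proportions["O1"] == {"F1": 1.0}

    def test_key_variable_must_match_general_unit_role(self, tiny_ledger):
        from dataclasses import replace
        from hospicost.ledger import KeyMeasurement

        ledger = replace(
            tiny_ledger,
            keys=tuple(
                KeyMeasurement(k.source_center_id, "n_meals",
                               k.target_center_id, k.key_value)
                if k.source_center_id == "S1" else k
                for k in tiny_ledger.keys
            ),
        )
        with pytest.raises(ValueError, match="laundry_kg"):
            build_allocation_matrix(ledger, ["O1", "S1", "F1", "F2"])

    def test_undistributable_center_is_hard_error(self, tiny_ledger):
        from dataclasses import replace

        ledger = replace(tiny_ledger, keys=tiny_ledger.keys[:3])  # S1 has no keys
        direct = {"O1": (100.0, 0.0), "S1": (60.0, 0.0),
                  "F1": (80.0, 0.0), "F2": (40.0, 0.0)}
        with pytest.raises(UndistributableCenterError, match="S1"):
            build_allocation_matrix(ledger, ["O1", "S1", "F1", "F2"], direct)
        matrix = build_allocation_matrix(
            ledger, ["O1", "S1", "F1", "F2"], direct, uniform_fallback=True
        )
        assert matrix.proportions["S1"] == pytest.approx({"F1": 0.5, "F2": 0.5})

    def test_order_must_put_generals_before_finals(self, tiny_ledger):
        with pytest.raises(ValueError, match="ordered after"):
            build_allocation_matrix(tiny_ledger, ["O1", "F1", "S1", "F2"])

    def test_backflow_proportions_rejected(self):
        with pytest.raises(ValueError, match="backflow"):
            AllocationMatrix(("a", "b", "f"), ("a", "b"),
                             {"a": {"f": 1.0}, "b": {"a": 1.0}})

    def test_default_order_generals_then_finals(self, tiny_ledger):
        order = default_cascade_order(tiny_ledger)
        assert order == ["O1", "S1", "F1", "F2"]


class TestCascade:
    def test_three_center_chain(self):
        """Overhead 120 split 1/3-2/3 between support and final; support's 60
        plus its share flow on; the final holds everything: 120+60+50 = 230."""
        matrix = AllocationMatrix(
            ("O", "S", "F"), ("O", "S"),
            {"O": {"S": 1 / 3, "F": 2 / 3}, "S": {"F": 1.0}},
        )
        direct = {"O": (120.0,), "S": (60.0,), "F": (50.0,)}
        result = stepdown_allocate(direct, matrix)
        assert result.full_cost("F") == pytest.approx(230.0, rel=1e-12)
        assert all(r == 0.0 for r in result.residuals.values())

    def test_no_sources_is_identity(self):
        matrix = AllocationMatrix(("F1", "F2"), (), {})
        result = stepdown_allocate({"F1": (80.0,), "F2": (40.0,)}, matrix)
        assert result.full_cost("F1") == 80.0
        assert result.full_cost("F2") == 40.0

    def test_overhead_split_25_75(self):
        matrix = AllocationMatrix(
            ("O", "F1", "F2"), ("O",), {"O": {"F1": 0.25, "F2": 0.75}}
        )
        result = stepdown_allocate({"O": (100.0,), "F1": (0.0,), "F2": (0.0,)},
                                   matrix)
        assert result.full_cost("F1") == pytest.approx(25.0)
        assert result.full_cost("F2") == pytest.approx(75.0)

    def test_monotone_in_source_cost(self):
        matrix = AllocationMatrix(
            ("O", "F1", "F2"), ("O",), {"O": {"F1": 0.3, "F2": 0.7}}
        )
        base = {"O": (100.0,), "F1": (10.0,), "F2": (10.0,)}
        bumped = {"O": (100.0 + 5.0,), "F1": (10.0,), "F2": (10.0,)}
        t0 = stepdown_allocate(base, matrix).total_full_cost
        t1 = stepdown_allocate(bumped, matrix).total_full_cost
        assert t1 - t0 == pytest.approx(5.0, rel=1e-12)

    def test_grand_total_invariant_to_admissible_order(self, tiny_ledger):
        direct = {"O1": (100.0, 0.0, 0.0), "S1": (60.0, 0.0, 0.0),
                  "F1": (80.0, 0.0, 50.0), "F2": (40.0, 0.0, 0.0)}
        totals = []
        for order in (["O1", "S1", "F1", "F2"], ["S1", "O1", "F1", "F2"]):
            # O1->S1 key must be dropped for the second order (backflow)
            matrix = build_allocation_matrix(tiny_ledger, order, direct)
            totals.append(stepdown_allocate(direct, matrix, order).total_full_cost)
        assert totals[0] == pytest.approx(totals[1], rel=1e-12)
        assert totals[0] == pytest.approx(280.0, rel=1e-12)


class TestOracleAgreement:
    def test_three_center_chain_oracle(self):
        matrix = AllocationMatrix(
            ("O", "S", "F"), ("O", "S"),
            {"O": {"S": 1 / 3, "F": 2 / 3}, "S": {"F": 1.0}},
        )
        direct = {"O": (120.0,), "S": (60.0,), "F": (50.0,)}
        solved = oracle_solve(direct, matrix)
        assert float(solved["F"].sum()) == pytest.approx(230.0, rel=1e-12)

    def test_identity_matrix_returns_direct(self):
        matrix = AllocationMatrix(("F1", "F2"), (), {})
        solved = oracle_solve({"F1": (80.0,), "F2": (40.0,)}, matrix)
        assert float(solved["F1"][0]) == 80.0

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(deadline=None, max_examples=50)
    def test_sequential_cascade_equals_triangular_solve(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 51))
        direct, matrix = random_cascade_instance(rng, n)
        seq = stepdown_allocate(direct, matrix)
        solved = oracle_solve(direct, matrix)
        for cid, vec in seq.final_costs.items():
            np.testing.assert_allclose(vec, solved[cid], rtol=1e-9)


@given(st.integers(min_value=0, max_value=2**31 - 1))
@settings(deadline=None, max_examples=100)
def test_conservation_on_random_instances(seed):
    """Sum of final full costs equals the sum of all direct costs."""
    rng = np.random.default_rng(seed)
    direct, matrix = random_cascade_instance(rng, int(rng.integers(2, 20)))
    result = stepdown_allocate(direct, matrix)
    total_direct = sum(sum(v) for v in direct.values())
    total_final = sum(float(v.sum()) for v in result.final_costs.values())
    assert total_final == pytest.approx(total_direct, rel=1e-9)
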