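import numpy as np
import pytest

from hospicost.config import Config
from hospicost.ledger import (
    ActivityRecord,
    CostCenter,
    ExpenditureLine,
    HospitalLedger,
    KeyMeasurement,
)
from hospicost.stepdown import AllocationMatrix


@pytest.fixture
def tiny_ledger() -> HospitalLedger:
    """Minimal hospital: one overhead (cleaning), one support (laundry),
    two final centers with activity volumes."""
    h = "h1"
    centers = (
        CostCenter("O1", h, "cleaning", "overhead", code_l1="cleaning"),
        CostCenter("S1", h, "laundry", "support", code_l1="laundry"),
        CostCenter("F1", h, "surgery ward", "final", code_l1="U0",
                   code_l2="surgery_hospitalization",
                   output_unit="hospitalization_day"),
        CostCenter("F2", h, "medicine ward", "final", code_l1="U1",
                   code_l2="medicine_hospitalization",
                   output_unit="hospitalization_day"),
    )
    expenditures = (
        ExpenditureLine("O1", "personnel", 100.0),
        ExpenditureLine("S1", "other", 60.0),
        ExpenditureLine("F1", "pharmaceuticals", 50.0),
        ExpenditureLine("F1", "other", 30.0),
        ExpenditureLine("F2", "personnel", 40.0),
    )
    keys = (
        KeyMeasurement("O1", "m2", "S1", 50.0),
        KeyMeasurement("O1", "m2", "F1", 25.0),
        KeyMeasurement("O1", "m2", "F2", 25.0),
        KeyMeasurement("S1", "laundry_kg", "F1", 300.0),
        KeyMeasurement("S1", "laundry_kg", "F2", 100.0),
    )
    activities = (
        ActivityRecord("F1", "hospitalization_day", 10.0),
        ActivityRecord("F2", "hospitalization_day", 20.0),
    )
    ledger = HospitalLedger(
        hospital_id=h, level="provincial", region="r1", currency="USD",
        centers=centers, expenditures=expenditures, keys=keys,
        activities=activities,
    )
    ledger.validate()
    return ledger


@pytest.fixture
def identity_config() -> Config:
    return Config(exchange_rate=1.0)


def random_cascade_instance(rng: np.random.Generator, n_centers: int):
    """Random admissible cascade: strictly-forward proportions, >= 1 final.

    Returns (direct, matrix) usable by both the sequential cascade and the
    triangular-solve oracle.
    """
    n_final = int(rng.integers(1, max(2, n_centers // 2)))
    ids = [f"c{i}" for i in range(n_centers)]
    sources, finals = ids[: n_centers - n_final], ids[n_centers - n_final:]
    proportions = {}
    for i, src in enumerate(sources):
        later = ids[i + 1:]
        k = int(rng.integers(1, len(later) + 1))
        targets = list(rng.choice(later, size=k, replace=False))
        weights = rng.dirichlet(np.ones(len(targets)))
        proportions[src] = {t: float(w) for t, w in zip(targets, weights)}
    matrix = AllocationMatrix(tuple(ids), tuple(sources), proportions)
    direct = {cid: (float(rng.uniform(0, 1000)), float(rng.uniform(0, 200)),
                    float(rng.uniform(0, 100))) for cid in ids}
    return direct, matrix
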