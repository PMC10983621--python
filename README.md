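# hospicost

Step-down hospital costing and bottom-up financing-size estimation for
multi-level public hospital networks, built around the Moroccan public
hospital system (provincial, regional and teaching/university hospitals).

Health-financing analysts preparing universal-health-coverage reforms need
two things from hospital accounts: *comparable unit costs* (what does one
inpatient day, consultation, lab unit B, radiology unit Z or surgical unit K
actually cost, at each level of care?) and a *bottom-up estimate of the
budget envelope* the hospital network requires. This package implements the
full chain from raw per-hospital ledgers to both.

## The method

**Costing.** Each hospital is a set of cost centers: overhead
(administration), support (laundry, catering, pharmacy store, …) and final
(patient-facing) centers. Per center, direct recurrent cost is the sum of
expenditure lines plus staff salaries split across centers by full-time
fraction (volunteers imputed at the market salary of a similar position);
capital cost is the equivalent annual cost of the asset inventory,

    EAC = price / A(n, r),   A(n, r) = (1 − (1+r)^−n) / r,

with lifespans 10 y (equipment), 5 y (informatics/transport), 25 y
(buildings) and r = 5 %, no salvage. Overhead and support costs are then
*cascaded* ("step-down without iteration"): in a fixed order, each
non-final center's balance is distributed over strictly-later centers in
proportion to its allocation key (m² for cleaning, kg washed for laundry,
meals served for catering, EFT staffing for the directorate, …) and zeroed.
Final-center unit cost = full cost / activity volume, with and without the
capital component; level aggregates are volume-weighted
(Σ cost / Σ volume) per harmonized activity center.

**Financing size.** National admissions are projected to the target year by
an OLS linear trend (pandemic shock years 2020–2021 excluded), ventilated
over activity types by the sample frequency profile
(largest-remainder apportionment, counts sum exactly), multiplied by
per-admission costs, plus per-inpatient laboratory (B) and radiology (Z)
consumption, plus the outpatient-consultation line — all in exact decimal
arithmetic.

Because the real 39-hospital ledgers are not public, the package ships a
synthetic-ledger generator that *reverse-constructs* hospitals from known
target unit costs, making end-to-end recovery an exact test, and packages
the published national reference tables (unit costs per level,
pharmaceutical shares, financing tables) as constants for lookup and
reproduction.

## Worked example

```python
from hospicost import Config, SyntheticSpec, generate_hospital, cost_hospital

ledger, truth = generate_hospital(SyntheticSpec(seed=1), "provincial", 0)
run = cost_hospital(ledger, Config(exchange_rate=1.0))
surgery = next(r for r in run.unit_costs
               if r.activity_code == "surgery_hospitalization")
print(round(surgery.unit_cost_with_dep, 2),
      round(truth.finals[f"{ledger.hospital_id}-F0"]["unit_cost_with_dep"], 2))
```

prints `73.92 73.92` — the pipeline (staff imputation → depreciation →
cascade → unit costs) recovers the generator's ground-truth cost of a
provincial surgery inpatient day exactly; across all synthetic hospitals the
worst relative recovery error is ~3e-16.

The numbered drivers under `analysis/` run the full story:

```
python analysis/01_simulate_ledgers.py      # synthetic sample + ground truth
python analysis/02_cost_hospitals.py        # pipeline, dispersion, recovery check
python analysis/03_reproduce_financing.py   # national financing tables
```

`03_reproduce_financing.py` ends with

```
== provincial hospitals ==
  ...
  column sum                     199950950.91   (published level total 199950950.91)
grand total financing, all public hospitals, 2023: 1193377166.77 USD
```

i.e. the provincial column sum reproduces the published level total to the
cent, the regional one to within 0.40 USD, and the grand total
($1,193,377,166.77 for 2023) exactly. There is also a CLI
(`hospicost simulate | validate | run | report | financing`).

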