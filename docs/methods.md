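# Methods

## The costing model

A hospital ledger is an accounting graph: cost centers (overhead, support,
final), recurrent expenditure lines per center, staff assignments with FTE
splits, a capital asset inventory, allocation-key measurements, and activity
volumes for final centers. Final centers carry a two-level code whose second
level is one of 14 harmonized activity centers (surgery hospitalization,
medicine hospitalization, maternity, neonatology, pediatrics, psychiatry,
ICU, emergency, outpatient consultation, radiology, laboratory, operating
theater, hemodialysis, oncology) so unit costs are comparable across
hospitals that organize their wards differently.

**Direct costs.** Recurrent direct cost per center = booked expenditure
lines + imputed staff lines. Each staff member contributes
`salary × fte_fraction` per assigned center; volunteers and contract staff
without a booked salary are costed at the market salary of a similar
position (a mandatory lookup table in the config). A total assignment below
1 FTE is allowed with a logged warning (`W-FTE-UNASSIGNED`) — part-time
public-sector positions exist — while over-assignment (> 1 FTE) is a
validation error. Negative expenditure lines (refunds) are rejected: the
cascade's conservation property assumes nonnegative balances. Validation is
aggregated — every violation in a file set is reported at once — and no
downstream stage runs on an invalid ledger. Currency: all amounts carry the
ledger's currency tag; conversion to the reporting currency is one scalar
multiplication (`exchange_rate`, required in the config; 1.0 = identity),
and converting an already-converted ledger raises.

**Capital.** Equivalent annual cost: `EAC = quantity × price / A(n, r)`
with `A(n, r) = (1 − (1+r)^−n)/r`, the present value of an n-year unit
annuity. Defaults: r = 0.05; lifespans equipment 10 y,
informatics/transport 5 y, buildings 25 y; salvage value fixed at zero.
`A` is evaluated as `−expm1(−n·log1p(r))/r` to avoid cancellation at small
rates, and r = 0 returns the limit `A = n` (supporting zero-discount
sensitivity analyses) rather than erroring. Asset age is ignored — the
annuity is constant over the lifespan — because the inventory schema
carries no acquisition years. Capital is cascaded as a separate parallel
component, so "with depreciation" and "without depreciation" results come
from one allocation pass.

**Step-down cascade.** Non-final centers are processed in a fixed order;
each one's accumulated balance (direct + received) is distributed over
strictly-later centers in proportion to its allocation key, then zeroed.
No backflow, no iteration: the flow system is triangular. Keys are the
nationally validated variables per general unit (EFT for the directorate
and human resources, m² for cleaning/space maintenance/gardening/
electricity, kg washed for laundry, meals served for catering, items
distributed for the pharmacy store, patients + HR for the water bill, total
expenditures for financial/accounting services, …). Sources prescribing the
total-expenditure variable with no explicit key rows fall back to the
targets' direct recurrent costs computed *before* allocation, consistent
with the non-iterative design. Because the publication order of the cascade
is not part of the method's definition, and step-down without iteration is
order-dependent, the default order is: overhead centers in the canonical
general-unit sequence, support centers by descending direct cost, then
finals; the order actually used is recorded in the run manifest and is
configurable. A source holding cost with zero eligible key mass is a hard
"undistributable center" error by default; a uniform spread over later
final centers is available behind `cascade.uniform_fallback` and logged.

Two independent code paths compute the same allocation: the sequential
cascade and a dense triangular solve of `b = d + Aᵀb` (`oracle_solve`);
tests require agreement to 1e-9 relative on random instances up to 50
centers, and conservation (Σ final full costs = Σ all direct costs) holds
on every instance to 1e-9 relative.

**Unit costs and aggregation.** Unit cost = full cost / volume per final
center, merged by activity code within a hospital, then aggregated per care
level as the volume-weighted mean Σcost/Σvolume — the cost of producing one
unit at that level, which is the standard costing convention; an unweighted
mean-of-ratios mode exists for sensitivity (`aggregation_weighted: false`).
Zero-volume centers with positive cost yield flagged records (NaN unit
cost, excluded from aggregation) instead of division errors. Laboratory B,
surgical K and radiology Z outputs are the complexity-weighted virtual
units of the Moroccan nomenclature of procedures; volumes arrive
pre-converted in `activity.csv` — no nomenclature table is shipped.

**Pharmaceutical share.** Drug expenditure is tracked as a third parallel
cascade component: direct pharmaceutical lines plus drug cost received
through allocated flows (in practice, from the pharmacy store, which is
where drug expenditure sits). Cascading the component uniformly for all
sources keeps it exactly conserved (Σ pharma in finals = Σ pharma direct),
and coincides with tagging only pharmacy-store flows whenever overhead
centers hold no drug lines. The share is the pharma component over the
full with-depreciation cost.

## Financing-size estimation

Admissions are projected by OLS on (year, admissions) — the functional form
is a package choice; an exponential trend was considered and rejected as
unidentifiable on short series — with configurable excluded years
defaulting to {2020, 2021}, the pandemic years when hospital use collapsed.
The prediction is rounded to the nearest integer and floored at zero, and
at least three usable observations are required.

The projected total is split over activity types by the care level's
frequency profile using largest-remainder apportionment: floors of the
exact quotas, leftovers to the largest fractional remainders, so counts sum
exactly to the total. (No standard rounding reproduces the published
tables' printed counts — e.g. 23.19 % × 306,706 = 71,125.1 against a
printed 71,127 — so the engine's counts are self-consistent rather than
table-identical.)

Per-activity total = cost per admission × count; ancillary totals =
units per inpatient × unit cost × total admissions; level totals and the
grand total (three levels + outpatient consultations) are exact `Decimal`
sums, order-invariant, quantized to cents only at report time.

**Reproduction mode.** The packaged national tables' printed row totals
were computed from unrounded unit costs, so re-multiplying the *printed*
(rounded) unit costs by the printed counts cannot reproduce them —
products differ from printed row totals by up to ~8 % on the ancillary
rows, and the provincial/regional inpatient rows are further scaled in
ways the published inputs do not determine. `estimate_level_financing`
therefore accepts given row totals (`row_totals=`), in which case only the
column sum is recomputed. On the packaged inputs this reproduces the
provincial level total ($199,950,950.91) exactly and the regional one to
within 0.40 USD of the printed $97,992,516.80. The teaching level total
($814,273,550.81) exceeds its own printed rows' column sum by a wide
margin in the source tables; it is packaged as a given input and enters
only the grand-total sum, which reproduces $1,193,377,166.77 exactly. The
published outpatient total likewise differs from the product of its own
printed inputs by ≈ 0.0125 % (unit-cost rounding); the package reports the
product ($81,150,002.35) and ships the printed value as reference. For the
teaching inpatient rows, printed-unit-cost × printed-count does agree with
the printed row totals to ≤ 0.01 % — asserted in the test suite, maternity
row explicitly. The published radiology unit costs *decrease* from
provincial to university level; the reporting machinery is
direction-agnostic and makes no monotonicity assumption.

## Synthetic data: what it emulates, and what it does not

The generator reverse-constructs hospitals: it draws each final center's
target with-depreciation unit cost (log-normally dispersed around the
published per-level magnitudes, spread controlled by `dispersion`) and
volume, splits the implied full cost into capital (`capital_share`, default
0.15, matching the published with/without-depreciation gaps) and recurrent,
carves `overhead_share` (default 0.35, a typical overhead + support burden)
out of recurrent cost and distributes it over overhead/support centers with
Dirichlet weights, then writes allocation keys whose normalized proportions
deliver exactly the carved amounts back — every source's final-center
proportions equal each final's share of total allocated cost, which makes
the delivered amount independent of the overhead→support routing. Staff
(including a split-FTE physician and a market-imputed volunteer nurse),
expenditure categories and capital assets (priced so their EAC equals the
target capital) are fabricated to sum exactly to the targets. Ground truth
is therefore exact, and the recovery test demands agreement to 1e-9
relative (observed: ~1e-16).

Default sample shape is two hospitals per level for speed; the published
study's 10/11/18 shape is available (`FULL_SAMPLE_SHAPE`, CLI
`--full-shape`). Each hospital draws from an independent substream keyed by
(seed, level, index), so any single hospital is reproducible in isolation
and generation is byte-deterministic per seed.

Deliberate unrealism, and hence what passing tests do *not* show: real
ledgers have misclassified lines, inconsistent keys, partially missing
inventories and volumes estimated from registries; the generator's keys are
exactly consistent with the intended flows, capital sits only in final
centers, and every cross-reference resolves. The recovery test validates
the *arithmetic* of the pipeline, not robustness to dirty accounting — the
validation layer (aggregated errors, flagged zero-volume centers,
undistributable-center detection) is what addresses the latter, and it is
tested separately.

## Problem sizes and numerical choices

Test and acceptance runs use desk-scale instances chosen as the package's
own defaults: 1,000 random cascade instances (2–12 centers) for
conservation, 20 instances of 50 centers against the dense solve, 20
synthetic hospitals for recovery, 200 random assets for present-value
conservation, 200 seeds for the projection-bias Monte Carlo. Tolerances:
1e-9 relative for conservation/recovery/PV identities (observed errors are
at machine precision); 1e-6 relative for the annuity zero-rate limit
(tested at r = 1e-9); exact equality for decimal money sums, ventilation
counts, and the reproduced provincial and grand totals; ≤ 1 USD for the
regional column sum (the printed table itself is internally inconsistent
at the 0.40 USD level). Ties in largest-remainder apportionment break by
profile order; money is quantized to cents only in reports.

## Known limitations

- Step-down without iteration ignores mutual service flows (reciprocal
  allocation is out of scope by design); results depend on the cascade
  order, which is why the order is manifest-recorded.
- The packaged financing tables are inputs, not outputs: the per-admission
  costs behind them cannot be derived from the packaged per-day unit costs
  without lengths of stay, which the source does not provide.
- Real per-hospital unit-cost dispersions (the published 29–154 USD
  provincial surgery spread) cannot be reproduced — the underlying hospital
  data are not public; the dispersion report machinery is exercised on
  synthetic samples and on the published range endpoints as fixtures.
- `exchange_rate` is a single scalar; no time-varying FX, no inflation
  adjustment across accounting years.
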