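"""Annuitized (equivalent annual cost) depreciation of hospital capital.

Capital goods — medical equipment, informatics/transport, buildings — are
converted into a constant yearly charge by dividing the purchase price by the
annuity factor at a fixed real interest rate over the asset-class lifespan.
This is the "economic depreciation" convention of the health-economics costing
literature: the asset is treated as if financed by a loan repaid in equal
annual installments, with no salvage value at the end of life.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping

__all__ = [
    "DepreciationPolicy",
    "annuity_factor",
    "equivalent_annual_cost",
    "depreciate_inventory",
]

#: Default lifespans (years) per asset class, as validated by the national
#: costing exercise: equipment 10 y, informatics & transport 5 y, buildings 25 y.
DEFAULT_LIFESPANS: Mapping[str, int] = {
    "equipment": 10,
    "informatics_transport": 5,
    "building": 25,
}

DEFAULT_INTEREST_RATE = 0.05


@dataclass(frozen=True)
class DepreciationPolicy:
    """Lifespans per asset class and the discount rate used for annuitization.

    ``salvage_value`` is fixed at zero: capital is assumed not to be resold at
    the end of its lifespan.
    """

    lifespan_years: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_LIFESPANS)
    )
    interest_rate: float = DEFAULT_INTEREST_RATE
    salvage_value: float = 0.0

    def __post_init__(self) -> None:
        if any(n <= 0 for n in self.lifespan_years.values()):
            raise ValueError("asset lifespans must be positive integers")
        if self.interest_rate < 0:
            raise ValueError("interest rate must be >= 0")
        if self.salvage_value != 0.0:
            raise ValueError("salvage value is fixed at 0 (assets are not resold)")


def annuity_factor(n: int, r: float) -> float:
    """Present value of an n-year annuity of 1 per year at rate ``r``.

    ``A(n, r) = (1 - (1 + r)^-n) / r`` for ``r > 0``; the zero-rate limit is
    ``A(n, 0) = n``. Dividing a purchase price by this factor yields the
    constant annual payment whose present value equals the price.
    """
    if n < 1:
        raise ValueError(f"annuity horizon must be >= 1 year, got {n}")
    if r < 0:
        raise ValueError(f"interest rate must be >= 0, got {r}")
    if r == 0 or 1.0 + r == 1.0:  # zero-rate branch, incl. float underflow
        return float(n)
    # -expm1(-n log1p(r))/r == (1 - (1+r)^-n)/r without cancellation at small r
    return -math.expm1(-n * math.log1p(r)) / r


def equivalent_annual_cost(asset: "CapitalAsset", policy: DepreciationPolicy) -> float:
    """Constant yearly charge for one inventory line (price x quantity).

    ``EAC = quantity * purchase_price / A(lifespan, rate)``; no salvage
    deduction is applied.
    """
    try:
        lifespan = policy.lifespan_years[asset.asset_class]
    except KeyError:
        raise KeyError(
            f"asset class {asset.asset_class!r} has no configured lifespan "
            f"(known: {sorted(policy.lifespan_years)})"
        ) from None
    factor = annuity_factor(lifespan, policy.interest_rate)
    return asset.quantity * asset.purchase_price / factor


def depreciate_inventory(
    assets: Iterable["CapitalAsset"], policy: DepreciationPolicy
) -> dict[str, float]:
    """Sum equivalent annual costs per cost center.

    Centers absent from the inventory simply do not appear in the map; callers
    treat a missing key as zero capital charge.
    """
    eac: dict[str, float] = defaultdict(float)
    for asset in assets:
        eac[asset.center_id] += equivalent_annual_cost(asset, policy)
    return dict(eac)
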