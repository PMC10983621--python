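"""Reproduce the national bottom-up financing tables from the packaged inputs.

Prints, per care level, the per-activity and ancillary totals and their exact
decimal column sum, the all-levels outpatient line (product of its two
inputs, alongside the published figure), and the grand total over the three
levels plus outpatient care. Writes the same numbers to
results/financing_reproduction.json.
"""

import json
from decimal import Decimal
from pathlib import Path

from hospicost.financing import (
    estimate_outpatient_financing,
    published_grand_total,
    published_level_estimate,
)
from hospicost.reference import financing_levels, financing_outpatient

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    meta = financing_levels().set_index("level")
    payload = {}
    for level in ("teaching", "regional", "provincial"):
        est = published_level_estimate(level)
        published = meta.loc[level, "printed_level_total"]
        print(f"\n== {level} hospitals ==")
        for code, total in {**est.activity_totals, **est.ancillary_totals}.items():
            print(f"  {code:<26} {total:>16.2f}")
        print(f"  {'column sum':<26} {est.level_total:>16.2f}"
              f"   (published level total {published})")
        payload[level] = {
            "column_sum": str(est.quantized()),
            "published": str(published),
        }

    out_row = financing_outpatient()
    product = estimate_outpatient_financing(
        out_row["unit_cost"], int(out_row["total_consultations"])
    )
    print(f"\n== outpatient consultations (all levels) ==")
    print(f"  {out_row['unit_cost']} USD x {out_row['total_consultations']:,} "
          f"= {product:.2f}   (published {out_row['printed_total']})")
    grand = published_grand_total()
    print(f"\ngrand total financing, all public hospitals, 2023: {grand} USD")
    payload["outpatient"] = {"product": str(product.quantize(Decimal('0.01'))),
                             "published": str(out_row["printed_total"])}
    payload["grand_total"] = str(grand.quantize(Decimal("0.01")))

    OUT.mkdir(exist_ok=True)
    (OUT / "financing_reproduction.json").write_text(
        json.dumps(payload, indent=2, sort_keys=True)
    )
    print(f"\nwrote {OUT / 'financing_reproduction.json'}")


if __name__ == "__main__":
    main()
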