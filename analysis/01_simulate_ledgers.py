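"""Generate the synthetic hospital sample used by the downstream analyses.

Writes one CSV ledger set per hospital (two per care level by default) plus
ground_truth.json under results/synthetic_sample/. Every number downstream is
recomputable from these files and the seed alone.
"""

import sys
from pathlib import Path

from hospicost.synthetic import SyntheticSpec, write_sample

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
OUT = Path(__file__).resolve().parents[1] / "results" / "synthetic_sample"


def main() -> None:
    spec = SyntheticSpec(seed=SEED)
    paths = write_sample(spec, OUT)
    print(f"seed {SEED}: wrote {len(paths)} hospital ledgers under {OUT}")
    for p in paths:
        print(f"  {p.name}")
    print("ground truth (exact target unit costs): ground_truth.json")


if __name__ == "__main__":
    main()
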