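#!/usr/bin/env python
"""Reproduce the published association tables from the embedded counts.

Recomputes allele/genotype frequencies, odds ratios with Woolf CIs,
chi-square and Fisher p-values for both loci, the per-haplotype
case-control contrasts, and control-group Hardy-Weinberg tests; checks
every value against its printed counterpart at printed rounding and
writes the full bundle to results/association.json.
"""

import argparse
import json
from pathlib import Path

from linedrop.reporting import reproduce_study

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1,
                    help="accepted for driver uniformity; the "
                    "reproduction is deterministic")
    ap.parse_args()
    bundle = reproduce_study()
    RESULTS.mkdir(exist_ok=True)
    out = RESULTS / "association.json"
    out.write_text(json.dumps(bundle, indent=2) + "\n")

    n_ok = sum(c["ok"] for c in bundle["checks"]["items"])
    n = len(bundle["checks"]["items"])
    print(f"reproduced {n_ok}/{n} printed statistics at printed rounding")
    print(f"  I148M allele:  OR {bundle['allele']['I148M']['or_str']}, "
          f"p = {bundle['allele']['I148M']['p_chi2']:.3f}")
    print(f"  WT/Ins allele: OR {bundle['allele']['WT/Ins']['or_str']}, "
          f"p = {bundle['allele']['WT/Ins']['p_chi2']:.3f}"
          " -> the insertion itself is not associated with NAFLD")
    print(f"  WT-148M haplotype: OR {bundle['haplotype']['WT-M']['or_str']}"
          " (the risk signal is carried by 148M alone)")
    print(f"  Ins-148M haplotype: absent in 578 chromosomes (printed 'na')")
    print(f"wrote {out}")
    if not bundle["checks"]["all_ok"]:
        raise SystemExit(1)


if __name__ == "__main__":
    main()
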