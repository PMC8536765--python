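#!/usr/bin/env python
"""Linkage disequilibrium between the LINE-1 insertion and I148M.

Computes D, D' and r2 on the pooled 578 study chromosomes (complete
coupling of Ins with 148I: D' = 1, r2 = 0.286) and per group, then
demonstrates that EM haplotype estimation from unphased genotypes
recovers the absent Ins-148M haplotype class on simulated cohorts.
"""

import argparse
import json
from pathlib import Path

from linedrop.cohort import load_study_counts
from linedrop.ld import HaplotypeFreqs, em_haplotype_freqs, ld_stats, \
    pooled_ld
from linedrop.simulate import CohortSimParams, POOLED_STUDY_FREQS, \
    joint_genotype_counts, simulate_cohort

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n", type=int, default=5000,
                    help="simulated cohort size for the EM recovery demo")
    args = ap.parse_args()

    hap = load_study_counts("haplotypes")
    stats, freqs = pooled_ld(hap)
    out = {"pooled": {**stats.to_dict(),
                      "n_chromosomes": freqs.n_chromosomes},
           "per_group": {}}
    print(f"pooled ({freqs.n_chromosomes} chromosomes): "
          f"D' = {stats.D_prime:.3f}, r2 = {stats.r2:.3f}")
    for group in hap.counts:
        f = HaplotypeFreqs.from_counts(hap.counts[group])
        s = ld_stats(f)
        out["per_group"][group] = {**s.to_dict(),
                                   "n_chromosomes": f.n_chromosomes}
        print(f"  {group:8s}: D' = {s.D_prime:.3f}, r2 = {s.r2:.3f}")

    params = CohortSimParams({"case": POOLED_STUDY_FREQS}, {"case": args.n},
                             seed=args.seed % 2**31)
    counts = joint_genotype_counts(simulate_cohort(params))
    est = em_haplotype_freqs(counts)
    out["em_recovery"] = {"truth": POOLED_STUDY_FREQS,
                          "estimate": est.as_tuple(), "n": args.n}
    err = max(abs(e - t) for e, t in zip(est.as_tuple(),
                                         POOLED_STUDY_FREQS))
    print(f"EM on an unphased simulated cohort (n={args.n}): estimated "
          f"Ins-M frequency {est.d:.4f} (truth 0), max abs error {err:.4f}")

    RESULTS.mkdir(exist_ok=True)
    (RESULTS / "ld.json").write_text(json.dumps(out, indent=2) + "\n")
    print(f"wrote {RESULTS / 'ld.json'}")


if __name__ == "__main__":
    main()
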