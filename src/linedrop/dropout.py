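"""Primer-blocking allele dropout and the apparent-frequency bias it causes.

When a genotyping primer lands on sequence interrupted by a structural
insertion, the insertion-bearing chromosome yields no product: SNP
heterozygotes who carry the insertion are miscalled as homozygous for
the allele on their non-insertion (WT) chromosome, and insertion
homozygotes fail outright.  Because the insertion here is completely
coupled with the 148I allele, this selectively inflates the apparent
148M frequency.

Two routes are provided and cross-checked: an empirical transform of
per-individual calls (``apply_dropout``, no mating assumption) and the
closed-form expectation under random union of gametes
(``analytic_apparent_freq``): the expected apparent M frequency is
b/(a+b) — the M frequency among WT chromosomes — and the expected
no-call fraction is (c+d)^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .cohort import GROUPS, SNP_GENOTYPES, TwoLocusCohort
from .ld import HaplotypeFreqs


@dataclass(frozen=True)
class DropoutRule:
    """Which chromosome class fails to amplify and how failures are handled.

    ``dropout_probability`` is the per-chromosome chance that the blocked
    allele yields no product; the modelled scenario is all-or-nothing
    primer blocking, so it defaults to 1 (complete dropout).
    ``detectability`` records whether total failures (no product at all)
    are observable as such in the assay.
    """

    blocked_allele: str = "Ins"
    failure_policy: str = "exclude_no_calls"
    detectability: bool = True
    dropout_probability: float = 1.0

    def __post_init__(self) -> None:
        if self.blocked_allele != "Ins":
            raise ValueError("only the Ins chromosome class can be blocked")
        if self.failure_policy != "exclude_no_calls":
            raise ValueError(f"unknown failure policy {self.failure_policy!r}")
        if not 0.0 <= self.dropout_probability <= 1.0:
            raise ValueError("dropout probability must be in [0, 1]")


class PhaseRequiredError(ValueError):
    """An unphased double heterozygote cannot be transformed without phase."""


@dataclass
class ApparentCallSet:
    """Apparent SNP genotype calls after dropout, per group.

    ``counts`` maps group -> (I/I, I/M, M/M) apparent counts among called
    individuals; ``no_calls`` maps group -> individuals with no product.
    ``true_counts`` holds the pre-dropout SNP genotype counts.
    """

    counts: dict[str, tuple[int, int, int]]
    no_calls: dict[str, int]
    true_counts: dict[str, tuple[int, int, int]]
    rule: DropoutRule = field(default_factory=DropoutRule)

    def n_called(self, group: Optional[str] = None) -> int:
        groups = [group] if group else list(self.counts)
        return sum(sum(self.counts[g]) for g in groups)

    @property
    def n_no_call(self) -> int:
        return sum(self.no_calls.values())

    def apparent_m_freq(self, group: Optional[str] = None) -> float:
        groups = [group] if group else list(self.counts)
        het = sum(self.counts[g][1] for g in groups)
        hom = sum(self.counts[g][2] for g in groups)
        called = self.n_called(group)
        if called == 0:
            raise ValueError("no called individuals")
        return (het + 2 * hom) / (2 * called)

    def true_m_freq(self, group: Optional[str] = None) -> float:
        groups = [group] if group else list(self.true_counts)
        het = sum(self.true_counts[g][1] for g in groups)
        hom = sum(self.true_counts[g][2] for g in groups)
        n = sum(sum(self.true_counts[g]) for g in groups)
        return (het + 2 * hom) / (2 * n)

    @property
    def bias(self) -> float:
        """Pooled apparent minus true M frequency."""
        return self.apparent_m_freq() - self.true_m_freq()


def _wt_snp_allele(rec, assume_complete_linkage: bool) -> str:
    """SNP allele on the single WT chromosome of a WT/Ins heterozygote."""
    if rec.phase is not None:
        for hap in rec.phase:
            ins, snp = hap.split("-")
            if ins == "WT":
                return snp
        raise AssertionError("WT/Ins record without a WT haplotype")
    if rec.snp_gt == "I/I":
        return "I"
    if rec.snp_gt == "M/M":
        return "M"
    if assume_complete_linkage:
        # Ins always carries I, so the M of a double het sits on WT
        return "M"
    raise PhaseRequiredError(
        f"record {rec.sample_id}: unphased double heterozygote; supply "
        f"phase or set assume_complete_linkage=True")


def apply_dropout(cohort: TwoLocusCohort, rule: DropoutRule = DropoutRule(),
                  *, assume_complete_linkage: bool = False,
                  rng: Optional[np.random.Generator] = None,
                  ) -> ApparentCallSet:
    """Transform true two-locus genotypes into apparent SNP calls.

    Ins/Ins individuals yield no call; WT/Ins heterozygotes appear
    homozygous for their WT-chromosome SNP allele; WT/WT calls are
    unchanged.  With ``dropout_probability`` < 1 each Ins chromosome
    escapes blocking independently with the complementary probability
    (requires ``rng``).
    """
    p_drop = rule.dropout_probability
    if p_drop < 1.0 and rng is None:
        raise ValueError("partial dropout requires an rng")
    snp_idx = {g: i for i, g in enumerate(SNP_GENOTYPES)}
    counts = {g: [0, 0, 0] for g in GROUPS}
    true_counts = {g: [0, 0, 0] for g in GROUPS}
    no_calls = {g: 0 for g in GROUPS}
    for rec in cohort.records:
        true_counts[rec.group][snp_idx[rec.snp_gt]] += 1
        n_ins = {"WT/WT": 0, "WT/Ins": 1, "Ins/Ins": 2}[rec.ins_gt]
        dropped = n_ins if p_drop == 1.0 else int(
            (rng.random(n_ins) < p_drop).sum())
        if n_ins == 2 and dropped == 2:
            no_calls[rec.group] += 1
            continue
        if n_ins == 1 and dropped == 1:
            allele = _wt_snp_allele(rec, assume_complete_linkage)
            apparent = f"{allele}/{allele}"
        else:
            apparent = rec.snp_gt
        counts[rec.group][snp_idx[apparent]] += 1
    return ApparentCallSet(
        counts={g: tuple(c) for g, c in counts.items()},
        no_calls=no_calls,
        true_counts={g: tuple(c) for g, c in true_counts.items()},
        rule=rule)


def apparent_allele_freq(calls: ApparentCallSet) -> float:
    """Pooled apparent M frequency among called individuals."""
    return calls.apparent_m_freq()


def analytic_apparent_freq(freqs: HaplotypeFreqs) -> tuple[float, float]:
    """Closed-form (expected apparent M frequency, expected no-call fraction).

    Under random union of gametes with complete dropout of Ins
    chromosomes, every observed chromosome is a WT chromosome, so the
    apparent M frequency is b/(a+b); Ins/Ins individuals, probability
    (c+d)^2, are no-calls.
    """
    p_wt = freqs.a + freqs.b
    if p_wt == 0:
        raise ValueError("no WT chromosomes: every individual is a no-call")
    return freqs.b / p_wt, freqs.p_ins ** 2


def bias_surface(p_ins_grid, d_prime_grid, p_m: float) -> pd.DataFrame:
    """Apparent-frequency bias over a (p_Ins, D') grid at fixed p_M.

    The insertion is coupled with the I allele (the study's geometry):
    at each grid point d = p_Ins*p_M - D' * Dmax(-) with
    Dmax(-) = min(p_Ins*p_M, (1-p_Ins)(1-p_M)).  Infeasible frequency
    combinations are kept as rows with ``feasible=False`` and NaN
    outputs.
    """
    rows = []
    grid = [(p_ins, dp) for p_ins in p_ins_grid for dp in d_prime_grid]
    if not grid:
        raise ValueError("empty grid")
    for p_ins, dp in grid:
        if p_ins >= 1.0:
            rows.append({"p_ins": p_ins, "d_prime": dp, "feasible": False,
                         "apparent_m": np.nan, "bias": np.nan,
                         "no_call_fraction": np.nan})
            continue
        dmax = min(p_ins * p_m, (1 - p_ins) * (1 - p_m))
        d = p_ins * p_m - dp * dmax
        b = p_m - d
        c = p_ins - d
        a = 1.0 - b - c - d
        if min(a, b, c, d) < -1e-12:
            rows.append({"p_ins": p_ins, "d_prime": dp, "feasible": False,
                         "apparent_m": np.nan, "bias": np.nan,
                         "no_call_fraction": np.nan})
            continue
        freqs = HaplotypeFreqs(max(a, 0.0), max(b, 0.0), max(c, 0.0),
                               max(d, 0.0))
        apparent, no_call = analytic_apparent_freq(freqs)
        rows.append({"p_ins": p_ins, "d_prime": dp, "feasible": True,
                     "apparent_m": apparent, "bias": apparent - p_m,
                     "no_call_fraction": no_call})
    return pd.DataFrame(rows)
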