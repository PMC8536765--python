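"""Haplotype frequencies and linkage disequilibrium for two biallelic loci.

Haplotype order throughout is (WT-I, WT-M, Ins-I, Ins-M), with
frequencies (a, b, c, d).  Marginals are p_Ins = c + d and p_M = b + d.
D is computed on the (Ins, M) allele pair, D = d - p_Ins * p_M, so that
complete coupling of the insertion with the 148I allele (d = 0 with both
loci polymorphic) gives D < 0 and |D| / Dmax = 1.  D' is reported as the
absolute normalised value.

For unphased genotype data only the double heterozygote (WT/Ins + I/M)
is phase-ambiguous; ``em_haplotype_freqs`` resolves it with the standard
EM split proportional to a*d versus b*c.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .cohort import (GROUPS, HAPLOTYPES, HaplotypeCountTable, TwoLocusCohort)


@dataclass
class HaplotypeFreqs:
    """Four-haplotype frequencies (a, b, c, d) summing to 1."""

    a: float  # WT-I
    b: float  # WT-M
    c: float  # Ins-I
    d: float  # Ins-M
    n_chromosomes: int = 0
    source: str = "counted"  # counted | em

    def __post_init__(self) -> None:
        total = self.a + self.b + self.c + self.d
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"haplotype frequencies sum to {total}, not 1")
        if min(self.a, self.b, self.c, self.d) < -1e-12:
            raise ValueError("negative haplotype frequency")

    @property
    def p_ins(self) -> float:
        return self.c + self.d

    @property
    def p_m(self) -> float:
        return self.b + self.d

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.a, self.b, self.c, self.d)

    @classmethod
    def from_counts(cls, counts: Sequence[int],
                    source: str = "counted") -> "HaplotypeFreqs":
        counts = [int(x) for x in counts]
        n = sum(counts)
        if n == 0:
            raise ValueError("no chromosomes")
        return cls(*(x / n for x in counts), n_chromosomes=n, source=source)


@dataclass
class LdStats:
    """Pairwise LD: raw D, normalised |D|/Dmax, and squared correlation r^2.

    D_prime and r2 are ``None`` when either locus is monomorphic.
    """

    D: float
    D_prime: Optional[float]
    r2: Optional[float]

    def to_dict(self) -> dict:
        return {"D": self.D, "D_prime": self.D_prime, "r2": self.r2}


def count_haplotypes_phased(cohort: TwoLocusCohort) -> HaplotypeCountTable:
    """Per-group chromosome counts from a fully phased cohort."""
    idx = {h: i for i, h in enumerate(HAPLOTYPES)}
    counts = {g: [0, 0, 0, 0] for g in GROUPS}
    for rec in cohort.records:
        if rec.phase is None:
            raise ValueError(f"record {rec.sample_id} is unphased")
        for hap in rec.phase:
            counts[rec.group][idx[hap]] += 1
    return HaplotypeCountTable({g: tuple(c) for g, c in counts.items()})


def _genotype_class_probs(a: float, b: float, c: float, d: float) -> np.ndarray:
    """HWE probabilities of the 3x3 joint genotype classes.

    Rows: insertion genotype (WT/WT, WT/Ins, Ins/Ins); columns: SNP
    genotype (I/I, I/M, M/M).
    """
    p = np.empty((3, 3))
    p[0, 0] = a * a
    p[0, 1] = 2 * a * b
    p[0, 2] = b * b
    p[1, 0] = 2 * a * c
    p[1, 1] = 2 * a * d + 2 * b * c  # double heterozygote, two phasings
    p[1, 2] = 2 * b * d
    p[2, 0] = c * c
    p[2, 1] = 2 * c * d
    p[2, 2] = d * d
    return p


def em_haplotype_freqs(gt_counts: Sequence[Sequence[int]],
                       *, tol: float = 1e-8, max_iter: int = 10_000,
                       return_trace: bool = False,
                       ) -> HaplotypeFreqs | tuple[HaplotypeFreqs, list[float]]:
    """Maximum-likelihood haplotype frequencies from 3x3 joint genotype counts.

    Standard two-locus EM: every genotype class except the double
    heterozygote contributes known gametes; the double heterozygotes are
    split between the coupling phasings in proportion a*d : b*c at the
    current estimate.  Uniform (0.25 each) initialisation; iterate until
    the largest frequency change is below ``tol``.

    With ``return_trace`` the per-iteration log-likelihoods are also
    returned (they are non-decreasing, an EM guarantee the tests assert).
    """
    n = np.asarray(gt_counts, dtype=float)
    if n.shape != (3, 3):
        raise ValueError("expected a 3x3 joint genotype count table")
    if np.any(n < 0):
        raise ValueError("negative count")
    total = n.sum()
    if total == 0:
        raise ValueError("all-zero genotype table")
    chrom = 2.0 * total

    # gamete contributions of the unambiguous classes
    base = np.zeros(4)  # (a, b, c, d) chromosome counts
    base[0] = 2 * n[0, 0] + n[0, 1] + n[1, 0]          # WT-I
    base[1] = 2 * n[0, 2] + n[0, 1] + n[1, 2]          # WT-M
    base[2] = 2 * n[2, 0] + n[2, 1] + n[1, 0]          # Ins-I
    base[3] = 2 * n[2, 2] + n[2, 1] + n[1, 2]          # Ins-M
    n_dh = n[1, 1]

    freqs = np.full(4, 0.25)
    trace: list[float] = []
    for _ in range(max_iter):
        a, b, c, d = freqs
        if n_dh > 0:
            w = a * d + b * c
            split_ad = 0.5 if w == 0 else (a * d) / w
        else:
            split_ad = 0.0
        counts = base.copy()
        counts[0] += n_dh * split_ad        # WT-I from (WT-I, Ins-M) phasing
        counts[3] += n_dh * split_ad
        counts[1] += n_dh * (1 - split_ad)  # WT-M from (WT-M, Ins-I) phasing
        counts[2] += n_dh * (1 - split_ad)
        new = counts / chrom
        if return_trace:
            probs = _genotype_class_probs(*new)
            mask = n > 0
            trace.append(float(np.sum(n[mask] * np.log(probs[mask]))))
        delta = np.max(np.abs(new - freqs))
        freqs = new
        if delta < tol:
            break
    result = HaplotypeFreqs(*freqs, n_chromosomes=int(chrom), source="em")
    return (result, trace) if return_trace else result


def ld_stats(freqs: HaplotypeFreqs) -> LdStats:
    """D, D' and r^2 from four-haplotype frequencies.

    Dmax follows the usual piecewise definition:
    min(p_Ins*p_M, (1-p_Ins)(1-p_M)) for D < 0, and
    min(p_Ins*(1-p_M), (1-p_Ins)*p_M) for D >= 0.
    """
    p_ins, p_m = freqs.p_ins, freqs.p_m
    D = freqs.d - p_ins * p_m
    if p_ins in (0.0, 1.0) or p_m in (0.0, 1.0):
        return LdStats(D=D, D_prime=None, r2=None)
    if D < 0:
        dmax = min(p_ins * p_m, (1 - p_ins) * (1 - p_m))
    else:
        dmax = min(p_ins * (1 - p_m), (1 - p_ins) * p_m)
    d_prime = abs(D) / dmax
    r2 = D * D / (p_ins * (1 - p_ins) * p_m * (1 - p_m))
    return LdStats(D=D, D_prime=d_prime, r2=r2)


def pooled_ld(hap: HaplotypeCountTable) -> tuple[LdStats, HaplotypeFreqs]:
    """LD on the cases+controls pooled chromosome counts."""
    freqs = HaplotypeFreqs.from_counts(hap.pooled())
    return ld_stats(freqs), freqs
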