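"""Two-locus cohort data model and I/O.

A cohort records, for each individual, the genotype at the structural
locus (WT / Ins, presence of the intronic LINE-1 insertion) and at the
SNP locus (I / M, the PNPLA3 I148M substitution), an optional known
phase, and the case/control label.  Embedded count tables transcribe
the published NAFLD case-control study (122 cases, 167 controls).

File format: tab-separated, UTF-8, header
``sample_id  group  ins_gt  snp_gt  phase``; ``#``-prefixed lines are
ignored and the phase column may be empty.  Heterozygote order is
normalised on read (``Ins/WT`` becomes ``WT/Ins``, ``M/I`` becomes
``I/M``); phase is stored as an unordered pair serialised in canonical
order (WT before Ins, I before M).
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

GROUPS = ("case", "control")
INS_GENOTYPES = ("WT/WT", "WT/Ins", "Ins/Ins")
SNP_GENOTYPES = ("I/I", "I/M", "M/M")
HAPLOTYPES = ("WT-I", "WT-M", "Ins-I", "Ins-M")

_HAP_ORDER = {h: i for i, h in enumerate(HAPLOTYPES)}

_INS_NORMALISE = {
    "WT/WT": "WT/WT", "WT/Ins": "WT/Ins", "Ins/WT": "WT/Ins", "Ins/Ins": "Ins/Ins",
}
_SNP_NORMALISE = {"I/I": "I/I", "I/M": "I/M", "M/I": "I/M", "M/M": "M/M"}


class CohortParseError(ValueError):
    """Raised for malformed cohort files (names the offending line)."""


class CohortValidationError(ValueError):
    """Raised for records that violate cohort invariants."""


def _hap_alleles(hap: str) -> tuple[str, str]:
    ins, snp = hap.split("-")
    return ins, snp


@dataclass(frozen=True)
class TwoLocusGenotype:
    """One individual's genotypes at the insertion and SNP loci.

    ``phase``, when known, is the unordered pair of haplotypes carried
    on the two chromosomes; its allele multiset must match
    (``ins_gt``, ``snp_gt``).
    """

    sample_id: str
    group: str
    ins_gt: str
    snp_gt: str
    phase: Optional[tuple[str, str]] = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise CohortValidationError(
                f"{self.sample_id}: unknown group {self.group!r}")
        if self.ins_gt not in INS_GENOTYPES:
            raise CohortValidationError(
                f"{self.sample_id}: unknown insertion genotype {self.ins_gt!r}")
        if self.snp_gt not in SNP_GENOTYPES:
            raise CohortValidationError(
                f"{self.sample_id}: unknown SNP genotype {self.snp_gt!r}")
        if self.phase is not None:
            pair = tuple(sorted(self.phase, key=_HAP_ORDER.__getitem__))
            for hap in pair:
                if hap not in HAPLOTYPES:
                    raise CohortValidationError(
                        f"{self.sample_id}: unknown haplotype {hap!r}")
            ins_alleles = sorted(_hap_alleles(h)[0] for h in pair)
            snp_alleles = sorted(_hap_alleles(h)[1] for h in pair)
            gt_ins = sorted(self.ins_gt.split("/"))
            gt_snp = sorted(self.snp_gt.split("/"))
            if ins_alleles != gt_ins or snp_alleles != gt_snp:
                raise CohortValidationError(
                    f"{self.sample_id}: phase {pair} inconsistent with "
                    f"genotypes ({self.ins_gt}, {self.snp_gt})")
            object.__setattr__(self, "phase", pair)


@dataclass
class TwoLocusCohort:
    """A list of individuals; group sizes are always derived, never stored."""

    records: list[TwoLocusGenotype] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.sample_id in seen:
                raise CohortValidationError(
                    f"duplicate sample_id {rec.sample_id!r}")
            seen.add(rec.sample_id)

    @property
    def n_cases(self) -> int:
        return sum(1 for r in self.records if r.group == "case")

    @property
    def n_controls(self) -> int:
        return sum(1 for r in self.records if r.group == "control")

    def __len__(self) -> int:
        return len(self.records)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, TwoLocusCohort) and self.records == other.records

    def subset(self, group: str) -> "TwoLocusCohort":
        return TwoLocusCohort([r for r in self.records if r.group == group])

    def genotype_counts(self, locus: str) -> "GenotypeCountTable":
        """Per-group genotype counts at ``locus`` ('ins' or 'snp')."""
        if locus == "ins":
            cats, attr = INS_GENOTYPES, "ins_gt"
        elif locus == "snp":
            cats, attr = SNP_GENOTYPES, "snp_gt"
        else:
            raise ValueError(f"unknown locus {locus!r}")
        counts = {}
        for group in GROUPS:
            tally = Counter(getattr(r, attr) for r in self.records
                            if r.group == group)
            counts[group] = tuple(tally.get(c, 0) for c in cats)
        return GenotypeCountTable(locus=locus, categories=cats, counts=counts)


@dataclass
class GenotypeCountTable:
    """Per-group counts of the three genotypes at one locus."""

    locus: str
    categories: tuple[str, str, str]
    counts: dict[str, tuple[int, int, int]]

    def group_size(self, group: str) -> int:
        return sum(self.counts[group])

    def allele_counts(self, group: str) -> tuple[int, int]:
        """(ref, alt) chromosome counts: alt = het + 2*hom_alt."""
        hom_ref, het, hom_alt = self.counts[group]
        return (2 * hom_ref + het, het + 2 * hom_alt)

    def to_json(self) -> str:
        return json.dumps({"locus": self.locus,
                           "categories": list(self.categories),
                           "counts": {g: list(c) for g, c in self.counts.items()}})


@dataclass
class HaplotypeCountTable:
    """Per-group chromosome counts of the four two-locus haplotypes.

    Values are chromosomes, not individuals: each group's counts sum to
    twice the group size.
    """

    counts: dict[str, tuple[int, int, int, int]]
    haplotypes: tuple[str, ...] = HAPLOTYPES

    def group_chromosomes(self, group: str) -> int:
        return sum(self.counts[group])

    def pooled(self) -> tuple[int, int, int, int]:
        return tuple(sum(self.counts[g][i] for g in self.counts)
                     for i in range(4))

    def marginal_allele_counts(self, group: str, locus: str) -> tuple[int, int]:
        """(ref, alt) chromosome counts implied by the haplotype margins."""
        a, b, c, d = self.counts[group]
        if locus == "ins":
            return (a + b, c + d)
        if locus == "snp":
            return (a + c, b + d)
        raise ValueError(f"unknown locus {locus!r}")

    def to_json(self) -> str:
        return json.dumps({"haplotypes": list(self.haplotypes),
                           "counts": {g: list(c) for g, c in self.counts.items()}})


# ---------------------------------------------------------------------------
# TSV round trip

_HEADER = ["sample_id", "group", "ins_gt", "snp_gt", "phase"]


def read_cohort(path: str | Path) -> TwoLocusCohort:
    """Read a cohort TSV (see module docstring for the dialect)."""
    path = Path(path)
    records: list[TwoLocusGenotype] = []
    with path.open(encoding="utf-8") as fh:
        header: Optional[list[str]] = None
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                if [f.strip() for f in fields] != _HEADER:
                    raise CohortParseError(
                        f"{path}:{lineno}: bad header {fields!r}; "
                        f"expected {_HEADER}")
                header = fields
                continue
            if len(fields) not in (4, 5):
                raise CohortParseError(
                    f"{path}:{lineno}: expected 4-5 tab-separated fields, "
                    f"got {len(fields)}")
            sample_id, group, ins_gt, snp_gt = (f.strip() for f in fields[:4])
            phase_str = fields[4].strip() if len(fields) == 5 else ""
            try:
                ins_gt = _INS_NORMALISE[ins_gt]
                snp_gt = _SNP_NORMALISE[snp_gt]
            except KeyError as exc:
                raise CohortParseError(
                    f"{path}:{lineno}: unknown genotype token {exc.args[0]!r}"
                ) from None
            phase = None
            if phase_str:
                parts = phase_str.split("/")
                if len(parts) != 2:
                    raise CohortParseError(
                        f"{path}:{lineno}: malformed phase {phase_str!r}")
                phase = (parts[0].strip(), parts[1].strip())
            try:
                records.append(TwoLocusGenotype(sample_id, group, ins_gt,
                                                snp_gt, phase))
            except CohortValidationError as exc:
                raise CohortValidationError(f"{path}:{lineno}: {exc}") from None
    if header is None:
        raise CohortParseError(f"{path}: empty file (no header)")
    return TwoLocusCohort(records)


def write_cohort(cohort: TwoLocusCohort, path: str | Path) -> None:
    """Write a cohort TSV such that ``read_cohort`` round-trips it."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("\t".join(_HEADER) + "\n")
        for rec in cohort.records:
            phase = "/".join(rec.phase) if rec.phase is not None else ""
            fh.write("\t".join([rec.sample_id, rec.group, rec.ins_gt,
                                rec.snp_gt, phase]) + "\n")


# ---------------------------------------------------------------------------
# Embedded study counts (case-control study: 122 NAFLD cases, 167 controls)

_STUDY_FIXTURES = {
    # I148M genotypes: (I/I, I/M, M/M)
    "i148m_genotypes": GenotypeCountTable(
        locus="snp", categories=SNP_GENOTYPES,
        counts={"case": (50, 56, 16), "control": (94, 61, 12)}),
    # WT/Ins genotypes: (WT/WT, WT/Ins, Ins/Ins)
    "wtins_genotypes": GenotypeCountTable(
        locus="ins", categories=INS_GENOTYPES,
        counts={"case": (45, 60, 17), "control": (54, 88, 25)}),
    # haplotype chromosome counts: (WT-I, WT-M, Ins-I, Ins-M);
    # published caption says "subjects" but the values sum to 2N
    # (62+88+94 = 244 = 2*122), i.e. chromosomes.
    "haplotypes": HaplotypeCountTable(
        counts={"case": (62, 88, 94, 0), "control": (111, 85, 138, 0)}),
}


def load_study_counts(name: str) -> GenotypeCountTable | HaplotypeCountTable:
    """Return an embedded count table from the published study.

    ``name`` is one of ``i148m_genotypes``, ``wtins_genotypes``,
    ``haplotypes``.
    """
    try:
        return _STUDY_FIXTURES[name]
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; choose from "
            f"{sorted(_STUDY_FIXTURES)}") from None


@dataclass
class ConsistencyReport:
    consistent: bool
    messages: list[str]


def validate_consistency(gt: GenotypeCountTable,
                         hap: HaplotypeCountTable) -> ConsistencyReport:
    """Check that haplotype-derived allele counts match genotype-derived ones.

    Compares, per group, the allele counts implied by ``hap``'s margins at
    ``gt.locus`` with ``gt``'s own allele counts.
    """
    messages: list[str] = []
    for group in gt.counts:
        if group not in hap.counts:
            messages.append(f"group {group!r} missing from haplotype table")
            continue
        from_gt = gt.allele_counts(group)
        from_hap = hap.marginal_allele_counts(group, gt.locus)
        if from_gt != from_hap:
            messages.append(
                f"{group}: {gt.locus} allele counts differ "
                f"(genotypes imply {from_gt}, haplotypes imply {from_hap})")
    return ConsistencyReport(consistent=not messages, messages=messages)


def cohort_from_counts(gt_joint: Sequence[Sequence[int]],
                       group: str = "case",
                       prefix: str = "S") -> TwoLocusCohort:
    """Expand a 3x3 joint genotype count table into an unphased cohort.

    Rows index the insertion genotype (WT/WT, WT/Ins, Ins/Ins), columns
    the SNP genotype (I/I, I/M, M/M).  Convenience for feeding count
    data to record-level operations.
    """
    records = []
    k = 0
    for i, ins_gt in enumerate(INS_GENOTYPES):
        for j, snp_gt in enumerate(SNP_GENOTYPES):
            for _ in range(int(gt_joint[i][j])):
                records.append(TwoLocusGenotype(f"{prefix}{k:05d}", group,
                                                ins_gt, snp_gt))
                k += 1
    return TwoLocusCohort(records)
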