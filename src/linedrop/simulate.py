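"""Synthetic cohorts, sequences, primer panels and qPCR plates.

The generators emulate the statistical structure the analyses assume:

* cohorts of diploid individuals whose chromosomes are drawn i.i.d.
  from per-group four-haplotype frequencies (random union of gametes;
  the case/control contrast is encoded directly as different haplotype
  frequencies) — including the complete-linkage geometry where the
  Ins-M haplotype frequency is exactly zero;
* genomic templates carrying a ~1.1 kb insertion with a 16 bp
  target-site duplication, a biallelic SNP 122 bp downstream of the
  breakpoint, and an allele-specific restriction site so the SNP is
  RFLP-typeable;
* primer panels straddling the breakpoint, with the expected
  success/failure pattern of each reaction on the insertion allele;
* qPCR plates with group-level log2 fold changes and per-replicate
  Gaussian Ct noise.

Every generator is deterministic given its seed.  The insert body is
random sequence (no real LINE-1 claim); the difficult-to-sequence
homopolymeric filler motif (T)14 GGTGATG (T)34 is included verbatim at
the 5' end of the insert for realism.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .cohort import HAPLOTYPES, TwoLocusCohort, TwoLocusGenotype
from .dropout import PhaseRequiredError
from .pcr import (BTSCI, Enzyme, InsertionSpec, Primer, build_templates,
                  call_genotype_from_sizes, digest, find_primer_sites)
from .qpcr import QpcrMeasurement

_HAP_ORDER = {h: i for i, h in enumerate(HAPLOTYPES)}
FILLER_MOTIF = "T" * 14 + "GGTGATG" + "T" * 34


# ---------------------------------------------------------------------------
# cohorts

@dataclass
class CohortSimParams:
    """Per-group haplotype frequencies (WT-I, WT-M, Ins-I, Ins-M) and sizes."""

    freqs: dict[str, tuple[float, float, float, float]]
    sizes: dict[str, int]
    seed: int = 0

    def __post_init__(self) -> None:
        for group, f in self.freqs.items():
            if abs(sum(f) - 1.0) > 1e-9 or min(f) < 0:
                raise ValueError(f"{group}: infeasible frequencies {f}")
        for group, n in self.sizes.items():
            if n < 0:
                raise ValueError(f"{group}: negative size")


# pooled study frequencies: 346 WT-I+WT-M and 232 Ins-I chromosomes of 578
POOLED_STUDY_FREQS = (173 / 578, 173 / 578, 232 / 578, 0.0)
STUDY_GROUP_FREQS = {
    "case": (62 / 244, 88 / 244, 94 / 244, 0.0),
    "control": (111 / 334, 85 / 334, 138 / 334, 0.0),
}
STUDY_GROUP_SIZES = {"case": 122, "control": 167}


def simulate_cohort(params: CohortSimParams) -> TwoLocusCohort:
    """Draw a fully phased cohort: two haplotypes per individual, i.i.d."""
    rng = np.random.default_rng(params.seed)
    records = []
    for group in params.sizes:
        n = params.sizes[group]
        f = np.asarray(params.freqs[group], dtype=float)
        draws = rng.choice(4, size=2 * n, p=f)
        for i in range(n):
            h1, h2 = HAPLOTYPES[draws[2 * i]], HAPLOTYPES[draws[2 * i + 1]]
            pair = tuple(sorted((h1, h2), key=_HAP_ORDER.__getitem__))
            ins_alleles = sorted(h.split("-")[0] for h in pair)
            snp_alleles = sorted(h.split("-")[1] for h in pair)
            ins_gt = {("Ins", "Ins"): "Ins/Ins", ("Ins", "WT"): "WT/Ins",
                      ("WT", "WT"): "WT/WT"}[tuple(ins_alleles)]
            snp_gt = "/".join(snp_alleles)
            records.append(TwoLocusGenotype(f"{group}_{i:05d}", group,
                                            ins_gt, snp_gt, pair))
    return TwoLocusCohort(records)


def joint_genotype_counts(cohort: TwoLocusCohort,
                          group: Optional[str] = None) -> np.ndarray:
    """3x3 joint genotype counts (rows: ins genotype, cols: SNP genotype)."""
    ins_idx = {"WT/WT": 0, "WT/Ins": 1, "Ins/Ins": 2}
    snp_idx = {"I/I": 0, "I/M": 1, "M/M": 2}
    out = np.zeros((3, 3), dtype=int)
    for rec in cohort.records:
        if group is None or rec.group == group:
            out[ins_idx[rec.ins_gt], snp_idx[rec.snp_gt]] += 1
    return out


# ---------------------------------------------------------------------------
# sequences

@dataclass
class SequenceSimParams:
    """Geometry of the simulated locus.

    The defaults mirror the characterised locus: a 1114 nt insert with a
    16 nt target-site duplication, the SNP 122 bp downstream of the
    breakpoint (1-based offset, as in g.4921/4922 vs g.5043), and a
    BtsCI site created by the M allele.
    """

    ref_len: int = 5000
    breakpoint: int = 2400
    tsd_len: int = 16
    insert_len: int = 1114
    snp_offset: int = 122  # 1-based distance breakpoint -> SNP
    seed: int = 0
    enzyme: Enzyme = field(default_factory=lambda: BTSCI)

    def __post_init__(self) -> None:
        if self.snp_offset <= 0:
            raise ValueError("snp_offset must be positive")
        if self.breakpoint + self.snp_offset >= self.ref_len:
            raise ValueError("SNP falls beyond the reference end")
        if self.tsd_len > self.breakpoint:
            raise ValueError("tsd_len exceeds breakpoint")
        if self.insert_len < len(FILLER_MOTIF):
            raise ValueError(
                f"insert_len must be >= {len(FILLER_MOTIF)} (filler motif)")

    @property
    def snp_pos(self) -> int:
        """0-based SNP position on the WT reference."""
        return self.breakpoint + self.snp_offset - 1


@dataclass
class SimulatedLocus:
    """A simulated reference plus the truth needed to verify every assay."""

    params: SequenceSimParams
    ref: str                      # WT reference (SNP site = I allele)
    insertion: InsertionSpec
    snp_pos: int                  # 0-based, WT coordinates
    snp_alleles: dict[str, str]   # {"I": base, "M": base}

    @property
    def wt_len(self) -> int:
        return len(self.ref)

    @property
    def ins_extra(self) -> int:
        return len(self.insertion.insert_seq) + self.insertion.tsd_len

    def template(self, haplotype: str) -> str:
        """Full chromosome sequence for one haplotype (e.g. 'Ins-I')."""
        ins, snp = haplotype.split("-")
        seq = (self.ref[:self.snp_pos] + self.snp_alleles[snp]
               + self.ref[self.snp_pos + 1:])
        if ins == "Ins":
            _, seq = build_templates(seq, self.insertion)
        return seq

    def templates(self) -> tuple[str, str]:
        """(WT, Ins) templates both carrying the I allele."""
        return self.template("WT-I"), self.template("Ins-I")


def _scrub_sites(seq: np.ndarray, motifs: Sequence[str],
                 rng: np.random.Generator) -> None:
    """Mutate bases in place until no motif occurs (expected O(1) passes)."""
    bases = np.array(list("ACGT"))
    text = "".join(seq)
    changed = True
    while changed:
        changed = False
        for motif in motifs:
            start = text.find(motif)
            while start != -1:
                pos = start + len(motif) // 2
                old = seq[pos]
                choices = [b for b in bases if b != old]
                seq[pos] = rng.choice(choices)
                changed = True
                text = "".join(seq)
                start = text.find(motif)


def simulate_sequences(params: SequenceSimParams) -> SimulatedLocus:
    """Build the locus: reference, insert, SNP-linked restriction site.

    The reference and insert body are random sequence scrubbed of the
    enzyme's recognition site on both strands; the SNP context is then
    planted so that the M allele (and only the M allele) completes one
    recognition site, making the SNP RFLP-typeable by construction.
    """
    from Bio.Seq import reverse_complement
    rng = np.random.default_rng(params.seed)
    bases = np.array(list("ACGT"))
    motifs = [params.enzyme.recognition,
              reverse_complement(params.enzyme.recognition)]

    ref = rng.choice(bases, size=params.ref_len)
    _scrub_sites(ref, motifs, rng)
    # plant the SNP context: GGAT + snp base; M (G) completes GGATG, I (C)
    # does not (generic for any enzyme: last recognition base is the SNP)
    rec = params.enzyme.recognition
    snp = params.snp_pos
    ctx_start = snp - (len(rec) - 1)
    ref[ctx_start:snp] = list(rec[:-1])
    m_base = rec[-1]
    i_base = rng.choice([b for b in bases if b != m_base])
    ref[snp] = i_base
    ref_str = "".join(ref)

    body_len = params.insert_len - len(FILLER_MOTIF)
    body = rng.choice(bases, size=body_len)
    _scrub_sites(body, motifs, rng)
    insert_seq = FILLER_MOTIF + "".join(body)

    spec = InsertionSpec(params.breakpoint, insert_seq, params.tsd_len)
    return SimulatedLocus(params=params, ref=ref_str, insertion=spec,
                          snp_pos=snp,
                          snp_alleles={"I": str(i_base), "M": m_base})


# ---------------------------------------------------------------------------
# primer panels

@dataclass
class SimulatedPanel:
    """A primer panel with per-reaction truth on the insertion allele."""

    primers: list[Primer]
    fwd_intervals: dict[str, tuple[int, int]]   # WT coordinates
    rev_intervals: dict[str, tuple[int, int]]
    expected: dict[tuple[str, str], bool]       # reaction success on Ins/Ins
    max_len: int

    def results(self) -> list[tuple[tuple[int, int], tuple[int, int], bool]]:
        """Panel outcomes in localize_insertion input form."""
        return [(self.fwd_intervals[f], self.rev_intervals[r], ok)
                for (f, r), ok in self.expected.items()]


def simulate_primer_panel(locus: SimulatedLocus, n_forward: int = 4,
                          n_reverse: int = 3, primer_len: int = 20,
                          spacing: int = 150, seed: int = 0,
                          max_len: int = 700,
                          forward_starts: Optional[Sequence[int]] = None,
                          reverse_starts: Optional[Sequence[int]] = None,
                          ) -> SimulatedPanel:
    """Primers straddling the breakpoint, with expected Ins-allele outcomes.

    Default geometry mirrors the combinatorial walking experiment:
    forward primers at roughly ``spacing``-spaced offsets upstream of
    the breakpoint plus one just downstream of it, reverse primers
    downstream of the SNP.  ``max_len`` defaults to a short-range
    polymerase's ~700 bp ceiling, so any reaction spanning the ~1.1 kb
    insertion fails on the insertion allele.

    A reaction on the insertion homozygote succeeds iff its forward
    primer footprint does not contain the breakpoint and the product
    (grown by insert+TSD when it spans the breakpoint) stays within
    ``max_len``.
    """
    if n_forward < 1 or n_reverse < 1:
        raise ValueError("need at least one forward and one reverse primer")
    rng = np.random.default_rng(seed)
    bp = locus.insertion.breakpoint
    if forward_starts is None:
        jitter = rng.integers(0, max(1, spacing // 3), size=n_forward - 1) \
            if n_forward > 1 else np.array([], dtype=int)
        forward_starts = [bp - (n_forward - 1 - k) * spacing - primer_len
                          - int(jitter[k]) for k in range(n_forward - 1)]
        forward_starts.append(bp + 12)  # the one that escapes the insertion
    if reverse_starts is None:
        jitter = rng.integers(0, max(1, spacing // 3), size=n_reverse)
        reverse_starts = [locus.snp_pos + 30 + k * spacing + int(jitter[k])
                          for k in range(n_reverse)]
    if min(forward_starts) < 0 or \
            max(reverse_starts) + primer_len > locus.wt_len:
        raise ValueError("panel does not fit the reference (spacing overflow)")

    primers: list[Primer] = []
    fwd_iv: dict[str, tuple[int, int]] = {}
    rev_iv: dict[str, tuple[int, int]] = {}
    for k, s in enumerate(sorted(forward_starts)):
        name = f"F{k + 1}"
        primers.append(Primer(name, locus.ref[s:s + primer_len], "forward"))
        fwd_iv[name] = (s, s + primer_len)
    from Bio.Seq import reverse_complement
    for k, s in enumerate(sorted(reverse_starts)):
        name = f"R{k + 1}"
        primers.append(Primer(name,
                              reverse_complement(locus.ref[s:s + primer_len]),
                              "reverse"))
        rev_iv[name] = (s, s + primer_len)

    expected: dict[tuple[str, str], bool] = {}
    for fname, (fs, fe) in fwd_iv.items():
        for rname, (rs, re_) in rev_iv.items():
            if rs < fe:
                continue
            disrupted = fs < bp < fe
            spans = fs < bp <= re_
            length_on_ins = (re_ - fs) + (locus.ins_extra if spans else 0)
            expected[(fname, rname)] = (not disrupted
                                        and length_on_ins <= max_len)
    return SimulatedPanel(primers, fwd_iv, rev_iv, expected, max_len)


# ---------------------------------------------------------------------------
# end-to-end assay simulation

def _pair_products(template: str, forward: Primer, reverse: Primer,
                   max_len: int) -> list[int]:
    """ok product lengths for one primer pair on one chromosome template."""
    fsites = find_primer_sites(template, forward)
    rsites = find_primer_sites(template, reverse)
    out = []
    for (fs, fe), _ in fsites:
        for (rs, re_), _ in rsites:
            if rs >= fe and re_ - fs <= max_len:
                out.append(re_ - fs)
    return out


def genotype_by_long_pcr(locus: SimulatedLocus, record: TwoLocusGenotype,
                         forward: Primer, reverse: Primer,
                         max_len: int = 10_000,
                         tolerance: int = 10) -> Optional[str]:
    """Insertion genotype of one individual by long-range sizing PCR.

    Runs the primer pair on both chromosome templates, pools the
    product sizes, and calls the genotype from them — the in-silico twin
    of the 1112 bp (WT) / 2232 bp (Ins) sizing assay.
    """
    if record.phase is None:
        raise PhaseRequiredError(f"{record.sample_id}: phase required")
    (fs, fe), = [iv for iv, _ in find_primer_sites(locus.ref, forward)]
    (rs, re_), = [iv for iv, _ in find_primer_sites(locus.ref, reverse)]
    expected = {"WT": re_ - fs, "Ins": re_ - fs + locus.ins_extra}
    observed: set[int] = set()
    for hap in record.phase:
        observed.update(_pair_products(locus.template(hap), forward, reverse,
                                       max_len))
    return call_genotype_from_sizes(observed, expected, tolerance)


def rflp_snp_call(locus: SimulatedLocus, record: TwoLocusGenotype,
                  forward: Primer, reverse: Primer,
                  max_len: int = 700) -> Optional[str]:
    """Apparent SNP genotype of one individual by PCR-RFLP.

    Each chromosome template is amplified separately; chromosomes whose
    product exceeds ``max_len`` (the insertion allele, when the forward
    primer sits upstream of the breakpoint) contribute nothing.  Each
    product is digested; a cut product reports the M allele, an uncut
    one the I allele.  Returns the apparent genotype or ``None`` when no
    chromosome yields product.
    """
    if record.phase is None:
        raise PhaseRequiredError(f"{record.sample_id}: phase required")
    alleles: list[str] = []
    for hap in record.phase:
        template = locus.template(hap)
        for (fs, fe), _ in find_primer_sites(template, forward):
            for (rs, re_), _ in find_primer_sites(template, reverse):
                if rs < fe or re_ - fs > max_len:
                    continue
                product = template[fs:re_]
                fragments = digest(product, locus.params.enzyme)
                alleles.append("I" if fragments == [len(product)] else "M")
    if not alleles:
        return None
    alleles = sorted(set(alleles))
    if alleles == ["I"]:
        return "I/I"
    if alleles == ["M"]:
        return "M/M"
    return "I/M"


def snp_primer_pair(locus: SimulatedLocus, upstream_of_breakpoint: bool,
                    primer_len: int = 20, margin: int = 40,
                    ) -> tuple[Primer, Primer]:
    """A forward/reverse pair bracketing the SNP.

    With ``upstream_of_breakpoint`` the forward primer sits before the
    insertion site — the mis-designed assay whose insertion-bearing
    chromosomes drop out; otherwise it sits between breakpoint and SNP
    (the safe design).
    """
    bp = locus.insertion.breakpoint
    if upstream_of_breakpoint:
        fs = bp - margin - primer_len
    else:
        fs = bp + 12
        if fs + primer_len + margin >= locus.snp_pos:
            raise ValueError("no room for a safe forward primer")
    rs = locus.snp_pos + margin
    from Bio.Seq import reverse_complement
    fwd = Primer("snpF", locus.ref[fs:fs + primer_len], "forward")
    rev = Primer("snpR", reverse_complement(
        locus.ref[rs:rs + primer_len]), "reverse")
    return fwd, rev


# ---------------------------------------------------------------------------
# qPCR plates

def simulate_qpcr(effects: dict[str, float], n_per_group: dict[str, int],
                  noise_sd: float, seed: int = 0, replicates: int = 3,
                  target_assay: str = "target", reference_assay: str = "ref",
                  baseline_ref_ct: float = 22.0, baseline_delta_ct: float = 4.0,
                  ) -> list[QpcrMeasurement]:
    """Triplicate Ct plates with group-level log2 fold changes.

    Each sample's true target quantity is scaled by 2**effect for its
    group, i.e. its target Ct is lowered by the effect; every replicate
    of both assays gets independent Gaussian noise of ``noise_sd``
    cycles.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    rng = np.random.default_rng(seed)
    out: list[QpcrMeasurement] = []
    for group, n in n_per_group.items():
        effect = effects.get(group, 0.0)
        for i in range(n):
            sid = f"{group}_{i:03d}"
            ref_cts = baseline_ref_ct + rng.normal(0, noise_sd, replicates) \
                if noise_sd > 0 else np.full(replicates, baseline_ref_ct)
            tgt_mean = baseline_ref_ct + baseline_delta_ct - effect
            tgt_cts = tgt_mean + rng.normal(0, noise_sd, replicates) \
                if noise_sd > 0 else np.full(replicates, tgt_mean)
            out.append(QpcrMeasurement(sid, reference_assay, group,
                                       tuple(ref_cts)))
            out.append(QpcrMeasurement(sid, target_assay, group,
                                       tuple(tgt_cts)))
    return out
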