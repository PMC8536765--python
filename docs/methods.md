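# Methods

## The model

Two biallelic loci ~122 bp apart on one chromosome: a structural locus
(WT vs Ins, presence of a LINE-1 insertion) and a SNP (I vs M, PNPLA3
I148M). At that distance recombination between them is negligible, so a
chromosome is one of four haplotypes with frequencies
a = f(WT-I), b = f(WT-M), c = f(Ins-I), d = f(Ins-M), a+b+c+d = 1.
Individuals are random unions of two gametes drawn i.i.d. from their
group's haplotype frequencies; the case/control contrast is encoded
directly as different frequencies per group, with no explicit disease
model. The studied locus pair has d = 0 (complete coupling of the
insertion with the I allele), which the machinery treats as an ordinary
point of the parameter space, not a special case.

## Association statistics

Allele frequencies come from genotype triples as (het + 2·hom)/2n.
Hardy-Weinberg is a 1-df chi-square goodness of fit against (p², 2pq,
q²); a monomorphic locus is reported as trivial equilibrium (chi2 = 0,
p = 1) rather than undefined. Contingency tests are Pearson chi-square
without continuity correction (scipy), plus the two-sided Fisher exact
test for 2x2 tables. Odds ratios use the cross-product with the Woolf
interval exp(ln OR ± 1.96·√Σ1/cell); any zero cell makes the OR and CI
undefined and they are reported "na" — no Haldane-Anscombe 0.5
correction, because an absent haplotype class (d = 0) is a finding, not
a numerical nuisance.

Two deliberate choices follow the source data rather than the source
narrative. First, although the study text names the Fisher exact test,
every printed p-value is reproduced to printed precision by the
uncorrected chi-square; report p-values therefore use chi-square, with
Fisher computed alongside and labelled. Second, the printed "global"
haplotype p is not reproducible from a plain 2xK chi-square on the
haplotype table; the report carries the plain chi-square value with an
explicit caveat and the reproduction checks exclude it.

Report rounding is half away from zero at the printed precision
(2 decimals for ORs/CIs, 3 for frequencies and p-values); the
reproduction checks use half-ULP tolerances, |delta| <= 0.005 and
0.0005 respectively.

## Haplotype estimation and LD

Phased cohorts are counted directly. For unphased 3x3 joint genotype
counts, only the double heterozygote (WT/Ins + I/M) is ambiguous
between the coupling phasings (WT-I, Ins-M) and (WT-M, Ins-I); the EM
step splits that class in proportion a·d : b·c at the current estimate,
starting from (0.25, 0.25, 0.25, 0.25) and iterating to a 1e-8 change
tolerance (cap 10,000 iterations; in practice tens suffice). The
log-likelihood is available per iteration and is non-decreasing (an EM
guarantee the tests assert). No rare-haplotype trimming is applied —
the rare class d is exactly the quantity of interest.

D is computed on the (Ins, M) allele pair, D = d − p_Ins·p_M, so the
studied geometry (Ins coupled with I) gives D < 0; D' is reported as
|D|/D_max with the usual sign-dependent D_max, and r² as
D²/(p_Ins q_Ins p_M q_M). Both are undefined (None, not 0) when a locus
is monomorphic, to avoid spurious "no LD" readings. LD on the study
tables is pooled over cases and controls by default (the published
estimate pools 289 individuals); per-group statistics are available.

## Dropout model

The blocked-primer scenario is all-or-nothing: an insertion-bearing
chromosome yields no product. Ins/Ins individuals are no-calls and are
excluded (not imputed) — this is how the phenomenon was noticed, as
unexplained PCR failures; WT/Ins individuals appear homozygous for
their WT-chromosome SNP allele; WT/WT calls are untouched. A
dropout-probability parameter exists for partial dropout but defaults
to 1. Phase for double heterozygotes comes from the record or, under an
explicit assume-complete-linkage flag, from the d = 0 geometry (Ins
always carries I, so the M allele must sit on the WT chromosome);
anything else raises rather than guesses.

The closed form assumes random union of gametes: every surviving
chromosome is a WT chromosome, so the expected apparent M frequency is
b/(a+b) and the expected no-call fraction (c+d)². The empirical
transform makes no mating assumption; the two routes are cross-checked
by Monte-Carlo at n = 100,000 (observed |delta| ~ 2e-4, asserted
< 0.005). At the pooled study frequencies (a, b, c, d) =
(0.299, 0.299, 0.401, 0), b/(a+b) = 0.500. The study's own
per-individual data put the apparent frequency at 0.47; that dataset is
a supplementary file not printed in the article text, and the 0.50
expectation differs from it only through the cohort's deviation from
exact HWE diplotype proportions. The bias-surface generalization
constructs (a, b, c, d) from (p_Ins, D', p_M) with Ins-I coupling and
is feasible by construction for p_Ins < 1; p_Ins = 1 rows are flagged
infeasible (no WT chromosome left to observe).

## In-silico PCR

Coordinates are 0-based half-open; a 1-based HGVS gap position
g.X_X+1ins maps to gap index X. The insertion allele is
ref[:bp] + insert + ref[bp−tsd:bp] + ref[bp:], i.e. the tsd bases left
of the breakpoint flank the insert on both sides, so
len(Ins) = len(WT) + insert + tsd. Primer matching is string-based with
mismatches allowed only outside an exact 3'-terminal anchor (default 3
nt); thermodynamics are out of scope because the modelled phenomenon is
positional. Amplicons pair every forward site with every downstream
reverse site; products beyond max_len are emitted as too_long (no
product). max_len is the polymerase's effective ceiling: ~700 bp for
the short-range chemistry, 2,500 default, 10,000 for long-range.
Digestion cuts at site_end + cut_offset_top for plus-strand recognition
sites and site_start − cut_offset_bottom for minus-strand sites (BtsCI
GGATG(2/0) ships as the default enzyme); fragments always partition the
input. Size-based genotype calls require expected allele lengths
separated by more than twice the tolerance (default 10 bp) and raise on
unassignable products.

Breakpoint localization takes (forward interval, reverse interval,
success) triples: the candidate region is the intersection of the
failed amplicon spans minus the union of successful spans and
successful primer footprints, half-open throughout. No failures means
no element detected; a non-empty failure set whose evidence cancels
entirely is reported as an inconsistent panel. A known edge of the
half-open convention: an element sitting exactly on an amplicon
boundary is convention-dependent, so the simulated panels keep the
breakpoint strictly interior.

The assay's printed product sizes (1112 bp WT, 2232 bp Ins) imply a
1120 bp insertion footprint, while the characterised insert plus TSD is
1114 + 16 = 1130; the source itself flags homopolymer-length
uncertainty in the insert sequence. The two numbers are parameterized
independently: sizing fixtures reproduce 1112/2232, sequence-simulation
defaults use 1114 + 16.

## qPCR

Per sample, dCt = mean Ct(target) − mean Ct(reference) over replicates;
ddCt subtracts the median dCt of the calibrator group (median, not
mean, to match median/IQR reporting); quantity = 2^−ddCt × 100%, so the
calibrator median is exactly 100%. Amplification efficiency is fixed at
2.0 (none reported to calibrate against). The allele-specific ratio is
the same construction with the M-allele assay as the within-sample
reference. Mann-Whitney is exact by full enumeration (tie-safe) for
combined n <= 12 and a tie- and continuity-corrected normal
approximation above — the threshold places the study's 12-vs-7
comparison in the approximation branch. The published group medians
(145%, 93%, ...) are not reproduction targets: raw Cts are not printed,
so the module is validated by construction on synthetic plates with
known fold changes and by a null type-I-error check (~0.05 over 1,000
seeded plates at n = 12 vs 7, sd 0.2 cycles).

## Synthetic data

Generators are deterministic given their seed (numpy default_rng);
multi-stage drivers derive stage seeds from one global seed. Cohort
simulation draws 2n haplotypes i.i.d. per group — so marginal genotypes
are HWE-consistent, which the tests verify as a near-nominal HWE
rejection rate across seeds. Sequence simulation uses random ACGT
scrubbed of the enzyme's recognition site on both strands, then plants
the site's first k−1 bases before the SNP so that exactly one SNP
allele completes a recognition site: RFLP-typeability holds by
construction. The insert is the verbatim homopolymeric filler motif
(T)14 GGTGATG (T)34 plus a scrubbed random body — no real LINE-1
sequence is claimed. Default geometry: 5,000 bp reference, breakpoint
at 2,400, insert 1,114 nt, TSD 16 nt, SNP 122 bp downstream (1-based),
matching the characterised locus. Panel simulation places forward
primers at ~150 bp spacing upstream of the breakpoint plus one 12 bp
downstream of it (the escape primer), reverse primers downstream of the
SNP, with seeded jitter; expected success on the insertion allele is
computed from geometry (primer not interrupted, product within
max_len = 700 for short-range chemistry).

What the synthetic data does not emulate: genotyping error other than
structural blocking, partial allelic imbalance, contamination,
population structure, recombination between the loci, read-level
sequencing noise, or qPCR efficiency drift. Tests passing on this data
show the estimators and transforms are correct under the stated model,
not that real assays are free of those additional effects.

A per-individual cohort consistent with all published count tables is
used in tests (tests/conftest.py): the three printed tables leave one
free parameter per group (the split of WT/WT individuals between SNP
genotypes given the margins), fixed at its HWE expectation. It is a
synthetic stand-in — the study's true per-individual table is a
supplementary file not printed in the article — and is labelled as such
where it is defined.

## Problem sizes

Defaults were chosen so the entire pipeline is desk-scale: Monte-Carlo
dropout at n = 100,000 individuals, EM recovery at n = 5,000,
type-I-error calibration over 1,000 plates, property tests at 50-150
examples each. The full test suite runs in well under a minute.
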