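import pytest

from linedrop.cohort import TwoLocusCohort, TwoLocusGenotype, HAPLOTYPES
from linedrop.simulate import SequenceSimParams, simulate_sequences

_HAP_ORDER = {h: i for i, h in enumerate(HAPLOTYPES)}

# Synthetic per-individual realization of the study cohort: diplotype
# counts chosen to reproduce, simultaneously, the published WT/Ins
# genotype counts, I148M genotype counts and haplotype chromosome counts
# for both groups.  Those tables leave one degree of freedom per group
# (how WT/WT splits between I/I, I/M given the margins); it is fixed at
# the Hardy-Weinberg expectation.  The study's true per-individual table
# is not printed, so this is a stand-in consistent with everything that is.
STUDY_DIPLOTYPES = {
    "case": {("WT-I", "WT-I"): 8, ("WT-I", "WT-M"): 21,
             ("WT-M", "WT-M"): 16, ("WT-I", "Ins-I"): 25,
             ("WT-M", "Ins-I"): 35, ("Ins-I", "Ins-I"): 17},
    "control": {("WT-I", "WT-I"): 18, ("WT-I", "WT-M"): 24,
                ("WT-M", "WT-M"): 12, ("WT-I", "Ins-I"): 51,
                ("WT-M", "Ins-I"): 37, ("Ins-I", "Ins-I"): 25},
}


def cohort_from_diplotypes(diplotypes_by_group):
    """Deterministic phased cohort realizing exact diplotype counts."""
    records = []
    for group, diplotypes in diplotypes_by_group.items():
        i = 0
        for pair, n in diplotypes.items():
            pair = tuple(sorted(pair, key=_HAP_ORDER.__getitem__))
            ins = sorted(h.split("-")[0] for h in pair)
            snp = sorted(h.split("-")[1] for h in pair)
            ins_gt = {("Ins", "Ins"): "Ins/Ins", ("Ins", "WT"): "WT/Ins",
                      ("WT", "WT"): "WT/WT"}[tuple(ins)]
            for _ in range(n):
                records.append(TwoLocusGenotype(f"{group}_{i:04d}", group,
                                                ins_gt, "/".join(snp), pair))
                i += 1
    return TwoLocusCohort(records)


@pytest.fixture(scope="session")
def study_cohort():
    """Synthetic phased cohort consistent with every printed count table."""
    return cohort_from_diplotypes(STUDY_DIPLOTYPES)


@pytest.fixture(scope="session")
def locus():
    """One simulated locus shared across sequence-level tests."""
    return simulate_sequences(SequenceSimParams(seed=11))
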