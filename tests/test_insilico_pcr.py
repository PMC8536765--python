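import numpy as np
import pytest
from Bio.Seq import reverse_complement
from hypothesis import given, settings, strategies as st

from linedrop.pcr import (BTSCI, Enzyme, InconsistentPanelError,
                          InsertionSpec, Primer, UnexpectedProductError,
                          build_templates, call_genotype_from_sizes, digest,
                          find_primer_sites, localize_insertion,
                          predict_amplicons)

RNG = np.random.default_rng(42)
BASES = np.array(list("ACGT"))


def random_seq(n, rng=RNG):
    return "".join(rng.choice(BASES, size=n))


class TestBuildTemplates:
    def test_length_arithmetic_matches_locus_geometry(self):
        ref = random_seq(5000)
        wt, ins = build_templates(ref, InsertionSpec(2400, random_seq(1114),
                                                     tsd_len=16))
        assert len(wt) == 5000 and len(ins) == 5000 + 1114 + 16

    def test_empty_insert_is_identity(self):
        ref = random_seq(100)
        wt, ins = build_templates(ref, InsertionSpec(50, "", tsd_len=0))
        assert ins == wt == ref

    def test_target_site_duplication_count_increments(self):
        ref = random_seq(400)
        spec = InsertionSpec(200, random_seq(60), tsd_len=16)
        wt, ins = build_templates(ref, spec)
        tsd = ref[184:200]
        assert ins.count(tsd) == wt.count(tsd) + 1

    def test_geometry_errors(self):
        with pytest.raises(ValueError):
            build_templates("ACGT" * 10, InsertionSpec(100, "A"))
        with pytest.raises(ValueError):
            InsertionSpec(5, "A", tsd_len=6)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(0, 200), st.integers(0, 120), st.integers(0, 30),
           st.integers(0))
    def test_length_identity_property(self, bp, ins_len, tsd, seed):
        rng = np.random.default_rng(seed)
        ref = random_seq(200, rng)
        tsd = min(tsd, bp)
        insert = random_seq(ins_len, rng) if ins_len else ""
        _, ins = build_templates(ref, InsertionSpec(bp, insert, tsd))
        assert len(ins) == len(ref) + ins_len + tsd


class TestPrimerSites:
    def test_forward_exact_site(self):
        t = random_seq(400)
        p = Primer("F", t[100:120], "forward")
        assert find_primer_sites(t, p) == [((100, 120), "+")]

    def test_reverse_site_is_reverse_complement(self):
        t = random_seq(400)
        p = Primer("R", reverse_complement(t[200:220]), "reverse")
        assert find_primer_sites(t, p) == [((200, 220), "-")]

    def test_mismatch_tolerated_outside_anchor_only(self):
        t = "A" * 50 + "ACGTACGTACGTACGTACGT" + "A" * 50
        primer = "TCGTACGTACGTACGTACGT"  # mismatch at 5' end
        assert find_primer_sites(t, Primer("F", primer, "forward"),
                                 max_mismatch=1) == [((50, 70), "+")]
        assert find_primer_sites(t, Primer("F", primer, "forward"),
                                 max_mismatch=0) == []
        threeprime = "ACGTACGTACGTACGTACGA"  # mismatch inside the 3' anchor
        assert find_primer_sites(t, Primer("F", threeprime, "forward"),
                                 max_mismatch=3) == []

    def test_primer_spanning_breakpoint_lost_on_insertion_allele(self):
        # tsd_len=0: with a TSD, the duplicated bases can rebuild most of
        # a spanning primer's site at the insert junction by chance
        rng = np.random.default_rng(99)
        ref = random_seq(600, rng)
        wt, ins = build_templates(ref, InsertionSpec(300, random_seq(80, rng),
                                                     tsd_len=0))
        p = Primer("F", ref[290:310], "forward")  # straddles the breakpoint
        assert find_primer_sites(wt, p) == [((290, 310), "+")]
        assert find_primer_sites(ins, p) == []


def sizing_fixture():
    """WT/Ins template pair whose primer pair yields the assay's printed
    1112 / 2232 bp products (insert sized to the observed 1120 bp gap)."""
    rng = np.random.default_rng(7)
    ref = random_seq(3000, rng)
    wt, ins = build_templates(ref, InsertionSpec(1500, random_seq(1104, rng),
                                                 tsd_len=16))
    fwd = Primer("6L", ref[1000:1020], "forward")
    rev = Primer("1R", reverse_complement(ref[2092:2112]), "reverse")
    return wt, ins, fwd, rev


class TestPredictAmplicons:
    def test_wt_product_is_1112(self):
        wt, _, fwd, rev = sizing_fixture()
        amps = predict_amplicons({"WT": wt}, [fwd, rev], max_len=2500)
        assert [(a.length, a.status) for a in amps] == [(1112, "ok")]

    def test_ins_product_is_2232_with_long_range(self):
        _, ins, fwd, rev = sizing_fixture()
        amps = predict_amplicons({"Ins": ins}, [fwd, rev], max_len=10_000)
        assert [(a.length, a.status) for a in amps] == [(2232, "ok")]

    def test_ins_product_fails_short_range(self):
        _, ins, fwd, rev = sizing_fixture()
        amps = predict_amplicons({"Ins": ins}, [fwd, rev], max_len=1500)
        assert [a.status for a in amps] == ["too_long"]

    def test_monotone_in_max_len(self):
        wt, ins, fwd, rev = sizing_fixture()
        templates = {"WT": wt, "Ins": ins}
        for lo, hi in [(700, 1500), (1500, 2500), (2500, 10_000)]:
            ok_lo = {(a.template, a.start, a.end) for a in
                     predict_amplicons(templates, [fwd, rev], max_len=lo)
                     if a.status == "ok"}
            ok_hi = {(a.template, a.start, a.end) for a in
                     predict_amplicons(templates, [fwd, rev], max_len=hi)
                     if a.status == "ok"}
            assert ok_lo <= ok_hi

    def test_panel_needs_both_orientations(self):
        wt, _, fwd, _ = sizing_fixture()
        with pytest.raises(ValueError):
            predict_amplicons({"WT": wt}, [fwd])


class TestDigest:
    def test_single_top_strand_site(self):
        # GGATG occupying [10, 15), offsets (2, 0): top cut at 17
        seq = "A" * 10 + "GGATG" + "A" * 35
        assert digest(seq, BTSCI) == [17, 33]

    def test_minus_strand_site_uses_bottom_offset(self):
        # CATCC on top = GGATG on bottom; cut at site start - 0 = 20
        seq = "A" * 20 + "CATCC" + "A" * 25
        assert digest(seq, BTSCI) == [20, 30]

    def test_no_site_returns_whole_sequence(self):
        assert digest("A" * 60, BTSCI) == [60]

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.integers(0), st.integers(20, 300), st.integers(0, 4),
           st.integers(0, 4))
    def test_fragments_partition_sequence(self, seed, n, off_top, off_bot):
        rng = np.random.default_rng(seed)
        seq = random_seq(n, rng)
        enzyme = Enzyme("X", random_seq(rng.integers(4, 7), rng),
                        off_top, off_bot)
        fragments = digest(seq, enzyme)
        assert sum(fragments) == n
        assert all(f > 0 for f in fragments)


class TestGenotypeCalls:
    EXPECTED = {"WT": 1112, "Ins": 2232}

    @pytest.mark.parametrize("observed,call", [
        ({1112}, "WT/WT"),
        ({2232}, "Ins/Ins"),
        ({1112, 2232}, "WT/Ins"),
        (set(), None),
    ])
    def test_size_based_calls(self, observed, call):
        assert call_genotype_from_sizes(observed, self.EXPECTED) == call

    def test_within_tolerance_sizes_accepted(self):
        assert call_genotype_from_sizes({1105, 2240}, self.EXPECTED) \
            == "WT/Ins"

    def test_unexpected_product_raises(self):
        with pytest.raises(UnexpectedProductError):
            call_genotype_from_sizes({1500}, self.EXPECTED)

    def test_unseparable_expected_lengths_rejected(self):
        with pytest.raises(ValueError, match="separable"):
            call_genotype_from_sizes({100}, {"WT": 100, "Ins": 110},
                                     tolerance=10)


class TestLocalize:
    def test_interval_set_arithmetic(self):
        res = localize_insertion([
            (((400, 420)), ((880, 900)), False),
            (((520, 540)), ((880, 900)), True),
        ])
        assert res.element_detected
        assert res.intervals == [(400, 520)]

    def test_all_successful_means_nothing_detected(self):
        res = localize_insertion([((10, 30), (200, 220), True)])
        assert not res.element_detected and res.intervals == []

    def test_contradictory_panel_raises(self):
        with pytest.raises(InconsistentPanelError):
            localize_insertion([
                ((100, 120), (300, 320), False),
                ((100, 120), (300, 320), True),
            ])
        with pytest.raises(InconsistentPanelError):
            localize_insertion([
                ((100, 120), (200, 220), False),
                ((400, 420), (500, 520), False),
            ])

    def test_primer_walking_geometry_brackets_breakpoint(self):
        # breakpoint at 4921, variant at 5042: forwards at the published
        # offsets relative to the variant (-607..+12), reverses downstream;
        # only the +12 forward escapes the insertion
        bp, snp = 4921, 5042
        fwd_offsets = [-607, -380, -130, 12]
        forwards = [(snp + off, snp + off + 20) for off in fwd_offsets]
        reverses = [(snp + 90, snp + 110), (snp + 260, snp + 280)]
        results = []
        for f in forwards:
            for r in reverses:
                ok = f[0] > bp  # spanning reactions fail on the Ins allele
                results.append((f, r, ok))
        res = localize_insertion(results)
        lo, hi = res.interval
        assert lo <= bp < hi
        width = hi - lo
        assert 100 <= width <= 160  # the walking resolution of the panel

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(0))
    def test_consistent_random_panels_bracket_the_breakpoint(self, seed):
        # even primer coordinates, odd breakpoint: the element can never
        # sit exactly on an amplicon edge, where success is convention-bound
        rng = np.random.default_rng(seed)
        bp = 2 * int(rng.integers(250, 750)) + 1
        results = []
        n_fail = 0
        for _ in range(rng.integers(3, 9)):
            fs = 2 * int(rng.integers(0, 950))
            rs = 2 * int(rng.integers(fs // 2 + 20, 990))
            f, r = (fs, fs + 20), (rs, rs + 20)
            ok = not (fs < bp < rs + 20)
            n_fail += not ok
            results.append((f, r, ok))
        if n_fail == 0:
            assert not localize_insertion(results).element_detected
            return
        res = localize_insertion(results)
        assert any(lo <= bp < hi for lo, hi in res.intervals)
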