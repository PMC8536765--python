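"""Sequence-level simulation of insertion-aware PCR genotyping assays.

Covers: construction of WT and insertion-bearing templates (with the
target-site duplication that flanks a retrotransposon insert), string
matching of primers with a 3'-anchor rule, amplicon prediction with
size-based failure, restriction digestion with asymmetric cutters such
as BtsCI (GGATG 2/0), genotype calling from observed product sizes, and
localization of a blocking element from a panel of successful and
failed reactions.

All coordinates are 0-based half-open.  A 1-based HGVS-style insertion
position ``g.X_X+1ins`` corresponds to gap index ``X`` here.  Primer
matching is purely positional (no melting temperature): mismatches are
allowed outside the 3'-terminal anchor, which must match exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

from Bio.Seq import reverse_complement

_VALID_BASES = set("ACGT")


class SequenceError(ValueError):
    pass


class UnexpectedProductError(ValueError):
    """An observed product length matches no expected allele."""


class InconsistentPanelError(ValueError):
    """A primer panel's success/failure pattern admits no blocking element."""


def _check_seq(seq: str, what: str = "sequence") -> str:
    seq = seq.upper()
    if not seq:
        raise SequenceError(f"empty {what}")
    bad = set(seq) - _VALID_BASES
    if bad:
        raise SequenceError(
            f"{what} contains non-ACGT characters {sorted(bad)} "
            f"(degenerate bases are rejected)")
    return seq


@dataclass(frozen=True)
class InsertionSpec:
    """An insertion with a target-site duplication.

    ``breakpoint`` is a 0-based gap index into the reference; the
    ``tsd_len`` bases immediately left of it are duplicated so they
    flank the insert on both sides.  The inserted allele is
    ``ref[:bp] + insert_seq + ref[bp-tsd:bp] + ref[bp:]``, hence
    len(Ins) = len(WT) + len(insert_seq) + tsd_len.
    """

    breakpoint: int
    insert_seq: str
    tsd_len: int = 0

    def __post_init__(self) -> None:
        if self.breakpoint < 0:
            raise ValueError("breakpoint must be nonnegative")
        if self.tsd_len < 0:
            raise ValueError("tsd_len must be nonnegative")
        if self.tsd_len > self.breakpoint:
            raise ValueError("tsd_len exceeds breakpoint")


@dataclass(frozen=True)
class Primer:
    """A PCR primer, sequence written 5' to 3'."""

    name: str
    sequence: str
    orientation: str  # forward | reverse

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence",
                           _check_seq(self.sequence, f"primer {self.name}"))
        if self.orientation not in ("forward", "reverse"):
            raise ValueError(f"bad orientation {self.orientation!r}")


@dataclass(frozen=True)
class Amplicon:
    """A predicted PCR product on one template."""

    template: str
    start: int
    end: int
    status: str  # ok | too_long | primer_disrupted
    forward: str = ""
    reverse: str = ""

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Enzyme:
    """A restriction enzyme with cut offsets past the recognition end.

    Offsets follow the catalogue (top/bottom) notation: BtsCI is
    GGATG(2/0) — top-strand cut two bases downstream of the site, bottom
    cut immediately after it.
    """

    name: str
    recognition: str
    cut_offset_top: int
    cut_offset_bottom: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "recognition",
                           _check_seq(self.recognition,
                                      f"recognition site of {self.name}"))


BTSCI = Enzyme("BtsCI", "GGATG", 2, 0)


def load_enzyme(path: str | Path) -> Enzyme:
    """Read an enzyme config JSON: {name, recognition, cut_top, cut_bottom}."""
    cfg = json.loads(Path(path).read_text())
    return Enzyme(cfg["name"], cfg["recognition"],
                  int(cfg["cut_top"]), int(cfg["cut_bottom"]))


# ---------------------------------------------------------------------------
# templates

def build_templates(ref: str, spec: InsertionSpec) -> tuple[str, str]:
    """Return (WT template, insertion template) for a reference sequence."""
    ref = _check_seq(ref, "reference")
    bp = spec.breakpoint
    if bp > len(ref):
        raise ValueError(f"breakpoint {bp} beyond reference end {len(ref)}")
    insert = _check_seq(spec.insert_seq, "insert") if spec.insert_seq else ""
    tsd = ref[bp - spec.tsd_len:bp]
    ins_allele = ref[:bp] + insert + tsd + ref[bp:]
    return ref, ins_allele


# ---------------------------------------------------------------------------
# primer matching

def _mismatches_outside_anchor(window: str, pattern: str, anchor_at_end: bool,
                               anchor: int) -> Optional[int]:
    """Mismatch count, or None if the exact-match anchor fails."""
    L = len(pattern)
    anchor = min(anchor, L)
    if anchor_at_end:
        if window[L - anchor:] != pattern[L - anchor:]:
            return None
        body = range(0, L - anchor)
    else:
        if window[:anchor] != pattern[:anchor]:
            return None
        body = range(anchor, L)
    return sum(1 for i in body if window[i] != pattern[i])


def find_primer_sites(template: str, primer: Primer, max_mismatch: int = 0,
                      anchor_3prime: int = 3,
                      ) -> list[tuple[tuple[int, int], str]]:
    """All binding sites of a primer on a template.

    Forward primers are matched on the plus strand (3' end rightmost);
    reverse primers as their reverse complement (3' end leftmost on the
    plus strand).  Up to ``max_mismatch`` mismatches are tolerated
    outside the 3'-terminal ``anchor_3prime`` bases, which must match
    exactly.  Returns ``((start, end), strand)`` tuples in template
    coordinates.
    """
    template = _check_seq(template, "template")
    L = len(primer.sequence)
    if L >= len(template):
        raise ValueError("primer not shorter than template")
    if primer.orientation == "forward":
        pattern, strand, anchor_at_end = primer.sequence, "+", True
    else:
        pattern, strand, anchor_at_end = (reverse_complement(primer.sequence),
                                          "-", False)
    sites = []
    for i in range(len(template) - L + 1):
        mm = _mismatches_outside_anchor(template[i:i + L], pattern,
                                        anchor_at_end, anchor_3prime)
        if mm is not None and mm <= max_mismatch:
            sites.append(((i, i + L), strand))
    return sites


# ---------------------------------------------------------------------------
# amplification

def predict_amplicons(templates: dict[str, str], panel: Sequence[Primer],
                      max_len: int = 2500, max_mismatch: int = 0,
                      anchor_3prime: int = 3) -> list[Amplicon]:
    """Predicted products for every forward x downstream-reverse site pair.

    An amplicon spans [forward site start, reverse site end); products
    longer than ``max_len`` are emitted with status ``too_long`` (no
    product in the tube).  ``max_len`` defaults to a standard-PCR 2.5 kb;
    use ~10 kb for long-range chemistry.
    """
    forwards = [p for p in panel if p.orientation == "forward"]
    reverses = [p for p in panel if p.orientation == "reverse"]
    if not forwards or not reverses:
        raise ValueError("panel needs at least one forward and one reverse "
                         "primer")
    out: list[Amplicon] = []
    for label, seq in templates.items():
        fsites = [(p.name, iv) for p in forwards
                  for iv, _ in find_primer_sites(seq, p, max_mismatch,
                                                 anchor_3prime)]
        rsites = [(p.name, iv) for p in reverses
                  for iv, _ in find_primer_sites(seq, p, max_mismatch,
                                                 anchor_3prime)]
        for fname, (fs, fe) in fsites:
            for rname, (rs, re_) in rsites:
                if rs < fe:
                    continue  # reverse site must lie downstream
                length = re_ - fs
                status = "too_long" if length > max_len else "ok"
                out.append(Amplicon(label, fs, re_, status, fname, rname))
    return out


def amplicon_sequences(templates: dict[str, str],
                       amplicons: Iterable[Amplicon]) -> dict[str, list[str]]:
    """Sequences of the ok products, grouped by template label."""
    out: dict[str, list[str]] = {k: [] for k in templates}
    for amp in amplicons:
        if amp.status == "ok":
            out[amp.template].append(templates[amp.template][amp.start:amp.end])
    return out


# ---------------------------------------------------------------------------
# digestion

def digest(seq: str, enzyme: Enzyme) -> list[int]:
    """Fragment lengths after a complete double-strand digestion.

    Every occurrence of the recognition sequence on either strand cuts
    once: plus-strand sites at ``site_end + cut_offset_top``,
    minus-strand sites at ``site_start - cut_offset_bottom`` (the
    bottom-strand geometry mirrored into top coordinates).  Cuts falling
    outside the sequence are clamped away; fragments are reported 5' to
    3' and always partition the sequence.
    """
    seq = _check_seq(seq)
    rec = enzyme.recognition
    rc = reverse_complement(rec)
    cuts: set[int] = set()
    start = seq.find(rec)
    while start != -1:
        cuts.add(start + len(rec) + enzyme.cut_offset_top)
        start = seq.find(rec, start + 1)
    if rc != rec:
        start = seq.find(rc)
        while start != -1:
            cuts.add(start - enzyme.cut_offset_bottom)
            start = seq.find(rc, start + 1)
    positions = sorted(c for c in cuts if 0 < c < len(seq))
    bounds = [0] + positions + [len(seq)]
    return [b - a for a, b in zip(bounds, bounds[1:])]


# ---------------------------------------------------------------------------
# genotype calling

def call_genotype_from_sizes(observed: Iterable[int],
                             expected: dict[str, int],
                             tolerance: int = 10) -> Optional[str]:
    """Size-based genotype call from observed product lengths.

    ``expected`` maps allele name ("WT", "Ins") to product length;
    lengths must be separated by more than twice the tolerance.  Returns
    "WT/WT", "Ins/Ins", "WT/Ins", or ``None`` for no product at all.
    Raises :class:`UnexpectedProductError` for an unassignable length.
    """
    alleles = list(expected)
    lengths = list(expected.values())
    for i in range(len(lengths)):
        for j in range(i + 1, len(lengths)):
            if abs(lengths[i] - lengths[j]) <= 2 * tolerance:
                raise ValueError("expected allele lengths are not separable "
                                 "at this tolerance")
    seen: set[str] = set()
    for size in observed:
        matched = [a for a in alleles if abs(expected[a] - size) <= tolerance]
        if not matched:
            raise UnexpectedProductError(
                f"product of {size} bp matches no expected allele "
                f"{expected}")
        seen.add(matched[0])
    if not seen:
        return None
    if seen == {"WT"}:
        return "WT/WT"
    if seen == {"Ins"}:
        return "Ins/Ins"
    return "WT/Ins"


# ---------------------------------------------------------------------------
# breakpoint localization

@dataclass
class LocalizationResult:
    """Candidate interval(s) for a blocking element, WT coordinates."""

    intervals: list[tuple[int, int]]
    element_detected: bool

    @property
    def interval(self) -> tuple[int, int]:
        if not self.intervals:
            raise ValueError("no candidate interval")
        return self.intervals[0]


def _subtract(intervals: list[tuple[int, int]],
              holes: list[tuple[int, int]]) -> list[tuple[int, int]]:
    for hs, he in holes:
        nxt = []
        for s, e in intervals:
            if he <= s or hs >= e:
                nxt.append((s, e))
                continue
            if s < hs:
                nxt.append((s, hs))
            if he < e:
                nxt.append((he, e))
        intervals = nxt
    return intervals


def localize_insertion(panel_results: Sequence[tuple[tuple[int, int],
                                                     tuple[int, int], bool]],
                       ) -> LocalizationResult:
    """Infer where a blocking element sits from reaction outcomes.

    Each panel entry is (forward primer interval, reverse primer
    interval, success flag), all on the WT reference.  A failed reaction
    places the element inside its would-be amplicon
    [forward start, reverse end); a successful one excludes the span of
    its amplicon and its primer footprints.  The candidate region is the
    intersection of the failed spans minus the union of the successful
    evidence.

    No failed reaction at all means no element was detected.  Failures
    whose evidence cancels out entirely are mutually inconsistent with a
    single blocking element and raise :class:`InconsistentPanelError`.
    """
    failed = [(f[0], r[1]) for f, r, ok in panel_results if not ok]
    if not failed:
        return LocalizationResult([], element_detected=False)
    lo = max(s for s, _ in failed)
    hi = min(e for _, e in failed)
    if lo >= hi:
        raise InconsistentPanelError("failed amplicons share no region")
    holes: list[tuple[int, int]] = []
    for f, r, ok in panel_results:
        if ok:
            holes.append((f[0], r[1]))
            holes.append(f)
            holes.append(r)
    candidates = _subtract([(lo, hi)], holes)
    if not candidates:
        raise InconsistentPanelError(
            "successful reactions cover every failed region: no single "
            "blocking element explains the panel")
    return LocalizationResult(sorted(candidates), element_detected=True)


# ---------------------------------------------------------------------------
# FASTA / TSV plumbing

def write_fasta(records: dict[str, str], path: str | Path) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    seqs = [SeqRecord(Seq(s), id=name, description="")
            for name, s in records.items()]
    SeqIO.write(seqs, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO
    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(path), "fasta")}


def read_primers(path: str | Path) -> list[Primer]:
    """Primers from FASTA (headers ``name|forward``) or TSV
    (columns name, sequence, orientation)."""
    path = Path(path)
    if path.suffix.lower() in (".fa", ".fasta", ".fna"):
        out = []
        for header, seq in read_fasta(path).items():
            name, _, orient = header.partition("|")
            if orient not in ("forward", "reverse"):
                raise ValueError(f"primer header {header!r} lacks "
                                 f"'|forward' / '|reverse'")
            out.append(Primer(name, seq, orient))
        return out
    out = []
    for line in path.read_text().splitlines():
        if not line.strip() or line.startswith("#") or \
                line.startswith("name\t"):
            continue
        name, seq, orient = line.split("\t")[:3]
        out.append(Primer(name.strip(), seq.strip(), orient.strip()))
    return out
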