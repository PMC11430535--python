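"""Allele-specific PCR marker design and in-silico validation.

The discrimination principle: primer extension proceeds only when the
primer's 3'-terminal base pairs perfectly with the template.  The
allele-specific (AS) forward primer therefore ends exactly on the SNP
with the mutant allele as its 3'-terminal base, and carries one
deliberate *secondary* mismatch near the 3' end (default: the
penultimate base, a fixed transversion) so that even on the mutant
template the primer is one mismatch away from perfect — sharpening the
difference against the wild-type template, where the additional
terminal mismatch blocks extension.  The common reverse primer and the
control pair sit on variant-free footprints so their sequence is
identical on both alleles.

Melting temperatures use the Wallace rule, Tm = 2(A+T) + 4(G+C), which
is exact on integers and therefore directly testable; a
nearest-neighbor estimate is available as an alternative.

Product length is defined throughout as the inclusive span between the
two primers' 3'-terminal genomic coordinates:
``reverse.three_prime_pos - forward.three_prime_pos + 1``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np

from .errors import DesignError, UsageError
from .formats import Genome, VariantRecord, revcomp

log = logging.getLogger(__name__)

#: Fixed transversion map for the engineered secondary mismatch.  It is an
#: involution (A<->C, G<->T), always yields a genuine mismatch, and swaps a
#: weak for a strong base (or vice versa), keeping the Tm shift to +/-2 C.
TRANSVERSION_MAP = {"A": "C", "C": "A", "G": "T", "T": "G"}


@dataclass(frozen=True)
class PrimerParams:
    """Tunable primer-design parameters (lengths in bases, Tm in deg C)."""

    target_tm: float = 58.0
    min_len: int = 18
    max_len: int = 30
    product_min: int = 100
    product_max: int = 300
    mismatch_offset: int = 2  # 3'-terminal base is offset 1
    mismatch_map: dict = field(default_factory=lambda: dict(TRANSVERSION_MAP))
    max_total_mm: int = 1
    tm_method: str = "wallace"
    control_anchor: int = 1000
    control_step: int = 50

    def __post_init__(self):
        if not (0 < self.min_len <= self.max_len):
            raise UsageError("need 0 < min_len <= max_len")
        if not (0 < self.product_min <= self.product_max):
            raise UsageError("need 0 < product_min <= product_max")
        if self.mismatch_offset < 1:
            raise UsageError("mismatch_offset counts the 3' terminus as 1")


@dataclass(frozen=True)
class Primer:
    """An oligonucleotide with its genomic footprint.

    ``three_prime_pos`` is the genomic coordinate of the 3'-terminal
    base: the highest footprint coordinate for a plus-strand primer,
    the lowest for a minus-strand one.  ``engineered_mismatch`` is
    ``(offset_from_3prime, introduced_base, original_base)``.
    """

    name: str
    sequence: str
    chrom: str
    strand: str
    three_prime_pos: int
    tm: float
    engineered_mismatch: Optional[tuple[int, str, str]] = None
    tm_target_reached: bool = True

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def footprint(self) -> tuple[int, int]:
        """Genomic interval [start, end] covered by the primer."""
        if self.strand == "+":
            return (self.three_prime_pos - len(self) + 1, self.three_prime_pos)
        return (self.three_prime_pos, self.three_prime_pos + len(self) - 1)


@dataclass(frozen=True)
class PrimerSet:
    """AS forward + common reverse, plus the amplification-control pair."""

    as_forward: Primer
    common_reverse: Primer
    control_forward: Primer
    control_reverse: Primer
    expected_product_len: int
    control_product_len: int

    def primers(self):
        yield "as_forward", self.as_forward
        yield "common_reverse", self.common_reverse
        yield "control_forward", self.control_forward
        yield "control_reverse", self.control_reverse


@dataclass(frozen=True)
class AmpliconResult:
    """Outcome of one in-silico PCR on one haplotype template."""

    template_label: str
    amplified: bool
    product_len: Optional[int]
    forward_mismatch_offsets: tuple[int, ...]
    reverse_mismatch_offsets: tuple[int, ...]


@dataclass(frozen=True)
class MarkerValidation:
    """AS and control amplification on both haplotypes, plus the verdict."""

    as_wt: AmpliconResult
    as_mut: AmpliconResult
    control_wt: AmpliconResult
    control_mut: AmpliconResult

    @property
    def discriminating(self) -> bool:
        return (
            self.as_mut.amplified
            and not self.as_wt.amplified
            and self.control_wt.amplified
            and self.control_mut.amplified
        )


# ---------------------------------------------------------------------------
# Tm and the engineered mismatch


def melting_temp(sequence: str, method: str = "wallace") -> float:
    """Primer melting temperature in deg C.

    ``wallace``: Tm = 2(A+T) + 4(G+C), exact.  ``nn``: nearest-neighbor
    thermodynamic estimate (Biopython), monotone in GC at fixed length.
    """
    if not sequence:
        raise UsageError("empty sequence")
    seq = sequence.upper()
    if any(c not in "ACGT" for c in seq):
        raise UsageError(f"non-ACGT character in primer sequence {sequence!r}")
    if method == "wallace":
        gc = seq.count("G") + seq.count("C")
        return float(2 * (len(seq) - gc) + 4 * gc)
    if method == "nn":
        from Bio.SeqUtils import MeltingTemp

        return float(MeltingTemp.Tm_NN(seq))
    raise UsageError(f"unknown Tm method {method!r}")


def apply_secondary_mismatch(
    primer_seq: str, offset: int = 2, rule: dict | None = None
) -> str:
    """Substitute the base ``offset`` positions from the 3' end.

    Offset counts the 3'-terminal base as 1, so the default (2) mutates
    the penultimate base.  The default rule is the fixed transversion
    map A<->C, G<->T; the replacement always differs from the original.
    """
    rule = rule or TRANSVERSION_MAP
    if not 1 <= offset <= len(primer_seq):
        raise UsageError(
            f"mismatch offset {offset} outside primer of length {len(primer_seq)}"
        )
    i = len(primer_seq) - offset
    new = rule[primer_seq[i]]
    if new == primer_seq[i]:
        raise UsageError("mismatch rule returned the original base")
    return primer_seq[:i] + new + primer_seq[i + 1 :]


# ---------------------------------------------------------------------------
# Blocked-locus bookkeeping


def blocked_loci(*record_sets: Iterable) -> dict[str, np.ndarray]:
    """Per-chromosome sorted arrays of positions covered by any variant.

    Accepts variant records or polymorphic loci; an InDel blocks its
    whole reference span so primer footprints can never straddle one.
    """
    pos: dict[str, set[int]] = {}
    for records in record_sets:
        for r in records:
            span = len(r.ref)
            s = pos.setdefault(r.chrom, set())
            s.update(range(r.pos, r.pos + span))
    return {c: np.array(sorted(p), dtype=np.int64) for c, p in pos.items()}


def _overlaps_blocked(blocked: dict, chrom: str, start: int, end: int) -> bool:
    arr = blocked.get(chrom)
    if arr is None or len(arr) == 0:
        return False
    i = np.searchsorted(arr, start, side="left")
    return i < len(arr) and arr[i] <= end


# ---------------------------------------------------------------------------
# Primer construction


def _extend_to_tm(build_seq, params: PrimerParams) -> tuple[str, int, float, bool]:
    """Find the shortest length in [min_len, max_len] whose Tm meets target.

    ``build_seq(L)`` returns the final primer sequence at length L (with
    any allele substitution and engineered mismatch already applied).
    """
    seq, tm = "", 0.0
    for L in range(params.min_len, params.max_len + 1):
        seq = build_seq(L)
        tm = melting_temp(seq, params.tm_method)
        if tm >= params.target_tm:
            return seq, L, tm, True
    return seq, params.max_len, tm, False


def design_as_forward(genome: Genome, candidate, params: PrimerParams | None = None) -> Primer:
    """Allele-specific forward primer ending on the mutant allele.

    Plus-strand primer whose 3'-terminal base sits on the SNP and
    carries the mutant allele; the engineered secondary mismatch is
    applied at ``params.mismatch_offset``; the 5' end is extended until
    the Wallace Tm of the final sequence reaches ``target_tm`` (a
    too-cold primer at ``max_len`` is emitted flagged, with a warning).
    """
    params = params or PrimerParams()
    if candidate.vtype != "SNP":
        raise UsageError("allele-specific primers are designed for SNP candidates")
    chrom, pos = candidate.chrom, candidate.pos
    if pos < params.max_len:
        raise DesignError(
            f"{chrom}:{pos}: upstream flank shorter than max primer length"
        )
    mut_allele = candidate.mut_allele

    def build(L: int) -> str:
        flank = genome.fetch(chrom, pos - L + 1, pos)
        seq = flank[:-1] + mut_allele
        return apply_secondary_mismatch(seq, params.mismatch_offset, params.mismatch_map)

    seq, L, tm, reached = _extend_to_tm(build, params)
    if not reached:
        log.warning(
            "%s:%d: AS forward primer reached max_len with Tm %.1f < target %.1f",
            chrom, pos, tm, params.target_tm,
        )
    i = L - params.mismatch_offset
    original = (genome.fetch(chrom, pos - L + 1, pos)[:-1] + mut_allele)[i]
    return Primer(
        name=f"AS_{chrom}_{pos}_F",
        sequence=seq,
        chrom=chrom,
        strand="+",
        three_prime_pos=pos,
        tm=tm,
        engineered_mismatch=(params.mismatch_offset, seq[i], original),
        tm_target_reached=reached,
    )


def design_common_reverse(
    genome: Genome,
    candidate,
    blocked: dict[str, np.ndarray],
    params: PrimerParams | None = None,
    forward_tm: float | None = None,
) -> Primer:
    """Minus-strand reverse primer shared by both alleles.

    Scans 3'-end positions downstream of the SNP so the product length
    (3'-end to 3'-end, inclusive) falls in ``[product_min,
    product_max]``; among feasible positions picks the one whose Tm is
    closest to the forward primer's, breaking ties toward the smaller
    product.  The footprint must not overlap any blocked (variant)
    locus, which guarantees an identical primer on both alleles.
    """
    params = params or PrimerParams()
    chrom, f3 = candidate.chrom, candidate.pos
    if forward_tm is None:
        forward_tm = params.target_tm
    chrom_len = genome.length(chrom)
    best = None
    for r3 in range(f3 + params.product_min - 1, f3 + params.product_max):
        def build(L: int, r3=r3) -> str:
            return revcomp(genome.fetch(chrom, r3, r3 + L - 1))

        if r3 + params.max_len - 1 > chrom_len:
            break
        seq, L, tm, reached = _extend_to_tm(build, params)
        if not reached:
            continue
        if _overlaps_blocked(blocked, chrom, r3, r3 + L - 1):
            continue
        product = r3 - f3 + 1
        key = (abs(tm - forward_tm), product)
        if best is None or key < best[0]:
            best = (key, r3, L, tm, seq)
    if best is None:
        raise DesignError(
            f"{chrom}:{f3}: no feasible reverse-primer window — every 3'-end "
            f"position in [{f3 + params.product_min - 1},{f3 + params.product_max - 1}] "
            "fails the Tm target, chromosome bounds, or variant-free footprint"
        )
    _, r3, L, tm, seq = best
    return Primer(
        name=f"AS_{chrom}_{f3}_R",
        sequence=seq,
        chrom=chrom,
        strand="-",
        three_prime_pos=r3,
        tm=tm,
    )


def design_control_pair(
    genome: Genome,
    blocked: dict[str, np.ndarray],
    params: PrimerParams | None = None,
    chrom: str | None = None,
) -> tuple[Primer, Primer]:
    """Amplification-control pair on a completely variant-free window.

    Deterministic scan from ``params.control_anchor`` (stepping by
    ``control_step``) across chromosomes until a window is found whose
    primer footprints *and* enclosed product contain no blocked locus,
    with product length in the control range.
    """
    params = params or PrimerParams()
    chroms = [chrom] if chrom is not None else genome.names
    for c in chroms:
        chrom_len = genome.length(c)
        f3 = params.control_anchor + params.max_len
        while f3 + params.product_max + params.max_len < chrom_len:
            def build_f(L: int, f3=f3, c=c) -> str:
                return genome.fetch(c, f3 - L + 1, f3)

            seq_f, Lf, tm_f, reached = _extend_to_tm(build_f, params)
            if reached and not _overlaps_blocked(blocked, c, f3 - Lf + 1, f3):
                try:
                    anchor = _ControlAnchor(c, f3)
                    rev = design_common_reverse(
                        genome, anchor, blocked, params, forward_tm=tm_f
                    )
                    span_start = f3 - Lf + 1
                    span_end = rev.three_prime_pos + len(rev) - 1
                    if not _overlaps_blocked(blocked, c, span_start, span_end):
                        fwd = Primer(
                            name=f"CTRL_{c}_{f3}_F",
                            sequence=seq_f,
                            chrom=c,
                            strand="+",
                            three_prime_pos=f3,
                            tm=tm_f,
                        )
                        rev = replace(rev, name=f"CTRL_{c}_{f3}_R")
                        return fwd, rev
                except DesignError:
                    pass
            f3 += params.control_step
    raise DesignError("no variant-free control window on any chromosome")


@dataclass(frozen=True)
class _ControlAnchor:
    chrom: str
    pos: int


def design_marker_set(
    genome: Genome,
    candidate,
    blocked: dict[str, np.ndarray],
    params: PrimerParams | None = None,
    control_pair: tuple[Primer, Primer] | None = None,
) -> PrimerSet:
    """Full AS-PCR primer set for one SNP candidate.

    The control pair is designed once per genome and may be shared
    across sets (pass it in); otherwise it is designed here.
    """
    params = params or PrimerParams()
    fwd = design_as_forward(genome, candidate, params)
    rev = design_common_reverse(genome, candidate, blocked, params, forward_tm=fwd.tm)
    if control_pair is None:
        control_pair = design_control_pair(genome, blocked, params)
    cf, cr = control_pair
    return PrimerSet(
        as_forward=fwd,
        common_reverse=rev,
        control_forward=cf,
        control_reverse=cr,
        expected_product_len=rev.three_prime_pos - fwd.three_prime_pos + 1,
        control_product_len=cr.three_prime_pos - cf.three_prime_pos + 1,
    )


# ---------------------------------------------------------------------------
# Haplotype templates and in-silico PCR


class HaplotypeTemplate:
    """A reference genome with one sample's homozygous variants applied.

    Keeps a per-chromosome coordinate map so reference coordinates of
    primer footprints can be located on the shifted (InDel-containing)
    haplotype sequence.
    """

    def __init__(self, label: str, genome: Genome, records: Iterable[VariantRecord]):
        self.label = label
        self._seqs: dict[str, str] = {}
        self._shift_pos: dict[str, np.ndarray] = {}
        self._shift_cum: dict[str, np.ndarray] = {}
        by_chrom: dict[str, list[VariantRecord]] = {c: [] for c in genome.names}
        for r in records:
            if r.is_homozygous and r.allele1 == r.alt:
                by_chrom.setdefault(r.chrom, []).append(r)
        for chrom in genome.names:
            ref_seq = genome[chrom]
            parts = []
            cursor = 1
            ends = []
            cums = []
            delta = 0
            for v in sorted(by_chrom.get(chrom, []), key=lambda r: r.pos):
                if ref_seq[v.pos - 1 : v.pos - 1 + len(v.ref)] != v.ref:
                    raise UsageError(
                        f"{chrom}:{v.pos}: ref allele {v.ref!r} does not match genome"
                    )
                parts.append(ref_seq[cursor - 1 : v.pos - 1])
                parts.append(v.alt)
                cursor = v.pos + len(v.ref)
                delta += len(v.alt) - len(v.ref)
                ends.append(cursor)  # first ref position after the variant
                cums.append(delta)
            parts.append(ref_seq[cursor - 1 :])
            self._seqs[chrom] = "".join(parts)
            self._shift_pos[chrom] = np.array(ends, dtype=np.int64)
            self._shift_cum[chrom] = np.array(cums, dtype=np.int64)

    def sequence(self, chrom: str) -> str:
        return self._seqs[chrom]

    def shift(self, chrom: str, pos: int) -> int:
        """Haplotype coordinate of reference position ``pos`` (1-based)."""
        ends = self._shift_pos[chrom]
        i = int(np.searchsorted(ends, pos, side="right"))
        delta = int(self._shift_cum[chrom][i - 1]) if i > 0 else 0
        return pos + delta


def _primer_mismatches(
    template: HaplotypeTemplate, primer: Primer
) -> tuple[int, ...]:
    """Offsets (from the 3' end, 1-based) where primer and template differ."""
    start, end = primer.footprint
    t_start = template.shift(primer.chrom, start)
    seq = template.sequence(primer.chrom)
    L = len(primer)
    if t_start < 1 or t_start - 1 + L > len(seq):
        raise UsageError(
            f"primer {primer.name} footprint outside template {template.label}"
        )
    window = seq[t_start - 1 : t_start - 1 + L]
    if primer.strand == "-":
        window = revcomp(window)
    return tuple(
        sorted(L - i for i in range(L) if window[i] != primer.sequence[i])
    )


def _extension_allowed(
    primer: Primer, offsets: tuple[int, ...], params: PrimerParams
) -> bool:
    """3'-end complete-alignment rule plus the mismatch budget."""
    if 1 in offsets:  # 3'-terminal base must pair perfectly
        return False
    if len(offsets) > params.max_total_mm:
        return False
    engineered = primer.engineered_mismatch[0] if primer.engineered_mismatch else None
    for o in offsets:
        if o <= 3 and o != engineered:
            return False
    return True


def insilico_pcr(
    template: HaplotypeTemplate,
    forward: Primer,
    reverse: Primer,
    params: PrimerParams | None = None,
) -> AmpliconResult:
    """Predict amplification of one primer pair on one haplotype.

    Each primer is checked only at its recorded genomic footprint (no
    genome-wide search): extension requires a perfectly paired
    3'-terminal base, at most ``max_total_mm`` total mismatches, and no
    mismatch at 3'-end offsets 1–3 other than the engineered one.
    """
    params = params or PrimerParams()
    f_off = _primer_mismatches(template, forward)
    r_off = _primer_mismatches(template, reverse)
    ok = _extension_allowed(forward, f_off, params) and _extension_allowed(
        reverse, r_off, params
    )
    return AmpliconResult(
        template_label=template.label,
        amplified=ok,
        product_len=(reverse.three_prime_pos - forward.three_prime_pos + 1)
        if ok
        else None,
        forward_mismatch_offsets=f_off,
        reverse_mismatch_offsets=r_off,
    )


def validate_marker(
    genome: Genome,
    wt_records: Sequence[VariantRecord],
    mut_records: Sequence[VariantRecord],
    primer_set: PrimerSet,
    params: PrimerParams | None = None,
) -> MarkerValidation:
    """In-silico allele discrimination check for one primer set.

    Builds the WT and mutant haplotype templates (each sample's
    homozygous variants applied to the reference), runs the AS pair and
    the control pair on both, and reports whether the marker
    discriminates: AS product on the mutant haplotype only, control
    product on both.
    """
    params = params or PrimerParams()
    wt_t = HaplotypeTemplate("WT", genome, wt_records)
    mut_t = HaplotypeTemplate("mutant", genome, mut_records)
    return MarkerValidation(
        as_wt=insilico_pcr(wt_t, primer_set.as_forward, primer_set.common_reverse, params),
        as_mut=insilico_pcr(mut_t, primer_set.as_forward, primer_set.common_reverse, params),
        control_wt=insilico_pcr(wt_t, primer_set.control_forward, primer_set.control_reverse, params),
        control_mut=insilico_pcr(mut_t, primer_set.control_forward, primer_set.control_reverse, params),
    )
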