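"""Two-sample comparison of variant tables and marker-candidate filtering.

A locus is *polymorphic* when the wild-type and mutant samples carry
different unordered allele pairs.  Positions called in only one sample
are imputed homozygous-reference in the other (depth unknown).  The
polymorphism class is binary: ``homo`` when both genotypes are
homozygous, ``hetero`` otherwise — including the rare het-vs-het case
with differing pairs, which is folded into ``hetero`` so the two
classes always sum to the polymorphic total.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .classify import GeneIndex, RegionClass
from .errors import ConsistencyError, UsageError
from .formats import GeneModel, VariantRecord

log = logging.getLogger(__name__)

MIN_DEPTH_SNP = 20
MIN_DEPTH_INDEL = 10


@dataclass(frozen=True)
class PolymorphicLocus:
    """One locus where the two samples' unordered allele pairs differ."""

    chrom: str
    pos: int
    ref: str
    wt_alleles: tuple[str, str]
    mut_alleles: tuple[str, str]
    wt_depth: Optional[int]
    mut_depth: Optional[int]
    vtype: str
    polymorph_class: str

    def __post_init__(self):
        assert self.wt_alleles != self.mut_alleles
        assert self.polymorph_class in ("homo", "hetero")


@dataclass(frozen=True)
class MarkerCandidate:
    """A mutant-specific homozygous locus that passed the depth gate."""

    locus: PolymorphicLocus
    region: RegionClass
    mut_allele: str
    passes_depth: bool

    @property
    def chrom(self) -> str:
        return self.locus.chrom

    @property
    def pos(self) -> int:
        return self.locus.pos

    @property
    def ref(self) -> str:
        return self.locus.ref

    @property
    def vtype(self) -> str:
        return self.locus.vtype


def classify_polymorphism(
    wt_alleles: Sequence[str], mut_alleles: Sequence[str]
) -> str:
    """Binary class of a polymorphic locus: ``homo`` iff both pairs homozygous.

    Raises :class:`UsageError` when the unordered pairs are identical
    (such a locus is not polymorphic).
    """
    wt = tuple(sorted(wt_alleles))
    mut = tuple(sorted(mut_alleles))
    if wt == mut:
        raise UsageError("allele pairs are identical; locus is not polymorphic")
    wt_hom = wt[0] == wt[1]
    mut_hom = mut[0] == mut[1]
    if wt_hom and mut_hom:
        return "homo"
    if wt_hom != mut_hom:
        return "hetero"
    # het vs het with differing pairs: folded into "hetero" (binary scheme)
    log.debug("het-vs-het locus with differing pairs classed 'hetero'")
    return "hetero"


def compare_samples(
    wt_records: Iterable[VariantRecord],
    mut_records: Iterable[VariantRecord],
) -> list[PolymorphicLocus]:
    """Polymorphic loci over the union of positions called in either sample.

    A position absent from one table is imputed homozygous-reference
    there with unknown depth.  Loci with identical unordered pairs are
    not emitted.  Both tables must agree on the reference allele at
    shared positions.
    """
    wt_by_pos = {(r.chrom, r.pos): r for r in wt_records}
    mut_by_pos = {(r.chrom, r.pos): r for r in mut_records}
    loci: list[PolymorphicLocus] = []
    for key in sorted(set(wt_by_pos) | set(mut_by_pos)):
        wt = wt_by_pos.get(key)
        mut = mut_by_pos.get(key)
        if wt is not None and mut is not None and wt.ref != mut.ref:
            raise ConsistencyError(
                f"{key[0]}:{key[1]}: reference allele mismatch between samples "
                f"({wt.ref!r} vs {mut.ref!r})"
            )
        present = wt if wt is not None else mut
        ref = present.ref
        wt_pair = wt.alleles if wt is not None else (ref, ref)
        mut_pair = mut.alleles if mut is not None else (ref, ref)
        if tuple(sorted(wt_pair)) == tuple(sorted(mut_pair)):
            continue
        loci.append(
            PolymorphicLocus(
                chrom=key[0],
                pos=key[1],
                ref=ref,
                wt_alleles=tuple(sorted(wt_pair)),
                mut_alleles=tuple(sorted(mut_pair)),
                wt_depth=wt.depth if wt is not None else None,
                mut_depth=mut.depth if mut is not None else None,
                vtype=present.vtype,
                polymorph_class=classify_polymorphism(wt_pair, mut_pair),
            )
        )
    return loci


def filter_marker_candidates(
    polymorphic: Iterable[PolymorphicLocus],
    genes: Sequence[GeneModel] | GeneIndex,
    min_depth_snp: int = MIN_DEPTH_SNP,
    min_depth_indel: int = MIN_DEPTH_INDEL,
    require_both_depths: bool = False,
) -> list[MarkerCandidate]:
    """Mutant-specific homozygous loci passing the strict depth gate.

    Keeps class-``homo`` loci where the mutant is homozygous for a
    non-reference allele and the minimum known depth strictly exceeds
    the per-type threshold (SNP > ``min_depth_snp``, InDel >
    ``min_depth_indel``).  With ``require_both_depths`` a locus whose
    depth is unknown in either sample is dropped; by default the gate
    applies to whichever depths were observed.
    """
    if min_depth_snp < 0 or min_depth_indel < 0:
        raise UsageError("depth thresholds must be non-negative")
    index = genes if isinstance(genes, GeneIndex) else GeneIndex(genes)
    out: list[MarkerCandidate] = []
    for loc in polymorphic:
        if loc.polymorph_class != "homo":
            continue
        mut_allele = loc.mut_alleles[0]
        if loc.mut_alleles[0] != loc.mut_alleles[1] or mut_allele == loc.ref:
            continue  # mutant must be homozygous non-reference
        depths = [d for d in (loc.wt_depth, loc.mut_depth) if d is not None]
        if not depths:
            continue
        if require_both_depths and (loc.wt_depth is None or loc.mut_depth is None):
            continue
        threshold = min_depth_snp if loc.vtype == "SNP" else min_depth_indel
        if min(depths) <= threshold:
            continue
        out.append(
            MarkerCandidate(
                locus=loc,
                region=index.classify(loc.chrom, loc.pos),
                mut_allele=mut_allele,
                passes_depth=True,
            )
        )
    return out


def polymorphism_summary(loci: Sequence[PolymorphicLocus]) -> dict:
    """Total/homo/hetero counts per variant type, in the two-class layout."""
    out: dict[str, dict[str, int]] = {}
    for vt in ("SNP", "InDel"):
        sub = [
            l
            for l in loci
            if (l.vtype == "SNP") == (vt == "SNP")
        ]
        out[vt] = {
            "total": len(sub),
            "homo": sum(1 for l in sub if l.polymorph_class == "homo"),
            "hetero": sum(1 for l in sub if l.polymorph_class == "hetero"),
        }
    return out
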