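"""Amino-acid consequence of coding SNPs.

Maps a genomic SNP inside a gene's CDS to its position in the spliced
coding sequence, extracts the affected codon and translates reference
and alternate codons with the standard nuclear genetic code (stop as
``*``).  InDel consequences (frameshifts) are deliberately not
computed; coding InDels are reported as ``coding-indel`` without a
protein-level prediction.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Seq import Seq

from .errors import UsageError
from .formats import GeneModel, Genome, revcomp


@dataclass(frozen=True)
class AAChange:
    """One codon-level substitution in a gene's protein."""

    gene_id: str
    cds_offset: int  # 1-based position within the spliced CDS
    codon_number: int
    ref_codon: str
    alt_codon: str
    ref_aa: str
    alt_aa: str
    synonymous: bool

    def __post_init__(self):
        assert self.codon_number == (self.cds_offset + 2) // 3
        assert self.synonymous == (self.ref_aa == self.alt_aa)


@dataclass(frozen=True)
class CodingSNPEffect:
    """An :class:`AAChange` together with its genomic coordinates."""

    chrom: str
    pos: int
    ref: str
    alt: str
    change: AAChange


def translate_codon(codon: str) -> str:
    """Standard-code translation of a single codon; stop is ``*``."""
    if len(codon) != 3:
        raise UsageError(f"codon must have length 3, got {codon!r}")
    return str(Seq(codon).translate())


def splice_cds(gene: GeneModel, genome: Genome) -> str:
    """Spliced coding sequence in transcription (5'→3') order.

    Minus-strand genes are reverse-complemented; the result starts at
    the annotated start codon and its length is a multiple of 3.
    """
    parts = [genome.fetch(gene.chrom, s, e) for s, e in gene.cds]
    seq = "".join(parts)
    return revcomp(seq) if gene.strand == "-" else seq


def genomic_to_cds_offset(gene: GeneModel, pos: int) -> int:
    """1-based offset of genomic position ``pos`` within the spliced CDS."""
    containing = next(((s, e) for s, e in gene.cds if s <= pos <= e), None)
    if containing is None:
        raise UsageError(
            f"position {gene.chrom}:{pos} is not inside the CDS of {gene.gene_id}"
        )
    if gene.strand == "+":
        before = sum(e - s + 1 for s, e in gene.cds if e < containing[0])
        return before + (pos - containing[0] + 1)
    after = sum(e - s + 1 for s, e in gene.cds if s > containing[1])
    return after + (containing[1] - pos + 1)


def annotate_effect(snp, gene: GeneModel, genome: Genome) -> AAChange:
    """Codon-level effect of a coding SNP.

    ``snp`` needs ``pos``, ``ref`` and a mutant allele (``mut_allele``
    or ``alt``); the alternate base is complemented for minus-strand
    genes before substitution into the codon.
    """
    pos = snp.pos
    alt = getattr(snp, "mut_allele", None) or snp.alt
    ref = snp.ref
    if len(ref) != 1 or len(alt) != 1:
        raise UsageError("effect annotation applies to SNPs only")
    offset = genomic_to_cds_offset(gene, pos)
    cds = splice_cds(gene, genome)
    if gene.strand == "-":
        ref, alt = revcomp(ref), revcomp(alt)
    if cds[offset - 1] != ref:
        raise UsageError(
            f"reference allele {snp.ref!r} does not match the CDS of "
            f"{gene.gene_id} at offset {offset}"
        )
    codon_number = (offset + 2) // 3
    cstart = (codon_number - 1) * 3
    ref_codon = cds[cstart : cstart + 3]
    within = (offset - 1) % 3
    alt_codon = ref_codon[:within] + alt + ref_codon[within + 1 :]
    ref_aa = translate_codon(ref_codon)
    alt_aa = translate_codon(alt_codon)
    return AAChange(
        gene_id=gene.gene_id,
        cds_offset=offset,
        codon_number=codon_number,
        ref_codon=ref_codon,
        alt_codon=alt_codon,
        ref_aa=ref_aa,
        alt_aa=alt_aa,
        synonymous=ref_aa == alt_aa,
    )


def annotate_candidate_effects(candidates, genes, genome: Genome):
    """Annotate every CDS SNP candidate; returns :class:`CodingSNPEffect` list.

    Coding InDel candidates are skipped here (reported elsewhere as
    ``coding-indel``); non-CDS candidates are ignored.
    """
    by_id = {g.gene_id: g for g in genes}
    out = []
    for c in candidates:
        if c.region.value != "CDS" or c.vtype != "SNP":
            continue
        gene = by_id[c.region.gene_id]
        change = annotate_effect(c, gene, genome)
        out.append(
            CodingSNPEffect(
                chrom=c.chrom, pos=c.pos, ref=c.ref, alt=c.mut_allele, change=change
            )
        )
    return out
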