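"""Zygosity and genomic-region classification of variant calls.

Region classes are strictly exclusive — ``CDS``, ``exon_noncoding``,
``intron``, ``intergenic`` — so that they partition any variant table.
For display in the conventional style, "exon" counts can be recovered
as ``CDS + exon_noncoding``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from intervaltree import IntervalTree

from .errors import ReferenceError_
from .formats import GeneModel, VariantRecord

REGION_VALUES = ("CDS", "exon_noncoding", "intron", "intergenic")
_REGION_RANK = {v: i for i, v in enumerate(REGION_VALUES)}


@dataclass(frozen=True)
class RegionClass:
    """Exclusive region assignment of one position; gene_id is None iff intergenic."""

    value: str
    gene_id: Optional[str] = None

    def __post_init__(self):
        assert self.value in REGION_VALUES
        assert (self.gene_id is not None) == (self.value != "intergenic")


INTERGENIC = RegionClass("intergenic", None)


def classify_zygosity(record: VariantRecord) -> str:
    """``homozygous`` iff the two genotype alleles are identical."""
    return "homozygous" if record.allele1 == record.allele2 else "heterozygous"


class GeneIndex:
    """Interval index over gene exon hulls for fast region lookup.

    Ties between overlapping genes resolve by region priority
    CDS > exon_noncoding > intron, then smallest gene_id.
    """

    def __init__(self, genes: Iterable[GeneModel]):
        self._trees: dict[str, IntervalTree] = {}
        self._genes: dict[str, GeneModel] = {}
        for g in genes:
            self._genes[g.gene_id] = g
            tree = self._trees.setdefault(g.chrom, IntervalTree())
            tree.addi(g.start, g.end + 1, g.gene_id)  # half-open internally

    def classify(self, chrom: str, pos: int) -> RegionClass:
        tree = self._trees.get(chrom)
        if tree is None:
            return INTERGENIC
        hits = []
        for iv in tree.at(pos):
            g = self._genes[iv.data]
            if any(s <= pos <= e for s, e in g.cds):
                value = "CDS"
            elif any(s <= pos <= e for s, e in g.exons):
                value = "exon_noncoding"
            else:
                value = "intron"
            hits.append((_REGION_RANK[value], g.gene_id, value))
        if not hits:
            return INTERGENIC
        _, gene_id, value = min(hits)
        return RegionClass(value, gene_id)


def annotate_region(
    variant: VariantRecord,
    genes: Sequence[GeneModel] | GeneIndex,
    genome=None,
) -> RegionClass:
    """Region class of a variant's anchor position.

    InDels are assigned by their anchored start position only.  If a
    genome is supplied the chromosome name is validated against it.
    """
    if genome is not None and variant.chrom not in genome:
        raise ReferenceError_(f"unknown chromosome {variant.chrom!r}")
    index = genes if isinstance(genes, GeneIndex) else GeneIndex(genes)
    return index.classify(variant.chrom, variant.pos)


@dataclass
class CountsSummary:
    """Per-sample variant counts by type, zygosity and region.

    Invariants (asserted by :meth:`check`): zygosity classes partition
    the total; insertion + deletion = InDel total; region classes
    partition the total.
    """

    total: int = 0
    by_vtype: dict = field(default_factory=lambda: {"SNP": 0, "insertion": 0, "deletion": 0})
    by_zygosity: dict = field(default_factory=lambda: {"homozygous": 0, "heterozygous": 0})
    by_zygosity_vtype: dict = field(
        default_factory=lambda: {
            z: {"SNP": 0, "insertion": 0, "deletion": 0}
            for z in ("homozygous", "heterozygous")
        }
    )
    by_region: dict = field(default_factory=lambda: {v: 0 for v in REGION_VALUES})

    @property
    def n_indel(self) -> int:
        return self.by_vtype["insertion"] + self.by_vtype["deletion"]

    @property
    def genic(self) -> int:
        return self.by_region["CDS"] + self.by_region["exon_noncoding"] + self.by_region["intron"]

    @property
    def exon_display(self) -> int:
        """Conventional 'exon' count: CDS plus non-coding exon."""
        return self.by_region["CDS"] + self.by_region["exon_noncoding"]

    def check(self) -> None:
        assert sum(self.by_zygosity.values()) == self.total
        assert sum(self.by_vtype.values()) == self.total
        assert sum(self.by_region.values()) == self.total
        for z in self.by_zygosity:
            assert sum(self.by_zygosity_vtype[z].values()) == self.by_zygosity[z]

    def report(self, label: str = "sample") -> str:
        lines = [
            f"== Variant summary: {label} ==",
            f"total variants       {self.total}",
            f"  SNPs               {self.by_vtype['SNP']}",
            f"  InDels             {self.n_indel} "
            f"(insertions {self.by_vtype['insertion']}, deletions {self.by_vtype['deletion']})",
            f"homozygous           {self.by_zygosity['homozygous']}",
            f"heterozygous         {self.by_zygosity['heterozygous']}",
            f"genic                {self.genic} "
            f"(exon {self.exon_display} [CDS {self.by_region['CDS']}, "
            f"non-coding {self.by_region['exon_noncoding']}], "
            f"intron {self.by_region['intron']})",
            f"intergenic           {self.by_region['intergenic']}",
        ]
        return "\n".join(lines)

    def to_rows(self):
        yield ("total", self.total)
        for k, v in self.by_vtype.items():
            yield (f"vtype/{k}", v)
        for k, v in self.by_zygosity.items():
            yield (f"zygosity/{k}", v)
            for vt, n in self.by_zygosity_vtype[k].items():
                yield (f"zygosity/{k}/{vt}", n)
        for k, v in self.by_region.items():
            yield (f"region/{k}", v)
        yield ("region/genic", self.genic)


def summarize_variants(
    records: Iterable[VariantRecord],
    genes: Sequence[GeneModel] | GeneIndex,
) -> CountsSummary:
    """Count a sample's variants by type, zygosity and region class."""
    index = genes if isinstance(genes, GeneIndex) else GeneIndex(genes)
    s = CountsSummary()
    for rec in records:
        s.total += 1
        s.by_vtype[rec.vtype] += 1
        zyg = classify_zygosity(rec)
        s.by_zygosity[zyg] += 1
        s.by_zygosity_vtype[zyg][rec.vtype] += 1
        s.by_region[index.classify(rec.chrom, rec.pos).value] += 1
    s.check()
    return s
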