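"""File formats and core domain types.

Everything downstream works in 1-based, inclusive genomic coordinates,
the native convention of GFF3 and VCF.  This module is the only place
where 0-based library conventions (Biopython slices, cyvcf2 ``POS``)
are converted.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Optional, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import (
    AlphabetError,
    ConsistencyError,
    FormatError,
    ModelError,
    ReferenceError_,
    UsageError,
)

log = logging.getLogger(__name__)

DNA = frozenset("ACGT")
DNA_N = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an upper-case DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


class Genome:
    """Ordered collection of named chromosome sequences over {A,C,G,T}.

    Parameters
    ----------
    chromosomes
        Ordered mapping of chromosome name to upper-case sequence.
    allow_n
        Accept ``N`` bases (default: rejected with :class:`AlphabetError`).
    """

    def __init__(self, chromosomes: Mapping[str, str], allow_n: bool = False):
        alphabet = DNA_N if allow_n else DNA
        self._chroms: dict[str, str] = {}
        for name, seq in chromosomes.items():
            if not name:
                raise FormatError("empty chromosome name")
            if name in self._chroms:
                raise FormatError(f"duplicate chromosome name {name!r}")
            if not seq:
                raise FormatError(f"chromosome {name!r} has empty sequence")
            seq = seq.upper()
            bad = next((i for i, c in enumerate(seq) if c not in alphabet), None)
            if bad is not None:
                raise AlphabetError(
                    f"illegal character {seq[bad]!r} in {name!r} at position {bad + 1}"
                )
            self._chroms[name] = seq

    @property
    def names(self) -> list[str]:
        return list(self._chroms)

    def __contains__(self, name: str) -> bool:
        return name in self._chroms

    def __getitem__(self, name: str) -> str:
        try:
            return self._chroms[name]
        except KeyError:
            raise ReferenceError_(f"unknown chromosome {name!r}") from None

    def __iter__(self) -> Iterator[str]:
        return iter(self._chroms)

    def __len__(self) -> int:
        return len(self._chroms)

    def length(self, name: str) -> int:
        return len(self[name])

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Subsequence at 1-based inclusive coordinates ``[start, end]``."""
        seq = self[chrom]
        if not (1 <= start <= end <= len(seq)):
            raise ReferenceError_(
                f"coordinates [{start},{end}] outside {chrom!r} (length {len(seq)})"
            )
        return seq[start - 1 : end]


@dataclass(frozen=True)
class GeneModel:
    """Stranded gene with exon and CDS intervals (1-based inclusive).

    Invariants: exons sorted and non-overlapping; every CDS interval is
    contained in an exon; total CDS length divisible by 3.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds: tuple[tuple[int, int], ...]

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ModelError(f"{self.gene_id}: strand must be '+' or '-'")
        if not self.exons:
            raise ModelError(f"{self.gene_id}: no exons")
        object.__setattr__(self, "exons", tuple(sorted(map(tuple, self.exons))))
        object.__setattr__(self, "cds", tuple(sorted(map(tuple, self.cds))))
        prev_end = 0
        for s, e in self.exons:
            if s <= prev_end:
                raise ModelError(f"{self.gene_id}: exons overlap or are unsorted")
            if e < s or s < 1:
                raise ModelError(f"{self.gene_id}: bad exon interval [{s},{e}]")
            prev_end = e
        for cs, ce in self.cds:
            if not any(s <= cs and ce <= e for s, e in self.exons):
                raise ModelError(
                    f"{self.gene_id}: CDS [{cs},{ce}] not contained in any exon"
                )
        if self.cds_length % 3 != 0:
            raise ModelError(
                f"{self.gene_id}: CDS length {self.cds_length} not divisible by 3"
            )

    @property
    def start(self) -> int:
        """First exon start (the gene's exon-hull start)."""
        return self.exons[0][0]

    @property
    def end(self) -> int:
        """Last exon end (the gene's exon-hull end)."""
        return self.exons[-1][1]

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds)

    def validate_bounds(self, genome: Genome) -> None:
        if self.chrom not in genome:
            raise ModelError(f"{self.gene_id}: unknown chromosome {self.chrom!r}")
        if self.end > genome.length(self.chrom):
            raise ModelError(
                f"{self.gene_id}: exon end {self.end} beyond chromosome "
                f"{self.chrom!r} (length {genome.length(self.chrom)})"
            )


@dataclass(frozen=True)
class VariantRecord:
    """One called locus in one sample.

    ``allele1``/``allele2`` is the unphased genotype; each allele equals
    either ``ref`` or ``alt``.  InDels are VCF-style anchored: ref and alt
    share their first base and differ in length.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    allele1: str
    allele2: str
    depth: int

    def __post_init__(self):
        if self.ref == self.alt:
            raise FormatError(f"{self.chrom}:{self.pos}: ref equals alt")
        for a in (self.ref, self.alt):
            if not a or any(c not in DNA for c in a):
                raise FormatError(f"{self.chrom}:{self.pos}: bad allele {a!r}")
        if len(self.ref) > 1 or len(self.alt) > 1:
            if self.ref[0] != self.alt[0]:
                raise FormatError(
                    f"{self.chrom}:{self.pos}: InDel alleles lack a shared anchor base"
                )
        for a in (self.allele1, self.allele2):
            if a not in (self.ref, self.alt):
                raise FormatError(
                    f"{self.chrom}:{self.pos}: genotype allele {a!r} is neither ref nor alt"
                )
        if self.depth < 0:
            raise FormatError(f"{self.chrom}:{self.pos}: negative depth")

    @property
    def vtype(self) -> str:
        """``SNP``, ``insertion`` or ``deletion`` (derived from allele lengths)."""
        if len(self.ref) == len(self.alt) == 1:
            return "SNP"
        return "insertion" if len(self.alt) > len(self.ref) else "deletion"

    @property
    def is_homozygous(self) -> bool:
        return self.allele1 == self.allele2

    @property
    def alleles(self) -> tuple[str, str]:
        """Unordered genotype as a sorted pair."""
        return tuple(sorted((self.allele1, self.allele2)))


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | os.PathLike, allow_n: bool = False) -> Genome:
    """Read a FASTA file into a :class:`Genome` (record order preserved)."""
    chroms: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in chroms:
            raise FormatError(f"duplicate FASTA header {rec.id!r}")
        chroms[rec.id] = str(rec.seq)
    if not chroms:
        raise FormatError(f"no FASTA records in {path}")
    return Genome(chroms, allow_n=allow_n)


def write_fasta(genome: Genome, path: str | os.PathLike) -> None:
    """Write a genome as FASTA, 60 columns per line."""
    records = [
        SeqRecord(Seq(genome[name]), id=name, description="") for name in genome.names
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# GFF3


def read_gff3(path: str | os.PathLike, genome: Genome) -> list[GeneModel]:
    """Parse gene/mRNA/exon/CDS features into :class:`GeneModel` objects.

    One model per gene; where a gene carries several mRNAs the
    lexicographically smallest transcript ID is used.
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    models: list[GeneModel] = []
    for gene in db.features_of_type("gene", order_by=("seqid", "start")):
        mrnas = sorted(db.children(gene, featuretype="mRNA"), key=lambda f: f.id)
        parent = mrnas[0] if mrnas else gene
        exons = [(f.start, f.end) for f in db.children(parent, featuretype="exon")]
        cds = [(f.start, f.end) for f in db.children(parent, featuretype="CDS")]
        if not exons:  # gene without explicit exons: the gene span is one exon
            exons = [(gene.start, gene.end)]
        model = GeneModel(
            gene_id=gene.id,
            chrom=gene.seqid,
            strand=gene.strand,
            exons=tuple(exons),
            cds=tuple(cds),
        )
        if model.chrom not in genome:
            raise ModelError(
                f"{model.gene_id}: chromosome {model.chrom!r} not in the genome"
            )
        model.validate_bounds(genome)
        models.append(model)
    return models


# ---------------------------------------------------------------------------
# VCF


def read_vcf(path: str | os.PathLike) -> tuple[str, list[VariantRecord]]:
    """Read a single-sample VCF (GT:DP) into variant records.

    Returns ``(sample_id, records)``.  Multi-allelic rows are rejected;
    phase is ignored; records lacking DP are dropped with a warning.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    if len(vcf.samples) != 1:
        raise UsageError(
            f"{path}: expected exactly one sample column, found {len(vcf.samples)}"
        )
    sample = vcf.samples[0]
    records: list[VariantRecord] = []
    seen: set[tuple[str, int]] = set()
    for v in vcf:
        if len(v.ALT) != 1:
            raise FormatError(
                f"{v.CHROM}:{v.POS}: multi-allelic row (ALT={','.join(v.ALT)}); "
                "split or filter the VCF first"
            )
        key = (v.CHROM, v.POS)
        if key in seen:
            raise FormatError(f"{v.CHROM}:{v.POS}: duplicate record for this position")
        seen.add(key)
        gts = v.genotypes
        if not gts or gts[0][0] < 0 or gts[0][1] < 0:
            raise FormatError(f"{v.CHROM}:{v.POS}: missing GT")
        a1, a2 = gts[0][0], gts[0][1]
        dp = v.format("DP")
        if dp is None:
            log.warning("%s:%d: missing DP, record dropped", v.CHROM, v.POS)
            continue
        depth = int(dp[0][0])
        if depth < 0:
            log.warning("%s:%d: missing DP, record dropped", v.CHROM, v.POS)
            continue
        ref, alt = v.REF.upper(), v.ALT[0].upper()
        alleles = [ref, alt]
        records.append(
            VariantRecord(
                chrom=v.CHROM,
                pos=v.POS,
                ref=ref,
                alt=alt,
                allele1=alleles[a1],
                allele2=alleles[a2],
                depth=depth,
            )
        )
    return sample, records


# ---------------------------------------------------------------------------
# Tabular output

CANDIDATE_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "class",
    "vtype",
    "depth_wt",
    "depth_mut",
    "region",
    "gene_id",
]

EFFECT_COLUMNS = [
    "gene_id",
    "chrom",
    "pos",
    "ref",
    "alt",
    "codon_number",
    "ref_aa",
    "alt_aa",
    "synonymous",
]

PRIMER_COLUMNS = [
    "set_id",
    "role",
    "name",
    "chrom",
    "strand",
    "three_prime_pos",
    "length",
    "tm",
    "sequence",
    "engineered_mismatch",
]

VALIDATION_COLUMNS = [
    "set_id",
    "pair",
    "template",
    "amplified",
    "product_len",
    "forward_mismatch_offsets",
    "reverse_mismatch_offsets",
    "discriminating",
]


def _write_tsv(path: str, columns: Sequence[str], rows: Iterable[Sequence]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(columns) + "\n")
        for row in rows:
            fh.write("\t".join("" if v is None else str(v) for v in row) + "\n")


def write_candidates_tsv(candidates, path: str | os.PathLike) -> None:
    """Write marker candidates (one row per locus) as TSV."""
    rows = []
    for c in candidates:
        loc = c.locus
        rows.append(
            [
                loc.chrom,
                loc.pos,
                loc.ref,
                c.mut_allele,
                loc.polymorph_class,
                loc.vtype,
                loc.wt_depth,
                loc.mut_depth,
                c.region.value,
                c.region.gene_id,
            ]
        )
    _write_tsv(str(path), CANDIDATE_COLUMNS, rows)


def write_effects_tsv(effects, path: str | os.PathLike) -> None:
    rows = [
        [
            e.change.gene_id,
            e.chrom,
            e.pos,
            e.ref,
            e.alt,
            e.change.codon_number,
            e.change.ref_aa,
            e.change.alt_aa,
            str(e.change.synonymous).lower(),
        ]
        for e in effects
    ]
    _write_tsv(str(path), EFFECT_COLUMNS, rows)


def write_primers_tsv(primer_sets, path: str | os.PathLike) -> None:
    rows = []
    for set_id, ps in primer_sets:
        for role, primer in ps.primers():
            mm = primer.engineered_mismatch
            rows.append(
                [
                    set_id,
                    role,
                    primer.name,
                    primer.chrom,
                    primer.strand,
                    primer.three_prime_pos,
                    len(primer.sequence),
                    primer.tm,
                    primer.sequence,
                    "" if mm is None else f"{mm[0]}:{mm[2]}>{mm[1]}",
                ]
            )
    _write_tsv(str(path), PRIMER_COLUMNS, rows)


def write_primers_fasta(primer_sets, path: str | os.PathLike) -> None:
    """Primer FASTA; headers carry the primer role and 3' genomic coordinate."""
    with open(path, "w") as fh:
        for set_id, ps in primer_sets:
            for role, primer in ps.primers():
                fh.write(
                    f">{set_id}|{role}|{primer.chrom}:{primer.three_prime_pos}"
                    f"|strand={primer.strand}\n{primer.sequence}\n"
                )


def write_validation_tsv(validations, path: str | os.PathLike) -> None:
    rows = []
    for set_id, rep in validations:
        for pair, res in (
            ("AS", rep.as_wt),
            ("AS", rep.as_mut),
            ("control", rep.control_wt),
            ("control", rep.control_mut),
        ):
            rows.append(
                [
                    set_id,
                    pair,
                    res.template_label,
                    str(res.amplified).lower(),
                    res.product_len,
                    ",".join(map(str, res.forward_mismatch_offsets)),
                    ",".join(map(str, res.reverse_mismatch_offsets)),
                    str(rep.discriminating).lower(),
                ]
            )
    _write_tsv(str(path), VALIDATION_COLUMNS, rows)


def write_summary_report(summaries: Mapping[str, "object"], path) -> None:
    """Structured text report of per-sample variant count summaries."""
    with open(path, "w") as fh:
        for label, s in summaries.items():
            fh.write(s.report(label) + "\n")
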