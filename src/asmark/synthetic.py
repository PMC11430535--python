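"""Synthetic genome, gene models and planted variant tables.

Generates a reference genome, non-overlapping gene models, and two
single-sample variant tables (wild type and mutant) with a known
planted truth, so that every downstream stage — zygosity/region
classification, two-sample comparison, depth filtering, effect
annotation and AS-PCR design — can be tested end-to-end without any
external data.

Planted roles
-------------
``shared``         homozygous alternate in both samples (not polymorphic)
``wt_only_hom``    homozygous alternate in the wild type only
``mut_only_hom``   homozygous alternate in the mutant only — the marker
                   candidates when their depth clears the gate
``mut_only_het``   heterozygous in the mutant only
``decoy``          mutant-only homozygous variants planted *below* the
                   depth gate (SNPs at ``depth_low``, InDels at
                   ``depth_indel_decoy``)

Depths are fixed constants per role so filter behaviour is exactly
predictable; ``noisy_depth`` draws Poisson depths around the constants
instead (off by default).  Planted loci are pairwise at least
``min_spacing`` apart and at least ``exon_margin`` from every exon/CDS
boundary, keeping primer windows and codon context clean.
"""

from __future__ import annotations

import os
from bisect import bisect_left, insort
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import CapacityError, UsageError
from .formats import Genome, GeneModel, VariantRecord, write_fasta

TRUTH_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "vtype",
    "planted_role",
    "expected_class",
    "expected_candidate",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class PlantingDesign:
    """Counts, depths and geometry of the planted variant set.

    Defaults are the reference study conditions used throughout the
    test-suite: a deeply covered mutant-specific homozygous set
    (``depth_high`` = 30, above the SNP gate of 20), candidate InDels at
    ``depth_low`` = 15 (above the InDel gate of 10 but below the SNP
    gate), and decoys that must be rejected by the depth filter.
    """

    n_shared_snp: int = 500
    n_wt_only_hom_snp: int = 300
    n_mut_only_hom_snp: int = 50
    n_mut_only_het_snp: int = 40
    n_mut_only_hom_indel: int = 20
    n_low_depth_decoys: int = 25
    depth_high: int = 30
    depth_low: int = 15
    depth_indel_decoy: int = 8
    cds_fraction: float = 0.4
    min_spacing: int = 50
    exon_margin: int = 30
    end_margin: int = 400
    noisy_depth: bool = False
    seed: int = 1

    def __post_init__(self):
        counts = (
            self.n_shared_snp,
            self.n_wt_only_hom_snp,
            self.n_mut_only_hom_snp,
            self.n_mut_only_het_snp,
            self.n_mut_only_hom_indel,
            self.n_low_depth_decoys,
        )
        if any(n < 0 for n in counts):
            raise UsageError("planting counts must be non-negative")
        if not self.depth_high > 20:
            raise UsageError("depth_high must exceed the SNP gate (20)")
        if not self.depth_low <= 20:
            raise UsageError("depth_low must not exceed the SNP gate (20)")
        if not self.depth_indel_decoy <= 10:
            raise UsageError("depth_indel_decoy must not exceed the InDel gate (10)")
        if not 0.0 <= self.cds_fraction <= 1.0:
            raise UsageError("cds_fraction must lie in [0,1]")


def simulate_genome(
    seed: int,
    chrom_lengths: tuple[int, ...] = (600_000, 400_000),
    gc_fraction: float = 0.38,
) -> Genome:
    """I.i.d. random genome with the requested GC content.

    Chromosomes are named ``chr1``, ``chr2``, ...  Deterministic for a
    fixed seed; base composition converges on ``gc_fraction`` (within
    ±2% for lengths ≥ 100 kb by the binomial concentration bound).
    """
    if any(l < 10_000 for l in chrom_lengths):
        raise UsageError("chromosome lengths must be >= 10,000")
    if not 0.0 < gc_fraction < 1.0:
        raise UsageError("gc_fraction must lie strictly in (0,1)")
    rng = np.random.default_rng(seed)
    at = (1.0 - gc_fraction) / 2.0
    gc = gc_fraction / 2.0
    chroms = {}
    for i, length in enumerate(chrom_lengths, start=1):
        draws = rng.choice(4, size=length, p=[at, gc, gc, at])
        chroms[f"chr{i}"] = "".join(_BASES[draws])
    return Genome(chroms)


def simulate_gene_models(
    genome: Genome, n_genes: int, seed: int
) -> list[GeneModel]:
    """Place non-overlapping genes with 1–5 exons on both strands.

    Each gene has short UTR segments on its terminal exons so the
    ``exon_noncoding`` region class is exercised; total CDS length is a
    multiple of 3 by construction.
    """
    rng = np.random.default_rng(seed)
    total_len = sum(genome.length(c) for c in genome.names)
    quotas = {}
    assigned = 0
    for c in genome.names:
        q = int(round(n_genes * genome.length(c) / total_len))
        quotas[c] = q
        assigned += q
    # fix rounding drift on the first chromosome
    if genome.names:
        quotas[genome.names[0]] += n_genes - assigned

    genes: list[GeneModel] = []
    idx = 0
    for chrom in genome.names:
        length = genome.length(chrom)
        cursor = int(rng.integers(300, 1500))
        placed = 0
        while placed < quotas[chrom]:
            n_exons = int(rng.integers(1, 6))
            exon_lens = rng.integers(120, 361, size=n_exons)
            intron_lens = rng.integers(80, 251, size=max(n_exons - 1, 0))
            span = int(exon_lens.sum() + intron_lens.sum())
            if cursor + span + 300 > length:
                raise CapacityError(
                    f"cannot place {n_genes} genes: chromosome {chrom!r} "
                    f"exhausted after {placed} of {quotas[chrom]}"
                )
            exons = []
            pos = cursor
            for k in range(n_exons):
                exons.append((pos, pos + int(exon_lens[k]) - 1))
                pos = exons[-1][1] + 1
                if k < n_exons - 1:
                    pos += int(intron_lens[k])
            utr5 = int(rng.integers(5, 21))
            utr3 = int(rng.integers(5, 21))
            total_exonic = int(exon_lens.sum())
            utr3 += (total_exonic - utr5 - utr3) % 3
            cds = [list(iv) for iv in exons]
            cds[0][0] += utr5
            cds[-1][1] -= utr3
            strand = "+" if rng.random() < 0.5 else "-"
            idx += 1
            genes.append(
                GeneModel(
                    gene_id=f"gene{idx:04d}",
                    chrom=chrom,
                    strand=strand,
                    exons=tuple(tuple(iv) for iv in exons),
                    cds=tuple(tuple(iv) for iv in cds),
                )
            )
            placed += 1
            cursor = exons[-1][1] + 1 + int(rng.integers(300, 1500))
    return genes


class _Spacer:
    """Per-chromosome chosen-position sets enforcing a minimum spacing."""

    def __init__(self, spacing: int):
        self.spacing = spacing
        self._chosen: dict[str, list[int]] = {}

    def try_add(self, chrom: str, pos: int) -> bool:
        lst = self._chosen.setdefault(chrom, [])
        i = bisect_left(lst, pos)
        if i > 0 and pos - lst[i - 1] < self.spacing:
            return False
        if i < len(lst) and lst[i] - pos < self.spacing:
            return False
        insort(lst, pos)
        return True


def _eligibility_masks(genome: Genome, genes, design: PlantingDesign):
    """Boolean masks (0-based) of plantable positions per chromosome.

    ``eligible``: away from chromosome ends and from every exon/CDS
    boundary.  ``in_cds``: inside a CDS interval (per strand).
    """
    eligible = {}
    cds_plus = {}
    cds_minus = {}
    m = design.exon_margin
    for chrom in genome.names:
        L = genome.length(chrom)
        e = np.ones(L, dtype=bool)
        e[: design.end_margin] = False
        e[L - design.end_margin :] = False
        eligible[chrom] = e
        cds_plus[chrom] = np.zeros(L, dtype=bool)
        cds_minus[chrom] = np.zeros(L, dtype=bool)
    for g in genes:
        e = eligible[g.chrom]
        L = len(e)
        for intervals in (g.exons, g.cds):
            for s, end in intervals:
                for b in (s, end):
                    e[max(b - 1 - m, 0) : min(b + m, L)] = False
        tgt = cds_plus if g.strand == "+" else cds_minus
        for s, end in g.cds:
            tgt[g.chrom][s - 1 : end] = True
    return eligible, cds_plus, cds_minus


def _sample_positions(rng, pool_by_chrom, spacer, n, what):
    """Draw ``n`` spaced positions (1-based) from per-chromosome pools."""
    chroms = [c for c, p in pool_by_chrom.items() if len(p)]
    sizes = np.array([len(pool_by_chrom[c]) for c in chroms], dtype=float)
    if not chroms or sizes.sum() < n:
        raise CapacityError(f"not enough eligible positions for {what}")
    out = []
    attempts = 0
    max_attempts = 200 * max(n, 1) + 1000
    probs = sizes / sizes.sum()
    while len(out) < n:
        attempts += 1
        if attempts > max_attempts:
            raise CapacityError(
                f"could not place {n} {what} loci with the required spacing"
            )
        c = chroms[int(rng.choice(len(chroms), p=probs))]
        pool = pool_by_chrom[c]
        pos = int(pool[int(rng.integers(len(pool)))]) + 1  # to 1-based
        if spacer.try_add(c, pos):
            out.append((c, pos))
    return out


def plant_variants(
    genome: Genome, genes, design: PlantingDesign
) -> tuple[list[VariantRecord], list[VariantRecord], pd.DataFrame]:
    """Plant the designed variant set; returns (wt, mutant, truth) tables.

    A fraction ``cds_fraction`` of the mutant-only homozygous SNPs is
    placed inside CDS, split between plus- and minus-strand genes, to
    exercise amino-acid effect annotation.  InDels (1–10 bp, anchored)
    are planted outside CDS only.
    """
    rng = np.random.default_rng(design.seed)
    eligible, cds_plus, cds_minus = _eligibility_masks(genome, genes, design)
    spacer = _Spacer(design.min_spacing)

    pools = {}
    pools["cds+"] = {c: np.flatnonzero(eligible[c] & cds_plus[c]) for c in genome.names}
    pools["cds-"] = {c: np.flatnonzero(eligible[c] & cds_minus[c]) for c in genome.names}
    noncds = {
        c: np.flatnonzero(eligible[c] & ~cds_plus[c] & ~cds_minus[c])
        for c in genome.names
    }
    anywhere = {c: np.flatnonzero(eligible[c]) for c in genome.names}

    n_cds = int(round(design.cds_fraction * design.n_mut_only_hom_snp))
    n_cds_plus = n_cds // 2
    n_cds_minus = n_cds - n_cds_plus
    n_snp_decoys = (design.n_low_depth_decoys + 1) // 2
    n_indel_decoys = design.n_low_depth_decoys - n_snp_decoys

    placements = {
        "mut_only_hom_snp_cds+": _sample_positions(
            rng, pools["cds+"], spacer, n_cds_plus, "CDS(+) candidate SNP"
        ),
        "mut_only_hom_snp_cds-": _sample_positions(
            rng, pools["cds-"], spacer, n_cds_minus, "CDS(-) candidate SNP"
        ),
        "mut_only_hom_snp": _sample_positions(
            rng, noncds, spacer, design.n_mut_only_hom_snp - n_cds, "candidate SNP"
        ),
        "shared": _sample_positions(
            rng, anywhere, spacer, design.n_shared_snp, "shared SNP"
        ),
        "wt_only_hom": _sample_positions(
            rng, anywhere, spacer, design.n_wt_only_hom_snp, "WT-only SNP"
        ),
        "mut_only_het": _sample_positions(
            rng, anywhere, spacer, design.n_mut_only_het_snp, "mutant het SNP"
        ),
        "mut_only_hom_indel": _sample_positions(
            rng, noncds, spacer, design.n_mut_only_hom_indel, "candidate InDel"
        ),
        "decoy_snp": _sample_positions(
            rng, noncds, spacer, n_snp_decoys, "decoy SNP"
        ),
        "decoy_indel": _sample_positions(
            rng, noncds, spacer, n_indel_decoys, "decoy InDel"
        ),
    }

    def depth(base: int) -> int:
        if design.noisy_depth:
            return max(int(rng.poisson(base)), 1)
        return base

    def snp_alt(chrom: str, pos: int) -> tuple[str, str]:
        ref = genome[chrom][pos - 1]
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        return ref, alt

    def indel_alleles(chrom: str, pos: int) -> tuple[str, str]:
        anchor = genome[chrom][pos - 1]
        k = int(rng.integers(1, 11))
        if rng.random() < 0.5:  # insertion
            ins = "".join(rng.choice(list("ACGT"), size=k))
            return anchor, anchor + ins
        return genome.fetch(chrom, pos, pos + k), anchor

    wt: list[VariantRecord] = []
    mut: list[VariantRecord] = []
    truth_rows = []

    def add(role, chrom, pos, ref, alt, in_wt, in_mut, hom_in_mut, d_wt, d_mut,
            expected_class, expected_candidate):
        if in_wt:
            wt.append(
                VariantRecord(chrom, pos, ref, alt, alt, alt, d_wt)
            )
        if in_mut:
            a1, a2 = (alt, alt) if hom_in_mut else (ref, alt)
            mut.append(VariantRecord(chrom, pos, ref, alt, a1, a2, d_mut))
        vtype = (
            "SNP"
            if len(ref) == len(alt) == 1
            else ("insertion" if len(alt) > len(ref) else "deletion")
        )
        truth_rows.append(
            dict(
                chrom=chrom,
                pos=pos,
                ref=ref,
                alt=alt,
                vtype=vtype,
                planted_role=role,
                expected_class=expected_class,
                expected_candidate=expected_candidate,
            )
        )

    for c, p in placements["shared"]:
        ref, alt = snp_alt(c, p)
        add("shared", c, p, ref, alt, True, True, True,
            depth(design.depth_high), depth(design.depth_high), "none", False)
    for c, p in placements["wt_only_hom"]:
        ref, alt = snp_alt(c, p)
        add("wt_only_hom", c, p, ref, alt, True, False, True,
            depth(design.depth_high), 0, "homo", False)
    for key in ("mut_only_hom_snp_cds+", "mut_only_hom_snp_cds-", "mut_only_hom_snp"):
        for c, p in placements[key]:
            ref, alt = snp_alt(c, p)
            add("mut_only_hom", c, p, ref, alt, False, True, True,
                0, depth(design.depth_high), "homo", True)
    for c, p in placements["mut_only_het"]:
        ref, alt = snp_alt(c, p)
        add("mut_only_het", c, p, ref, alt, False, True, False,
            0, depth(design.depth_high), "hetero", False)
    for c, p in placements["mut_only_hom_indel"]:
        ref, alt = indel_alleles(c, p)
        add("mut_only_hom", c, p, ref, alt, False, True, True,
            0, depth(design.depth_low), "homo", design.depth_low > 10)
    for c, p in placements["decoy_snp"]:
        ref, alt = snp_alt(c, p)
        add("decoy", c, p, ref, alt, False, True, True,
            0, depth(design.depth_low), "homo", False)
    for c, p in placements["decoy_indel"]:
        ref, alt = indel_alleles(c, p)
        add("decoy", c, p, ref, alt, False, True, True,
            0, depth(design.depth_indel_decoy), "homo", False)

    order = {c: i for i, c in enumerate(genome.names)}
    wt.sort(key=lambda r: (order[r.chrom], r.pos))
    mut.sort(key=lambda r: (order[r.chrom], r.pos))
    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    truth = truth.sort_values(
        ["chrom", "pos"], key=lambda s: s.map(order) if s.name == "chrom" else s
    ).reset_index(drop=True)
    return wt, mut, truth


# ---------------------------------------------------------------------------
# Bundle emission (plain-text GFF3 / VCF writers for the synthetic truth)


def write_gff3(genes, genome: Genome, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom in genome.names:
            fh.write(f"##sequence-region {chrom} 1 {genome.length(chrom)}\n")
        for g in genes:
            attrs = f"ID={g.gene_id}"
            fh.write(
                f"{g.chrom}\tasmark\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            mrna_id = f"{g.gene_id}.t1"
            fh.write(
                f"{g.chrom}\tasmark\tmRNA\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={mrna_id};Parent={g.gene_id}\n"
            )
            for i, (s, e) in enumerate(g.exons, 1):
                fh.write(
                    f"{g.chrom}\tasmark\texon\t{s}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={mrna_id}.exon{i};Parent={mrna_id}\n"
                )
            cds_iv = list(g.cds) if g.strand == "+" else list(g.cds)[::-1]
            phase = 0
            for i, (s, e) in enumerate(cds_iv, 1):
                fh.write(
                    f"{g.chrom}\tasmark\tCDS\t{s}\t{e}\t.\t{g.strand}\t{phase}\t"
                    f"ID={mrna_id}.cds{i};Parent={mrna_id}\n"
                )
                phase = (3 - ((e - s + 1) - phase) % 3) % 3


def write_vcf(records, genome: Genome, sample: str, path: str | os.PathLike) -> None:
    """Write a minimal single-sample VCF v4.2 with GT:DP genotypes."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in genome.names:
            fh.write(f"##contig=<ID={chrom},length={genome.length(chrom)}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample + "\n"
        )
        for r in records:
            gt_alleles = sorted(
                "0" if a == r.ref else "1" for a in (r.allele1, r.allele2)
            )
            gt = "/".join(gt_alleles)
            fh.write(
                f"{r.chrom}\t{r.pos}\t.\t{r.ref}\t{r.alt}\t.\t.\t.\tGT:DP\t"
                f"{gt}:{r.depth}\n"
            )


@dataclass
class SyntheticBundle:
    """In-memory handles plus file paths of an emitted synthetic data set."""

    genome: Genome
    genes: list
    wt_records: list
    mut_records: list
    truth: pd.DataFrame
    paths: dict = field(default_factory=dict)


def simulate_bundle(
    outdir: str | os.PathLike,
    design: PlantingDesign | None = None,
    chrom_lengths: tuple[int, ...] = (600_000, 400_000),
    gc_fraction: float = 0.38,
    n_genes: int = 200,
) -> SyntheticBundle:
    """Generate and write a complete synthetic data set to ``outdir``.

    Emits ``genome.fasta``, ``genes.gff3``, ``wt.vcf``, ``mutant.vcf``
    and ``truth.tsv``.  Fully deterministic for a fixed design seed.
    """
    design = design or PlantingDesign()
    os.makedirs(outdir, exist_ok=True)
    genome = simulate_genome(design.seed, chrom_lengths, gc_fraction)
    genes = simulate_gene_models(genome, n_genes, design.seed + 1)
    wt, mut, truth = plant_variants(genome, genes, design)
    paths = {
        "genome": os.path.join(outdir, "genome.fasta"),
        "gff3": os.path.join(outdir, "genes.gff3"),
        "wt_vcf": os.path.join(outdir, "wt.vcf"),
        "mut_vcf": os.path.join(outdir, "mutant.vcf"),
        "truth": os.path.join(outdir, "truth.tsv"),
    }
    write_fasta(genome, paths["genome"])
    write_gff3(genes, genome, paths["gff3"])
    write_vcf(wt, genome, "WT", paths["wt_vcf"])
    write_vcf(mut, genome, "mutant", paths["mut_vcf"])
    truth.to_csv(paths["truth"], sep="\t", index=False)
    return SyntheticBundle(genome, genes, wt, mut, truth, paths)
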