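# asmark

Selection-marker discovery for induced plant mutants: compare a mutant's
whole-genome variant calls against its wild-type (WT) progenitor, keep the
mutant-specific homozygous variants that are trustworthy at the observed
sequencing depth, annotate their protein-level consequences, and design
allele-specific PCR (AS-PCR) genotyping markers that are validated *in
silico* before anyone orders an oligo.

The package targets the common breeding-program situation (e.g. a
gamma-ray citrus mutant and its parent cultivar resequenced against one
reference assembly): two single-sample VCFs, one reference FASTA, one GFF3
— and the need for a cheap PCR assay that tells the mutant apart from the
WT and from sibling varieties.

## The method

**Polymorphic loci.** Over the union of positions called in either
sample, a locus is *polymorphic* when the two samples' unordered genotype
pairs differ (a position called in only one sample is imputed
homozygous-reference in the other). Each locus gets a binary class:
*homo* when both genotypes are homozygous, *hetero* otherwise — so
`homo + hetero = total` always.

**Candidate filter.** Marker candidates are the class-*homo* loci where
the mutant is homozygous for a non-reference allele and the read depth
strictly exceeds 20 for SNPs and 10 for InDels (depth exactly at the
threshold is rejected).

**Effect annotation.** Candidate SNPs inside a CDS are mapped to their
offset in the spliced coding sequence; the reference and alternate codons
are translated with the standard genetic code, and the residue number is
`⌈offset/3⌉` (e.g. CDS offset 1177 → residue 393).

**AS-PCR design.** For each SNP candidate the allele-specific forward
primer ends exactly on the SNP with the mutant base as its 3′-terminal
nucleotide, and carries one engineered mismatch at the penultimate base
(a fixed transversion A↔C, G↔T). The 5′ end grows until the Wallace
melting temperature, Tm = 2(A+T) + 4(G+C), reaches 58 °C. The common
reverse primer and the amplification-control pair are placed on
variant-free footprints, so their sequence is identical on both alleles.

**In-silico PCR.** Extension requires a perfectly paired 3′-terminal
base, at most one total mismatch, and no mismatch in the 3′-terminal
three bases other than the engineered one. On the mutant haplotype the
AS forward is one (tolerated) internal mismatch from perfect; on the WT
haplotype the added terminal mismatch blocks extension. A marker is
*discriminating* when the AS pair amplifies the mutant haplotype only and
the control pair amplifies both.

A synthetic-data module generates a random genome, gene models and two
variant tables with a known planted truth, so the whole pipeline is
testable end-to-end without any sequencing data.

## Worked example

Simulate a 1 Mb two-chromosome genome with 200 genes and the default
planted design (500 shared SNPs, 300 WT-only homozygous SNPs, 50
mutant-only homozygous SNPs at depth 30, 40 mutant-only heterozygous
SNPs, 20 mutant-only homozygous InDels at depth 15, 25 low-depth decoys),
then run the full pipeline:

```sh
asmark simulate --seed 1 -o sim/
asmark run --genome sim/genome.fasta --gff3 sim/genes.gff3 \
           --wt-vcf sim/wt.vcf --mut-vcf sim/mutant.vcf -o out/
```

`out/polymorphism_summary.tsv` shows the two-class comparison:

```
vtype   total   homo    hetero
SNP     403     363     40
InDel   32      32      0
```

403 SNP loci differ between the samples (the 500 shared variants are
identical in both and are correctly absent); the 40 mutant-heterozygous
SNPs land in the *hetero* class. The depth gate then keeps exactly the 70
planted mutant-specific homozygous variants (50 SNPs + 20 InDels) in
`out/candidates.tsv`:

```
chrom  pos    ref  alt  class  vtype      depth_wt  depth_mut  region      gene_id
chr1   25744  T  TCCCGAT  homo  insertion            15        intergenic
chr1   33394  G  C        homo  SNP                  30        CDS         gene0016
```

`out/effects.tsv` reports the codon consequence of each coding SNP
(e.g. `gene0016 … codon 86, T→S, non-synonymous`), and `out/primers.tsv`
holds the designed sets — note the forward primer's engineered `2:A>C`
mismatch at its penultimate base:

```
set_id      role            strand  three_prime_pos  tm    sequence               engineered_mismatch
chr1_33394  as_forward      +       33394            58.0  TGTATAACCATAAAACCCACC  2:A>C
chr1_33394  common_reverse  -       33493            58.0  TCGGAACTAAACTAGAGGAAT
```

`out/validation.tsv` confirms discrimination for every marker: the AS
pair fails on the WT template (mismatch offsets `1,2`: the allele
mismatch at the terminus plus the engineered one) and amplifies the
mutant template (offset `2` only), while the control amplifies both:

```
set_id      pair     template  amplified  product_len  forward_mismatch_offsets
chr1_33394  AS       WT        false                   1,2
chr1_33394  AS       mutant    true       100          2
chr1_33394  control  WT        true       100
chr1_33394  control  mutant    true       100
```

The same workflow runs on real data by pointing the flags (or a
`key=value` config file, see `asmark run --show-config`) at your own
FASTA/GFF3/VCF files; an optional `--go-map` TSV adds per-aspect GO term
tallies for the candidate-affected genes.

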