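# Methods

This note documents the models, rules and parameter choices behind
`asmark`, what the synthetic data do and do not emulate, and the
numerical conventions the implementation commits to.

## Coordinates and record model

All coordinates are 1-based and inclusive end-to-end (the native GFF3 /
VCF convention); the format readers are the only place 0-based library
conventions are converted. Variants are biallelic, VCF-style: a SNP has
single-base ref and alt; InDels share an anchor base and differ in
length. Multi-allelic rows are rejected rather than split — the
two-class polymorphism scheme below is defined on two alleles, and
splitting would silently create multiple records at one position.
Genotype phase is ignored (`1|0` ≡ `0/1`): only zygosity matters here.
Records without a DP value are dropped with a warning, because the
candidate filter is a depth filter.

## Zygosity, regions, and the two-sample comparison

A genotype is *homozygous* iff its two alleles are identical. Region
classes are strictly exclusive — `CDS`, `exon_noncoding`, `intron`
(inside the exon hull of a gene but in no exon), `intergenic` — so they
partition any variant table and the partition is testable; the
conventional "exon" count is recovered as `CDS + exon_noncoding` for
display. Where genes overlap, a position takes the highest-priority
class (CDS > exon_noncoding > intron), ties broken by smallest gene ID.
InDels are assigned by their anchor position only; a span-aware rule
would need a policy for InDels crossing region boundaries and is left as
a future option. Gene extent is the exon hull as annotated — no
promoter or UTR extension beyond the GFF3.

`compare_samples` takes the union of positions called in either sample.
A position absent from one call set is imputed homozygous-reference
there, with that sample's depth recorded as unknown: two call sets
against one shared reference can only yield sample-specific homozygous
variants under this imputation. The risk that "absent" means "no
coverage" rather than "reference" is mitigated by the depth gate. Loci
where both samples carry the same unordered pair are not polymorphic and
are not emitted. The polymorphism class is binary: *homo* when both
genotypes are homozygous, *hetero* otherwise. The rare het-vs-het locus
with differing pairs is folded into *hetero* (and logged at debug
level), which keeps `homo + hetero = total` an exact invariant.

## The candidate filter

A marker candidate is a class-*homo* polymorphic locus where the mutant
is homozygous for a non-reference allele and depth strictly exceeds the
per-type threshold: SNPs > 20, InDels > 10 ("exceeding", so depth 20
and 10 are rejected). The gate is applied to the minimum of the depths
actually observed; mutant-specific loci have no WT record and hence no
WT depth, so by default the gate acts on the mutant depth alone. A
stricter `require_both_depths` mode drops any locus with an unobserved
depth — useful when the WT VCF is an all-sites file and absence really
is missing data.

## Effect annotation

Candidate SNPs in CDS are mapped to a 1-based offset in the spliced
coding sequence (minus-strand genes reverse-complemented, the alternate
base complemented before substitution). The affected codon is
`⌈offset/3⌉`; reference and alternate codons are translated with the
standard nuclear genetic code (translation table 1 — these are nuclear
plant genes; organellar codes are out of scope). Stops are reported as
`*` with no special "start-lost" class. InDel consequences
(frameshifts) are deliberately not predicted; coding InDels are
reported as such without a protein-level claim. The test suite checks
annotation against an independent oracle: mutate the genome, re-splice,
re-translate the entire protein, and diff.

## AS-PCR design model

*Allele-specific forward.* A plus-strand primer ending exactly on the
SNP, 3′-terminal base set to the mutant allele. One engineered mismatch
is placed at the second base from the 3′ end (the penultimate base;
offset 2 with the terminus as offset 1). The alternative
antepenultimate reading (offset 3) exists in AS-PCR practice and is
selectable via `--mismatch-offset`. The mismatch base comes from a
fixed transversion map A↔C, G↔T: it is deterministic, an involution,
always a true mismatch, and swaps a weak for a strong pairing so the Tm
moves by only ±2 °C. Strength-balancing schemes could be plugged in via
the `mismatch_map` parameter. The 5′ end is extended from 18 nt until
the Wallace Tm of the final (mismatch-containing) sequence reaches the
58 °C target, capped at 30 nt (a too-cold primer is emitted flagged,
with a warning, rather than silently dropped).

*Melting temperature.* The Wallace rule Tm = 2(A+T) + 4(G+C) is the
default for all lengths because it is exact integer arithmetic and
therefore directly assertable in tests; a nearest-neighbor estimate
(`method="nn"`, Biopython's implementation) is available but is not the
surface any contract depends on.

*Common reverse.* Scans 3′-end positions downstream so the product —
defined throughout as the inclusive distance between the two primers'
3′-terminal coordinates — falls in 100–300 bp, keeps only windows whose
footprint overlaps no variant locus of either sample, and among those
picks the Tm closest to the forward primer's, ties toward the smaller
product. Footprints are blocked against *all* called variants of both
samples, not only polymorphic loci: a variant shared by both samples
still differs from the reference the primer is copied from, and would
otherwise cost the "zero mismatches on both haplotypes" guarantee. The
100–300 bp default suits a 15 s extension step and resolves cleanly on
a 2% agarose gel.

*Control pair.* A deterministic scan (from position 1000, step 50,
chromosome by chromosome) for a window whose primer footprints and
whole enclosed product are variant-free; it amplifies both haplotypes
by construction and is designed once per run and shared across sets.

## In-silico PCR

Haplotype templates are built by applying each sample's homozygous
non-reference variants to the reference; a per-chromosome offset map
translates reference coordinates of primer footprints onto the
InDel-shifted haplotype. Primers are checked only at their design
coordinates — the discrimination contract is local, and a genome-wide
specificity scan is a separate concern (an exhaustive mode would be
quadratic and is not implemented). Extension requires: a perfectly
paired 3′-terminal base; at most `max_total_mm` mismatches in total
(default 1 — whether a real polymerase tolerates more internal
mismatches is assay-dependent, so this is an explicit model parameter);
and no mismatch at 3′ offsets 1–3 except the engineered one. A marker
*discriminates* iff the AS pair amplifies the mutant haplotype only and
the control amplifies both.

## Synthetic data: what it emulates, and what it does not

The generator emulates the *structure* of a WT/mutant resequencing
comparison: an i.i.d. random genome (default 1 Mb over two chromosomes,
GC 0.38, a typical plant nuclear value), 200 non-overlapping gene models
with 1–5 exons, short terminal UTRs and CDS length divisible by 3, and
a planted variant set with shared, WT-only, mutant-only homozygous and
heterozygous SNPs, mutant-only InDels (1–10 bp, outside CDS), and
below-threshold decoys. Depths are fixed constants per role
(high = 30 > the SNP gate; low = 15, above the InDel gate but not the
SNP gate; InDel decoys at 8) so that filter behaviour is exactly
predictable; a Poisson `noisy_depth` option exists, off by default,
because exact expected counts are what make the end-to-end contract
sharp. 40% of the mutant-only homozygous SNPs are placed inside CDS,
split between strands, to exercise effect annotation on both.

Planted loci are pairwise ≥ 50 bp apart and ≥ 30 bp from every
exon/CDS boundary, and ≥ 400 bp from chromosome ends, so every
candidate has clean primer windows. Consequently the planted set never
lands in the short UTR segments (the `exon_noncoding` class is
exercised by unit tests instead), and no primer footprint ever overlaps
a foreign variant — real data offer no such guarantees. The simulator
also omits sequencing error, genotyping error, multi-allelic sites,
linkage structure and coverage dropouts; passing tests therefore
demonstrate the correctness of the comparison/filter/design logic under
its stated assumptions, not robustness to miscalled genotypes.
Het-vs-het loci differing between samples are not planted by default
(the binary class scheme gives them no class of their own); the
comparison handles them anyway, folding them into *hetero*.

## Determinism and numerical conventions

Every stochastic step flows from a single integer seed through
`numpy.random.default_rng`; the same seed and configuration produce
byte-identical output files, and the run manifest records the
configuration, seed and input checksums (no timestamps). Ties are broken
deterministically everywhere (lexicographic gene IDs; smaller product
length in primer scans). Depth thresholds are strict inequalities.
Problem sizes in the test-suite and acceptance script (1 Mb genome, 200
genes, ~935 planted loci; smaller genomes for the randomized-design
sweeps) were chosen so a complete run is a matter of seconds while every
count remains exactly predictable.

## Known limitations

- No genome-wide primer specificity screen, thermodynamic
  secondary-structure checks (hairpins, dimers), or multiplex design.
- No frameshift/protein prediction for InDels; no splice-site or UTR
  effect classes.
- The GO stage is a direct-annotation tally (count distinct genes per
  term per namespace) with no ancestor propagation or enrichment
  statistics — annotation provenance is the caller's responsibility.
- Two samples only; population-scale comparison and genotype-likelihood
  modelling are out of scope.
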