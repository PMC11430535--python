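import pytest

from asmark import PipelineConfig, run_pipeline
from asmark.formats import GeneModel, Genome
from asmark.synthetic import PlantingDesign, simulate_bundle


@pytest.fixture(scope="session")
def bundle(tmp_path_factory):
    """Reference synthetic bundle: 1 Mb over two chromosomes, 200 genes,
    default planted design, seed 1."""
    outdir = tmp_path_factory.mktemp("bundle")
    return simulate_bundle(str(outdir), PlantingDesign(seed=1))


@pytest.fixture(scope="session")
def pipeline_results(bundle, tmp_path_factory):
    """Full pipeline run (through validation) on the reference bundle."""
    outdir = tmp_path_factory.mktemp("pipeline_out")
    cfg = PipelineConfig(
        genome=bundle.paths["genome"],
        gff3=bundle.paths["gff3"],
        wt_vcf=bundle.paths["wt_vcf"],
        mut_vcf=bundle.paths["mut_vcf"],
        outdir=str(outdir),
    )
    return run_pipeline(cfg, through="validate")


@pytest.fixture
def tiny_genome():
    """60 bp toy chromosome with a hand-placed gene context."""
    #           1234567890...
    seq = "ATGGTTACCGGATCCATTGGCATGCAAGTTCCGGAATTCAAGGTTGACTAAACGTACGT"
    return Genome({"chr1": seq})


@pytest.fixture
def tiny_gene():
    """Single-exon plus-strand gene on tiny_genome: CDS spans 1..45."""
    return GeneModel(
        gene_id="gA", chrom="chr1", strand="+",
        exons=((1, 52),), cds=((1, 45),),
    )
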