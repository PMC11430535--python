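"""End-to-end orchestration: classify → compare → filter → annotate →
design → validate → GO tally, with deterministic outputs and a run
manifest."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Optional

from . import __version__
from .classify import GeneIndex, summarize_variants
from .compare import (
    compare_samples,
    filter_marker_candidates,
    polymorphism_summary,
)
from .design import (
    HaplotypeTemplate,
    MarkerValidation,
    PrimerParams,
    blocked_loci,
    design_control_pair,
    design_marker_set,
    insilico_pcr,
)
from .effects import annotate_candidate_effects
from .errors import AsmarkError, ConsistencyError, DesignError, UsageError
from .formats import (
    read_fasta,
    read_gff3,
    read_vcf,
    write_candidates_tsv,
    write_effects_tsv,
    write_primers_fasta,
    write_primers_tsv,
    write_summary_report,
    write_validation_tsv,
)
from .gotally import read_go_map, tally_go

log = logging.getLogger(__name__)

STAGES = ("classify", "compare", "design", "validate", "all")


@dataclass
class PipelineConfig:
    """Paths, thresholds and primer parameters for one pipeline run."""

    genome: str = ""
    gff3: str = ""
    wt_vcf: str = ""
    mut_vcf: str = ""
    go_map: str = ""
    outdir: str = "asmark_out"
    min_depth_snp: int = 20
    min_depth_indel: int = 10
    require_both_depths: bool = False
    target_tm: float = 58.0
    min_len: int = 18
    max_len: int = 30
    product_min: int = 100
    product_max: int = 300
    mismatch_offset: int = 2
    max_total_mm: int = 1
    go_top_n: int = 20
    permissive: bool = False
    seed: int = 1

    def __post_init__(self):
        if self.min_depth_snp < 0 or self.min_depth_indel < 0:
            raise UsageError("depth thresholds must be non-negative")

    def primer_params(self) -> PrimerParams:
        return PrimerParams(
            target_tm=self.target_tm,
            min_len=self.min_len,
            max_len=self.max_len,
            product_min=self.product_min,
            product_max=self.product_max,
            mismatch_offset=self.mismatch_offset,
            max_total_mm=self.max_total_mm,
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_file(cls, path: str, **overrides) -> "PipelineConfig":
        """Flat ``key=value`` config file; CLI overrides take precedence."""
        values: dict = {}
        fields = {f.name: f.type for f in dataclasses.fields(cls)}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                if "=" not in line:
                    raise UsageError(f"{path}:{lineno}: expected key=value")
                key, _, raw = line.partition("=")
                key, raw = key.strip(), raw.strip()
                if key not in fields:
                    raise UsageError(f"{path}:{lineno}: unknown config key {key!r}")
                values[key] = _coerce(raw)
        values.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**values)


def _coerce(raw: str):
    if raw.lower() in ("true", "false"):
        return raw.lower() == "true"
    for cast in (int, float):
        try:
            return cast(raw)
        except ValueError:
            pass
    return raw


@dataclass
class PipelineResults:
    """Everything a run computed, with file outputs listed in ``written``."""

    config: PipelineConfig
    wt_sample: str = ""
    mut_sample: str = ""
    summaries: dict = field(default_factory=dict)
    polymorphic: list = field(default_factory=list)
    poly_summary: dict = field(default_factory=dict)
    candidates: list = field(default_factory=list)
    effects: list = field(default_factory=list)
    primer_sets: list = field(default_factory=list)  # (set_id, PrimerSet)
    design_failures: list = field(default_factory=list)  # (set_id, message)
    validations: list = field(default_factory=list)  # (set_id, MarkerValidation)
    go_tally: Optional[object] = None
    written: list = field(default_factory=list)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _check_reference_names(genome, wt_records, mut_records):
    bad = sorted(
        {r.chrom for r in (*wt_records, *mut_records) if r.chrom not in genome}
    )
    if bad:
        raise ConsistencyError(
            "VCF chromosomes absent from the reference FASTA: " + ", ".join(bad)
        )


def run_pipeline(config: PipelineConfig, through: str = "all") -> PipelineResults:
    """Run the pipeline up to and including stage ``through``.

    Stages in order: ``classify`` (per-sample summaries), ``compare``
    (polymorphic loci + candidate filter), ``design`` (+ effect
    annotation and primer sets), ``validate`` (in-silico PCR), ``all``
    (adds the optional GO tally).  Raises :class:`DesignError` at the
    end if any candidate failed design, unless ``config.permissive``.
    """
    if through not in STAGES:
        raise UsageError(f"unknown stage {through!r}")
    depth = STAGES.index(through)
    os.makedirs(config.outdir, exist_ok=True)
    res = PipelineResults(config=config)

    genome = read_fasta(config.genome)
    genes = read_gff3(config.gff3, genome)
    index = GeneIndex(genes)
    res.wt_sample, wt = read_vcf(config.wt_vcf)
    res.mut_sample, mut = read_vcf(config.mut_vcf)
    _check_reference_names(genome, wt, mut)

    def out(name: str) -> str:
        path = os.path.join(config.outdir, name)
        res.written.append(path)
        return path

    # -- classify
    res.summaries = {
        res.wt_sample: summarize_variants(wt, index),
        res.mut_sample: summarize_variants(mut, index),
    }
    write_summary_report(res.summaries, out("summary.txt"))

    if depth >= 1:  # compare
        res.polymorphic = compare_samples(wt, mut)
        res.poly_summary = polymorphism_summary(res.polymorphic)
        res.candidates = filter_marker_candidates(
            res.polymorphic,
            index,
            min_depth_snp=config.min_depth_snp,
            min_depth_indel=config.min_depth_indel,
            require_both_depths=config.require_both_depths,
        )
        write_candidates_tsv(res.candidates, out("candidates.tsv"))
        with open(out("polymorphism_summary.tsv"), "w") as fh:
            fh.write("vtype\ttotal\thomo\thetero\n")
            for vt, row in res.poly_summary.items():
                fh.write(f"{vt}\t{row['total']}\t{row['homo']}\t{row['hetero']}\n")

    if depth >= 2:  # design (+ effects)
        res.effects = annotate_candidate_effects(res.candidates, genes, genome)
        write_effects_tsv(res.effects, out("effects.tsv"))
        params = config.primer_params()
        blocked = blocked_loci(wt, mut)
        try:
            control = design_control_pair(genome, blocked, params)
        except DesignError as exc:
            if not config.permissive:
                raise
            log.warning("control-pair design failed: %s", exc)
            control = None
        for cand in res.candidates:
            if cand.vtype != "SNP":
                continue
            set_id = f"{cand.chrom}_{cand.pos}"
            try:
                ps = design_marker_set(
                    genome, cand, blocked, params, control_pair=control
                )
            except DesignError as exc:
                res.design_failures.append((set_id, str(exc)))
                continue
            res.primer_sets.append((set_id, ps))
        write_primers_tsv(res.primer_sets, out("primers.tsv"))
        write_primers_fasta(res.primer_sets, out("primers.fasta"))

    if depth >= 3:  # validate
        params = config.primer_params()
        wt_t = HaplotypeTemplate("WT", genome, wt)
        mut_t = HaplotypeTemplate("mutant", genome, mut)
        for set_id, ps in res.primer_sets:
            rep = MarkerValidation(
                as_wt=insilico_pcr(wt_t, ps.as_forward, ps.common_reverse, params),
                as_mut=insilico_pcr(mut_t, ps.as_forward, ps.common_reverse, params),
                control_wt=insilico_pcr(
                    wt_t, ps.control_forward, ps.control_reverse, params
                ),
                control_mut=insilico_pcr(
                    mut_t, ps.control_forward, ps.control_reverse, params
                ),
            )
            res.validations.append((set_id, rep))
        write_validation_tsv(res.validations, out("validation.tsv"))

    if depth >= 4 and config.go_map:  # GO tally (optional stage)
        if os.path.exists(config.go_map):
            go_map = read_go_map(config.go_map)
            gene_ids = sorted(
                {c.region.gene_id for c in res.candidates if c.region.gene_id}
            )
            res.go_tally = tally_go(gene_ids, go_map, top_n=config.go_top_n)
            res.go_tally.write(config.outdir)
            for aspect in res.go_tally.per_aspect:
                res.written.append(
                    os.path.join(config.outdir, f"go_tally_{aspect}.tsv")
                )
        else:
            log.info("GO map %s not found; GO stage skipped", config.go_map)
    elif depth >= 4:
        log.info("no GO map configured; GO stage skipped")

    manifest = {
        "tool": "asmark",
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "inputs": {
            name: _sha256(path)
            for name, path in (
                ("genome", config.genome),
                ("gff3", config.gff3),
                ("wt_vcf", config.wt_vcf),
                ("mut_vcf", config.mut_vcf),
            )
            if path and os.path.exists(path)
        },
        "outputs": sorted(os.path.relpath(p, config.outdir) for p in res.written),
    }
    with open(os.path.join(config.outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")

    if res.design_failures and not config.permissive:
        raise DesignError(
            f"{len(res.design_failures)} candidate(s) failed primer design; "
            "first: " + res.design_failures[0][1]
        )
    return res
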