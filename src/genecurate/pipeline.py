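"""Filter-pipeline configuration and execution.

The filter order is fixed and logged: isoform separation, length minima
(intron, exon, CDS), incomplete removal, mono/multi partition, start codon,
stop codon, in-frame stops, canonical splice, functional gate, and finally
collapsing each cluster to a unique model.  Structural checks run before the
genome-dependent ones because they are cheaper and independent of sequence;
collapsing runs last so that it chooses among models that already passed
every quality gate.

The bundled ``nine-filter`` preset is the demonstration configuration: minimum
intron and exon of 20 nt, minimum CDS of 150 nt, ATG-only start, required
stop, zero in-frame stops, canonical GT/AG splice sites only, a functional
hit (similarity search or gene family), and unique-transcript collapsing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

from . import analytics, writers
from .errors import ConfigurationError
from .genome import GenomeIndex
from .models import FilterLog, FilterLogEntry, GeneTable
from .parsers import FunctionalMap, parse_annotation, parse_functional
from .sequence_filters import (
    StartCodonPolicy,
    StopPolicy,
    filter_canonical_splice,
    filter_inframe_stops,
    filter_start_codon,
    filter_stop_codon,
)
from .structural_filters import (
    LengthCriterion,
    collapse_unique,
    filter_by_length,
    partition_by_exon_count,
    remove_incompletes,
    separate_isoforms,
)
from .functional_filters import filter_functional

PRESETS = ("nine-filter",)


@dataclass
class PipelineConfig:
    """Everything one curation run needs; every threshold is overridable."""

    input_path: str = ""
    dialect: str = "gtf_generic"
    genome_path: str | None = None
    functional_path: str | None = None

    # filters (None / False = disabled)
    min_intron: int | None = None
    min_exon: int | None = None
    min_cds: int | None = None
    remove_incomplete: bool = False
    keep_exon_class: str | None = None  # 'monoexonic' | 'multiexonic'
    require_start: bool = False
    allow_alt_starts: bool = False
    require_stop: bool = False
    max_inframe_stops: int | None = None
    canonical_only: bool = False
    require_functional: str | None = None  # 'any' | 'similarity' | 'family'
    unique: bool = False

    # analytics / outputs
    statistics: bool = False
    distributions: bool = False
    splice_table: bool = False
    nt_content: bool = False
    emit_gtf: bool = False
    emit_gff3: str | None = None  # flavor
    emit_fasta: tuple[str, ...] = ()
    out_dir: str = "."

    translation_table: int = 1
    trim_terminal_stop: bool = True
    functional_query_col: str = "Query Sequence"
    functional_similarity_col: str = "Subject Sequence"
    functional_family_col: str = "EggNOG Seed Ortholog"

    def needs_genome(self) -> bool:
        return bool(
            self.require_start
            or self.require_stop
            or self.max_inframe_stops is not None
            or self.canonical_only
            or self.splice_table
            or self.nt_content
            or self.emit_fasta
        )

    def validate(self) -> None:
        if self.needs_genome() and not self.genome_path:
            raise ConfigurationError(
                "a genome FASTA (--fasta) is required by the enabled "
                "sequence-level filters/outputs"
            )
        if self.require_functional and not self.functional_path:
            raise ConfigurationError(
                "--require-functional needs a functional annotation file (--entap)"
            )
        if self.require_functional and self.require_functional not in (
            "any", "similarity", "family",
        ):
            raise ConfigurationError(
                f"require_functional must be any/similarity/family, "
                f"got {self.require_functional!r}"
            )
        if self.keep_exon_class not in (None, "monoexonic", "multiexonic"):
            raise ConfigurationError(
                f"keep_exon_class must be monoexonic/multiexonic, "
                f"got {self.keep_exon_class!r}"
            )
        if self.translation_table not in (1, 11):
            raise ConfigurationError("translation table must be 1 or 11")


def apply_preset(config: PipelineConfig, preset: str) -> PipelineConfig:
    if preset not in PRESETS:
        raise ConfigurationError(f"unknown preset {preset!r}; available: {PRESETS}")
    return replace(
        config,
        min_intron=20,
        min_exon=20,
        min_cds=150,
        require_start=True,
        allow_alt_starts=False,
        require_stop=True,
        max_inframe_stops=0,
        canonical_only=True,
        require_functional="any",
        unique=True,
    )


@dataclass
class PipelineResult:
    table: GeneTable
    log: FilterLog
    stats: analytics.StatsReport | None = None
    dists: analytics.DistributionTables | None = None
    splice: analytics.SpliceUsage | None = None
    content: analytics.ContentReport | None = None
    outputs: dict[str, Path] = field(default_factory=dict)


def run_filters(
    table: GeneTable,
    config: PipelineConfig,
    genome: GenomeIndex | None = None,
    fmap: FunctionalMap | None = None,
) -> tuple[GeneTable, FilterLog]:
    """Apply the enabled filters in the fixed pipeline order."""
    log = FilterLog()

    if config.unique:
        table, clusters = separate_isoforms(table)
        log.append(
            FilterLogEntry(
                "separate_isoforms",
                {"clusters": len(clusters)},
                len(table),
                len(table),
                [],
            )
        )
    if config.min_intron is not None:
        table, entry = filter_by_length(table, LengthCriterion("intron", config.min_intron))
        log.append(entry)
    if config.min_exon is not None:
        table, entry = filter_by_length(
            table, LengthCriterion("exon_segment", config.min_exon)
        )
        log.append(entry)
    if config.min_cds is not None:
        table, entry = filter_by_length(table, LengthCriterion("total_cds", config.min_cds))
        log.append(entry)
    if config.remove_incomplete:
        table, entry = remove_incompletes(table)
        log.append(entry)
    if config.keep_exon_class:
        table, entry = partition_by_exon_count(table, config.keep_exon_class)
        log.append(entry)
    if config.require_start:
        policy = (
            StartCodonPolicy.with_alternates()
            if config.allow_alt_starts
            else StartCodonPolicy()
        )
        table, entry = filter_start_codon(table, genome, policy)
        log.append(entry)
    stop_policy = StopPolicy(
        translation_table=config.translation_table,
        max_inframe_stops=config.max_inframe_stops or 0,
    )
    if config.require_stop:
        table, entry = filter_stop_codon(table, genome, stop_policy)
        log.append(entry)
    if config.max_inframe_stops is not None:
        table, entry = filter_inframe_stops(table, genome, stop_policy)
        log.append(entry)
    if config.canonical_only:
        table, entry = filter_canonical_splice(table, genome)
        log.append(entry)
    if config.require_functional:
        mode = {
            "any": "similarity_or_family",
            "similarity": "similarity_only",
            "family": "family_only",
        }[config.require_functional]
        table, entry = filter_functional(table, fmap, mode=mode)
        log.append(entry)
    if config.unique:
        table, entry = collapse_unique(table)
        log.append(entry)
    return table, log


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Parse inputs, filter, compute requested analytics and write outputs."""
    config.validate()
    table = parse_annotation(config.input_path, config.dialect)
    genome = GenomeIndex.from_fasta(config.genome_path) if config.genome_path else None
    fmap = (
        parse_functional(
            config.functional_path,
            query_col=config.functional_query_col,
            similarity_col=config.functional_similarity_col,
            family_col=config.functional_family_col,
        )
        if config.functional_path
        else None
    )

    table, log = run_filters(table, config, genome=genome, fmap=fmap)

    result = PipelineResult(table=table, log=log)
    outdir = Path(config.out_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    log_path = outdir / "filter_log.txt"
    writers.write_log(log, log_path)
    result.outputs["log"] = log_path

    if config.statistics:
        result.stats = analytics.compute_statistics(table, genome)
        path = outdir / "statistics.txt"
        analytics.write_stats(result.stats, path)
        result.outputs["statistics"] = path
    if config.distributions:
        result.dists = analytics.compute_distributions(table)
        for p in analytics.write_distributions(result.dists, outdir):
            result.outputs[p.stem] = p
    if config.splice_table:
        result.splice = analytics.splice_usage(table, genome)
        path = outdir / "splice_usage.tsv"
        analytics.write_splice_table(result.splice, path)
        result.outputs["splice_usage"] = path
    if config.nt_content:
        result.content = analytics.nucleotide_content(table, genome)
        path = outdir / "nt_content.tsv"
        analytics.write_content(result.content, path)
        result.outputs["nt_content"] = path
    if config.emit_gtf:
        path = outdir / "models.gtf"
        writers.write_gtf(table, path)
        result.outputs["gtf"] = path
    if config.emit_gff3:
        path = outdir / "models.gff3"
        writers.write_gff3(table, path, flavor=config.emit_gff3)
        result.outputs["gff3"] = path
    for mode in config.emit_fasta:
        suffix = {"protein": "proteins.faa", "cds": "cds.fna",
                  "gene_with_introns": "genes.fna"}[mode]
        path = outdir / suffix
        writers.write_fasta(
            table, genome, mode, path,
            translation_table=config.translation_table,
            trim_terminal_stop=config.trim_terminal_stop,
        )
        result.outputs[mode] = path
    return result
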