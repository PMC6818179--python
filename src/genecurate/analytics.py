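"""Annotation statistics, distribution tables, splice usage and base content.

The statistics catalog is fixed at 41 named entries so that report layout is
stable across versions and runs: counts and ratios over models, length
summaries for CDS / exon segments / introns / gene spans, completeness and
overlap bookkeeping, and five genome-dependent entries that read "n/a" when
no reference sequence was supplied.

Distribution outputs are deliberately raw: one feature per row, plain TSV
with a header, ready for import into R/pandas for plotting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from statistics import mean, median
from typing import IO

import pandas as pd

from .genome import GenomeIndex, intron_dinucleotides, spliced_cds
from .models import GeneTable, derive_introns
from .structural_filters import cluster_models

NA = "n/a"

#: number of entries in the statistics catalog, fixed
CATALOG_SIZE = 41


def _summary(values: list[int], prefix: str, with_total: bool = False) -> list[tuple]:
    out = []
    if with_total:
        out.append((f"{prefix}_total_nt", sum(values) if values else 0))
    out.append((f"{prefix}_mean_nt", float(mean(values)) if values else NA))
    out.append((f"{prefix}_median_nt", float(median(values)) if values else NA))
    out.append((f"{prefix}_min_nt", min(values) if values else NA))
    out.append((f"{prefix}_max_nt", max(values) if values else NA))
    return out


@dataclass
class StatsReport:
    """Ordered catalog of named annotation statistics."""

    entries: list[tuple[str, object]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.entries)

    def __getitem__(self, name: str):
        for key, value in self.entries:
            if key == name:
                return value
        raise KeyError(name)

    def names(self) -> list[str]:
        return [k for k, _ in self.entries]

    def to_text(self) -> str:
        width = max(len(k) for k, _ in self.entries)
        lines = ["# annotation statistics"]
        for key, value in self.entries:
            if isinstance(value, float):
                value = f"{value:.4f}"
            lines.append(f"{key.ljust(width)}  {value}")
        return "\n".join(lines) + "\n"


def compute_statistics(
    table: GeneTable, genome: GenomeIndex | None = None
) -> StatsReport:
    """Compute the full 41-entry catalog for a table (genome optional)."""
    models = list(table)
    cds_lengths = [m.cds_length for m in models]
    exon_lengths = [s.length for m in models for s in m.segments]
    intron_lengths = [e - s + 1 for m in models for s, e in derive_introns(m)]
    spans = [m.span for m in models]
    exons_per_model = [len(m.segments) for m in models]

    mono = sum(1 for m in models if m.is_monoexonic)
    multi = len(models) - mono
    clusters = cluster_models(table)
    cluster_sizes = [len(c) for c in clusters]

    entries: list[tuple[str, object]] = [
        ("gene_count", len({m.gene_id for m in models})),
        ("transcript_count", len(models)),
        ("monoexonic_count", mono),
        ("multiexonic_count", multi),
        ("mono_multi_ratio", mono / multi if multi else NA),
        ("plus_strand_count", sum(1 for m in models if m.strand == "+")),
        ("minus_strand_count", sum(1 for m in models if m.strand == "-")),
        ("scaffold_count", len({m.scaffold for m in models})),
    ]
    entries += _summary(cds_lengths, "cds", with_total=True)
    entries += _summary(exon_lengths, "exon")
    entries += [
        ("exon_count", len(exon_lengths)),
        ("exons_per_model_mean", float(mean(exons_per_model)) if models else NA),
        ("exons_per_model_max", max(exons_per_model) if models else NA),
    ]
    entries += [("intron_count", len(intron_lengths))]
    entries += _summary(intron_lengths, "intron")
    entries += _summary(spans, "gene_span", with_total=True)
    entries += [
        ("five_prime_partial_count", sum(1 for m in models if m.five_prime_partial)),
        ("three_prime_partial_count", sum(1 for m in models if m.three_prime_partial)),
        ("complete_count",
         sum(1 for m in models
             if not m.five_prime_partial and not m.three_prime_partial)),
        ("isoform_cluster_count", len(clusters)),
        ("cluster_size_max", max(cluster_sizes) if cluster_sizes else NA),
        ("cluster_size_mean", float(mean(cluster_sizes)) if cluster_sizes else NA),
    ]

    if genome is not None:
        usage = splice_usage(table, genome)
        content = nucleotide_content(table, genome)
        gc, at, n = content.aggregate
        entries += [
            ("canonical_intron_fraction",
             usage.canonical_fraction if usage.canonical_fraction is not None else NA),
            ("cds_gc_fraction", gc if cds_lengths else NA),
            ("cds_at_fraction", at if cds_lengths else NA),
            ("cds_n_fraction", n if cds_lengths else NA),
            ("splice_class_count", len(usage.counts)),
        ]
    else:
        entries += [
            ("canonical_intron_fraction", NA),
            ("cds_gc_fraction", NA),
            ("cds_at_fraction", NA),
            ("cds_n_fraction", NA),
            ("splice_class_count", NA),
        ]

    assert len(entries) == CATALOG_SIZE
    return StatsReport(entries)


# --------------------------------------------------------------------------
# Distributions
# --------------------------------------------------------------------------

@dataclass
class DistributionTables:
    """Raw per-feature values: gene spans, CDS lengths, exon lengths, and
    exon length by 5'→3' ordinal position."""

    gene_lengths: pd.DataFrame
    cds_lengths: pd.DataFrame
    exon_lengths: pd.DataFrame
    exon_by_order: pd.DataFrame

    def items(self):
        return {
            "gene_lengths": self.gene_lengths,
            "cds_lengths": self.cds_lengths,
            "exon_lengths": self.exon_lengths,
            "exon_by_order": self.exon_by_order,
        }.items()


def compute_distributions(table: GeneTable) -> DistributionTables:
    gene_rows, cds_rows, exon_rows, order_rows = [], [], [], []
    for m in table:
        gene_rows.append((m.transcript_id, m.span))
        cds_rows.append((m.transcript_id, m.cds_length))
        for s in m.segments:
            exon_rows.append((m.transcript_id, s.length))
        for idx, s in enumerate(m.segments_5p_to_3p(), start=1):
            order_rows.append((m.transcript_id, idx, s.length))
    return DistributionTables(
        gene_lengths=pd.DataFrame(gene_rows, columns=["transcript_id", "gene_span_nt"]),
        cds_lengths=pd.DataFrame(cds_rows, columns=["transcript_id", "cds_nt"]),
        exon_lengths=pd.DataFrame(exon_rows, columns=["transcript_id", "exon_nt"]),
        exon_by_order=pd.DataFrame(
            order_rows, columns=["transcript_id", "exon_order", "exon_nt"]
        ),
    )


# --------------------------------------------------------------------------
# Splice usage and nucleotide content
# --------------------------------------------------------------------------

@dataclass
class SpliceUsage:
    """Counts of (donor, acceptor) dinucleotide pairs over all introns."""

    counts: dict[tuple[str, str], int]
    canonical_fraction: float | None  # None when there are no introns

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def splice_usage(table: GeneTable, genome: GenomeIndex) -> SpliceUsage:
    counts: dict[tuple[str, str], int] = {}
    for m in table:
        for pair in intron_dinucleotides(genome, m):
            counts[pair] = counts.get(pair, 0) + 1
    total = sum(counts.values())
    fraction = counts.get(("GT", "AG"), 0) / total if total else None
    return SpliceUsage(counts=counts, canonical_fraction=fraction)


@dataclass
class ContentReport:
    """GC/AT/N fractions of each model's spliced CDS plus the aggregate."""

    per_model: dict[str, tuple[float, float, float]]
    aggregate: tuple[float, float, float]


def nucleotide_content(table: GeneTable, genome: GenomeIndex) -> ContentReport:
    per_model = {}
    tot_gc = tot_at = tot_n = tot_len = 0
    for m in table:
        cds = spliced_cds(genome, m)
        gc = cds.count("G") + cds.count("C")
        at = cds.count("A") + cds.count("T")
        n = cds.count("N")
        length = len(cds)
        per_model[m.transcript_id] = (gc / length, at / length, n / length)
        tot_gc += gc
        tot_at += at
        tot_n += n
        tot_len += length
    if tot_len:
        aggregate = (tot_gc / tot_len, tot_at / tot_len, tot_n / tot_len)
    else:
        aggregate = (0.0, 0.0, 0.0)
    return ContentReport(per_model=per_model, aggregate=aggregate)


# --------------------------------------------------------------------------
# Report writers
# --------------------------------------------------------------------------

def write_stats(report: StatsReport, destination: str | Path | IO[str]) -> None:
    if isinstance(destination, (str, Path)):
        Path(destination).write_text(report.to_text(), encoding="utf-8")
    else:
        destination.write(report.to_text())


def write_distributions(dist: DistributionTables, outdir: str | Path) -> list[Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, df in dist.items():
        path = outdir / f"{name}.tsv"
        df.to_csv(path, sep="\t", index=False)
        written.append(path)
    return written


def write_splice_table(usage: SpliceUsage, destination: str | Path) -> None:
    lines = ["donor\tacceptor\tcount"]
    for (donor, acceptor), count in sorted(
        usage.counts.items(), key=lambda kv: (-kv[1], kv[0])
    ):
        lines.append(f"{donor}\t{acceptor}\t{count}")
    frac = NA if usage.canonical_fraction is None else f"{usage.canonical_fraction:.4f}"
    lines.append(f"# canonical_fraction\t{frac}")
    Path(destination).write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_content(report: ContentReport, destination: str | Path) -> None:
    lines = ["transcript_id\tgc_fraction\tat_fraction\tn_fraction"]
    for tid, (gc, at, n) in sorted(report.per_model.items()):
        lines.append(f"{tid}\t{gc:.4f}\t{at:.4f}\t{n:.4f}")
    gc, at, n = report.aggregate
    lines.append(f"# aggregate\t{gc:.4f}\t{at:.4f}\t{n:.4f}")
    Path(destination).write_text("\n".join(lines) + "\n", encoding="utf-8")
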