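"""Emit curated models as GTF, GFF3 and FASTA, plus the filtering log.

Phase is always recomputed on write from the cumulative 5'→3' CDS length
(first coding segment phase 0), never copied from the input: the supported
dialects disagree about phase conventions and recomputation guarantees the
output is internally consistent.  Row order is deterministic (scaffold,
start, transcript_id) so identical inputs produce byte-identical files.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import IO

from .errors import BoundsError, GenomeLookupError
from .genome import GenomeIndex, gene_region, spliced_cds, translate
from .models import FilterLog, GeneTable, TranscriptModel

log = logging.getLogger(__name__)

FASTA_MODES = ("protein", "cds", "gene_with_introns")
GFF3_FLAVORS = ("snpeff", "jbrowse")


def _out(destination):
    if isinstance(destination, (str, Path)):
        return open(destination, "w", encoding="utf-8", newline="\n"), True
    return destination, False


def phases_5p_to_3p(model: TranscriptModel) -> dict[tuple[int, int], int]:
    """Recomputed phase per segment, keyed by (start, end).

    Phase is the count of bases needed to reach the next codon boundary:
    0 for the 5'-most segment, then (3 - cumulative_length mod 3) mod 3.
    """
    phases = {}
    cumulative = 0
    for seg in model.segments_5p_to_3p():
        phases[(seg.start, seg.end)] = (3 - cumulative % 3) % 3
        cumulative += seg.length
    return phases


def _escape_gff3(value: str) -> str:
    return (
        value.replace("%", "%25").replace(";", "%3B")
        .replace("=", "%3D").replace(",", "%2C").replace("\t", "%09")
    )


def write_gtf(table: GeneTable, destination: str | Path | IO[str]) -> None:
    """One CDS row per coding segment with gene_id/transcript_id attributes.

    Declared partial flags are carried as extra attributes so that a
    reparse preserves completeness information.
    """
    fh, close = _out(destination)
    try:
        fh.write("#gtf: curated gene models\n")
        for m in table:
            phases = phases_5p_to_3p(m)
            for seg in m.segments:
                attrs = f'gene_id "{m.gene_id}"; transcript_id "{m.transcript_id}";'
                if m.five_prime_partial:
                    attrs += ' five_prime_partial "true";'
                if m.three_prime_partial:
                    attrs += ' three_prime_partial "true";'
                fh.write(
                    "\t".join(
                        (
                            m.scaffold,
                            "genecurate",
                            "CDS",
                            str(seg.start),
                            str(seg.end),
                            ".",
                            m.strand,
                            str(phases[(seg.start, seg.end)]),
                            attrs,
                        )
                    )
                    + "\n"
                )
    finally:
        if close:
            fh.close()


def write_gff3(
    table: GeneTable, destination: str | Path | IO[str], flavor: str = "snpeff"
) -> None:
    """gene → mRNA → exon + CDS hierarchy linked by ID/Parent.

    Both flavors share the structure genome browsers and variant annotators
    expect: every CDS row has an mRNA parent, every mRNA a gene parent, and
    parents are emitted before children.  The jbrowse flavor additionally
    puts a Name attribute on gene rows for display.
    """
    if flavor not in GFF3_FLAVORS:
        raise ValueError(f"flavor must be one of {GFF3_FLAVORS}, got {flavor!r}")
    fh, close = _out(destination)
    try:
        fh.write("##gff-version 3\n")
        by_gene: dict[str, list[TranscriptModel]] = {}
        for m in table:
            by_gene.setdefault(m.gene_id, []).append(m)
        gene_order = sorted(
            by_gene,
            key=lambda g: (
                by_gene[g][0].scaffold,
                min(m.start for m in by_gene[g]),
                g,
            ),
        )
        for gid in gene_order:
            members = by_gene[gid]
            scaffold = members[0].scaffold
            strand = members[0].strand
            g_start = min(m.start for m in members)
            g_end = max(m.end for m in members)
            gid_esc = _escape_gff3(gid)
            gene_attrs = f"ID={gid_esc}"
            if flavor == "jbrowse":
                gene_attrs += f";Name={gid_esc}"
            fh.write(
                "\t".join(
                    (scaffold, "genecurate", "gene", str(g_start), str(g_end),
                     ".", strand, ".", gene_attrs)
                )
                + "\n"
            )
            for m in sorted(members, key=lambda m: (m.start, m.transcript_id)):
                tid_esc = _escape_gff3(m.transcript_id)
                mrna_attrs = f"ID={tid_esc};Parent={gid_esc}"
                if m.five_prime_partial:
                    mrna_attrs += ";five_prime_partial=true"
                if m.three_prime_partial:
                    mrna_attrs += ";three_prime_partial=true"
                fh.write(
                    "\t".join(
                        (m.scaffold, "genecurate", "mRNA", str(m.start),
                         str(m.end), ".", m.strand, ".", mrna_attrs)
                    )
                    + "\n"
                )
                phases = phases_5p_to_3p(m)
                # Coding-only models: exon rows mirror the CDS segments.
                for i, seg in enumerate(m.segments, start=1):
                    fh.write(
                        "\t".join(
                            (m.scaffold, "genecurate", "exon", str(seg.start),
                             str(seg.end), ".", m.strand, ".",
                             f"ID={tid_esc}.exon{i};Parent={tid_esc}")
                        )
                        + "\n"
                    )
                    fh.write(
                        "\t".join(
                            (m.scaffold, "genecurate", "CDS", str(seg.start),
                             str(seg.end), ".", m.strand,
                             str(phases[(seg.start, seg.end)]),
                             f"ID={tid_esc}.cds;Parent={tid_esc}")
                        )
                        + "\n"
                    )
    finally:
        if close:
            fh.close()


def _wrap(seq: str, width: int = 60) -> str:
    return "\n".join(seq[i : i + width] for i in range(0, len(seq), width))


def write_fasta(
    table: GeneTable,
    genome: GenomeIndex,
    mode: str,
    destination: str | Path | IO[str],
    translation_table: int = 1,
    trim_terminal_stop: bool = True,
) -> int:
    """Write one FASTA record per model; returns the number written.

    Modes: ``protein`` (translated spliced CDS), ``cds`` (spliced CDS) and
    ``gene_with_introns`` (genomic slice from first to last segment,
    reverse-complemented on the minus strand).  Models whose coordinates fall
    outside the genome are skipped with a logged error rather than aborting
    the whole write.
    """
    if mode not in FASTA_MODES:
        raise ValueError(f"mode must be one of {FASTA_MODES}, got {mode!r}")
    fh, close = _out(destination)
    written = 0
    try:
        for m in table:
            try:
                if mode == "gene_with_introns":
                    seq = gene_region(genome, m)
                else:
                    seq = spliced_cds(genome, m)
                    if mode == "protein":
                        seq = translate(seq, table_id=translation_table)
                        if trim_terminal_stop and seq.endswith("*"):
                            seq = seq[:-1]
            except (BoundsError, GenomeLookupError, ValueError) as exc:
                log.error("skipping %s: %s", m.transcript_id, exc)
                continue
            header = (
                f">{m.transcript_id} gene={m.gene_id} "
                f"loc={m.scaffold}:{m.start}-{m.end}({m.strand})"
            )
            fh.write(header + "\n" + _wrap(seq) + "\n")
            written += 1
    finally:
        if close:
            fh.close()
    return written


def write_log(log_obj: FilterLog, destination: str | Path | IO[str]) -> None:
    """Human-readable report of every filter: parameters, counts, removals."""
    fh, close = _out(destination)
    try:
        fh.write("# filtering log\n")
        if not log_obj.entries:
            fh.write("no filters applied\n")
            return
        for i, entry in enumerate(log_obj, start=1):
            params = ", ".join(f"{k}={v}" for k, v in entry.parameters.items()) or "-"
            fh.write(
                f"\n[{i}] {entry.filter_name} ({params})\n"
                f"    models before: {entry.models_before}\n"
                f"    models after:  {entry.models_after}\n"
                f"    removed:       {len(entry.removed)}\n"
            )
            for tid, reason in entry.removed:
                fh.write(f"      - {tid}\t{reason}\n")
    finally:
        if close:
            fh.close()
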