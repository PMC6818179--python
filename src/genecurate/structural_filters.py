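"""Filters that need only the gene table, no reference sequence.

These cover length minima on exon segments, introns and total CDS;
removal of declared-incomplete models (with a phase fallback when nothing
was declared); mono/multiexonic partitioning; isoform separation by
coordinate overlap; and collapsing each isoform cluster to a single,
longest model after exact-duplicate removal.

Every filter is contractive (output is a subset of the input) and
idempotent, and returns both the surviving table and a log entry recording
what was removed and why.
"""

from __future__ import annotations

from dataclasses import dataclass

from .models import (
    FilterLogEntry,
    GeneTable,
    TranscriptModel,
    derive_introns,
    make_entry,
)

FEATURE_KINDS = ("exon_segment", "intron", "total_cds")

#: defaults applied when a length criterion is enabled without a value
DEFAULT_MINIMA = {"exon_segment": 20, "intron": 20, "total_cds": 150}


@dataclass(frozen=True)
class LengthCriterion:
    """Minimum length (nt) required of every feature of one kind."""

    feature_kind: str
    minimum: int

    def __post_init__(self) -> None:
        if self.feature_kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.feature_kind!r}")
        if self.minimum < 1:
            raise ValueError("minimum length must be >= 1")


def _feature_lengths(model: TranscriptModel, kind: str) -> list[int]:
    if kind == "exon_segment":
        return [s.length for s in model.segments]
    if kind == "intron":
        return [e - s + 1 for s, e in derive_introns(model)]
    return [model.cds_length]


def filter_by_length(
    table: GeneTable, criterion: LengthCriterion
) -> tuple[GeneTable, FilterLogEntry]:
    """Drop models with any feature of the criterion's kind below the minimum."""
    survivors, removed = [], []
    for m in table:
        offending = [
            n for n in _feature_lengths(m, criterion.feature_kind)
            if n < criterion.minimum
        ]
        if offending:
            removed.append(
                (m.transcript_id,
                 f"{criterion.feature_kind}_length_{min(offending)}_below_{criterion.minimum}")
            )
        else:
            survivors.append(m)
    entry = make_entry(
        f"min_{criterion.feature_kind}",
        {"minimum_nt": criterion.minimum},
        table,
        removed,
    )
    return GeneTable(survivors, provenance=table.provenance), entry


def remove_incompletes(table: GeneTable) -> tuple[GeneTable, FilterLogEntry]:
    """Remove models declared 5'- or 3'-partial by their source.

    When the source declared nothing at all (both flags None), fall back to
    the recorded phase of the 5'-most coding segment: a non-zero phase means
    the reading frame starts mid-codon, i.e. the start exon is missing.  This
    heuristic is for genome-less runs; with a genome the sequence-level
    start/stop filters give the authoritative answer.
    """
    survivors, removed = [], []
    for m in table:
        if m.five_prime_partial or m.three_prime_partial:
            which = []
            if m.five_prime_partial:
                which.append("5p")
            if m.three_prime_partial:
                which.append("3p")
            removed.append((m.transcript_id, "declared_partial_" + "_".join(which)))
        elif m.five_prime_partial is None and m.three_prime_partial is None:
            phase = m.first_segment_5p().phase
            if phase not in (None, 0):
                removed.append((m.transcript_id, f"first_segment_phase_{phase}"))
            else:
                survivors.append(m)
        else:
            survivors.append(m)
    entry = make_entry("remove_incompletes", {}, table, removed)
    return GeneTable(survivors, provenance=table.provenance), entry


def partition_by_exon_count(
    table: GeneTable, keep: str
) -> tuple[GeneTable, FilterLogEntry]:
    """Keep only monoexonic (0 introns) or only multiexonic (>=1 intron) models."""
    if keep not in ("monoexonic", "multiexonic"):
        raise ValueError(f"keep must be 'monoexonic' or 'multiexonic', got {keep!r}")
    want_mono = keep == "monoexonic"
    survivors, removed = [], []
    for m in table:
        if m.is_monoexonic == want_mono:
            survivors.append(m)
        else:
            removed.append(
                (m.transcript_id,
                 "multiexonic" if want_mono else "monoexonic")
            )
    entry = make_entry("keep_" + keep, {"keep": keep}, table, removed)
    return GeneTable(survivors, provenance=table.provenance), entry


# --------------------------------------------------------------------------
# Isoform handling
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class IsoformCluster:
    """Single-linkage component of models connected by CDS overlap."""

    label: str
    transcript_ids: tuple[str, ...]
    scaffold: str
    strand: str

    def __len__(self) -> int:
        return len(self.transcript_ids)


def cluster_models(table: GeneTable) -> list[IsoformCluster]:
    """Connected components under same-scaffold, same-strand CDS overlap.

    Two models are linked when any coding segment of one overlaps any coding
    segment of the other by at least 1 bp; clusters are the transitive
    closure.  A sweep over segment intervals finds segment overlaps (a
    segment whose start is at or before the running maximum end overlaps the
    segment holding that maximum); union-find over transcript IDs then merges
    models, which also ties together the runs bridged by a model whose own
    segments sit far apart.
    """
    groups: dict[tuple[str, str], list[TranscriptModel]] = {}
    for m in table:
        groups.setdefault((m.scaffold, m.strand), []).append(m)

    parent: dict[str, str] = {m.transcript_id: m.transcript_id for m in table}

    def find(tid: str) -> str:
        while parent[tid] != tid:
            parent[tid] = parent[parent[tid]]
            tid = parent[tid]
        return tid

    def union(a: str, b: str) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    for members in groups.values():
        events = sorted(
            (s.start, s.end, m.transcript_id)
            for m in members
            for s in m.segments
        )
        max_end = -1
        max_end_tid = ""
        for start, end, tid in events:
            if max_end_tid and start <= max_end:
                union(max_end_tid, tid)
            if end > max_end:
                max_end = end
                max_end_tid = tid

    component_ids: dict[tuple[str, str, str], set[str]] = {}
    starts: dict[tuple[str, str, str], int] = {}
    for (scaffold, strand), members in groups.items():
        for m in members:
            key = (scaffold, strand, find(m.transcript_id))
            component_ids.setdefault(key, set()).add(m.transcript_id)
            starts[key] = min(starts.get(key, m.start), m.start)

    raw_clusters = [
        (scaffold, strand, sorted(tids), starts[(scaffold, strand, root)])
        for (scaffold, strand, root), tids in component_ids.items()
    ]

    raw_clusters.sort(key=lambda c: (c[0], c[3], c[2][0], c[1]))
    return [
        IsoformCluster(
            label=f"cluster_{i + 1:05d}",
            transcript_ids=tuple(tids),
            scaffold=scaffold,
            strand=strand,
        )
        for i, (scaffold, strand, tids, _start) in enumerate(raw_clusters)
    ]


def separate_isoforms(table: GeneTable) -> tuple[GeneTable, list[IsoformCluster]]:
    """Assign every model to an overlap cluster and relabel gene_id by cluster.

    Conflicting evidence (isoforms, competing predictions) shows up as
    coordinate overlap; relabelling gene_id to the cluster lets downstream
    filters treat each transcript independently and gives the collapse step
    its grouping key.
    """
    clusters = cluster_models(table)
    label_of = {
        tid: c.label for c in clusters for tid in c.transcript_ids
    }
    relabelled = [
        TranscriptModel(
            gene_id=label_of[m.transcript_id],
            transcript_id=m.transcript_id,
            scaffold=m.scaffold,
            strand=m.strand,
            segments=m.segments,
            source_dialect=m.source_dialect,
            five_prime_partial=m.five_prime_partial,
            three_prime_partial=m.three_prime_partial,
            attributes=dict(m.attributes),
        )
        for m in table
    ]
    return GeneTable(relabelled, provenance=table.provenance), clusters


def collapse_unique(table: GeneTable) -> tuple[GeneTable, FilterLogEntry]:
    """Reduce each gene (cluster) to one representative model.

    First, models with byte-identical structure (scaffold, strand, ordered
    segment coordinates) are deduplicated to the lexicographically smallest
    transcript_id.  Then within each gene_id exactly one model survives: the
    one with maximal total CDS length, ties broken by smaller 5'-most genomic
    start, then smaller transcript_id.  Run after :func:`separate_isoforms`
    so gene_id reflects overlap clusters.
    """
    removed: list[tuple[str, str]] = []

    by_structure: dict[tuple, list[TranscriptModel]] = {}
    for m in table:
        key = (m.scaffold, m.strand, tuple((s.start, s.end) for s in m.segments))
        by_structure.setdefault(key, []).append(m)
    deduped: list[TranscriptModel] = []
    for group in by_structure.values():
        group.sort(key=lambda m: m.transcript_id)
        deduped.append(group[0])
        for dup in group[1:]:
            removed.append(
                (dup.transcript_id, f"duplicate_of:{group[0].transcript_id}")
            )

    by_gene: dict[str, list[TranscriptModel]] = {}
    for m in deduped:
        by_gene.setdefault(m.gene_id, []).append(m)
    survivors: list[TranscriptModel] = []
    for group in by_gene.values():
        group.sort(key=lambda m: (-m.cds_length, m.start, m.transcript_id))
        winner = group[0]
        survivors.append(winner)
        for loser in group[1:]:
            removed.append(
                (loser.transcript_id, f"collapsed_into:{winner.transcript_id}")
            )

    entry = make_entry("collapse_unique", {}, table, removed)
    return GeneTable(survivors, provenance=table.provenance), entry
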