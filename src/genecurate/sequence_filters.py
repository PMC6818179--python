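"""Genome-dependent filters: terminal codons, in-frame stops, splice sites.

These check the *predicted* model against the reference sequence — they never
re-predict.  "Has a start/stop" therefore means the spliced CDS begins with an
allowed start codon and ends with a stop codon of the configured translation
table; no ORF re-scanning is attempted.

N handling is conservative in both directions: a terminal codon containing N
fails the start/stop checks (the evidence for completeness is missing), while
internal N-containing codons are never counted as stops (the evidence for an
error is missing).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .genome import GenomeIndex, spliced_cds, stop_codons
from .models import FilterLogEntry, GeneTable, TranscriptModel, make_entry
from . import genome as _genome_mod

#: alternate initiation codons common in prokaryotes
ALTERNATE_STARTS = frozenset({"GTG", "TTG"})


@dataclass(frozen=True)
class StartCodonPolicy:
    """Which codons qualify as a translation start; ATG is always allowed."""

    allowed_starts: frozenset = frozenset({"ATG"})

    def __post_init__(self) -> None:
        if "ATG" not in self.allowed_starts:
            raise ValueError("ATG must always be an allowed start codon")

    @classmethod
    def with_alternates(cls) -> "StartCodonPolicy":
        return cls(frozenset({"ATG"}) | ALTERNATE_STARTS)


@dataclass(frozen=True)
class StopPolicy:
    """Stop-codon set (per translation table) and in-frame stop tolerance."""

    translation_table: int = 1
    max_inframe_stops: int = 0

    def __post_init__(self) -> None:
        if self.max_inframe_stops < 0:
            raise ValueError("max_inframe_stops must be >= 0")

    @property
    def stops(self) -> frozenset:
        return stop_codons(self.translation_table)


def _scan(table: GeneTable, genome: GenomeIndex, judge):
    """Apply a per-model judge returning None (keep) or a removal reason."""
    survivors, removed = [], []
    for m in table:
        reason = judge(m)
        if reason is None:
            survivors.append(m)
        else:
            removed.append((m.transcript_id, reason))
    return survivors, removed


def filter_start_codon(
    table: GeneTable,
    genome: GenomeIndex,
    policy: StartCodonPolicy = StartCodonPolicy(),
) -> tuple[GeneTable, FilterLogEntry]:
    """Keep models whose spliced CDS begins with an allowed start codon."""

    def judge(m: TranscriptModel):
        cds = spliced_cds(genome, m)
        if len(cds) < 3:
            return "cds_too_short"
        first = cds[:3]
        if "N" in first or first not in policy.allowed_starts:
            return f"start_codon_{first}"
        return None

    survivors, removed = _scan(table, genome, judge)
    entry = make_entry(
        "require_start_codon",
        {"allowed_starts": sorted(policy.allowed_starts)},
        table,
        removed,
    )
    return GeneTable(survivors, provenance=table.provenance), entry


def filter_stop_codon(
    table: GeneTable,
    genome: GenomeIndex,
    policy: StopPolicy = StopPolicy(),
) -> tuple[GeneTable, FilterLogEntry]:
    """Keep models whose spliced CDS ends with a stop codon."""
    stops = policy.stops

    def judge(m: TranscriptModel):
        cds = spliced_cds(genome, m)
        if len(cds) < 3:
            return "cds_too_short"
        last = cds[-3:]
        if "N" in last or last not in stops:
            return f"no_stop_codon_{last}"
        return None

    survivors, removed = _scan(table, genome, judge)
    entry = make_entry(
        "require_stop_codon",
        {"translation_table": policy.translation_table},
        table,
        removed,
    )
    return GeneTable(survivors, provenance=table.provenance), entry


def filter_inframe_stops(
    table: GeneTable,
    genome: GenomeIndex,
    policy: StopPolicy = StopPolicy(),
) -> tuple[GeneTable, FilterLogEntry]:
    """Keep models with at most ``max_inframe_stops`` premature stop codons.

    Codons are read in frame from position 1 of the spliced CDS; the final
    complete codon (the expected terminator) is never counted.
    """
    stops = policy.stops

    def judge(m: TranscriptModel):
        cds = spliced_cds(genome, m)
        n_codons = len(cds) // 3
        count = 0
        for i in range(n_codons - 1):  # exclude the terminal codon
            codon = cds[3 * i : 3 * i + 3]
            if "N" not in codon and codon in stops:
                count += 1
        if count > policy.max_inframe_stops:
            return f"inframe_stops_{count}"
        return None

    survivors, removed = _scan(table, genome, judge)
    entry = make_entry(
        "max_inframe_stops",
        {"max_inframe_stops": policy.max_inframe_stops,
         "translation_table": policy.translation_table},
        table,
        removed,
    )
    return GeneTable(survivors, provenance=table.provenance), entry


def filter_canonical_splice(
    table: GeneTable, genome: GenomeIndex
) -> tuple[GeneTable, FilterLogEntry]:
    """Keep multiexonic models whose every intron is GT..AG.

    Monoexonic models pass vacuously.  Dinucleotides containing N count as
    non-canonical: the canonical motif cannot be confirmed.
    """

    def judge(m: TranscriptModel):
        for donor, acceptor in _genome_mod.intron_dinucleotides(genome, m):
            if (donor, acceptor) != ("GT", "AG"):
                return f"noncanonical_splice_{donor}..{acceptor}"
        return None

    survivors, removed = _scan(table, genome, judge)
    entry = make_entry("canonical_splice_only", {}, table, removed)
    return GeneTable(survivors, provenance=table.provenance), entry
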