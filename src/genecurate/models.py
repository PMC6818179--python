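"""Core gene-model data structures and the intermediate table format.

Every supported annotation dialect is normalized into one in-memory
representation before any filtering happens: a :class:`GeneTable` holding
:class:`TranscriptModel` records, each an ordered run of coding segments on
one scaffold and strand.  All filters, statistics and writers operate on this
table, never on raw GTF/GFF lines, so dialect quirks are confined to the
parsers.

Coordinates are 1-based and inclusive throughout, matching the GTF/GFF
convention; any conversion happens inside parsers and writers only.  Segments
are stored in ascending genomic order on both strands; biological 5'-to-3'
order is derived from the strand where needed.

The table serializes to a plain TSV ("intermediate table") with one row per
transcript, designed to round-trip losslessly: parse(write(t)) == t.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator

from .errors import ParseError

STRANDS = ("+", "-")


@dataclass(frozen=True, order=True)
class CodingSegment:
    """One coding interval of a transcript, 1-based inclusive.

    ``phase`` is the 0/1/2 offset of the first complete codon as recorded in
    the source file; it is advisory (recomputed on write) and may be None.
    """

    start: int
    end: int
    phase: int | None = None

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"segment start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(f"segment end {self.end} < start {self.start}")
        if self.phase not in (None, 0, 1, 2):
            raise ValueError(f"phase must be 0, 1, 2 or None, got {self.phase!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class TranscriptModel:
    """One predicted transcript: ordered coding segments on one scaffold/strand.

    Partial flags are tri-state: ``True``/``False`` when the source declared
    completeness, ``None`` when it said nothing (filters then fall back to
    phase inspection).
    """

    gene_id: str
    transcript_id: str
    scaffold: str
    strand: str
    segments: tuple[CodingSegment, ...]
    source_dialect: str = "unknown"
    five_prime_partial: bool | None = None
    three_prime_partial: bool | None = None
    attributes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        segs = tuple(sorted(self.segments, key=lambda s: (s.start, s.end)))
        if not segs:
            raise ValueError(f"model {self.transcript_id!r} has no coding segments")
        for a, b in zip(segs, segs[1:]):
            if b.start <= a.end:
                raise ValueError(
                    f"model {self.transcript_id!r}: segments "
                    f"({a.start},{a.end}) and ({b.start},{b.end}) overlap"
                )
        self.segments = segs

    # --- derived geometry -------------------------------------------------

    @property
    def start(self) -> int:
        """Genomic start of the 5'-most-by-coordinate segment."""
        return self.segments[0].start

    @property
    def end(self) -> int:
        return self.segments[-1].end

    @property
    def span(self) -> int:
        """Genomic footprint, first segment start to last segment end."""
        return self.end - self.start + 1

    @property
    def cds_length(self) -> int:
        return sum(s.length for s in self.segments)

    @property
    def intron_count(self) -> int:
        return len(self.segments) - 1

    @property
    def is_monoexonic(self) -> bool:
        return len(self.segments) == 1

    def segments_5p_to_3p(self) -> tuple[CodingSegment, ...]:
        """Segments in transcription (5'→3') order."""
        return self.segments if self.strand == "+" else self.segments[::-1]

    def first_segment_5p(self) -> CodingSegment:
        return self.segments_5p_to_3p()[0]


def derive_introns(model: TranscriptModel) -> list[tuple[int, int]]:
    """Genomic intervals between consecutive coding segments.

    Returned 1-based inclusive and in ascending genomic order; a monoexonic
    model yields an empty list.
    """
    return [
        (a.end + 1, b.start - 1)
        for a, b in zip(model.segments, model.segments[1:])
    ]


@dataclass
class Provenance:
    path: str = ""
    dialect: str = "unknown"
    timestamp: str = ""


def _sort_key(m: TranscriptModel) -> tuple:
    return (m.scaffold, m.start, m.transcript_id)


@dataclass
class GeneTable:
    """The normalized annotation: a deterministic, ID-unique list of models.

    Models are kept sorted by (scaffold, start, transcript_id) so iteration
    order never depends on input file order.  Provenance is bookkeeping and
    excluded from equality.
    """

    models: list[TranscriptModel]
    provenance: Provenance | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        self.models = sorted(self.models, key=_sort_key)
        seen: set[str] = set()
        for m in self.models:
            if m.transcript_id in seen:
                raise ValueError(f"duplicate transcript_id {m.transcript_id!r}")
            seen.add(m.transcript_id)

    def __iter__(self) -> Iterator[TranscriptModel]:
        return iter(self.models)

    def __len__(self) -> int:
        return len(self.models)

    def transcript_ids(self) -> list[str]:
        return [m.transcript_id for m in self.models]

    def get(self, transcript_id: str) -> TranscriptModel:
        for m in self.models:
            if m.transcript_id == transcript_id:
                return m
        raise KeyError(transcript_id)


def models_equivalent(a: TranscriptModel, b: TranscriptModel) -> bool:
    """Structural equality: IDs, placement, coordinates and completeness.

    Ignores advisory phase, pass-through attributes and the source dialect,
    which legitimately change across write/reparse cycles.  An undeclared
    partial flag (None) is treated as "not partial".
    """
    return (
        a.gene_id == b.gene_id
        and a.transcript_id == b.transcript_id
        and a.scaffold == b.scaffold
        and a.strand == b.strand
        and [(s.start, s.end) for s in a.segments]
        == [(s.start, s.end) for s in b.segments]
        and bool(a.five_prime_partial) == bool(b.five_prime_partial)
        and bool(a.three_prime_partial) == bool(b.three_prime_partial)
    )


def tables_equivalent(a: GeneTable, b: GeneTable) -> bool:
    return len(a) == len(b) and all(
        models_equivalent(x, y) for x, y in zip(a, b)
    )


# --------------------------------------------------------------------------
# Filter log
# --------------------------------------------------------------------------

@dataclass
class FilterLogEntry:
    """Outcome of one filter application: counts plus per-model reasons."""

    filter_name: str
    parameters: dict
    models_before: int
    models_after: int
    removed: list[tuple[str, str]]  # (transcript_id, reason)

    def __post_init__(self) -> None:
        if self.models_after != self.models_before - len(self.removed):
            raise ValueError(
                f"{self.filter_name}: after ({self.models_after}) != "
                f"before ({self.models_before}) - removed ({len(self.removed)})"
            )


@dataclass
class FilterLog:
    """Ordered record of every filter applied in a run."""

    entries: list[FilterLogEntry] = field(default_factory=list)

    def append(self, entry: FilterLogEntry) -> None:
        self.entries.append(entry)

    def extend(self, entries: Iterable[FilterLogEntry]) -> None:
        for e in entries:
            self.append(e)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[FilterLogEntry]:
        return iter(self.entries)


def make_entry(
    filter_name: str,
    parameters: dict,
    before: GeneTable,
    removed: list[tuple[str, str]],
) -> FilterLogEntry:
    return FilterLogEntry(
        filter_name=filter_name,
        parameters=dict(parameters),
        models_before=len(before),
        models_after=len(before) - len(removed),
        removed=list(removed),
    )


# --------------------------------------------------------------------------
# Intermediate table serialization
# --------------------------------------------------------------------------

INTERMEDIATE_COLUMNS = (
    "gene_id",
    "transcript_id",
    "scaffold",
    "strand",
    "segments",
    "five_prime_partial",
    "three_prime_partial",
    "source_dialect",
    "attributes",
)

_TRI = {True: "true", False: "false", None: "."}
_TRI_BACK = {"true": True, "false": False, ".": None}


def _encode_segments(segments: tuple[CodingSegment, ...]) -> str:
    return ",".join(
        f"{s.start}-{s.end}/{'.' if s.phase is None else s.phase}"
        for s in segments
    )


def _decode_segments(text: str, lineno: int) -> tuple[CodingSegment, ...]:
    out = []
    for chunk in text.split(","):
        try:
            coords, phase = chunk.split("/")
            start, end = coords.split("-")
            out.append(
                CodingSegment(
                    int(start), int(end), None if phase == "." else int(phase)
                )
            )
        except (ValueError, TypeError) as exc:
            raise ParseError(f"bad segment field {chunk!r}: {exc}", lineno) from None
    return tuple(out)


def write_intermediate(table: GeneTable, destination: str | Path | IO[str]) -> None:
    """Write the table as TSV, one transcript per row, header first."""
    close = False
    if isinstance(destination, (str, Path)):
        fh = open(destination, "w", encoding="utf-8", newline="\n")
        close = True
    else:
        fh = destination
    try:
        fh.write("\t".join(INTERMEDIATE_COLUMNS) + "\n")
        for m in table:
            row = (
                m.gene_id,
                m.transcript_id,
                m.scaffold,
                m.strand,
                _encode_segments(m.segments),
                _TRI[m.five_prime_partial],
                _TRI[m.three_prime_partial],
                m.source_dialect,
                json.dumps(m.attributes, ensure_ascii=False),
            )
            fh.write("\t".join(row) + "\n")
    finally:
        if close:
            fh.close()


def read_intermediate(source: str | Path | IO[str]) -> GeneTable:
    """Parse an intermediate TSV back into a GeneTable (exact inverse of write)."""
    close = False
    if isinstance(source, (str, Path)):
        fh = open(source, encoding="utf-8")
        close = True
        path = str(source)
    else:
        fh = source
        path = getattr(source, "name", "<stream>")
    try:
        header = fh.readline().rstrip("\n")
        if header.split("\t") != list(INTERMEDIATE_COLUMNS):
            raise ParseError(f"unexpected header {header!r}", 1)
        models = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) != len(INTERMEDIATE_COLUMNS):
                raise ParseError(
                    f"expected {len(INTERMEDIATE_COLUMNS)} columns, got {len(cols)}",
                    lineno,
                )
            gid, tid, scaf, strand, segs, f5, f3, dialect, attrs = cols
            if f5 not in _TRI_BACK or f3 not in _TRI_BACK:
                raise ParseError(f"bad partial flag {f5!r}/{f3!r}", lineno)
            try:
                attributes = json.loads(attrs)
            except json.JSONDecodeError as exc:
                raise ParseError(f"bad attributes JSON: {exc}", lineno) from None
            try:
                model = TranscriptModel(
                    gene_id=gid,
                    transcript_id=tid,
                    scaffold=scaf,
                    strand=strand,
                    segments=_decode_segments(segs, lineno),
                    source_dialect=dialect,
                    five_prime_partial=_TRI_BACK[f5],
                    three_prime_partial=_TRI_BACK[f3],
                    attributes=attributes,
                )
            except ValueError as exc:
                raise ParseError(str(exc), lineno) from None
            models.append(model)
        return GeneTable(models, provenance=Provenance(path=path, dialect="intermediate"))
    finally:
        if close:
            fh.close()
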