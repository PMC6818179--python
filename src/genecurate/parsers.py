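"""Dialect adapters: GTF/GFF inputs and the functional-annotation flat file.

Nine common annotation producers reduce to four syntactic families, and each
family gets one adapter:

* ``gtf_generic``      — plain GTF: CDS rows carry ``gene_id``/``transcript_id``
                         attributes (gffread and similar emitters).
* ``gtf_augustus``     — AUGUSTUS / BRAKER GTF: same column layout, but the
                         attribute column may be a bare transcript token
                         (``g1.t1``) and the file is interleaved with comment
                         blocks (protein dumps) that are skipped.
* ``gff3_hierarchical``— gene → mRNA → CDS/exon linked by ID/Parent; serves
                         MAKER, EVidenceModeler, NCBI, Prokka, gffread and
                         GenomeThreader outputs (Prokka's mRNA-less
                         gene → CDS chains included).
* ``gff3_alignment``   — match / match_part (or repeated cDNA_match rows)
                         from spliced aligners such as GMAP and Exonerate;
                         aligned blocks are promoted to coding segments.

The dialect is always user-specified, never sniffed: the same column layout
is used by producers with incompatible ID conventions, so guessing is a
reliability hazard.  Hierarchical parsing is two-pass and therefore
independent of feature line order.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO
from urllib.parse import unquote

import pandas as pd

from .errors import ConfigurationError, ParseError
from .models import CodingSegment, GeneTable, Provenance, TranscriptModel

log = logging.getLogger(__name__)

#: dialect name -> short description (the supported set)
DIALECTS = {
    "gtf_generic": "generic GTF with gene_id/transcript_id attributes",
    "gtf_augustus": "AUGUSTUS/BRAKER GTF (bare transcript tokens allowed)",
    "gff3_hierarchical": "gene/mRNA/CDS GFF3 (MAKER, EVM, NCBI, Prokka, gffread, GenomeThreader)",
    "gff3_alignment": "match/match_part alignment GFF3 (GMAP, Exonerate)",
}

_TRANSCRIPT_TYPES = {
    "mRNA", "transcript", "tRNA", "rRNA", "ncRNA", "lnc_RNA", "snRNA",
    "snoRNA", "pseudogenic_transcript",
}
_GENE_TYPES = {"gene", "pseudogene"}
_MATCH_TYPES = {
    "match", "cDNA_match", "EST_match", "protein_match", "nucleotide_match",
    "translated_nucleotide_match", "nucleotide_to_protein_match",
}
_PART_TYPES = {"match_part"}

_TRUTHY = {"true", "1", "yes", "t"}


@dataclass(frozen=True)
class DialectSpec:
    """Resolved per-dialect parsing rules (informational; adapters do the work)."""

    name: str
    attr_syntax: str  # 'gtf' or 'gff3'
    coding_features: frozenset


def dialect_spec(name: str) -> DialectSpec:
    if name not in DIALECTS:
        raise ConfigurationError(
            f"unknown dialect {name!r}; supported: {', '.join(sorted(DIALECTS))}"
        )
    if name.startswith("gtf"):
        return DialectSpec(name, "gtf", frozenset({"CDS"}))
    if name == "gff3_hierarchical":
        return DialectSpec(name, "gff3", frozenset({"CDS", "exon"}))
    return DialectSpec(name, "gff3", frozenset(_MATCH_TYPES | _PART_TYPES))


# --------------------------------------------------------------------------
# Low-level line handling
# --------------------------------------------------------------------------

@dataclass
class _Row:
    lineno: int
    scaffold: str
    source: str
    type: str
    start: int
    end: int
    strand: str
    phase: int | None
    attrs: dict[str, str]


def _open(source):
    if isinstance(source, (str, Path)):
        return open(source, encoding="utf-8"), True, str(source)
    return source, False, getattr(source, "name", "<stream>")


def _iter_rows(fh, attr_syntax: str, bare_ok: bool = False):
    for lineno, raw in enumerate(fh, start=1):
        line = raw.rstrip("\n")
        if line.startswith("##FASTA"):
            break
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) < 8:
            raise ParseError(
                f"expected at least 8 tab-separated columns, got {len(cols)}",
                lineno,
            )
        scaf, src, ftype, start_s, end_s, _score, strand, phase_s = cols[:8]
        attr_text = cols[8] if len(cols) > 8 else ""
        try:
            start, end = int(start_s), int(end_s)
        except ValueError:
            raise ParseError(f"non-integer coordinates {start_s!r}/{end_s!r}", lineno) from None
        if start > end:
            raise ParseError(f"start {start} > end {end}", lineno)
        phase = int(phase_s) if phase_s in ("0", "1", "2") else None
        if attr_syntax == "gtf":
            attrs = _parse_gtf_attrs(attr_text, bare_ok, lineno)
        else:
            attrs = _parse_gff3_attrs(attr_text)
        yield _Row(lineno, scaf, src, ftype, start, end, strand, phase, attrs)


_GTF_ATTR_RE = re.compile(r'(\S+)\s+"([^"]*)"\s*;?')


def _parse_gtf_attrs(text: str, bare_ok: bool, lineno: int) -> dict[str, str]:
    text = text.strip()
    if not text:
        return {}
    pairs = dict(_GTF_ATTR_RE.findall(text))
    if pairs:
        return pairs
    if bare_ok and '"' not in text and "=" not in text:
        # AUGUSTUS-style bare transcript token in column 9
        token = text.split()[0].rstrip(";")
        gene = token.rsplit(".t", 1)[0] if ".t" in token else token
        return {"transcript_id": token, "gene_id": gene}
    raise ParseError(f"cannot parse GTF attributes {text!r}", lineno)


def _parse_gff3_attrs(text: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for chunk in text.strip().split(";"):
        chunk = chunk.strip()
        if not chunk or "=" not in chunk:
            continue
        key, value = chunk.split("=", 1)
        attrs[key.strip()] = unquote(value.strip())
    return attrs


def _partial_flags(attrs: dict[str, str]) -> tuple[bool | None, bool | None]:
    """Extract completeness declarations from column-9 attributes.

    Recognizes explicit ``five_prime_partial``/``three_prime_partial`` keys,
    plus the common ``partial`` key in either boolean form (NCBI) or the
    two-digit Prodigal/Prokka encoding ("10" = 5' open, "01" = 3' open).
    """
    lower = {k.lower(): v.strip().lower() for k, v in attrs.items()}
    f5 = f3 = None
    if "five_prime_partial" in lower:
        f5 = lower["five_prime_partial"] in _TRUTHY
    if "three_prime_partial" in lower:
        f3 = lower["three_prime_partial"] in _TRUTHY
    if "partial" in lower and f5 is None and f3 is None:
        v = lower["partial"]
        if v in _TRUTHY:
            f5 = f3 = True
        elif v in ("false", "no", "0"):
            f5 = f3 = False
        elif set(v) <= {"0", "1"} and len(v) == 2:
            f5, f3 = v[0] == "1", v[1] == "1"
    return f5, f3


def _merge_flag(a: bool | None, b: bool | None) -> bool | None:
    if a is None:
        return b
    if b is None:
        return a
    return a or b


def _merge_segments(raw: list[CodingSegment]) -> tuple[CodingSegment, ...]:
    """Sort and merge overlapping/duplicated intervals within one transcript."""
    segs = sorted(raw, key=lambda s: (s.start, s.end))
    merged: list[CodingSegment] = []
    for s in segs:
        if merged and s.start <= merged[-1].end:
            prev = merged[-1]
            merged[-1] = CodingSegment(prev.start, max(prev.end, s.end), prev.phase)
        else:
            merged.append(s)
    return tuple(merged)


class _Collector:
    """Accumulates segment rows per transcript, disambiguating transcripts
    whose ID recurs on another scaffold/strand (multi-mapping aligner output)
    with a ``.dupN`` suffix."""

    def __init__(self, dialect: str):
        self.dialect = dialect
        self._buckets: dict[str, list[dict]] = {}

    def add(self, tid: str, gid: str, row: _Row) -> None:
        buckets = self._buckets.setdefault(tid, [])
        for b in buckets:
            if b["scaffold"] == row.scaffold and b["strand"] == row.strand:
                bucket = b
                break
        else:
            if buckets:
                log.warning(
                    "transcript %r recurs on %s%s; disambiguating with .dup%d",
                    tid, row.scaffold, row.strand, len(buckets),
                )
            bucket = {
                "tid": tid if not buckets else f"{tid}.dup{len(buckets)}",
                "gid": gid,
                "scaffold": row.scaffold,
                "strand": row.strand,
                "segments": [],
                "f5": None,
                "f3": None,
                "attrs": {},
            }
            buckets.append(bucket)
        bucket["segments"].append(CodingSegment(row.start, row.end, row.phase))
        f5, f3 = _partial_flags(row.attrs)
        bucket["f5"] = _merge_flag(bucket["f5"], f5)
        bucket["f3"] = _merge_flag(bucket["f3"], f3)

    def set_container_attrs(self, tid: str, attrs: dict[str, str]) -> None:
        for b in self._buckets.get(tid, []):
            b["attrs"] = dict(attrs)
            f5, f3 = _partial_flags(attrs)
            b["f5"] = _merge_flag(b["f5"], f5)
            b["f3"] = _merge_flag(b["f3"], f3)

    def models(self) -> list[TranscriptModel]:
        out = []
        for buckets in self._buckets.values():
            for b in buckets:
                out.append(
                    TranscriptModel(
                        gene_id=b["gid"],
                        transcript_id=b["tid"],
                        scaffold=b["scaffold"],
                        strand=b["strand"] if b["strand"] in "+-" else "+",
                        segments=_merge_segments(b["segments"]),
                        source_dialect=self.dialect,
                        five_prime_partial=b["f5"],
                        three_prime_partial=b["f3"],
                        attributes=b["attrs"],
                    )
                )
        return out


# --------------------------------------------------------------------------
# Dialect adapters
# --------------------------------------------------------------------------

def parse_annotation(source, dialect: str) -> GeneTable:
    """Parse an annotation file in the named dialect into a GeneTable."""
    spec = dialect_spec(dialect)
    fh, close, path = _open(source)
    try:
        if spec.name in ("gtf_generic", "gtf_augustus"):
            models = _parse_gtf(fh, spec)
        elif spec.name == "gff3_hierarchical":
            models = _parse_gff3_hierarchical(fh, spec)
        else:
            models = _parse_gff3_alignment(fh, spec)
    finally:
        if close:
            fh.close()
    return GeneTable(models, provenance=Provenance(path=path, dialect=dialect))


def _parse_gtf(fh, spec: DialectSpec) -> list[TranscriptModel]:
    collector = _Collector(spec.name)
    bare_ok = spec.name == "gtf_augustus"
    for row in _iter_rows(fh, "gtf", bare_ok=bare_ok):
        if row.type != "CDS":
            continue
        tid = row.attrs.get("transcript_id")
        if not tid:
            raise ParseError("CDS row lacks transcript_id attribute", row.lineno)
        gid = row.attrs.get("gene_id", tid)
        collector.add(tid, gid, row)
    return collector.models()


def _parse_gff3_hierarchical(fh, spec: DialectSpec) -> list[TranscriptModel]:
    rows = list(_iter_rows(fh, "gff3"))
    by_id: dict[str, _Row] = {}
    for r in rows:
        rid = r.attrs.get("ID")
        if rid and rid not in by_id:
            by_id[rid] = r

    cds_children: dict[str, list[_Row]] = {}
    exon_children: dict[str, list[_Row]] = {}
    orphans: list[_Row] = []
    for r in rows:
        if r.type not in ("CDS", "exon"):
            continue
        parents = [p for p in r.attrs.get("Parent", "").split(",") if p]
        if not parents:
            if r.type == "CDS":
                orphans.append(r)
            continue
        target = cds_children if r.type == "CDS" else exon_children
        for p in parents:
            target.setdefault(p, []).append(r)

    collector = _Collector(spec.name)
    for container_id in sorted(set(cds_children) | set(exon_children)):
        # Exon rows stand in for CDS only when no CDS rows exist (pure
        # alignments routed through this adapter).
        segs = cds_children.get(container_id) or exon_children[container_id]
        container = by_id.get(container_id)
        if container is not None and container.type in _GENE_TYPES:
            tid = gid = container_id
        elif container is not None:
            gid = container.attrs.get("Parent", "").split(",")[0] or container_id
            tid = container_id
        else:
            tid = gid = container_id
        for r in segs:
            collector.add(tid, gid, r)
        if container is not None:
            collector.set_container_attrs(tid, container.attrs)
    for r in orphans:
        rid = r.attrs.get("ID") or f"cds_{r.lineno}"
        collector.add(rid, rid, r)
    return collector.models()


def _parse_gff3_alignment(fh, spec: DialectSpec) -> list[TranscriptModel]:
    rows = list(_iter_rows(fh, "gff3"))
    part_parents = {
        p
        for r in rows
        if r.type in _PART_TYPES
        for p in r.attrs.get("Parent", "").split(",")
        if p
    }
    collector = _Collector(spec.name)
    for r in rows:
        if r.type in _PART_TYPES:
            for p in r.attrs.get("Parent", "").split(","):
                if p:
                    collector.add(p, p, r)
        elif r.type in _MATCH_TYPES:
            rid = r.attrs.get("ID") or r.attrs.get("Name") or f"match_{r.lineno}"
            if rid in part_parents:
                collector.set_container_attrs(rid, r.attrs)
                continue  # span row; the parts carry the segments
            collector.add(rid, rid, r)
    return collector.models()


# --------------------------------------------------------------------------
# Functional-annotation flat file
# --------------------------------------------------------------------------

#: cell values meaning "no hit" in functional-annotation tables
SENTINELS = {"", "-", "NA"}

_ID_SUFFIX_RE = re.compile(r"\.[pt]\d+$")


@dataclass
class FunctionalMap:
    """Per-query functional evidence: similarity-search and gene-family hits."""

    entries: dict[str, tuple[bool, bool]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.entries)

    def lookup(self, query_id: str, strip_suffix: bool = True):
        """Return (has_similarity_hit, has_family_hit) or None if absent.

        With ``strip_suffix`` a trailing protein/transcript suffix (``.p1``,
        ``.t2``) is dropped for a second lookup attempt, since protein-FASTA
        query IDs often carry one relative to the transcript ID.
        """
        if query_id in self.entries:
            return self.entries[query_id]
        if strip_suffix:
            stripped = _ID_SUFFIX_RE.sub("", query_id)
            if stripped != query_id and stripped in self.entries:
                return self.entries[stripped]
        return None


def _is_hit(cell) -> bool:
    return str(cell).strip().upper() not in SENTINELS and str(cell).strip() != ""


def parse_functional(
    source,
    query_col: str = "Query Sequence",
    similarity_col: str = "Subject Sequence",
    family_col: str = "EggNOG Seed Ortholog",
) -> FunctionalMap:
    """Parse a functional-annotation TSV (EnTAP-style flat file).

    A query has a similarity hit iff its subject cell is non-empty and not a
    sentinel (``NA``, ``-``); the gene-family column is evaluated the same way.
    """
    df = pd.read_csv(source, sep="\t", dtype=str, keep_default_na=False)
    for col in (query_col, similarity_col, family_col):
        if col not in df.columns:
            raise ConfigurationError(
                f"functional file lacks configured column {col!r}; "
                f"available: {list(df.columns)}"
            )
    entries: dict[str, tuple[bool, bool]] = {}
    for _, row in df.iterrows():
        qid = str(row[query_col]).strip()
        if not qid:
            continue
        entries[qid] = (_is_hit(row[similarity_col]), _is_hit(row[family_col]))
    return FunctionalMap(entries)
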