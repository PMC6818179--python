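"""Synthetic genome + annotation generator with planted, countable defects.

The generator emits a random genome, a matching gene table, a functional
annotation TSV and a manifest naming exactly which defect each model carries.
Clean models satisfy every filter: ATG start, stop-codon end, no in-frame
stops, GT/AG introns, every exon and intron at least 20 nt, CDS at least
150 nt, unique coordinates and a functional hit.  Each violation tag edits in
exactly its own defect and nothing else, so for every filter the removed set
is predictable from the manifest alone.

Defects are planted by construction at exact coordinates (the coding sequence
is assembled codon-by-codon before being split into exons), never sampled
probabilistically, and the generator re-derives every planted property from
the finished genome before returning.  Generation is fully deterministic
given the seed; there is no default seed.

This emulates the *bookkeeping* structure of real annotations — dialects,
strands, isoforms, duplicates — not their biology: no realistic codon usage,
length distributions or intergenic composition.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field

from .errors import GenerationError
from .genome import GenomeIndex, reverse_complement, spliced_cds, intron_dinucleotides
from .models import CodingSegment, GeneTable, TranscriptModel, derive_introns

STOPS = ("TAA", "TAG", "TGA")
#: codons that no supported start policy accepts (and that are not stops)
BAD_STARTS = ("AAA", "CCC", "GGA", "CGT", "GAT")
_BASES = "ACGT"
NONSTOP_CODONS = tuple(
    a + b + c
    for a in _BASES
    for b in _BASES
    for c in _BASES
    if a + b + c not in STOPS
)

VIOLATION_TAGS = (
    "short_intron",
    "short_exon",
    "short_cds",
    "no_start",
    "alt_start",
    "no_stop",
    "inframe_stop",
    "noncanonical_splice",
    "duplicate_of",
    "isoform_of",
    "incomplete_5p",
    "no_functional_hit",
)

#: planted defect sizes / thresholds the clean models respect
CLEAN_MIN_EXON = 25
CLEAN_MIN_INTRON = 25
CLEAN_MIN_CDS = 180
SHORT_FEATURE_LEN = 10
SHORT_CDS_CODONS = 30  # 90 nt, below the 150 nt minimum

ENTAP_HEADER = "Query Sequence\tSubject Sequence\tEggNOG Seed Ortholog"


@dataclass
class PlantManifest:
    """Per-model record of planted violation tags (empty tuple = clean)."""

    tags: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def base_tags(self, transcript_id: str) -> set[str]:
        return {t.split(":", 1)[0] for t in self.tags.get(transcript_id, ())}

    def with_tag(self, tag: str) -> set[str]:
        """Transcript IDs carrying the given base tag."""
        return {tid for tid in self.tags if tag in self.base_tags(tid)}

    def clean_ids(self) -> set[str]:
        return {tid for tid, tags in self.tags.items() if not tags}

    def violated_ids(self) -> set[str]:
        return {tid for tid, tags in self.tags.items() if tags}

    def to_json(self) -> str:
        return json.dumps({k: list(v) for k, v in sorted(self.tags.items())}, indent=1)


@dataclass
class FixtureBundle:
    """Everything one run of the generator produced."""

    fasta: str
    table: GeneTable
    entap_tsv: str
    manifest: PlantManifest

    def genome(self) -> GenomeIndex:
        return GenomeIndex.from_text(self.fasta)


def default_violation_mix(per_tag: int = 5) -> dict[str, int]:
    """One entry for every supported tag, ``per_tag`` models each."""
    return {tag: per_tag for tag in VIOLATION_TAGS}


# --------------------------------------------------------------------------
# Sequence building blocks
# --------------------------------------------------------------------------

def _background(rng: random.Random, n: int, gc: float) -> str:
    return "".join(
        rng.choice("GC") if rng.random() < gc else rng.choice("AT") for _ in range(n)
    )


def _build_cds(
    rng: random.Random,
    n_codons: int,
    start: str = "ATG",
    stop: str | None = None,
    internal_stop_at: int | None = None,
    atg_at: int | None = None,
) -> str:
    codons = [start]
    codons += [rng.choice(NONSTOP_CODONS) for _ in range(n_codons - 2)]
    codons.append(stop if stop is not None else rng.choice(STOPS))
    if atg_at is not None:
        codons[atg_at] = "ATG"
    if internal_stop_at is not None:
        codons[internal_stop_at] = rng.choice(STOPS)
    return "".join(codons)


def _split_lengths(
    rng: random.Random,
    total: int,
    n_parts: int,
    minimum: int,
    forced: int | None = None,
) -> list[int]:
    """Partition ``total`` into n parts each >= minimum; optionally force one
    part to an exact (possibly sub-minimum) length."""
    if forced is not None:
        rest = _split_lengths(rng, total - forced, n_parts - 1, minimum)
        rest.insert(rng.randrange(n_parts), forced)
        return rest
    extra = total - minimum * n_parts
    if extra < 0:
        raise GenerationError(
            f"cannot split {total} nt into {n_parts} parts of >= {minimum} nt"
        )
    cuts = sorted(rng.randint(0, extra) for _ in range(n_parts - 1))
    bounds = [0, *cuts, extra]
    return [minimum + (b - a) for a, b in zip(bounds, bounds[1:])]


@dataclass
class _Unit:
    """One locus in transcript space, before genome placement."""

    region: str
    exon_offsets: list[tuple[int, int]]  # transcript order, 0-based inclusive
    tags: tuple[str, ...]
    five_prime_partial: bool | None = None
    satellite_offsets: list[tuple[int, int]] | None = None
    satellite_kind: str | None = None  # 'duplicate' or 'isoform'


def _assemble_region(
    rng: random.Random,
    cds: str,
    exon_lengths: list[int],
    intron_lengths: list[int],
    gc: float,
    noncanonical_at: int | None = None,
) -> tuple[str, list[tuple[int, int]]]:
    assert sum(exon_lengths) == len(cds)
    parts: list[str] = []
    offsets: list[tuple[int, int]] = []
    pos = 0
    cds_pos = 0
    for i, exon_len in enumerate(exon_lengths):
        parts.append(cds[cds_pos : cds_pos + exon_len])
        offsets.append((pos, pos + exon_len - 1))
        pos += exon_len
        cds_pos += exon_len
        if i < len(intron_lengths):
            donor = "GC" if noncanonical_at == i else "GT"
            ilen = intron_lengths[i]
            parts.append(donor + _background(rng, ilen - 4, gc) + "AG")
            pos += ilen
    return "".join(parts), offsets


def _build_unit(rng: random.Random, role: str, gc: float) -> _Unit:
    tags: list[str] = []
    start, stop = "ATG", None
    internal_stop_at = atg_at = None
    f5 = None
    forced_exon = None
    noncanonical_at = None
    short_intron = False

    if role == "iso_host":
        # Monoexonic host with a planted in-frame internal ATG; the isoform
        # satellite is the suffix starting there (a shorter valid model that
        # shares the stop codon and overlaps the host).
        n_codons, n_exons, atg_at = 100, 1, 30
    else:
        n_codons = rng.randint(65, 120)
        n_exons = rng.randint(1, 4)
        if role == "short_cds":
            n_codons, n_exons = SHORT_CDS_CODONS, 1
            tags.append("short_cds")
        elif role == "short_exon":
            n_exons = rng.randint(2, 4)
            forced_exon = SHORT_FEATURE_LEN
            tags.append("short_exon")
        elif role == "short_intron":
            n_exons = rng.randint(2, 4)
            short_intron = True
            tags.append("short_intron")
        elif role == "noncanonical_splice":
            n_exons = rng.randint(2, 4)
            tags.append("noncanonical_splice")
        elif role == "no_start":
            start = rng.choice(BAD_STARTS)
            tags.append("no_start")
        elif role == "alt_start":
            start = rng.choice(("GTG", "TTG"))
            tags.append("alt_start")
        elif role == "no_stop":
            stop = "GGG"
            tags.append("no_stop")
        elif role == "inframe_stop":
            internal_stop_at = rng.randint(1, n_codons - 2)
            tags.append("inframe_stop:1")
        elif role == "incomplete_5p":
            # a genuinely 5'-partial model is declared partial AND lacks its
            # start codon: both the declaration-based and the sequence-based
            # completeness filters catch it
            start = rng.choice(BAD_STARTS)
            f5 = True
            tags.append("incomplete_5p")
        elif role == "no_functional_hit":
            tags.append("no_functional_hit")
        elif role not in ("clean", "dup_host"):
            raise GenerationError(f"unknown role {role!r}")

    cds = _build_cds(rng, n_codons, start, stop, internal_stop_at, atg_at)
    exon_lengths = _split_lengths(
        rng, len(cds), n_exons, CLEAN_MIN_EXON, forced=forced_exon
    )
    intron_lengths = [rng.randint(CLEAN_MIN_INTRON, 80) for _ in range(n_exons - 1)]
    if short_intron:
        intron_lengths[rng.randrange(len(intron_lengths))] = SHORT_FEATURE_LEN
    if role == "noncanonical_splice":
        noncanonical_at = rng.randrange(n_exons - 1)

    region, offsets = _assemble_region(
        rng, cds, exon_lengths, intron_lengths, gc, noncanonical_at
    )
    unit = _Unit(region, offsets, tuple(tags), five_prime_partial=f5)
    if role == "iso_host":
        unit.satellite_offsets = [(3 * atg_at, len(region) - 1)]
        unit.satellite_kind = "isoform"
    elif role == "dup_host":
        unit.satellite_offsets = list(offsets)
        unit.satellite_kind = "duplicate"
    return unit


def _make_model(
    gene_id: str,
    transcript_id: str,
    scaffold: str,
    strand: str,
    origin: int,
    region_len: int,
    exon_offsets: list[tuple[int, int]],
    five_prime_partial: bool | None = None,
) -> TranscriptModel:
    segments = []
    cumulative = 0
    for a, b in exon_offsets:  # transcript order
        phase = (3 - cumulative % 3) % 3
        cumulative += b - a + 1
        if strand == "+":
            segments.append(CodingSegment(origin + a, origin + b, phase))
        else:
            segments.append(
                CodingSegment(
                    origin + region_len - 1 - b, origin + region_len - 1 - a, phase
                )
            )
    return TranscriptModel(
        gene_id=gene_id,
        transcript_id=transcript_id,
        scaffold=scaffold,
        strand=strand,
        segments=tuple(segments),
        source_dialect="synthetic",
        five_prime_partial=five_prime_partial,
    )


# --------------------------------------------------------------------------
# Generator
# --------------------------------------------------------------------------

def generate(
    genome_params: dict | None = None,
    model_params: dict | None = None,
    seed: int = None,
) -> FixtureBundle:
    """Generate a synthetic genome, annotation, functional file and manifest.

    ``genome_params``: n_scaffolds (default 4), scaffold_length (default
    60000), gc_fraction (default 0.45).  ``model_params``: n_models (default
    50), violation_mix mapping tag -> count (default empty: all clean).
    The seed is mandatory.
    """
    if seed is None:
        raise GenerationError("a seed is required; generation has no default seed")
    gp = {"n_scaffolds": 4, "scaffold_length": 60_000, "gc_fraction": 0.45}
    gp.update(genome_params or {})
    mp = {"n_models": 50, "violation_mix": {}}
    mp.update(model_params or {})
    mix: dict[str, int] = dict(mp["violation_mix"])
    for tag in mix:
        if tag not in VIOLATION_TAGS:
            raise GenerationError(f"unknown violation tag {tag!r}")
    n_models = mp["n_models"]
    n_violations = sum(mix.values())
    if n_violations > n_models:
        raise GenerationError(
            f"violation_mix asks for {n_violations} models but n_models={n_models}"
        )
    n_satellites = mix.get("duplicate_of", 0) + mix.get("isoform_of", 0)
    n_clean = n_models - n_violations
    if n_satellites > n_clean:
        raise GenerationError(
            f"{n_satellites} duplicate/isoform models need as many clean host "
            f"models, but only {n_clean} clean slots remain"
        )

    rng = random.Random(seed)

    # Roles for the non-satellite models; satellites ride along with hosts.
    roles = []
    for tag, count in sorted(mix.items()):
        if tag in ("duplicate_of", "isoform_of"):
            continue
        roles += [tag] * count
    roles += ["iso_host"] * mix.get("isoform_of", 0)
    roles += ["dup_host"] * mix.get("duplicate_of", 0)
    roles += ["clean"] * (n_clean - n_satellites)
    rng.shuffle(roles)

    gc = gp["gc_fraction"]
    scaffolds = [f"scaf{i + 1}" for i in range(gp["n_scaffolds"])]
    builders: dict[str, list[str]] = {s: [] for s in scaffolds}
    cursors: dict[str, int] = {s: 0 for s in scaffolds}

    models: list[TranscriptModel] = []
    manifest_tags: dict[str, tuple[str, ...]] = {}

    for i, role in enumerate(roles):
        unit = _build_unit(rng, role, gc)
        scaffold = scaffolds[i % len(scaffolds)]
        strand = rng.choice("+-")
        gap = rng.randint(80, 200)
        origin = cursors[scaffold] + gap + 1  # 1-based start of the region
        region_len = len(unit.region)
        if origin + region_len - 1 > gp["scaffold_length"]:
            raise GenerationError(
                f"scaffold_length={gp['scaffold_length']} too small: placing "
                f"model {i + 1}/{len(roles)} needs position "
                f"{origin + region_len - 1} on {scaffold}"
            )
        builders[scaffold].append(_background(rng, gap, gc))
        builders[scaffold].append(
            unit.region if strand == "+" else reverse_complement(unit.region)
        )
        cursors[scaffold] = origin + region_len - 1

        gene_id = f"g{i + 1:04d}"
        tid = f"{gene_id}.t1"
        models.append(
            _make_model(
                gene_id, tid, scaffold, strand, origin, region_len,
                unit.exon_offsets, unit.five_prime_partial,
            )
        )
        manifest_tags[tid] = unit.tags

        if unit.satellite_offsets is not None:
            if unit.satellite_kind == "isoform":
                sat_tid = f"{gene_id}.t2"
                sat_tags = (f"isoform_of:{tid}",)
            else:
                sat_tid = f"{tid}_dup"
                sat_tags = (f"duplicate_of:{tid}",)
            models.append(
                _make_model(
                    gene_id, sat_tid, scaffold, strand, origin, region_len,
                    unit.satellite_offsets,
                )
            )
            manifest_tags[sat_tid] = sat_tags

    # Pad scaffolds to the requested length and render FASTA.
    fasta_lines = []
    for s in scaffolds:
        seq = "".join(builders[s])
        seq += _background(rng, gp["scaffold_length"] - len(seq), gc)
        fasta_lines.append(f">{s}")
        fasta_lines += [seq[i : i + 70] for i in range(0, len(seq), 70)]
    fasta = "\n".join(fasta_lines) + "\n"

    table = GeneTable(models)
    manifest = PlantManifest(manifest_tags)
    entap = _render_entap(rng, table, manifest)
    _self_check(GenomeIndex.from_text(fasta), table, manifest)
    return FixtureBundle(fasta=fasta, table=table, entap_tsv=entap, manifest=manifest)


def _render_entap(
    rng: random.Random, table: GeneTable, manifest: PlantManifest
) -> str:
    lines = [ENTAP_HEADER]
    for m in table:
        tid = m.transcript_id
        if "no_functional_hit" in manifest.base_tags(tid):
            # absent entirely or present with sentinel cells — both mean no hit
            if rng.random() < 0.5:
                continue
            lines.append(f"{tid}\t{rng.choice(['NA', '-', ''])}\tNA")
        else:
            subject = f"sp|P{rng.randrange(10000, 99999)}|HIT_{rng.randrange(1000)}"
            family = f"{rng.randrange(2, 99999)}.ENOG{rng.randrange(10000, 99999)}"
            lines.append(f"{tid}\t{subject}\t{family}")
    return "\n".join(lines) + "\n"


def _self_check(
    genome: GenomeIndex, table: GeneTable, manifest: PlantManifest
) -> None:
    """Re-derive every planted property from the finished genome."""
    by_id = {m.transcript_id: m for m in table}
    for m in table:
        tags = manifest.base_tags(m.transcript_id)
        cds = spliced_cds(genome, m)
        introns = [e - s + 1 for s, e in derive_introns(m)]
        exons = [s.length for s in m.segments]
        dinucs = intron_dinucleotides(genome, m)
        internal = [
            cds[3 * i : 3 * i + 3] for i in range(len(cds) // 3 - 1)
        ]

        def expect(condition: bool, what: str) -> None:
            if not condition:
                raise GenerationError(
                    f"self-check failed for {m.transcript_id} ({sorted(tags)}): {what}"
                )

        no_atg_tags = {"no_start", "alt_start", "incomplete_5p"}
        expect(
            (cds[:3] == "ATG") == (not tags & no_atg_tags),
            f"start codon {cds[:3]}",
        )
        if "alt_start" in tags:
            expect(cds[:3] in ("GTG", "TTG"), f"alt start {cds[:3]}")
        expect((cds[-3:] in STOPS) == ("no_stop" not in tags), f"stop {cds[-3:]}")
        n_internal_stops = sum(c in STOPS for c in internal)
        expect(
            (n_internal_stops > 0) == ("inframe_stop" in tags),
            f"{n_internal_stops} internal stops",
        )
        expect(
            (bool(introns) and min(introns) < 20) == ("short_intron" in tags),
            f"intron lengths {introns}",
        )
        expect(
            (min(exons) < 20) == ("short_exon" in tags), f"exon lengths {exons}"
        )
        expect((len(cds) < 150) == ("short_cds" in tags), f"CDS length {len(cds)}")
        noncanonical = [d for d in dinucs if d != ("GT", "AG")]
        expect(
            bool(noncanonical) == ("noncanonical_splice" in tags),
            f"splice sites {dinucs}",
        )
        expect(
            bool(m.five_prime_partial) == ("incomplete_5p" in tags),
            f"partial flag {m.five_prime_partial}",
        )
        for tag in manifest.tags.get(m.transcript_id, ()):
            base, _, host_id = tag.partition(":")
            if base == "duplicate_of":
                host = by_id[host_id]
                expect(
                    m.segments == tuple(
                        CodingSegment(s.start, s.end, s.phase) for s in host.segments
                    )
                    and m.scaffold == host.scaffold
                    and m.strand == host.strand,
                    "duplicate does not match host",
                )
            elif base == "isoform_of":
                host = by_id[host_id]
                expect(
                    m.scaffold == host.scaffold
                    and m.strand == host.strand
                    and m.start <= host.end
                    and host.start <= m.end
                    and m.cds_length < host.cds_length,
                    "isoform does not overlap or is not shorter than host",
                )


#: which planted tags each filter (applied alone, at the default thresholds)
#: must remove — incomplete_5p models both declare partiality and lack a
#: start codon, so two filters list them
EXPECTED_REMOVALS = {
    "min_intron": ("short_intron",),
    "min_exon": ("short_exon",),
    "min_cds": ("short_cds",),
    "remove_incompletes": ("incomplete_5p",),
    "start_codon_strict": ("no_start", "alt_start", "incomplete_5p"),
    "start_codon_alternates": ("no_start", "incomplete_5p"),
    "stop_codon": ("no_stop",),
    "inframe_stops": ("inframe_stop",),
    "canonical_splice": ("noncanonical_splice",),
    "functional": ("no_functional_hit",),
    "collapse_unique": ("duplicate_of", "isoform_of"),
}


def expected_removals(manifest: PlantManifest, filter_key: str) -> set[str]:
    """Transcript IDs that the named filter must remove from the fixture."""
    tags = EXPECTED_REMOVALS[filter_key]
    out: set[str] = set()
    for tag in tags:
        out |= manifest.with_tag(tag)
    return out


# --------------------------------------------------------------------------
# Helpers for property testing
# --------------------------------------------------------------------------

def mirror_fixture(fasta: str, table: GeneTable) -> tuple[str, GeneTable]:
    """Reverse-complement every scaffold and mirror all model coordinates.

    The mirrored fixture describes the same biology read from the other
    strand, so every sequence-level operation and filter must give identical
    results on it.
    """
    genome = GenomeIndex.from_text(fasta)
    lengths = genome.lengths
    fasta_lines = []
    for name in genome.names:
        seq = reverse_complement(genome.slice(name, 1, lengths[name]))
        fasta_lines.append(f">{name}")
        fasta_lines += [seq[i : i + 70] for i in range(0, len(seq), 70)]
    mirrored_models = []
    for m in table:
        L = lengths[m.scaffold]
        strand = "-" if m.strand == "+" else "+"
        segs = sorted(
            (L - s.end + 1, L - s.start + 1) for s in m.segments
        )
        ordered = segs if strand == "+" else segs[::-1]  # transcript order
        cumulative = 0
        with_phase = []
        for a, b in ordered:
            with_phase.append(CodingSegment(a, b, (3 - cumulative % 3) % 3))
            cumulative += b - a + 1
        mirrored_models.append(
            TranscriptModel(
                gene_id=m.gene_id,
                transcript_id=m.transcript_id,
                scaffold=m.scaffold,
                strand=strand,
                segments=tuple(with_phase),
                source_dialect=m.source_dialect,
                five_prime_partial=m.five_prime_partial,
                three_prime_partial=m.three_prime_partial,
                attributes=dict(m.attributes),
            )
        )
    return "\n".join(fasta_lines) + "\n", GeneTable(mirrored_models)


def random_table(seed: int, n_models: int = 100, n_scaffolds: int = 5) -> GeneTable:
    """A random but structurally valid GeneTable (no genome), for round-trip
    and permutation tests."""
    rng = random.Random(seed)
    models = []
    i = 0
    while len(models) < n_models:
        i += 1
        gene_id = f"rg{i:04d}"
        scaffold = f"scaf{rng.randint(1, n_scaffolds)}"
        strand = rng.choice("+-")
        n_transcripts = 2 if rng.random() < 0.2 and n_models - len(models) > 1 else 1
        for j in range(1, n_transcripts + 1):
            pos = rng.randint(1, 500_000)
            segments = []
            for _ in range(rng.randint(1, 5)):
                length = rng.randint(1, 300)
                segments.append(
                    CodingSegment(
                        pos, pos + length - 1, rng.choice((None, 0, 1, 2))
                    )
                )
                pos += length + rng.randint(2, 400)
            models.append(
                TranscriptModel(
                    gene_id=gene_id,
                    transcript_id=f"{gene_id}.t{j}",
                    scaffold=scaffold,
                    strand=strand,
                    segments=tuple(segments),
                    source_dialect=rng.choice(list(("gtf_generic", "synthetic"))),
                    five_prime_partial=rng.choice((None, None, False, True)),
                    three_prime_partial=rng.choice((None, None, False, True)),
                    attributes={"note": f"n{i}"} if rng.random() < 0.3 else {},
                )
            )
    return GeneTable(models[:n_models])
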