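# Methods

## Data model

A *transcript model* is the coding structure of one predicted transcript:
a gene ID, transcript ID, scaffold, strand, and an ordered tuple of coding
segments in **1-based inclusive** genomic coordinates. Segments are stored
in ascending genomic order on both strands; 5′→3′ transcript order is
derived from the strand on demand. Introns are defined implicitly as the
gaps between consecutive coding segments of one transcript.

Completeness is tri-state: `five_prime_partial` / `three_prime_partial` are
`True`, `False`, or `None` ("the source declared nothing"). The distinction
matters for incomplete-model removal, which falls back to the first coding
segment's phase only when a model carries no declaration at all.

A *gene table* is a set of transcript models with unique transcript IDs,
canonically sorted by (scaffold, start, transcript ID). It serializes to a
9-column TSV (segments encoded `start-end/phase`, attributes as JSON) that
round-trips exactly, including the tri-state flags.

## Dialect normalization

Nine producer conventions are reduced to four adapter families:

| adapter | producers | convention handled |
|---|---|---|
| `gtf_generic` | BRAKER-style GTF | CDS rows, quoted `gene_id`/`transcript_id` |
| `gtf_augustus` | AUGUSTUS | bare-token attribute column; gene = transcript ID without its `.t<n>` suffix |
| `gff3_hierarchical` | MAKER, EVidenceModeler, NCBI, Prokka, gffread, GenomeThreader | gene → mRNA → CDS/exon by `ID`/`Parent`; exon rows promoted when a transcript has no CDS children; orphan CDS grouped by own ID |
| `gff3_alignment` | GMAP, Exonerate | `match`/`cDNA_match` with `match_part` children or repeated rows sharing one ID |

All adapters share one collector that merges overlapping segments from the
same transcript and disambiguates repeated transcript IDs on different loci
with a `.dupN` suffix. Parsing is line-order independent (two-pass for
GFF3), tolerant of comments and an embedded `##FASTA` section, and raises
errors that name the offending line number.

## Filters

Each filter maps a gene table to (smaller table, log entry); removals carry
machine-readable reasons. All filters are contractive and idempotent, and
their survivor sets are invariant under reverse-complementing the genome and
mirroring coordinates/strands (verified property).

* **Length minima** — any intron < N, any exon segment < N, or total CDS
  < N. Defaults 20/20/150 nt: 20 nt is well below the minimum a spliceosome
  can process, and 150 nt (50 aa) is a common floor for a credible protein.
* **Incomplete removal** — declared-partial models are removed; models with
  no declaration are removed when the first coding segment's phase is
  nonzero (a nonzero opening phase means the reading frame starts mid-codon,
  i.e. the model is 5′-truncated).
* **Mono/multiexonic partition** — keep one class only.
* **Isoform separation** — single-linkage clusters of same-scaffold,
  same-strand models connected by ≥1 bp of coding-segment overlap, computed
  by an interval sweep (a segment starting at or before the running maximum
  end overlaps the segment holding that maximum) feeding union-find over
  transcript IDs. Union-find, rather than the sweep runs alone, is required
  because one model's segments can bridge otherwise separate runs across a
  long intron. Gene IDs are relabelled to cluster labels.
* **Unique collapse** — byte-identical structures deduplicate to the
  smallest transcript ID; then each cluster keeps exactly one model:
  maximal CDS length, ties broken by smaller start, then smaller ID.
* **Start codon** — first 3 nt of the spliced CDS must be ATG (optionally
  also GTG/TTG for prokaryotes; ATG is always accepted). Any `N` in the
  codon fails: absence of evidence is treated as failure.
* **Stop codon** — last 3 nt must be a stop of the selected translation
  table (NCBI tables 1 and 11 supported).
* **In-frame stops** — stop codons among codons 1 .. n−1 (the final
  complete codon is never counted, and `N`-containing codons never count as
  stops) must not exceed a threshold (default 0).
* **Canonical splice** — every intron must read GT..AG in 5′→3′ transcript
  orientation; monoexonic models pass vacuously; any `N` in a dinucleotide
  is non-canonical.
* **Functional gate** — the transcript ID (falling back to a `.p1`/`.t1`
  suffix-stripped form, then to the gene ID) must appear in the functional
  flat file with a similarity hit, a gene-family assignment, or either,
  depending on mode. Empty cells and `-`/`NA` sentinels count as absent.

The pipeline applies enabled filters in a fixed, logged order: isoform
separation, length minima (intron, exon, CDS), incompletes, partition,
start, stop, in-frame stops, canonical splice, functional, collapse.
Cheap structural checks run first; collapse runs last so the surviving
representative has already passed every quality gate. The bundled
**nine-filter preset** enables: intron ≥ 20, exon ≥ 20, CDS ≥ 150, ATG-only
start, required stop, zero in-frame stops, canonical-only splice sites,
any functional evidence, and unique collapse.

## Sequence primitives and numerical choices

* Genome access validates the alphabet (A/C/G/T/N after uppercasing) at
  load, so softmasking is neutral by construction and ambiguity codes fail
  fast with the offending letter named.
* Spliced CDS = concatenation of segments in ascending genomic order,
  reverse-complemented as a whole on the minus strand.
* Translation walks codons directly: `N`-containing codons yield `X`, stops
  yield `*`, and a trailing 1–2 nt remainder is dropped with a warning
  rather than an error — out-of-frame models are precisely what the filters
  exist to flag. Codon assignments come from the standard NCBI tables.
* Phases are recomputed on every write as `(3 − cumulative_length mod 3)
  mod 3` in 5′→3′ order, so emitted GTF/GFF3 is internally consistent even
  when the input's phases were absent or wrong.
* Statistics use exact integer sums and Python's `statistics.mean`/`median`
  (even-sized median = mean of the middle pair). The catalog is fixed at 41
  entries; the five genome-dependent entries read `n/a` when no reference
  is supplied, so report layout never varies.

## The fixture generator

`genecurate.simulate.generate(genome_params, model_params, seed)` builds a
synthetic genome and annotation with planted violations. Models are
constructed in transcript space — a CDS assembled codon-by-codon from
non-stop codons, split into exons, interleaved with GT..AG introns — then
placed on scaffolds, reverse-complemented for minus-strand placements.
Twelve violation tags cover every filter (short intron/exon/CDS, missing or
alternate start, missing stop, in-frame stop, non-canonical splice,
duplicate, overlapping isoform, declared-5′-partial, no functional hit).
Duplicate and isoform plants ride as satellites of clean host models; the
isoform satellite is an in-frame suffix of its host starting at a planted
internal ATG. A self-check re-derives every planted property from the
emitted sequences before the bundle is returned, so the generator cannot
silently drift from the filters it is meant to exercise.

What it emulates: realistic coordinate bookkeeping on both strands,
multi-scaffold placement, functional flat files with sentinel and omitted
rows, and exactly-attributable filter failures. What it does **not**
emulate: realistic codon usage or GC content beyond a single tunable
fraction, UTRs and non-coding features, nested/overlapping genes beyond the
planted isoform pairs, sequencing gaps (`N` runs), or realistic
intron-length distributions. It is a correctness instrument, not a
biological simulator.

Determinism: a seed is mandatory; two calls with equal parameters and seed
produce byte-identical FASTA, annotation, functional file and manifest.

## Verification

The test suite (188 tests) checks every component against independent
oracles: per-base and per-codon brute-force recomputation for sequence
primitives (plus Biopython's translator as a cross-check), graph-search
connected components and argmax scans for clustering/collapse, raw-list
recomputation for all 41 statistics, an independent GFF3 library for the
hierarchical parser, and the generator's plant manifest for end-to-end
filter recovery. `scripts/acceptance.py` re-derives the headline quantities
from a fresh seeded fixture (see README).

## Limitations

* Only coding structure is modelled; UTRs, non-coding RNAs and alternative
  TSS/TES are out of scope.
* The functional gate is presence/absence per ID; scores, e-values and
  coverage thresholds are not interpreted.
* Translation tables other than 1 and 11 are not offered.
* Splice-site classification looks only at the terminal dinucleotides, so
  rare U12-type (AT..AC) introns count as non-canonical.
* The intermediate table keeps one row per transcript; per-exon evidence
  scores from the producers are preserved only as opaque attributes.
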