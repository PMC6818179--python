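# genecurate

Filter, analyze and convert predicted gene models.

## The problem

Automated gene predictors and annotation combiners (AUGUSTUS/BRAKER, MAKER,
EVidenceModeler, Prokka, alignment tools such as GMAP and Exonerate) emit
gene models in mutually incompatible GTF/GFF dialects, and a substantial
fraction of those models are structurally or biologically implausible:
micro-exons and micro-introns, coding sequences without a start or stop
codon, premature in-frame stops, non-canonical splice sites, duplicated or
overlapping predictions from competing evidence, and fragments without any
functional support. Downstream work (variant annotation, comparative
genomics, browser display) needs one clean, deduplicated, well-formed model
set.

`genecurate` addresses this in three stages:

1. **Normalize** — parse any supported producer dialect into a single
   intermediate table of transcript models (scaffold, strand, ordered coding
   segments in 1-based inclusive coordinates, completeness flags). The table
   round-trips exactly through a plain TSV.
2. **Filter** — apply any combination of structural filters (feature-length
   minima, incomplete-model removal, mono/multiexonic partition, isoform
   clustering and collapse to a unique representative), sequence filters
   against a reference FASTA (start codon, stop codon, in-frame stops,
   canonical GT/AG splice sites), and a functional-evidence gate against a
   similarity-search/gene-family flat file. Every removal is logged with
   the transcript ID and a machine-readable reason.
3. **Report and convert** — a fixed 41-entry statistics catalog, raw length
   distributions, a splice-site usage table, per-model GC/AT/N content, and
   writers for GTF, hierarchical GFF3 (SnpEff- or JBrowse-flavored), and
   FASTA (protein, spliced CDS, or gene with introns).

A seeded synthetic-fixture generator (`genecurate.simulate`) builds small
genomes with planted, self-checked violations of each filter, which is how
the package tests itself end to end without external data.

## Worked example

Build a small demonstration input (a 2-scaffold genome, 60 models of which
18 carry planted defects) and curate it with the nine-filter preset:

```bash
python - <<'EOF'
from genecurate import simulate
from genecurate.writers import write_gtf
b = simulate.generate(
    genome_params={"n_scaffolds": 2, "scaffold_length": 40_000},
    model_params={"n_models": 60, "violation_mix": {
        "short_exon": 3, "no_start": 3, "no_stop": 3,
        "noncanonical_splice": 3, "duplicate_of": 3, "no_functional_hit": 3,
    }},
    seed=11,
)
write_gtf(b.table, "models.gtf")
open("genome.fa", "w").write(b.fasta)
open("entap.tsv", "w").write(b.entap_tsv)
EOF

genecurate models.gtf --format gtf --fasta genome.fa --entap entap.tsv \
  --preset nine-filter --statistics --write-gtf --write-fasta protein -o curated
```

Output:

```
models in:  60
models out: 42
wrote log: curated/filter_log.txt
wrote statistics: curated/statistics.txt
wrote gtf: curated/models.gtf
wrote protein: curated/proteins.faa
```

Exactly the 18 planted defects are removed, three per filter, each with a
reason in `curated/filter_log.txt`:

```
[3] min_exon_segment (minimum_nt=20)
    models before: 60
    models after:  57
    removed:       3
      - g0049.t1	exon_segment_length_10_below_20
...
[10] collapse_unique (-)
    models before: 45
    models after:  42
    removed:       3
      - g0001.t1_dup	duplicate_of:g0001.t1
```

`curated/statistics.txt` begins:

```
# annotation statistics
gene_count                 42
transcript_count           42
monoexonic_count           14
multiexonic_count          28
mono_multi_ratio           0.5000
plus_strand_count          20
minus_strand_count         22
scaffold_count             2
cds_total_nt               11439
cds_mean_nt                272.3571
```

and `curated/proteins.faa` holds the translated survivors:

```
>g0001.t1 gene=cluster_00001 loc=scaf1:133-523(+)
MNTAYTRTCQRTNCGKIILFNLRVRRTAGIYGHPTHPKRYLTRIVTKNLSLSGDILEIVY
RRGRTRRIKHWSAHCNISRCAGATKSILQKYAPSQR
```

All filters are also individually addressable (`--min-intron-size`,
`--require-start`, `--canonical-only`, `--unique`, …); run
`genecurate --help` for the full flag list. Everything is equally available
as a Python API (`genecurate.pipeline.PipelineConfig` / `run_pipeline`).

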