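"""Dialect adapters and the functional-annotation flat file."""

import io
import random

import pytest

from genecurate.errors import ConfigurationError, ParseError
from genecurate.parsers import parse_annotation, parse_functional

GTF_MINIMAL = (
    'chr1\tsrc\tCDS\t100\t199\t.\t+\t0\tgene_id "g1"; transcript_id "t1";\n'
)

GFF3_HIER = """##gff-version 3
chr1\tmaker\tgene\t100\t700\t.\t+\t.\tID=gene1
chr1\tmaker\tmRNA\t100\t700\t.\t+\t.\tID=mrna1;Parent=gene1
chr1\tmaker\tCDS\t100\t200\t.\t+\t0\tID=cds1;Parent=mrna1
chr1\tmaker\tCDS\t300\t400\t.\t+\t1\tID=cds1;Parent=mrna1
chr1\tmaker\tCDS\t600\t700\t.\t+\t0\tID=cds1;Parent=mrna1
"""

GFF3_ALIGN = """##gff-version 3
chr2\tgmap\tmatch\t1000\t2000\t95\t-\t.\tID=aln1;Name=query7
chr2\tgmap\tmatch_part\t1000\t1400\t95\t-\t.\tID=aln1.p1;Parent=aln1
chr2\tgmap\tmatch_part\t1700\t2000\t95\t-\t.\tID=aln1.p2;Parent=aln1
"""


class TestGtf:
    def test_minimal_single_cds(self):
        table = parse_annotation(io.StringIO(GTF_MINIMAL), "gtf_generic")
        assert len(table) == 1
        m = table.models[0]
        assert (m.gene_id, m.transcript_id, m.scaffold, m.strand) == (
            "g1", "t1", "chr1", "+",
        )
        assert [(s.start, s.end) for s in m.segments] == [(100, 199)]

    def test_disjoint_rows_same_transcript_merge(self):
        text = GTF_MINIMAL + (
            'chr1\tsrc\tCDS\t300\t350\t.\t+\t2\tgene_id "g1"; transcript_id "t1";\n'
        )
        table = parse_annotation(io.StringIO(text), "gtf_generic")
        assert len(table) == 1
        assert len(table.models[0].segments) == 2

    def test_augustus_bare_token_column9(self):
        text = (
            "# start gene g1\n"
            "chr1\tAUGUSTUS\tCDS\t10\t60\t.\t+\t0\tg1.t1\n"
            "# protein sequence = [MAAA]\n"
        )
        table = parse_annotation(io.StringIO(text), "gtf_augustus")
        m = table.models[0]
        assert m.transcript_id == "g1.t1"
        assert m.gene_id == "g1"

    def test_partial_attribute_sets_flags(self):
        text = (
            'chr1\tprokka\tCDS\t10\t60\t.\t+\t0\t'
            'gene_id "g1"; transcript_id "t1"; partial "10";\n'
        )
        m = parse_annotation(io.StringIO(text), "gtf_generic").models[0]
        assert m.five_prime_partial is True
        assert m.three_prime_partial is False

    def test_same_id_on_two_scaffolds_disambiguated(self):
        text = GTF_MINIMAL + (
            'chr2\tsrc\tCDS\t100\t199\t.\t+\t0\tgene_id "g1"; transcript_id "t1";\n'
        )
        table = parse_annotation(io.StringIO(text), "gtf_generic")
        assert sorted(table.transcript_ids()) == ["t1", "t1.dup1"]

    @pytest.mark.parametrize(
        "line,match",
        [
            ("chr1\tsrc\tCDS\t100\n", "8 tab-separated"),
            ('chr1\tsrc\tCDS\t200\t100\t.\t+\t0\ttranscript_id "t";\n', "start"),
        ],
    )
    def test_parse_errors_cite_line(self, line, match):
        with pytest.raises(ParseError, match=match):
            parse_annotation(io.StringIO(line), "gtf_generic")

    def test_unknown_dialect_is_configuration_error(self):
        with pytest.raises(ConfigurationError):
            parse_annotation(io.StringIO(GTF_MINIMAL), "gtf_fancy")


class TestGff3Hierarchical:
    def test_gene_mrna_cds_chain(self):
        table = parse_annotation(io.StringIO(GFF3_HIER), "gff3_hierarchical")
        assert len(table) == 1
        m = table.models[0]
        assert (m.gene_id, m.transcript_id) == ("gene1", "mrna1")
        assert [(s.start, s.end) for s in m.segments] == [
            (100, 200), (300, 400), (600, 700),
        ]

    def test_line_order_independence(self):
        lines = GFF3_HIER.strip().splitlines()
        header, body = lines[0], lines[1:]
        reference = parse_annotation(io.StringIO(GFF3_HIER), "gff3_hierarchical")
        rng = random.Random(0)
        for _ in range(10):
            rng.shuffle(body)
            shuffled = "\n".join([header, *body]) + "\n"
            table = parse_annotation(io.StringIO(shuffled), "gff3_hierarchical")
            assert table.models == reference.models

    def test_prokka_style_gene_direct_cds(self):
        text = (
            "##gff-version 3\n"
            "chr1\tprokka\tgene\t1\t90\t.\t+\t.\tID=locus1\n"
            "chr1\tprokka\tCDS\t1\t90\t.\t+\t0\tID=locus1.cds;Parent=locus1;partial=true\n"
        )
        m = parse_annotation(io.StringIO(text), "gff3_hierarchical").models[0]
        assert m.gene_id == m.transcript_id == "locus1"
        assert m.five_prime_partial is True

    def test_exons_promoted_when_no_cds(self):
        text = (
            "##gff-version 3\n"
            "chr1\tgth\tmRNA\t10\t100\t.\t+\t.\tID=m1\n"
            "chr1\tgth\texon\t10\t40\t.\t+\t.\tID=m1.e1;Parent=m1\n"
            "chr1\tgth\texon\t70\t100\t.\t+\t.\tID=m1.e2;Parent=m1\n"
        )
        m = parse_annotation(io.StringIO(text), "gff3_hierarchical").models[0]
        assert [(s.start, s.end) for s in m.segments] == [(10, 40), (70, 100)]

    def test_fasta_section_skipped(self):
        text = GFF3_HIER + "##FASTA\n>chr1\nACGT\n"
        assert len(parse_annotation(io.StringIO(text), "gff3_hierarchical")) == 1


class TestGff3Alignment:
    def test_match_with_parts(self):
        table = parse_annotation(io.StringIO(GFF3_ALIGN), "gff3_alignment")
        assert len(table) == 1
        m = table.models[0]
        assert m.gene_id == m.transcript_id == "aln1"
        assert [(s.start, s.end) for s in m.segments] == [(1000, 1400), (1700, 2000)]
        assert m.strand == "-"

    def test_repeated_cdna_match_rows_share_id(self):
        text = (
            "##gff-version 3\n"
            "chr3\tgmap\tcDNA_match\t50\t80\t.\t+\t.\tID=hit9\n"
            "chr3\tgmap\tcDNA_match\t120\t200\t.\t+\t.\tID=hit9\n"
        )
        m = parse_annotation(io.StringIO(text), "gff3_alignment").models[0]
        assert [(s.start, s.end) for s in m.segments] == [(50, 80), (120, 200)]

    def test_agrees_with_independent_gffutils_parse(self, tmp_path):
        gffutils = pytest.importorskip("gffutils")
        path = tmp_path / "aln.gff3"
        path.write_text(GFF3_ALIGN)
        db = gffutils.create_db(
            str(path), ":memory:", merge_strategy="create_unique", keep_order=True
        )
        oracle = sorted(
            (f.start, f.end) for f in db.features_of_type("match_part")
        )
        ours = parse_annotation(io.StringIO(GFF3_ALIGN), "gff3_alignment")
        assert [(s.start, s.end) for s in ours.models[0].segments] == oracle


class TestFunctionalFlatFile:
    HEADER = "Query Sequence\tSubject Sequence\tEggNOG Seed Ortholog\n"

    def test_hits_and_sentinels(self):
        text = self.HEADER + "t1\tsubj123\tOG0001\n" + "t2\tNA\tNA\n"
        fmap = parse_functional(io.StringIO(text))
        assert fmap.lookup("t1") == (True, True)
        assert fmap.lookup("t2") == (False, False)
        assert fmap.lookup("absent") is None

    def test_missing_column_names_the_column(self):
        with pytest.raises(ConfigurationError, match="Subject Sequence"):
            parse_functional(io.StringIO("Query Sequence\tother\na\tb\n"))

    def test_random_sentinel_patterns_match_per_cell_oracle(self):
        rng = random.Random(11)
        cells = ["hit1", "NA", "-", "", "OG99", "sp|P1|X"]
        rows, expected = [], {}
        for i in range(100):
            sim, fam = rng.choice(cells), rng.choice(cells)
            qid = f"q{i}"
            rows.append(f"{qid}\t{sim}\t{fam}")
            expected[qid] = (
                sim not in ("", "NA", "-"),
                fam not in ("", "NA", "-"),
            )
        fmap = parse_functional(io.StringIO(self.HEADER + "\n".join(rows) + "\n"))
        assert {q: fmap.lookup(q) for q in expected} == expected

    def test_suffix_stripped_lookup(self):
        fmap = parse_functional(io.StringIO(self.HEADER + "t1\tx\ty\n"))
        assert fmap.lookup("t1.p1") == (True, True)
        assert fmap.lookup("t1.p1", strip_suffix=False) is None


class TestSelfRoundTripStability:
    def test_parse_write_parse_fixed_point(self, bundle, tmp_path):
        """parse(write_gtf(parse(x))) == parse(x) on the fixture GTF."""
        from genecurate.writers import write_gtf

        path1 = tmp_path / "a.gtf"
        write_gtf(bundle.table, path1)
        once = parse_annotation(path1, "gtf_generic")
        path2 = tmp_path / "b.gtf"
        write_gtf(once, path2)
        twice = parse_annotation(path2, "gtf_generic")
        assert twice.models == once.models
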