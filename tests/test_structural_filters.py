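"""Length minima, incompleteness, exon-count partition, isoforms, collapsing."""

import random
from collections import deque

import pytest

from genecurate.models import CodingSegment, GeneTable, TranscriptModel, derive_introns
from genecurate.simulate import random_table
from genecurate.structural_filters import (
    LengthCriterion,
    cluster_models,
    collapse_unique,
    filter_by_length,
    partition_by_exon_count,
    remove_incompletes,
    separate_isoforms,
)


def _model(segs, tid="t1", gid="g1", strand="+", scaffold="chr1", **kw):
    return TranscriptModel(
        gene_id=gid,
        transcript_id=tid,
        scaffold=scaffold,
        strand=strand,
        segments=tuple(
            CodingSegment(*s) if len(s) == 3 else CodingSegment(s[0], s[1])
            for s in segs
        ),
        **kw,
    )


def _ids(table):
    return set(table.transcript_ids())


class TestFilterByLength:
    def test_short_intron_removes_model(self):
        # introns of 500 and 18 nt; the 18 nt one is below the 20 nt minimum
        m = _model([(1, 100), (601, 700), (719, 800)])
        table, entry = filter_by_length(GeneTable([m]), LengthCriterion("intron", 20))
        assert len(table) == 0
        assert entry.removed[0][0] == "t1"
        assert "18" in entry.removed[0][1]

    def test_empty_table_logs_zero_to_zero(self):
        table, entry = filter_by_length(GeneTable([]), LengthCriterion("total_cds", 150))
        assert (entry.models_before, entry.models_after) == (0, 0)

    @pytest.mark.parametrize("kind", ["exon_segment", "intron", "total_cds"])
    def test_matches_exhaustive_feature_scan(self, kind):
        table = random_table(13, n_models=300)
        minimum = {"exon_segment": 100, "intron": 150, "total_cds": 400}[kind]
        filtered, entry = filter_by_length(table, LengthCriterion(kind, minimum))
        expected = set()
        for m in table:
            if kind == "exon_segment":
                feats = [s.length for s in m.segments]
            elif kind == "intron":
                feats = [e - s + 1 for s, e in derive_introns(m)]
            else:
                feats = [m.cds_length]
            if all(f >= minimum for f in feats):
                expected.add(m.transcript_id)
        assert _ids(filtered) == expected
        assert entry.models_before - len(entry.removed) == len(filtered)

    def test_idempotent_and_contractive(self):
        table = random_table(14, n_models=100)
        crit = LengthCriterion("exon_segment", 50)
        once, _ = filter_by_length(table, crit)
        twice, entry = filter_by_length(once, crit)
        assert _ids(once) <= _ids(table)
        assert _ids(twice) == _ids(once) and not entry.removed


class TestRemoveIncompletes:
    def test_declared_partial_removed(self):
        m = _model([(1, 90)], five_prime_partial=True)
        table, entry = remove_incompletes(GeneTable([m]))
        assert len(table) == 0
        assert "5p" in entry.removed[0][1]

    def test_complete_phase0_retained(self):
        m = _model([(1, 90, 0)])
        table, _ = remove_incompletes(GeneTable([m]))
        assert len(table) == 1

    def test_truth_table_oracle(self):
        """Randomized flags/phases against the decision rule computed directly."""
        rng = random.Random(9)
        models = []
        for i in range(200):
            f5 = rng.choice((None, True, False))
            f3 = rng.choice((None, True, False))
            phase = rng.choice((None, 0, 1, 2))
            strand = rng.choice("+-")
            segs = [(100, 199), (300, 399)]
            seg_objs = [CodingSegment(*s) for s in segs]
            five_idx = 0 if strand == "+" else 1
            seg_objs[five_idx] = CodingSegment(
                segs[five_idx][0], segs[five_idx][1], phase
            )
            models.append(
                TranscriptModel(
                    gene_id=f"g{i}", transcript_id=f"t{i}", scaffold="c",
                    strand=strand, segments=tuple(seg_objs),
                    five_prime_partial=f5, three_prime_partial=f3,
                )
            )
        table, _ = remove_incompletes(GeneTable(models))
        survivors = _ids(table)
        for m in models:
            if m.five_prime_partial or m.three_prime_partial:
                keep = False
            elif m.five_prime_partial is None and m.three_prime_partial is None:
                keep = m.first_segment_5p().phase in (None, 0)
            else:
                keep = True
            assert (m.transcript_id in survivors) == keep


class TestPartition:
    def test_monoexonic_kept_multiexonic_dropped(self):
        t = GeneTable([_model([(1, 9)], tid="a"), _model([(1, 9), (20, 30), (50, 60)], tid="b")])
        mono, _ = partition_by_exon_count(t, "monoexonic")
        multi, _ = partition_by_exon_count(t, "multiexonic")
        assert _ids(mono) == {"a"} and _ids(multi) == {"b"}

    def test_partition_conserves_the_table(self):
        table = random_table(21, n_models=150)
        mono, _ = partition_by_exon_count(table, "monoexonic")
        multi, _ = partition_by_exon_count(table, "multiexonic")
        assert _ids(mono) | _ids(multi) == _ids(table)
        assert not _ids(mono) & _ids(multi)


def _brute_force_clusters(models):
    """Pairwise segment-overlap graph + BFS components (the oracle)."""
    def overlaps(a, b):
        if a.scaffold != b.scaffold or a.strand != b.strand:
            return False
        return any(
            sa.start <= sb.end and sb.start <= sa.end
            for sa in a.segments
            for sb in b.segments
        )

    adj = {m.transcript_id: set() for m in models}
    for i, a in enumerate(models):
        for b in models[i + 1:]:
            if overlaps(a, b):
                adj[a.transcript_id].add(b.transcript_id)
                adj[b.transcript_id].add(a.transcript_id)
    seen, components = set(), []
    for m in models:
        if m.transcript_id in seen:
            continue
        queue, comp = deque([m.transcript_id]), set()
        while queue:
            tid = queue.popleft()
            if tid in comp:
                continue
            comp.add(tid)
            queue.extend(adj[tid] - comp)
        seen |= comp
        components.append(frozenset(comp))
    return set(components)


class TestIsoformClustering:
    def test_one_bp_overlap_joins(self):
        t = GeneTable([_model([(1, 100)], tid="a"), _model([(100, 200)], tid="b")])
        clusters = cluster_models(t)
        assert len(clusters) == 1 and set(clusters[0].transcript_ids) == {"a", "b"}

    def test_opposite_strands_never_join(self):
        t = GeneTable([
            _model([(1, 100)], tid="a", strand="+"),
            _model([(1, 100)], tid="b", strand="-"),
        ])
        assert len(cluster_models(t)) == 2

    def test_adjacent_but_not_overlapping_stay_apart(self):
        t = GeneTable([_model([(1, 100)], tid="a"), _model([(101, 200)], tid="b")])
        assert len(cluster_models(t)) == 2

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_matches_graph_components_oracle(self, seed):
        rng = random.Random(seed)
        models = []
        for i in range(100):
            pos = rng.randint(1, 4000)
            segs = []
            for _ in range(rng.randint(1, 3)):
                length = rng.randint(20, 400)
                segs.append((pos, pos + length - 1))
                pos += length + rng.randint(2, 150)
            models.append(
                _model(segs, tid=f"t{i}", gid=f"g{i}",
                       scaffold=f"c{rng.randint(1, 2)}", strand=rng.choice("+-"))
            )
        got = {
            frozenset(c.transcript_ids) for c in cluster_models(GeneTable(models))
        }
        assert got == _brute_force_clusters(models)

    def test_separate_isoforms_relabels_gene_ids(self):
        t = GeneTable([
            _model([(1, 100)], tid="a", gid="x"),
            _model([(50, 150)], tid="b", gid="y"),
            _model([(500, 600)], tid="c", gid="z"),
        ])
        relabelled, clusters = separate_isoforms(t)
        assert len(clusters) == 2
        gids = {m.transcript_id: m.gene_id for m in relabelled}
        assert gids["a"] == gids["b"] != gids["c"]


class TestCollapseUnique:
    def test_longest_cds_wins(self):
        t = GeneTable([
            _model([(1, 450)], tid="long", gid="cl1"),
            _model([(100, 399)], tid="short", gid="cl1"),
        ])
        out, entry = collapse_unique(t)
        assert _ids(out) == {"long"}
        assert entry.removed == [("short", "collapsed_into:long")]

    def test_exact_duplicates_deduplicated_to_smallest_id(self):
        t = GeneTable([
            _model([(1, 90)], tid="b", gid="cl"),
            _model([(1, 90)], tid="a", gid="cl"),
        ])
        out, entry = collapse_unique(t)
        assert _ids(out) == {"a"}
        assert ("b", "duplicate_of:a") in entry.removed

    def test_argmax_tiebreak_oracle_on_random_clusters(self):
        rng = random.Random(31)
        models = []
        for c in range(50):
            for j in range(rng.randint(1, 5)):
                start = rng.randint(1, 100)
                length = rng.choice((90, 120, 120, 150))
                models.append(
                    _model([(start, start + length - 1)],
                           tid=f"c{c}t{j}", gid=f"cluster{c}",
                           scaffold=f"s{c}")
                )
        table = GeneTable(models)
        out, _ = collapse_unique(table)
        # oracle: dedupe then per-cluster argmax with the documented tie-break
        by_cluster = {}
        seen_structures = {}
        for m in sorted(models, key=lambda m: m.transcript_id):
            key = (m.scaffold, m.strand, tuple((s.start, s.end) for s in m.segments))
            if key in seen_structures:
                continue
            seen_structures[key] = m
            by_cluster.setdefault(m.gene_id, []).append(m)
        expected = {
            min(group, key=lambda m: (-m.cds_length, m.start, m.transcript_id)).transcript_id
            for group in by_cluster.values()
        }
        assert _ids(out) == expected

    def test_output_has_no_duplicates_and_one_per_cluster(self):
        table = random_table(44, n_models=120)
        relabelled, _ = separate_isoforms(table)
        out, _ = collapse_unique(relabelled)
        structures = [
            (m.scaffold, m.strand, tuple((s.start, s.end) for s in m.segments))
            for m in out
        ]
        assert len(structures) == len(set(structures))
        assert len({m.gene_id for m in out}) == len(out)

    def test_idempotent(self):
        table, _ = separate_isoforms(random_table(45, n_models=80))
        once, _ = collapse_unique(table)
        twice, entry = collapse_unique(once)
        assert _ids(twice) == _ids(once) and not entry.removed


class TestOrderInvariance:
    def test_shuffled_input_same_membership(self):
        table = random_table(50, n_models=80)
        shuffled_models = list(table.models)
        random.Random(1).shuffle(shuffled_models)
        shuffled = GeneTable(shuffled_models)
        for crit in (LengthCriterion("intron", 100), LengthCriterion("total_cds", 300)):
            a, _ = filter_by_length(table, crit)
            b, _ = filter_by_length(shuffled, crit)
            assert _ids(a) == _ids(b)
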