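"""Trimming, tag mapping with iterative rescue, CTSS clustering, proximity."""

import numpy as np
import pytest

from promap.cage import (
    CageTag,
    CtssCluster,
    cluster_ctss,
    cluster_gene_assignment,
    extend_to_promoter_length,
    iterative_trim_rescue,
    map_tags,
    promoter_ctss_proximity,
    remove_singletons,
    resolve_tag,
    run_cage_pipeline,
    trim_reads,
)
from promap.aligner import AlignmentHit
from promap.core import GeneModel, GenomeSequence, GenomicInterval
from promap.simdata import random_seq

ADAPTER = "TCGTATGCCGTCTTCTGCTTG"
PREFIX = "ACACAGCG"


class TestTrim:
    def test_prefix_insert_adapter_layout_recovered(self):
        insert = "ACGTACGTACGTACGTACGTACGTA"  # 25 bp
        read = PREFIX + insert + ADAPTER[:3]
        tags, stats = trim_reads([("r1", read)], ADAPTER, len(PREFIX))
        assert stats == {"library_before": 1, "library_after": 1}
        assert tags[0].sequence == insert

    def test_reads_below_20bp_dropped(self):
        insert = "ACGTACGTACGTACGTACG"  # 19 bp
        read = PREFIX + insert + ADAPTER[: 36 - len(PREFIX) - 19]
        tags, stats = trim_reads([("r1", read)], ADAPTER, len(PREFIX))
        assert tags == [] and stats["library_after"] == 0
        # one base more survives
        insert20 = insert + "A"
        read20 = PREFIX + insert20 + ADAPTER[: 36 - len(PREFIX) - 20]
        tags20, _ = trim_reads([("r1", read20)], ADAPTER, len(PREFIX))
        assert len(tags20) == 1 and len(tags20[0].sequence) == 20

    def test_missing_adapter_keeps_full_insert(self):
        insert = "A" * 28
        tags, _ = trim_reads([("r1", PREFIX + insert)], "GGGCCCGGG", len(PREFIX))
        assert tags[0].sequence == insert

    def test_empty_library_warns_and_returns_empty(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="promap"):
            tags, stats = trim_reads([], ADAPTER, len(PREFIX))
        assert tags == [] and stats["library_before"] == 0
        assert any("empty" in r.message for r in caplog.records)


@pytest.fixture(scope="module")
def tag_genome():
    g = GenomeSequence()
    rng = np.random.default_rng(17)
    g.add_contig("chr1", random_seq(rng, 30_000))
    g.add_contig("GL0001", random_seq(rng, 5_000))
    return g


def _hit(contig, start, length, bit, strand="+"):
    return AlignmentHit(
        "t", GenomicInterval(contig, start, start + length, strand),
        int(bit), float(bit), 100.0, 1e-8,
    )


class TestResolveTag:
    def test_no_hits_unmapped(self, tag_genome):
        assert resolve_tag([], tag_genome) == ("unmapped", None)

    def test_score_ratio_accepts_top(self, tag_genome):
        cls, placement = resolve_tag(
            [_hit("chr1", 100, 25, 50), _hit("chr1", 900, 25, 40)], tag_genome
        )
        assert cls == "unique" and placement.start == 100

    def test_scaffold_clause_single_chromosome_hit(self, tag_genome):
        cls, placement = resolve_tag(
            [_hit("chr1", 100, 25, 50), _hit("GL0001", 50, 25, 49)], tag_genome
        )
        assert cls == "unique" and placement.contig == "chr1"

    def test_two_chromosome_hits_multimapped(self, tag_genome):
        cls, placement = resolve_tag(
            [_hit("chr1", 100, 25, 50), _hit("chr1", 900, 25, 49)], tag_genome
        )
        assert cls == "multimapped" and placement is None


class TestIterativeTrimRescue:
    def test_corrupt_ends_rescued_by_trimming(self, tag_genome):
        seq = tag_genome.contigs["chr1"]

        def flip(b):
            return "A" if b != "A" else "C"

        # 4 mismatching bases at each end defeat the 2-base soft clip and
        # push core identity below threshold until two trim iterations
        # have removed them
        bad = (
            "".join(flip(b) for b in seq[5_000:5_004])
            + seq[5_004:5_021]
            + "".join(flip(b) for b in seq[5_021:5_025])
        )
        tag = CageTag("r", bad)
        map_tags([tag], tag_genome, rescue=False)
        assert tag.map_class == "unmapped"
        n = iterative_trim_rescue([tag], tag_genome)
        assert n == 1 and tag.map_class == "rescued"
        assert tag.trim_iterations == 2
        assert tag.placement.contig == "chr1"
        assert tag.placement.start >= 5_000 and tag.placement.end <= 5_025

    def test_12bp_tag_stops_at_floor(self, tag_genome):
        tag = CageTag("r", "ACGTACGTACGT")  # 12 bp, nowhere in genome
        iterative_trim_rescue([tag], tag_genome)
        assert tag.map_class == "unmapped"
        assert tag.trim_iterations == 0  # 12 - 2 = 10 < 11: never trimmed

    def test_hopeless_tag_exhausts_iterations(self, tag_genome):
        tag = CageTag("r", "AC" * 13)  # 26 bp low-complexity, absent
        iterative_trim_rescue([tag], tag_genome)
        assert tag.map_class in ("unmapped", "multimapped")
        if tag.map_class == "unmapped":
            # trims until next step would cross the 11-bp floor
            assert tag.trim_iterations == (26 - 12 + 1) // 2

    def test_never_converts_mapped_tags(self, tag_genome):
        core = tag_genome.contigs["chr1"][6_000:6_025]
        tag = CageTag("r", core)
        map_tags([tag], tag_genome, rescue=True)
        assert tag.map_class == "unique"
        assert tag.trim_iterations == 0


class TestMapTagsConservation:
    def test_class_counts_partition_tags(self, tag_genome):
        rng = np.random.default_rng(3)
        tags = []
        for i in range(30):
            s = int(rng.integers(0, 29_000))
            tags.append(CageTag(f"r{i}", tag_genome.contigs["chr1"][s : s + 25]))
        for i in range(10):
            tags.append(CageTag(f"junk{i}", random_seq(rng, 25)))
        counts = map_tags(tags, tag_genome)
        assert (
            counts["unique"] + counts["rescued"] + counts["multimapped"]
            + counts["unmapped"]
            == len(tags)
        )


class TestExtension:
    def test_even_split(self):
        iv = extend_to_promoter_length(
            GenomicInterval("c", 1000, 1025, "+"), 10_000
        )
        assert (iv.start, iv.end) == (762, 1263)

    def test_odd_split_extra_base_five_prime(self):
        plus = extend_to_promoter_length(
            GenomicInterval("c", 1000, 1024, "+"), 10_000
        )
        assert (plus.start, plus.end) == (761, 1262)  # 239 up, 238 down
        minus = extend_to_promoter_length(
            GenomicInterval("c", 1000, 1024, "-"), 10_000
        )
        assert (minus.start, minus.end) == (762, 1263)  # 239 on the end side

    def test_contig_edge_clip(self):
        iv = extend_to_promoter_length(GenomicInterval("c", 10, 35, "+"), 10_000)
        assert iv.start == 0 and iv.end == 273

    def test_overlong_placement_unchanged(self, caplog):
        import logging

        iv = GenomicInterval("c", 0, 600, "+")
        with caplog.at_level(logging.WARNING, logger="promap"):
            out = extend_to_promoter_length(iv, 10_000)
        assert out == iv


def _brute_force_clusters(items):
    """O(n^2) repeated-merge oracle for >= 1 bp overlap clustering."""
    groups = [
        {"contig": iv.contig, "strand": iv.strand, "start": iv.start,
         "end": iv.end, "members": {mid}}
        for mid, iv in items
    ]
    changed = True
    while changed:
        changed = False
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                a, b = groups[i], groups[j]
                if (
                    a["contig"] == b["contig"] and a["strand"] == b["strand"]
                    and a["start"] < b["end"] and b["start"] < a["end"]
                ):
                    a["start"] = min(a["start"], b["start"])
                    a["end"] = max(a["end"], b["end"])
                    a["members"] |= b["members"]
                    del groups[j]
                    changed = True
                    break
            if changed:
                break
    return {
        (g["contig"], g["strand"], g["start"], g["end"],
         frozenset(g["members"]))
        for g in groups
    }


class TestClustering:
    def test_one_base_overlap_merges(self):
        items = [
            ("a", GenomicInterval("c", 100, 601, "+")),
            ("b", GenomicInterval("c", 500, 1001, "+")),
        ]
        clusters = cluster_ctss(items)
        assert len(clusters) == 1
        assert clusters[0].interval == GenomicInterval("c", 100, 1001, "+")
        assert clusters[0].tag_count == 2

    def test_abutting_intervals_do_not_merge(self):
        items = [
            ("a", GenomicInterval("c", 100, 601, "+")),
            ("b", GenomicInterval("c", 601, 1102, "+")),
        ]
        assert len(cluster_ctss(items)) == 2

    def test_opposite_strands_stay_separate(self):
        items = [
            ("a", GenomicInterval("c", 100, 601, "+")),
            ("b", GenomicInterval("c", 100, 601, "-")),
        ]
        assert len(cluster_ctss(items)) == 2

    def test_clustering_idempotent(self, rng):
        items = [
            (f"m{i}",
             GenomicInterval("c", s := int(rng.integers(0, 5_000)),
                             s + int(rng.integers(1, 600)), "+"))
            for i in range(200)
        ]
        clusters = cluster_ctss(items)
        again = cluster_ctss(
            [(f"c{i}", c.interval) for i, c in enumerate(clusters)]
        )
        assert [c.interval for c in again] == [c.interval for c in clusters]

    def test_matches_brute_force_oracle(self, rng):
        for trial in range(25):
            n = int(rng.integers(2, 40))
            items = []
            for i in range(n):
                s = int(rng.integers(0, 3_000))
                items.append(
                    (f"m{i}",
                     GenomicInterval(
                         "c", s, s + int(rng.integers(1, 400)),
                         "+" if rng.random() < 0.5 else "-",
                     ))
                )
            got = {
                (c.interval.contig, c.interval.strand, c.interval.start,
                 c.interval.end, frozenset(c.member_ids))
                for c in cluster_ctss(items)
            }
            assert got == _brute_force_clusters(items)

    def test_tag_count_sum_conserved(self, rng):
        items = [
            (f"m{i}",
             GenomicInterval("c", s := int(rng.integers(0, 10_000)),
                             s + 501, "+"))
            for i in range(300)
        ]
        clusters = cluster_ctss(items)
        assert sum(c.tag_count for c in clusters) == 300


class TestSingletons:
    def test_removal_reports_count(self):
        clusters = [
            CtssCluster(GenomicInterval("c", 0, 501, "+"), 1, ("a",)),
            CtssCluster(GenomicInterval("c", 1000, 1501, "+"), 2, ("b", "c")),
        ]
        kept, removed = remove_singletons(clusters)
        assert removed == 1 and [c.tag_count for c in kept] == [2]


class TestGeneAssignment:
    GENES = [
        GeneModel("gPlus", GenomicInterval("c", 10_000, 12_000, "+"), 2000),
        GeneModel("gMinus", GenomicInterval("c", 30_000, 32_000, "-"), 2000),
    ]

    def _cluster(self, start, end):
        return CtssCluster(GenomicInterval("c", start, end, "+"), 2, ("a", "b"))

    def test_1kb_upstream_assigned(self):
        m = cluster_gene_assignment([self._cluster(8_900, 9_100)], self.GENES)
        assert m == {0: "gPlus"}

    def test_inside_gene_body_assigned(self):
        m = cluster_gene_assignment([self._cluster(11_000, 11_200)], self.GENES)
        assert m == {0: "gPlus"}

    def test_3kb_upstream_unassigned(self):
        m = cluster_gene_assignment([self._cluster(6_800, 7_000)], self.GENES)
        assert m == {}

    def test_minus_strand_upstream_is_rightward(self):
        m = cluster_gene_assignment([self._cluster(33_000, 33_200)], self.GENES)
        assert m == {0: "gMinus"}


class TestProximity:
    def test_overlap_proximal_at_both_thresholds(self):
        clusters = [CtssCluster(GenomicInterval("c", 1000, 1501, "+"), 2)]
        promoters = [GenomicInterval("c", 1400, 1901, "+")]
        out = promoter_ctss_proximity(clusters, promoters)
        assert out["clusters_near_promoter_100"] == 1.0
        assert out["clusters_near_promoter_2000"] == 1.0

    def test_gap_150_only_at_2kb(self):
        clusters = [CtssCluster(GenomicInterval("c", 1000, 1501, "+"), 2)]
        promoters = [GenomicInterval("c", 1651, 2152, "+")]
        out = promoter_ctss_proximity(clusters, promoters)
        assert out["clusters_near_promoter_100"] == 0.0
        assert out["clusters_near_promoter_2000"] == 1.0
        assert out["promoters_near_cluster_100"] == 0.0
        assert out["promoters_near_cluster_2000"] == 1.0


class TestPipeline:
    def test_end_to_end_counts_consistent(self, tag_genome):
        rng = np.random.default_rng(23)
        reads = []
        for i in range(200):
            s = int(rng.integers(0, 29_000))
            insert = tag_genome.contigs["chr1"][s : s + 25]
            reads.append((f"r{i}", PREFIX + insert + ADAPTER[:3]))
        out = run_cage_pipeline(reads, tag_genome, ADAPTER, len(PREFIX))
        stats = out["stats"]
        assert stats["library_after"] == 200
        assert (
            stats["unique"] + stats["rescued"] + stats["multimapped"]
            + stats["unmapped"]
            == stats["library_after"]
        )
        placed = stats["unique"] + stats["rescued"]
        assert sum(c.tag_count for c in out["clusters_all"]) == placed
        assert (
            stats["n_clusters"]
            == stats["n_singleton_clusters"] + stats["n_clusters_kept"]
        )
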