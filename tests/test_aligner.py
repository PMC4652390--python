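"""Seeded search vs exhaustive DP oracle, scoring statistics, tag path."""

import numpy as np
import pytest

from promap.aligner import (
    AlignmentHit,
    ScoringScheme,
    find_hits,
    find_tag_hits,
    merge_close_hits,
    revcomp,
    sw_oracle,
)
from promap.core import GenomeSequence, GenomicInterval
from promap.simdata import mutate, random_seq


class TestScoringScheme:
    def test_validation(self):
        with pytest.raises(ValueError):
            ScoringScheme(reward=0)
        with pytest.raises(ValueError):
            ScoringScheme(lambda_=-1)

    def test_bit_score_strictly_increasing_in_raw(self):
        s = ScoringScheme.pass1()
        bits = [s.bit_score(r) for r in range(0, 100, 7)]
        assert all(b2 > b1 for b1, b2 in zip(bits, bits[1:]))

    def test_evalue_decreases_with_score_increases_with_space(self):
        s = ScoringScheme.pass1()
        assert s.evalue(50, 501, 1e5) < s.evalue(40, 501, 1e5)
        assert s.evalue(50, 501, 1e6) > s.evalue(50, 501, 1e5)


class TestSwOracle:
    def test_exact_embedded_query(self):
        s = ScoringScheme.pass1()
        raw, (ts, te), strand = sw_oracle("ACGT", "TTACGTTT", s)
        assert (raw, ts, te, strand) == (4, 2, 6, "+")

    def test_reverse_complement_hits_minus_strand(self):
        s = ScoringScheme.pass1()
        target = "TT" + revcomp("ACGTTGCA") + "GGG"
        raw, iv, strand = sw_oracle("ACGTTGCA", target, s)
        assert raw == 8 and strand == "-" and iv == (2, 10)

    def test_size_cap(self):
        s = ScoringScheme.pass1()
        with pytest.raises(ValueError, match="cap"):
            sw_oracle("A" * 20_000, "C" * 10_000, s)


class TestFindHits:
    def test_perfect_501bp_match_scores_full_length(self, random_genome):
        q = random_genome.contigs["chr1"][20_000:20_501]
        hits = find_hits(q, random_genome, ScoringScheme.pass1())
        assert hits[0].raw_score == 501
        assert hits[0].identity_pct == 100.0
        assert hits[0].interval == GenomicInterval("chr1", 20_000, 20_501, "+")

    def test_exact_locus_outranks_mismatched_copy(self):
        rng = np.random.default_rng(3)
        s = ScoringScheme.pass1()
        block = random_seq(rng, 501)
        mut = block[:250] + ("A" if block[250] != "A" else "C") + block[251:]
        g = GenomeSequence()
        spacer = random_seq(rng, 300)
        g.add_contig("c1", spacer + block + spacer + mut + spacer)
        hits = find_hits(block, g, s)
        assert hits[0].interval.start == 300 and hits[0].raw_score == 501
        # oracle agrees on both loci
        raw_exact, _, _ = sw_oracle(block, block, s)
        raw_mut, _, _ = sw_oracle(block, mut, s)
        assert raw_exact == 501 and raw_mut == 499
        assert hits[1].raw_score == 499

    def test_short_query_directed_to_tag_path(self, random_genome):
        with pytest.raises(ValueError, match="short-read"):
            find_hits("ACGTACGT", random_genome, ScoringScheme.pass1())

    def test_masked_seeds_are_skipped(self):
        rng = np.random.default_rng(4)
        block = random_seq(rng, 60)
        g = GenomeSequence()
        g.add_contig("c1", random_seq(rng, 500) + block + random_seq(rng, 500),
                     mask_intervals=[(500, 560)])
        s = ScoringScheme.pass1()
        assert find_hits(block, g, s, use_mask=True) == []
        unmasked = find_hits(block, g, s, use_mask=False)
        assert unmasked and unmasked[0].interval.start == 500
        assert unmasked[0].raw_score == 60

    def test_strand_symmetry(self, random_genome):
        s = ScoringScheme.pass1()
        q = random_genome.contigs["chr1"][40_000:40_300]
        fwd = find_hits(q, random_genome, s)
        rev = find_hits(revcomp(q), random_genome, s)
        assert [h.raw_score for h in fwd] == [h.raw_score for h in rev]
        assert [h.interval.start for h in fwd] == [h.interval.start for h in rev]
        assert {h.interval.strand for h in fwd} == {"+"}
        assert {h.interval.strand for h in rev} == {"-"}

    def test_random_query_typically_no_hit(self, random_genome):
        rng = np.random.default_rng(99)
        s = ScoringScheme.pass1()
        empty = sum(
            1
            for _ in range(25)
            if not find_hits(random_seq(rng, 501), random_genome, s)
        )
        assert empty >= 23  # e-value 0.01 keeps chance hits rare


class TestOracleAgreement:
    def test_seeded_search_matches_oracle_on_high_identity_pairs(self):
        """Top raw score never exceeds the exhaustive optimum; whenever a
        hit with >= 90% identity is reported it equals the optimum, and
        near-identical queries are essentially always found."""
        rng = np.random.default_rng(21)
        s = ScoringScheme.pass1()
        checked_eq = 0
        easy_found = easy_total = 0
        for _ in range(120):
            tlen = int(rng.integers(60, 201))
            target = random_seq(rng, tlen)
            qs = int(rng.integers(0, tlen - 40))
            qe = qs + int(rng.integers(30, min(150, tlen - qs) + 1))
            sub = float(rng.uniform(0, 0.3))
            query, _ = mutate(target[qs:qe], sub, 0.01, rng)
            if len(query) < 11:
                continue
            oracle_raw, _, _ = sw_oracle(query, target, s)
            hits = find_hits(query, GenomeSequenceFactory(target), s)
            top = hits[0].raw_score if hits else 0
            assert top <= oracle_raw
            if hits and hits[0].identity_pct >= 90.0:
                assert top == oracle_raw
                checked_eq += 1
            if sub <= 0.02 and len(query) >= 60:
                easy_total += 1
                easy_found += bool(hits)
        assert checked_eq >= 10
        assert easy_total == 0 or easy_found / easy_total >= 0.95


def GenomeSequenceFactory(seq: str) -> GenomeSequence:
    g = GenomeSequence()
    g.add_contig("t", seq)
    return g


class TestMergeCloseHits:
    def _hit(self, contig, start, end, strand, raw):
        return AlignmentHit(
            "q", GenomicInterval(contig, start, end, strand), raw,
            float(raw), 100.0, 1e-10,
        )

    def test_nearby_hsps_collapse_to_best(self):
        hits = [
            self._hit("c", 100, 200, "+", 90),
            self._hit("c", 230, 300, "+", 50),
            self._hit("c", 1000, 1100, "+", 70),
        ]
        merged = merge_close_hits(hits, max_gap=50)
        assert [h.raw_score for h in merged] == [90, 70]

    def test_strands_never_merge(self):
        hits = [
            self._hit("c", 100, 200, "+", 90),
            self._hit("c", 210, 300, "-", 80),
        ]
        assert len(merge_close_hits(hits, max_gap=50)) == 2


class TestTagPath:
    def test_exact_tag_unique_hit(self, random_genome):
        tag = random_genome.contigs["chr1"][60_000:60_025]
        hits = find_tag_hits(tag, random_genome)
        assert len(hits) == 1
        assert hits[0].interval == GenomicInterval("chr1", 60_000, 60_025, "+")
        assert hits[0].raw_score == 25

    def test_terminal_mismatch_recovered_by_soft_clip(self, random_genome):
        base = random_genome.contigs["chr1"][61_000:61_025]
        corrupt = base[:-1] + ("A" if base[-1] != "A" else "C")
        hits = find_tag_hits(corrupt, random_genome)
        assert hits, "soft clip should salvage a terminal mismatch"
        best = hits[0]
        assert best.interval.start == 61_000
        # clipped core is full-score
        assert best.raw_score == 24
        # without clipping the mismatch costs penalty instead
        noclip = find_tag_hits(corrupt, random_genome, soft_clip=0)
        assert not noclip or noclip[0].raw_score < 24

    def test_two_copy_repeat_yields_two_equal_hits(self):
        rng = np.random.default_rng(5)
        tagsrc = random_seq(rng, 25)
        g = GenomeSequence()
        g.add_contig(
            "c1",
            random_seq(rng, 200) + tagsrc + random_seq(rng, 200)
            + tagsrc + random_seq(rng, 200),
        )
        hits = find_tag_hits(tagsrc, g)
        assert len(hits) == 2
        assert hits[0].raw_score == hits[1].raw_score == 25

    def test_minus_strand_tag(self, random_genome):
        tag = revcomp(random_genome.contigs["chr1"][62_000:62_025])
        hits = find_tag_hits(tag, random_genome)
        assert hits[0].interval.strand == "-"
        assert hits[0].interval.start == 62_000

    def test_sub_seed_length_rejected(self, random_genome):
        with pytest.raises(ValueError):
            find_tag_hits("ACGTACGTAC", random_genome)
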