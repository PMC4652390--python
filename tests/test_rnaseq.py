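"""FPKM, windowed coverage orientation, evidence calls and integration."""

import numpy as np
import pytest

from promap.cage import CtssCluster
from promap.core import AlignedFragment, GeneModel, GenomicInterval
from promap.rnaseq import (
    MIDPOINT_WINDOW,
    N_WINDOWS,
    CoverageMatrix,
    gene_counts_fpkm,
    heatmap_subset,
    integrate_evidence,
    rnaseq_evidence_call,
    window_coverage,
)


def _frag(contig, start, end, rid="f", multi=False):
    return AlignedFragment(GenomicInterval(contig, start, end), rid, multi)


class TestFpkm:
    GENE = GeneModel("g", GenomicInterval("c", 10_000, 11_000, "+"), 1000)

    def test_closed_form(self):
        frags = [_frag("c", 10_100 + i, 10_180 + i, f"f{i}") for i in range(10)]
        df = gene_counts_fpkm(frags, [self.GENE], 1_000_000)
        assert df.loc["g", "count"] == 10
        assert df.loc["g", "fpkm"] == pytest.approx(10.0)

    def test_zero_count_zero_fpkm(self):
        df = gene_counts_fpkm([], [self.GENE], 1_000_000)
        assert df.loc["g", "count"] == 0 and df.loc["g", "fpkm"] == 0.0

    def test_multimapped_fragments_excluded(self):
        frags = [_frag("c", 10_100, 10_180, "f0", multi=True)]
        df = gene_counts_fpkm(frags, [self.GENE], 1_000_000)
        assert df.loc["g", "count"] == 0

    def test_ambiguous_two_gene_fragment_discarded(self):
        g2 = GeneModel("h", GenomicInterval("c", 10_900, 12_000, "+"), 1100)
        frags = [_frag("c", 10_950, 10_990)]  # overlaps both
        df = gene_counts_fpkm(frags, [self.GENE, g2], 1_000_000)
        assert df["count"].sum() == 0

    def test_linear_in_count_and_inverse_in_library(self):
        frags = [_frag("c", 10_100 + i, 10_180 + i, f"f{i}") for i in range(8)]
        f1 = gene_counts_fpkm(frags, [self.GENE], 10**6).loc["g", "fpkm"]
        f2 = gene_counts_fpkm(frags * 2, [self.GENE], 10**6).loc["g", "fpkm"]
        f3 = gene_counts_fpkm(frags, [self.GENE], 2 * 10**6).loc["g", "fpkm"]
        assert f2 == pytest.approx(2 * f1)
        assert f3 == pytest.approx(f1 / 2)

    def test_zero_library_rejected(self):
        with pytest.raises(ValueError):
            gene_counts_fpkm([], [self.GENE], 0)


class TestWindowCoverage:
    def test_matrix_shape_and_single_window_hit(self):
        mid = 50_000
        # window 51 (1-based) covers [mid, mid+100)
        frags = [_frag("c", mid + 10, mid + 60)]
        m = window_coverage([("p", "c", mid, "+")], frags)
        assert m.counts.shape == (1, N_WINDOWS) == (1, 250)
        assert m.midpoint_window_index == MIDPOINT_WINDOW == 51
        assert m.counts[0, 50] == 1
        assert m.counts.sum() == 1

    def test_straddling_fragment_counts_in_both_windows(self):
        mid = 50_000
        frags = [_frag("c", mid + 50, mid + 200)]  # spans windows 51,52
        m = window_coverage([("p", "c", mid, "+")], frags)
        assert m.counts[0, 50] == 1 and m.counts[0, 51] == 1

    def test_multimapped_fragments_included(self):
        mid = 50_000
        frags = [_frag("c", mid + 10, mid + 60, multi=True)]
        m = window_coverage([("p", "c", mid, "+")], frags)
        assert m.counts.sum() == 1

    def test_minus_strand_orientation_against_brute_force(self):
        """A fragment 300 bp 5' of a minus-strand midpoint lands in the
        column given by brute-force coordinate arithmetic (upstream is
        rightward in genome coordinates for minus-strand rows)."""
        mid = 50_000
        # 5' direction for '-' is +coords; 300 bp upstream: [mid+300, mid+380)
        frags = [_frag("c", mid + 300, mid + 380)]
        m = window_coverage([("p", "c", mid, "-")], frags)
        # brute force: genomic window containing [mid+300,...) for '-' rows:
        # genomic span is [mid-20000, mid+5000), window j covers
        # [mid-20000+j*100, ...); fragment sits in j = 203; column =
        # 250-1-203 = 46 (0-based) -> 1-based 47; straddling none.
        hit_cols = np.nonzero(m.counts[0])[0]
        j = (mid + 300 - (mid - 20_000)) // 100
        expected = N_WINDOWS - 1 - j
        assert list(hit_cols) == [expected]
        # and the fragment is upstream of the midpoint window (lower col)
        assert expected < MIDPOINT_WINDOW - 1

    def test_strand_flip_symmetry(self):
        """Mirroring all coordinates and flipping strand leaves the
        oriented matrix invariant."""
        L = 200_000
        rng = np.random.default_rng(8)
        frags, flipped = [], []
        for i in range(300):
            s = int(rng.integers(30_000, 70_000))
            e = s + 80
            frags.append(_frag("c", s, e, f"f{i}"))
            flipped.append(_frag("c", L - e, L - s, f"f{i}"))
        mid = 50_000
        fwd = window_coverage([("p", "c", mid, "+")], frags)
        rev = window_coverage([("p", "c", L - 1 - mid, "-")], flipped)
        # mirrored midpoint base maps to L-1-mid; window grids align to
        # within one window of discretisation
        assert int(np.abs(fwd.counts[0] - rev.counts[0]).sum()) <= 2 * len(frags) // 100

    def test_out_of_contig_windows_count_zero(self):
        m = window_coverage([("p", "c", 1_000, "+")], [])
        assert m.counts.sum() == 0


class TestHeatmapSubset:
    def _matrix(self, first100_sum):
        counts = np.zeros((1, N_WINDOWS), dtype=np.int64)
        counts[0, :100] = 0
        counts[0, 0] = first100_sum
        return CoverageMatrix(["p"], counts)

    def test_boundary_eleven_kept_ten_dropped(self):
        assert heatmap_subset(self._matrix(11)) == ["p"]
        assert heatmap_subset(self._matrix(10)) == []

    def test_signal_beyond_first_100_windows_ignored(self):
        counts = np.zeros((1, N_WINDOWS), dtype=np.int64)
        counts[0, 150] = 100
        assert heatmap_subset(CoverageMatrix(["p"], counts)) == []

    def test_empty_matrix(self):
        m = CoverageMatrix([], np.zeros((0, N_WINDOWS), dtype=np.int64))
        assert heatmap_subset(m) == []


class TestEvidenceCall:
    def _row(self, hot_1based=None, count=1):
        row = np.zeros(N_WINDOWS, dtype=np.int64)
        if hot_1based is not None:
            row[hot_1based - 1] = count
        return row

    def test_single_fragment_in_midpoint_window_supports(self):
        # 1 count, 100-bp window, library 1e6 -> window FPKM 10 >= 1
        assert rnaseq_evidence_call(self._row(MIDPOINT_WINDOW), 1_000_000)

    def test_distal_signal_does_not_support(self):
        row = self._row(200, count=1000)
        assert not rnaseq_evidence_call(row, 1_000_000)

    @pytest.mark.parametrize("offset,expected", [
        (-3, False), (-2, True), (-1, True), (0, True),
        (1, True), (2, True), (3, True), (4, True), (5, False),
    ])
    def test_seven_window_boundary_enumeration(self, offset, expected):
        row = self._row(MIDPOINT_WINDOW + offset)
        assert rnaseq_evidence_call(row, 1_000_000) is expected

    def test_fpkm_threshold_scales_with_library(self):
        row = self._row(MIDPOINT_WINDOW, count=1)
        # window FPKM = 1e9/(100*lib); at lib=1e7 it is exactly 1.0
        assert rnaseq_evidence_call(row, 10_000_000)
        assert not rnaseq_evidence_call(row, 10_000_001)


class TestIntegration:
    def test_adjacent_cluster_and_expression_gives_both(self):
        mapped = {"p": GenomicInterval("c", 10_000, 10_501, "+")}
        clusters = [CtssCluster(GenomicInterval("c", 10_600, 11_101, "+"), 2)]
        calls, summary = integrate_evidence(mapped, clusters, [], {"p": True})
        assert calls[0].category == "both"
        assert summary["both_fraction"] == 1.0

    def test_singleton_tag_counts_as_cage_support(self):
        mapped = {"p": GenomicInterval("c", 10_000, 10_501, "+")}
        singleton = [GenomicInterval("c", 11_000, 11_501, "+")]
        calls, _ = integrate_evidence(mapped, [], singleton, {"p": False})
        assert calls[0].category == "cage_only"

    def test_no_support_is_none(self):
        mapped = {"p": GenomicInterval("c", 10_000, 10_501, "+")}
        clusters = [CtssCluster(GenomicInterval("c", 50_000, 50_501, "+"), 2)]
        calls, summary = integrate_evidence(mapped, clusters, [], {"p": False})
        assert calls[0].category == "none"
        assert summary["supported_fraction"] == 0.0
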