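"""RNA-Seq evidence around projected promoters.

Aligned fragments are turned into per-gene FPKM, windowed coverage
matrices around mapped-promoter midpoints (250 non-overlapping 100-bp
windows spanning 5 kb upstream to 20 kb downstream, 5'->3' oriented),
heatmap-eligible subsets, and per-promoter expression-evidence calls
(>= 1 FPKM in any of the seven 100-bp windows covering -200..+400
around the midpoint). CAGE and RNA-Seq support are then integrated into
a four-way evidence category per promoter.

Fragment counting conventions differ deliberately between operations:
gene counting uses uniquely mapped fragments only and discards
fragments spanning two genes, while window coverage includes
multimapped fragments so duplicated gene families still show
qualitative expression.
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cage import CtssCluster
from .core import (
    AlignedFragment,
    FeatureIndex,
    GeneModel,
    GenomicInterval,
    closest_feature,
)

logger = logging.getLogger("promap")

WINDOW_SIZE = 100
UPSTREAM_SPAN = 5_000
DOWNSTREAM_SPAN = 20_000
N_WINDOWS = (UPSTREAM_SPAN + DOWNSTREAM_SPAN) // WINDOW_SIZE  # 250
#: 1-based index of the window containing the midpoint base; 50 upstream
#: windows put it at 51. ``midpoint_window_offset`` in the calls below
#: lets replication attempts shift it.
MIDPOINT_WINDOW = UPSTREAM_SPAN // WINDOW_SIZE + 1
HEATMAP_MIN_READS = 11
HEATMAP_SPAN_WINDOWS = 100
EVIDENCE_FPKM_MIN = 1.0
EVIDENCE_UP_WINDOWS = 2   # covering -200..0
EVIDENCE_DOWN_WINDOWS = 4  # covering 0..+400 beyond the midpoint window


@dataclass
class CoverageMatrix:
    """Fragment counts in 250 oriented 100-bp windows per promoter."""

    promoter_ids: list[str]
    counts: np.ndarray  # shape (n_promoters, N_WINDOWS)
    midpoint_window_index: int = MIDPOINT_WINDOW  # 1-based

    def row(self, promoter_id: str) -> np.ndarray:
        return self.counts[self.promoter_ids.index(promoter_id)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts,
            index=self.promoter_ids,
            columns=[f"w{i + 1}" for i in range(self.counts.shape[1])],
        )


@dataclass(frozen=True)
class EvidenceCall:
    promoter_id: str
    cage_support: bool
    rnaseq_support: bool

    @property
    def category(self) -> str:
        if self.cage_support and self.rnaseq_support:
            return "both"
        if self.cage_support:
            return "cage_only"
        if self.rnaseq_support:
            return "rnaseq_only"
        return "none"


# ---------------------------------------------------------------------------
# FPKM
# ---------------------------------------------------------------------------

def gene_counts_fpkm(
    fragments: Sequence[AlignedFragment],
    genes: Sequence[GeneModel],
    library_size: int,
) -> pd.DataFrame:
    """Per-gene fragment counts and FPKM.

    A fragment counts for a gene iff it is uniquely mapped and overlaps
    exactly one gene span (ambiguous fragments are discarded, as in
    union-rule counting). ``fpkm = count * 1e9 / (exonic_length *
    library_size)``.
    """
    if library_size <= 0:
        raise ValueError("library_size must be positive")
    by_contig: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_contig.setdefault(g.interval.contig, []).append(g)
    starts: dict[str, list[int]] = {}
    max_len: dict[str, int] = {}
    for contig, gs in by_contig.items():
        gs.sort(key=lambda g: g.interval.start)
        starts[contig] = [g.interval.start for g in gs]
        max_len[contig] = max(g.interval.length for g in gs)
    counts = {g.gene_id: 0 for g in genes}
    for f in fragments:
        if f.multimapped:
            continue
        contig = f.interval.contig
        gs = by_contig.get(contig)
        if not gs:
            continue
        lo = bisect.bisect_left(
            starts[contig], f.interval.start - max_len[contig]
        )
        overlapping: list[GeneModel] = []
        for g in gs[lo:]:
            if g.interval.start >= f.interval.end:
                break
            if g.interval.overlaps(f.interval):
                overlapping.append(g)
                if len(overlapping) > 1:
                    break
        if len(overlapping) == 1:
            counts[overlapping[0].gene_id] += 1
    rows = [
        {
            "gene_id": g.gene_id,
            "count": counts[g.gene_id],
            "fpkm": counts[g.gene_id] * 1e9 / (g.exonic_length * library_size),
        }
        for g in genes
    ]
    return pd.DataFrame(rows).set_index("gene_id")


# ---------------------------------------------------------------------------
# window coverage
# ---------------------------------------------------------------------------

class _FragmentLookup:
    """Per-contig sorted starts/ends for O(log n) any-overlap counts."""

    def __init__(self, fragments: Sequence[AlignedFragment]):
        starts: dict[str, list[int]] = {}
        ends: dict[str, list[int]] = {}
        for f in fragments:
            starts.setdefault(f.interval.contig, []).append(f.interval.start)
            ends.setdefault(f.interval.contig, []).append(f.interval.end)
        self.starts = {c: sorted(v) for c, v in starts.items()}
        self.ends = {c: sorted(v) for c, v in ends.items()}

    def count_overlapping(self, contig: str, start: int, end: int) -> int:
        s = self.starts.get(contig)
        if not s:
            return 0
        e = self.ends[contig]
        return bisect.bisect_left(s, end) - bisect.bisect_right(e, start)


def window_coverage(
    midpoints: Sequence[tuple[str, str, int, str]],
    fragments: Sequence[AlignedFragment],
    midpoint_window_offset: int = 0,
) -> CoverageMatrix:
    """Count fragments per 100-bp window around each promoter midpoint.

    ``midpoints`` rows are (promoter_id, contig, midpoint, strand). A
    fragment increments every window its interval overlaps; multimapped
    fragments are included. Windows run 5'->3': for minus-strand
    promoters the genomic column order is reversed so column 1 is always
    the 5'-most window. Windows beyond contig ends simply count zero.
    """
    lookup = _FragmentLookup(fragments)
    mat = np.zeros((len(midpoints), N_WINDOWS), dtype=np.int64)
    for r, (pid, contig, mid, strand) in enumerate(midpoints):
        if strand == "-":
            # genomic span [mid - 20000, mid + 5000), 5'-most window on
            # the right; reverse so column 1 is 5'-most
            lo = mid - DOWNSTREAM_SPAN
            for w in range(N_WINDOWS):
                ws = lo + w * WINDOW_SIZE
                mat[r, N_WINDOWS - 1 - w] = lookup.count_overlapping(
                    contig, ws, ws + WINDOW_SIZE
                )
        else:
            lo = mid - UPSTREAM_SPAN
            for w in range(N_WINDOWS):
                ws = lo + w * WINDOW_SIZE
                mat[r, w] = lookup.count_overlapping(
                    contig, ws, ws + WINDOW_SIZE
                )
    return CoverageMatrix(
        [m[0] for m in midpoints],
        mat,
        MIDPOINT_WINDOW + midpoint_window_offset,
    )


def heatmap_subset(
    matrix: CoverageMatrix,
    min_reads: int = HEATMAP_MIN_READS,
    span: int = HEATMAP_SPAN_WINDOWS,
) -> list[str]:
    """Promoters with at least ``min_reads`` fragments summed over the
    first ``span`` windows (the heatmap eligibility rule)."""
    sums = matrix.counts[:, :span].sum(axis=1)
    return [
        pid for pid, s in zip(matrix.promoter_ids, sums) if s >= min_reads
    ]


def rnaseq_evidence_call(
    row: np.ndarray,
    library_size: int,
    midpoint_window_index: int = MIDPOINT_WINDOW,
    fpkm_min: float = EVIDENCE_FPKM_MIN,
) -> bool:
    """Expression evidence near the midpoint: >= ``fpkm_min`` FPKM in
    any of the seven windows spanning -200..+400 (midpoint window, two
    upstream, four downstream). Window FPKM uses the 100-bp window as
    the per-kilobase feature length."""
    if library_size <= 0:
        raise ValueError("library_size must be positive")
    m = midpoint_window_index - 1  # 0-based
    lo = max(0, m - EVIDENCE_UP_WINDOWS)
    hi = min(len(row), m + EVIDENCE_DOWN_WINDOWS + 1)
    window_fpkm = row[lo:hi] * 1e9 / (WINDOW_SIZE * library_size)
    return bool((window_fpkm >= fpkm_min).any())


def evidence_calls_for_matrix(
    matrix: CoverageMatrix, library_size: int,
    fpkm_min: float = EVIDENCE_FPKM_MIN,
) -> dict[str, bool]:
    return {
        pid: rnaseq_evidence_call(
            matrix.counts[i], library_size,
            matrix.midpoint_window_index, fpkm_min,
        )
        for i, pid in enumerate(matrix.promoter_ids)
    }


# ---------------------------------------------------------------------------
# evidence integration
# ---------------------------------------------------------------------------

def integrate_evidence(
    mapped_promoters: Mapping[str, GenomicInterval],
    clusters: Sequence[CtssCluster],
    singleton_tags: Sequence[GenomicInterval],
    rnaseq_support: Mapping[str, bool],
    max_dist: int = 2000,
) -> tuple[list[EvidenceCall], dict[str, float]]:
    """Combine CAGE proximity and RNA-Seq window evidence per promoter.

    CAGE support means a CTSS cluster or a uniquely mapped singleton tag
    within ``max_dist`` bp of the promoter's mapped (extended) interval.
    Returns the calls plus summary fractions.
    """
    cage_features = [c.interval for c in clusters] + list(singleton_tags)
    index = FeatureIndex(cage_features) if cage_features else None
    calls: list[EvidenceCall] = []
    for pid in sorted(mapped_promoters):
        iv = mapped_promoters[pid]
        cage = (
            index is not None
            and closest_feature(iv, index, max_dist) is not None
        )
        calls.append(
            EvidenceCall(pid, cage, bool(rnaseq_support.get(pid, False)))
        )
    n = len(calls)
    n_both = sum(1 for c in calls if c.category == "both")
    n_supported = sum(1 for c in calls if c.category != "none")
    summary = {
        "n_promoters": float(n),
        "supported_fraction": n_supported / n if n else 0.0,
        "both_fraction": n_both / n if n else 0.0,
        "both_fraction_of_supported": (
            n_both / n_supported if n_supported else 0.0
        ),
        "cage_fraction": (
            sum(1 for c in calls if c.cage_support) / n if n else 0.0
        ),
        "rnaseq_fraction": (
            sum(1 for c in calls if c.rnaseq_support) / n if n else 0.0
        ),
    }
    logger.info("evidence integration: %s", summary)
    return calls, summary
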