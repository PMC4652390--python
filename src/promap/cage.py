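"""CAGE read processing: trimming, alignment, rescue, CTSS clustering.

Raw single-end CAGE reads are trimmed of their fixed 5' prefix
(barcode + restriction-enzyme bases) and 3' sequencing adapter, length
filtered (>= 20 bp, no base-quality filtering), and aligned to the
*unmasked* genome on the short-read path with up to two soft-clipped
bases per end. Unmapped reads are rescued by iterative 1-bp trimming
from both ends down to an 11-bp floor. Uniquely placed tags are
extended to the 501-bp promoter-window length, merged into CTSS
clusters (>= 1 bp overlap, strand-specific), singleton clusters are
removed, and clusters are related to genes and to projected promoters
by proximity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .aligner import AlignmentHit, ScoringScheme, find_tag_hits, SEED_K
from .core import (
    FeatureIndex,
    GeneModel,
    GenomeSequence,
    GenomicInterval,
    closest_feature,
)

logger = logging.getLogger("promap")

MIN_TAG_LENGTH = 20
TRIM_FLOOR = 11
RATIO_THRESHOLD = 0.95
PROMOTER_LENGTH = 501


@dataclass
class CageTag:
    read_id: str
    sequence: str
    placement: Optional[GenomicInterval] = None
    map_class: str = "unmapped"  # unique | rescued | multimapped | unmapped
    trim_iterations: int = 0
    n_hits: int = 0


@dataclass(frozen=True)
class CtssCluster:
    """Strand-specific merged set of extended tag placements."""

    interval: GenomicInterval
    tag_count: int
    member_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.tag_count < 1:
            raise ValueError("cluster needs >= 1 supporting tag")


# ---------------------------------------------------------------------------
# trimming
# ---------------------------------------------------------------------------

def _find_adapter_start(seq: str, adapter: str, min_overlap: int = 3) -> int:
    """Leftmost position where the read suffix matches the adapter start
    (>= min_overlap bp, <= 1 mismatch per 10 bp); len(seq) if absent."""
    L = len(seq)
    for i in range(0, L - min_overlap + 1):
        ovl = min(L - i, len(adapter))
        if ovl < min_overlap:
            break
        mm_allowed = ovl // 10
        mm = 0
        ok = True
        for a, b in zip(seq[i : i + ovl], adapter[:ovl]):
            if a != b:
                mm += 1
                if mm > mm_allowed:
                    ok = False
                    break
        if ok:
            return i
    return L


def read_fastq(path: str | Path) -> list[tuple[str, str]]:
    reads = []
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                break
            seq = fh.readline().rstrip("\n")
            fh.readline()
            fh.readline()
            reads.append((header.rstrip("\n").lstrip("@"), seq))
    return reads


def trim_reads(
    reads: Iterable[tuple[str, str]] | str | Path,
    adapter_3p: str,
    prefix_5p_len: int,
    min_len: int = MIN_TAG_LENGTH,
) -> tuple[list[CageTag], dict[str, int]]:
    """Trim adapter and 5' prefix; keep tags of ``min_len`` bases or more.

    No base-quality filtering is applied. Returns the surviving tags and
    {library_before, library_after} counts; the retention fraction is
    logged.
    """
    if isinstance(reads, (str, Path)):
        reads = read_fastq(reads)
    tags: list[CageTag] = []
    n_in = 0
    for rid, seq in reads:
        n_in += 1
        seq = seq.upper()
        cut = _find_adapter_start(seq, adapter_3p.upper())
        insert = seq[prefix_5p_len:cut]
        if len(insert) >= min_len:
            tags.append(CageTag(read_id=rid, sequence=insert))
    stats = {"library_before": n_in, "library_after": len(tags)}
    if n_in == 0:
        logger.warning("trim_reads: empty input library")
    else:
        logger.info(
            "trim_reads: kept %d/%d reads (%.1f%%)",
            len(tags), n_in, 100.0 * len(tags) / n_in,
        )
    return tags, stats


# ---------------------------------------------------------------------------
# alignment + rescue
# ---------------------------------------------------------------------------

def align_tag(
    tag: CageTag,
    genome: GenomeSequence,
    scheme: Optional[ScoringScheme] = None,
    soft_clip: int = 2,
) -> list[AlignmentHit]:
    """Short-read placements of the tag on the unmasked genome, ranked
    by bit-score."""
    return find_tag_hits(tag.sequence, genome, scheme, soft_clip)


def resolve_tag(
    hits: Sequence[AlignmentHit],
    genome: GenomeSequence,
    ratio_threshold: float = RATIO_THRESHOLD,
) -> tuple[str, Optional[GenomicInterval]]:
    """Single-placement decision for a tag.

    0 hits -> unmapped; 1 hit -> unique; >= 2 hits -> the top hit is a
    single placement when s2/s1 < 0.95 or when it is the only hit on a
    chromosome with all others on unplaced scaffolds; else multimapped.
    """
    if not hits:
        return "unmapped", None
    if len(hits) == 1:
        return "unique", hits[0].interval
    s1, s2 = hits[0].bit_score, hits[1].bit_score
    if s1 > 0 and s2 / s1 < ratio_threshold:
        return "unique", hits[0].interval
    on_chrom = [h for h in hits if not genome.is_scaffold(h.interval.contig)]
    if len(on_chrom) == 1:
        return "unique", on_chrom[0].interval
    return "multimapped", None


def iterative_trim_rescue(
    tags: Sequence[CageTag],
    genome: GenomeSequence,
    scheme: Optional[ScoringScheme] = None,
    min_len: int = TRIM_FLOOR,
    ratio_threshold: float = RATIO_THRESHOLD,
) -> int:
    """Rescue unmapped tags by trimming one base from each end and
    realigning, iterating until a single placement is found or the next
    trim would take the tag below ``min_len`` bases.

    Mutates the tags in place (map_class ``rescued`` on success,
    final multimapped/unmapped otherwise); returns the rescued count.
    Already-placed and multimapped tags are left untouched.
    """
    n_rescued = 0
    for tag in tags:
        if tag.map_class != "unmapped":
            continue
        seq = tag.sequence
        iters = 0
        final_multi = False
        while len(seq) - 2 >= min_len:
            seq = seq[1:-1]
            iters += 1
            if len(seq) < SEED_K:
                break
            hits = find_tag_hits(seq, genome, scheme)
            cls, placement = resolve_tag(hits, genome, ratio_threshold)
            if cls == "unique":
                tag.map_class = "rescued"
                tag.placement = placement
                tag.trim_iterations = iters
                tag.n_hits = len(hits)
                n_rescued += 1
                break
            final_multi = cls == "multimapped"
        if tag.map_class == "unmapped":
            tag.trim_iterations = iters
            if final_multi:
                tag.map_class = "multimapped"
    return n_rescued


def map_tags(
    tags: Sequence[CageTag],
    genome: GenomeSequence,
    scheme: Optional[ScoringScheme] = None,
    rescue: bool = True,
    ratio_threshold: float = RATIO_THRESHOLD,
) -> dict[str, int]:
    """Align all tags, resolve placements and (optionally) run the
    iterative trimming rescue. Mutates tags; returns class counts."""
    for tag in tags:
        hits = align_tag(tag, genome, scheme)
        cls, placement = resolve_tag(hits, genome, ratio_threshold)
        tag.map_class = cls
        tag.placement = placement
        tag.n_hits = len(hits)
    if rescue:
        iterative_trim_rescue(
            tags, genome, scheme, ratio_threshold=ratio_threshold
        )
    counts = {"unique": 0, "rescued": 0, "multimapped": 0, "unmapped": 0}
    for tag in tags:
        counts[tag.map_class] += 1
    counts["mapped"] = counts["unique"] + counts["rescued"]
    logger.info("map_tags: %s", counts)
    return counts


# ---------------------------------------------------------------------------
# extension + clustering
# ---------------------------------------------------------------------------

def extend_to_promoter_length(
    placement: GenomicInterval,
    contig_length: int,
    target_len: int = PROMOTER_LENGTH,
) -> GenomicInterval:
    """Extend a placement from both ends to the promoter-window length.

    The total added length is split evenly, the odd base going to the
    5' side (strand-aware); the result is clipped to the contig and may
    therefore be shorter than ``target_len`` at contig edges.
    """
    if placement.length > target_len:
        logger.warning(
            "placement %s longer than %d bp; returned unchanged",
            placement, target_len,
        )
        return placement
    add = target_len - placement.length
    five = (add + 1) // 2
    three = add - five
    if placement.strand == "-":
        s, e = placement.start - three, placement.end + five
    else:
        s, e = placement.start - five, placement.end + three
    return GenomicInterval(
        placement.contig, max(0, s), min(e, contig_length), placement.strand
    )


def cluster_ctss(
    placements: Sequence[tuple[str, GenomicInterval]],
) -> list[CtssCluster]:
    """Single-linkage merge of stranded intervals overlapping by >= 1 bp
    (abutting intervals do not merge), per contig and strand.

    ``placements`` are (member_id, extended interval) pairs. The cluster
    interval is the union of its members.
    """
    groups: dict[tuple[str, str], list[tuple[GenomicInterval, str]]] = {}
    for mid, iv in placements:
        groups.setdefault((iv.contig, iv.strand), []).append((iv, mid))
    clusters: list[CtssCluster] = []
    for (contig, strand), items in sorted(groups.items()):
        items.sort(key=lambda x: (x[0].start, x[0].end))
        cur_start, cur_end = items[0][0].start, items[0][0].end
        members = [items[0][1]]
        for iv, mid in items[1:]:
            if iv.start < cur_end:  # >= 1 bp overlap
                cur_end = max(cur_end, iv.end)
                members.append(mid)
            else:
                clusters.append(
                    CtssCluster(
                        GenomicInterval(contig, cur_start, cur_end, strand),
                        len(members), tuple(members),
                    )
                )
                cur_start, cur_end, members = iv.start, iv.end, [mid]
        clusters.append(
            CtssCluster(
                GenomicInterval(contig, cur_start, cur_end, strand),
                len(members), tuple(members),
            )
        )
    return clusters


def remove_singletons(
    clusters: Sequence[CtssCluster],
) -> tuple[list[CtssCluster], int]:
    """Drop clusters supported by a single tag; returns (kept, n_removed)."""
    kept = [c for c in clusters if c.tag_count >= 2]
    n_removed = len(clusters) - len(kept)
    logger.info(
        "singleton filter: removed %d of %d clusters", n_removed, len(clusters)
    )
    return kept, n_removed


def cluster_gene_assignment(
    clusters: Sequence[CtssCluster],
    genes: Sequence[GeneModel],
    upstream: int = 2000,
) -> dict[int, str]:
    """Assign clusters to genes they overlap or lie within ``upstream``
    bp of (strand-aware upstream window of the gene 5' end); nearest
    gene 5' end wins ties. Returns {cluster index: gene_id}."""
    regions: list[tuple[GenomicInterval, GeneModel]] = []
    for g in genes:
        iv = g.interval
        if iv.strand == "+":
            s, e = max(0, iv.start - upstream), iv.end
        else:
            s, e = iv.start, iv.end + upstream
        regions.append((GenomicInterval(iv.contig, s, e, iv.strand), g))
    by_contig: dict[str, list[tuple[GenomicInterval, GeneModel]]] = {}
    for iv, g in regions:
        by_contig.setdefault(iv.contig, []).append((iv, g))
    out: dict[int, str] = {}
    for i, c in enumerate(clusters):
        best: Optional[tuple[int, str]] = None
        for iv, g in by_contig.get(c.interval.contig, []):
            if c.interval.overlaps(iv):
                d = abs(c.interval.midpoint - g.tss)
                if best is None or (d, g.gene_id) < best:
                    best = (d, g.gene_id)
        if best is not None:
            out[i] = best[1]
    return out


def promoter_ctss_proximity(
    clusters: Sequence[CtssCluster],
    mapped_promoters: Sequence[GenomicInterval],
    thresholds: Sequence[int] = (100, 2000),
) -> dict[str, float]:
    """Fractions of clusters near a mapped promoter and of mapped
    promoters near a cluster, at each distance threshold (gap between
    closest ends; 0 for overlap)."""
    out: dict[str, float] = {}
    prom_index = FeatureIndex(mapped_promoters) if mapped_promoters else None
    clus_index = (
        FeatureIndex([c.interval for c in clusters]) if clusters else None
    )
    for d in thresholds:
        if clusters:
            n = sum(
                1
                for c in clusters
                if prom_index is not None
                and closest_feature(c.interval, prom_index, d) is not None
            )
            out[f"clusters_near_promoter_{d}"] = n / len(clusters)
        else:
            out[f"clusters_near_promoter_{d}"] = 0.0
        if mapped_promoters:
            n = sum(
                1
                for iv in mapped_promoters
                if clus_index is not None
                and closest_feature(iv, clus_index, d) is not None
            )
            out[f"promoters_near_cluster_{d}"] = n / len(mapped_promoters)
        else:
            out[f"promoters_near_cluster_{d}"] = 0.0
    return out


def multimapped_repeat_overlap(
    tags: Sequence[CageTag],
    genome: GenomeSequence,
    repeat_intervals: Optional[dict[str, list[tuple[int, int]]]] = None,
) -> int:
    """Count multimapped tags with at least one candidate placement
    overlapping a repeat interval (defaults to the genome mask).

    Multimapped tags carry no committed placement, so their candidate
    hits are recomputed here.
    """
    repeats = repeat_intervals if repeat_intervals is not None else genome.mask
    index = FeatureIndex(
        GenomicInterval(c, s, e)
        for c, ivs in repeats.items()
        for s, e in ivs
    )
    n = 0
    for tag in tags:
        if tag.map_class != "multimapped":
            continue
        for h in find_tag_hits(tag.sequence, genome):
            if closest_feature(h.interval, index, 0) is not None:
                n += 1
                break
    return n


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def run_cage_pipeline(
    reads: Iterable[tuple[str, str]] | str | Path,
    genome: GenomeSequence,
    adapter_3p: str,
    prefix_5p_len: int,
    scheme: Optional[ScoringScheme] = None,
) -> dict:
    """Reads -> trimmed tags -> placements -> extended CTSS clusters.

    Returns a dict with tags, clusters before/after singleton removal,
    singleton unique-tag intervals (kept for the evidence integration)
    and stage statistics.
    """
    tags, trim_stats = trim_reads(reads, adapter_3p, prefix_5p_len)
    map_stats = map_tags(tags, genome, scheme)
    extended: list[tuple[str, GenomicInterval]] = []
    for t in tags:
        if t.map_class in ("unique", "rescued") and t.placement is not None:
            extended.append(
                (
                    t.read_id,
                    extend_to_promoter_length(
                        t.placement, genome.length(t.placement.contig)
                    ),
                )
            )
    clusters_all = cluster_ctss(extended)
    clusters, n_singletons = remove_singletons(clusters_all)
    singleton_intervals = [
        c.interval for c in clusters_all if c.tag_count == 1
    ]
    return {
        "tags": tags,
        "clusters_all": clusters_all,
        "clusters": clusters,
        "singleton_intervals": singleton_intervals,
        "stats": {
            **trim_stats,
            **map_stats,
            "n_clusters": len(clusters_all),
            "n_singleton_clusters": n_singletons,
            "n_clusters_kept": len(clusters),
        },
    }
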