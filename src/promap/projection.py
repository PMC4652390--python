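"""Projection of source promoter windows onto a target genome.

The projection runs in three stages, mirroring the comparative mapping
procedure the package implements:

1. *Orthology pass* — promoters whose gene has known target orthologs
   are aligned only against the 2101-bp upstream windows of those
   orthologs; any qualifying hit reports the promoter as mapped.
2. *Genome-wide pass 1* — remaining promoters are aligned to the
   repeat-masked target genome with the permissive scheme; uniquely
   mapped promoters are reported, multimapped ones go through rescue.
3. *Genome-wide pass 2* — promoters still unmapped are re-aligned with
   the strict scheme (penalty -3, gap open 3, extend 3); rescue applies
   in the same way.

Multimapper rescue: the top hit is accepted when the second-best/top
bit-score ratio is below 0.95; failing that, a hit is accepted when it
is the only one on a chromosome and every other hit lies on an unplaced
scaffold. Everything else stays multimapped and is not reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

from .aligner import (
    AlignmentHit,
    ScoringScheme,
    find_hits,
    merge_close_hits,
)
from .core import (
    GeneModel,
    GenomeSequence,
    GenomicInterval,
    OrthologTable,
    PromoterRecord,
)

logger = logging.getLogger("promap")

RATIO_THRESHOLD = 0.95
PROMOTER_WINDOW_UP = 400
PROMOTER_WINDOW_DOWN = 100
ORTHOLOG_WINDOW_UP = 2000
ORTHOLOG_WINDOW_DOWN = 100
MIN_CLIPPED_WINDOW = 250

REPORTED_STATUSES = frozenset(
    {"ortholog_mapped", "unique", "rescued_ratio", "rescued_scaffold"}
)
NOT_REPORTED_STATUSES = frozenset({"multimapped", "unmapped"})


@dataclass
class MappingResult:
    """Final disposition of one promoter on one target genome."""

    promoter_id: str
    status: str
    chosen_hit: Optional[AlignmentHit] = None
    n_hits: int = 0

    def __post_init__(self) -> None:
        if (self.status in REPORTED_STATUSES) != (self.chosen_hit is not None):
            raise ValueError(
                f"{self.promoter_id}: status {self.status} inconsistent "
                "with chosen_hit"
            )

    @property
    def reported(self) -> bool:
        return self.chosen_hit is not None

    @property
    def midpoint(self) -> Optional[int]:
        """0-based centre of the chosen interval (start + length // 2)."""
        if self.chosen_hit is None:
            return None
        return self.chosen_hit.interval.midpoint


# ---------------------------------------------------------------------------
# window construction
# ---------------------------------------------------------------------------

def build_promoter_window(
    tss: int,
    strand: str,
    contig: str,
    contig_length: Optional[int] = None,
) -> tuple[GenomicInterval, bool]:
    """501-bp query window: 400 bp upstream + TSS base + 100 bp downstream.

    Returns (window, edge_truncated). A window clipped below 250 bp is
    flagged ``edge_truncated`` and excluded from projection by the caller.
    """
    if strand == "+":
        s, e = tss - PROMOTER_WINDOW_UP, tss + PROMOTER_WINDOW_DOWN + 1
    elif strand == "-":
        s, e = tss - PROMOTER_WINDOW_DOWN, tss + PROMOTER_WINDOW_UP + 1
    else:
        raise ValueError("promoter windows need a +/- strand")
    s_clip = max(0, s)
    e_clip = e if contig_length is None else min(e, contig_length)
    iv = GenomicInterval(contig, s_clip, e_clip, strand)
    truncated = iv.length < MIN_CLIPPED_WINDOW if (s_clip, e_clip) != (s, e) \
        else False
    return iv, truncated


def build_ortholog_window(
    gene: GeneModel, contig_length: Optional[int] = None
) -> GenomicInterval:
    """2101-bp window: 2 kb upstream + 5'-end base + 100 bp downstream,
    clipped to the contig."""
    tss = gene.tss
    if gene.interval.strand == "+":
        s, e = tss - ORTHOLOG_WINDOW_UP, tss + ORTHOLOG_WINDOW_DOWN + 1
    else:
        s, e = tss - ORTHOLOG_WINDOW_DOWN, tss + ORTHOLOG_WINDOW_UP + 1
    s = max(0, s)
    if contig_length is not None:
        e = min(e, contig_length)
    return GenomicInterval(gene.interval.contig, s, e, gene.interval.strand)


# ---------------------------------------------------------------------------
# rescue
# ---------------------------------------------------------------------------

def rescue_multimapped(
    hits: Sequence[AlignmentHit],
    genome: GenomeSequence,
    ratio_threshold: float = RATIO_THRESHOLD,
    scaffold_max_hits: Optional[int] = None,
) -> tuple[Optional[AlignmentHit], str]:
    """Resolve a multi-hit promoter.

    ``hits`` must be sorted by bit-score descending. Returns
    (chosen_hit, status): ``rescued_ratio`` when s2/s1 < threshold,
    ``rescued_scaffold`` when exactly one hit lies on a chromosome and
    all others on unplaced scaffolds, else (None, ``multimapped``).
    ``scaffold_max_hits`` optionally restricts the scaffold clause to
    hit lists of at most that size (the narrowest reading applies it
    only to two-hit cases).
    """
    if len(hits) < 2:
        raise ValueError("rescue_multimapped needs >= 2 hits")
    s1, s2 = hits[0].bit_score, hits[1].bit_score
    if s1 > 0 and s2 / s1 < ratio_threshold:
        return hits[0], "rescued_ratio"
    if scaffold_max_hits is None or len(hits) <= scaffold_max_hits:
        on_chrom = [h for h in hits if not genome.is_scaffold(h.interval.contig)]
        if len(on_chrom) == 1:
            return on_chrom[0], "rescued_scaffold"
    return None, "multimapped"


def _resolve_hits(
    promoter_id: str,
    hits: list[AlignmentHit],
    genome: GenomeSequence,
    ratio_threshold: float,
    scaffold_max_hits: Optional[int],
) -> MappingResult:
    if not hits:
        return MappingResult(promoter_id, "unmapped", None, 0)
    if len(hits) == 1:
        return MappingResult(promoter_id, "unique", hits[0], 1)
    chosen, status = rescue_multimapped(
        hits, genome, ratio_threshold, scaffold_max_hits
    )
    return MappingResult(promoter_id, status, chosen, len(hits))


# ---------------------------------------------------------------------------
# orthology pass
# ---------------------------------------------------------------------------

def _ortholog_window_genome(
    orthologs: OrthologTable,
    target_genes: Sequence[GeneModel],
    genome: GenomeSequence,
) -> tuple[GenomeSequence, dict[str, tuple[str, int]]]:
    """Mini-genome of all ortholog upstream windows (one contig per
    target gene), plus the map back to real coordinates."""
    by_id = {g.gene_id: g for g in target_genes}
    wanted = sorted({t for _, t in orthologs.pairs if t in by_id})
    mini = GenomeSequence()
    offsets: dict[str, tuple[str, int]] = {}
    for gid in wanted:
        g = by_id[gid]
        win = build_ortholog_window(g, genome.length(g.interval.contig))
        mini.add_contig(gid, genome.fetch(win), "chromosome")
        offsets[gid] = (g.interval.contig, win.start)
    return mini, offsets


def map_via_orthology(
    promoter: PromoterRecord,
    query: str,
    orthologs: OrthologTable,
    window_genome: GenomeSequence,
    window_offsets: dict[str, tuple[str, int]],
    scheme: ScoringScheme,
) -> Optional[MappingResult]:
    """Align the promoter query against its orthologs' upstream windows.

    Any qualifying hit reports the promoter as ``ortholog_mapped`` with
    the best-bit-score hit (ties broken by gene_id order); returns None
    (pass-through to the genome-wide stage) when the promoter has no
    ortholog or no window hit.
    """
    if promoter.gene_id is None:
        return None
    targets = [
        t for t in orthologs.targets_of(promoter.gene_id)
        if t in window_offsets
    ]
    if not targets:
        return None
    allowed = set(targets)
    hits = [
        h
        for h in find_hits(
            query, window_genome, scheme, use_mask=False,
            query_id=promoter.promoter_id,
        )
        if h.interval.contig in allowed
    ]
    if not hits:
        return None
    # bit-score desc, then gene_id order — find_hits already sorts by
    # (bit desc, contig asc, start), and contigs here are gene ids
    best = hits[0]
    contig, off = window_offsets[best.interval.contig]
    real = AlignmentHit(
        query_id=best.query_id,
        interval=GenomicInterval(
            contig,
            best.interval.start + off,
            best.interval.end + off,
            best.interval.strand,
        ),
        raw_score=best.raw_score,
        bit_score=best.bit_score,
        identity_pct=best.identity_pct,
        evalue=best.evalue,
    )
    return MappingResult(promoter.promoter_id, "ortholog_mapped", real, len(hits))


# ---------------------------------------------------------------------------
# full projection
# ---------------------------------------------------------------------------

def project_promoters(
    promoters: Sequence[PromoterRecord],
    source_genome: GenomeSequence,
    target_genome: GenomeSequence,
    orthologs: OrthologTable,
    target_genes: Sequence[GeneModel],
    scheme_pass1: Optional[ScoringScheme] = None,
    scheme_pass2: Optional[ScoringScheme] = None,
    ratio_threshold: float = RATIO_THRESHOLD,
    scaffold_max_hits: Optional[int] = None,
) -> list[MappingResult]:
    """Project every promoter; returns one MappingResult per promoter.

    Stage order: orthology pass, genome-wide pass 1 (repeat-masked) with
    rescue, genome-wide pass 2 on still-unmapped promoters with rescue.
    Promoters flagged edge_truncated are excluded (status ``unmapped``
    with zero hits, logged).
    """
    scheme_pass1 = scheme_pass1 or ScoringScheme.pass1()
    scheme_pass2 = scheme_pass2 or ScoringScheme.pass2()
    window_genome, window_offsets = _ortholog_window_genome(
        orthologs, target_genes, target_genome
    )
    results: list[MappingResult] = []
    n_edge = 0
    for p in promoters:
        if p.edge_truncated:
            n_edge += 1
            results.append(MappingResult(p.promoter_id, "unmapped", None, 0))
            continue
        query = source_genome.fetch(p.window)
        res = None
        if window_offsets:
            res = map_via_orthology(
                p, query, orthologs, window_genome, window_offsets,
                scheme_pass1,
            )
        if res is None:
            hits = merge_close_hits(
                find_hits(
                    query, target_genome, scheme_pass1, use_mask=True,
                    query_id=p.promoter_id,
                )
            )
            res = _resolve_hits(
                p.promoter_id, hits, target_genome, ratio_threshold,
                scaffold_max_hits,
            )
            if res.status == "unmapped":
                hits2 = merge_close_hits(
                    find_hits(
                        query, target_genome, scheme_pass2, use_mask=True,
                        query_id=p.promoter_id,
                    )
                )
                if hits2:
                    res = _resolve_hits(
                        p.promoter_id, hits2, target_genome,
                        ratio_threshold, scaffold_max_hits,
                    )
        results.append(res)
    counts: dict[str, int] = {}
    for r in results:
        counts[r.status] = counts.get(r.status, 0) + 1
    logger.info(
        "projection: %d promoters (%d edge-truncated): %s",
        len(results), n_edge,
        ", ".join(f"{k}={v}" for k, v in sorted(counts.items())),
    )
    return results


def within_upstream_of_ortholog(
    result: MappingResult,
    ortholog_gene: GeneModel,
    span: int = 20_000,
) -> bool:
    """True when the chosen interval overlaps the strand-aware
    ``span``-bp upstream window (TSS included) of the ortholog."""
    if result.chosen_hit is None:
        raise ValueError("result must be reported-mapped")
    iv = result.chosen_hit.interval
    g = ortholog_gene.interval
    if iv.contig != g.contig:
        return False
    tss = ortholog_gene.tss
    if g.strand == "+":
        s, e = max(0, tss - span), tss + 1
    else:
        s, e = tss, tss + span + 1
    return iv.start < e and s < iv.end


def summarize_statuses(results: Sequence[MappingResult]) -> dict[str, int]:
    out: dict[str, int] = {}
    for r in results:
        out[r.status] = out.get(r.status, 0) + 1
    out["reported"] = sum(1 for r in results if r.reported)
    out["not_reported"] = len(results) - out["reported"]
    out["total"] = len(results)
    return out
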