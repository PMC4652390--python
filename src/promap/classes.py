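"""Two-target classification of projected promoters and gene rollups.

Combines projections of one promoter set onto two target genomes into
the four-way call (target1-specific / target2-specific / both /
not-reported), per-annotation-class summaries, and the non-redundant
gene-union arithmetic used to count protein-coding genes with at least
one projected promoter.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .core import PromoterRecord
from .projection import MappingResult

CALLS = ("target1_specific", "target2_specific", "both", "not_reported")


@dataclass(frozen=True)
class CrossSpeciesCall:
    promoter_id: str
    anno_class: str
    call: str


def _round_half_up_pct(numerator: int, denominator: int) -> int:
    """Whole-number percent, round half up (table presentation rule)."""
    if denominator == 0:
        return 0
    return int((200 * numerator + denominator) // (2 * denominator))


def classify(
    results1: Sequence[MappingResult],
    results2: Sequence[MappingResult],
    promoters: Sequence[PromoterRecord],
) -> tuple[list[CrossSpeciesCall], pd.DataFrame]:
    """Partition promoters by where they were reported mapped.

    ``not_reported`` covers promoters reported in neither target
    (including multimapped ones in either). Raises when the two result
    sets do not cover the same promoter universe.

    Returns the per-promoter calls and a summary frame with one row per
    annotation class plus a Total row: counts, whole-percent shares and
    distinct associated gene counts for the species-specific columns.
    """
    r1 = {r.promoter_id: r for r in results1}
    r2 = {r.promoter_id: r for r in results2}
    ids = {p.promoter_id for p in promoters}
    if set(r1) != ids or set(r2) != ids:
        missing = (ids ^ set(r1)) | (ids ^ set(r2))
        raise ValueError(
            "result sets must cover the same promoter universe; "
            f"mismatched ids e.g. {sorted(missing)[:5]}"
        )
    calls: list[CrossSpeciesCall] = []
    by_class: dict[str, dict[str, list[PromoterRecord]]] = {}
    for p in promoters:
        in1 = r1[p.promoter_id].reported
        in2 = r2[p.promoter_id].reported
        if in1 and in2:
            call = "both"
        elif in1:
            call = "target1_specific"
        elif in2:
            call = "target2_specific"
        else:
            call = "not_reported"
        calls.append(CrossSpeciesCall(p.promoter_id, p.anno_class, call))
        by_class.setdefault(p.anno_class, {c: [] for c in CALLS})[call].append(p)

    rows = []
    class_order = [c for c in ("c11", "c10", "c00") if c in by_class]
    for cls in class_order + ["Total"]:
        if cls == "Total":
            cell = {
                c: [p for v in by_class.values() for p in v[c]] for c in CALLS
            }
        else:
            cell = by_class[cls]
        total = sum(len(v) for v in cell.values())
        row: dict[str, object] = {"anno_class": cls, "total_promoters": total}
        for c in CALLS:
            row[f"n_{c}"] = len(cell[c])
            row[f"pct_{c}"] = _round_half_up_pct(len(cell[c]), total)
        for c in ("target1_specific", "target2_specific"):
            row[f"genes_{c}"] = len(
                {p.gene_id for p in cell[c] if p.gene_id is not None}
            )
        row["total_genes"] = len(
            {p.gene_id for v in cell.values() for p in v if p.gene_id}
        )
        rows.append(row)
    return calls, pd.DataFrame(rows)


def gene_rollup_unmapped(
    results: Sequence[MappingResult],
    promoters: Sequence[PromoterRecord],
) -> tuple[set[str], set[str]]:
    """Gene sets by unmapped TSS: ``genes_tss`` = genes with at least
    one unmapped promoter, ``genes_none`` = genes whose promoters are
    all unmapped. Only promoters with a gene association count."""
    status = {r.promoter_id: r.status for r in results}
    per_gene: dict[str, list[str]] = {}
    for p in promoters:
        if p.gene_id is None:
            continue
        per_gene.setdefault(p.gene_id, []).append(status[p.promoter_id])
    genes_tss = {
        g for g, sts in per_gene.items() if any(s == "unmapped" for s in sts)
    }
    genes_none = {
        g for g, sts in per_gene.items() if all(s == "unmapped" for s in sts)
    }
    return genes_tss, genes_none


def nonredundant_gene_union(
    source_ids_mapped: int,
    source_with_target2_ortholog: int,
    target2_extra_ids: int,
) -> int:
    """Non-redundant gene count from component counts.

    Source-species gene IDs with a mapped promoter are converted to
    their second-species ortholog IDs where one exists
    (``source_with_target2_ortholog`` of them); adding the
    ``target2_extra_ids`` found only by the second species' promoters
    gives the ortholog-space union, and the source IDs without any
    ortholog are appended unconverted:

    ``total = (source_with_target2_ortholog + target2_extra_ids)
    + (source_ids_mapped - source_with_target2_ortholog)``
    """
    if min(source_ids_mapped, source_with_target2_ortholog,
           target2_extra_ids) < 0:
        raise ValueError("component counts must be non-negative")
    if source_with_target2_ortholog > source_ids_mapped:
        raise ValueError(
            "orthologous subset cannot exceed the mapped-ID count"
        )
    return (
        source_with_target2_ortholog
        + target2_extra_ids
        + (source_ids_mapped - source_with_target2_ortholog)
    )


def nonredundant_gene_union_sets(
    source_ids_mapped: set[str],
    source_to_target2: Mapping[str, str],
    target2_ids_mapped: set[str],
) -> int:
    """Set-based form of :func:`nonredundant_gene_union`: converts the
    mapped source IDs through the ortholog map, unions with the second
    species' mapped IDs, and appends the unconvertible source IDs."""
    converted = {
        source_to_target2[s]
        for s in source_ids_mapped
        if s in source_to_target2
    }
    unconverted = {
        s for s in source_ids_mapped if s not in source_to_target2
    }
    return len(converted | target2_ids_mapped) + len(unconverted)


def at_least_one_mapped_tss(
    promoters: Sequence[PromoterRecord],
    results: Sequence[MappingResult],
    gene_universe: Optional[Iterable[str]] = None,
) -> tuple[set[str], float]:
    """Genes with at least one reported promoter, and their fraction of
    the gene universe (defaults to all genes with an associated
    promoter). A gene counts once however many promoters map."""
    reported = {r.promoter_id for r in results if r.reported}
    genes = {
        p.gene_id
        for p in promoters
        if p.gene_id is not None and p.promoter_id in reported
    }
    if gene_universe is None:
        universe = {p.gene_id for p in promoters if p.gene_id is not None}
    else:
        universe = set(gene_universe)
    frac = len(genes) / len(universe) if universe else 0.0
    return genes, frac
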