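"""End-to-end orchestration, summary tables and worked-example arithmetic.

``run_all`` drives simulate -> project (two targets) -> classify ->
CAGE pipeline -> RNA-Seq evidence -> integration from one
:class:`RunConfig`, writing machine-readable stage summaries and
BED/TSV artefacts into a run directory. Re-running with the same config
and seed is bit-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml

from . import cage as cage_mod
from . import classes as classes_mod
from . import rnaseq as rnaseq_mod
from .core import (
    AlignedFragment,
    GenomicInterval,
    PromoterRecord,
)
from .projection import MappingResult, project_promoters, summarize_statuses
from .simdata import (
    SimConfig,
    simulate_cage_fastq,
    simulate_genome_pair,
    simulate_rnaseq_fragments,
    write_sim_result,
)

logger = logging.getLogger("promap")


def percent(numerator: int, denominator: int) -> int:
    """Whole-number percent, round half up — the presentation rule used
    in all summary tables."""
    if denominator == 0:
        return 0
    return int((200 * numerator + denominator) // (2 * denominator))


@dataclass
class RunConfig:
    """Single source of truth for thresholds; defaults are the study
    values (0.95 score ratio, 20-bp minimum tag, 11-bp trim floor,
    100 bp / 2 kb proximity, >= 11 reads heatmap filter, 1 FPKM in the
    seven midpoint windows)."""

    seed: int = 0
    sim: SimConfig = field(default_factory=SimConfig)
    ratio_threshold: float = 0.95
    scaffold_max_hits: Optional[int] = None
    min_tag_length: int = 20
    trim_floor: int = 11
    proximity_thresholds: tuple[int, int] = (100, 2000)
    heatmap_min_reads: int = 11
    evidence_fpkm_min: float = 1.0
    midpoint_window_offset: int = 0

    def __post_init__(self) -> None:
        if self.sim.seed != self.seed:
            self.sim = dataclasses.replace(self.sim, seed=self.seed)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        sim = SimConfig(**data.pop("sim", {}))
        cfg = cls(sim=sim, **data)
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


# ---------------------------------------------------------------------------
# small readers/writers for pipeline artefacts
# ---------------------------------------------------------------------------

def write_promoters_bed(
    promoters: Sequence[PromoterRecord], path: str | Path
) -> None:
    """BED6+3: window, promoter id, strand, gene_id, ortholog flag, class."""
    with open(path, "w") as fh:
        for p in promoters:
            w = p.window
            fh.write(
                f"{w.contig}\t{w.start}\t{w.end}\t{p.promoter_id}\t0"
                f"\t{p.strand}\t{p.gene_id or '.'}"
                f"\t{int(p.has_target_ortholog)}\t{p.anno_class}\n"
            )


def read_promoters_bed(path: str | Path) -> list[PromoterRecord]:
    promoters = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            window = GenomicInterval(f[0], int(f[1]), int(f[2]), f[5])
            strand = f[5]
            tss = (
                window.start + 400 if strand == "+" else window.end - 1 - 400
            )
            promoters.append(
                PromoterRecord(
                    promoter_id=f[3],
                    source_contig=f[0],
                    tss=tss,
                    strand=strand,
                    window=window,
                    gene_id=None if f[6] == "." else f[6],
                    has_target_ortholog=bool(int(f[7])),
                )
            )
    return promoters


def write_mappings_bed(
    results: Sequence[MappingResult], path: str | Path
) -> None:
    """BED6 + status + bit-score for reported mappings; not-reported
    promoters appear with a '.' placement for auditability."""
    with open(path, "w") as fh:
        for r in sorted(results, key=lambda x: x.promoter_id):
            if r.chosen_hit is not None:
                iv = r.chosen_hit.interval
                fh.write(
                    f"{iv.contig}\t{iv.start}\t{iv.end}\t{r.promoter_id}"
                    f"\t0\t{iv.strand}\t{r.status}\t{r.chosen_hit.bit_score:.2f}\n"
                )
            else:
                fh.write(
                    f".\t0\t1\t{r.promoter_id}\t0\t.\t{r.status}\t0\n"
                )


def write_fragments_bed(
    fragments: Sequence[AlignedFragment], path: str | Path
) -> None:
    """BED6+1 with the multimap flag in column 7."""
    with open(path, "w") as fh:
        for f in fragments:
            iv = f.interval
            fh.write(
                f"{iv.contig}\t{iv.start}\t{iv.end}\t{f.read_id}\t0"
                f"\t{iv.strand}\t{int(f.multimapped)}\n"
            )


def read_fragments_bed(path: str | Path) -> list[AlignedFragment]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            out.append(
                AlignedFragment(
                    GenomicInterval(f[0], int(f[1]), int(f[2]), f[5]),
                    f[3],
                    bool(int(f[6])) if len(f) > 6 else False,
                )
            )
    return out


# ---------------------------------------------------------------------------
# summary table
# ---------------------------------------------------------------------------

def summarize_mapping_table(summary: pd.DataFrame, path: str | Path) -> None:
    """Write the class-by-call summary with bracketed whole percents."""
    cols = [
        "anno_class",
        "n_target1_specific", "pct_target1_specific", "genes_target1_specific",
        "n_target2_specific", "pct_target2_specific", "genes_target2_specific",
        "n_both", "pct_both",
        "n_not_reported", "pct_not_reported",
        "total_promoters", "total_genes",
    ]
    df = summary[cols].copy()
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for _, row in df.iterrows():
            cells = []
            for c in cols:
                v = row[c]
                cells.append(
                    f"[{v}%]" if c.startswith("pct_") else str(v)
                )
            fh.write("\t".join(cells) + "\n")


def _mapped_orientation(source_strand: str, hit_strand: str) -> str:
    return "+" if source_strand == hit_strand else "-"


# ---------------------------------------------------------------------------
# run-all
# ---------------------------------------------------------------------------

def run_all(config: RunConfig, out_dir: str | Path) -> dict:
    """Execute the full pipeline on simulated inputs.

    Stages: simulate -> project onto both targets -> classify -> CAGE
    (trim, map, rescue, cluster) -> RNA-Seq (FPKM, coverage, evidence)
    -> integrate. Every stage appends a JSON summary to ``stages.jsonl``
    and the per-stage artefacts are written as BED/TSV. Returns the
    collected summary dict.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summaries: dict[str, dict] = {}

    def _stage(name: str, payload: dict) -> None:
        summaries[name] = payload
        logger.info("stage %s done", name)

    # --- simulate
    sim = simulate_genome_pair(config.sim)
    write_sim_result(sim, out / "sim")
    _stage("simulate", {
        "n_promoters": len(sim.source_promoters),
        "n_genes": len(sim.source_genes),
        "source_bp": sim.source_genome.total_length,
        "target_bp": sim.target_genome.total_length,
    })

    # --- project
    results1 = project_promoters(
        sim.source_promoters, sim.source_genome, sim.target_genome,
        sim.orthologs, sim.target_genes,
        ratio_threshold=config.ratio_threshold,
        scaffold_max_hits=config.scaffold_max_hits,
    )
    write_mappings_bed(results1, out / "mappings_target1.bed")
    _stage("project_target1", summarize_statuses(results1))
    if sim.target2_genome is None:
        raise ValueError(
            "run_all needs a second target (set sim.target2_divergence); "
            "classification is defined over two targets"
        )
    results2 = project_promoters(
        sim.source_promoters, sim.source_genome, sim.target2_genome,
        sim.orthologs2, sim.target2_genes,
        ratio_threshold=config.ratio_threshold,
        scaffold_max_hits=config.scaffold_max_hits,
    )
    write_mappings_bed(results2, out / "mappings_target2.bed")
    _stage("project_target2", summarize_statuses(results2))

    # --- classify
    calls, summary = classes_mod.classify(
        results1, results2, sim.source_promoters
    )
    summarize_mapping_table(summary, out / "class_summary.tsv")
    with open(out / "class_calls.tsv", "w") as fh:
        fh.write("promoter_id\tanno_class\tcall\n")
        for c in sorted(calls, key=lambda x: x.promoter_id):
            fh.write(f"{c.promoter_id}\t{c.anno_class}\t{c.call}\n")
    genes_tss, genes_none = classes_mod.gene_rollup_unmapped(
        results1, sim.source_promoters
    )
    mapped_genes, frac = classes_mod.at_least_one_mapped_tss(
        sim.source_promoters, results1
    )
    _stage("classify", {
        "calls": {
            c: sum(1 for x in calls if x.call == c)
            for c in classes_mod.CALLS
        },
        "genes_tss": len(genes_tss),
        "genes_none": len(genes_none),
        "genes_with_mapped_tss": len(mapped_genes),
        "genes_with_mapped_tss_pct": percent(
            len(mapped_genes),
            len({p.gene_id for p in sim.source_promoters if p.gene_id}),
        ),
    })

    # --- CAGE
    reads = simulate_cage_fastq(
        sim.truth, sim.target_genome, config.sim, out / "cage_reads.fastq"
    )
    cage_out = cage_mod.run_cage_pipeline(
        reads, sim.target_genome,
        adapter_3p=config.sim.adapter_3p,
        prefix_5p_len=len(config.sim.prefix_5p),
    )
    with open(out / "ctss_clusters.bed", "w") as fh:
        for c in sorted(
            cage_out["clusters"],
            key=lambda x: (x.interval.contig, x.interval.start),
        ):
            iv = c.interval
            fh.write(
                f"{iv.contig}\t{iv.start}\t{iv.end}\tctss\t{c.tag_count}"
                f"\t{iv.strand}\n"
            )
    _stage("cage", dict(cage_out["stats"]))

    # --- mapped-promoter extended intervals (same 501-bp extension)
    mapped_extended: dict[str, GenomicInterval] = {}
    midpoints: list[tuple[str, str, int, str]] = []
    by_id = {p.promoter_id: p for p in sim.source_promoters}
    for r in results1:
        if r.chosen_hit is None:
            continue
        iv = r.chosen_hit.interval
        orient = _mapped_orientation(by_id[r.promoter_id].strand, iv.strand)
        oriented = GenomicInterval(iv.contig, iv.start, iv.end, orient)
        # gapped alignments can exceed 501 bp on the target; extension
        # only applies to shorter placements
        if oriented.length < cage_mod.PROMOTER_LENGTH:
            oriented = cage_mod.extend_to_promoter_length(
                oriented, sim.target_genome.length(iv.contig)
            )
        mapped_extended[r.promoter_id] = oriented
        midpoints.append((r.promoter_id, iv.contig, iv.midpoint, orient))

    proximity = cage_mod.promoter_ctss_proximity(
        cage_out["clusters"],
        list(mapped_extended.values()),
        config.proximity_thresholds,
    )
    _stage("proximity", proximity)

    # --- RNA-Seq
    fragments, library_size = simulate_rnaseq_fragments(
        sim.truth, sim.target_genes, config.sim
    )
    write_fragments_bed(fragments, out / "rnaseq_fragments.bed")
    fpkm = rnaseq_mod.gene_counts_fpkm(
        fragments, sim.target_genes, max(library_size, 1)
    )
    fpkm.to_csv(out / "gene_fpkm.tsv", sep="\t")
    matrix = rnaseq_mod.window_coverage(
        midpoints, fragments, config.midpoint_window_offset
    )
    matrix.to_frame().to_csv(out / "coverage_matrix.tsv", sep="\t")
    heat = rnaseq_mod.heatmap_subset(matrix, config.heatmap_min_reads)
    rna_support = rnaseq_mod.evidence_calls_for_matrix(
        matrix, max(library_size, 1), config.evidence_fpkm_min
    )
    _stage("rnaseq", {
        "library_size": library_size,
        "genes_fpkm_gt0": int((fpkm["fpkm"] > 0).sum()),
        "genes_fpkm_gt1": int((fpkm["fpkm"] > 1).sum()),
        "heatmap_rows": len(heat),
        "rnaseq_supported": sum(rna_support.values()),
    })

    # --- integrate
    ev_calls, ev_summary = rnaseq_mod.integrate_evidence(
        mapped_extended,
        cage_out["clusters"],
        cage_out["singleton_intervals"],
        rna_support,
        max_dist=config.proximity_thresholds[-1],
    )
    with open(out / "evidence.tsv", "w") as fh:
        fh.write("promoter_id\tcage_support\trnaseq_support\tcategory\n")
        for c in ev_calls:
            fh.write(
                f"{c.promoter_id}\t{int(c.cage_support)}"
                f"\t{int(c.rnaseq_support)}\t{c.category}\n"
            )
    _stage("integrate", ev_summary)

    with open(out / "stages.jsonl", "w") as fh:
        for name in summaries:
            fh.write(
                json.dumps({"stage": name, **summaries[name]}, sort_keys=True)
                + "\n"
            )
    return summaries
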