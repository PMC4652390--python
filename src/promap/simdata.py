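"""Synthetic paired genomes, CAGE reads and RNA-Seq fragments.

The generator builds a "source" genome (the species whose CAGE-defined
promoters are projected) and a "target" genome, both descended from
shared ancestor segments. Each gene occupies one ancestor block (500 bp
of upstream promoter context plus the gene body); the source and target
copies of a block are mutated independently at the configured
substitution and indel rates, so a divergence knob ``d`` yields pairwise
identity of roughly ``(1-d)^2 + d^2/3`` between the two extant species.
Spacer sequence between blocks is drawn independently per genome and
carries no homology.

Ground truth (expected target interval and mapping status per promoter,
per-gene expression, tag-generating TSS positions) is recorded in a
:class:`TruthTable` so every downstream stage has a parameter-recovery
surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .core import (
    CHROMOSOME,
    UNPLACED_SCAFFOLD,
    AlignedFragment,
    GeneModel,
    GenomeSequence,
    GenomicInterval,
    OrthologTable,
    PromoterRecord,
    write_fasta,
    write_gene_models,
    write_ortholog_tsv,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: planted repeat motifs; insertions are recorded in the target mask the
#: way RepeatMasker output would be
REPEAT_MOTIFS = (
    "GGCCGGGCGCGGTGGCTCACGCCTGTAATCCCAGCACTTTGGGAGGCCGAGG",
    "TTTTTTTTTTTAGACGGAGTCTCGCTCTGTCGCCCAGGCTGGAGTGCAGTGG",
    "CATAAAATGGAATCGAATGGAATCATCATCGAATGGAATCGAATGGAATCAT",
)

DEFAULT_PREFIX_5P = "ACACAGCG"  # barcode + restriction-site stand-in, 8 bp
DEFAULT_ADAPTER_3P = "TCGTATGCCGTCTTCTGCTTG"


@dataclass
class SimConfig:
    seed: int = 0
    n_genes: int = 200
    #: (name, length, class) for the target genome; the source genome uses
    #: only the chromosome entries (it emulates a finished assembly)
    contig_layout: tuple[tuple[str, int, str], ...] = (
        ("chr1", 140_000, CHROMOSOME),
        ("chr2", 140_000, CHROMOSOME),
        ("GL000001", 15_000, UNPLACED_SCAFFOLD),
        ("GL000002", 15_000, UNPLACED_SCAFFOLD),
    )
    promoter_divergence: float = 0.05  # per-lineage substitution rate
    #: divergence of the second target lineage (the less conserved species
    #: in the two-target classification); None disables the second target
    target2_divergence: float | None = 0.15
    target2_ortholog_fraction: float = 0.6
    #: regulatory loss is more extensive in the second target lineage, so
    #: a larger fraction of promoter homologs is absent there
    target2_homolog_missing_fraction: float = 0.25
    indel_rate: float = 0.005  # per-base, per lineage
    repeat_insertion: tuple[float, tuple[int, int]] = (0.15, (50, 300))
    duplication_fraction: float = 0.05
    scaffold_copy_fraction: float = 0.5
    ortholog_fraction: float = 0.7
    homolog_missing_fraction: float = 0.05
    c00_fraction: float = 0.10  # extra gene-less promoters, rel. to n_genes
    broad_fraction: float = 0.4  # promoters with a broad TSS distribution
    broad_sigma: float = 25.0
    gene_length_range: tuple[int, int] = (300, 600)
    spacer_range: tuple[int, int] = (100, 300)
    upstream_homology: int = 500
    cage_depth: int = 50_000
    rnaseq_depth: int = 100_000
    cage_read_length: int = 36
    cage_insert_length: int = 25
    cage_error_rate: float = 0.01
    cage_unalignable_fraction: float = 0.05
    cage_short_fraction: float = 0.02
    prefix_5p: str = DEFAULT_PREFIX_5P
    adapter_3p: str = DEFAULT_ADAPTER_3P
    rnaseq_fragment_length: int = 80
    zero_expression_fraction: float = 0.10

    def __post_init__(self) -> None:
        for name in (
            "promoter_divergence", "indel_rate", "duplication_fraction",
            "scaffold_copy_fraction", "ortholog_fraction",
            "homolog_missing_fraction", "broad_fraction",
            "cage_error_rate", "cage_unalignable_fraction",
            "zero_expression_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if any(length <= 0 for _, length, _ in self.contig_layout):
            raise ValueError("contig lengths must be positive")


@dataclass
class PromoterTruth:
    promoter_id: str
    expected_interval: Optional[GenomicInterval]  # target coords, or None
    expected_status: str  # MappingResult status at nominal divergence
    duplicate_interval: Optional[GenomicInterval] = None
    gene_id: Optional[str] = None
    target_gene_id: Optional[str] = None


@dataclass
class GeneTruth:
    target_gene_id: str
    expression: float
    target_tss: int
    contig: str
    strand: str
    tss_shape: str  # sharp | broad
    duplicated: bool = False


@dataclass
class TruthTable:
    promoters: dict[str, PromoterTruth] = field(default_factory=dict)
    genes: dict[str, GeneTruth] = field(default_factory=dict)
    #: expectations for the second target genome, when simulated
    promoters2: dict[str, PromoterTruth] = field(default_factory=dict)


@dataclass
class SimResult:
    config: SimConfig
    source_genome: GenomeSequence
    source_promoters: list[PromoterRecord]
    source_genes: list[GeneModel]
    target_genome: GenomeSequence
    target_genes: list[GeneModel]
    orthologs: OrthologTable
    truth: TruthTable
    target2_genome: GenomeSequence | None = None
    target2_genes: list[GeneModel] = field(default_factory=list)
    orthologs2: OrthologTable = field(default_factory=OrthologTable)


# ---------------------------------------------------------------------------
# sequence helpers
# ---------------------------------------------------------------------------

def random_seq(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, n)].tobytes().decode()


def mutate(
    seq: str,
    sub_rate: float,
    indel_rate: float,
    rng: np.random.Generator,
) -> tuple[str, np.ndarray]:
    """Mutate one lineage's copy of an ancestor segment.

    Returns the mutated sequence and a coordinate map ``m`` of length
    ``len(seq) + 1`` with ``m[i]`` = offset in the mutated sequence of
    ancestor position ``i`` (monotone; ``m[len]`` = new length).
    """
    out: list[str] = []
    cmap = np.empty(len(seq) + 1, dtype=np.int64)
    subs = rng.random(len(seq)) < sub_rate
    indels = rng.random(len(seq)) < indel_rate
    ins_or_del = rng.random(len(seq)) < 0.5
    sub_choice = rng.integers(0, 3, len(seq))
    ins_base = rng.integers(0, 4, len(seq))
    alphabet = "ACGT"
    for i, base in enumerate(seq):
        cmap[i] = len(out)
        if indels[i]:
            if ins_or_del[i]:
                out.append(alphabet[ins_base[i]])
            else:
                continue  # deletion
        if subs[i]:
            others = alphabet.replace(base, "") if base in alphabet else "ACG"
            out.append(others[sub_choice[i] % len(others)])
        else:
            out.append(base)
    cmap[len(seq)] = len(out)
    return "".join(out), cmap


# ---------------------------------------------------------------------------
# genome pair
# ---------------------------------------------------------------------------

class _ContigBuilder:
    def __init__(self, name: str, capacity: int, contig_cls: str):
        self.name = name
        self.capacity = capacity
        self.contig_cls = contig_cls
        self.parts: list[str] = []
        self.length = 0
        self.mask: list[tuple[int, int]] = []

    def append(self, seq: str, mask_offsets: list[tuple[int, int]] = ()) -> int:
        """Append a segment; returns its start offset."""
        off = self.length
        self.parts.append(seq)
        self.length += len(seq)
        for s, e in mask_offsets:
            self.mask.append((off + s, off + e))
        return off

    def room(self, n: int) -> bool:
        return self.length + n <= self.capacity

    def finish(self, rng: np.random.Generator) -> tuple[str, list]:
        pad = self.capacity - self.length
        if pad > 0:
            self.parts.append(random_seq(rng, pad))
            self.length = self.capacity
        return "".join(self.parts), sorted(self.mask)


def simulate_genome_pair(config: SimConfig) -> SimResult:
    """Build the paired genomes, annotations and truth table.

    Deterministic for a given seed. When ``config.target2_divergence`` is
    set, a second (more diverged) target genome is built from the same
    ancestor blocks so projections onto two species can be classified.
    Raises if the contig layout cannot hold all gene blocks.
    """
    rng = np.random.default_rng([101, config.seed])
    U = config.upstream_homology

    src_builders = [
        _ContigBuilder(n, L, c)
        for n, L, c in config.contig_layout
        if c == CHROMOSOME
    ]
    tgt_builders = {
        n: _ContigBuilder(n, L, c) for n, L, c in config.contig_layout
    }
    tgt_chroms = [b for b in tgt_builders.values() if b.contig_cls == CHROMOSOME]
    tgt_scaffolds = [
        b for b in tgt_builders.values() if b.contig_cls == UNPLACED_SCAFFOLD
    ]
    if not src_builders:
        raise ValueError("contig_layout needs at least one chromosome")
    t2_enabled = config.target2_divergence is not None
    t2_builders = (
        {n: _ContigBuilder(n, L, c) for n, L, c in config.contig_layout}
        if t2_enabled
        else {}
    )
    t2_chroms = [b for b in t2_builders.values() if b.contig_cls == CHROMOSOME]

    n_c00 = int(round(config.c00_fraction * config.n_genes))
    promoters: list[PromoterRecord] = []
    source_genes: list[GeneModel] = []
    target_genes: list[GeneModel] = []
    target2_genes: list[GeneModel] = []
    orthologs = OrthologTable()
    orthologs2 = OrthologTable()
    truth = TruthTable()
    dup_queue: list[tuple[str, str, str]] = []  # (block_seq, promoter_id, kind)

    for idx in range(config.n_genes + n_c00):
        is_c00 = idx >= config.n_genes
        pid = f"p{idx:05d}"
        sgid = None if is_c00 else f"SRC_G{idx:04d}"
        tgid = None if is_c00 else f"TGT_G{idx:04d}"
        glen = (
            200
            if is_c00
            else int(rng.integers(*config.gene_length_range))
        )
        block_len = U + glen
        ancestor = random_seq(rng, block_len)
        strand = "+" if rng.random() < 0.5 else "-"

        has_homolog = rng.random() >= config.homolog_missing_fraction
        duplicated = has_homolog and rng.random() < config.duplication_fraction
        dup_on_scaffold = duplicated and (
            rng.random() < config.scaffold_copy_fraction
        )
        # duplicated loci bypass the ortholog table so projection exercises
        # the genome-wide multimapper path
        has_ortholog = (
            (not is_c00)
            and has_homolog
            and not duplicated
            and rng.random() < config.ortholog_fraction
        )
        has_homolog2 = t2_enabled and (
            rng.random() >= config.target2_homolog_missing_fraction
        )
        has_ortholog2 = (
            (not is_c00)
            and has_homolog2
            and rng.random() < config.target2_ortholog_fraction
        )

        src_seq, smap = mutate(
            ancestor, config.promoter_divergence, config.indel_rate, rng
        )
        # --- place on source
        sb = src_builders[idx % len(src_builders)]
        spacer = random_seq(rng, int(rng.integers(*config.spacer_range)))
        if not sb.room(len(spacer) + len(src_seq)):
            sb = next(
                (b for b in src_builders if b.room(len(spacer) + len(src_seq))),
                None,
            )
            if sb is None:
                raise ValueError("contig_layout too small for requested genes")
        sb.append(spacer)
        placed = src_seq if strand == "+" else _rc(src_seq)
        off_s = sb.append(placed)
        slen = len(src_seq)

        def s_pos(a: int) -> int:
            return (
                off_s + int(smap[a]) if strand == "+"
                else off_s + slen - int(smap[a])
            )

        if strand == "+":
            g_iv = GenomicInterval(sb.name, s_pos(U), s_pos(block_len), "+")
            tss_s = g_iv.start
        else:
            g_iv = GenomicInterval(sb.name, s_pos(block_len), s_pos(U), "-")
            tss_s = g_iv.end - 1
        if not is_c00:
            source_genes.append(GeneModel(sgid, g_iv, g_iv.length))

        win = _promoter_window(tss_s, strand, sb.name)
        promoters.append(
            PromoterRecord(
                promoter_id=pid,
                source_contig=sb.name,
                tss=tss_s,
                strand=strand,
                window=win,
                gene_id=sgid,
                # classification flag: ortholog in the second species
                has_target_ortholog=bool(sgid) and has_ortholog2,
            )
        )

        # --- place on target 1
        if not has_homolog:
            truth.promoters[pid] = PromoterTruth(
                pid, None, "unmapped", gene_id=sgid
            )
        else:
            tgt_seq, tmap = mutate(
                ancestor, config.promoter_divergence, config.indel_rate, rng
            )
            mask_offsets: list[tuple[int, int]] = []
            p_rep, (rmin, rmax) = config.repeat_insertion
            if rng.random() < p_rep:
                motif = REPEAT_MOTIFS[int(rng.integers(0, len(REPEAT_MOTIFS)))]
                rep_len = int(rng.integers(rmin, rmax + 1))
                motif = (motif * (rep_len // len(motif) + 1))[:rep_len]
                a_pos = int(rng.integers(U - 350, U + min(50, glen - 1)))
                t_at = int(tmap[a_pos])
                tgt_seq = tgt_seq[:t_at] + motif + tgt_seq[t_at:]
                tmap = tmap.copy()
                tmap[a_pos:] += rep_len  # bases at/after the insertion shift
                mask_offsets.append((t_at, t_at + rep_len))
            tlen = len(tgt_seq)
            placed_t = tgt_seq if strand == "+" else _rc(tgt_seq)
            if strand == "-":
                mask_offsets = [(tlen - e, tlen - s) for s, e in mask_offsets]
            tb = tgt_chroms[idx % len(tgt_chroms)]
            spacer_t = random_seq(rng, int(rng.integers(*config.spacer_range)))
            if not tb.room(len(spacer_t) + tlen):
                tb = next(
                    (b for b in tgt_chroms if b.room(len(spacer_t) + tlen)),
                    None,
                )
                if tb is None:
                    raise ValueError("contig_layout too small for target genes")
            tb.append(spacer_t)
            off_t = tb.append(placed_t, mask_offsets)

            def t_pos(a: int) -> int:
                return (
                    off_t + int(tmap[a]) if strand == "+"
                    else off_t + tlen - int(tmap[a])
                )

            a_lo, a_hi = _window_anchor(U)
            if strand == "+":
                tg_iv = GenomicInterval(tb.name, t_pos(U), t_pos(block_len), "+")
                tss_t = tg_iv.start
                exp_iv = GenomicInterval(tb.name, t_pos(a_lo), t_pos(a_hi), "+")
            else:
                tg_iv = GenomicInterval(tb.name, t_pos(block_len), t_pos(U), "-")
                tss_t = tg_iv.end - 1
                exp_iv = GenomicInterval(tb.name, t_pos(a_hi), t_pos(a_lo), "-")
            if not is_c00:
                target_genes.append(GeneModel(tgid, tg_iv, tg_iv.length))
                if has_ortholog:
                    orthologs.add(sgid, tgid)

            if duplicated:
                dup_queue.append(
                    (placed_t, pid, "scaffold" if dup_on_scaffold else "chrom")
                )
                status = "rescued_scaffold" if dup_on_scaffold else "multimapped"
            elif has_ortholog:
                status = "ortholog_mapped"
            else:
                status = "unique"
            truth.promoters[pid] = PromoterTruth(
                pid, exp_iv, status, None, gene_id=sgid, target_gene_id=tgid
            )
            if not is_c00:
                shape = (
                    "broad" if rng.random() < config.broad_fraction else "sharp"
                )
                expr = (
                    0.0
                    if rng.random() < config.zero_expression_fraction
                    else float(rng.lognormal(0.0, 1.0))
                )
                truth.genes[tgid] = GeneTruth(
                    tgid, expr, tss_t, tb.name, strand, shape,
                    duplicated=duplicated,
                )

        # --- place on target 2
        if t2_enabled:
            t2gid = None if is_c00 else f"T2_G{idx:04d}"
            if not has_homolog2:
                truth.promoters2[pid] = PromoterTruth(
                    pid, None, "unmapped", gene_id=sgid
                )
            else:
                t2_seq, t2map = mutate(
                    ancestor, config.target2_divergence, config.indel_rate, rng
                )
                t2len = len(t2_seq)
                placed_2 = t2_seq if strand == "+" else _rc(t2_seq)
                b2 = t2_chroms[idx % len(t2_chroms)]
                spacer_2 = random_seq(
                    rng, int(rng.integers(*config.spacer_range))
                )
                if not b2.room(len(spacer_2) + t2len):
                    b2 = next(
                        (b for b in t2_chroms if b.room(len(spacer_2) + t2len)),
                        None,
                    )
                    if b2 is None:
                        raise ValueError(
                            "contig_layout too small for second target"
                        )
                b2.append(spacer_2)
                off_2 = b2.append(placed_2)

                def t2_pos(a: int) -> int:
                    return (
                        off_2 + int(t2map[a]) if strand == "+"
                        else off_2 + t2len - int(t2map[a])
                    )

                a_lo, a_hi = _window_anchor(U)
                if strand == "+":
                    g2_iv = GenomicInterval(
                        b2.name, t2_pos(U), t2_pos(block_len), "+"
                    )
                    exp2 = GenomicInterval(
                        b2.name, t2_pos(a_lo), t2_pos(a_hi), "+"
                    )
                else:
                    g2_iv = GenomicInterval(
                        b2.name, t2_pos(block_len), t2_pos(U), "-"
                    )
                    exp2 = GenomicInterval(
                        b2.name, t2_pos(a_hi), t2_pos(a_lo), "-"
                    )
                if not is_c00:
                    target2_genes.append(GeneModel(t2gid, g2_iv, g2_iv.length))
                    if has_ortholog2:
                        orthologs2.add(sgid, t2gid)
                truth.promoters2[pid] = PromoterTruth(
                    pid,
                    exp2,
                    "ortholog_mapped" if has_ortholog2 else "unique",
                    gene_id=sgid,
                    target_gene_id=t2gid,
                )

    # --- duplicated verbatim copies (target 1 only)
    for block, pid, where in dup_queue:
        pool = (
            tgt_scaffolds if (where == "scaffold" and tgt_scaffolds)
            else tgt_chroms
        )
        placed_ok = False
        for b in pool + tgt_chroms:
            if b.room(len(block) + 50):
                b.append(random_seq(rng, 50))
                off = b.append(block)
                truth.promoters[pid].duplicate_interval = GenomicInterval(
                    b.name, off, off + len(block), "."
                )
                placed_ok = True
                break
        if not placed_ok:
            raise ValueError("contig_layout too small for duplicated copies")

    source_genome = GenomeSequence()
    for b in src_builders:
        seq, mask = b.finish(rng)
        source_genome.add_contig(b.name, seq, b.contig_cls, mask)
    target_genome = GenomeSequence()
    for b in tgt_builders.values():
        seq, mask = b.finish(rng)
        target_genome.add_contig(b.name, seq, b.contig_cls, mask)
    target2_genome = None
    if t2_enabled:
        target2_genome = GenomeSequence()
        for b in t2_builders.values():
            seq, mask = b.finish(rng)
            target2_genome.add_contig(b.name, seq, b.contig_cls, mask)

    return SimResult(
        config=config,
        source_genome=source_genome,
        source_promoters=promoters,
        source_genes=source_genes,
        target_genome=target_genome,
        target_genes=target_genes,
        orthologs=orthologs,
        truth=truth,
        target2_genome=target2_genome,
        target2_genes=target2_genes,
        orthologs2=orthologs2,
    )


def _rc(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def _promoter_window(tss: int, strand: str, contig: str) -> GenomicInterval:
    if strand == "+":
        return GenomicInterval(contig, tss - 400, tss + 101, strand)
    return GenomicInterval(contig, tss - 100, tss + 401, strand)


def _window_anchor(u: int) -> tuple[int, int]:
    """Ancestor coordinates of the promoter window around the TSS at
    block offset ``u`` (block-local, 5'->3' orientation)."""
    return u - 400, u + 101


# ---------------------------------------------------------------------------
# CAGE reads
# ---------------------------------------------------------------------------

def simulate_cage_fastq(
    truth: TruthTable,
    target_genome: GenomeSequence,
    config: SimConfig,
    path: Optional[str | Path] = None,
) -> list[tuple[str, str]]:
    """Simulate single-end CAGE reads from the target genome.

    Each read is 5'-prefix + insert + 3'-adapter-start, truncated to the
    configured read length; the insert's first base sits at the tag's
    5' position (the sampled TSS). Returns ``(read_id, sequence)`` pairs
    and optionally writes a FASTQ (constant quality).
    """
    rng = np.random.default_rng([202, config.seed])
    expressed = [
        g for g in truth.genes.values() if g.expression > 0
    ]
    reads: list[tuple[str, str]] = []
    if expressed and config.cage_depth > 0:
        weights = np.array([g.expression for g in expressed])
        weights = weights / weights.sum()
        picks = rng.choice(len(expressed), size=config.cage_depth, p=weights)
        kinds = rng.random(config.cage_depth)
        offsets = rng.normal(0.0, config.broad_sigma, config.cage_depth)
        for n, (gi, kind, off) in enumerate(zip(picks, kinds, offsets)):
            g = expressed[gi]
            rid = f"tag{n:07d}|{g.target_gene_id}"
            if kind < config.cage_unalignable_fraction:
                insert = random_seq(rng, config.cage_insert_length)
                rid += "|junk"
            elif kind < (
                config.cage_unalignable_fraction + config.cage_short_fraction
            ):
                short_len = int(rng.integers(10, 19))
                insert = random_seq(rng, short_len)
                rid += "|short"
            else:
                pos = g.target_tss
                if g.tss_shape == "broad":
                    shift = int(round(off))
                    pos = pos + shift if g.strand == "+" else pos - shift
                contig_seq = target_genome.contigs[g.contig]
                L = config.cage_insert_length
                if g.strand == "+":
                    s, e = pos, pos + L
                else:
                    s, e = pos - L + 1, pos + 1
                if s < 0 or e > len(contig_seq):
                    insert = random_seq(rng, L)
                    rid += "|edge"
                else:
                    insert = contig_seq[s:e]
                    if g.strand == "-":
                        insert = _rc(insert)
                    rid += f"|{g.contig}:{pos}:{g.strand}"
            read = (config.prefix_5p + insert + config.adapter_3p)[
                : config.cage_read_length
            ]
            arr = np.frombuffer(read.encode(), dtype=np.uint8).copy()
            errs = rng.random(len(arr)) < config.cage_error_rate
            if errs.any():
                repl = _BASES[rng.integers(0, 4, int(errs.sum()))]
                arr[errs] = repl
                read = arr.tobytes().decode()
            reads.append((rid, read))
    if path is not None:
        with open(path, "w") as fh:
            for rid, seq in reads:
                fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")
    return reads


# ---------------------------------------------------------------------------
# RNA-Seq fragments
# ---------------------------------------------------------------------------

def simulate_rnaseq_fragments(
    truth: TruthTable,
    genes: list[GeneModel],
    config: SimConfig,
) -> tuple[list[AlignedFragment], int]:
    """Place RNA-Seq fragments in target gene spans.

    Per-gene counts are multinomial with probability proportional to
    expression x exonic length; fragments are uniform within the gene
    span. Fragments in duplicated loci carry the multimapped flag.
    Returns (fragments, library_size).
    """
    rng = np.random.default_rng([303, config.seed])
    by_id = {g.gene_id: g for g in genes}
    gene_ids = [gid for gid in truth.genes if gid in by_id]
    if not gene_ids or config.rnaseq_depth <= 0:
        return [], 0
    w = np.array(
        [
            truth.genes[gid].expression * by_id[gid].exonic_length
            for gid in gene_ids
        ],
        dtype=float,
    )
    if w.sum() == 0:
        return [], 0
    counts = rng.multinomial(config.rnaseq_depth, w / w.sum())
    fragments: list[AlignedFragment] = []
    n = 0
    for gid, c in zip(gene_ids, counts):
        if c == 0:
            continue
        g = by_id[gid]
        flen = min(config.rnaseq_fragment_length, g.interval.length)
        hi = g.interval.end - flen
        starts = rng.integers(g.interval.start, hi + 1, c)
        multi = truth.genes[gid].duplicated
        for s in starts:
            fragments.append(
                AlignedFragment(
                    GenomicInterval(g.interval.contig, int(s), int(s) + flen),
                    read_id=f"frag{n:07d}|{gid}",
                    multimapped=multi,
                )
            )
            n += 1
    return fragments, len(fragments)


# ---------------------------------------------------------------------------
# evidence-integration scenario (independent planted support rates)
# ---------------------------------------------------------------------------

def simulate_evidence_scenario(
    n_promoters: int,
    p_cage: float,
    p_rna: float,
    seed: int = 0,
    library_size: int = 1_000_000,
):
    """Toy single-contig scenario with independent planted CAGE and
    RNA-Seq support, for recovery tests of the evidence integration.

    Returns (mapped_intervals, clusters_intervals, fragments,
    library_size, cage_flags, rna_flags). Promoters are spaced far apart
    so support never leaks between neighbours.
    """
    rng = np.random.default_rng([404, seed])
    spacing = 60_000
    mapped: dict[str, GenomicInterval] = {}
    clusters: list[GenomicInterval] = []
    fragments: list[AlignedFragment] = []
    cage_flags: dict[str, bool] = {}
    rna_flags: dict[str, bool] = {}
    for i in range(n_promoters):
        pid = f"ep{i:05d}"
        start = 30_000 + i * spacing
        iv = GenomicInterval("chrE", start, start + 501, "+")
        mapped[pid] = iv
        has_cage = bool(rng.random() < p_cage)
        has_rna = bool(rng.random() < p_rna)
        cage_flags[pid] = has_cage
        rna_flags[pid] = has_rna
        if has_cage:
            gap = int(rng.integers(0, 1500))
            clusters.append(
                GenomicInterval("chrE", iv.end + gap, iv.end + gap + 120, "+")
            )
        if has_rna:
            mid = iv.midpoint
            for _ in range(3):
                s = mid + int(rng.integers(-150, 350))
                fragments.append(
                    AlignedFragment(
                        GenomicInterval("chrE", s, s + 80), f"ef{i}", False
                    )
                )
    return mapped, clusters, fragments, library_size, cage_flags, rna_flags


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_sim_result(result: SimResult, out_dir: str | Path) -> None:
    """Write FASTA/BED/TSV artefacts plus the truth table."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta(result.source_genome, out / "source.fa")
    write_fasta(result.target_genome, out / "target.fa")
    write_gene_models(result.source_genes, out / "source_genes.bed")
    write_gene_models(result.target_genes, out / "target_genes.bed")
    write_ortholog_tsv(result.orthologs, out / "orthologs.tsv")
    if result.target2_genome is not None:
        write_fasta(result.target2_genome, out / "target2.fa")
        write_gene_models(result.target2_genes, out / "target2_genes.bed")
        write_ortholog_tsv(result.orthologs2, out / "orthologs2.tsv")
    with open(out / "source_promoters.bed", "w") as fh:
        for p in result.source_promoters:
            w = p.window
            fh.write(
                f"{w.contig}\t{w.start}\t{w.end}\t{p.promoter_id}\t0"
                f"\t{p.strand}\t{p.gene_id or '.'}"
                f"\t{int(p.has_target_ortholog)}\t{p.anno_class}\n"
            )
    with open(out / "truth_promoters.tsv", "w") as fh:
        fh.write(
            "promoter_id\texpected_status\tcontig\tstart\tend\tstrand\n"
        )
        for pid in sorted(result.truth.promoters):
            t = result.truth.promoters[pid]
            if t.expected_interval is None:
                fh.write(f"{pid}\t{t.expected_status}\t.\t-1\t-1\t.\n")
            else:
                iv = t.expected_interval
                fh.write(
                    f"{pid}\t{t.expected_status}\t{iv.contig}\t{iv.start}"
                    f"\t{iv.end}\t{iv.strand}\n"
                )
    with open(out / "truth_genes.tsv", "w") as fh:
        fh.write("gene_id\texpression\tcontig\ttss\tstrand\tshape\n")
        for gid in sorted(result.truth.genes):
            g = result.truth.genes[gid]
            fh.write(
                f"{gid}\t{g.expression:.6g}\t{g.contig}\t{g.target_tss}"
                f"\t{g.strand}\t{g.tss_shape}\n"
            )
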