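"""Shared coordinate types, genome containers and flat-file I/O.

Every stage of the pipeline speaks in terms of the types defined here:
0-based half-open :class:`GenomicInterval` coordinates internally, BED6
(0-based half-open) on disk, 1-based inclusive only in human-readable
report text.
"""

from __future__ import annotations

import bisect
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

from Bio import SeqIO

logger = logging.getLogger("promap")

#: contig names starting with one of these are classed as unplaced scaffolds
#: unless the caller overrides the rule (config key ``scaffold_prefixes``).
DEFAULT_SCAFFOLD_PREFIXES = ("GL", "JH", "scaffold", "AEMK")

VALID_BASES = frozenset("ACGTN")

CHROMOSOME = "chromosome"
UNPLACED_SCAFFOLD = "unplaced_scaffold"


class PromapError(Exception):
    """Base class for pipeline errors."""


class ParseError(PromapError):
    """Raised for malformed input files."""


# ---------------------------------------------------------------------------
# intervals
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class GenomicInterval:
    """0-based half-open interval ``[start, end)`` on a named contig."""

    contig: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.contig}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        """Midpoint base; for even lengths, ``start + length // 2``."""
        return self.start + self.length // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.contig == other.contig
            and self.start < other.end
            and other.start < self.end
        )

    def gap_to(self, other: "GenomicInterval") -> Optional[int]:
        """Gap in bp between closest ends; 0 if overlapping; None if on
        different contigs. Strand-agnostic."""
        if self.contig != other.contig:
            return None
        if self.overlaps(other):
            return 0
        if other.start >= self.end:
            return other.start - self.end
        return self.start - other.end

    def clip(self, contig_length: int) -> "GenomicInterval":
        """Clip to ``[0, contig_length)``; idempotent."""
        s = max(0, self.start)
        e = min(self.end, contig_length)
        if s == self.start and e == self.end:
            return self
        if s >= e:
            raise ValueError(
                f"interval {self.contig}:{self.start}-{self.end} lies "
                f"entirely outside contig of length {contig_length}"
            )
        return GenomicInterval(self.contig, s, e, self.strand)


# ---------------------------------------------------------------------------
# genome / annotation containers
# ---------------------------------------------------------------------------

@dataclass
class GenomeSequence:
    """A genome held in memory: upper-case sequence plus a repeat mask.

    ``contig_class`` distinguishes assembled chromosomes from unplaced
    scaffolds; the multimapper rescue rules treat scaffold placements as
    lower-confidence.
    """

    contigs: dict[str, str] = field(default_factory=dict)
    contig_class: dict[str, str] = field(default_factory=dict)
    mask: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    def add_contig(
        self,
        name: str,
        sequence: str,
        contig_cls: Optional[str] = None,
        mask_intervals: Optional[list[tuple[int, int]]] = None,
        scaffold_prefixes: Sequence[str] = DEFAULT_SCAFFOLD_PREFIXES,
    ) -> None:
        if name in self.contigs:
            raise ParseError(f"duplicate contig name {name!r}")
        seq = sequence.upper()
        bad = set(seq) - VALID_BASES
        if bad:
            raise ParseError(
                f"contig {name!r} contains invalid symbol(s): "
                + ", ".join(sorted(bad))
            )
        if contig_cls is None:
            contig_cls = classify_contig_name(name, scaffold_prefixes)
        ivs = sorted(mask_intervals or [])
        for s, e in ivs:
            if not (0 <= s < e <= len(seq)):
                raise ValueError(
                    f"mask interval ({s},{e}) outside contig {name!r}"
                )
        self.contigs[name] = seq
        self.contig_class[name] = contig_cls
        self.mask[name] = ivs

    def length(self, contig: str) -> int:
        return len(self.contigs[contig])

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.contigs.values())

    @property
    def total_unmasked_length(self) -> int:
        masked = sum(
            e - s for ivs in self.mask.values() for s, e in ivs
        )
        return self.total_length - masked

    def fetch(self, interval: GenomicInterval) -> str:
        """Plus-strand sequence of an interval (caller handles strand)."""
        return self.contigs[interval.contig][interval.start:interval.end]

    def is_scaffold(self, contig: str) -> bool:
        return self.contig_class[contig] == UNPLACED_SCAFFOLD


def classify_contig_name(
    name: str, scaffold_prefixes: Sequence[str] = DEFAULT_SCAFFOLD_PREFIXES
) -> str:
    for p in scaffold_prefixes:
        if name.startswith(p):
            return UNPLACED_SCAFFOLD
    return CHROMOSOME


@dataclass(frozen=True)
class GeneModel:
    """A gene with its span, strand-aware 5' end and exonic length (for
    FPKM normalisation)."""

    gene_id: str
    interval: GenomicInterval
    exonic_length: int

    def __post_init__(self) -> None:
        if self.exonic_length < 1:
            raise ValueError(f"gene {self.gene_id}: exonic_length must be >=1")
        if self.interval.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be +/-")

    @property
    def tss(self) -> int:
        """0-based position of the 5' end."""
        if self.interval.strand == "+":
            return self.interval.start
        return self.interval.end - 1


ANNO_CLASSES = ("c11", "c10", "c00")


@dataclass(frozen=True)
class PromoterRecord:
    """A CAGE-defined TSS with its 501-bp query window.

    Annotation classes follow the gene/ortholog cross: c11 = associated
    gene with a known target-2 ortholog, c10 = gene without ortholog,
    c00 = no gene association.
    """

    promoter_id: str
    source_contig: str
    tss: int
    strand: str
    window: GenomicInterval
    gene_id: Optional[str] = None
    has_target_ortholog: bool = False
    edge_truncated: bool = False

    def __post_init__(self) -> None:
        if not self.edge_truncated and self.window.length != 501:
            raise ValueError(
                f"promoter {self.promoter_id}: window length "
                f"{self.window.length} != 501"
            )
        if self.gene_id is None and self.has_target_ortholog:
            raise ValueError(
                f"promoter {self.promoter_id}: ortholog flag without gene"
            )

    @property
    def anno_class(self) -> str:
        if self.gene_id is None:
            return "c00"
        return "c11" if self.has_target_ortholog else "c10"


class OrthologTable:
    """Set of (source_gene_id, target_gene_id) ortholog pairs."""

    def __init__(self, pairs: Iterable[tuple[str, str]] = ()):
        self.pairs: set[tuple[str, str]] = set()
        self._by_source: dict[str, list[str]] = {}
        for s, t in pairs:
            self.add(s, t)

    def add(self, source_gene: str, target_gene: str) -> None:
        pair = (source_gene, target_gene)
        if pair in self.pairs:
            return
        self.pairs.add(pair)
        self._by_source.setdefault(source_gene, []).append(target_gene)

    def targets_of(self, source_gene: str) -> list[str]:
        return sorted(self._by_source.get(source_gene, []))

    def __len__(self) -> int:
        return len(self.pairs)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return pair in self.pairs


@dataclass(frozen=True)
class AlignedFragment:
    """An aligned RNA-Seq fragment (or mapped CAGE tag) placement."""

    interval: GenomicInterval
    read_id: str
    multimapped: bool = False


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def _lowercase_runs(seq: str) -> list[tuple[int, int]]:
    runs = []
    start = None
    for i, c in enumerate(seq):
        if c.islower():
            if start is None:
                start = i
        elif start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(seq)))
    return runs


def read_fasta(
    path: str | Path,
    mask_mode: str = "lowercase",
    scaffold_prefixes: Sequence[str] = DEFAULT_SCAFFOLD_PREFIXES,
) -> GenomeSequence:
    """Read a genome FASTA.

    mask_mode: ``lowercase`` derives the repeat mask from soft-masked
    (lower-case) bases; ``bed:<path>`` reads mask intervals from a BED
    file; ``none`` records no mask.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    bed_mask: dict[str, list[tuple[int, int]]] = {}
    if mask_mode.startswith("bed:"):
        for iv, _name, _score in read_bed(mask_mode[4:]):
            bed_mask.setdefault(iv.contig, []).append((iv.start, iv.end))
    elif mask_mode not in ("lowercase", "none"):
        raise ValueError(f"unknown mask_mode {mask_mode!r}")

    genome = GenomeSequence()
    with open(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            raw = str(rec.seq)
            if mask_mode == "lowercase":
                mask = _lowercase_runs(raw)
            else:
                mask = bed_mask.get(rec.id, [])
            genome.add_contig(
                rec.id, raw, mask_intervals=mask,
                scaffold_prefixes=scaffold_prefixes,
            )
    if not genome.contigs:
        warnings.warn(f"no sequences found in {path}", stacklevel=2)
        logger.warning("empty FASTA: %s", path)
    return genome


def write_fasta(genome: GenomeSequence, path: str | Path, width: int = 70) -> None:
    """Write contigs with masked stretches lower-cased (soft masking)."""
    with open(path, "w") as fh:
        for name in sorted(genome.contigs):
            seq = list(genome.contigs[name])
            for s, e in genome.mask.get(name, []):
                for i in range(s, e):
                    seq[i] = seq[i].lower()
            fh.write(f">{name}\n")
            s = "".join(seq)
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def write_bed(
    records: Iterable[tuple[GenomicInterval, str, float]],
    path: str | Path,
    genome: Optional[GenomeSequence] = None,
) -> None:
    """Write BED6 (0-based half-open). ``genome`` enables bounds checks."""
    with open(path, "w") as fh:
        for iv, name, score in records:
            if genome is not None:
                if iv.contig not in genome.contigs:
                    raise ValueError(f"unknown contig {iv.contig!r}")
                if iv.end > genome.length(iv.contig):
                    raise ValueError(
                        f"interval {iv.contig}:{iv.start}-{iv.end} out of "
                        f"contig bounds"
                    )
            fh.write(
                f"{iv.contig}\t{iv.start}\t{iv.end}\t{name}\t{score:g}"
                f"\t{iv.strand}\n"
            )


def read_bed(path: str | Path) -> list[tuple[GenomicInterval, str, float]]:
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise ParseError(f"{path}:{ln}: expected >=3 BED columns")
            try:
                iv = GenomicInterval(
                    f[0], int(f[1]), int(f[2]),
                    f[5] if len(f) > 5 else ".",
                )
            except (ValueError, IndexError) as exc:
                raise ParseError(f"{path}:{ln}: {exc}") from exc
            name = f[3] if len(f) > 3 else "."
            score = float(f[4]) if len(f) > 4 and f[4] != "." else 0.0
            out.append((iv, name, score))
    return out


def write_gene_models(genes: Iterable[GeneModel], path: str | Path) -> None:
    """BED6+1: standard BED6 plus exonic_length."""
    with open(path, "w") as fh:
        for g in genes:
            iv = g.interval
            fh.write(
                f"{iv.contig}\t{iv.start}\t{iv.end}\t{g.gene_id}\t0"
                f"\t{iv.strand}\t{g.exonic_length}\n"
            )


def read_gene_models(path: str | Path) -> list[GeneModel]:
    genes = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 7:
                raise ParseError(
                    f"{path}:{ln}: gene models need 7 columns (BED6+length)"
                )
            iv = GenomicInterval(f[0], int(f[1]), int(f[2]), f[5])
            genes.append(GeneModel(f[3], iv, int(f[6])))
    return genes


def write_ortholog_tsv(table: OrthologTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("source_gene\ttarget_gene\n")
        for s, t in sorted(table.pairs):
            fh.write(f"{s}\t{t}\n")


def read_ortholog_tsv(path: str | Path) -> OrthologTable:
    table = OrthologTable()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["source_gene", "target_gene"]:
            raise ParseError(
                f"{path}: expected header 'source_gene\\ttarget_gene'"
            )
        for ln, line in enumerate(fh, 2):
            line = line.rstrip("\n")
            if not line:
                continue
            f = line.split("\t")
            if len(f) < 2:
                raise ParseError(f"{path}:{ln}: expected 2 columns")
            table.add(f[0], f[1])
    return table


# ---------------------------------------------------------------------------
# proximity
# ---------------------------------------------------------------------------

class FeatureIndex:
    """Per-contig sorted interval index for nearest-feature queries.

    Mirrors ``bedtools closest`` semantics: distance is the gap between
    closest ends, 0 for any overlap, features on other contigs are never
    returned, and ties go to the leftmost start.
    """

    def __init__(self, features: Iterable[GenomicInterval]):
        self._by_contig: dict[str, list[GenomicInterval]] = {}
        for iv in features:
            self._by_contig.setdefault(iv.contig, []).append(iv)
        self._starts: dict[str, list[int]] = {}
        self._max_len: dict[str, int] = {}
        for contig, ivs in self._by_contig.items():
            ivs.sort(key=lambda i: (i.start, i.end))
            self._starts[contig] = [i.start for i in ivs]
            self._max_len[contig] = max(i.length for i in ivs)

    def closest(
        self, query: GenomicInterval, max_dist: int
    ) -> Optional[tuple[GenomicInterval, int]]:
        ivs = self._by_contig.get(query.contig)
        if not ivs:
            return None
        starts = self._starts[query.contig]
        # Any feature within max_dist starts no later than query.end +
        # max_dist and no earlier than query.start - max_dist - longest
        # feature length (else even its end cannot reach the window).
        lo = bisect.bisect_left(
            starts, query.start - max_dist - self._max_len[query.contig]
        )
        hi = bisect.bisect_right(starts, query.end + max_dist)
        best: Optional[tuple[int, int, GenomicInterval]] = None
        for iv in ivs[lo:hi]:
            gap = query.gap_to(iv)
            assert gap is not None
            if gap <= max_dist and (
                best is None or (gap, iv.start) < (best[0], best[1])
            ):
                best = (gap, iv.start, iv)
        if best is None:
            return None
        return best[2], best[0]


def closest_feature(
    query: GenomicInterval,
    features: Iterable[GenomicInterval] | FeatureIndex,
    max_dist: int,
) -> Optional[tuple[GenomicInterval, int]]:
    """Nearest feature on the query's contig within ``max_dist`` bp.

    Returns ``(feature, distance)`` with distance 0 for overlap, or None
    when no feature lies within the threshold.
    """
    index = (
        features
        if isinstance(features, FeatureIndex)
        else FeatureIndex(features)
    )
    return index.closest(query, max_dist)
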