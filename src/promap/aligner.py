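"""Seeded local alignment of promoter windows and CAGE tags.

Two search paths share one k-mer genome index:

* :func:`find_hits` — blastn-style seed-and-extend for window queries
  (>= 11 bp): contiguous 11-mer seeds, candidate loci from seed diagonal
  clusters, gapped local extension, Karlin-Altschul bit-scores and
  e-values, identity/e-value filtering.
* :func:`find_tag_hits` — short-read path for CAGE tags: ungapped,
  near-full-length match with up to two soft-clipped bases per end and
  no e-value step (uniqueness is decided downstream by the 0.95
  score-ratio rescue rule, as in the original read-mapper procedure).

:func:`sw_oracle` is an exhaustive affine-gap Smith-Waterman/Gotoh
optimum, written independently of the search path, used as the test
oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from Bio import Align
from numba import njit

from .core import GenomeSequence, GenomicInterval

SEED_K = 11  # global minimum query length; also seed word size

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScoringScheme:
    """Match/mismatch/gap scores plus Karlin-Altschul constants.

    Gap convention: a gap of length L costs ``gap_open + L * gap_extend``
    (opening may be free). ``lambda_`` and ``k`` convert raw scores to
    bit-scores, ``bit = (lambda_*S - ln k) / ln 2``, and e-values,
    ``E = k * m * n * exp(-lambda_*S)``.
    """

    reward: int = 1
    penalty: int = -1
    gap_open: int = 0
    gap_extend: int = 2
    min_identity_pct: float = 20.0
    max_evalue: float = 0.01
    #: ungapped Karlin-Altschul constants for reward 1 / penalty -1 at
    #: uniform base composition (lambda = ln 3); applied to gapped
    #: scores, as short-read aligners and blastn presets do
    lambda_: float = 1.0986
    k: float = 0.333

    def __post_init__(self) -> None:
        if self.reward <= 0 or self.penalty > 0:
            raise ValueError("need reward > 0 and penalty <= 0")
        if self.lambda_ <= 0 or self.k <= 0:
            raise ValueError("lambda_ and k must be positive")

    def bit_score(self, raw: float) -> float:
        return (self.lambda_ * raw - math.log(self.k)) / math.log(2)

    def evalue(self, raw: float, query_len: int, db_len: int) -> float:
        return self.k * query_len * db_len * math.exp(-self.lambda_ * raw)

    @classmethod
    def pass1(cls) -> "ScoringScheme":
        """Permissive cross-species scheme (reward 1, penalty -1, free gap
        open, 2/base extension, >=20% identity, e-value <= 0.01)."""
        return cls()

    @classmethod
    def pass2(cls) -> "ScoringScheme":
        """Stricter rescoring for previously unmapped queries (penalty -3,
        gap open 3, extend 3); identity/e-value cutoffs kept from pass 1."""
        return cls(
            reward=1, penalty=-3, gap_open=3, gap_extend=3,
            min_identity_pct=20.0, max_evalue=0.01,
            lambda_=1.37, k=0.71,
        )

    @classmethod
    def tag(cls) -> "ScoringScheme":
        """Short-tag scheme: strict mismatch cost, 90% core identity; the
        e-value field is unused on the tag path."""
        return cls(
            reward=1, penalty=-3, gap_open=3, gap_extend=3,
            min_identity_pct=90.0, max_evalue=math.inf,
            lambda_=1.37, k=0.71,
        )


@dataclass(frozen=True)
class AlignmentHit:
    """One local-alignment placement of a query on the target genome."""

    query_id: str
    interval: GenomicInterval  # strand = alignment orientation
    raw_score: int
    bit_score: float
    identity_pct: float
    evalue: float


def sort_hits(hits: list[AlignmentHit]) -> list[AlignmentHit]:
    """Deterministic ranking: bit-score desc, then contig, then start."""
    return sorted(
        hits,
        key=lambda h: (-h.bit_score, h.interval.contig, h.interval.start),
    )


def merge_close_hits(
    hits: list[AlignmentHit], max_gap: int = 50
) -> list[AlignmentHit]:
    """Collapse HSPs within ``max_gap`` bp on the same contig and strand
    into one hit, keeping the best-scoring member.

    Uniqueness and the score-ratio rescue are judged on merged hits, so a
    locus fragmented into several HSPs does not masquerade as a
    multi-locus mapping.
    """
    groups: dict[tuple[str, str], list[AlignmentHit]] = {}
    for h in hits:
        groups.setdefault((h.interval.contig, h.interval.strand), []).append(h)
    out: list[AlignmentHit] = []
    for members in groups.values():
        members.sort(key=lambda h: h.interval.start)
        chain = [members[0]]
        chain_end = members[0].interval.end
        for h in members[1:]:
            if h.interval.start - chain_end <= max_gap:
                chain.append(h)
                chain_end = max(chain_end, h.interval.end)
            else:
                out.append(max(chain, key=lambda x: x.raw_score))
                chain = [h]
                chain_end = h.interval.end
        out.append(max(chain, key=lambda x: x.raw_score))
    return sort_hits(out)


# ---------------------------------------------------------------------------
# k-mer index
# ---------------------------------------------------------------------------

class KmerIndex:
    """Exact k-mer location index over all contigs of a genome."""

    def __init__(self, genome: GenomeSequence, k: int = SEED_K):
        self.k = k
        self.genome = genome
        self.positions: dict[str, list[tuple[str, int]]] = {}
        for name, seq in genome.contigs.items():
            for pos in range(len(seq) - k + 1):
                word = seq[pos : pos + k]
                if "N" in word:
                    continue
                self.positions.setdefault(word, []).append((name, pos))

    def lookup(self, word: str) -> list[tuple[str, int]]:
        return self.positions.get(word, [])


def _get_index(genome: GenomeSequence, k: int = SEED_K) -> KmerIndex:
    cache = getattr(genome, "_kmer_index_cache", None)
    if cache is None:
        cache = {}
        genome._kmer_index_cache = cache  # type: ignore[attr-defined]
    if k not in cache:
        cache[k] = KmerIndex(genome, k)
    return cache[k]


def _seed_wholly_masked(
    genome: GenomeSequence, contig: str, pos: int, k: int
) -> bool:
    import bisect as _bisect

    ivs = genome.mask.get(contig)
    if not ivs:
        return False
    idx = _bisect.bisect_right(ivs, (pos, float("inf"))) - 1
    if idx < 0:
        return False
    s, e = ivs[idx]
    return s <= pos and pos + k <= e


# ---------------------------------------------------------------------------
# gapped extension (window queries)
# ---------------------------------------------------------------------------

def _make_pairwise_aligner(scheme: ScoringScheme) -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "local"
    al.match_score = scheme.reward
    al.mismatch_score = scheme.penalty
    al.open_gap_score = -(scheme.gap_open + scheme.gap_extend)
    al.extend_gap_score = -scheme.gap_extend
    return al


def _cluster_diagonals(
    seeds: list[tuple[str, int]], band: int = 50
) -> dict[str, list[list[int]]]:
    """Group projected query-start diagonals per contig; diagonals more
    than ``band`` apart start a new candidate locus."""
    per_contig: dict[str, list[int]] = {}
    for contig, diag in seeds:
        per_contig.setdefault(contig, []).append(diag)
    clusters: dict[str, list[list[int]]] = {}
    for contig, diags in per_contig.items():
        diags.sort()
        groups = [[diags[0]]]
        for d in diags[1:]:
            if d - groups[-1][-1] <= band:
                groups[-1].append(d)
            else:
                groups.append([d])
        clusters[contig] = groups
    return clusters


def _kadane(qarr: np.ndarray, tarr: np.ndarray, scheme: ScoringScheme) -> int:
    """Best ungapped segment score of two equal-length encoded arrays."""
    if len(qarr) == 0:
        return 0
    per_base = np.where(qarr == tarr, scheme.reward, scheme.penalty)
    best = run = 0
    for v in per_base:
        run = max(0, run + int(v))
        best = max(best, run)
    return best


_ENC = np.zeros(128, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _ENC[ord(_b)] = _i + 1


def encode(seq: str) -> np.ndarray:
    """A,C,G,T -> 1..4; anything else (incl. N) -> 0, matching nothing."""
    return _ENC[np.frombuffer(seq.encode(), dtype=np.uint8)]


def find_hits(
    query: str,
    genome: GenomeSequence,
    scheme: ScoringScheme,
    use_mask: bool = False,
    query_id: str = "query",
    band: int = 50,
    flank: int = 100,
) -> list[AlignmentHit]:
    """Local-alignment hits of ``query`` on both strands of ``genome``.

    Hits failing the scheme's identity or e-value cutoff are dropped;
    when ``use_mask`` is set, seeds lying wholly inside masked intervals
    are skipped (extension may still cross masked sequence). Ordering is
    deterministic: bit-score desc, then contig name, then start.
    """
    query = query.upper()
    if len(query) < SEED_K:
        raise ValueError(
            f"query length {len(query)} < {SEED_K}: use the short-read "
            "(tag) alignment path for sub-seed-length queries"
        )
    index = _get_index(genome)
    db_len = genome.total_unmasked_length if use_mask else genome.total_length
    aligner = _make_pairwise_aligner(scheme)
    qlen = len(query)
    # Ungapped trigger, as in blastn: sparse-seed candidate loci must
    # reach the e-value-implied minimum reportable score on the seed
    # diagonal before gapped extension is attempted. Without it, chance
    # seeds in long queries accrete weak gapped alignments that the
    # (ungapped) Karlin-Altschul constants cannot screen out.
    prefilter = qlen > 250
    if math.isfinite(scheme.max_evalue) and scheme.max_evalue > 0:
        trigger = int(
            math.ceil(
                math.log(scheme.k * qlen * db_len / scheme.max_evalue)
                / scheme.lambda_
            )
        )
    else:
        trigger = 15
    hits: list[AlignmentHit] = []
    for strand, qseq in (("+", query), ("-", revcomp(query))):
        qarr = encode(qseq)
        seeds: list[tuple[str, int]] = []
        for i in range(qlen - SEED_K + 1):
            word = qseq[i : i + SEED_K]
            for contig, pos in index.lookup(word):
                if use_mask and _seed_wholly_masked(
                    genome, contig, pos, SEED_K
                ):
                    continue
                seeds.append((contig, pos - i))
        if not seeds:
            continue
        for contig, groups in _cluster_diagonals(seeds, band).items():
            tseq = genome.contigs[contig]
            windows: list[tuple[int, int]] = []
            for diags in groups:
                if prefilter and len(diags) < 3:
                    # modal diagonal, ungapped check
                    diag = max(set(diags), key=diags.count)
                    ts = max(0, diag)
                    te = min(len(tseq), diag + qlen)
                    if te <= ts:
                        continue
                    qs, qe = ts - diag, te - diag
                    if (
                        _kadane(qarr[qs:qe], encode(tseq[ts:te]), scheme)
                        < trigger
                    ):
                        continue
                ws = max(0, diags[0] - flank)
                we = min(len(tseq), diags[-1] + qlen + flank)
                if windows and ws <= windows[-1][1]:
                    windows[-1] = (windows[-1][0], max(windows[-1][1], we))
                else:
                    windows.append((ws, we))
            for ws, we in windows:
                hit = _extend_in_window(
                    aligner, qseq, tseq, contig, ws, we, strand,
                    scheme, qlen, db_len, query_id,
                )
                if hit is not None:
                    hits.append(hit)
    return sort_hits(hits)


def _extend_in_window(
    aligner: Align.PairwiseAligner,
    qseq: str,
    tseq: str,
    contig: str,
    ws: int,
    we: int,
    strand: str,
    scheme: ScoringScheme,
    qlen: int,
    db_len: int,
    query_id: str,
) -> Optional[AlignmentHit]:
    twin = tseq[ws:we]
    score = aligner.score(twin, qseq)
    if score <= 0:
        return None
    ev = scheme.evalue(score, qlen, db_len)
    if ev > scheme.max_evalue:
        return None
    aln = aligner.align(twin, qseq)[0]
    counts = aln.counts()
    aln_len = counts.identities + counts.mismatches + counts.gaps
    identity = 100.0 * counts.identities / aln_len if aln_len else 0.0
    if identity < scheme.min_identity_pct:
        return None
    tsegs = aln.aligned[0]
    tstart, tend = int(tsegs[0][0]) + ws, int(tsegs[-1][1]) + ws
    return AlignmentHit(
        query_id=query_id,
        interval=GenomicInterval(contig, tstart, tend, strand),
        raw_score=int(round(score)),
        bit_score=scheme.bit_score(score),
        identity_pct=identity,
        evalue=ev,
    )


# ---------------------------------------------------------------------------
# short-read (tag) path
# ---------------------------------------------------------------------------

def find_tag_hits(
    tag: str,
    genome: GenomeSequence,
    scheme: Optional[ScoringScheme] = None,
    soft_clip: int = 2,
) -> list[AlignmentHit]:
    """Ungapped near-full-length placements of a short tag.

    Up to ``soft_clip`` terminal bases on each end may be left unscored;
    the remaining core must meet the scheme's identity threshold. The
    genome is searched unmasked on both strands.
    """
    if scheme is None:
        scheme = ScoringScheme.tag()
    tag = tag.upper()
    L = len(tag)
    if L < SEED_K:
        raise ValueError(f"tag length {L} < {SEED_K}")
    index = _get_index(genome)
    hits: dict[tuple[str, int, int, str], AlignmentHit] = {}
    for strand, qseq in (("+", tag), ("-", revcomp(tag))):
        qarr = encode(qseq)
        cand: set[tuple[str, int]] = set()
        for i in range(L - SEED_K + 1):
            for contig, pos in index.lookup(qseq[i : i + SEED_K]):
                cand.add((contig, pos - i))
        for contig, diag in cand:
            tseq = genome.contigs[contig]
            ts = max(0, diag)
            te = min(len(tseq), diag + L)
            if te - ts < L - 2 * soft_clip:
                continue
            qs, qe = ts - diag, te - diag
            match = (qarr[qs:qe] == encode(tseq[ts:te]))
            best = None
            n = len(match)
            # allow clipping only at true sequence ends, not contig edges
            left_room = soft_clip if ts == diag else 0
            right_room = soft_clip if te == diag + L else 0
            for cl in range(left_room + 1):
                for cr in range(right_room + 1):
                    core = match[cl : n - cr] if cr else match[cl:]
                    if len(core) < L - 2 * soft_clip:
                        continue
                    m = int(core.sum())
                    mm = len(core) - m
                    score = m * scheme.reward + mm * scheme.penalty
                    ident = 100.0 * m / len(core)
                    if ident < scheme.min_identity_pct:
                        continue
                    if best is None or score > best[0]:
                        best = (score, cl, cr, ident)
            if best is None:
                continue
            score, cl, cr, ident = best
            iv = GenomicInterval(contig, ts + cl, te - cr, strand)
            key = (contig, iv.start, iv.end, strand)
            hit = AlignmentHit(
                query_id="tag",
                interval=iv,
                raw_score=score,
                bit_score=scheme.bit_score(score),
                identity_pct=ident,
                evalue=scheme.evalue(score, L, genome.total_length),
            )
            prev = hits.get(key)
            if prev is None or hit.raw_score > prev.raw_score:
                hits[key] = hit
    return sort_hits(list(hits.values()))


# ---------------------------------------------------------------------------
# exhaustive oracle
# ---------------------------------------------------------------------------

@njit(cache=False)
def _gotoh_best_end(q, t, reward, penalty, open_ext, ext):  # pragma: no cover
    lq, lt = len(q), len(t)
    H = np.zeros(lt + 1, dtype=np.int64)
    E = np.full(lt + 1, -(10 ** 9), dtype=np.int64)
    best = 0
    bi = 0
    bj = 0
    F = np.full(lt + 1, -(10 ** 9), dtype=np.int64)
    for i in range(1, lq + 1):
        prev_diag = H[0]
        H[0] = 0
        e_run = -(10 ** 9)
        for j in range(1, lt + 1):
            if q[i - 1] != 0 and q[i - 1] == t[j - 1]:
                s = reward
            else:
                s = penalty
            F[j] = max(H[j] - open_ext, F[j] - ext)
            e_run = max(H[j - 1] - open_ext, e_run - ext)
            h = prev_diag + s
            if F[j] > h:
                h = F[j]
            if e_run > h:
                h = e_run
            if h < 0:
                h = 0
            prev_diag = H[j]
            H[j] = h
            if h > best:
                best = h
                bi = i
                bj = j
    return best, bi, bj


def sw_oracle(
    query: str,
    target_sequence: str,
    scheme: ScoringScheme,
    both_strands: bool = True,
) -> tuple[int, tuple[int, int], str]:
    """Exhaustive affine-gap local alignment optimum.

    Returns ``(raw_score, (target_start, target_end), strand)`` of the
    best-scoring local alignment; score 0 means no positive-scoring
    alignment exists. Independent of the seeded search path.
    """
    if len(query) * len(target_sequence) > 10 ** 8:
        raise ValueError("query*target size exceeds the 1e8-cell oracle cap")
    tarr = encode(target_sequence.upper())
    open_ext = scheme.gap_open + scheme.gap_extend
    strands = ("+", "-") if both_strands else ("+",)
    best = (0, (0, 0), "+")
    for strand in strands:
        qs = query.upper() if strand == "+" else revcomp(query.upper())
        qarr = encode(qs)
        score, qi, tj = _gotoh_best_end(
            qarr, tarr, scheme.reward, scheme.penalty,
            open_ext, scheme.gap_extend,
        )
        if score <= 0 or score <= best[0]:
            continue
        # locate the start by rerunning on the reversed prefixes
        rscore, rqi, rtj = _gotoh_best_end(
            qarr[:qi][::-1].copy(), tarr[:tj][::-1].copy(),
            scheme.reward, scheme.penalty, open_ext, scheme.gap_extend,
        )
        assert rscore == score
        best = (int(score), (int(tj - rtj), int(tj)), strand)
    return best
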