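# Methods

This note documents the models and procedures `promap` implements, the
parameters that matter, what the synthetic data does and does not
emulate, and the numerical choices made where the design was open.

## Coordinates and containers

All coordinates are 0-based half-open internally and in BED output;
human-readable report text is 1-based inclusive. Genomes are held in
memory upper-cased; repeat masking is stored as per-contig interval
lists (read from soft-masked FASTA or a companion BED), because stages
differ in whether they consult the mask: cross-species projection
aligns against the masked genome, within-species CAGE tag alignment
against the unmasked one. Contigs are classed as chromosomes or
unplaced scaffolds by a configurable name-prefix rule (default `GL`,
`JH`, `scaffold`, `AEMK`); the class drives the scaffold arm of
multimapper rescue.

## Promoter projection

A promoter is queried as the 501-bp window `[TSS−400, TSS+100]`
(strand-aware, TSS base included). Projection runs in three stages:

1. **Orthology pass.** If the promoter's gene has target orthologs, the
   query is aligned only against their 2101-bp upstream windows
   (`[5'−2000, 5'+100]`). Any hit passing the identity/e-value cutoffs
   reports the promoter (`ortholog_mapped`); the best bit-score wins,
   ties broken by gene-id order. No separate acceptance threshold
   exists for this pass, and window hits are never ruled multimapped —
   with several orthologs the best hit simply wins.
2. **Genome-wide pass 1** on the repeat-masked genome with the
   permissive scheme (reward 1, penalty −1, gap open 0, gap extend 2,
   `perc_identity` 20, e-value 0.01). "Gap open 0, extend 2" is read
   literally: opening costs nothing, every gap base costs 2.
3. **Genome-wide pass 2** re-aligns promoters that were *unmapped*
   (not multimapped ones) with the strict scheme (penalty −3, gap open
   3, gap extend 3); the identity/e-value cutoffs carry over since only
   the changed parameters are specified.

HSPs within 50 bp on the same contig and strand are merged (best score
kept) before uniqueness is judged, so one fragmented locus is one hit.
Exactly one surviving hit ⇒ `unique`. Two or more trigger rescue:
`s2/s1 < 0.95` on bit-scores ⇒ top hit (`rescued_ratio`); else exactly
one hit on a chromosome with all others on unplaced scaffolds ⇒ that
hit (`rescued_scaffold`); else `multimapped`. The scaffold clause is
applied to any number of hits by default — the motivating situation,
assembly fragmentation, is not specific to two-hit cases — and
`scaffold_max_hits` restores the narrow two-hit reading. "Reported
mapped" means a hit was chosen; multimapped and unmapped promoters are
not reported.

Windows clipped below 250 bp at contig edges are flagged
`edge_truncated` and excluded from projection. The midpoint of an
even-length interval is `start + length//2`.

## Alignment engine

Window queries use seed-and-extend: contiguous 11-mer exact seeds
(11 bp is also the pipeline's global minimum query length), clustered
by diagonal within a 50-bp band per contig, extended by affine-gap
local DP inside a padded window (the DP itself is delegated to
Biopython's `PairwiseAligner`; seeding, candidate selection and all
score statistics are this package's). Both strands are searched. Hits
are ranked bit-score descending, then contig, then start — fully
deterministic.

Scores convert to bit-scores and e-values with ungapped
Karlin–Altschul constants at uniform base composition, applied to
gapped scores the way blastn's presets do: λ = ln 3 ≈ 1.0986,
K ≈ 0.333 for (1,−1); λ = 1.374, K = 0.711 for (1,−3). The (1,−1)
pair is derived from the Karlin–Altschul identity
`¼e^λ + ¾e^{−λ} = 1` rather than taken from a preset table, because
the commonly quoted (1.28, 0.46) pair belongs to a different scheme
and understates e-values ~35-fold here — enough to admit a steady
trickle of chance hits at `E ≤ 0.01`. The e-value search space is
`m × n` with `n` the (unmasked, when masking applies) genome length.
Only score *ratios* drive rescue decisions, and those are invariant to
the λ choice, so rescue behaviour does not depend on this calibration.

Two guards keep the heuristic honest on long queries: seeds lying
wholly inside masked intervals are skipped (extension may still cross
a mask), and a candidate locus supported by fewer than three seeds
must reach the e-value-implied minimum reportable score ungapped on
its seed diagonal before gapped extension is attempted — the analogue
of blastn's ungapped trigger. Absolute bit-scores of this engine are
not comparable to any external aligner's; ratio-based decisions are.

`sw_oracle` is an independent, hand-written affine-gap Smith–Waterman
/ Gotoh DP (numba-compiled, score-only with a reversed-prefix rerun to
locate the start), capped at 10⁸ cells. The test suite holds the
seeded engine to it: never above the optimum, equal whenever a
≥90%-identity hit is reported.

**CAGE tag path.** Short tags are placed ungapped: seed, then compare
the full tag at each candidate diagonal, allowing up to two unscored
(soft-clipped) bases per end, requiring ≥90% identity on the remaining
core. No e-value filter applies — read mappers do not use one, and an
11-bp rescued tag could never pass `E ≤ 0.01` anyway; uniqueness is
instead decided by the same 0.95 ratio / scaffold rule as promoters
(0 hits ⇒ unmapped, 1 ⇒ unique).

## CAGE pipeline

Reads are trimmed of their 3' adapter (longest read-suffix match to
the adapter start, ≥3 bp, ≤1 mismatch per 10 bp) and a fixed-length 5'
prefix (barcode + restriction-enzyme bases); survivors need ≥20 bases.
No base-quality filtering is applied at any point. Unmapped tags are
iteratively trimmed by exactly one base from each end and realigned
until a single placement emerges or the next trim would cross the
11-bp floor; multimapped tags are not re-trimmed (the procedure is
defined for unmapped reads), and rescue never converts a placed tag
back to unmapped. The 11-bp floor is kept from the original procedure,
where it was chosen against gigabase genomes; note that at the
simulator's ~10³-fold smaller scale a chance 11-mer is often unique,
so a minority of genuinely unalignable reads is "rescued" to random
loci — visible as small scattered clusters. This is a faithful
consequence of the procedure at desk scale, not a bug, and the
acceptance tests account for it by weighting cluster/TSS
correspondence by tag count.

Uniquely placed tags (including rescues) are extended symmetrically to
501 bp — odd remainder to the 5' side, clipped at contig edges — and
merged into CTSS clusters per contig and strand when they overlap by
at least one base (abutting intervals do not merge); cluster intervals
are member unions. Clustering is strand-aware: CTSS semantics are
strand-specific even though the original description is silent.
Singleton clusters are removed in a separate, reported step but the
singleton intervals are retained, because uniquely mapped singletons
still count as CAGE support in evidence integration. Clusters are
assigned to a gene when they overlap the gene span or its strand-aware
2-kb upstream window (nearest 5' end wins ties), and cluster/promoter
proximity is reported in both directions at 100 bp and 2 kb (gap
between closest ends; 0 for overlap; strand-agnostic).

## RNA-Seq evidence

Gene counting uses uniquely mapped fragments overlapping exactly one
gene span (ambiguous fragments are discarded);
`FPKM = count·10⁹/(exonic_length·library_size)`. Window coverage
around mapped-promoter midpoints deliberately *includes* multimapped
fragments so duplicated gene families still show qualitative signal.
Each mapped promoter contributes 250 non-overlapping 100-bp windows
spanning 5 kb upstream to 20 kb downstream in 5'→3' orientation
(columns reversed for minus-strand rows); a fragment increments every
window it overlaps — totals therefore differ from 5'-end binning, and
the any-overlap convention is the simplest consistent with per-window
read counting. Windows beyond contig ends count zero.

With 50 upstream windows the midpoint base falls in window 51; the
original description says 52, which appears to be an off-by-one of
presentation, and a configuration offset (`midpoint_window_offset`)
exists for exact replication attempts. The evidence rule takes the
seven windows `m−2..m+4` — the only contiguous seven-window set
covering −200..+400 that includes the midpoint window — and requires
≥1 FPKM in any of them, with the 100-bp window as the per-kilobase
denominator (window FPKM = `count·10⁹/(100·library)`). Heatmap
eligibility requires ≥11 fragments summed over the first 100 windows.
CAGE support in the final integration means a CTSS cluster or a
uniquely mapped singleton tag within 2 kb of the mapped, 501-bp
re-extended promoter interval; categories are both / cage-only /
rnaseq-only / none.

## Synthetic data

The generator emulates the features of real comparative data that
drive the pipeline's decision points, with defaults chosen as the
study conditions at desk scale:

* **Homology by descent.** Each gene occupies an ancestor block
  (500 bp upstream context + a 300–600-bp gene body). Source and
  target copies are mutated *independently* from the ancestor at the
  per-lineage substitution rate `promoter_divergence` (default 0.05)
  and indel rate (0.005/base), giving pairwise identity
  ≈ `(1−d)² + d²/3` — ~90% at d=0.05, dropping below local-alignment
  detectability around d≈0.4. Divergence between two extant species is
  a two-lineage quantity; modelling it per lineage is what lets a
  single knob span "conserved promoter" to "diverged beyond
  recognition". Mutations are uniform per base with no
  transition/transversion bias — the simplest model that satisfies the
  divergence knob. Spacers between blocks are drawn independently per
  genome and carry no homology.
* **Second target.** A second, more diverged target lineage
  (`target2_divergence` = 0.15) is built from the same ancestors, with
  a higher promoter-loss rate (25% vs 5%), emulating more extensive
  regulatory turnover in the less conserved species; this is what
  makes the two-species classification non-degenerate.
* **Confounders.** Repeat motifs from a small planted library are
  inserted into 15% of target promoter regions (50–300 bp) and
  recorded in the target mask; 5% of target loci are duplicated
  verbatim, half of the copies landing on unplaced scaffolds — the
  constructs that exercise masked seeding, multimapping and both
  rescue arms. Duplicated loci are withheld from the ortholog table so
  they reach the genome-wide multimapper path rather than being
  short-circuited by the orthology pass.
* **Reads.** 50,000 CAGE reads (36 bp = 8-bp prefix + 25-bp insert +
  adapter start) are drawn from expressed genes proportional to
  expression, 5' ends at the TSS (sharp) or normally spread with
  σ=25 bp (broad, 40% of promoters), with 1% per-base error, 5%
  unalignable and 2% short inserts to exercise the unmapped and
  length-filter paths. 100,000 RNA-Seq fragments (80 bp) are
  multinomial per gene ∝ expression × exonic length, uniform within
  the gene span, flagged multimapped inside duplicated loci.
  Expression is lognormal(0,1) with 10% silent genes.

A single seed drives explicit per-component streams (genome/reads/
fragments), so stages can be re-simulated independently and all
outputs are byte-reproducible. The truth table records each
promoter's expected target interval and status and each gene's
expression and TSS.

What the generator does **not** emulate: realistic repeat families,
splicing and transcript structure (genes are single-exon, so span
length equals exonic length), sequencing-quality models beyond a
constant score, base-composition bias, CAGE TPM normalisation across
libraries, and genome sizes beyond a few hundred kb. Passing recovery
tests therefore demonstrate the decision logic (windows, rescue,
clustering, evidence rules) under controlled homology, not performance
on gigabase genomes or real repeat landscapes.

Test and run problem sizes are the package's own choices: the
full-scale suite uses ~280–310-kb genomes, 200 genes (+10% gene-less
promoters), 50k CAGE reads and 100k RNA-Seq fragments; oracle
equivalence sweeps use 500 alignment pairs ≤200 bp, 200 clustering
sets, and randomised nearest-feature scans.

## Degenerate inputs and tie-breaks

Empty FASTA yields an empty genome with a warning; duplicate contig
names, non-ACGTN symbols and out-of-bounds intervals are errors.
Nearest-feature ties go to the leftmost start. Hit ordering is total
(bit, contig, start). An all-singleton cluster set survives as an
empty kept list. A placement already longer than 501 bp is returned
unchanged (with a warning) by the extension step. Zero library size is
an error wherever FPKM is computed.

## Known limitations

* Absolute bit-scores are engine-specific; only ratio-based decisions
  are portable, so published bit-score distributions cannot be
  compared numerically.
* The seeded search can miss homology whose longest exact match is
  below 11 bp (short queries near the identity threshold); the
  exhaustive oracle bounds, but does not eliminate, this gap.
* The orthology pass accepts any qualifying window hit; if the true
  locus lies outside every ortholog window it cannot be recovered in
  that stage (it would surface in the genome-wide passes only if the
  window hit were absent).
* The 11-bp rescue floor admits chance placements at desk-scale
  genome sizes, as discussed above.
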