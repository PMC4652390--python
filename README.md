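# promap

Cross-species projection of CAGE-defined promoters, with expression
evidence from the target species' own CAGE and RNA-Seq data.

## The problem

Cap Analysis of Gene Expression (CAGE) atlases define promoters in
well-studied genomes (human, mouse) as fixed windows around the main
transcription start site (TSS). For a species with sparse annotation —
the motivating case is the pig — those promoter windows can be
*projected* onto the draft genome by sequence alignment, providing
preliminary regulatory annotation, evidence of orthology, and pointers
to assembly problems. `promap` implements that pipeline end to end for
anyone who wants to run, test, or stress the procedure at desk scale:

1. **Promoter windows.** Each source promoter is the 501-bp window
   `[-400, TSS, +100]` around the CAGE-defined TSS.
2. **Orthology-first projection.** Windows whose gene has known
   orthologs in the target are aligned only against the 2101-bp
   upstream windows (2 kb + 101 bp) of those orthologs; any qualifying
   hit reports the promoter as mapped.
3. **Genome-wide projection.** Remaining windows are aligned to the
   repeat-masked target genome with a permissive local-alignment scheme
   (reward 1, penalty −1, free gap open, 2/base extension, ≥20%
   identity, e-value ≤ 0.01); windows still unmapped are re-scored with
   a strict scheme (penalty −3, gap open 3, extend 3).
4. **Multimapper rescue.** A multi-hit promoter is rescued when the
   second-best/best bit-score ratio `s2/s1 < 0.95`, or when exactly one
   hit lies on an assembled chromosome and all others on unplaced
   scaffolds. Everything else is *not reported* (multimapped or
   unmapped). Bit-scores are Karlin–Altschul:
   `bit = (λ·S − ln K)/ln 2`, `E = K·m·n·e^{−λS}`.
5. **Two-species classification.** Projections onto two targets are
   combined per promoter into target1-specific / target2-specific /
   both / not-reported, per annotation class (gene with ortholog `c11`,
   gene without `c10`, no gene `c00`), plus gene-level rollups and the
   non-redundant gene-union count.
6. **CAGE validation.** Raw target-species CAGE reads are trimmed
   (3' adapter, 5' barcode/enzyme prefix, ≥20 bp kept, no quality
   filtering), aligned to the unmasked genome with ≤2 soft-clipped
   bases per end, rescued by iterative 1-bp end-trimming down to 11 bp,
   extended to 501 bp, merged into CTSS clusters (≥1 bp overlap,
   strand-specific), singleton clusters removed, and related to
   projected promoters by proximity (100 bp / 2 kb).
7. **RNA-Seq validation.** Aligned fragments give per-gene FPKM
   (`count·10⁹ / (exonic_length·library)`), coverage in 250 oriented
   100-bp windows spanning −5 kb..+20 kb around each mapped promoter
   midpoint, and an expression-evidence call (≥1 FPKM in any of the
   seven windows covering −200..+400). CAGE and RNA-Seq support combine
   into a four-way evidence category per promoter.

A first-class synthetic-data module generates paired genomes descended
from common ancestor blocks (per-lineage divergence, indels, planted
repeat insertions, verbatim duplicated loci, unplaced scaffolds), CAGE
reads with trimmable prefix/adapter and sharp/broad TSS shapes, and
expression-proportional RNA-Seq fragments — with a full ground-truth
table, so every stage has a parameter-recovery test surface.

## Worked example

```sh
promap run-all --seed 7 --n-genes 40 --out runs/demo
```

simulates a study (40 genes plus gene-less promoters, two target
genomes, 50,000 CAGE reads, 100,000 RNA-Seq fragments), projects,
classifies and integrates evidence. The final line printed is the
evidence summary:

```
{"both_fraction": 0.875, "both_fraction_of_supported": 0.875,
 "cage_fraction": 1.0, "n_promoters": 40.0, "rnaseq_fraction": 0.875,
 "supported_fraction": 1.0}
```

i.e. all 40 reported promoter mappings have a CTSS cluster within 2 kb,
and 87.5% additionally show ≥1 FPKM RNA-Seq signal near the midpoint.
`runs/demo/stages.jsonl` holds one JSON summary per stage, e.g. the
first projection:

```
{"multimapped": 1, "not_reported": 4, "ortholog_mapped": 25,
 "reported": 40, "stage": "project_target1", "total": 44,
 "unique": 15, "unmapped": 3}
```

25 promoters mapped in the orthology pass, 15 genome-wide, 3 had their
homolog deleted from the target, 1 hit a duplicated locus and stayed
multimapped. `class_summary.tsv` is the class-by-call table with
bracketed whole percents, `mappings_target*.bed`, `ctss_clusters.bed`
and `evidence.tsv` the per-feature tracks.

Library use without the CLI:

```python
from promap import SimConfig, simulate_genome_pair, project_promoters

sim = simulate_genome_pair(SimConfig(seed=1, n_genes=100))
results = project_promoters(
    sim.source_promoters, sim.source_genome, sim.target_genome,
    sim.orthologs, sim.target_genes,
)
```

## Layout

| module | contents |
| --- | --- |
| `promap.core` | intervals, genome/annotation containers, FASTA/BED/TSV I/O, nearest-feature queries |
| `promap.aligner` | seeded local alignment, bit-scores/e-values, tag path with soft clipping, exhaustive DP oracle |
| `promap.simdata` | synthetic genomes, CAGE reads, RNA-Seq fragments, truth tables |
| `promap.projection` | promoter/ortholog windows, three-stage projection, multimapper rescue |
| `promap.classes` | two-target classification, gene rollups, gene-union arithmetic |
| `promap.cage` | trimming, tag mapping, iterative rescue, CTSS clustering, proximity |
| `promap.rnaseq` | FPKM, windowed coverage, heatmap subset, evidence calls and integration |
| `promap.report` | run orchestration, summary tables, artefact I/O |
| `promap.cli` | `promap {simulate, project, cage, rnaseq, run-all}` |

See `docs/methods.md` for the model, parameter and design notes.
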