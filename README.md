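# droughtmem

Tools for finding **drought stress-memory genes** with a 3'-anchored
oligonucleotide microarray, modelled on two-cycle drought/recovery
experiments in soybean (*Glycine max*).

Plants that have experienced drought respond differently the next time:
a subset of drought-responsive genes — *memory genes* — shows strongly
amplified induction or repression under a second drought. Identifying them
requires (i) an isoform-aware probe design anchored at the stop codon,
(ii) careful intensity preprocessing and replicate-consistent fold-change
screens across the four sampled states, and (iii) downstream functional
and network analysis. `droughtmem` implements that whole chain as a
library plus a `droughtmem` command-line tool, together with a seeded
synthetic-data generator so every stage can be exercised and validated
without any array scans or downloads.

## What it computes

**States and taxonomy.** Samples come from four states, two biological
replicates each: WT1 (watered control), DR1 (first drought), WT2
(re-watered recovery), DR2 (second drought). With intensity ratios
computed per replicate:

- **DIT** (drought-induced transcript): DR1/WT1 > 4 in *both* replicates;
- **DRT** (drought-repressed): DR1/WT1 < 1/4 in both;
- **DIMT** (induced memory): a DIT with DR2/DR1 > 4 in both replicates;
- **DRMT** (repressed memory): a DRT with DR2/DR1 < 1/4 in both.

Thresholds are strict ("more than fourfold") and memory labels are gated
on first-cycle responsiveness. Recovery at WT2 (WT2/WT1 within twofold in
both replicates) is annotated separately.

**Probe design.** For each gene a representative isoform (longest CDS) is
chosen and three 60-nt probes are tiled at 30-bp steps so their union
covers exactly 120 bases: the last 60 bases of the CDS and the first 60
of the 3'-UTR. Alternatively spliced isoforms get their own tiles plus a
probe centered in a *unique exon* (an exon absent from every sibling
isoform). Probes whose exact 60-mer (or reverse complement) occurs in
another gene's transcripts are dropped, keeping at least two tiles per
gene. Organellar genes and selection markers (gfp, gus, hyg, bar, kan)
enter as end-anchored control tiles.

**Statistics.** Per-column percentile background subtraction with a
positive floor, log2 transform, optional between-array quantile
normalization; per-row linear model on condition means with
empirical-Bayes variance shrinkage (moderated t; prior estimated by
closed-form moment matching on log s²), Benjamini–Hochberg adjustment for
the contrasts DR1−WT1, WT2−WT1, DR2−DR1; the screen keeps rows with
adjusted p < 0.05 and |log2 level vs WT1| > 1 at some stage.

**Enrichment and networks.** GO-term over-representation by the
hypergeometric upper tail, with a randomization FDR (random same-size
gene sets, 100 draws) and a signed 0.5–5 heat score for significant
terms; ortholog mapping from BLAST-like tables at score ≥ 70; depth-0
Pearson co-expression networks at |r| ≥ 0.65 with connected-component
clusters and average-linkage Newick trees (d = 1 − r).

## Worked example

Simulate a 500-gene study, preprocess, classify, and test enrichment
(the toy arrays share one distribution by construction, so between-array
quantile normalization is disabled here; see `docs/methods.md`):

```bash
droughtmem simulate --seed 7 --n-genes 500 --outdir demo
droughtmem normalize --matrix demo/raw_matrix.tsv --samples demo/samples.tsv \
    --out demo/normalized.tsv --no-quantile
droughtmem classify --matrix demo/normalized.tsv --samples demo/samples.tsv \
    --out demo/classification.tsv
```

which prints the label counts:

```
{"DIT": 30, "DRT": 31, "DIMT": 10, "DRMT": 10, "non_responsive": 449, "recovered": 464}
```

This simulation planted 30 DITs, 30 DRTs, 10 DIMTs and 10 DRMTs (the
truth table is in `demo/truth.tsv`): the screens recover every planted
induced/memory transcript, with one false-positive DRT. The moderated
statistics and the GO stage:

```bash
droughtmem diff --matrix demo/normalized.tsv --samples demo/samples.tsv --out demo/diff.tsv
# -> 63 significant rows (adj p < 0.05, |level| > 1.0); d0=4.71
droughtmem enrich --sets demo/classification.tsv --anno demo/go.tsv \
    --out-prefix demo/enrich --seed 7
```

`demo/enrich_scores.tsv` then contains the signed heat-score matrix; the
generator's planted term reaches the maximal score in the induced
classes and 0 elsewhere:

```
term_id      DIT   DRT   DIMT  DRMT
GO:PLANTED   5.0   -0.0  5.0   -0.0
```

A co-expression network over the 20 classified memory transcripts:

```bash
droughtmem network --expr demo/normalized.tsv --genes demo/memory_genes.txt \
    --abs-r 0.65 --edges demo/edges.tsv --newick demo/tree.nwk
# -> 190 edges; component sizes [20]
```

The whole chain also runs from one config file
(`droughtmem run --config run.yaml`), writing a manifest with per-output
checksums; reruns with the same seed are byte-identical.

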