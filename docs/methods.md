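# Methods

This note documents the models, rules and numerical choices behind
`droughtmem`, and what the synthetic-data experiments do and do not show.

## Transcript anatomy and probe geometry

Gene models are read from GFF3 (1-based closed intervals) with genome
FASTA. Transcript coordinates are 1-based with position 1 at the 5' end;
on the minus strand the spliced sequence is reverse-complemented so all
probe arithmetic is strand-free. The stop-codon anchor `stop_end_tx` is
the transcript coordinate of the last annotated CDS base; for GFF3
dialects that exclude the stop codon from the CDS, `stop_included=False`
extends the anchor by 3.

The representative isoform per locus is the one with the longest CDS,
ties broken by longest spliced sequence, then lexicographically smallest
transcript id. The rule is deterministic and favors a well-defined stop
codon, which the 3'-anchored design needs.

Tiling places three 60-nt probes stepping 30 nt so that, with at least
60 bases of CDS upstream flank and of 3'-UTR, probe 1 ends on the
stop-codon end and the union covers exactly 120 bases split evenly across
the CDS/UTR boundary. A 3'-UTR shorter than 60 bases shifts the whole
frame upstream so probe 3 ends at the transcript end (preserving three
probes and the 30-bp spacing); any probe whose start would fall before
position 1 is then omitted. Control sequences without a CDS model are
anchored at their 3' end.

A *unique exon* is an exon of the representative whose genomic boundaries
match no exon of any sibling isoform exactly; partial-overlap uniqueness
is a recognized alternative but the exact-boundary test is unambiguous
and directly testable. Unique exons of length ≥ 60 receive one centered
probe.

Cross-hybridization screening flags a probe whose exact 60-mer or its
reverse complement occurs in a transcript of a different gene (same-gene
isoforms exempt). Per gene at most one of the three tiles is dropped: the
two tiles with the fewest cross-matches are kept, ties keeping the lower
transcript start. Near-match screening (k mismatches) is deliberately not
the default; exact matching is reproducible and has a trivial dictionary
oracle, which the tests exploit.

## Intensity model and preprocessing

Raw intensities are treated as strictly positive with an additive
background. Preprocessing defaults: per-column background estimate = 5th
percentile, subtracted and floored at 1.0; log2; between-array quantile
normalization (columns replaced by the across-column mean of order
statistics at their ranks, tie groups receiving the mean of their
rank-range targets). All steps are deterministic; a single-column matrix
is returned unchanged by quantile normalization.

Quantile normalization assumes all arrays share one intensity
distribution. On simulated arrays that assumption holds *exactly* except
for the planted effects, so QN can only redistribute the planted signal;
with a few hundred rows the planted transcripts dominate the extreme
order statistics and QN compresses the second-drought surge (DR2-only
increments map onto rank targets averaged with the unstressed arrays).
For that reason the parameter-recovery experiments (and the worked
example) run the fold-change screens on background-corrected log2 data
with QN disabled (`--no-quantile`, `RunConfig.quantile=False`); on real
scans, where arrays differ by genuine technical effects and responsive
genes are a small fraction of tens of thousands of rows, QN remains the
default and the appropriate choice. The QN implementation itself is
validated against Bioconductor limma's `normalizeQuantiles` and by its
equal-multiset invariant.

## Moderated differential statistics

Per row, condition means are fit for WT1/DR1/WT2/DR2 (two replicates
each); the residual variance s² pools within-condition scatter (d = 4
df). Row variances are modelled as s² ~ s0²·F(d, d0); the prior (d0, s0²)
is estimated in closed form by moment matching on log s² using
digamma/trigamma identities (trigamma inverted by Newton iteration), with
d0 = ∞ when the spread of log s² does not exceed the χ²_d expectation.
The posterior variance is s̃² = (d0·s0² + d·s²)/(d0 + d), the moderated t
is Δ/(s̃·c) with d0 + d degrees of freedom, and p-values are adjusted per
contrast by Benjamini–Hochberg. Limits: d0 = 0 reproduces the ordinary
linear-model t exactly; d0 → ∞ tests every row against the common prior
variance. Both limits and the agreement with limma's `lmFit`/`eBayes` on
identical input are asserted in the tests.

The significance screen keeps rows with adjusted p < 0.05 in at least
one contrast *and* |log2(stage mean) − log2(WT1 mean)| > 1 at some stage;
both cutoffs are parameters.

## Memory taxonomy

Ratios are evaluated per replicate on the linear scale from log2 data;
both replicates must pass ("in two independent experiments"). Thresholds
are strict (> 4, < 1/4). Comparisons are made on the log2 scale with a
1e-9 guard so that a ratio sitting exactly on the boundary — up to float
noise from the log2 round trip — is excluded rather than randomly
included. Memory labels are gated (DIMT ⊆ DIT, DRMT ⊆ DRT); an ungated
DR2-vs-DR1 screen is available behind `gate_on_response=False`.
Control/organellar rows never receive memory labels. The recovery flag
(WT2/WT1 within a twofold tolerance in both replicates) is an annotation
only; the twofold tolerance is this package's choice, since recovery is
descriptive, not a filter.

## Enrichment

Term enrichment is the hypergeometric upper tail P(X ≥ k) over a fixed
universe with flat annotations (no GO-DAG propagation). The
randomization FDR draws R = 100 random gene sets of the query's size,
recomputes all term p-values per draw, and estimates FDR(term) as the
mean count of terms with p' ≤ p_obs(term) divided by the observed count
of terms with p ≤ p_obs(term), capped at 1 and made monotone in the
observed p by a running maximum (so a more significant term never reports
a larger FDR). Terms with FDR < 0.05 in at least one class are kept and
mapped to a signed heat score: 0 when non-significant, otherwise
0.5 + 4.5·(0.05 − FDR)/0.05, i.e. 0.5 at the cutoff and 5 at FDR 0,
negated for repressed-direction classes. The linear form is this
package's construction for the stated 0.5–5 range. Hierarchical
clustering of term score profiles (average linkage, Euclidean) orders the
heat rows; it is presentation-only.

## Co-expression

Ortholog mapping filters a 12-column BLAST-like table at score ≥ 70
(bit-score column by default, configurable) and keeps the best hit per
query (ties → lexicographically smallest subject). Networks use depth-0
semantics: Pearson correlations are computed only within the supplied
gene set, edges kept at |r| ≥ 0.65, clusters are connected components
(largest first). Constant-profile genes are excluded (undefined r). Trees
use d = 1 − r (preserving anti-correlation separation; `use_abs=True`
switches to 1 − |r|), average linkage, and Newick export with each branch
length half the merge-height difference, so two leaves at d = 1 read
`(A:0.5,B:0.5);`.

## Synthetic data

The generator emulates the study design end to end. Genomes: 1–4 exons
per gene, random intron lengths, a CDS ending in a stop codon, 5'-UTRs of
0–100 nt and 3'-UTRs of 0–200 nt (so the probe frame-shift rule is
exercised), both strands; a configurable fraction of genes carries a
second isoform skipping one internal exon, which makes that exon unique
to the representative. Expression: per-transcript baseline log2
intensity ~ N(7.85, 2.0) — anchoring the raw-scale median near 230, the
magnitude typical of this chip class — with drought response of ±3 log2
added in DR1 and DR2, a further ±3 log2 memory increment in DR2 only
(so the DR2/DR1 fold is controlled directly), WT2 at baseline, replicate
noise N(0, 0.25) on the log2 scale, and raw = 2^value + 20 (additive
background). Planted responsive transcripts draw baselines from the upper
intensity range (N(12, 1.5), clipped at 10): drought-repressed memory
genes in this system are abundant photosynthesis transcripts and induced
memory genes reach chip maxima, and a fourfold-times-fourfold repression
is physically unmeasurable from near the array background — placing
planted rows there would test the detection limit, not the taxonomy. GO
annotations: 30 background terms with uniform random membership plus one
planted term containing 80% of the planted memory genes. All generators
are deterministic under a seed.

What the simulations do **not** emulate: probe-level hybridization
physics, dye and spatial artifacts, array-to-array technical effects
(hence the QN caveat above), correlated biological co-regulation beyond
the planted labels, and realistic GO term-size/overlap structure. Passing
recovery tests therefore demonstrates the correctness and calibration of
the screens under the stated noise model, not field performance on scans.

## Problem sizes and defaults

The parameter-recovery study uses n = 500 transcripts + 10 control rows,
2 replicates × 4 conditions, 30/30/10/10 planted DIT/DRT/DIMT/DRMT, 20
seeds; enrichment uses 100 randomizations. The end-to-end pipeline demo
runs at n = 120–500. Oracle-equivalence checks run on ≤ 50 kb
transcriptomes, ≤ 12-gene universes (exhaustive enumeration) and ≤ 100
gene networks. Thresholds default to the study values: fourfold screens,
adjusted p < 0.05, |level| > 1, |r| ≥ 0.65, ortholog score ≥ 70.

## Known limitations

- Cross-hybridization screening is exact-match only by default; a
  mismatch-tolerant screen would need a k-mer neighborhood or alignment
  index.
- The accession-scale headline counts of the motivating study depend on
  its deposited arrays and genome annotation and are not reproduced at
  toy scale; the package reproduces the *rules*, validated on planted
  truth.
- GO annotations are taken as given (no DAG propagation), matching flat
  term tables.
- Depth ≥ 1 network expansion (growing the gene set by neighbors) is out
  of scope; clusters are connected components, not modularity
  communities.
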