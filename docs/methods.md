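# Methods

## Scope and data model

`mitoreg` covers four analysis stages and the generator that feeds
them. All genomic coordinates are 0-based half-open internally (the
BED/narrowPeak convention); GTF input is converted once on read. The
TSS of a `-`-strand gene is `end - 1`, the last covered base, so the
TSS always lies inside the half-open gene span. Chromosome names are
matched exactly — no `chr` aliasing — and peaks on chromosomes absent
from the annotation are dropped with a warning rather than silently
renamed, since name mismatches usually indicate mixed genome builds.

## Screen synergy scoring

Eye scores are ordinal integers 0–5; Index-R is the plain mean of a
genotype's scores normalised to the matched control arm's mean. Means
of ordinal scores are used as-is (no rank transform): the index is a
ratio of averages on a scale the scorer defined to be roughly linear in
eye size. Calling uses the ratio `r = IR_combo / IR_RNAi`:

* enhancer iff `r < s_e` (default `s_e = 0.75`),
* suppressor iff `r > s_s` (default `s_s = 1.5`),
* otherwise none.

Both comparisons are strict, so a point on a threshold line is not a
hit. This matters for calibration: `calibrate_enhancer_slope` returns a
reference gene's own ratio, and comparing on the ratio (rather than on
`IR_combo` against `slope × IR_RNAi`) guarantees the reference lands
exactly on its boundary in floating point. A zero RNAi-arm index leaves
the ratio undefined; the gene is flagged (`undefined_ratio`) and not
called. Lethal genotypes are encoded as score 0 with a `lethal` flag
that propagates to the output.

Genes screened with several RNAi lines are consolidated by the extreme
line — minimum ratio for the enhancer direction, maximum for the
suppressor direction — reflecting screen practice where any scoring
line counts; lines disagreeing in direction yield `none` plus a
`conflict` flag. Group summaries report enhancer fractions per gene
group and a hypergeometric upper-tail enrichment p-value against a
reference group; the p-value is reporting only and never feeds back
into calling.

## Promoter windows and binding

The default promoter window is 2 kb on each side of the TSS,
configurable via `w_up`/`w_down`. The symmetric default matches the
empirical concentration of TF peak summits around the TSS; an
upstream-only window is a one-flag change. `-`-strand windows are exact
mirror images of `+`-strand windows, which the tests verify by
reflecting whole instances. Assignment requires ≥ 1 bp overlap of the
*peak interval* with the window — summits are used only for the
genomic-distribution and TSS-profile summaries, where classification
priority is promoter > gene body > intergenic. `gene_region` mode uses
the gene span extended `w_up` upstream of the TSS, for whole-gene
("genomic region") binding statements. Interval lookup uses an interval
tree; a quadratic all-pairs scan is kept in the test suite as the
independent oracle.

Coverage statistics are computed on the intersection of a gene set
with the matrix's universe; "binds more than half of the set" is
strict (`> 0.5 · |set ∩ universe|`).

## Vertex-sort hierarchy

The TF–TF graph is condensed over SCCs (Tarjan via networkx, checked
against transitive-closure mutual reachability on small graphs).
Supernode classification:

* **top** — condensation source with outgoing edges, but only if it is
  a singleton without a self-loop. An SCC of size ≥ 2, or a self-looped
  node, has upstream regulators (its members, or itself) by definition
  and is therefore never top; a self-loop-only singleton is classified
  core, not isolated, for the same reason.
* **bottom** — condensation sink with incoming edges (SCCs allowed).
* **isolated** — no edges at all.
* **core** — everything else; this is what "middle layer" refers to.

Levels are longest-path positions on the condensation DAG:
`level_min` is the longest path (in edges) from any source supernode,
and `level_max = (H − 1) − (longest path to any sink)`, with `H` the
number of levels (longest source-to-sink path + 1). Longest paths are
computed by dynamic programming over a topological order; exhaustive
path enumeration on ≤ 8-node DAGs is retained as a test oracle. All
orderings (SCC ids, table rows, edge lists) are sorted by node name so
outputs are byte-stable.

`indirect_targets(tf)` returns genes bound by `tf`'s downstream TFs
but not by `tf` itself, with per-gene provenance (which downstream TF
binds it). When a DEG table is supplied the downstream TFs are first
filtered to those whose encoding gene is differentially expressed. The
focal TF's own gene is excluded from the indirect set: the knocked-out
locus is the perturbation, not one of its targets.

## DEG classification and integration

`down` iff `log2fc < −1` and `q < 0.05`; `up` symmetrically; otherwise
`ns`. Both thresholds are strict, matching the usual reading of
"more than two-fold at FDR 0.05", and both are parameters
(`DEGClassParams`). Genes missing from the DEG table count as `ns`
rather than being dropped, so the fractions reported against a gene
inventory keep inventory-based denominators. Missing q-values also map
to `ns` with a flag. Overlap enrichment is the exact hypergeometric
upper tail (`scipy.stats.hypergeom.sf`), checked against combinatorial
enumeration for all universes ≤ 12. DESeq2-style model fitting is out
of scope: DEG tables are inputs.

## The synthetic generator

The generator emulates the *structure* of the real inputs, not their
sequence content:

* **Annotation** — genes packed without overlap, TSSs ≥ 5 kb apart, a
  configurable fraction labelled mitochondrial (default 0.25, half of
  those tagged Mito-EBR). The spacing floor means default promoter
  windows of neighbouring genes cannot swallow each other's planted
  peaks, which is what makes zero-noise recovery exact.
* **Hierarchy** — explicit layer counts (default 2 top / 6 core / 3
  bottom) with planted core SCC cycles (default one 3-cycle) plus
  chance chords; all other edges run strictly downward, so planted
  tops are exactly the condensation sources and bottoms the sinks.
* **Peaks** — one peak per true target with the summit at the TSS
  (jitter SD 50 bp under noise), width U(150, 400) bp, per-target
  false-negative rate 0.05, Poisson(10) background peaks per TF, and
  higher signalValues for true peaks than background. TF-encoding genes
  are drawn from non-mitochondrial genes and excluded from the random
  target pool so no unplanned TF–TF edges arise.
* **DEG table** — direct targets at log2fc ~ N(−2, 0.4), indirect at
  N(−1.5, 0.4), null at N(0, 0.4); affected genes get q = 10^−U(3,8),
  null genes q ~ U(0,1). q-values are generated directly rather than
  via a count model because the pipeline consumes the statistic, not
  reads.
* **Screen** — latent eye size = control mean × per-gene severity
  U(0.7, 1.0), with the combined arm additionally multiplied by the
  synergy factor (default 0.5) for planted hits; scores are
  clamp(round(latent + N(0, 0.5)), 0, 5) over 30 flies per arm.
  Control means are 5.0 (RNAi arm) and 4.5 (combined arm — mtDNA
  deficiency alone mildly reduces eye size). Over the default severity
  range the integer rounding keeps every null ratio strictly inside
  (0.75, 1.5) and every synergy ratio below 0.75 even at zero noise,
  so zero-noise calls are exact by construction, not by luck.

One global seed drives everything through per-stage
`SeedSequence.spawn` substreams, so identical configs emit
byte-identical files and stages can be regenerated independently.

### What the benchmarks do and do not show

Zero-noise recovery demonstrates that the pipeline's bookkeeping —
windows, matrix, condensation, set algebra, normalisation — is exact;
it says nothing about robustness to the correlated noise of real ChIP
(open-chromatin bias, replicate disagreement) or real screens
(batch-varying expressivity), which the generator does not model. The
noisy-mode checks cover independent per-observation noise only. The
power experiment (synergy factor 0.6, score SD 0.5, 30 flies/arm, 500
replicates) shows the enhancer call is conservative and powerful under
those conditions; real screens with weaker knockdowns or coarser
scoring will do worse. Problem sizes throughout (default 300 genes,
11 TFs; oracle checks up to 10⁴ peaks × 10³ genes) were chosen as the
smallest at which every structural feature — multi-chromosome
annotations, SCCs, all four layers, both DEG effect tiers — is
exercised.

## Numerical and design choices

* Strict inequalities at every published threshold (slopes, FDR,
  fold-change); boundary cases are `none`/`ns` by construction.
* Modifier calls compare on the combo/RNAi ratio so threshold points
  are exact in floating point.
* Hypergeometric tails go through `hypergeom.sf(k−1, …)`, avoiding
  1 − CDF cancellation.
* Ties and orderings are resolved by lexicographic node/gene names
  everywhere; outputs of every stage are deterministic.
* Degenerate inputs (zero control mean, empty gene sets, empty
  universes, unmapped TFs) raise typed errors or warn-and-continue as
  documented per function; the pipeline runner converts stage failures
  into recorded skips rather than aborting the run.

## Known limitations

* The promoter definition behind whole-compendium coverage numbers is
  a modelling choice (symmetric 2 kb); upstream-only definitions can
  change gene-level coverage by a few percent on real data.
* `gene_region` mode approximates "the genomic region of a gene" as
  span + upstream extension; it is not a nearest-gene annotator.
* Gene-level consolidation of multi-line screens (extreme line wins)
  is one of several defensible rules; per-line tables are always
  emitted so other rules can be applied downstream.
* Level spans use the longest-path formulation of vertex sort;
  variants that enumerate all topological orders can assign wider
  spans to weakly constrained nodes.
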