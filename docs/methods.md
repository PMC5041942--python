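# Methods

`mircross` re-implements, as a tested pipeline, a network analysis of
miRNA-regulated pathway crosstalk across tumor grades: which pathways do
differentially expressed miRNAs repress through their targets, which
pathway pairs show coordinated dysregulation, and can the resulting module
signature stratify patient survival.  Because the original cohort data
(grade-annotated matched miRNA/mRNA expression) is not redistributable, the
pipeline ships a synthetic-data generator that plants every layer of
structure the analysis is supposed to find, so each stage can be validated
against a known ground truth.

## The analysis chain

**Differential calling.**  Grade II samples are controls; grade III and
grade IV cases are compared against them feature by feature with an
unpaired pooled-variance Student's t-test (Welch's correction available via
`t_variant="welch"`).  Benjamini–Hochberg adjustment is applied within each
(feature kind, contrast) family and features are called at FDR < 5%
(`alpha`).  Direction is *up* iff the case mean exceeds the control mean.
Features that are constant and identical in both groups have an undefined
statistic; they are retained with p = 1 (rather than dropped) so the gene
universe N used by the enrichment stage does not drift.

**Signature pairs.**  A predicted miRNA→gene pair becomes a signature pair
for a contrast when both partners are differential in that contrast with
opposite directions and their expression is inversely correlated:
Pearson r ≤ −0.4 with two-sided p < 0.05 from the t transform
t = r·√((n−2)/(1−r²)).  Correlation is computed over grade II plus the
contrast's case samples (`correlation_samples="per_contrast"`, the
self-contained choice; `"all"` uses every sample).

**miRNA–pathway network.**  For each (miRNA, contrast), the miRNA's
inversely correlated target set is tested against every pathway with the
cumulative hypergeometric law

&nbsp;&nbsp;&nbsp;&nbsp;p = P(X ≥ m), X ~ Hypergeom(N, M, n),

with N the universe (measured genes annotated to ≥ 1 pathway by default;
`universe="measured"` uses all measured genes), M the pathway size, n the
target-set size and m the overlap.  Relations with p < 0.05 become edges of
a bipartite network; pathway nodes inherit a grade association (III / IV /
both) from the contrasts that contribute their edges.  Some presentations
of the cumulative test write the sum with an upper bound that corresponds
to P(X > m); both tails are implemented (`tail={"ge","gt"}`) with the
standard enrichment convention `ge` as default.  No multiplicity correction
is applied to these enrichment p-values — the operating point is a raw 0.05
threshold — though `bh_adjust` can be applied by callers who want it.
Hub miRNAs are the top 15% by degree, ties at the cut included (the
inclusive rule is deterministic; with 60 untied miRNAs it yields 9 hubs).

**Pathway crosstalk.**  Candidate pathways are those enriched (same
hypergeometric test, p < 0.05) by the per-contrast unions of signature
target genes, split by gene direction — four groups in all; each retained
pathway carries the grade(s) and direction(s) that selected it.  For a
pathway pair (i, j), every PPI edge (a, b) with a ∈ i, b ∈ j and both
genes differential contributes a Fisher's-method interaction strength

&nbsp;&nbsp;&nbsp;&nbsp;w(a,b) = −2·(ln P(a) + ln P(b) + ln P(a,b)),

where P(a), P(b) are differential t-test p-values and P(a,b) is the
correlation p-value of the two genes' expression over all samples.  The
pair's crosstalk weight is Σ w over qualifying edges, each unordered edge
counted once even when the pathways overlap.  P-values below 1e−300
(`log_floor`) are clipped so the statistic stays finite.  A gene
significant in either contrast enters with the smaller of its two contrast
p-values; the analysis builds one network spanning both contrasts, and the
contrast-resolved alternative is a caller-side filter away.

**Permutation null.**  Significance comes from gene-set resampling: both
pathways' differential-gene sets are replaced by uniform without-replacement
same-size draws from the pooled differential genes, the weight is recomputed,
and perm_p = (r+1)/(B+1) with r the count of permuted weights ≥ observed.
The pseudo-count form is used because the raw exceedance frequency can
return 0, which is not a valid p-value.  Both sets are redrawn jointly by
default (`randomization="joint"`); `"single"` holds one side fixed.  The
default B is 1000; the statistic is implemented so that B up to 1e6 is
tractable (per-edge strengths over the pool are precomputed once and each
permutation reduces to a boolean masked sum).  Pairs with observed weight 0
are assigned perm_p = 1 without drawing, which is exact under the
pseudo-count formula.  Pairs with perm_p < 0.05 form the crosstalk network.

**Modules.**  Biclique modules of the miRNA–pathway network — maximal
complete bipartite subgraphs — are enumerated via the reduction to maximal
cliques: adding all within-side edges makes the maximal cliques with both
sides nonempty exactly the maximal bicliques.  Size floors default to 1×1
so single-miRNA modules remain representable.  Crosstalk communities use
k-clique percolation (k = 3 by default, the smallest nontrivial choice;
configurable): two k-cliques are adjacent when they share k−1 pathways, and
a community is a connected component of that relation.  The *core module*
is the community containing an anchor pathway (the pipeline anchors at the
highest-degree node, ties broken lexicographically) plus "indirect route"
pathways: non-members adjacent to at least two community members.  Modules
get deterministic sequential IDs after lexicographic sorting.

**Survival.**  The survival signature is the set of signature-pair target
genes annotated to core-module pathways plus the miRNAs with network edges
into those pathways.  Samples are clustered into two groups by K-means
(k = 2, 10 seeded restarts) on the per-feature standardized signature
expression — standardization is needed because the gene and miRNA layers
sit on different scales and would otherwise contribute unequally to
Euclidean distance.  Kaplan–Meier curves are estimated per group (grouped
product-limit tie handling); the group with the smaller median — smallest t
with S(t) ≤ 0.5, with mean observed time as tie-break — is labeled *short*;
separation is tested with the two-group log-rank test (1 df).  Gene-only
and miRNA-only modes reproduce the single-layer comparisons.  Heatmap
orderings cluster samples within each grade (complete linkage, Euclidean),
keep grades contiguous II→III→IV, and cluster features across all samples.

## The synthetic cohort

Defaults emulate a 160-sample three-grade glioma-like cohort: 63 / 33 / 64
samples in grades II / III / IV, 150 miRNAs, 600 genes, 30 pathways of 40
genes (overlapping membership allowed).  The feature and pathway space is
deliberately a scaled-down panel relative to genome-wide profiling; this
keeps every stage, including the permutation null, runnable in seconds
while preserving the relative proportions that matter (30% of genes
differential per contrast, pathway-sized gene sets, sparse PPI).

Planted structure, all on log2 scale with Normal(0, `noise_sd`=0.5)
residuals:

* **Differential features** — per contrast, 30 miRNAs and 180 genes with a
  ±2 log2-unit (`effect_size`) case-grade mean shift, directions
  alternating; contrasts use disjoint feature blocks.
* **miRNA→target coupling** — each planted miRNA drives
  `n_targets_per_mirna`=3 target genes with slope `coupling_beta`=−0.8, so
  targets are inversely correlated with their miRNA and shift in the
  opposite direction; the remaining planted genes get direct shifts.
* **Pathway enrichment** — `mirnas_per_pathway`=3 same-(contrast,
  direction) miRNAs share a pathway home holding all their targets (nine
  planted members per enriched pathway), which plants both the per-miRNA
  and the union-group enrichment the selection stages test.
* **Crosstalk** — 5 disjoint pathway pairs receive inter-pathway PPI edges
  among their differential genes at 5× the background density
  (`baseline_ppi_density`=0.05).  Differential members of these pathways
  are kept exclusive to them: membership overlap would otherwise leak the
  dense blocks into unrelated pathway pairs and break the exchangeability
  the permutation null relies on.
* **Survival** — a latent two-group risk factor (fair-coin assignment,
  independent of grade) loads on every planted miRNA
  (`risk_factor_loading`=1.0 log2 units; targets inherit it through the
  coupling) and scales the exponential event-time hazard by
  `hazard_ratio`=3 around a 30-month baseline median.  Censoring times are
  uniform on [0, h] with h solved numerically so the expected censored
  fraction equals `censoring_rate`=0.2 under the hazard mixture.

The target-pair list contains every planted couple plus an equal number of
decoy pairs drawn uniformly from non-differential miRNAs × non-differential
genes, giving the correlation filter measurable specificity.  The written
PPI file also includes sub-threshold (score < 900) rows that the reader's
combined-score filter must drop.  Identical (config, seed) produces
byte-identical files.

What the generator does *not* emulate: batch effects, grade-dependent
censoring, heavy-tailed expression noise, correlated background PPI
topology (hubs, modules), realistic miRNA nomenclature, or target-prediction
biases.  Passing tests therefore demonstrate the statistical machinery is
correct and calibrated under the planted model, not that the biological
conclusions of any particular cohort transfer.

## Numerical choices and degenerate inputs

* Correlation of a constant vector is undefined: reported as (r=0, p=1)
  with a warning.  Correlation p-values are floored at the smallest
  positive double; Fisher's-method inputs are clipped at `log_floor`.
* BH adjustment of an empty vector returns an empty vector; inputs outside
  [0,1] are errors, not clipped.
* Zero pooled variance with distinct means yields t = ±∞ and the smallest
  representable p (maximally significant), matching the limit.
* K-means restarts keep the best within-cluster sum of squares; the seed
  fixes the restart stream, so runs are reproducible.
* Permutation RNG streams are spawned per pathway pair from the stage seed,
  so results do not depend on pair iteration order.
* All writers sort rows and use a fixed float format; two runs with the
  same seed are byte-identical (manifests exclude the output location).

## Problem sizes used by the test suite

Oracle tests run exhaustive enumeration where it is exact: all
hypergeometric configurations with N ≤ 12, brute-force subset enumeration
for bicliques and k-clique communities on graphs of ≤ 12 vertices, and a
naive double loop for pair weights.  Monte-Carlo checks use the default
cohort (permutation calibration over 435 pathway pairs at B = 200; planted
crosstalk recovery at B = 500; 50 replicates for FDR control and the
survival chain).  These sizes were chosen so the whole suite completes in
about a minute while keeping the binomial/KS error bars well inside the
asserted margins.

## Known limitations

* The permutation null's calibration assumes pathway membership is
  exchangeable with the differential-gene pool; strongly nested or
  hierarchical pathway collections (as in real KEGG) violate this and make
  the test conservative or anticonservative pair by pair.
* Fisher's method treats the three p-values per edge as independent, which
  the differential and correlation statistics are not; the permutation
  null absorbs this at the pair level but the per-edge weights themselves
  are not calibrated quantities.
* Enrichment p-values are thresholded raw, by design fidelity; with many
  pathways this admits the expected number of false relations.
* The survival stage assumes the two-group K-means split is the relevant
  stratification; it does not search over k or regularize feature choice.
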