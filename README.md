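# mircross

Pipeline for dissecting miRNA-regulated **pathway crosstalk** in tumor
progression, with a planted-structure simulator for end-to-end validation.

Tumor progression is rarely driven by a single pathway: miRNAs repress sets
of target genes that sit in different pathways, and the coordinated
dysregulation of pathway *pairs* carries prognostic signal that single
pathways miss.  `mircross` implements the full analysis chain for a cohort
with matched miRNA and gene expression across tumor grades (II / III / IV,
grade II serving as control):

1. **Differential calling** — unpaired Student's t-test per grade contrast,
   Benjamini–Hochberg FDR < 5% per (feature kind, contrast) family.
2. **Signature pairs** — predicted miRNA→gene pairs, both partners
   differential with opposite directions, inversely correlated with
   Pearson *r* ≤ −0.4 (p < 0.05).
3. **miRNA–pathway network** — cumulative hypergeometric enrichment of each
   miRNA's inversely correlated targets,
   `p = P(X ≥ m), X ~ Hypergeom(N, M, n)`; edges at p < 0.05; hub miRNAs =
   inclusive top 15% by degree.
4. **Pathway crosstalk** — for differential genes a ∈ pathway i, b ∈
   pathway j linked in a protein–protein interaction network
   (combined score ≥ 900), Fisher's-method interaction strength
   `w(a,b) = −2(ln P(a) + ln P(b) + ln P(a,b))`
   summed over edges; significance from B gene-set resamplings of the
   differential-gene pool, `perm_p = (r+1)/(B+1)`; network edges at
   perm_p < 0.05.
5. **Modules** — maximal bicliques of the miRNA–pathway network; k-clique
   percolation (k = 3) communities of the crosstalk network; a core module
   around an anchor pathway with its bridge pathways.
6. **Survival** — K-means (k = 2) on standardized core-module signature
   expression, Kaplan–Meier curves, log-rank test.

Because grade-annotated cohort data is not redistributable, the
`synthdata` module generates all five inputs (expression matrices, sample
annotation with survival, target-pair list, scored PPI edge list, GMT gene
sets) with known planted structure — differential shifts, negative
miRNA→target coupling, pathway enrichment, dense inter-pathway PPI blocks,
and a two-group hazard difference — so every stage is testable against
ground truth.  See `docs/methods.md` for the model, parameters and
limitations.

## Worked example

The numbered drivers under `analysis/` run the stages in order on a
simulated cohort (63/33/64 samples in grades II/III/IV, seed 1), writing
tables to `results/pipeline/`:

```bash
python analysis/01_simulate.py
python analysis/02_differential.py
...
python analysis/07_survival_stratification.py
```

Selected output:

```
miRNA III_vs_II: 30 significant (15 up, 15 down) of 150
gene  III_vs_II: 188 significant (93 up, 95 down) of 600
planted miRNA recovery III_vs_II: 100.0%

III_vs_II: 90 pairs, 30 miRNAs, 90 genes   (planted recovery: 100.0%)
decoy false positives: 0.0% of 180 decoys

network: 60 miRNAs, 24 pathways, 71 edges
hub miRNAs (10): miR-0031, miR-0034, ...

candidate pathways: 24; scored pairs: 276; significant crosstalk edges: 27
planted pairs among candidates: 5 of 5; significant: 5 of 5

biclique modules: 31
clique-percolation communities (k=3): 1
core module around PW003: 9 community pathways, 1 bridge pathways

groups: 85 short vs 75 long survivors
median survival: 9.47 vs 30.98 months
log-rank: chi2 = 31.32, p = 2.19e-08
agreement with planted risk groups: 100.0%
```

Reading: the t-test stage recovers all 60 planted differential miRNAs; the
inverse-correlation filter keeps all 180 planted miRNA→target couples and
none of the 180 decoys; all five planted crosstalk pathway pairs are
significant under the permutation null; and clustering on the core-module
signature splits the cohort into groups whose survival medians differ
threefold (the planted hazard ratio is 3), with the split matching the
planted risk groups exactly.

The same stages are available as a CLI over a shared YAML config
(precedence: flags > file > defaults):

```bash
mircross all --outdir results/run1 --seed 1
mircross crosstalk --config my.yaml -B 100000
```

Each stage writes a manifest (config snapshot, seed, input checksums);
identical config + seed reproduces every output byte for byte.

## Layout

```
src/mircross/     library: synthdata, io, diffexpr, regnet, crosstalk,
                  netmodules, survival, pipeline, cli
analysis/         numbered narrative drivers over the library
scripts/          acceptance.py
tests/            pytest suite (unit, property and end-to-end tests)
docs/methods.md   model, parameter and design documentation
```
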