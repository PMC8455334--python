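# netsig

Network-guided discovery of blood gene-expression signatures that classify
year-by-year growth response to recombinant human growth hormone (r-hGH) in
two paediatric conditions — growth hormone deficiency (GHD) and Turner
syndrome (TS) — implemented as a tested, reusable pipeline and exercised on
synthetic cohorts with planted ground truth.

## Who this is for

Prediction of r-hGH response from baseline clinical phenotype (age, weight
SDS, birthweight SDS, distance to target height, GH peak) explains roughly
half of the variance in first-year height velocity.  The strategy
implemented here asks whether baseline *blood transcriptome* adds
predictive value, and — because the differentially expressed gene lists of
GHD and TS overlap only weakly — whether the two conditions nonetheless
share *network modules* whose member genes can serve as a common
classification signature.  The package is for methodologists who want to
study, stress-test or extend that discovery strategy with full control of
the ground truth.

## The pipeline

For each condition and treatment year (height velocity `hv1..hv5`, cm/yr):

1. **Association scan** — covariate-residualized rank regression of each
   gene's expression on the year's height velocity (batch, age, baseline
   BMI; sex and GH peak in GHD; Tanner stage per year).  Both sides are
   residualized by OLS, midrank-transformed, and tested with the 1-df
   nested-model F statistic (exact permutation p at very small n).
   Genes at p < 0.01 become network *seeds*.
2. **Seed network** — induced subgraph of the interactome on seeds plus
   their first neighbours.
3. **Overlapping modules** — an influence landscape
   `influence(v) = Σ_{d(s,v)≤depth} λ^d` (λ = 0.5, depth = 3) whose local
   maxima seed overlapping modules (walk-count basins, modularity
   consolidation, label-propagation membership).  Each module's *metanode*
   is its 10 most central genes; the union of metanodes is the network's
   functional core.
4. **Signature** — the year's GHD and TS cores are intersected
   (hypergeometric overlap test); shared genes associated at p < 0.05 in
   either condition form the year's classification signature.
5. **Classification** — low- and high-response quartiles (⌊n/4⌋ rule)
   classified by a 1000-tree random forest with SMOTE rebalancing inside
   each bootstrap, reporting out-of-bag (OOB) error and AUC with DeLong
   95% CI, for clinical features alone vs clinical + signature expression;
   BORUTA shadow-feature selection confirms signature genes; PLS-DA and
   DAPC provide ordination views.
6. **Methylation** — gene-level (median) beta values scanned against
   response (exact rank test at n = 6), tallying the share of negative
   associations (hypermethylation at low response) and mapping signature
   genes at |Spearman r| > 0.3.

Genotype association (Kruskal–Wallis under genotypic/dominant/recessive
models with LD-block-aware Bonferroni and Benjamini–Hochberg FDR, X-marker
hemizygosity handling) is provided alongside.

The synthetic-data generator (`netsig.simulate`) is first-class, tested
code: it plants a 60-gene interactome module whose members load on a latent
biological response component, calibrates clinical covariates to explain a
requested variance share (defaults 0.61 GHD / 0.46 TS), reproduces the
declining year-1→5 height-velocity profile with dropout, and emulates
LD-blocked genotypes and hypermethylation-skewed methylation.  See
`docs/methods.md` for the full model and its limits.

## Worked example

Run the full default-scale experiment (8,000 genes, n = 70 GHD + 43 TS,
planted 60-gene module) from Python:

```python
from netsig.io import PipelineConfig
from netsig.pipeline import run_pipeline

config = PipelineConfig(rf_trees=300)   # default study scale, lighter forest
manifest = run_pipeline(config, seed=1)

for year, sig in manifest.signatures.items():
    print(f"year {year}: shared core {len(sig.shared):2d} genes, "
          f"signature {len(sig.genes):2d}, overlap p = {sig.overlap_p:.2e}")
```

prints

```
year 1: shared core 12 genes, signature 12, overlap p = 1.82e-13
year 2: shared core 13 genes, signature 12, overlap p = 1.01e-16
year 3: shared core  7 genes, signature  6, overlap p = 3.47e-07
year 4: shared core 10 genes, signature  8, overlap p = 3.18e-09
year 5: shared core  6 genes, signature  5, overlap p = 2.67e-07
```

— the GHD and TS network cores overlap far beyond chance in every year
(universe: the genes present in both the expression matrix and the
interactome), exactly the cross-condition convergence the design looks
for.  The recovery scores against the planted truth,

```python
for k, v in manifest.recovery.items():
    print(f"{k}: {v:.3f}")
```

```
signature_sensitivity: 0.467
signature_precision: 0.966
signature_union_size: 29.000
mean_delta_auc: 0.079
uplift_fraction: 0.750
methyl_negative_share: 0.500
```

read as: the union of the five yearly signatures contains 29 genes, 96.6%
of which are genuinely planted (precision), covering 46.7% of the planted
module (sensitivity — bounded by the 10-gene metanode rule, see
`docs/methods.md`); adding the signature to clinical features raises the
OOB AUC by +0.08 on average across the 20 condition × year × quartile
classification cells, with an improvement in 75% of them.  Per-cell
metrics live in `manifest.classification`, e.g.

```
GHD year-1 low quartile, clinical                 AUC 0.757 (0.634-0.881), OOB error 0.229
GHD year-1 low quartile, clinical+transcriptome   AUC 0.729 (0.562-0.896), OOB error 0.186
```

The same run is available from the shell:

```
netsig run --seed 1 --outdir results/run1
netsig simulate --seed 1 --outdir data/     # just the synthetic inputs
```

`netsig associate | netmod | signature | classify | methyl` expose the
individual stages over the written TSV/JSON files.

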