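# repact

Disease-trajectory regression and intra-donor vs inter-donor heterogeneity
decomposition for single-cell RNA-seq and single-nucleus ATAC-seq cohorts.

## The problem

In diseases like type 2 diabetes, affected cell types (e.g. pancreatic
β-cells) rarely split into discrete "sick" subpopulations: the molecular
differences between health and disease are continuous, subtle, and easily
masked by donor-to-donor variation, and cohorts contain only a handful of
donors. This package implements a trajectory-based analysis for that
setting, for computational biologists working with case/control single-cell
cohorts:

1. **Disease trajectory (RePACT).** Cells are embedded (PCA on the 500 most
   dispersed genes for RNA; TF-IDF + LSI for ATAC) and a ridge-penalized
   logistic regression of the binary phenotype on components 1–10 defines a
   per-cell *disease pseudo-index* p̂(c) = σ(β₀ + βᵀx_c) ∈ [0, 1], ranking
   every cell from healthy-like to disease-like.
2. **Trajectory features.** Cells are grouped into 20 equal-width
   pseudo-index bins; per feature, the per-bin mean profile is regressed on
   the bin positions (occupancy-weighted least squares), with Storey
   q-values across features. Genes at q < 0.05 are trajectory genes; ATAC
   peaks at q < 0.01 with z-scored-profile |slope| > 0.5 gain or lose
   accessibility.
3. **Intra- vs inter-donor decomposition.** Each donor's cells are
   re-binned over that donor's own index range and re-tested, and the
   per-donor p-values are combined with Fisher's method,
   −2 Σₖ log pₖ ~ χ²(2k). Trajectory features with combined q < 0.01
   (heterogeneity score −log₁₀ q > 2) vary reproducibly *within* donors
   (intra-donor heterogeneous); the rest differ only *between* donors.

Around this core: the hormone-based doublet and consistency filters, snATAC
cell QC, CCA co-embedding with RBF-SVM label transfer and a weighted-KNN
unambiguity filter, pseudo-bulk RPKM peak specificity with K-means
clustering, binomial motif/gene-set enrichment, three-mode peak–gene
linking (TSS proximity ≤ 10 kb, cross-cell-type correlation r > 0.7 within
1 Mb, chromatin loops), regulatory-circuit reconstruction with
Fisher's-exact category enrichment, and TF-target prediction. A seeded
synthetic-cohort generator with planted intra/inter/null features makes
every stage testable offline.

## Worked example

```python
import repact

cfg = repact.CohortConfig(seed=1)            # 4+4 donors x 400 cells, 2000 genes
rna, atac, cells, truth = repact.generate_cohort(cfg)

genes = repact.select_informative_genes(rna, n=500)
embedding = repact.pca_embed(rna, genes, n_components=10)
phenotype = cells.phenotype_of(rna.cell_ids)

result = repact.RePACT(embedding, phenotype).fit()
print(result.summary())

trends = result.test_features(rna)
calls = repact.call_trajectory_genes(trends, q_cut=0.05)
called = calls["up"] + calls["down"]
het = repact.heterogeneity_analysis(rna, result, cells, trends, called)
```

The summary shows the fitted trajectory:

```
Disease trajectory (ridge-logistic on embedding components)
  cells: 3200  (disease: 1600, healthy: 1600)
  components used: 1-10   ridge: 1
  intercept: -0.0833
  coefficients:
    comp1    0.3782
    comp2    0.2194
    comp3   -0.0255
    ...
  pseudo-index: min 0.0033  median 0.4980  max 0.9853
  mean pseudo-index (disease): 0.8691
  mean pseudo-index (healthy): 0.1309
```

Disease cells sit high on the pseudo-index and healthy cells low, with a
continuous spread in between — the within-donor part of that spread is what
the decomposition exploits. The trend test calls 159 up- and 157
down-regulated trajectory genes (this cohort plants 150 of each), and the
Fisher decomposition splits them into the four categories:

```
inter_up      84
inter_down    82
intra_up      75
intra_down    75
```

matching the planted design (75 intra-up, 75 intra-down, and the inter
features split likewise). The top-scoring features are unambiguous:

```
 feature   p_combined     score category
gene1269 1.062243e-33 29.749053 intra_up
 gene575 4.332364e-31 27.439582 intra_up
gene1975 6.777044e-31 27.421358 intra_up
```

`result.plot_pseudo_index(cells)` draws the per-donor pseudo-index violins.
The same flow runs for ATAC via `tfidf_transform` → `lsi_embed` →
`RePACT(...).fit()` → `test_features(atac, scale="zscore")` →
`call_trajectory_peaks`.

A command-line interface drives the same stages on on-disk artifacts
(MatrixMarket matrices, TSV tables, BED/BEDPE/FIMO/GMT inputs):

```sh
repact-suite simulate --seed 1 --outdir run/
repact-suite embed --modality rna --indir run/ --outdir run/
repact-suite repact-rna --indir run/ --outdir run/
repact-suite intra-donor --modality rna --indir run/ --outdir run/
```

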