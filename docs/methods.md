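# Methods

## The model

The package analyses case/control single-cell cohorts (scRNA-seq and
single-nucleus ATAC-seq) in which disease acts through a continuous latent
cell state rather than a discrete subpopulation. The analysis has three
layers.

**1. Disease trajectory.** Cells are embedded in a low-dimensional space —
PCA of the normalized expression of the most dispersed genes for RNA
(components 1–10), latent semantic indexing (TF-IDF followed by truncated
SVD, 50 components, of which 1–10 are used) for ATAC. A logistic regression
of the binary phenotype on the leading components defines the direction of
maximal phenotype association; each cell's fitted probability is its
*disease pseudo-index*, ranking cells from healthy-like to disease-like.
The logistic fit carries a ridge penalty on the slopes, parameterized *per
cell* (total penalty `ridge · n · ‖β‖²/2`, default `ridge = 1`). This is a
substantive choice, not a numerical nicety: donor-structured cohorts are
typically linearly separable in the embedding (each donor forms a tight
cluster), and a weakly penalized fit saturates the pseudo-index at {0, 1},
destroying the binned analysis downstream. An O(1) per-cell penalty keeps
the index continuous while preserving its ranking; the fit itself is
Newton/IRLS from a zero start, so it is deterministic and exactly
antisymmetric under label reversal.

**2. Trajectory features.** Cells are grouped into 20 equal-width
pseudo-index bins; each feature's per-bin mean profile is regressed on the
bin positions, and the slope's two-sided t-test p-value is adjusted to
q-values (Storey's smoothed-π₀ estimator; Benjamini–Hochberg available).
Genes with q < 0.05 are trajectory genes, split into up/down by slope sign.
For ATAC, each peak's 20-bin profile is z-scored and regressed against bin
positions rescaled to [0, 1], so the gain/loss thresholds (q < 0.01 and
|slope| > 0.5) are scale-free. Per-cell motif-deviation matrices
(chromVAR-style, computed elsewhere) are tested with the same machinery on
raw per-bin means.

**3. Intra- vs inter-donor decomposition.** For every donor separately, the
donor's cells are re-binned into 20 equal-width bins over that donor's own
pseudo-index range and the same trend regression is run, giving a per-donor
p-value. Fisher's method combines them: the statistic −2 Σₖ log pₖ is
referred to the χ² distribution with 2k degrees of freedom (evaluated by
the exact even-df survival; a single p is returned unchanged). Trajectory
features whose combined q-value falls below 0.01 trend reproducibly
*within* donors (intra-donor heterogeneous); the rest vary between donors
only (inter-donor). The heterogeneity score is −log₁₀ of the combined
q-value, so the classification cutoff sits at a score of 2; together with
the global direction this yields the four categories intra/inter × up/down.

## Statistical guards in the trend tests

Three places where the naive estimator is misleading at realistic cohort
sizes, and what the package does about them. All three are exposed as
options and can be switched off to recover the plain estimator.

**Occupancy-weighted regression** (`weighted=True`). Equal-width binning of
a skewed pseudo-index leaves tail bins with a handful of cells. A bin
mean's sampling variance scales as 1/n, so unweighted least squares treats
the noisiest points as exact; on permuted-index data the unweighted test
yields ~12% of p-values below 0.05 at donor scale. Weighting each bin by
its cell count restores calibration (~5–6%).

**Control-feature size factors** (`size_factors="auto"`). Every raw count
scales with the cell's capture depth, and the fitted index is never
perfectly depth-free, so raw-count trends conflate biology with depth.
Dividing by total counts instead couples every feature to the trajectory-
responsive content of the cell (a feature flat in absolute expression
acquires a relative-abundance trend). The compromise: size factors from the
summed counts of features *outside* the embedding basis, refined by a
second pass that also excludes first-pass trajectory calls. These track
technical depth while being insensitive to the trajectory.

**Leave-one-out pseudo-index** (`leave_one_out=True`). The pseudo-index is
estimated from the same cells it ranks. A feature that entered the
embedding therefore correlates with its own noise along the trajectory; in
the per-donor tests Fisher's method amplifies even mild anticonservativeness
eightfold. Because the index is linear in the embedding basis
(η = β₀ + basis · w with w = loadings · β), each tested feature's own term
can be subtracted exactly before that feature's binning. Features outside
the basis are untouched.

**Fisher q-values over the full universe** (`qvalue_universe="all"`). The
globally called set is *selected* for association with the trajectory, so
adjusting the combined p-values only within it double-dips the selection:
in null data the handful of leaked calls would classify intra almost by
construction. Adjusting against all tested features restores honest
multiplicity; cohorts with genuine intra-donor structure supply enough
small combined p-values that borderline true features remain called. The
per-call restriction remains available (`"called"`).

## The synthetic cohort generator

`generate_cohort` emulates the structure the decomposition assumes: donors
d carry a severity mean b_d ~ Normal(δ·1[disease], σ_b²) (defaults δ = 2,
σ_b = 0.5); cells add u_c ~ Normal(0, σ_u²) (σ_u = 1) giving s_c = b_d +
u_c. *Intra* features load on s_c (log-scale slope γ = ±0.5, signs
alternating), *inter* features on b_d only, *null* features on nothing. RNA
counts are negative binomial (shape θ = 5) around `lib_c · exp(α_g + γ_g
x)` with log-normal library factors (sd 0.3); the means are drawn on the
absolute scale deliberately — renormalizing them per cell would make every
null gene's absolute expression depend on the planted content, so "null"
would no longer mean null. ATAC entries are Binomial(2, sigmoid(a_p + c_p
x)), near-binary like real snATAC data. The default design is 4 + 4 donors
× 400 cells, 2000 genes/peaks with 150 intra + 150 inter planted — chosen
as the smallest design at which the decomposition has full power while a
complete analysis runs in seconds.

What the generator does *not* emulate: batch effects, cell-type mixtures,
doublets, gene–gene co-regulation beyond the shared latent, UMI saturation,
chromatin co-accessibility structure. Passing tests therefore demonstrate
the statistical machinery is correct and calibrated under the stated
generative model, not that any particular biological dataset satisfies that
model.

`generate_toy_regulome` places genes on a 100 kb grid of one toy
chromosome, plants a configurable fraction of peaks within 10 kb of a TSS
and the rest in mid-gap positions, joins distal peaks to other genes' TSSs
through ~5 kb loop anchors, and plants motif hits in labeled peak subsets;
all relationships are emitted as truth, computed from the final coordinates
by brute-force enumeration so linker output can be compared exactly.

## QC rules

Hormone-doublet calling treats cells with nonzero counts as a hormone's
positive population (the definition is an explicit choice; an
assigned-cell-type strategy could substitute) and flags cells exceeding 10%
of the positive-population median for two or more hormones. The
post-clustering consistency filter removes typed cells with more than 15
transcripts of a foreign hormone (strict). snATAC cell QC requires
fraction-of-reads-in-peaks > 0.15 and total reads > 1500, both strict. The
KNN unambiguity score is the ratio of the second-smallest to the smallest
mean neighbor-type distance (k = 20); cells pass at score ≥ 10. The ratio
is oriented so larger = less ambiguous — the opposite orientation would be
bounded by 1 and incompatible with a cutoff of 10; ties in type ranking
break alphabetically and are logged.

## Numerical conventions

* Coordinates are 0-based half-open everywhere; MatrixMarket's 1-based
  indices convert exactly once at the I/O boundary.
* Binning is half-open with the maximum value joining the last bin; empty
  bins are dropped from regression, and donors yielding fewer than 5
  non-empty bins are excluded from the Fisher combination (df shrinks to
  2 × included donors).
* Zero-variance feature profiles get slope 0 and p = 1 rather than NaN.
* p = 0 entering Fisher's method is clamped to the smallest positive float
  with a warning.
* SVD-based embeddings fix each component's sign by making the
  largest-magnitude loading positive; multi-TSS genes take the 5′-most TSS
  on their strand; phenotype labels are normalized case-insensitively from
  {healthy, T2D, disease}.
* Peak–TSS distance is the minimal gap between interval and point (0 when
  contained); the proximal rule is inclusive at 10 kb; nearest-gene ties go
  to the lexicographically smaller name.
* The ATAC gene-activity matrix used for CCA co-embedding sums peak counts
  in a ±2 kb window around the TSS — a documented stand-in, as no standard
  definition exists.
* The specificity ratio adds a pseudocount of 0.01 RPKM to numerator and
  maximum to handle zero denominators.

## Problem sizes

The shipped tests and the acceptance script run the full pipeline on
cohorts of 3 200 cells × 2 000 genes/peaks (10 null cohorts, 3 planted
cohorts, both modalities), oracle comparisons on 1 000 Fisher combinations,
2 000 regression features and 500 exact-test tables, and toy regulomes of
25 genes / 80 peaks — sizes at which every check completes in minutes on
one core while leaving the statistical conclusions unambiguous.

## Known limitations

* The decomposition tests *presence* of reproducible within-donor trend,
  not its effect size; a feature with a tiny but ultra-consistent trend
  classifies intra.
* The per-donor leave-one-out guard removes each feature's own linear
  contribution but cannot remove realized noise correlation *between*
  embedding features selected by the SVD; the full-universe q-value
  adjustment absorbs the residual leakage in practice.
* Continuous phenotypes (e.g. BMI) are out of scope; the trajectory fit is
  binary-only.
* The CCA co-embedding is the diagonal (cross-product SVD) variant; no
  anchor-based correction is applied.
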