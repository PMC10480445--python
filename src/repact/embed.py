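"""Dimensionality reductions and cross-modality label transfer.

RNA: informative-gene selection by normalized dispersion, counts-per-10k /
log1p / per-gene z-score normalization, then PCA (top 10 components feed the
trajectory fit).  ATAC: TF-IDF weighting then LSI (truncated SVD, 50
components; the trajectory fit uses components 1-10).  The two modalities
are co-embedded by a diagonal CCA over shared features (SVD of the
cross-product of the standardized cell x feature matrices) with L2 row
normalization, on which an RBF-SVM transfers cell-type labels with
half/half validation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.svm import SVC

from .io import FeatureMatrix, GenomicIntervals, TssTable

__all__ = [
    "Embedding",
    "LabelTransferResult",
    "select_informative_genes",
    "normalize_rna",
    "pca_embed",
    "tfidf_transform",
    "lsi_embed",
    "atac_gene_scores",
    "cca_coembed",
    "svm_label_transfer",
]


@dataclass
class Embedding:
    """Cells x components coordinates.

    When produced by :func:`pca_embed` / :func:`lsi_embed`, the embedding
    also carries its factorization: ``basis`` (the centered, normalized
    cells x features matrix that was decomposed) and ``loadings`` (features
    x components), so downstream per-feature analyses can remove a single
    feature's own contribution from any linear score along the components.
    """

    coordinates: np.ndarray
    cell_ids: list[str]
    kind: str  # "pca" | "lsi" | "cca"
    component_variance: np.ndarray | None = None
    basis: np.ndarray | None = None
    loadings: np.ndarray | None = None
    basis_feature_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if np.isnan(self.coordinates).any():
            raise ValueError("embedding contains missing values")
        if self.coordinates.shape[0] != len(self.cell_ids):
            raise ValueError("coordinate rows do not match cell ids")

    @property
    def n_components(self) -> int:
        return self.coordinates.shape[1]

    def to_frame(self) -> pd.DataFrame:
        cols = [f"{self.kind}{i+1}" for i in range(self.n_components)]
        return pd.DataFrame(self.coordinates, index=self.cell_ids, columns=cols)


@dataclass
class LabelTransferResult:
    predicted_type: pd.Series      # per query cell
    validation_accuracy: float
    train_fraction: float


def _fix_signs(scores: np.ndarray, loadings: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic component orientation: largest-|loading| positive."""
    idx = np.argmax(np.abs(loadings), axis=0)
    signs = np.sign(loadings[idx, np.arange(loadings.shape[1])])
    signs[signs == 0] = 1.0
    return scores * signs, loadings * signs


def select_informative_genes(rna: FeatureMatrix, n: int = 500, n_bins: int = 20) -> list[str]:
    """Top-``n`` genes by normalized dispersion.

    Dispersion = variance/mean of depth-normalized counts, z-scored within
    equal-frequency mean bins so highly expressed genes do not dominate.
    Deterministic: ties broken by gene order.
    """
    counts = np.asarray(rna.values.todense(), dtype=float)
    depth = counts.sum(axis=1, keepdims=True)
    depth[depth == 0] = 1.0
    norm = counts / depth * 1e4
    mean = norm.mean(axis=0)
    var = norm.var(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        disp = np.where(mean > 0, var / mean, 0.0)
    if n >= rna.n_features:
        if n > rna.n_features:
            warnings.warn(
                f"requested {n} informative genes but matrix has "
                f"{rna.n_features}; returning all", stacklevel=2,
            )
        return list(rna.feature_ids)
    # equal-frequency bins over mean expression; keep >= 5 genes per bin so
    # the within-bin z-score is informative
    n_bins = max(1, min(n_bins, rna.n_features // 5))
    order = np.argsort(mean, kind="stable")
    bin_id = np.empty(rna.n_features, dtype=int)
    bin_id[order] = np.minimum(
        (np.arange(rna.n_features) * n_bins) // rna.n_features, n_bins - 1
    )
    zdisp = np.zeros_like(disp)
    for b in range(n_bins):
        m = bin_id == b
        if m.sum() == 0:
            continue
        mu, sd = disp[m].mean(), disp[m].std(ddof=0)
        zdisp[m] = (disp[m] - mu) / sd if sd > 0 else 0.0
    top = np.argsort(-zdisp, kind="stable")[:n]
    return [rna.feature_ids[i] for i in sorted(top)]


def normalize_rna(rna: FeatureMatrix, genes: list[str] | None = None,
                  target: float = 1e4, regress_depth: bool = False) -> np.ndarray:
    """Counts-per-``target`` -> log1p -> per-gene z-score (dense).

    ``regress_depth`` additionally removes each gene's linear dependence on
    log library size (off by default: total depth mixes technical capture
    with biological content, and regressing the mixture out can distort the
    biological axes; depth-aware trend tests downstream are the preferred
    guard).
    """
    counts = np.asarray(rna.values.todense(), dtype=float)
    full_depth = counts.sum(axis=1, keepdims=True)
    full_depth[full_depth == 0] = 1.0
    if genes is not None:
        counts = counts[:, rna.feature_index(genes)]
    xl = np.log1p(counts / full_depth * target)
    mu = xl.mean(axis=0)
    sd = xl.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    z = (xl - mu) / sd
    if regress_depth:
        g = np.log(full_depth.ravel())
        gc = g - g.mean()
        ss = float(gc @ gc)
        if ss > 0:
            coef = (gc @ z) / ss
            z = z - np.outer(gc, coef)
    return z


def pca_embed(rna: FeatureMatrix, genes: list[str] | None = None,
              n_components: int = 10) -> Embedding:
    """PCA of the normalized expression of the informative genes."""
    Z = normalize_rna(rna, genes)
    if rna.n_cells < n_components:
        raise ValueError(
            f"{rna.n_cells} cells < {n_components} requested components"
        )
    Zc = Z - Z.mean(axis=0)
    U, S, Vt = np.linalg.svd(Zc, full_matrices=False)
    k = min(n_components, S.size)
    scores, load = _fix_signs(U[:, :k] * S[:k], Vt[:k].T)
    var = (S[:k] ** 2) / max(Z.shape[0] - 1, 1)
    return Embedding(
        scores, list(rna.cell_ids), "pca", var,
        basis=Zc, loadings=load,
        basis_feature_ids=list(genes) if genes is not None else list(rna.feature_ids),
    )


def tfidf_transform(atac: FeatureMatrix) -> FeatureMatrix:
    """TF-IDF weighting of a cell x peak count matrix.

    entry(c,p) = (count(c,p) / depth_c) * log(1 + N_cells / (1 + df_p))
    where df_p is the number of cells with the peak open.
    """
    M = sp.csr_matrix(atac.values, dtype=float)
    depth = np.asarray(M.sum(axis=1)).ravel()
    zero = np.flatnonzero(depth == 0)
    if zero.size:
        ids = [atac.cell_ids[i] for i in zero[:5]]
        raise ValueError(f"all-zero cells (remove via QC first): {ids}")
    df = np.asarray((M > 0).sum(axis=0)).ravel()
    idf = np.log(1.0 + M.shape[0] / (1.0 + df))
    tf = sp.diags(1.0 / depth) @ M
    out = tf @ sp.diags(idf)
    return FeatureMatrix(
        sp.csr_matrix(out), list(atac.cell_ids), list(atac.feature_ids),
        atac.feature_kind, is_normalized=True,
    )


def lsi_embed(tfidf: FeatureMatrix, dims: int = 50) -> Embedding:
    """Latent semantic indexing: truncated SVD of the TF-IDF matrix.

    Component 1 is retained; its correlation with cell depth is exposed via
    the returned variances so callers can inspect or drop it.
    """
    M = np.asarray(tfidf.values.todense(), dtype=float)
    rank = min(M.shape)
    if dims > rank:
        warnings.warn(
            f"dims={dims} exceeds matrix rank bound {rank}; reducing",
            stacklevel=2,
        )
        dims = rank
    U, S, Vt = np.linalg.svd(M, full_matrices=False)
    scores, load = _fix_signs(U[:, :dims] * S[:dims], Vt[:dims].T)
    var = (S[:dims] ** 2) / max(M.shape[0] - 1, 1)
    return Embedding(
        scores, list(tfidf.cell_ids), "lsi", var,
        basis=M, loadings=load, basis_feature_ids=list(tfidf.feature_ids),
    )


def atac_gene_scores(
    atac: FeatureMatrix,
    peaks: GenomicIntervals,
    tss: TssTable,
    upstream: int = 2_000,
    downstream: int = 2_000,
) -> FeatureMatrix:
    """Per-cell gene activity from peak counts.

    Sums counts of peaks overlapping a window around each gene's TSS
    (``upstream`` bp before, ``downstream`` bp after, strand-aware).  This
    is a documented stand-in for a gene-score matrix; real pipelines may
    use full gene bodies.
    """
    pk = peaks.table.set_index("id").loc[list(atac.feature_ids)]
    genes, cols = [], []
    for _, row in tss.table.iterrows():
        if row["strand"] == "+":
            lo, hi = row["tss"] - upstream, row["tss"] + downstream
        else:
            lo, hi = row["tss"] - downstream, row["tss"] + upstream
        m = (
            (pk["chrom"] == row["chrom"])
            & (pk["start"] < hi)
            & (pk["end"] > lo)
        ).to_numpy()
        genes.append(row["gene"])
        cols.append(m)
    sel = sp.csr_matrix(np.column_stack(cols).astype(float))
    scores = sp.csr_matrix(atac.values, dtype=float) @ sel
    return FeatureMatrix(
        sp.csr_matrix(scores), list(atac.cell_ids), genes, "gene",
        is_normalized=True,
    )


def _standardize_shared(fm: FeatureMatrix, shared: list[str]) -> np.ndarray:
    X = np.asarray(fm.values.todense(), dtype=float)[:, fm.feature_index(shared)]
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    return (X - mu) / sd


def cca_coembed(
    rna: FeatureMatrix, atac_genescore: FeatureMatrix, n_cc: int = 20
) -> Embedding:
    """Diagonal-CCA co-embedding of RNA cells and ATAC cells.

    Both matrices are restricted to shared feature names and standardized
    per feature within modality; the SVD of the cross-product X Y^T gives
    the RNA (left) and ATAC (right) cell coordinates, stacked and L2
    row-normalized.
    """
    shared = [f for f in rna.feature_ids if f in set(atac_genescore.feature_ids)]
    if len(shared) < n_cc:
        raise ValueError(
            f"only {len(shared)} shared features; need >= n_cc={n_cc}"
        )
    X = _standardize_shared(rna, shared)
    Y = _standardize_shared(atac_genescore, shared)
    K = X @ Y.T
    U, S, Vt = np.linalg.svd(K, full_matrices=False)
    k = min(n_cc, S.size)
    # orient by the RNA-side vectors so both modalities flip together
    idx = np.argmax(np.abs(U[:, :k]), axis=0)
    signs = np.sign(U[idx, np.arange(k)])
    signs[signs == 0] = 1.0
    coords = np.vstack([U[:, :k] * signs, Vt[:k].T * signs])
    norms = np.linalg.norm(coords, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    coords = coords / norms
    return Embedding(
        coords, list(rna.cell_ids) + list(atac_genescore.cell_ids), "cca",
        (S[:k] ** 2),
    )


def svm_label_transfer(
    embedding: Embedding,
    labels: dict[str, str],
    query: list[str],
    train_fraction: float = 0.5,
    cost: float = 10.0,
    seed: int = 0,
) -> LabelTransferResult:
    """RBF-SVM label transfer with stratified half/half validation.

    Half of the labeled reference cells (per class, seeded) train an SVM
    with radial kernel and the given cost; accuracy is reported on the
    held-out half; all query cells receive predictions.
    """
    frame = embedding.to_frame()
    ref_cells = [c for c in frame.index if c in labels]
    y = pd.Series({c: labels[c] for c in ref_cells})
    counts = y.value_counts()
    if counts.size < 2:
        raise ValueError("need >= 2 reference classes")
    singletons = counts[counts < 2].index.tolist()
    if singletons:
        raise ValueError(
            f"classes with a single member (merge them first): {singletons}"
        )
    rng = np.random.default_rng(seed)
    train_idx: list[str] = []
    for cls, members in y.groupby(y).groups.items():
        members = list(members)
        perm = rng.permutation(len(members))
        n_train = max(1, int(round(train_fraction * len(members))))
        n_train = min(n_train, len(members) - 1)  # keep a validation cell
        train_idx.extend(members[i] for i in perm[:n_train])
    train_set = set(train_idx)
    val_idx = [c for c in ref_cells if c not in train_set]

    clf = SVC(kernel="rbf", C=cost)
    clf.fit(frame.loc[train_idx].to_numpy(), y.loc[train_idx].to_numpy())
    acc = float(
        (clf.predict(frame.loc[val_idx].to_numpy()) == y.loc[val_idx].to_numpy())
        .mean()
    )
    pred = clf.predict(frame.loc[list(query)].to_numpy())
    return LabelTransferResult(
        predicted_type=pd.Series(pred, index=list(query)),
        validation_accuracy=acc,
        train_fraction=train_fraction,
    )
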