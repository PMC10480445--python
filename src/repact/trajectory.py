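"""Disease-trajectory regression: the RePACT engine.

The model: cells of a case/control cohort are embedded in a low-dimensional
space (PCA for RNA, LSI for ATAC); a ridge-stabilized logistic regression of
the binary phenotype on the top components defines a direction of maximal
phenotype association, and each cell's fitted probability is its disease
pseudo-index.  Cells are then grouped into equal-width pseudo-index bins and
every feature's per-bin mean profile is regressed against the bin positions;
the slope and its t-test p-value (q-value adjusted across features) call
trajectory features.

Exposed both as a statsmodels-style model (`RePACT(...).fit()` returning
:class:`RePACTResults`) and as the underlying functions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.stats

from .io import FeatureMatrix
from .stats import qvalues

__all__ = [
    "RePACT",
    "RePACTResults",
    "BinnedProfile",
    "fit_trajectory",
    "bin_by_index",
    "feature_trend_test",
    "call_trajectory_genes",
    "call_trajectory_peaks",
    "motif_trend_test",
]


def _sigmoid(eta: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * eta))


def _ridge_logistic(
    X: np.ndarray, y: np.ndarray, ridge: float, max_iter: int = 100,
    tol: float = 1e-12,
) -> tuple[np.ndarray, float]:
    """Newton/IRLS fit of logistic regression with an L2 penalty on the
    slopes (intercept unpenalized).  ``ridge`` is per observation (the total
    penalty is ridge * n * ||beta||^2 / 2), so its meaning does not change
    with cohort size.  Starts at zero: deterministic, and the iterates
    negate under label reversal."""
    n, d = X.shape
    Xa = np.hstack([np.ones((n, 1)), X])
    beta = np.zeros(d + 1)
    pen = np.full(d + 1, ridge * n)
    pen[0] = 0.0
    for _ in range(max_iter):
        eta = Xa @ beta
        mu = _sigmoid(eta)
        w = mu * (1.0 - mu)
        grad = Xa.T @ (mu - y) + pen * beta
        H = (Xa * w[:, None]).T @ Xa + np.diag(pen)
        step = np.linalg.solve(H, grad)
        beta = beta - step
        if np.max(np.abs(step)) < tol:
            break
    return beta[1:], float(beta[0])


@dataclass
class BinnedProfile:
    """Equal-width binning of cells along the pseudo-index."""

    n_bins: int
    edges: np.ndarray            # length n_bins + 1, strictly increasing
    bin_of_cell: np.ndarray      # int per cell
    bin_value: np.ndarray        # representative index per bin (center)
    cells_per_bin: np.ndarray    # counts, length n_bins

    @property
    def nonempty(self) -> np.ndarray:
        return self.cells_per_bin > 0

    def bin_means(self, values) -> np.ndarray:
        """Per-bin, per-feature mean; rows = bins (all, incl. empty->nan)."""
        if isinstance(values, FeatureMatrix):
            values = values.values
        if sp.issparse(values):
            values = sp.csr_matrix(values)
            n_cells = values.shape[0]
        else:
            values = np.asarray(values, dtype=float)
            n_cells = values.shape[0]
        if n_cells != self.bin_of_cell.size:
            raise ValueError("matrix rows do not match binned cells")
        ind = sp.csr_matrix(
            (
                np.ones(n_cells),
                (self.bin_of_cell, np.arange(n_cells)),
            ),
            shape=(self.n_bins, n_cells),
        )
        sums = np.asarray((ind @ values).todense()) if sp.issparse(values) else ind @ values
        counts = self.cells_per_bin.astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            means = sums / counts[:, None]
        means[counts == 0] = np.nan
        return means


def bin_by_index(pseudo_index: np.ndarray, n_bins: int = 20) -> BinnedProfile:
    """Group cells into ``n_bins`` equal-width intervals over the observed
    pseudo-index range.  The maximum value joins the last bin; interior
    boundary values go to the right bin (half-open convention)."""
    x = np.asarray(pseudo_index, dtype=float)
    lo, hi = float(x.min()), float(x.max())
    if hi == lo:
        raise ValueError("constant pseudo-index: degenerate trajectory")
    if np.unique(x).size < n_bins:
        warnings.warn(
            f"fewer distinct pseudo-index values ({np.unique(x).size}) than "
            f"bins ({n_bins})", stacklevel=2,
        )
    edges = np.linspace(lo, hi, n_bins + 1)
    width = (hi - lo) / n_bins
    b = np.floor((x - lo) / width).astype(int)
    b = np.clip(b, 0, n_bins - 1)
    counts = np.bincount(b, minlength=n_bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return BinnedProfile(n_bins, edges, b, centers, counts)


def feature_trend_test(
    matrix,
    bins: BinnedProfile,
    scale: str = "raw_mean",
    feature_ids: list[str] | None = None,
    x_mode: str = "center",
    qvalue_method: str = "storey",
    weighted: bool = True,
    covariate: np.ndarray | None = None,
    size_factors: np.ndarray | None = None,
    compute_q: bool = True,
) -> pd.DataFrame:
    """Per-feature trend along the trajectory.

    For every feature, ordinary least squares of the per-bin mean on the bin
    positions; two-sided p from the slope t-statistic; q-values across all
    features in the call.

    Parameters
    ----------
    matrix : FeatureMatrix, sparse/dense array, or DataFrame (cells x features).
    scale : per-bin statistic.
        "raw_mean" (default for RNA) — mean raw transcript counts per bin.
        "norm_mean" — mean of depth-normalized counts (per 10k within each
        cell); note that normalizing couples every feature to the total
        cellular content, so features flat in absolute expression can
        acquire relative-abundance trends.
        "zscore" (ATAC) — each feature's per-bin profile z-scored and
        regressed against bins rescaled to [0, 1], making the slope
        threshold scale-free.
    x_mode : regress against bin centers ("center") or bin rank ("rank").
    weighted : weight each bin by its cell count (default).  A bin mean's
        sampling variance scales as 1/n_cells, and equal-width binning of a
        skewed pseudo-index leaves near-empty tail bins; unweighted least
        squares treats those noisy points as exact and is anticonservative.
        ``weighted=False`` gives the plain unweighted regression.
    covariate : optional per-cell nuisance values (e.g. a technical depth
        estimate).  Its per-bin mean enters the regression as an extra
        column, so feature trends that merely track the covariate are
        absorbed; the reported slope/p are for the bin position only.
    """
    if scale not in ("norm_mean", "raw_mean", "zscore"):
        raise ValueError(f"unknown scale {scale!r}")
    if isinstance(matrix, pd.DataFrame):
        feature_ids = feature_ids or [str(c) for c in matrix.columns]
        values = matrix.to_numpy(dtype=float)
    elif isinstance(matrix, FeatureMatrix):
        feature_ids = feature_ids or list(matrix.feature_ids)
        values = matrix
    else:
        values = matrix
        if feature_ids is None:
            feature_ids = [f"f{i}" for i in range(np.shape(matrix)[1])]

    if size_factors is not None:
        sf = np.asarray(size_factors, dtype=float).ravel()
        if np.any(sf <= 0):
            raise ValueError("size factors must be positive")
        raw = values.values if isinstance(values, FeatureMatrix) else values
        raw = sp.csr_matrix(raw, dtype=float) if sp.issparse(raw) else np.asarray(raw, dtype=float)
        values = sp.diags(sf.mean() / sf) @ raw
    elif scale == "norm_mean":
        raw = values.values if isinstance(values, FeatureMatrix) else values
        raw = sp.csr_matrix(raw, dtype=float) if sp.issparse(raw) else np.asarray(raw, dtype=float)
        depth = np.asarray(raw.sum(axis=1)).ravel()
        depth[depth == 0] = 1.0
        scaler = sp.diags(1e4 / depth)
        values = scaler @ raw

    means = bins.bin_means(values)          # n_bins x F, empty bins nan
    keep = bins.nonempty
    k = int(keep.sum())
    if k < 3:
        raise ValueError(f"only {k} non-empty bins; need >= 3 for regression")
    Y = means[keep]
    if x_mode == "center":
        x = bins.bin_value[keep].astype(float)
    elif x_mode == "rank":
        x = np.flatnonzero(keep).astype(float) + 1.0
    else:
        raise ValueError(f"unknown x_mode {x_mode!r}")

    if scale == "zscore":
        x = (x - x.min()) / (x.max() - x.min())
        mu = Y.mean(axis=0)
        sd = Y.std(axis=0, ddof=1)
        zero = sd == 0
        sd_safe = np.where(zero, 1.0, sd)
        Y = (Y - mu) / sd_safe
        Y[:, zero] = 0.0

    w = bins.cells_per_bin[keep].astype(float) if weighted else np.ones(k)
    if covariate is not None:
        cov = np.asarray(covariate, dtype=float).ravel()
        cbin = bins.bin_means(cov[:, None])[keep].ravel()
        D = np.column_stack([np.ones(k), x, cbin])
        if k < 4:
            raise ValueError("need >= 4 non-empty bins with a covariate")
        DtW = D.T * w
        G = DtW @ D
        B = np.linalg.solve(G, DtW @ Y)      # 3 x F
        resid = Y - D @ B
        df = k - 3
        s2 = (w @ (resid ** 2)) / df
        Ginv = np.linalg.inv(G)
        with np.errstate(invalid="ignore", divide="ignore"):
            se = np.sqrt(Ginv[1, 1] * s2)
            t = B[1] / se
        slope = B[1]
        yc = Y - (w @ Y) / w.sum()
    else:
        wsum = w.sum()
        xbar = float((w @ x) / wsum)
        xc = x - xbar
        sxx = float(w @ (xc ** 2))
        ybar = (w @ Y) / wsum
        yc = Y - ybar
        sxy = (w * xc) @ yc
        slope = sxy / sxx
        resid = yc - np.outer(xc, slope)
        df = k - 2
        s2 = (w @ (resid ** 2)) / df
        with np.errstate(invalid="ignore", divide="ignore"):
            se = np.sqrt(s2 / sxx)
            t = slope / se
    p = 2.0 * scipy.stats.t.sf(np.abs(t), df)
    # zero-variance profiles: no trend by convention
    flat = Y.std(axis=0) == 0
    slope[flat] = 0.0
    p[flat] = 1.0
    p = np.clip(p, 0.0, 1.0)
    out = pd.DataFrame(
        {
            "feature": feature_ids,
            "slope": slope,
            "p": p,
            "direction": np.where(slope >= 0, "up", "down"),
        }
    )
    out["q"] = qvalues(p, method=qvalue_method) if compute_q else np.nan
    return out[["feature", "slope", "p", "q", "direction"]]


def control_depth(matrix: FeatureMatrix, exclude: list[str] | None) -> np.ndarray:
    """Per-cell technical depth estimated from features outside ``exclude``.

    Total counts over the non-embedding features track capture depth while
    being insensitive to the biological axes the embedding represents, so
    they make clean size factors for trend tests on raw counts."""
    if not exclude:
        return np.asarray(matrix.values.sum(axis=1)).ravel().astype(float)
    excl = set(exclude)
    keep = [i for i, f in enumerate(matrix.feature_ids) if f not in excl]
    if not keep:
        return np.asarray(matrix.values.sum(axis=1)).ravel().astype(float)
    return np.asarray(matrix.values[:, keep].sum(axis=1)).ravel().astype(float)


def call_trajectory_genes(results: pd.DataFrame, q_cut: float = 0.05) -> dict[str, list[str]]:
    """Significant trajectory genes at q < ``q_cut`` (strict), split by
    slope direction."""
    sig = results[results["q"] < q_cut]
    return {
        "up": sig.loc[sig["slope"] > 0, "feature"].tolist(),
        "down": sig.loc[sig["slope"] < 0, "feature"].tolist(),
    }


def call_trajectory_peaks(
    results: pd.DataFrame, q_cut: float = 0.01, slope_cut: float = 0.5
) -> dict[str, list[str]]:
    """Gain/loss of accessibility: q < ``q_cut`` and |slope| > ``slope_cut``
    (both strict), on z-scored per-bin profiles."""
    sig = results[results["q"] < q_cut]
    return {
        "gain": sig.loc[sig["slope"] > slope_cut, "feature"].tolist(),
        "loss": sig.loc[sig["slope"] < -slope_cut, "feature"].tolist(),
    }


def motif_trend_test(motif_z: pd.DataFrame, bins: BinnedProfile) -> pd.DataFrame:
    """Trend of per-cell motif deviation z-scores (chromVAR-style, supplied
    externally) along the trajectory: per-bin mean z regressed on bin
    position with the same machinery as gene/peak trends.  Deviations are
    already depth-corrected, so the raw per-bin mean is used."""
    return feature_trend_test(motif_z, bins, scale="raw_mean")


# ---------------------------------------------------------------------------
# model / results objects


class RePACT:
    """Disease-trajectory model over an embedding and binary phenotype.

    Parameters
    ----------
    embedding : Embedding or (cells x components) array.
    phenotype : binary labels aligned to embedding rows (1 = disease).
    components : how many leading components enter the logistic fit
        (default 10, i.e. components 1-10).
    ridge : per-cell L2 penalty on the slopes.  Donor-structured cohorts
        are often linearly separable in the embedding, which drives an
        unpenalized fit to a saturated 0/1 pseudo-index; an O(1) per-cell
        ridge keeps the index continuous while preserving its ranking.
    """

    def __init__(self, embedding, phenotype, components: int = 10,
                 ridge: float = 1.0):
        coords = getattr(embedding, "coordinates", embedding)
        self.embedding = embedding if hasattr(embedding, "coordinates") else None
        self.cell_ids = list(getattr(embedding, "cell_ids", range(len(coords))))
        coords = np.asarray(coords, dtype=float)
        y = np.asarray(phenotype)
        if y.ndim != 1 or y.size != coords.shape[0]:
            raise ValueError("phenotype must align with embedding rows")
        classes = np.unique(y)
        if classes.size < 2:
            raise ValueError("both phenotype classes must be present")
        if classes.size > 2:
            raise ValueError("phenotype must be binary")
        self.X = coords[:, : min(components, coords.shape[1])]
        self.y = (y == classes.max()).astype(float)
        self.components = self.X.shape[1]
        self.ridge = float(ridge)

    def fit(self, max_iter: int = 100, tol: float = 1e-12) -> "RePACTResults":
        beta, intercept = _ridge_logistic(
            self.X, self.y, self.ridge, max_iter=max_iter, tol=tol
        )
        eta = self.X @ beta + intercept
        return RePACTResults(self, beta, intercept, _sigmoid(eta))


@dataclass
class RePACTResults:
    """Fitted trajectory: coefficients and per-cell pseudo-index."""

    model: RePACT
    params: np.ndarray
    intercept: float
    pseudo_index: np.ndarray

    @property
    def linear_predictor(self) -> np.ndarray:
        return self.model.X @ self.params + self.intercept

    def feature_weights(self) -> pd.Series | None:
        """Per-feature weight in the linear predictor (loadings @ beta),
        available when the embedding carries its factorization.  The
        trajectory score is ``intercept + basis @ feature_weights``, so a
        single feature's own contribution can be removed exactly."""
        emb = self.model.embedding
        if emb is None or getattr(emb, "loadings", None) is None:
            return None
        w = emb.loadings[:, : self.model.components] @ self.params
        return pd.Series(w, index=emb.basis_feature_ids)

    def bin(self, n_bins: int = 20) -> BinnedProfile:
        return bin_by_index(self.pseudo_index, n_bins)

    def test_features(
        self,
        matrix,
        n_bins: int = 20,
        scale: str = "raw_mean",
        size_factors="auto",
        leave_one_out: bool = True,
        refine_size_factors: bool = True,
        **kw,
    ) -> pd.DataFrame:
        """Per-feature trend along the fitted trajectory.

        ``size_factors="auto"`` divides raw gene counts by the control-
        feature depth (counts over features outside the embedding basis),
        removing technical capture depth without introducing compositional
        coupling; pass ``None`` or an array to override.  ATAC z-score
        profiles are left unscaled.  With ``refine_size_factors`` the test
        runs twice: features called at q < 0.05 in the first pass are also
        excluded from the control set, so strong trajectory features that
        escaped the embedding basis cannot tilt the size factors.

        ``leave_one_out`` re-bins each embedding-basis feature along a
        pseudo-index with that feature's own contribution removed from the
        linear predictor.  The index is estimated from the same cells, so
        a feature that helped build it trends along its own noise; the
        leave-one-out index breaks this circularity while leaving features
        outside the basis untouched.
        """
        if isinstance(size_factors, str) and size_factors == "auto":
            if (
                isinstance(matrix, FeatureMatrix)
                and matrix.feature_kind == "gene"
                and not matrix.is_normalized
                and scale in ("raw_mean", "norm_mean")
            ):
                emb = self.model.embedding
                exclude = list(
                    getattr(emb, "basis_feature_ids", None) or []
                ) if emb is not None else []
                size_factors = control_depth(matrix, exclude)
                scale = "raw_mean"
                if refine_size_factors:
                    first = self.test_features(
                        matrix, n_bins=n_bins, scale=scale,
                        size_factors=size_factors,
                        leave_one_out=leave_one_out, **kw,
                    )
                    hit = first.loc[first["q"] < 0.05, "feature"].tolist()
                    size_factors = control_depth(matrix, exclude + hit)
            else:
                size_factors = None

        weights = self.feature_weights() if leave_one_out else None
        bins = self.bin(n_bins)
        if weights is None:
            return feature_trend_test(
                matrix, bins, scale=scale, size_factors=size_factors, **kw
            )

        if isinstance(matrix, FeatureMatrix):
            feature_ids = list(matrix.feature_ids)
        elif isinstance(matrix, pd.DataFrame):
            feature_ids = [str(c) for c in matrix.columns]
        else:
            feature_ids = [f"f{i}" for i in range(np.shape(matrix)[1])]
        wset = {f for f in feature_ids if f in weights.index and weights[f] != 0}
        loo_feats = [f for f in feature_ids if f in wset]
        plain_feats = [f for f in feature_ids if f not in wset]

        parts = []
        if plain_feats:
            if isinstance(matrix, FeatureMatrix):
                plain = matrix.subset_features(plain_feats)
                sf_p = size_factors
            elif isinstance(matrix, pd.DataFrame):
                plain, sf_p = matrix[plain_feats], size_factors
            else:
                idx = [feature_ids.index(f) for f in plain_feats]
                plain, sf_p = np.asarray(matrix)[:, idx], size_factors
            parts.append(
                feature_trend_test(
                    plain, bins, scale=scale, size_factors=sf_p,
                    compute_q=False, **kw,
                )
            )
        if loo_feats:
            eta = self.linear_predictor
            emb = self.model.embedding
            bcols = {f: j for j, f in enumerate(emb.basis_feature_ids)}
            if isinstance(matrix, FeatureMatrix):
                dense = np.asarray(
                    matrix.subset_features(loo_feats).values.todense(), float
                )
            elif isinstance(matrix, pd.DataFrame):
                dense = matrix[loo_feats].to_numpy(dtype=float)
            else:
                idx = [feature_ids.index(f) for f in loo_feats]
                dense = np.asarray(matrix, dtype=float)[:, idx]
            for j, f in enumerate(loo_feats):
                eta_f = eta - emb.basis[:, bcols[f]] * weights[f]
                pi_f = _sigmoid(eta_f)
                if np.unique(pi_f).size < 2:
                    continue
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    bins_f = bin_by_index(pi_f, n_bins)
                parts.append(
                    feature_trend_test(
                        dense[:, [j]], bins_f, scale=scale,
                        feature_ids=[f], size_factors=size_factors,
                        compute_q=False, **kw,
                    )
                )
        out = pd.concat(parts, ignore_index=True)
        out = out.set_index("feature").loc[
            [f for f in feature_ids if f in set(out["feature"])]
        ].reset_index()
        out["q"] = qvalues(out["p"].to_numpy())
        return out[["feature", "slope", "p", "q", "direction"]]

    def summary(self) -> str:
        y = self.model.y
        lines = [
            "Disease trajectory (ridge-logistic on embedding components)",
            f"  cells: {y.size}  (disease: {int(y.sum())}, "
            f"healthy: {int(y.size - y.sum())})",
            f"  components used: 1-{self.model.components}   "
            f"ridge: {self.model.ridge:g}",
            f"  intercept: {self.intercept: .4f}",
            "  coefficients:",
        ]
        for i, b in enumerate(self.params, start=1):
            lines.append(f"    comp{i:<3d} {b: .4f}")
        pi = self.pseudo_index
        lines.append(
            f"  pseudo-index: min {pi.min():.4f}  median {np.median(pi):.4f}  "
            f"max {pi.max():.4f}"
        )
        for label, val in (("disease", 1.0), ("healthy", 0.0)):
            lines.append(
                f"  mean pseudo-index ({label}): {pi[y == val].mean():.4f}"
            )
        return "\n".join(lines)

    def plot_pseudo_index(self, cells=None, ax=None):
        """Violin plot of the per-cell pseudo-index, split by donor when a
        cell table is given, otherwise by phenotype."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 3))
        pi = self.pseudo_index
        if cells is not None:
            donor = cells.donor_of(list(self.model.cell_ids))
            pheno = cells.phenotype_of(list(self.model.cell_ids))
            order = sorted(set(donor), key=lambda d: (pheno[donor == d][0], d))
            data = [pi[donor == d] for d in order]
            parts = ax.violinplot(data, showmedians=True)
            for body, d in zip(parts["bodies"], order):
                body.set_facecolor(
                    "firebrick" if pheno[donor == d][0] else "steelblue"
                )
            ax.set_xticks(range(1, len(order) + 1), order)
            ax.set_xlabel("donor")
        else:
            y = self.model.y
            ax.violinplot([pi[y == 0], pi[y == 1]], showmedians=True)
            ax.set_xticks([1, 2], ["healthy", "disease"])
        ax.set_ylabel("disease pseudo-index")
        return ax

    def to_dict(self) -> dict:
        return {
            "coefficients": self.params.tolist(),
            "intercept": self.intercept,
            "components_used": list(range(1, self.model.components + 1)),
            "ridge": self.model.ridge,
        }


def fit_trajectory(
    embedding, phenotype, components: int = 10, ridge: float = 1.0
) -> RePACTResults:
    """Functional wrapper: build and fit a :class:`RePACT` model."""
    return RePACT(embedding, phenotype, components=components, ridge=ridge).fit()
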