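"""Intra-donor vs inter-donor heterogeneity decomposition.

Along the global disease trajectory, each donor's cells are re-binned over
that donor's own pseudo-index range and every feature's per-bin trend is
tested within the donor.  Fisher's method combines the per-donor p-values:

    combined p = P( X > -2 * sum_k log p_k ),   X ~ chi-square(df = 2k)

where k counts the included donors.  Features whose combined q-value is
below 0.01 show a trend reproducibly *within* donors (intra-donor
heterogeneous); the remaining trajectory features vary between donors only
(inter-donor).  The heterogeneity score is -log10 of the combined q-value,
so the classification cutoff sits at a score of 2.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .io import CellTable, FeatureMatrix
from .stats import qvalues
from .trajectory import (
    RePACTResults,
    bin_by_index,
    control_depth,
    feature_trend_test,
)

__all__ = [
    "FisherCombination",
    "fisher_combine",
    "per_donor_trends",
    "classify_heterogeneity",
    "heterogeneity_analysis",
]

log = logging.getLogger(__name__)

_TINY = np.finfo(float).tiny


@dataclass
class FisherCombination:
    statistic: float
    n_donors: int
    df: int
    p_combined: float


def fisher_combine(p_list) -> FisherCombination:
    """Fisher's method over per-donor p-values.

    statistic = -2 * sum log p;  combined p = chi-square(2k) survival of the
    statistic.  A single p-value is returned unchanged (the df=2 survival of
    -2 log p is the identity).  p = 0 is clamped to the smallest positive
    float with a warning.
    """
    p = np.asarray(p_list, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if np.any(p == 0):
        warnings.warn("p = 0 clamped to the smallest positive float", stacklevel=2)
        p = np.maximum(p, _TINY)
    k = p.size
    stat = float(-2.0 * np.sum(np.log(p)))
    if k == 1:
        return FisherCombination(stat, 1, 2, float(p[0]))
    return FisherCombination(stat, k, 2 * k, float(scipy.stats.chi2.sf(stat, 2 * k)))


def _sigmoid(eta: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * eta))


def per_donor_trends(
    matrix,
    results: RePACTResults,
    cells: CellTable,
    n_bins: int = 20,
    min_bins: int = 5,
    scale: str = "raw_mean",
    covariate: np.ndarray | None = None,
    size_factors: np.ndarray | None = None,
    leave_one_out: bool = True,
) -> pd.DataFrame:
    """Per-(feature, donor) trend along the global trajectory.

    Each donor's cells are re-binned into ``n_bins`` equal-width intervals
    over that donor's own pseudo-index range, then tested with the same
    binned regression as the global call.  Donors yielding fewer than
    ``min_bins`` non-empty bins are excluded (logged), shrinking the later
    Fisher df.

    Two guards keep the within-donor p-values honest at this resolution
    (Fisher's method amplifies even mild per-donor anticonservativeness):

    * ``leave_one_out`` — when the trajectory carries its embedding
      factorization, each tested feature's own contribution is subtracted
      from the linear predictor before that feature's binning.  The
      pseudo-index is estimated from the same cells, so a feature that
      helped build it correlates with its own noise along the trajectory;
      removing the feature's term breaks that circularity.  Features
      outside the embedding basis are unaffected.
    * ``covariate`` — per-cell nuisance values passed through to the
      trend regression (see :func:`feature_trend_test`); typically a
      technical depth estimate, since all raw counts scale with capture
      depth and the fitted index is never perfectly depth-free.

    Returns a long table: feature, donor, slope, p, n_cells, n_bins_used.
    """
    if isinstance(matrix, FeatureMatrix):
        cell_ids = list(matrix.cell_ids)
        feature_ids = list(matrix.feature_ids)
    else:
        cell_ids = list(results.model.cell_ids)
        matrix = pd.DataFrame(matrix)
        feature_ids = [str(c) for c in matrix.columns]
    donor = pd.Series(cells.donor_of(cell_ids), index=cell_ids)
    order = pd.Index(list(results.model.cell_ids)).get_indexer(cell_ids)
    if (order < 0).any():
        raise ValueError("matrix cells absent from the fitted trajectory")
    pidx = results.pseudo_index[order]
    if covariate is not None:
        covariate = np.asarray(covariate, dtype=float).ravel()
        if covariate.size != len(cell_ids):
            raise ValueError("covariate must align with matrix cells")
    if size_factors is not None:
        size_factors = np.asarray(size_factors, dtype=float).ravel()
        if size_factors.size != len(cell_ids):
            raise ValueError("size factors must align with matrix cells")

    weights = (
        results.feature_weights()
        if leave_one_out and hasattr(results, "feature_weights")
        else None
    )
    eta = None
    basis = None
    if weights is not None:
        eta = results.linear_predictor[order]
        emb = results.model.embedding
        basis = pd.DataFrame(
            emb.basis, index=list(results.model.cell_ids),
            columns=emb.basis_feature_ids,
        ).iloc[order]

    rows = []
    for d in pd.unique(donor):
        mask = (donor == d).to_numpy()
        members = donor.index[mask]
        x = pidx[mask]
        if np.unique(x).size < 2:
            log.warning("donor %s has a constant pseudo-index; excluded", d)
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            bins = bin_by_index(x, n_bins)
        used = int(bins.nonempty.sum())
        if used < max(min_bins, 3):
            log.warning(
                "donor %s yields %d non-empty bins (< %d); excluded",
                d, used, max(min_bins, 3),
            )
            continue
        if isinstance(matrix, FeatureMatrix):
            sub = matrix.subset_cells(list(members))
        else:
            sub = matrix.loc[list(members)]
        cov_d = covariate[mask] if covariate is not None else None
        sf_d = size_factors[mask] if size_factors is not None else None

        loo_feats = (
            [f for f in feature_ids if f in weights.index and weights[f] != 0]
            if weights is not None else []
        )
        plain_feats = [f for f in feature_ids if f not in set(loo_feats)]

        parts = []
        if plain_feats:
            plain = (
                sub.subset_features(plain_feats)
                if isinstance(sub, FeatureMatrix) else sub[plain_feats]
            )
            parts.append(
                feature_trend_test(
                    plain, bins, scale=scale, covariate=cov_d,
                    size_factors=sf_d, compute_q=False,
                )
            )
        if loo_feats:
            eta_d = eta[mask]
            B = basis[mask]
            dense = (
                np.asarray(sub.subset_features(loo_feats).values.todense(), float)
                if isinstance(sub, FeatureMatrix)
                else sub[loo_feats].to_numpy(dtype=float)
            )
            for j, f in enumerate(loo_feats):
                eta_f = eta_d - B[f].to_numpy() * weights[f]
                pi_f = _sigmoid(eta_f)
                if np.unique(pi_f).size < 2:
                    continue
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    bins_f = bin_by_index(pi_f, n_bins)
                if int(bins_f.nonempty.sum()) < max(min_bins, 3):
                    continue
                parts.append(
                    feature_trend_test(
                        dense[:, [j]], bins_f, scale=scale,
                        feature_ids=[f], covariate=cov_d,
                        size_factors=sf_d, compute_q=False,
                    )
                )
        if not parts:
            continue
        res = pd.concat(parts, ignore_index=True)[["feature", "slope", "p"]]
        res["donor"] = d
        res["n_cells"] = len(members)
        res["n_bins_used"] = used
        rows.append(res)
    if not rows:
        raise ValueError("no donor passed the binning inclusion rule")
    out = pd.concat(rows, ignore_index=True)
    return out[["feature", "donor", "slope", "p", "n_cells", "n_bins_used"]]


_COMBINED_COLS = [
    "feature", "statistic", "n_donors", "df", "p_combined", "median_slope"
]


def combine_per_donor(trends: pd.DataFrame) -> pd.DataFrame:
    """Fisher-combine per-donor p-values per feature."""
    if trends.empty:
        return pd.DataFrame(columns=_COMBINED_COLS)
    rows = []
    for feature, grp in trends.groupby("feature", sort=False):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fc = fisher_combine(grp["p"].to_numpy())
        rows.append(
            {
                "feature": feature,
                "statistic": fc.statistic,
                "n_donors": fc.n_donors,
                "df": fc.df,
                "p_combined": fc.p_combined,
                "median_slope": float(grp["slope"].median()),
            }
        )
    return pd.DataFrame(rows)


def classify_heterogeneity(
    global_results: pd.DataFrame,
    combined: pd.DataFrame,
    called_features: list[str],
    q_cut: float = 0.01,
    sign_consistent: bool = False,
    qvalue_universe: str = "all",
) -> pd.DataFrame:
    """Four-way classification of globally called trajectory features.

    q-values of the Fisher-combined p are computed over all tested features
    by default (``qvalue_universe="all"``): the called set is selected for
    association with the trajectory, so adjusting within it alone
    double-dips the selection and lets a handful of selection-inflated
    combined p-values reach significance; against the full universe they
    face honest multiplicity, while cohorts with genuine intra-donor
    structure supply enough small p-values to keep borderline features
    called.  ``qvalue_universe="called"`` restricts the adjustment to the
    classified population.  Category = global direction x (intra if
    q_combined < q_cut else inter); score = -log10(q_combined), so exactly
    0.01 (score exactly 2) classifies as inter (strict).

    With ``sign_consistent=True`` a feature must additionally have a median
    per-donor slope whose sign matches the global direction to be intra.
    """
    if qvalue_universe not in ("called", "all"):
        raise ValueError("qvalue_universe must be 'called' or 'all'")
    out_cols = [
        "feature", "statistic", "n_donors", "df", "p_combined",
        "q_combined", "score", "category", "median_slope",
    ]
    if combined.empty:
        return pd.DataFrame(columns=out_cols)
    gl = global_results.set_index("feature")
    combined = combined.copy()
    unknown = [f for f in combined["feature"] if f not in gl.index]
    if unknown:
        log.warning("%d combined features absent from global calls; ignored",
                    len(unknown))
        combined = combined[~combined["feature"].isin(unknown)]
    if qvalue_universe == "called":
        combined = combined[combined["feature"].isin(set(called_features))]
        combined = combined.reset_index(drop=True)
        combined["q_combined"] = qvalues(combined["p_combined"].to_numpy())
    else:
        combined = combined.reset_index(drop=True)
        combined["q_combined"] = qvalues(combined["p_combined"].to_numpy())
        combined = combined[combined["feature"].isin(set(called_features))]
        combined = combined.reset_index(drop=True)

    direction = gl.loc[combined["feature"], "direction"].to_numpy()
    intra = combined["q_combined"].to_numpy() < q_cut
    if sign_consistent:
        gslope = np.sign(gl.loc[combined["feature"], "slope"].to_numpy())
        mslope = np.sign(combined["median_slope"].to_numpy())
        intra = intra & (gslope == mslope)
    with np.errstate(divide="ignore"):
        score = -np.log10(combined["q_combined"].to_numpy())
    combined["score"] = score
    combined["category"] = [
        f"{'intra' if i else 'inter'}_{d}" for i, d in zip(intra, direction)
    ]
    return combined[
        ["feature", "statistic", "n_donors", "df", "p_combined",
         "q_combined", "score", "category", "median_slope"]
    ]


def heterogeneity_analysis(
    matrix,
    results: RePACTResults,
    cells: CellTable,
    global_results: pd.DataFrame,
    called_features: list[str],
    n_bins: int = 20,
    min_bins: int = 5,
    scale: str = "raw_mean",
    q_cut: float = 0.01,
    covariate: np.ndarray | None = None,
    size_factors="auto",
    leave_one_out: bool = True,
    qvalue_universe: str = "all",
    **classify_kw,
) -> pd.DataFrame:
    """Full pipeline: per-donor trends -> Fisher combination -> four-way call.

    With the default ``qvalue_universe="all"`` the per-donor trends are
    computed for every feature in ``global_results`` so the Fisher q-value
    adjustment sees the full universe; ``"called"`` restricts both to the
    globally called set.

    ``size_factors="auto"`` divides raw gene counts by the control-feature
    depth estimate (:func:`repact.trajectory.control_depth`, counts over
    features outside the embedding basis) — the same convention as the
    global :meth:`RePACTResults.test_features`; z-scored (ATAC) trends are
    left unscaled.  Pass an array or ``None`` to override.
    """
    if isinstance(size_factors, str) and size_factors == "auto":
        if (
            isinstance(matrix, FeatureMatrix)
            and matrix.feature_kind == "gene"
            and not matrix.is_normalized
            and scale in ("raw_mean", "norm_mean")
        ):
            emb = getattr(results.model, "embedding", None)
            exclude = list(
                getattr(emb, "basis_feature_ids", None) or []
            ) if emb is not None else []
            # called features are also excluded so trajectory-responsive
            # content cannot tilt the size factors
            size_factors = control_depth(
                matrix, exclude + list(called_features)
            )
            scale = "raw_mean"
        else:
            size_factors = None
    universe = (
        set(global_results["feature"]) if qvalue_universe == "all"
        else set(called_features)
    )
    if isinstance(matrix, FeatureMatrix):
        present = [f for f in matrix.feature_ids if f in universe]
        matrix = matrix.subset_features(present)
    trends = per_donor_trends(
        matrix, results, cells, n_bins=n_bins, min_bins=min_bins, scale=scale,
        covariate=covariate, size_factors=size_factors,
        leave_one_out=leave_one_out,
    )
    trends = trends[trends["feature"].isin(universe)]
    combined = combine_per_donor(trends)
    return classify_heterogeneity(
        global_results, combined, called_features, q_cut=q_cut,
        qvalue_universe=qvalue_universe, **classify_kw,
    )
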