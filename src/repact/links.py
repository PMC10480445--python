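"""Pseudo-bulk specificity, enrichment tests, and peak-gene linking.

Peaks are aggregated per cell type into RPKM; an endocrine/non-endocrine
RPKM ratio classifies peak specificity, K-means groups the specific peaks,
and motif or gene-set over-representation is scored with upper-tail
binomial tests against a background frequency.  Peaks are linked to genes
three ways — TSS proximity (<= 10 kb), cross-cell-type RPKM correlation
(1 Mb window, Pearson r > 0.7), and chromatin loops (peak in one anchor,
TSS in the other) — and trajectory circuits join trajectory genes to
trajectory peaks through the proximal and loop modes, with two-sided
Fisher's-exact enrichment between the heterogeneity categories.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.stats
from sklearn.cluster import KMeans

from .io import (
    FeatureMatrix,
    GenomicIntervals,
    LoopSet,
    MotifHitTable,
    GeneSets,
    TssTable,
)
from .stats import qvalues

__all__ = [
    "PseudoBulk",
    "pseudobulk_rpkm",
    "classify_peak_specificity",
    "kmeans_peak_clusters",
    "motif_enrichment",
    "geneset_enrichment",
    "link_proximal",
    "link_nearest",
    "link_by_correlation",
    "link_by_loops",
    "circuit_table",
    "category_enrichment",
    "predict_tf_targets",
]

log = logging.getLogger(__name__)


@dataclass
class PseudoBulk:
    """feature x cell-type RPKM matrix."""

    rpkm: pd.DataFrame            # index: feature, columns: cell types
    cell_type_sizes: pd.Series    # cells per type
    feature_lengths: pd.Series    # bp per feature


def pseudobulk_rpkm(
    matrix: FeatureMatrix,
    cell_types: dict[str, str],
    feature_lengths: pd.Series | dict | None,
) -> PseudoBulk:
    """Aggregate single-cell counts per cell type and normalize to RPKM:

        RPKM(f, t) = 1e9 * counts(f, t) / (length_f * total_counts_t)

    With ``feature_lengths=None`` a counts-per-million fallback is used
    (warned; per-type correlations are unaffected by lengths).
    """
    types = pd.Series({c: cell_types[c] for c in matrix.cell_ids})
    levels = sorted(types.unique())
    M = sp.csr_matrix(matrix.values, dtype=float)
    agg = np.zeros((matrix.n_features, len(levels)))
    sizes = {}
    for j, t in enumerate(levels):
        rows = np.flatnonzero((types == t).to_numpy())
        agg[:, j] = np.asarray(M[rows].sum(axis=0)).ravel()
        sizes[t] = len(rows)
    totals = agg.sum(axis=0)
    if np.any(totals == 0):
        bad = [levels[j] for j in np.flatnonzero(totals == 0)]
        raise ValueError(f"cell types with zero total counts: {bad}")
    if feature_lengths is None:
        warnings.warn(
            "no feature lengths; computing counts-per-million instead of RPKM",
            stacklevel=2,
        )
        lengths = pd.Series(1000.0, index=matrix.feature_ids)
    else:
        lengths = pd.Series(feature_lengths).astype(float)
        lengths = lengths.loc[list(matrix.feature_ids)]
        if (lengths <= 0).any():
            bad = lengths.index[lengths <= 0].tolist()[:5]
            raise ValueError(f"zero/negative feature lengths: {bad}")
    rpkm = 1e9 * agg / (lengths.to_numpy()[:, None] * totals[None, :])
    return PseudoBulk(
        pd.DataFrame(rpkm, index=list(matrix.feature_ids), columns=levels),
        pd.Series(sizes),
        lengths,
    )


def classify_peak_specificity(
    pb: PseudoBulk,
    endocrine_types: list[str],
    non_endocrine_types: list[str],
    eps: float = 0.01,
    hi: float = 2.0,
    lo: float = 0.5,
) -> pd.DataFrame:
    """Endocrine vs non-endocrine peak classes by max-RPKM ratio.

    ratio = (max endocrine RPKM + eps) / (max non-endocrine RPKM + eps);
    > 2 endocrine-specific, < 0.5 non-endocrine-specific, else common
    (strict thresholds; the pseudocount handles zero denominators).
    """
    if not endocrine_types or not non_endocrine_types:
        raise ValueError("both type groups must be non-empty")
    endo = pb.rpkm[endocrine_types].max(axis=1)
    non = pb.rpkm[non_endocrine_types].max(axis=1)
    ratio = (endo + eps) / (non + eps)
    cls = np.where(ratio > hi, "endocrine",
                   np.where(ratio < lo, "non_endocrine", "common"))
    return pd.DataFrame(
        {"peak": pb.rpkm.index, "ratio": ratio.to_numpy(), "class": cls}
    ).reset_index(drop=True)


def kmeans_peak_clusters(
    pb_rows: pd.DataFrame, k: int, seed: int
) -> pd.Series:
    """K-means over row-normalized (max = 1) pseudo-bulk profiles.

    Cluster labels are renumbered by each cluster's argmax cell type (then
    by mean profile) for stable naming; deterministic given the seed.
    """
    X = pb_rows.to_numpy(dtype=float)
    rowmax = X.max(axis=1, keepdims=True)
    rowmax[rowmax == 0] = 1.0
    Xn = X / rowmax
    km = KMeans(n_clusters=k, random_state=seed, n_init=10)
    raw = km.fit_predict(Xn)
    centers = km.cluster_centers_
    order = sorted(
        range(k), key=lambda c: (int(np.argmax(centers[c])), -centers[c].max())
    )
    remap = {old: f"C{i+1}" for i, old in enumerate(order)}
    return pd.Series([remap[r] for r in raw], index=pb_rows.index, name="cluster")


# ---------------------------------------------------------------------------
# enrichment


def _binom_upper(observed: int, n: int, freq: float) -> float:
    """P(X >= observed), X ~ Binomial(n, freq)."""
    if observed <= 0:
        return 1.0
    return float(scipy.stats.binom.sf(observed - 1, n, freq))


def motif_enrichment(
    hits: MotifHitTable,
    foreground: set[str],
    background: set[str],
) -> pd.DataFrame:
    """Binomial motif over-representation in a peak group.

    Per motif: background frequency = fraction of background peaks with at
    least one hit; p = upper-tail Binomial(|foreground|, background freq)
    at the observed number of hit foreground peaks; q across motifs.
    """
    foreground, background = set(foreground), set(background)
    if not foreground:
        raise ValueError("empty foreground peak set")
    if not foreground <= background:
        raise ValueError("foreground must be a subset of background")
    n = len(foreground)
    rows = []
    for motif in sorted(hits.table["motif_id"].unique()):
        peaks = hits.peaks_with_motif(motif)
        bg_hit = len(peaks & background)
        if bg_hit == 0:
            warnings.warn(f"motif {motif} absent from background; skipped",
                          stacklevel=2)
            continue
        freq = bg_hit / len(background)
        obs = len(peaks & foreground)
        rows.append(
            {
                "term": motif,
                "observed": obs,
                "group_size": n,
                "background_freq": freq,
                "p": _binom_upper(obs, n, freq),
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["q"] = qvalues(out["p"].to_numpy())
        out = out.sort_values("q", kind="stable").reset_index(drop=True)
    return out


def geneset_enrichment(
    genes: list[str], sets: GeneSets, universe: list[str]
) -> pd.DataFrame:
    """Iterative binomial gene-set over-representation, ranked by q-value."""
    genes_s, universe_s = set(genes), set(universe)
    if not genes_s <= universe_s:
        raise ValueError("query genes must be a subset of the universe")
    n = len(genes_s)
    rows = []
    for name, members in sets.sets.items():
        in_uni = set(members) & universe_s
        freq = len(in_uni) / len(universe_s)
        obs = len(genes_s & in_uni)
        rows.append(
            {
                "term": name,
                "observed": obs,
                "group_size": n,
                "background_freq": freq,
                "p": _binom_upper(obs, n, freq) if freq > 0 else 1.0,
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["q"] = qvalues(out["p"].to_numpy())
        out = out.sort_values("q", kind="stable").reset_index(drop=True)
    return out


# ---------------------------------------------------------------------------
# peak-gene linking


def _peak_tss_distance(start: int, end: int, tss: int) -> int:
    """Minimal gap between a half-open interval and a point (0 if inside)."""
    if start <= tss < end:
        return 0
    return min(abs(tss - start), abs(tss - (end - 1)))


def _pair_frame(rows: list[dict]) -> pd.DataFrame:
    cols = ["peak", "gene", "mode", "distance", "r", "loop_id"]
    if not rows:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame(rows)[cols]


def link_proximal(
    peaks: GenomicIntervals, tss: TssTable, max_dist: int = 10_000
) -> pd.DataFrame:
    """All (peak, gene) pairs with peak-TSS distance <= ``max_dist``
    (inclusive boundary)."""
    rows = []
    for _, pk in peaks.table.iterrows():
        sub = tss.table[tss.table["chrom"] == pk["chrom"]]
        for _, g in sub.iterrows():
            d = _peak_tss_distance(pk["start"], pk["end"], g["tss"])
            if d <= max_dist:
                rows.append(
                    {"peak": pk["id"], "gene": g["gene"], "mode": "proximal",
                     "distance": d, "r": np.nan, "loop_id": None}
                )
    return _pair_frame(rows)


def link_nearest(peaks: GenomicIntervals, tss: TssTable) -> pd.DataFrame:
    """One nearest gene per peak (ties -> lexicographically smaller name)."""
    rows = []
    for _, pk in peaks.table.iterrows():
        sub = tss.table[tss.table["chrom"] == pk["chrom"]]
        if sub.empty:
            continue
        d = sub["tss"].map(
            lambda t: _peak_tss_distance(pk["start"], pk["end"], t)
        )
        best = d.min()
        cands = sorted(sub.loc[d == best, "gene"])
        if len(cands) > 1:
            log.info("nearest-gene tie for %s: %s; smallest name wins",
                     pk["id"], cands)
        rows.append(
            {"peak": pk["id"], "gene": cands[0], "mode": "nearest",
             "distance": int(best), "r": np.nan, "loop_id": None}
        )
    return _pair_frame(rows)


def link_by_correlation(
    pb_peaks: PseudoBulk,
    pb_genes: PseudoBulk,
    peaks: GenomicIntervals,
    tss: TssTable,
    window: int = 1_000_000,
    r_min: float = 0.7,
) -> pd.DataFrame:
    """Correlation-based links: candidate (peak, gene) pairs within
    ``window`` bp; Pearson r of their per-cell-type RPKM profiles must
    exceed ``r_min`` (strict)."""
    shared = [t for t in pb_peaks.rpkm.columns if t in pb_genes.rpkm.columns]
    if len(shared) < 3:
        raise ValueError("need >= 3 shared cell types for correlation links")
    P = pb_peaks.rpkm[shared]
    G = pb_genes.rpkm[shared]
    rows = []
    for _, pk in peaks.table.iterrows():
        if pk["id"] not in P.index:
            continue
        pvec = P.loc[pk["id"]].to_numpy()
        mid = (pk["start"] + pk["end"]) // 2
        sub = tss.table[tss.table["chrom"] == pk["chrom"]]
        for _, g in sub.iterrows():
            if g["gene"] not in G.index:
                continue
            dist = abs(int(g["tss"]) - int(mid))
            if dist > window:
                continue
            gvec = G.loc[g["gene"]].to_numpy()
            if np.std(pvec) == 0 or np.std(gvec) == 0:
                log.info("zero-variance profile for (%s, %s); skipped",
                         pk["id"], g["gene"])
                continue
            r = float(np.corrcoef(pvec, gvec)[0, 1])
            if r > r_min:
                rows.append(
                    {"peak": pk["id"], "gene": g["gene"], "mode": "correlation",
                     "distance": dist, "r": r, "loop_id": None}
                )
    return _pair_frame(rows)


def link_by_loops(
    peaks: GenomicIntervals, tss: TssTable, loops: LoopSet
) -> pd.DataFrame:
    """Loop-supported links: peak overlapping one anchor, TSS inside the
    other (either orientation)."""
    rows = []
    for _, lp in loops.table.iterrows():
        pk_sub = peaks.table[peaks.table["chrom"] == lp["chrom"]]
        g_sub = tss.table[tss.table["chrom"] == lp["chrom"]]
        for a_s, a_e, b_s, b_e in (
            (lp["start_a"], lp["end_a"], lp["start_b"], lp["end_b"]),
            (lp["start_b"], lp["end_b"], lp["start_a"], lp["end_a"]),
        ):
            pk_in = pk_sub[(pk_sub["start"] < a_e) & (pk_sub["end"] > a_s)]
            g_in = g_sub[(g_sub["tss"] >= b_s) & (g_sub["tss"] < b_e)]
            for _, pk in pk_in.iterrows():
                mid = (pk["start"] + pk["end"]) // 2
                for _, g in g_in.iterrows():
                    rows.append(
                        {"peak": pk["id"], "gene": g["gene"], "mode": "loop",
                         "distance": abs(int(g["tss"]) - int(mid)),
                         "r": np.nan, "loop_id": lp["loop_id"]}
                    )
    out = _pair_frame(rows)
    if len(out):
        out = out.drop_duplicates(subset=["peak", "gene", "loop_id"]).reset_index(
            drop=True
        )
    return out


# ---------------------------------------------------------------------------
# circuits


def circuit_table(
    gene_calls: dict[str, list[str]],
    peak_calls: dict[str, list[str]],
    links: pd.DataFrame,
) -> pd.DataFrame:
    """Trajectory circuit: trajectory genes attached to trajectory peaks by
    proximal (promoter, <= 10 kb) or loop links.  Correlation-only links do
    not count as explaining a gene.  Genes with >= 1 such peak are the
    'explained' genes."""
    gene_cat = {g: c for c, gs in gene_calls.items() for g in gs}
    peak_cat = {p: c for c, ps in peak_calls.items() for p in ps}
    sub = links[
        links["mode"].isin(["proximal", "loop"])
        & links["gene"].isin(gene_cat)
        & links["peak"].isin(peak_cat)
    ]
    out = sub.copy()
    out["gene_category"] = out["gene"].map(gene_cat)
    out["peak_category"] = out["peak"].map(peak_cat)
    return out.reset_index(drop=True)[
        ["gene", "peak", "mode", "distance", "loop_id",
         "gene_category", "peak_category"]
    ]


def category_enrichment(
    gene_categories: dict[str, str],
    peak_categories: dict[str, str],
    circuit: pd.DataFrame,
) -> pd.DataFrame:
    """Two-sided Fisher's-exact enrichment between gene and peak categories.

    For every (gene category, peak category) pair: a 2x2 table of genes in
    vs not in the gene category, split by whether they link to >= 1 peak of
    the peak category; odds ratio and two-sided p; q across the grid.
    """
    genes = sorted(gene_categories)
    linked: dict[str, set[str]] = {g: set() for g in genes}
    for _, row in circuit.iterrows():
        if row["gene"] in linked and row["peak"] in peak_categories:
            linked[row["gene"]].add(peak_categories[row["peak"]])
    rows = []
    for gcat in sorted(set(gene_categories.values())):
        in_gcat = np.array([gene_categories[g] == gcat for g in genes])
        if not in_gcat.any():
            warnings.warn(f"empty gene category {gcat}; skipped", stacklevel=2)
            continue
        for pcat in sorted(set(peak_categories.values())):
            has_link = np.array([pcat in linked[g] for g in genes])
            a = int((in_gcat & has_link).sum())
            b = int((in_gcat & ~has_link).sum())
            c = int((~in_gcat & has_link).sum())
            d = int((~in_gcat & ~has_link).sum())
            orr, p = scipy.stats.fisher_exact([[a, b], [c, d]],
                                              alternative="two-sided")
            rows.append(
                {"gene_category": gcat, "peak_category": pcat,
                 "linked": a, "not_linked": b, "other_linked": c,
                 "other_not_linked": d, "odds_ratio": orr, "p": p}
            )
    out = pd.DataFrame(rows)
    if len(out):
        out["q"] = qvalues(out["p"].to_numpy())
    return out


def predict_tf_targets(
    tf_motif: str,
    hits: MotifHitTable,
    trajectory_peaks: list[str],
    nearest_links: pd.DataFrame,
    loop_links: pd.DataFrame,
    trajectory_genes: list[str],
) -> pd.DataFrame:
    """TF target prediction: trajectory peaks carrying the TF motif are
    followed to their nearest genes and loop-connected genes; candidates
    intersected with the trajectory genes are the predicted targets, with
    one evidence row per (target, peak, mode)."""
    motif_peaks = hits.peaks_with_motif(tf_motif) & set(trajectory_peaks)
    traj_genes = set(trajectory_genes)
    rows = []
    for table in (nearest_links, loop_links):
        for _, row in table.iterrows():
            if row["peak"] in motif_peaks and row["gene"] in traj_genes:
                rows.append(
                    {"gene": row["gene"], "peak": row["peak"],
                     "mode": row["mode"]}
                )
    out = pd.DataFrame(rows, columns=["gene", "peak", "mode"])
    return out.drop_duplicates().sort_values(
        ["gene", "peak", "mode"], kind="stable"
    ).reset_index(drop=True)
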