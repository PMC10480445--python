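import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
import scipy.stats

from repact.io import FeatureMatrix, GeneSets, GenomicIntervals, LoopSet, MotifHitTable, TssTable
from repact.links import (
    category_enrichment,
    circuit_table,
    classify_peak_specificity,
    geneset_enrichment,
    kmeans_peak_clusters,
    link_by_correlation,
    link_by_loops,
    link_nearest,
    link_proximal,
    motif_enrichment,
    predict_tf_targets,
    pseudobulk_rpkm,
)


def _pb_matrix(counts, types, lengths=None, kind="peak"):
    counts = np.asarray(counts)
    ids = [f"c{i}" for i in range(counts.shape[0])]
    feats = [f"{'p' if kind == 'peak' else 'g'}{j}" for j in range(counts.shape[1])]
    fm = FeatureMatrix(sp.csr_matrix(counts), ids, feats, kind)
    cell_types = dict(zip(ids, types))
    if lengths is None:
        lengths = pd.Series(1000.0, index=feats)
    else:
        lengths = pd.Series(lengths, index=feats)
    return pseudobulk_rpkm(fm, cell_types, lengths)


# --- pseudo-bulk RPKM ------------------------------------------------------


def test_rpkm_arithmetic():
    """1 kb peak with 10 of a type's 1 M reads gives RPKM 10."""
    counts = np.zeros((1, 2), dtype=int)
    counts[0] = [10, 999_990]
    pb = _pb_matrix(counts, ["T"], lengths=[1000.0, 1000.0])
    assert pb.rpkm.loc["p0", "T"] == pytest.approx(10.0)


def test_rpkm_invariant_to_uniform_scaling():
    rng = np.random.default_rng(0)
    counts = rng.integers(1, 20, size=(6, 5))
    types = ["A"] * 3 + ["B"] * 3
    pb1 = _pb_matrix(counts, types)
    doubled = counts.copy()
    doubled[:3] *= 2  # every count in type A doubled
    pb2 = _pb_matrix(doubled, types)
    assert np.allclose(pb1.rpkm["A"], pb2.rpkm["A"], atol=1e-12)


def test_rpkm_absent_feature_zero_and_errors():
    counts = np.array([[0, 5], [0, 7]])
    pb = _pb_matrix(counts, ["A", "A"])
    assert pb.rpkm.loc["p0", "A"] == 0.0
    with pytest.raises(ValueError, match="length"):
        _pb_matrix(counts, ["A", "A"], lengths=[0.0, 1000.0])


# --- specificity -----------------------------------------------------------


def _pb_from_frame(df):
    from repact.links import PseudoBulk

    return PseudoBulk(df, pd.Series(1, index=df.columns),
                      pd.Series(1000.0, index=df.index))


def test_specificity_ratio_cases():
    df = pd.DataFrame(
        {
            "endo1": [10.0, 5.0, 1.0],
            "endo2": [2.0, 5.0, 0.0],
            "non1": [4.0, 5.0, 0.0],
        },
        index=["pk_endo", "pk_common", "pk_zero"],
    )
    out = classify_peak_specificity(
        _pb_from_frame(df), ["endo1", "endo2"], ["non1"]
    ).set_index("peak")
    assert out.loc["pk_endo", "class"] == "endocrine"       # 10.01/4.01 ~ 2.5
    assert out.loc["pk_common", "class"] == "common"        # ratio 1
    assert out.loc["pk_zero", "class"] == "endocrine"       # (1+eps)/eps >> 2
    assert out.loc["pk_endo", "ratio"] == pytest.approx(10.01 / 4.01)


def test_specificity_partitions_peaks():
    rng = np.random.default_rng(1)
    df = pd.DataFrame(rng.uniform(0, 10, size=(50, 4)),
                      index=[f"p{i}" for i in range(50)],
                      columns=["e1", "e2", "n1", "n2"])
    out = classify_peak_specificity(_pb_from_frame(df), ["e1", "e2"], ["n1", "n2"])
    assert set(out["class"]) <= {"endocrine", "non_endocrine", "common"}
    assert len(out) == 50 and out["peak"].is_unique


def test_kmeans_recovers_prototypes():
    rng = np.random.default_rng(2)
    protos = np.eye(4) * 10
    rows = np.vstack([protos[i % 4] + rng.normal(0, 0.05, 4) for i in range(40)])
    df = pd.DataFrame(rows, index=[f"p{i}" for i in range(40)],
                      columns=list("ABCD"))
    labels = kmeans_peak_clusters(df, k=4, seed=0)
    for i in range(4):
        members = labels[df.index[i::4]]
        assert members.nunique() == 1
    assert kmeans_peak_clusters(df, k=4, seed=0).equals(labels)  # deterministic
    assert kmeans_peak_clusters(df, k=1, seed=0).nunique() == 1


# --- enrichment ------------------------------------------------------------


def _hits_table(rows):
    return MotifHitTable(
        pd.DataFrame(rows, columns=["motif_id", "peak_id", "start", "stop",
                                    "score", "p_value"])
    )


def test_motif_enrichment_exact_binomial():
    """Background 100/1000 peaks hit, foreground 8/20 hit: upper-tail
    binomial sum."""
    bg_peaks = {f"b{i}" for i in range(1000)}
    fg_peaks = {f"b{i}" for i in range(20)}
    rows = [("M", f"b{i}", 1, 5, 10.0, 1e-8) for i in range(8)]
    rows += [("M", f"b{i}", 1, 5, 10.0, 1e-8) for i in range(100, 192)]
    hits = _hits_table(rows)
    out = motif_enrichment(hits, fg_peaks, bg_peaks).iloc[0]
    oracle = sum(
        scipy.stats.binom.pmf(i, 20, 0.1) for i in range(8, 21)
    )
    assert out["observed"] == 8
    assert out["background_freq"] == pytest.approx(0.1)
    assert out["p"] == pytest.approx(oracle, abs=1e-12)


def test_motif_matching_background_freq_not_significant():
    bg = {f"b{i}" for i in range(100)}
    fg = {f"b{i}" for i in range(20)}
    rows = [("M", f"b{i}", 1, 5, 10.0, 1e-8) for i in range(0, 100, 5)]
    out = motif_enrichment(_hits_table(rows), fg, bg)
    assert out.iloc[0]["p"] >= 0.3


def test_motif_absent_from_background_skipped():
    bg = {"a", "b"}
    rows = [("M", "zzz", 1, 5, 10.0, 1e-8)]
    with pytest.warns(UserWarning, match="skipped"):
        out = motif_enrichment(_hits_table(rows), {"a"}, bg)
    assert len(out) == 0


def test_geneset_enrichment_extreme_case():
    """All 10 query genes inside a set covering 10% of the universe:
    p = 0.1^10."""
    universe = [f"g{i}" for i in range(100)]
    genes = universe[:10]
    sets = GeneSets({"S": universe[:10], "other": universe[50:60]})
    out = geneset_enrichment(genes, sets, universe).set_index("term")
    assert out.loc["S", "p"] == pytest.approx(0.1 ** 10, rel=1e-9)


def test_geneset_empty_intersection_no_crash():
    universe = [f"g{i}" for i in range(50)]
    sets = GeneSets({"S": universe[40:]})
    out = geneset_enrichment(universe[:5], sets, universe)
    assert out.iloc[0]["observed"] == 0
    assert out.iloc[0]["p"] == 1.0


def test_geneset_random_draws_rarely_significant():
    rng = np.random.default_rng(3)
    universe = [f"g{i}" for i in range(500)]
    sets = GeneSets(
        {f"S{j}": list(rng.choice(universe, 25, replace=False)) for j in range(50)}
    )
    hits = 0
    for seed in range(10):
        genes = list(np.random.default_rng(seed).choice(universe, 20, replace=False))
        out = geneset_enrichment(genes, sets, universe)
        if out["q"].min() < 0.05:
            hits += 1
    assert hits <= 1


# --- linking ---------------------------------------------------------------


def _simple_geometry():
    peaks = GenomicIntervals(
        pd.DataFrame(
            {
                "chrom": ["chr1"] * 3,
                "start": [1000, 5000 - 500, 300_000],
                "end": [1500, 5000, 300_500],
                "id": ["pk_in", "pk_edge", "pk_far"],
            }
        )
    )
    tss = TssTable(
        pd.DataFrame(
            {
                "gene": ["gA", "gB"],
                "chrom": ["chr1", "chr1"],
                "tss": [1200, 14_999],
                "strand": ["+", "-"],
            }
        )
    )
    return peaks, tss


def test_proximal_containment_and_boundary():
    peaks, tss = _simple_geometry()
    out = link_proximal(peaks, tss)
    pairs = set(zip(out["peak"], out["gene"]))
    assert ("pk_in", "gA") in pairs          # TSS inside the peak, distance 0
    assert ("pk_edge", "gB") in pairs        # gap exactly 10 kb, inclusive
    d = out.set_index(["peak", "gene"])["distance"]
    assert d.loc[("pk_in", "gA")] == 0
    assert d.loc[("pk_edge", "gB")] == 10_000
    assert "pk_far" not in set(out["peak"])


def test_nearest_tie_breaks_to_smaller_name():
    peaks = GenomicIntervals(
        pd.DataFrame({"chrom": ["c"], "start": [1000], "end": [1001],
                      "id": ["pk"]})
    )
    tss = TssTable(
        pd.DataFrame({"gene": ["zz", "aa"], "chrom": ["c", "c"],
                      "tss": [900, 1100], "strand": ["+", "+"]})
    )
    out = link_nearest(peaks, tss)
    assert out.iloc[0]["gene"] == "aa"


def test_proximity_links_equal_planted_truth(toy_regulome):
    tss, peaks, loops, hits, truth = toy_regulome
    out = link_proximal(peaks, tss)
    assert set(zip(out["peak"], out["gene"])) == truth.proximal_pairs


def test_loop_links_equal_planted_truth(toy_regulome):
    tss, peaks, loops, hits, truth = toy_regulome
    out = link_by_loops(peaks, tss, loops)
    assert set(zip(out["peak"], out["gene"])) == truth.loop_pairs


def test_loop_links_symmetric_in_anchor_order(toy_regulome):
    tss, peaks, loops, hits, truth = toy_regulome
    swapped = loops.table.rename(
        columns={"start_a": "start_b", "end_a": "end_b",
                 "start_b": "start_a", "end_b": "end_a"}
    )
    out1 = link_by_loops(peaks, tss, loops)
    out2 = link_by_loops(peaks, tss, LoopSet(swapped, loops.strength_cols))
    assert set(zip(out1["peak"], out1["gene"])) == set(
        zip(out2["peak"], out2["gene"])
    )


def test_empty_loopset_empty_links(toy_regulome):
    tss, peaks, *_ = toy_regulome
    empty = LoopSet(
        pd.DataFrame(columns=["chrom", "start_a", "end_a", "start_b",
                              "end_b", "loop_id", "strength"])
    )
    assert len(link_by_loops(peaks, tss, empty)) == 0


def test_correlation_links_match_pearson_oracle():
    types = list("ABCDEFG")
    peaks = GenomicIntervals(
        pd.DataFrame({"chrom": ["c"] * 2, "start": [1000, 2000],
                      "end": [1500, 2500], "id": ["p_cor", "p_anti"]})
    )
    tss = TssTable(
        pd.DataFrame({"gene": ["g1"], "chrom": ["c"], "tss": [5000],
                      "strand": ["+"]})
    )
    from repact.links import PseudoBulk

    gvec = np.array([1.0, 2, 3, 4, 5, 6, 7])
    pcor = gvec * 2 + np.array([0.1, -0.1, 0.2, 0, 0.1, -0.2, 0])
    panti = gvec[::-1].copy()
    pb_p = PseudoBulk(
        pd.DataFrame([pcor, panti], index=["p_cor", "p_anti"], columns=types),
        pd.Series(1, index=types), pd.Series(500.0, index=["p_cor", "p_anti"]),
    )
    pb_g = PseudoBulk(
        pd.DataFrame([gvec], index=["g1"], columns=types),
        pd.Series(1, index=types), pd.Series(2000.0, index=["g1"]),
    )
    out = link_by_correlation(pb_p, pb_g, peaks, tss)
    assert set(out["peak"]) == {"p_cor"}
    r_oracle = scipy.stats.pearsonr(pcor, gvec).statistic
    assert out.iloc[0]["r"] == pytest.approx(r_oracle, abs=1e-12)


def test_correlation_window_excludes_distant_pairs():
    from repact.links import PseudoBulk

    types = list("ABC")
    peaks = GenomicIntervals(
        pd.DataFrame({"chrom": ["c"], "start": [0], "end": [500], "id": ["p"]})
    )
    tss = TssTable(
        pd.DataFrame({"gene": ["g"], "chrom": ["c"], "tss": [2_000_000],
                      "strand": ["+"]})
    )
    v = pd.Series(1, index=types)
    pb_p = PseudoBulk(pd.DataFrame([[1.0, 2, 3]], index=["p"], columns=types),
                      v, pd.Series(500.0, index=["p"]))
    pb_g = PseudoBulk(pd.DataFrame([[1.0, 2, 3]], index=["g"], columns=types),
                      v, pd.Series(1000.0, index=["g"]))
    assert len(link_by_correlation(pb_p, pb_g, peaks, tss)) == 0


# --- circuits and TF targets ----------------------------------------------


def test_circuit_counts_proximal_and_loop_only(toy_regulome):
    tss, peaks, loops, hits, truth = toy_regulome
    prox = link_proximal(peaks, tss)
    loop = link_by_loops(peaks, tss, loops)
    fake_corr = prox.assign(mode="correlation")
    links = pd.concat([prox, loop, fake_corr], ignore_index=True)
    gene_calls = {"up": list(tss.table["gene"])}
    peak_calls = {"gain": list(peaks.table["id"])}
    out = circuit_table(gene_calls, peak_calls, links)
    assert set(out["mode"]) <= {"proximal", "loop"}
    explained = set(out["gene"])
    expected = {g for _, g in truth.proximal_pairs} | {g for _, g in truth.loop_pairs}
    assert explained == expected


def test_circuit_gene_without_peak_absent():
    links = pd.DataFrame(
        {"peak": ["p1"], "gene": ["g1"], "mode": ["proximal"],
         "distance": [100], "r": [np.nan], "loop_id": [None]}
    )
    out = circuit_table({"up": ["g1", "g_lonely"]}, {"gain": ["p1"]}, links)
    assert set(out["gene"]) == {"g1"}


def test_category_enrichment_matches_hypergeometric_oracle():
    """A frozen 2x2 table checked against the exact two-sided Fisher sum."""
    gene_categories = {f"g{i}": ("X" if i < 10 else "Y") for i in range(20)}
    peak_categories = {"p": "PX"}
    # 8 of the X genes linked, 1 of the Y genes linked -> table [[8,2],[1,9]]
    circuit = pd.DataFrame(
        {
            "peak": ["p"] * 9,
            "gene": [f"g{i}" for i in range(8)] + ["g15"],
            "mode": ["proximal"] * 9,
        }
    )
    out = category_enrichment(gene_categories, peak_categories, circuit)
    row = out[(out["gene_category"] == "X")].iloc[0]
    oracle = scipy.stats.fisher_exact([[8, 2], [1, 9]])[1]
    assert row["p"] == pytest.approx(oracle, abs=1e-12)
    assert [row[k] for k in ["linked", "not_linked", "other_linked",
                             "other_not_linked"]] == [8, 2, 1, 9]


def test_category_enrichment_balanced_table_flat():
    gene_categories = {f"g{i}": ("X" if i < 20 else "Y") for i in range(40)}
    peak_categories = {"p": "PX"}
    circuit = pd.DataFrame(
        {
            "peak": ["p"] * 20,
            "gene": [f"g{i}" for i in range(10)] + [f"g{i}" for i in range(20, 30)],
            "mode": ["proximal"] * 20,
        }
    )
    out = category_enrichment(gene_categories, peak_categories, circuit)
    row = out[out["gene_category"] == "X"].iloc[0]
    assert row["odds_ratio"] == pytest.approx(1.0)
    assert row["p"] == pytest.approx(1.0)


def test_tf_targets_from_planted_regulome(toy_regulome):
    tss, peaks, loops, hits, truth = toy_regulome
    nearest = link_nearest(peaks, tss)
    loop = link_by_loops(peaks, tss, loops)
    motif = "MOTIF_A"
    traj_peaks = list(peaks.table["id"])
    traj_genes = list(tss.table["gene"])
    out = predict_tf_targets(motif, hits, traj_peaks, nearest, loop, traj_genes)
    # oracle: brute-force expected target set
    motif_peaks = truth.motif_peaks[motif]
    expected = set()
    for _, row in nearest.iterrows():
        if row["peak"] in motif_peaks:
            expected.add(row["gene"])
    for _, row in loop.iterrows():
        if row["peak"] in motif_peaks:
            expected.add(row["gene"])
    assert set(out["gene"]) == (expected & set(traj_genes))
    assert set(out["gene"]) <= set(traj_genes)
    assert not out.duplicated(["gene", "peak", "mode"]).any()


def test_tf_targets_no_hits_empty(toy_regulome):
    tss, peaks, loops, hits, truth = toy_regulome
    nearest = link_nearest(peaks, tss)
    loop = link_by_loops(peaks, tss, loops)
    out = predict_tf_targets("MOTIF_NONE", hits, list(peaks.table["id"]),
                             nearest, loop, list(tss.table["gene"]))
    assert len(out) == 0
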