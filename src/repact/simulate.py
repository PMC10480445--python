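"""Seeded synthetic multi-donor cohorts and toy regulomes.

The generator emulates the statistical structure that the trajectory
decomposition assumes: a binary-phenotype cohort in which disease shifts a
continuous latent severity, donors differ in their mean severity, and cells
within a donor spread around that mean.  Features come in three classes:

* ``intra``  — load on the full per-cell severity ``s_c = b_d + u_c``
  (disease-associated *and* variable within each donor),
* ``inter``  — load on the donor mean ``b_d`` only (between-donor shift,
  flat within a donor),
* ``null``   — no association.

RNA counts are negative binomial with log-normal library sizes and optional
extra dropout; ATAC entries are Binomial(2, sigmoid(...)), near-binary like
real single-nucleus accessibility data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import (
    CellTable,
    FeatureMatrix,
    GenomicIntervals,
    LoopSet,
    MotifHitTable,
    TssTable,
)

__all__ = ["CohortConfig", "GroundTruth", "generate_cohort", "generate_toy_regulome"]


class ConfigError(ValueError):
    """Invalid generator configuration; the message names the field."""


@dataclass
class CohortConfig:
    """Study-design parameters for a synthetic cohort.

    Defaults describe a desk-scale islet-like cohort: a balanced set of
    donors with a strong disease shift (``disease_shift`` = 2 latent s.d.
    units), moderate donor-to-donor spread, and unit within-donor spread so
    intra-donor variation carries real signal.
    """

    n_donors_healthy: int = 4
    n_donors_disease: int = 4
    cells_per_donor: int = 400
    n_genes: int = 2000
    n_peaks: int = 2000
    n_intra_features: int = 150
    n_inter_features: int = 150
    disease_shift: float = 2.0  # donor-severity mean shift (delta)
    donor_sd: float = 0.5       # sigma_b
    cell_sd: float = 1.0        # sigma_u
    effect_size: float = 0.5    # log-scale slope gamma per unit severity
    dispersion: float = 5.0     # negative-binomial shape theta
    libsize_sd: float = 0.3     # log-normal sd of per-cell depth
    dropout: float = 0.0        # extra zero-inflation pi
    seed: int = 0

    def validate(self) -> None:
        for name in (
            "n_donors_healthy", "n_donors_disease", "cells_per_donor",
            "n_genes", "n_peaks",
        ):
            if int(getattr(self, name)) <= 0:
                raise ConfigError(f"{name} must be > 0")
        for name in ("n_intra_features", "n_inter_features"):
            if int(getattr(self, name)) < 0:
                raise ConfigError(f"{name} must be >= 0")
        planted = self.n_intra_features + self.n_inter_features
        if planted > self.n_genes:
            raise ConfigError("n_intra_features + n_inter_features exceeds n_genes")
        if planted > self.n_peaks:
            raise ConfigError("n_intra_features + n_inter_features exceeds n_peaks")
        for name in ("donor_sd", "cell_sd", "dispersion"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")
        if not 0 <= self.dropout < 1:
            raise ConfigError("dropout must be in [0, 1)")
        if self.libsize_sd < 0:
            raise ConfigError("libsize_sd must be >= 0")


@dataclass
class GroundTruth:
    """Planted structure emitted alongside a cohort."""

    cell_severity: pd.Series        # s_c per cell id
    donor_severity: pd.Series       # b_d per donor id
    cell_latent: pd.Series          # u_c per cell id (s_c = b_d + u_c)
    feature_class: dict[str, pd.Series]      # modality -> class per feature
    feature_direction: dict[str, pd.Series]  # modality -> up/down (non-null)
    cell_libsize: pd.Series | None = None    # technical depth factor per cell

    def features_of(self, modality: str, cls: str) -> list[str]:
        s = self.feature_class[modality]
        return s.index[s == cls].tolist()


def _assign_classes(
    rng: np.random.Generator, ids: list[str], n_intra: int, n_inter: int
) -> tuple[pd.Series, pd.Series]:
    n = len(ids)
    classes = np.array(["null"] * n, dtype=object)
    order = rng.permutation(n)
    intra_idx = order[:n_intra]
    inter_idx = order[n_intra:n_intra + n_inter]
    classes[intra_idx] = "intra"
    classes[inter_idx] = "inter"
    direction = np.array([""] * n, dtype=object)
    # alternate signs so both directions are always represented
    for idx in (intra_idx, inter_idx):
        for j, f in enumerate(idx):
            direction[f] = "up" if j % 2 == 0 else "down"
    return (
        pd.Series(classes, index=ids, name="class"),
        pd.Series(direction, index=ids, name="direction"),
    )


def generate_cohort(
    config: CohortConfig,
) -> tuple[FeatureMatrix, FeatureMatrix, CellTable, GroundTruth]:
    """Draw a seeded cohort (RNA counts, ATAC counts, metadata, truth).

    The same latent severity drives both modalities, so matched RNA/ATAC
    analyses see a shared trajectory.  Fixed seed gives bit-identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    donors = (
        [f"H{i+1}" for i in range(config.n_donors_healthy)]
        + [f"D{i+1}" for i in range(config.n_donors_disease)]
    )
    is_disease = np.array(
        [0] * config.n_donors_healthy + [1] * config.n_donors_disease
    )
    n_donors = len(donors)
    n_cells = n_donors * config.cells_per_donor

    b_d = config.disease_shift * is_disease + rng.normal(
        0.0, config.donor_sd, n_donors
    )
    donor_of_cell = np.repeat(np.arange(n_donors), config.cells_per_donor)
    u_c = rng.normal(0.0, config.cell_sd, n_cells)
    s_c = b_d[donor_of_cell] + u_c

    cell_ids = [
        f"{donors[d]}_c{j+1}"
        for d in range(n_donors)
        for j in range(config.cells_per_donor)
    ]
    gene_ids = [f"gene{i+1}" for i in range(config.n_genes)]
    peak_ids = [f"peak{i+1}" for i in range(config.n_peaks)]

    gene_class, gene_dir = _assign_classes(
        rng, gene_ids, config.n_intra_features, config.n_inter_features
    )
    peak_class, peak_dir = _assign_classes(
        rng, peak_ids, config.n_intra_features, config.n_inter_features
    )

    # --- RNA ---------------------------------------------------------------
    alpha_g = rng.normal(np.log(0.5), 0.5, config.n_genes)  # baseline log-mean
    gamma_g = np.zeros(config.n_genes)
    sign = np.where(gene_dir.to_numpy() == "down", -1.0, 1.0)
    loaded = gene_class.to_numpy() != "null"
    gamma_g[loaded] = config.effect_size * sign[loaded]
    x_gene = np.zeros((n_cells, config.n_genes))
    intra_mask = gene_class.to_numpy() == "intra"
    inter_mask = gene_class.to_numpy() == "inter"
    x_gene[:, intra_mask] = s_c[:, None]
    x_gene[:, inter_mask] = b_d[donor_of_cell, None]

    # absolute-scale means: null genes are flat in expectation regardless of
    # severity, so "null" means null in transcript counts, not merely in
    # relative abundance (per-cell renormalization would couple every gene
    # to the planted content)
    log_mu = alpha_g[None, :] + gamma_g[None, :] * x_gene
    lib = np.exp(rng.normal(0.0, config.libsize_sd, n_cells))
    mean = np.exp(log_mu) * lib[:, None]

    theta = config.dispersion
    # NB as gamma-Poisson mixture
    lam = rng.gamma(theta, mean / theta)
    rna = rng.poisson(lam)
    if config.dropout > 0:
        keep = rng.random(rna.shape) >= config.dropout
        rna = rna * keep

    # --- ATAC --------------------------------------------------------------
    a_p = rng.normal(-1.0, 0.5, config.n_peaks)
    c_p = np.zeros(config.n_peaks)
    psign = np.where(peak_dir.to_numpy() == "down", -1.0, 1.0)
    ploaded = peak_class.to_numpy() != "null"
    c_p[ploaded] = config.effect_size * psign[ploaded]
    x_peak = np.zeros((n_cells, config.n_peaks))
    x_peak[:, peak_class.to_numpy() == "intra"] = s_c[:, None]
    x_peak[:, peak_class.to_numpy() == "inter"] = b_d[donor_of_cell, None]
    logit = a_p[None, :] + c_p[None, :] * x_peak
    p_open = 1.0 / (1.0 + np.exp(-logit))
    atac = rng.binomial(2, p_open)
    if config.dropout > 0:
        keep = rng.random(atac.shape) >= config.dropout
        atac = atac * keep

    rna_fm = FeatureMatrix(sp.csr_matrix(rna), cell_ids, gene_ids, "gene")
    atac_fm = FeatureMatrix(sp.csr_matrix(atac), cell_ids, peak_ids, "peak")
    cells = CellTable(
        pd.DataFrame(
            {
                "cell_id": cell_ids,
                "donor_id": [donors[d] for d in donor_of_cell],
                "phenotype": [
                    "disease" if is_disease[d] else "healthy" for d in donor_of_cell
                ],
            }
        )
    )
    truth = GroundTruth(
        cell_severity=pd.Series(s_c, index=cell_ids, name="s_c"),
        donor_severity=pd.Series(b_d, index=donors, name="b_d"),
        cell_latent=pd.Series(u_c, index=cell_ids, name="u_c"),
        feature_class={"rna": gene_class, "atac": peak_class},
        feature_direction={"rna": gene_dir, "atac": peak_dir},
        cell_libsize=pd.Series(lib, index=cell_ids, name="libsize"),
    )
    return rna_fm, atac_fm, cells, truth


# ---------------------------------------------------------------------------
# toy regulome


@dataclass
class RegulomeTruth:
    """Planted peak-gene relationships of a toy regulome."""

    proximal_pairs: set[tuple[str, str]]   # (peak, gene) within 10 kb of TSS
    loop_pairs: set[tuple[str, str]]       # (peak, gene) joined by a loop
    motif_peaks: dict[str, set[str]]       # motif -> peaks carrying it


def generate_toy_regulome(
    n_genes: int,
    n_peaks: int,
    n_loops: int,
    seed: int,
    proximal_fraction: float = 0.3,
    motif_ids: tuple[str, ...] = ("MOTIF_A", "MOTIF_B"),
    proximal_max_dist: int = 10_000,
) -> tuple[TssTable, GenomicIntervals, LoopSet, MotifHitTable, RegulomeTruth]:
    """Place genes and peaks on one toy chromosome with known relationships.

    Genes sit on a 100 kb grid.  A ``proximal_fraction`` of peaks is placed
    within ``proximal_max_dist`` of a TSS; the rest are mid-gap distal peaks
    (>10 kb from every TSS).  Loops connect distal peaks to TSSs of other
    genes through ~5 kb anchors.  Motif hits are planted in a labeled subset
    of peaks.  All planted relationships are returned as truth.
    """
    if min(n_genes, n_peaks) <= 0:
        raise ConfigError("n_genes and n_peaks must be > 0")
    if n_loops < 0:
        raise ConfigError("n_loops must be >= 0")
    rng = np.random.default_rng(seed)
    chrom = "chrT"
    spacing = 100_000
    tss_pos = spacing * (1 + np.arange(n_genes))
    genes = [f"gene{i+1}" for i in range(n_genes)]
    strands = rng.choice(["+", "-"], n_genes)
    tss = TssTable(
        pd.DataFrame(
            {"gene": genes, "chrom": chrom, "tss": tss_pos, "strand": strands}
        )
    )

    peak_rows = []
    proximal_pairs: set[tuple[str, str]] = set()
    n_prox = int(round(proximal_fraction * n_peaks))
    width = 500
    for i in range(n_peaks):
        pid = f"peak{i+1}"
        if i < n_prox:
            g = int(rng.integers(n_genes))
            offset = int(rng.integers(-proximal_max_dist // 2, proximal_max_dist // 2))
            start = int(tss_pos[g]) + offset
        else:
            # mid-gap: 30-45 kb past a TSS, far from all TSSs on the grid
            g = int(rng.integers(n_genes))
            start = int(tss_pos[g]) + int(rng.integers(30_000, 45_000))
        start = max(0, start)
        peak_rows.append((chrom, start, start + width, pid))
    peaks = GenomicIntervals(
        pd.DataFrame(peak_rows, columns=["chrom", "start", "end", "id"])
    )

    # truth for proximity: computed from emitted coordinates (min gap to TSS)
    for _, pk in peaks.table.iterrows():
        for g, pos in zip(genes, tss_pos):
            gap = 0 if pk["start"] <= pos < pk["end"] else min(
                abs(pos - pk["start"]), abs(pos - (pk["end"] - 1))
            )
            if gap <= proximal_max_dist:
                proximal_pairs.add((pk["id"], g))

    # loops join distal peaks to other genes' TSSs
    loop_rows = []
    distal_ids = peaks.table["id"].tolist()[n_prox:]
    anchor = 5_000
    for j in range(n_loops):
        if not distal_ids:
            break
        pid = distal_ids[j % len(distal_ids)]
        pk = peaks.table.set_index("id").loc[pid]
        g = int(rng.integers(n_genes))
        gpos = int(tss_pos[g])
        pmid = int((pk["start"] + pk["end"]) // 2)
        loop_rows.append(
            (
                chrom,
                pmid - anchor // 2, pmid + anchor // 2,
                gpos - anchor // 2, gpos + anchor // 2,
                f"loop{j+1}", float(rng.uniform(1, 100)),
            )
        )

    # loop truth by brute-force enumeration over emitted coordinates:
    # a pair is planted iff the peak overlaps one anchor and the TSS sits
    # in the other (either orientation)
    loop_pairs: set[tuple[str, str]] = set()
    for row in loop_rows:
        _, sa, ea, sb, eb, _, _ = row
        for _, pk in peaks.table.iterrows():
            in_a = pk["start"] < ea and pk["end"] > sa
            in_b = pk["start"] < eb and pk["end"] > sb
            for g, pos in zip(genes, tss_pos):
                tss_in_a = sa <= pos < ea
                tss_in_b = sb <= pos < eb
                if (in_a and tss_in_b) or (in_b and tss_in_a):
                    loop_pairs.add((pk["id"], g))
    loops = LoopSet(
        pd.DataFrame(
            loop_rows,
            columns=[
                "chrom", "start_a", "end_a", "start_b", "end_b",
                "loop_id", "strength",
            ],
        )
    )

    # plant motif hits in a random subset of peaks per motif
    hit_rows = []
    motif_peaks: dict[str, set[str]] = {}
    all_ids = peaks.table["id"].tolist()
    for m in motif_ids:
        chosen = rng.choice(all_ids, size=max(1, n_peaks // 4), replace=False)
        motif_peaks[m] = set(chosen)
        for pid in chosen:
            s = int(rng.integers(0, width - 10))
            hit_rows.append((m, pid, s, s + 10, float(rng.uniform(5, 20)), 1e-8))
    hits = MotifHitTable(
        pd.DataFrame(
            hit_rows,
            columns=["motif_id", "peak_id", "start", "stop", "score", "p_value"],
        )
    )
    truth = RegulomeTruth(proximal_pairs, loop_pairs, motif_peaks)
    return tss, peaks, loops, hits, truth
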