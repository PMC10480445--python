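"""Cell-level quality filters.

Four rules: (1) hormone-based doublet calling on raw RNA counts — a cell
highly expressing two or more hormone genes is a doublet; (2) a
post-clustering consistency check flagging cells carrying many transcripts
of a hormone foreign to their assigned type; (3) snATAC cell QC on
fraction-of-reads-in-peaks and total reads; (4) a weighted-KNN unambiguity
score on a co-embedding that flags cross-modality doublets.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from .embed import Embedding
from .io import FeatureMatrix

__all__ = [
    "DoubletCall",
    "AmbiguityScore",
    "AtacCellQc",
    "HORMONE_GENES",
    "hormone_doublet_filter",
    "hormone_consistency_filter",
    "atac_cell_qc",
    "knn_unambiguity_filter",
]

log = logging.getLogger(__name__)

HORMONE_GENES = ["INS", "GCG", "SST", "PPY"]


@dataclass
class DoubletCall:
    cell_id: str
    high_hormones: frozenset[str]
    is_doublet: bool


@dataclass
class AmbiguityScore:
    cell_id: str
    nearest_type: str
    second_type: str | None
    score: float  # >= 1; inf when all neighbors share one type
    passes: bool


@dataclass
class AtacCellQc:
    cell_id: str
    reads_in_peaks: int
    total_reads: int
    frac_in_peaks: float
    passes: bool


def hormone_doublet_filter(
    rna: FeatureMatrix,
    hormone_genes: list[str] | None = None,
    frac: float = 0.10,
) -> list[DoubletCall]:
    """Call doublets from hormone co-expression.

    For each hormone the positive population is the cells with nonzero
    counts; a cell is "high" when its count exceeds ``frac`` times the
    median count of that positive population; two or more highs make a
    doublet.
    """
    hormone_genes = hormone_genes or HORMONE_GENES
    idx = pd.Index(rna.feature_ids)
    missing = [g for g in hormone_genes if g not in idx]
    if missing:
        raise KeyError(f"hormone genes absent from matrix: {missing}")
    counts = np.asarray(
        rna.values[:, rna.feature_index(hormone_genes)].todense()
    )
    high = np.zeros(counts.shape, dtype=bool)
    for j, gene in enumerate(hormone_genes):
        col = counts[:, j]
        pos = col[col > 0]
        if pos.size == 0:
            warnings.warn(
                f"no positive cells for hormone {gene}; it contributes no "
                "high calls", stacklevel=2,
            )
            continue
        threshold = frac * float(np.median(pos))
        high[:, j] = col > threshold
    calls = []
    for i, cell in enumerate(rna.cell_ids):
        hs = frozenset(g for j, g in enumerate(hormone_genes) if high[i, j])
        calls.append(DoubletCall(cell, hs, len(hs) >= 2))
    return calls


def hormone_consistency_filter(
    rna: FeatureMatrix,
    cell_types: dict[str, str],
    type_hormone: dict[str, str],
    max_off: int = 15,
) -> set[str]:
    """Flag typed cells carrying more than ``max_off`` transcripts of a
    hormone not expected for their assigned type (strict inequality).
    Untyped cells and types with no hormone mapping pass."""
    hormones = sorted(set(type_hormone.values()))
    present = [h for h in hormones if h in set(rna.feature_ids)]
    counts = np.asarray(rna.values[:, rna.feature_index(present)].todense())
    col = {h: j for j, h in enumerate(present)}
    flagged: set[str] = set()
    for i, cell in enumerate(rna.cell_ids):
        ctype = cell_types.get(cell)
        if ctype is None:
            continue
        expected = type_hormone.get(ctype)
        if expected is None:
            log.info("type %s has no hormone mapping; cell %s passes", ctype, cell)
            continue
        for h in present:
            if h != expected and counts[i, col[h]] > max_off:
                flagged.add(cell)
                break
    return flagged


def atac_cell_qc(
    reads_in_peaks,
    total_reads,
    cell_ids: list[str] | None = None,
    min_frac: float = 0.15,
    min_reads: int = 1500,
) -> list[AtacCellQc]:
    """snATAC cell QC: pass iff fraction-in-peaks > ``min_frac`` AND total
    reads > ``min_reads`` (both strict)."""
    rip = np.asarray(reads_in_peaks)
    tot = np.asarray(total_reads)
    if rip.shape != tot.shape:
        raise ValueError("reads_in_peaks and total_reads must align")
    if np.any(rip < 0) or np.any(tot < 0):
        raise ValueError("read counts must be non-negative")
    if np.any(rip > tot):
        bad = int(np.flatnonzero(rip > tot)[0])
        raise ValueError(
            f"reads_in_peaks > total_reads at position {bad}"
        )
    if cell_ids is None:
        cell_ids = [f"cell{i}" for i in range(rip.size)]
    out = []
    for cid, r, t in zip(cell_ids, rip, tot):
        frac = r / t if t > 0 else 0.0
        out.append(
            AtacCellQc(cid, int(r), int(t), float(frac),
                       bool(frac > min_frac and t > min_reads))
        )
    return out


def knn_unambiguity_filter(
    embedding: Embedding,
    labeled_reference: dict[str, str],
    query_cells: list[str],
    k: int = 20,
    cutoff: float = 10.0,
    direction: str = "min_score",
) -> list[AmbiguityScore]:
    """Unambiguity score of query cells against a labeled reference.

    For each query cell: its ``k`` nearest reference cells (Euclidean in
    the embedding), neighbor distances grouped by type; the score is the
    ratio of the second-smallest to the smallest mean type distance (>= 1;
    +inf when all neighbors share one type).  A cell passes when score >=
    ``cutoff`` — high scores mean one type dominates the neighborhood, so
    the cell is unambiguous; low scores mark potential doublets.
    The ratio orientation (larger/smaller) is this package's reading; with
    ``direction="max_score"`` the filter flips to keep low scores instead.
    """
    frame = embedding.to_frame()
    ref_cells = [c for c in frame.index if c in labeled_reference]
    if len(set(labeled_reference[c] for c in ref_cells)) < 2:
        raise ValueError("reference needs >= 2 cell types")
    if k > len(ref_cells):
        raise ValueError(f"k={k} exceeds reference size {len(ref_cells)}")
    ref = frame.loc[ref_cells].to_numpy()
    types = np.array([labeled_reference[c] for c in ref_cells])
    nn = NearestNeighbors(n_neighbors=k).fit(ref)
    q = frame.loc[list(query_cells)].to_numpy()
    dist, idx = nn.kneighbors(q)
    out = []
    for i, cell in enumerate(query_cells):
        ts = types[idx[i]]
        means = (
            pd.Series(dist[i]).groupby(pd.Series(ts)).mean().sort_values()
        )
        # tie-break on equal means: alphabetical type order (stable sort)
        if len(means) == 1:
            score = float("inf")
            nearest, second = str(means.index[0]), None
        else:
            if means.iloc[0] == means.iloc[1]:
                log.info("tied nearest-type means for %s; name order used", cell)
            nearest, second = str(means.index[0]), str(means.index[1])
            if means.iloc[0] == 0:
                score = float("inf")
            else:
                score = float(means.iloc[1] / means.iloc[0])
        passes = score >= cutoff if direction == "min_score" else score <= cutoff
        out.append(AmbiguityScore(cell, nearest, second, score, bool(passes)))
    return out
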