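"""Readers, writers, and in-memory containers for the on-disk formats.

All genomic coordinates are held 0-based half-open (BED convention).
MatrixMarket coordinate files use 1-based indices; the conversion happens
exactly once, inside :func:`read_feature_matrix` / :func:`write_feature_matrix`
(delegated to :mod:`scipy.io`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = [
    "FeatureMatrix",
    "CellTable",
    "GenomicIntervals",
    "TssTable",
    "LoopSet",
    "MotifHitTable",
    "GeneSets",
    "FormatError",
    "read_feature_matrix",
    "write_feature_matrix",
    "read_cells",
    "write_cells",
    "read_bed",
    "write_bed",
    "read_bedpe",
    "write_bedpe",
    "read_fimo",
    "write_fimo",
    "read_gmt",
    "write_gmt",
    "read_tss",
    "write_tss",
]


class FormatError(ValueError):
    """Raised when an on-disk file violates its format contract."""


def _check_unique(names: Sequence[str], what: str) -> None:
    s = pd.Index(names)
    if s.has_duplicates:
        dups = s[s.duplicated()].unique().tolist()[:5]
        raise FormatError(f"duplicate {what} ids: {dups}")


@dataclass
class FeatureMatrix:
    """Sparse cells x features matrix with attached names.

    ``values`` is CSR, cells in rows.  Raw matrices are integer counts;
    after normalization (TF-IDF etc.) ``is_normalized`` is set and the
    dtype is float.
    """

    values: sp.csr_matrix
    cell_ids: list[str]
    feature_ids: list[str]
    feature_kind: str = "gene"  # "gene" | "peak"
    is_normalized: bool = False

    def __post_init__(self) -> None:
        self.values = sp.csr_matrix(self.values)
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.feature_ids = [str(f) for f in self.feature_ids]
        n, m = self.values.shape
        if n != len(self.cell_ids):
            raise FormatError(
                f"matrix has {n} rows but {len(self.cell_ids)} cell ids"
            )
        if m != len(self.feature_ids):
            raise FormatError(
                f"matrix has {m} columns but {len(self.feature_ids)} feature ids"
            )
        _check_unique(self.cell_ids, "cell")
        _check_unique(self.feature_ids, "feature")
        if self.feature_kind not in ("gene", "peak"):
            raise FormatError(f"feature_kind must be gene|peak, got {self.feature_kind!r}")
        if not self.is_normalized:
            if self.values.nnz and np.any(self.values.data < 0):
                raise FormatError("raw count matrix contains negative entries")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_dense(self) -> np.ndarray:
        return np.asarray(self.values.todense())

    def feature_index(self, names: Sequence[str]) -> np.ndarray:
        idx = pd.Index(self.feature_ids)
        pos = idx.get_indexer(list(names))
        missing = [n for n, p in zip(names, pos) if p < 0]
        if missing:
            raise KeyError(f"features not in matrix: {missing[:5]}")
        return pos

    def subset_features(self, keep: Sequence[str]) -> "FeatureMatrix":
        pos = self.feature_index(keep)
        return FeatureMatrix(
            self.values[:, pos],
            list(self.cell_ids),
            [self.feature_ids[i] for i in pos],
            self.feature_kind,
            self.is_normalized,
        )

    def subset_cells(self, keep: Sequence[str]) -> "FeatureMatrix":
        idx = pd.Index(self.cell_ids)
        pos = idx.get_indexer(list(keep))
        if (pos < 0).any():
            raise KeyError("some requested cells absent from matrix")
        return FeatureMatrix(
            self.values[pos],
            [self.cell_ids[i] for i in pos],
            list(self.feature_ids),
            self.feature_kind,
            self.is_normalized,
        )


@dataclass
class CellTable:
    """Per-cell metadata: donor, binary phenotype, optional cell type."""

    table: pd.DataFrame  # columns: cell_id, donor_id, phenotype[, cell_type]

    PHENOTYPES = ("healthy", "disease")
    # accepted input spellings, case-insensitive
    _ALIASES = {"healthy": "healthy", "t2d": "disease", "disease": "disease"}

    def __post_init__(self) -> None:
        t = self.table.copy()
        required = {"cell_id", "donor_id", "phenotype"}
        if not required.issubset(t.columns):
            raise FormatError(f"cell table needs columns {sorted(required)}")
        _check_unique(t["cell_id"].tolist(), "cell")
        norm = t["phenotype"].astype(str).str.lower().map(self._ALIASES)
        bad = t.loc[norm.isna(), "phenotype"].unique().tolist()
        if bad:
            raise FormatError(
                f"unknown phenotype labels {bad}; accepted: healthy, T2D, disease"
            )
        t["phenotype"] = norm
        self.table = t.reset_index(drop=True)

    @property
    def cell_ids(self) -> list[str]:
        return self.table["cell_id"].tolist()

    def phenotype_of(self, cells: Sequence[str]) -> np.ndarray:
        """Binary labels (1 = disease) aligned to ``cells``."""
        m = self.table.set_index("cell_id")["phenotype"]
        return (m.loc[list(cells)] == "disease").to_numpy().astype(int)

    def donor_of(self, cells: Sequence[str]) -> np.ndarray:
        m = self.table.set_index("cell_id")["donor_id"]
        return m.loc[list(cells)].to_numpy()


@dataclass
class GenomicIntervals:
    """Named intervals, 0-based half-open."""

    table: pd.DataFrame  # columns: chrom, start, end, id

    def __post_init__(self) -> None:
        t = self.table.reset_index(drop=True)
        if not {"chrom", "start", "end", "id"}.issubset(t.columns):
            raise FormatError("intervals need columns chrom,start,end,id")
        if (t["start"] >= t["end"]).any():
            bad = t[t["start"] >= t["end"]].iloc[0]
            raise FormatError(f"interval start >= end at {bad['id']}")
        _check_unique(t["id"].tolist(), "interval")
        self.table = t

    def __len__(self) -> int:
        return len(self.table)

    @property
    def ids(self) -> list[str]:
        return self.table["id"].tolist()

    def midpoints(self) -> np.ndarray:
        return ((self.table["start"] + self.table["end"]) // 2).to_numpy()


@dataclass
class TssTable:
    """One TSS per gene (5'-most on the gene's strand when several exist)."""

    table: pd.DataFrame  # columns: gene, chrom, tss, strand

    def __post_init__(self) -> None:
        t = self.table.reset_index(drop=True)
        if not {"gene", "chrom", "tss", "strand"}.issubset(t.columns):
            raise FormatError("TSS table needs columns gene,chrom,tss,strand")
        _check_unique(t["gene"].tolist(), "gene")
        if not t["strand"].isin(["+", "-"]).all():
            raise FormatError("strand must be + or -")
        self.table = t

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class LoopSet:
    """Chromatin loops: two ~5 kb anchors plus per-condition strength."""

    table: pd.DataFrame
    # columns: chrom, start_a, end_a, start_b, end_b, loop_id, strength columns

    strength_cols: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        t = self.table.reset_index(drop=True)
        need = {"chrom", "start_a", "end_a", "start_b", "end_b", "loop_id"}
        if not need.issubset(t.columns):
            raise FormatError(f"loop table needs columns {sorted(need)}")
        if not self.strength_cols:
            self.strength_cols = [
                c for c in t.columns if c.startswith("strength")
            ]
        for c in self.strength_cols:
            if (t[c] < 0).any():
                raise FormatError(f"negative loop strength in column {c}")
        self.table = t

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class MotifHitTable:
    """FIMO-style motif occurrences within peaks, filtered at ingestion."""

    table: pd.DataFrame  # columns: motif_id, peak_id, start, stop, score, p_value

    def __post_init__(self) -> None:
        t = self.table.reset_index(drop=True)
        need = {"motif_id", "peak_id", "start", "stop", "score", "p_value"}
        if not need.issubset(t.columns):
            raise FormatError(f"motif hit table needs columns {sorted(need)}")
        if ((t["p_value"] <= 0) | (t["p_value"] > 1)).any():
            raise FormatError("motif hit p-values must be in (0, 1]")
        self.table = t

    def __len__(self) -> int:
        return len(self.table)

    def peaks_with_motif(self, motif_id: str) -> set[str]:
        t = self.table
        return set(t.loc[t["motif_id"] == motif_id, "peak_id"])


@dataclass
class GeneSets:
    """Named gene sets (GMT semantics)."""

    sets: dict[str, list[str]]

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise FormatError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)


# ---------------------------------------------------------------------------
# feature matrices


def read_feature_matrix(
    path_matrix: str | Path,
    path_cells: str | Path,
    path_features: str | Path,
    kind: str = "gene",
) -> FeatureMatrix:
    """Load a cells x features matrix (MatrixMarket triplet or dense TSV)."""
    path_matrix = Path(path_matrix)
    if path_matrix.suffix == ".mtx":
        mat = sp.csr_matrix(scipy.io.mmread(path_matrix))
    else:
        mat = sp.csr_matrix(
            pd.read_csv(path_matrix, sep="\t", header=None).to_numpy()
        )
    cells = Path(path_cells).read_text().splitlines()
    feats = Path(path_features).read_text().splitlines()
    cells = [c for c in cells if c]
    feats = [f for f in feats if f]
    if np.all(mat.data == np.round(mat.data)) if mat.nnz else True:
        mat = mat.astype(np.int64)
        normalized = False
    else:
        normalized = True
    return FeatureMatrix(mat, cells, feats, kind, is_normalized=normalized)


def write_feature_matrix(
    fm: FeatureMatrix,
    path_matrix: str | Path,
    path_cells: str | Path,
    path_features: str | Path,
) -> None:
    scipy.io.mmwrite(str(path_matrix), sp.coo_matrix(fm.values))
    Path(path_cells).write_text("\n".join(fm.cell_ids) + "\n")
    Path(path_features).write_text("\n".join(fm.feature_ids) + "\n")


# ---------------------------------------------------------------------------
# tables


def read_cells(path: str | Path) -> CellTable:
    return CellTable(pd.read_csv(path, sep="\t", dtype={"cell_id": str, "donor_id": str}))


def write_cells(cells: CellTable, path: str | Path) -> None:
    cells.table.to_csv(path, sep="\t", index=False)


def read_bed(path: str | Path) -> GenomicIntervals:
    t = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "id"], usecols=[0, 1, 2, 3],
        dtype={0: str, 3: str},
    )
    return GenomicIntervals(t)


def write_bed(iv: GenomicIntervals, path: str | Path) -> None:
    iv.table[["chrom", "start", "end", "id"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def read_tss(path: str | Path) -> TssTable:
    t = pd.read_csv(path, sep="\t")
    if "gene" not in t.columns:  # headerless BED4+strand fallback
        t = pd.read_csv(
            path, sep="\t", header=None,
            names=["chrom", "tss", "_end", "gene", "_score", "strand"],
            usecols=[0, 1, 2, 3, 4, 5],
        )[["gene", "chrom", "tss", "strand"]]
    return TssTable(t)


def write_tss(tss: TssTable, path: str | Path) -> None:
    tss.table[["gene", "chrom", "tss", "strand"]].to_csv(path, sep="\t", index=False)


def read_bedpe(path: str | Path, top_k: int | None = None) -> LoopSet:
    """Read loops; ``top_k`` keeps the strongest rows by the first strength
    column (rank filter over contact strength)."""
    t = pd.read_csv(path, sep="\t")
    if "chrom" not in t.columns:
        raise FormatError("BEDPE loop file needs a header with a 'chrom' column")
    ls = LoopSet(t)
    if top_k is not None and top_k < len(ls):
        col = ls.strength_cols[0]
        keep = ls.table.nlargest(top_k, col, keep="first")
        ls = LoopSet(keep.reset_index(drop=True), ls.strength_cols)
    return ls


def write_bedpe(loops: LoopSet, path: str | Path) -> None:
    loops.table.to_csv(path, sep="\t", index=False)


def read_fimo(path: str | Path, p_max: float = 1e-6) -> MotifHitTable:
    """Read a FIMO TSV; hits with p-value > ``p_max`` are dropped at the
    boundary (significant-hit definition)."""
    t = pd.read_csv(path, sep="\t", comment="#")
    rename = {"sequence_name": "peak_id", "p-value": "p_value"}
    t = t.rename(columns=rename)
    need = {"motif_id", "peak_id", "start", "stop", "score", "p_value"}
    if not need.issubset(t.columns):
        raise FormatError(f"FIMO table needs columns {sorted(need)}")
    kept = t[t["p_value"] < p_max].reset_index(drop=True)
    return MotifHitTable(
        kept[["motif_id", "peak_id", "start", "stop", "score", "p_value"]]
    )


def write_fimo(hits: MotifHitTable, path: str | Path) -> None:
    t = hits.table.rename(columns={"peak_id": "sequence_name", "p_value": "p-value"})
    cols = ["motif_id", "sequence_name", "start", "stop", "score", "p-value"]
    t[cols].to_csv(path, sep="\t", index=False)


def read_gmt(path: str | Path) -> GeneSets:
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise FormatError(f"GMT line with <3 fields: {line[:50]!r}")
        sets[parts[0]] = [g for g in parts[2:] if g]
    return GeneSets(sets)


def write_gmt(gene_sets: GeneSets, path: str | Path) -> None:
    lines = [
        "\t".join([name, name] + genes) for name, genes in gene_sets.sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")
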