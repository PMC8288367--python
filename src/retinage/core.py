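"""Core containers and primitive operations shared by every pipeline stage.

The universal input is a :class:`CellMatrix`: a sparse gene x cell matrix of
raw UMI counts together with per-cell metadata (donor, species, age in years,
and retinal region, fovea or periphery).  Everything downstream consumes the
library-size-normalized, log-transformed :class:`NormalizedMatrix` produced by
:func:`normalize`.

Counts are stored genes-in-rows (CSR), matching the Matrix Market layout the
readers and writers use (CellRanger v3 style ``matrix.mtx`` / ``features.tsv``
/ ``barcodes.tsv`` plus a ``cells.tsv`` metadata table).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
import yaml
from scipy import io as spio
from scipy import stats
from statsmodels.stats.multitest import multipletests

REGIONS = ("fovea", "periphery")
SPECIES = ("human", "macaque")
META_COLUMNS = ("donor_id", "species", "age_years", "region")

__all__ = [
    "REGIONS",
    "SPECIES",
    "META_COLUMNS",
    "CellMatrix",
    "NormalizedMatrix",
    "MarkerPanel",
    "SubtypeRule",
    "StageMap",
    "DEFAULT_STAGE_MAP",
    "read_matrix",
    "write_matrix",
    "normalize",
    "pseudobulk",
    "differential_expression",
]


def _as_str_array(values: Iterable[str], what: str) -> np.ndarray:
    arr = np.asarray(list(values), dtype=object)
    if arr.ndim != 1:
        raise ValueError(f"{what} must be one-dimensional")
    if len(set(arr)) != len(arr):
        dup = pd.Series(arr).value_counts()
        dup = dup[dup > 1].index.tolist()[:5]
        raise ValueError(f"duplicate {what}: {dup}")
    return arr


@dataclass
class CellMatrix:
    """Raw counts (genes x cells) with aligned per-cell metadata.

    ``meta`` is indexed by barcode and carries ``donor_id``, ``species``,
    ``age_years`` and ``region``.  ``truth`` optionally carries ground-truth
    labels from the synthetic-data generator for recovery testing.
    """

    counts: sp.spmatrix
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    meta: pd.DataFrame
    truth: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.gene_ids = _as_str_array(self.gene_ids, "gene_ids")
        self.cell_ids = _as_str_array(self.cell_ids, "cell_ids")
        if self.counts.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        data = self.counts.data
        if data.size and (np.any(data < 0) or np.any(data != np.round(data))):
            raise ValueError("counts must be non-negative integers")
        self.counts.data = np.asarray(np.round(data), dtype=np.int64)
        if not isinstance(self.meta, pd.DataFrame):
            raise TypeError("meta must be a pandas DataFrame indexed by barcode")
        missing_cols = [c for c in META_COLUMNS if c not in self.meta.columns]
        if missing_cols:
            raise ValueError(f"meta is missing columns {missing_cols}")
        missing = [b for b in self.cell_ids if b not in self.meta.index]
        if missing:
            raise ValueError(
                f"metadata missing for {len(missing)} barcode(s), "
                f"e.g. {missing[:5]}"
            )
        if len(self.meta) != len(self.cell_ids):
            extra = set(self.meta.index) - set(self.cell_ids)
            raise ValueError(
                f"metadata has {len(extra)} barcode(s) absent from the matrix, "
                f"e.g. {sorted(extra)[:5]}"
            )
        self.meta = self.meta.loc[list(self.cell_ids)]
        bad_region = set(self.meta["region"]) - set(REGIONS)
        if bad_region:
            raise ValueError(f"unknown region value(s) {sorted(bad_region)}")
        bad_species = set(self.meta["species"]) - set(SPECIES)
        if bad_species:
            raise ValueError(f"unknown species value(s) {sorted(bad_species)}")
        ages = np.asarray(self.meta["age_years"], dtype=float)
        if np.any(ages < 0) or np.any(~np.isfinite(ages)):
            raise ValueError("age_years must be finite and non-negative")
        if self.truth is not None:
            self.truth = self.truth.loc[list(self.cell_ids)]

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def library_sizes(self) -> np.ndarray:
        return np.asarray(self.counts.sum(axis=0)).ravel()

    def gene_index(self, genes: Sequence[str]) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in lookup]
        if missing:
            raise KeyError(f"gene(s) not in matrix: {missing[:10]}")
        return np.array([lookup[g] for g in genes], dtype=int)


@dataclass
class NormalizedMatrix:
    """Library-size-normalized, natural-log transformed expression values.

    ``values[g, c] = log(1 + counts[g, c] * scale_total / libsize(c))``.
    Shape and identifiers match the source :class:`CellMatrix`.
    """

    values: sp.spmatrix
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    meta: pd.DataFrame
    scale_total: float
    truth: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.values = sp.csr_matrix(self.values)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError("values shape does not match gene/cell identifiers")
        if self.values.data.size and np.any(self.values.data < 0):
            raise ValueError("normalized values must be non-negative")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    gene_index = CellMatrix.gene_index

    def cell_mask(self, cells: Sequence[str] | np.ndarray) -> np.ndarray:
        """Boolean mask over columns from barcodes, indices or a mask."""
        cells = np.asarray(cells)
        if cells.dtype == bool:
            if cells.shape != (self.n_cells,):
                raise ValueError("boolean cell mask has wrong length")
            return cells
        if np.issubdtype(cells.dtype, np.integer):
            mask = np.zeros(self.n_cells, dtype=bool)
            mask[cells] = True
            return mask
        lookup = {b: i for i, b in enumerate(self.cell_ids)}
        missing = [b for b in cells if b not in lookup]
        if missing:
            raise KeyError(f"barcode(s) not in matrix: {missing[:5]}")
        mask = np.zeros(self.n_cells, dtype=bool)
        mask[[lookup[b] for b in cells]] = True
        return mask

    def dense(self, gene_rows: np.ndarray | None = None,
              cell_mask: np.ndarray | None = None) -> np.ndarray:
        sub = self.values
        if gene_rows is not None:
            sub = sub[gene_rows]
        if cell_mask is not None:
            sub = sub[:, cell_mask]
        return np.asarray(sub.todense())


@dataclass(frozen=True)
class SubtypeRule:
    positive_markers: tuple[str, ...]
    negative_markers: tuple[str, ...] = ()


@dataclass
class MarkerPanel:
    """Positive marker genes per major cell type plus subtype rules.

    ``subtype_rules`` maps ``(cell_type, subtype)`` to a :class:`SubtypeRule`;
    a subtype may only be declared for a cell type present in ``entries``.
    """

    entries: dict[str, list[str]]
    subtype_rules: dict[tuple[str, str], SubtypeRule] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("marker panel has no cell types")
        for cell_type, markers in self.entries.items():
            if not markers or any(not m for m in markers):
                raise ValueError(f"empty marker symbol for cell type {cell_type!r}")
        for (cell_type, subtype), rule in self.subtype_rules.items():
            if cell_type not in self.entries:
                raise ValueError(
                    f"subtype {subtype!r} declared for absent cell type {cell_type!r}"
                )
            for m in (*rule.positive_markers, *rule.negative_markers):
                if not m:
                    raise ValueError("empty marker symbol in subtype rule")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "MarkerPanel":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        rules = {}
        for cell_type, subtypes in (raw.get("subtypes") or {}).items():
            for subtype, spec_ in subtypes.items():
                rules[(cell_type, subtype)] = SubtypeRule(
                    tuple(spec_.get("positive", [])),
                    tuple(spec_.get("negative", [])),
                )
        return cls(entries={k: list(v) for k, v in raw["markers"].items()},
                   subtype_rules=rules)

    def to_yaml(self, path: str | Path) -> Path:
        subtypes: dict[str, dict] = {}
        for (cell_type, subtype), rule in self.subtype_rules.items():
            subtypes.setdefault(cell_type, {})[subtype] = {
                "positive": list(rule.positive_markers),
                "negative": list(rule.negative_markers),
            }
        with open(path, "w") as fh:
            yaml.safe_dump({"markers": self.entries, "subtypes": subtypes}, fh)
        return Path(path)


@dataclass(frozen=True)
class StageMap:
    """Ordered, non-overlapping donor-age intervals defining stage groups.

    The default mirrors a three-stage adult/mid/aging split of human donors:
    adult 18-45 y, mid 46-70 y, aging 71-120 y.  Ages outside every interval
    map to ``"unstaged"``.
    """

    boundaries: tuple[tuple[str, float, float], ...] = (
        ("adult", 18.0, 45.0),
        ("mid", 46.0, 70.0),
        ("aging", 71.0, 120.0),
    )

    def __post_init__(self) -> None:
        names = [b[0] for b in self.boundaries]
        if len(set(names)) != len(names):
            raise ValueError("stage names must be unique")
        prev_hi = -np.inf
        for name, lo, hi in self.boundaries:
            if lo > hi:
                raise ValueError(f"stage {name!r} has min_age > max_age")
            if lo <= prev_hi:
                raise ValueError("stage intervals must be ordered and non-overlapping")
            prev_hi = hi

    @property
    def stage_names(self) -> tuple[str, ...]:
        return tuple(b[0] for b in self.boundaries)

    def assign(self, age_years: float) -> str:
        if age_years < 0 or not np.isfinite(age_years):
            raise ValueError(f"invalid age {age_years!r}")
        for name, lo, hi in self.boundaries:
            if lo <= age_years <= hi:
                return name
        return "unstaged"

    def assign_many(self, ages: Iterable[float]) -> np.ndarray:
        return np.array([self.assign(a) for a in ages], dtype=object)


DEFAULT_STAGE_MAP = StageMap()


# ---------------------------------------------------------------------------
# IO: CellRanger-v3-style MTX triplet + cells.tsv metadata table
# ---------------------------------------------------------------------------

_FILES = ("matrix.mtx", "features.tsv", "barcodes.tsv", "cells.tsv")


def write_matrix(matrix: CellMatrix, dir_path: str | Path) -> Path:
    """Write ``matrix.mtx`` + ``features.tsv`` + ``barcodes.tsv`` + ``cells.tsv``.

    Round-trips exactly through :func:`read_matrix`.  Truth labels, when
    present, go to ``truth.tsv`` alongside.
    """
    if matrix.n_cells == 0 or matrix.n_genes == 0:
        raise ValueError("refusing to write an empty matrix (0 genes or 0 cells)")
    out = Path(dir_path)
    out.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(out / "matrix.mtx", sp.coo_matrix(matrix.counts), field="integer")
    feat = pd.DataFrame(
        {"id": matrix.gene_ids, "name": matrix.gene_ids,
         "type": "Gene Expression"}
    )
    feat.to_csv(out / "features.tsv", sep="\t", header=False, index=False)
    pd.Series(matrix.cell_ids).to_csv(
        out / "barcodes.tsv", sep="\t", header=False, index=False
    )
    meta = matrix.meta.loc[list(matrix.cell_ids), list(META_COLUMNS)].copy()
    meta.insert(0, "barcode", matrix.cell_ids)
    meta.to_csv(out / "cells.tsv", sep="\t", index=False)
    if matrix.truth is not None:
        truth = matrix.truth.copy()
        truth.insert(0, "barcode", matrix.cell_ids)
        truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    return out


def read_matrix(dir_path: str | Path) -> CellMatrix:
    """Read the MTX triplet plus ``cells.tsv`` metadata written by
    :func:`write_matrix` (or any CellRanger-v3-style export with a metadata
    table keyed by barcode)."""
    src = Path(dir_path)
    missing = [f for f in _FILES if not (src / f).exists()]
    if missing:
        raise FileNotFoundError(f"missing file(s) in {src}: {missing}")
    counts = spio.mmread(src / "matrix.mtx")
    if counts.data.size and np.any(counts.data != np.round(counts.data)):
        raise ValueError("matrix.mtx contains non-integer counts")
    features = pd.read_csv(src / "features.tsv", sep="\t", header=None)
    gene_ids = features.iloc[:, 0].astype(str).to_numpy()
    barcodes = (
        pd.read_csv(src / "barcodes.tsv", sep="\t", header=None)
        .iloc[:, 0].astype(str).to_numpy()
    )
    meta = pd.read_csv(src / "cells.tsv", sep="\t")
    if "barcode" not in meta.columns:
        raise ValueError("cells.tsv must have a leading 'barcode' column")
    meta = meta.set_index("barcode")
    missing_bc = [b for b in barcodes if b not in meta.index]
    if missing_bc:
        raise ValueError(
            f"cells.tsv is missing metadata for barcode(s) {missing_bc[:5]}"
        )
    truth = None
    if (src / "truth.tsv").exists():
        truth = pd.read_csv(src / "truth.tsv", sep="\t").set_index("barcode")
    return CellMatrix(counts=counts, gene_ids=gene_ids, cell_ids=barcodes,
                      meta=meta, truth=truth)


# ---------------------------------------------------------------------------
# Normalization, pseudobulk, differential expression
# ---------------------------------------------------------------------------


def normalize(matrix: CellMatrix, scale_total: float = 1e4) -> NormalizedMatrix:
    """Depth-normalize to ``scale_total`` counts per cell, then log1p.

    Counts-per-10,000 followed by a natural-log ``log(1 + x)`` transform, the
    droplet-data convention.  Cells with zero library size are rejected.
    """
    lib = matrix.library_sizes().astype(float)
    if np.any(lib <= 0):
        bad = list(np.asarray(matrix.cell_ids)[lib <= 0][:10])
        raise ValueError(f"cell(s) with zero library size: {bad}")
    scaled = matrix.counts.astype(float).multiply(scale_total / lib[None, :])
    values = sp.csr_matrix(scaled)
    values.data = np.log1p(values.data)
    return NormalizedMatrix(
        values=values,
        gene_ids=matrix.gene_ids,
        cell_ids=matrix.cell_ids,
        meta=matrix.meta,
        scale_total=float(scale_total),
        truth=matrix.truth,
    )


def pseudobulk(matrix: NormalizedMatrix, group_key: str | pd.Series) -> pd.DataFrame:
    """Mean normalized expression per group (genes x groups).

    ``group_key`` is a metadata column name or an aligned per-cell Series.
    """
    if isinstance(group_key, str):
        if group_key not in matrix.meta.columns:
            raise KeyError(f"unknown metadata key {group_key!r}")
        groups = matrix.meta[group_key].to_numpy()
    else:
        groups = np.asarray(pd.Series(group_key).loc[list(matrix.cell_ids)])
    labels, codes = np.unique(groups, return_inverse=True)
    ind = sp.csr_matrix(
        (np.ones(matrix.n_cells), (np.arange(matrix.n_cells), codes)),
        shape=(matrix.n_cells, len(labels)),
    )
    sums = np.asarray((matrix.values @ ind).todense())
    counts = np.bincount(codes, minlength=len(labels)).astype(float)
    return pd.DataFrame(sums / counts[None, :], index=matrix.gene_ids,
                        columns=labels)


def _linear_means(values: sp.csr_matrix) -> np.ndarray:
    """Per-gene mean of de-logged (expm1) normalized values."""
    lin = values.copy()
    lin.data = np.expm1(lin.data)
    return np.asarray(lin.mean(axis=1)).ravel()


def log2_fold_change(mean_a: np.ndarray, mean_b: np.ndarray,
                     pseudocount: float = 1.0) -> np.ndarray:
    """log2((mean_a + c) / (mean_b + c)) on linear-scale means."""
    return np.log2((np.asarray(mean_a) + pseudocount)
                   / (np.asarray(mean_b) + pseudocount))


def wilcoxon_rank_sum(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Two-sided Wilcoxon rank-sum p-values, rows = genes.

    Thin wrapper over the tie-corrected normal approximation; degenerate rows
    (all values identical across both groups) get p = 1.
    """
    with np.errstate(all="ignore"):
        res = stats.mannwhitneyu(a, b, axis=1, alternative="two-sided",
                                 method="asymptotic")
    p = np.asarray(res.pvalue, dtype=float)
    flat = (a.min(axis=1) == a.max(axis=1)) & (b.min(axis=1) == b.max(axis=1)) \
        & (a.min(axis=1) == b.min(axis=1))
    p[flat] = 1.0
    p = np.nan_to_num(p, nan=1.0)
    return np.clip(p, 0.0, 1.0)


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone, >= raw p)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def differential_expression(
    matrix: NormalizedMatrix,
    cells_a,
    cells_b,
    min_frac: float = 0.10,
    pseudocount: float = 1.0,
    chunk_size: int = 512,
) -> pd.DataFrame:
    """Wilcoxon rank-sum DE between two cell groups.

    Genes detected in fewer than ``min_frac`` of cells of both groups are
    filtered out.  Fold changes are log2 ratios of de-logged group means with
    a linear-scale pseudocount; p-values are BH-adjusted into ``fdr``.
    """
    mask_a = matrix.cell_mask(cells_a)
    mask_b = matrix.cell_mask(cells_b)
    if mask_a.sum() < 3 or mask_b.sum() < 3:
        raise ValueError(
            f"both groups need >= 3 cells (got {int(mask_a.sum())}, {int(mask_b.sum())})"
        )
    if np.any(mask_a & mask_b):
        raise ValueError("cell groups overlap")

    va = sp.csc_matrix(matrix.values[:, mask_a])
    vb = sp.csc_matrix(matrix.values[:, mask_b])
    na, nb = int(mask_a.sum()), int(mask_b.sum())
    frac_a = np.asarray((va > 0).sum(axis=1)).ravel() / na
    frac_b = np.asarray((vb > 0).sum(axis=1)).ravel() / nb
    keep = (frac_a >= min_frac) | (frac_b >= min_frac)
    if not keep.any():
        raise ValueError("no gene passes the expression filter")
    idx = np.flatnonzero(keep)

    mean_a = _linear_means(sp.csr_matrix(va[idx]))
    mean_b = _linear_means(sp.csr_matrix(vb[idx]))
    lfc = log2_fold_change(mean_a, mean_b, pseudocount)

    pvals = np.empty(len(idx))
    va_r, vb_r = sp.csr_matrix(va), sp.csr_matrix(vb)
    for start in range(0, len(idx), chunk_size):
        rows = idx[start:start + chunk_size]
        a = np.asarray(va_r[rows].todense())
        b = np.asarray(vb_r[rows].todense())
        pvals[start:start + chunk_size] = wilcoxon_rank_sum(a, b)

    return pd.DataFrame(
        {
            "gene": np.asarray(matrix.gene_ids)[idx],
            "group_a_mean": mean_a,
            "group_b_mean": mean_b,
            "log2_fold_change": lfc,
            "p_value": pvals,
            "fdr": bh_adjust(pvals),
            "frac_expr_a": frac_a[idx],
            "frac_expr_b": frac_b[idx],
        }
    ).set_index("gene")
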