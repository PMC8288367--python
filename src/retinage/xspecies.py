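"""Cross-species cell-type correlation over one-to-one orthologs.

Both matrices are restricted to a shared ortholog gene space; cell-type
centroids (mean normalized expression) are then correlated between species
(Spearman by default, Pearson by flag) and banded with the conventional
thresholds: low below 0.3, mid for [0.3, 0.5], high above 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats

from .core import NormalizedMatrix
from .annotate import CellAnnotation

__all__ = [
    "OrthologTable",
    "CorrelationMap",
    "band_of",
    "restrict_to_orthologs",
    "celltype_correlation",
]

BAND_LOW_MAX = 0.3   # below: "low"
BAND_HIGH_MIN = 0.5  # above: "high"; [0.3, 0.5] inclusive: "mid"


@dataclass
class OrthologTable:
    """One-to-one gene correspondence between two species."""

    rows: pd.DataFrame  # columns gene_a, gene_b

    def __post_init__(self) -> None:
        if not {"gene_a", "gene_b"} <= set(self.rows.columns):
            raise ValueError("ortholog table needs columns gene_a, gene_b")
        for col in ("gene_a", "gene_b"):
            if self.rows[col].duplicated().any():
                dup = self.rows.loc[self.rows[col].duplicated(), col]
                raise ValueError(
                    f"ortholog mapping not one-to-one in {col}: "
                    f"{dup.tolist()[:5]}"
                )

    @classmethod
    def identity(cls, genes) -> "OrthologTable":
        genes = list(genes)
        return cls(pd.DataFrame({"gene_a": genes, "gene_b": genes}))

    @classmethod
    def from_tsv(cls, path) -> "OrthologTable":
        df = pd.read_csv(path, sep="\t")
        df.columns = ["gene_a", "gene_b"] + list(df.columns[2:])
        return cls(df[["gene_a", "gene_b"]])


def band_of(r: float) -> str:
    """Band label for a correlation coefficient (low / mid / high)."""
    if np.isnan(r):
        return "undefined"
    if r < BAND_LOW_MAX:
        return "low"
    if r > BAND_HIGH_MIN:
        return "high"
    return "mid"


@dataclass
class CorrelationMap:
    """Cross-species cell-type correlation matrix plus band labels."""

    corr: pd.DataFrame   # cell types A x cell types B
    bands: pd.DataFrame
    method: str = "spearman"

    def __post_init__(self) -> None:
        vals = self.corr.to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        if finite.size and (finite.min() < -1 - 1e-9 or finite.max() > 1 + 1e-9):
            raise ValueError("correlation coefficients outside [-1, 1]")
        expected = self.corr.map(band_of)
        if not expected.equals(self.bands):
            raise ValueError("band labels inconsistent with thresholds")


def restrict_to_orthologs(
    matrix_a: NormalizedMatrix,
    matrix_b: NormalizedMatrix,
    table: OrthologTable,
    min_shared: int = 50,
) -> tuple[NormalizedMatrix, NormalizedMatrix]:
    """Reindex both matrices to the ortholog intersection, order-aligned.

    Gene identifiers of the second matrix are mapped onto the first species'
    symbols so downstream comparisons share one gene space.
    """
    genes_a = set(matrix_a.gene_ids)
    genes_b = set(matrix_b.gene_ids)
    shared = table.rows[
        table.rows["gene_a"].isin(genes_a) & table.rows["gene_b"].isin(genes_b)
    ]
    if len(shared) < min_shared:
        raise ValueError(
            f"only {len(shared)} shared ortholog genes (< {min_shared})"
        )
    shared = shared.sort_values("gene_a")
    rows_a = matrix_a.gene_index(shared["gene_a"].tolist())
    rows_b = matrix_b.gene_index(shared["gene_b"].tolist())

    def _sub(m: NormalizedMatrix, rows: np.ndarray, new_ids) -> NormalizedMatrix:
        return NormalizedMatrix(
            values=sp.csr_matrix(m.values[rows]),
            gene_ids=np.asarray(new_ids, dtype=object),
            cell_ids=m.cell_ids,
            meta=m.meta,
            scale_total=m.scale_total,
            truth=m.truth,
        )

    ids = shared["gene_a"].to_numpy(dtype=object)
    return _sub(matrix_a, rows_a, ids), _sub(matrix_b, rows_b, ids)


def _centroids(matrix: NormalizedMatrix, annot: CellAnnotation,
               min_cells: int = 3) -> pd.DataFrame:
    labels = annot.cells["cell_type"]
    counts = labels.value_counts()
    too_small = counts[counts < min_cells]
    if len(too_small):
        raise ValueError(
            f"cell type(s) with < {min_cells} cells: "
            f"{too_small.index.tolist()}"
        )
    ind = pd.get_dummies(labels).to_numpy(dtype=float)
    sums = np.asarray((matrix.values @ sp.csr_matrix(ind)).todense())
    means = sums / ind.sum(axis=0)[None, :]
    return pd.DataFrame(means, index=matrix.gene_ids,
                        columns=sorted(labels.unique()))


def celltype_correlation(
    matrix_a: NormalizedMatrix,
    matrix_b: NormalizedMatrix,
    annot_a: CellAnnotation,
    annot_b: CellAnnotation,
    method: str = "spearman",
) -> CorrelationMap:
    """Correlate cell-type centroid profiles across species.

    Requires the matrices to share a gene space (see
    :func:`restrict_to_orthologs`) and at least two cell types per side.
    """
    if list(matrix_a.gene_ids) != list(matrix_b.gene_ids):
        raise ValueError("matrices must share an identical ordered gene space")
    cent_a = _centroids(matrix_a, annot_a)
    cent_b = _centroids(matrix_b, annot_b)
    if cent_a.shape[1] < 2 or cent_b.shape[1] < 2:
        raise ValueError("need >= 2 cell types per side")

    if method == "spearman":
        res = stats.spearmanr(cent_a.to_numpy(), cent_b.to_numpy())
        full = np.atleast_2d(res.statistic)
        block = full[: cent_a.shape[1], cent_a.shape[1]:]
    elif method == "pearson":
        a = cent_a.to_numpy()
        b = cent_b.to_numpy()
        a = (a - a.mean(axis=0)) / a.std(axis=0)
        b = (b - b.mean(axis=0)) / b.std(axis=0)
        block = a.T @ b / a.shape[0]
    else:
        raise ValueError(f"unknown method {method!r}")

    corr = pd.DataFrame(block, index=cent_a.columns, columns=cent_b.columns)
    bands = corr.map(band_of)
    return CorrelationMap(corr=corr, bands=bands, method=method)
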