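"""Disease-gene expression maps with bootstrap gene-set enrichment.

Each gene's mean expression per (cell type x region) group is z-scaled
across groups; a disease's score in a group is the mean over its genes.
Specificity is assessed against size-matched random gene sets drawn from
expressed genes: p = (1 + #{null >= observed}) / (n_boot + 1), so the floor
is 1/(n_boot+1).  BH-adjusted q-values across all rows are reported
alongside raw p.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import DEFAULT_STAGE_MAP, NormalizedMatrix, StageMap, bh_adjust, pseudobulk
from .annotate import CellAnnotation

__all__ = [
    "DiseaseGeneTable",
    "make_synthetic_disease_table",
    "group_zscore_matrix",
    "aggregate_disease_score",
    "bootstrap_test",
    "bootstrap_enrichment",
    "disease_score_by_age",
]


@dataclass
class DiseaseGeneTable:
    """(disease, gene) association rows; RETNET-style TSVs load directly."""

    rows: pd.DataFrame  # columns disease_name, gene_symbol

    def __post_init__(self) -> None:
        required = {"disease_name", "gene_symbol"}
        if not required <= set(self.rows.columns):
            raise ValueError(f"disease table needs columns {sorted(required)}")
        if self.rows.duplicated(["disease_name", "gene_symbol"]).any():
            raise ValueError("duplicate (disease, gene) pairs")
        if self.rows.empty:
            raise ValueError("empty disease table")

    @classmethod
    def from_tsv(cls, path) -> "DiseaseGeneTable":
        df = pd.read_csv(path, sep="\t")
        df.columns = [c.lower() for c in df.columns]
        rename = {}
        for cand in ("disease", "disease_name"):
            if cand in df.columns:
                rename[cand] = "disease_name"
        for cand in ("gene", "symbol", "gene_symbol"):
            if cand in df.columns:
                rename[cand] = "gene_symbol"
        return cls(df.rename(columns=rename)[["disease_name", "gene_symbol"]])

    def gene_lists(self) -> dict[str, list[str]]:
        return {
            d: sorted(g["gene_symbol"])
            for d, g in self.rows.groupby("disease_name")
        }


def make_synthetic_disease_table(
    genes: list[str],
    n_diseases: int = 55,
    n_assoc: int = 178,
    seed: int = 0,
) -> DiseaseGeneTable:
    """A synthetic stand-in with the shape of a retinal-disease gene table.

    Draws ``n_assoc`` distinct genes and partitions them into ``n_diseases``
    nonempty lists (sizes as even as possible, remainder spread).  Purely a
    shape fixture for pipeline exercise; carries no curated biology.
    """
    rng = np.random.default_rng(seed)
    if n_assoc > len(genes):
        raise ValueError("not enough genes for the requested associations")
    chosen = rng.choice(np.asarray(genes, dtype=object), size=n_assoc,
                        replace=False)
    sizes = np.full(n_diseases, n_assoc // n_diseases)
    sizes[: n_assoc % n_diseases] += 1
    rows = []
    start = 0
    for i, size in enumerate(sizes):
        for g in chosen[start:start + size]:
            rows.append({"disease_name": f"disease_{i + 1:02d}", "gene_symbol": g})
        start += size
    return DiseaseGeneTable(pd.DataFrame(rows))


def group_zscore_matrix(
    matrix: NormalizedMatrix,
    annot: CellAnnotation,
    by: tuple[str, ...] = ("cell_type", "region"),
    stages: pd.Series | np.ndarray | None = None,
    stage_map: StageMap = DEFAULT_STAGE_MAP,
) -> pd.DataFrame:
    """Gene x group matrix of mean expression z-scaled across groups.

    Grouping keys may be ``cell_type`` (from the annotation), any metadata
    column, or ``stage`` (donor age staged through ``stage_map``).  Genes
    constant across groups scale to zeros.
    """
    parts = []
    for key in by:
        if key == "cell_type":
            parts.append(annot.cells["cell_type"].to_numpy())
        elif key == "stage":
            if stages is None:
                parts.append(stage_map.assign_many(
                    matrix.meta["age_years"].to_numpy()))
            else:
                parts.append(np.asarray(stages, dtype=object))
        elif key in matrix.meta.columns:
            parts.append(matrix.meta[key].to_numpy())
        else:
            raise KeyError(f"unknown grouping key {key!r}")
    combo = pd.Series(
        [" | ".join(str(v) for v in tup) for tup in zip(*parts)],
        index=pd.Index(matrix.cell_ids, name="barcode"),
    )
    means = pseudobulk(matrix, combo)  # genes x groups
    mu = means.mean(axis=1)
    sd = means.std(axis=1, ddof=0)
    sd[sd == 0] = 1.0
    return means.sub(mu, axis=0).div(sd, axis=0)


def aggregate_disease_score(
    matrix: NormalizedMatrix,
    annot: CellAnnotation,
    disease_table: DiseaseGeneTable,
    by: tuple[str, ...] = ("cell_type", "region"),
    **kwargs,
) -> pd.DataFrame:
    """Disease x group score table (mean z-scaled expression over the set).

    Diseases whose genes are all absent from the matrix get an all-NaN row
    (marked missing, never silently zero).
    """
    z = group_zscore_matrix(matrix, annot, by=by, **kwargs)
    present = set(z.index)
    rows = {}
    any_present = False
    for disease, genes in disease_table.gene_lists().items():
        hits = [g for g in genes if g in present]
        if hits:
            any_present = True
            rows[disease] = z.loc[hits].mean(axis=0)
        else:
            rows[disease] = pd.Series(np.nan, index=z.columns)
    if not any_present:
        raise ValueError("no disease gene present in the matrix")
    out = pd.DataFrame(rows).T
    out.index.name = "disease"
    return out


def _null_scores(z: pd.DataFrame, expressed: np.ndarray, set_size: int,
                 n_boot: int, rng: np.random.Generator) -> np.ndarray:
    """(n_boot x groups) scores of random size-matched gene sets."""
    if set_size > len(expressed):
        raise ValueError(
            f"cannot draw gene sets of size {set_size} from "
            f"{len(expressed)} expressed genes"
        )
    zmat = z.to_numpy()
    picks = np.empty((n_boot, set_size), dtype=int)
    for b in range(n_boot):
        picks[b] = rng.choice(len(expressed), size=set_size, replace=False)
    return zmat[expressed[picks]].mean(axis=1)


def _expressed_rows(matrix: NormalizedMatrix, min_frac: float) -> np.ndarray:
    frac = np.asarray((matrix.values > 0).sum(axis=1)).ravel() / matrix.n_cells
    return np.flatnonzero(frac >= min_frac)


def bootstrap_test(
    score_row: pd.Series,
    matrix: NormalizedMatrix,
    annot: CellAnnotation,
    disease_size: int,
    n_boot: int = 1000,
    seed: int = 0,
    by: tuple[str, ...] = ("cell_type", "region"),
    min_frac: float = 0.05,
    **kwargs,
) -> pd.Series:
    """Per-group bootstrap p-values for one disease's score row.

    The null draws ``n_boot`` random gene sets of the disease's size from
    expressed genes; p = (1 + #{null >= observed}) / (n_boot + 1).
    """
    if n_boot < 200:
        raise ValueError("n_boot must be >= 200")
    z = group_zscore_matrix(matrix, annot, by=by, **kwargs)
    expressed = _expressed_rows(matrix, min_frac)
    rng = np.random.default_rng(seed)
    null = _null_scores(z, expressed, disease_size, n_boot, rng)
    obs = score_row.loc[z.columns].to_numpy(dtype=float)
    exceed = (null >= obs[None, :]).sum(axis=0)
    return pd.Series((1 + exceed) / (n_boot + 1), index=z.columns, name="p")


def bootstrap_enrichment(
    matrix: NormalizedMatrix,
    annot: CellAnnotation,
    disease_table: DiseaseGeneTable,
    n_boot: int = 1000,
    seed: int = 0,
    by: tuple[str, ...] = ("cell_type", "region"),
    min_frac: float = 0.05,
    **kwargs,
) -> pd.DataFrame:
    """Scores plus bootstrap p (and BH q) for every (disease, group) row.

    Null gene-set draws are shared across diseases of equal set size, which
    keeps the test identical to per-disease :func:`bootstrap_test` in
    distribution while avoiding redundant sampling.
    """
    if n_boot < 200:
        raise ValueError("n_boot must be >= 200")
    z = group_zscore_matrix(matrix, annot, by=by, **kwargs)
    expressed = _expressed_rows(matrix, min_frac)
    present = set(z.index)
    lists = disease_table.gene_lists()
    rng = np.random.default_rng(seed)

    sizes = sorted({len([g for g in genes if g in present])
                    for genes in lists.values()} - {0})
    nulls = {s: _null_scores(z, expressed, s, n_boot, rng) for s in sizes}

    records = []
    for disease, genes in lists.items():
        hits = [g for g in genes if g in present]
        for group in z.columns:
            if not hits:
                records.append({"disease": disease, "group": group,
                                "score": np.nan, "p": np.nan,
                                "n_genes": 0, "n_boot": n_boot})
                continue
            obs = float(z.loc[hits, group].mean())
            exceed = int((nulls[len(hits)][:, z.columns.get_loc(group)] >= obs).sum())
            records.append({"disease": disease, "group": group, "score": obs,
                            "p": (1 + exceed) / (n_boot + 1),
                            "n_genes": len(hits), "n_boot": n_boot})
    out = pd.DataFrame.from_records(records)
    valid = out["p"].notna()
    out["q"] = np.nan
    out.loc[valid, "q"] = bh_adjust(out.loc[valid, "p"].to_numpy())
    return out


def disease_score_by_age(
    matrix: NormalizedMatrix,
    annot: CellAnnotation,
    disease_table: DiseaseGeneTable,
    include_region: bool = False,
    stages: pd.Series | np.ndarray | None = None,
    stage_map: StageMap = DEFAULT_STAGE_MAP,
) -> pd.DataFrame:
    """Disease scores aggregated by donor stage (optionally x region)."""
    by = ("stage", "region") if include_region else ("stage",)
    return aggregate_disease_score(matrix, annot, disease_table, by=by,
                                   stages=stages, stage_map=stage_map)
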