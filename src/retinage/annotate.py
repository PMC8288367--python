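"""Cell clustering, major-type annotation, subtype classification, proportions.

The flow mirrors a cluster-then-annotate pipeline: community detection on a
kNN graph in PCA space (delegated to scanpy), marker-panel scoring of cluster
centroids, then targeted subtype rules for rods (MYO9A detection split) and
horizontal cells (H1 = LHX1/PCP4 vs H2 = ISL1/CALB1 score argmax), and finally
group-wise proportion estimates with percentile-bootstrap confidence
intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import MarkerPanel, NormalizedMatrix, SubtypeRule

__all__ = [
    "DEFAULT_MARKER_PANEL",
    "CellAnnotation",
    "cluster_cells",
    "score_cell_types",
    "classify_rod_subtype",
    "classify_hc_subtype",
    "co_positive_cells",
    "estimate_proportions",
]

# Canonical retinal markers: rods (NRL/RHO/GNAT1), cones (ARR3/PDE6H/OPN1LW),
# bipolar (VSX2/GRM6/CABP5), horizontal (ONECUT1/ONECUT2), Muller glia
# (RLBP1/GLUL/SLC1A3), amacrine (GAD1/TFAP2A/SLC32A1).  Subtype rules: the
# MYO9A +/- rod split and the H1/H2 horizontal-cell split.
DEFAULT_MARKER_PANEL = MarkerPanel(
    entries={
        "rod": ["NRL", "RHO", "GNAT1"],
        "cone": ["ARR3", "PDE6H", "OPN1LW"],
        "bipolar": ["VSX2", "GRM6", "CABP5"],
        "horizontal": ["ONECUT1", "ONECUT2"],
        "muller_glia": ["RLBP1", "GLUL", "SLC1A3"],
        "amacrine": ["GAD1", "TFAP2A", "SLC32A1"],
    },
    subtype_rules={
        ("rod", "MYO9A+"): SubtypeRule(positive_markers=("MYO9A",)),
        ("rod", "MYO9A-"): SubtypeRule(positive_markers=(), negative_markers=("MYO9A",)),
        ("horizontal", "H1"): SubtypeRule(positive_markers=("LHX1", "PCP4")),
        ("horizontal", "H2"): SubtypeRule(positive_markers=("ISL1", "CALB1")),
    },
)

HC_RULES = {
    "H1": ("LHX1", "PCP4"),
    "H2": ("ISL1", "CALB1"),
}


@dataclass
class CellAnnotation:
    """Per-cell labels plus the cluster-level type-score matrix.

    ``cells`` is indexed by barcode with columns ``cluster_id`` (int),
    ``cell_type`` (str), ``subtype`` (str or NA) and ``tie_flag`` (bool, set
    where an argmax was tie-broken lexicographically).  ``type_scores`` holds
    one score vector per cluster (clusters x panel types); cells inherit the
    vector of their cluster.
    """

    cells: pd.DataFrame
    type_scores: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        required = {"cluster_id", "cell_type", "subtype", "tie_flag"}
        missing = required - set(self.cells.columns)
        if missing:
            raise ValueError(f"annotation missing columns {sorted(missing)}")
        if self.cells["cell_type"].isna().any():
            raise ValueError("every cell must carry a cell_type label")

    def copy(self) -> "CellAnnotation":
        return CellAnnotation(self.cells.copy(), self.type_scores.copy())

    def labels(self, subtype_over_type: bool = False) -> pd.Series:
        """cell_type labels, optionally replaced by subtype where set."""
        lab = self.cells["cell_type"].copy()
        if subtype_over_type:
            has = self.cells["subtype"].notna()
            lab[has] = self.cells.loc[has, "subtype"]
        return lab


def cluster_cells(
    matrix: NormalizedMatrix,
    n_neighbors: int = 15,
    resolution: float = 1.0,
    n_pcs: int = 30,
    seed: int = 0,
) -> np.ndarray:
    """Leiden community detection on a kNN graph in top-PC space.

    Deterministic under a fixed seed.  Raises on fewer than 50 cells or a
    matrix with no expression variance (all cells identical).
    """
    import anndata as ad
    import scanpy as sc

    if matrix.n_cells < 50:
        raise ValueError(f"clustering needs >= 50 cells, got {matrix.n_cells}")
    X = matrix.values.T.tocsr().astype(np.float32)
    spread = np.asarray(X.max(axis=0).todense()).ravel() - \
        np.asarray(X.min(axis=0).todense()).ravel()
    if not np.any(spread > 0):
        raise ValueError("degenerate input: all cells are identical")
    adata = ad.AnnData(X=X)
    n_pcs = int(min(n_pcs, matrix.n_cells - 1, matrix.n_genes - 1))
    sc.pp.pca(adata, n_comps=n_pcs, random_state=seed)
    sc.pp.neighbors(adata, n_neighbors=n_neighbors, use_rep="X_pca",
                    random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        sc.tl.leiden(
            adata,
            resolution=resolution,
            random_state=seed,
            flavor="igraph",
            n_iterations=2,
            directed=False,
        )
    return adata.obs["leiden"].astype(int).to_numpy()


def _zscore_rows(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (x - mu) / sd


def score_cell_types(
    matrix: NormalizedMatrix,
    clusters: np.ndarray,
    panel: MarkerPanel,
) -> CellAnnotation:
    """Label clusters by marker-panel score; cells inherit cluster labels.

    Per cluster and panel type, the score is the mean (over that type's
    markers) of the cluster-mean expression z-scored per gene across clusters.
    Cluster label = argmax score, lexicographic on ties (flagged).  Markers
    absent from the matrix are warned about and dropped; a type with no marker
    present is an error.
    """
    clusters = np.asarray(clusters)
    if clusters.shape != (matrix.n_cells,):
        raise ValueError("clusters must align with matrix cells")
    if not panel.entries:
        raise ValueError("empty marker panel")

    gene_set = set(matrix.gene_ids)
    usable: dict[str, list[str]] = {}
    for cell_type, markers in panel.entries.items():
        present = [m for m in markers if m in gene_set]
        dropped = sorted(set(markers) - set(present))
        if dropped:
            warnings.warn(
                f"marker(s) missing from matrix for {cell_type!r}: {dropped}",
                stacklevel=2,
            )
        if not present:
            raise ValueError(f"all markers missing for cell type {cell_type!r}")
        usable[cell_type] = present

    labels, codes = np.unique(clusters, return_inverse=True)
    if np.issubdtype(labels.dtype, np.integer):
        cluster_ids = labels.astype(int)
    else:  # string cluster labels: re-code to dense integer ids
        cluster_ids = np.arange(len(labels))
    all_markers = sorted({m for ms in usable.values() for m in ms})
    rows = matrix.gene_index(all_markers)
    marker_expr = matrix.dense(gene_rows=rows)  # markers x cells
    # cluster means
    sums = np.zeros((len(all_markers), len(labels)))
    np.add.at(sums.T, codes, marker_expr.T)
    n_per = np.bincount(codes, minlength=len(labels)).astype(float)
    cluster_means = sums / n_per[None, :]
    z = _zscore_rows(cluster_means)
    z_by_gene = {g: z[i] for i, g in enumerate(all_markers)}

    types = sorted(usable)
    score_mat = np.vstack(
        [np.mean([z_by_gene[m] for m in usable[t]], axis=0) for t in types]
    )  # types x clusters
    type_scores = pd.DataFrame(score_mat.T, index=cluster_ids, columns=types)
    type_scores.index.name = "cluster_id"

    ties = (score_mat == score_mat.max(axis=0, keepdims=True)).sum(axis=0) > 1
    cluster_label = np.array(
        [min(t for t, s in zip(types, score_mat[:, k]) if s == score_mat[:, k].max())
         for k in range(len(labels))],
        dtype=object,
    )

    cells = pd.DataFrame(
        {
            "cluster_id": cluster_ids[codes],
            "cell_type": cluster_label[codes],
            "subtype": pd.array([pd.NA] * matrix.n_cells, dtype="string"),
            "tie_flag": ties[codes],
        },
        index=pd.Index(matrix.cell_ids, name="barcode"),
    )
    return CellAnnotation(cells=cells, type_scores=type_scores)


def classify_rod_subtype(
    matrix: NormalizedMatrix,
    annot: CellAnnotation,
    gene: str = "MYO9A",
    rod_label: str = "rod",
) -> CellAnnotation:
    """Split rods into ``{gene}+`` / ``{gene}-`` by transcript detection.

    A rod is positive when at least one raw count was observed (equivalently,
    its normalized value is > 0).  Non-rod cells are untouched.
    """
    row = matrix.gene_index([gene])[0]
    rods = (annot.cells["cell_type"] == rod_label).to_numpy()
    if not rods.any():
        raise ValueError(f"annotation contains no {rod_label!r} cells")
    detected = np.asarray(matrix.values[row].todense()).ravel() > 0
    out = annot.copy()
    sub = np.where(detected[rods], f"{gene}+", f"{gene}-")
    out.cells.loc[rods, "subtype"] = sub
    return out


def classify_hc_subtype(
    matrix: NormalizedMatrix,
    annot: CellAnnotation,
    rules: dict[str, tuple[str, ...]] | None = None,
    hc_label: str = "horizontal",
) -> CellAnnotation:
    """Assign H1/H2 subtype to horizontal cells by marker-score argmax.

    Each rule gene is z-scored across the HC population; the subtype score is
    the mean z over that subtype's markers, and the label is the argmax with a
    lexicographic tie-break (flagged).
    """
    rules = rules or HC_RULES
    hcs = (annot.cells["cell_type"] == hc_label).to_numpy()
    if not hcs.any():
        raise ValueError(f"annotation contains no {hc_label!r} cells")
    all_genes = sorted({g for gs in rules.values() for g in gs})
    rows = matrix.gene_index(all_genes)  # raises if rule genes absent
    expr = matrix.dense(gene_rows=rows, cell_mask=hcs)  # genes x HCs
    z = _zscore_rows(expr)
    z_by_gene = {g: z[i] for i, g in enumerate(all_genes)}
    names = sorted(rules)
    scores = np.vstack([
        np.mean([z_by_gene[g] for g in rules[name]], axis=0) for name in names
    ])  # subtypes x HCs
    top = scores.max(axis=0, keepdims=True)
    ties = (scores == top).sum(axis=0) > 1
    label = np.array(
        [min(n for n, s in zip(names, scores[:, j]) if s == scores[:, j].max())
         for j in range(scores.shape[1])],
        dtype=object,
    )
    out = annot.copy()
    out.cells.loc[hcs, "subtype"] = label
    out.cells.loc[hcs, "tie_flag"] = out.cells.loc[hcs, "tie_flag"].to_numpy() | ties
    return out


def co_positive_cells(
    matrix: NormalizedMatrix,
    genes: tuple[str, str] = ("OTX2", "RLBP1"),
) -> np.ndarray:
    """Boolean mask of cells with >= 1 raw count in both query genes.

    A convenience query for candidate double-positive populations (e.g. the
    OTX2+/RLBP1+ cells sitting between rod/bipolar and Muller-glia identity).
    """
    rows = matrix.gene_index(list(genes))
    dense = matrix.dense(gene_rows=rows)
    return np.asarray((dense > 0).all(axis=0))


def estimate_proportions(
    annot: CellAnnotation | pd.Series,
    meta: pd.DataFrame,
    group_keys: list[str],
    label: str = "cell_type",
    n_boot: int = 1000,
    ci: float = 0.95,
    seed: int = 0,
) -> pd.DataFrame:
    """Label proportions per metadata group with percentile-bootstrap CIs.

    Cells are resampled with replacement within each group; the CI is the
    percentile interval of the bootstrap proportions.  ``label`` selects
    ``cell_type`` or ``subtype`` when ``annot`` is a :class:`CellAnnotation`;
    a plain label Series (indexed by barcode) is also accepted.
    """
    if isinstance(annot, CellAnnotation):
        lab = annot.cells[label]
    else:
        lab = annot
    if n_boot < 200:
        raise ValueError("n_boot must be >= 200 for a stable percentile CI")
    missing_keys = [k for k in group_keys if k not in meta.columns]
    if missing_keys:
        raise KeyError(f"group key(s) not in metadata: {missing_keys}")
    lab = lab.loc[meta.index]
    keep = lab.notna().to_numpy()
    lab = lab[keep]
    meta = meta.loc[keep]
    if len(lab) == 0:
        raise ValueError("no labeled cells to tabulate")

    rng = np.random.default_rng(seed)
    alpha = (1.0 - ci) / 2.0
    records = []
    grouped = meta.groupby(group_keys, sort=True, observed=True)
    for group, sub in grouped:
        if not isinstance(group, tuple):
            group = (group,)
        codes, uniques = pd.factorize(lab.loc[sub.index], sort=True)
        n = len(codes)
        counts = np.bincount(codes, minlength=len(uniques))
        idx = rng.integers(0, n, size=(n_boot, n))
        sampled = codes[idx]
        for li, lab_name in enumerate(uniques):
            boot_prop = (sampled == li).mean(axis=1)
            lo, hi = np.quantile(boot_prop, [alpha, 1.0 - alpha])
            records.append(
                dict(zip(group_keys, group))
                | {
                    "label": lab_name,
                    "count": int(counts[li]),
                    "proportion": counts[li] / n,
                    "ci_low": float(lo),
                    "ci_high": float(hi),
                }
            )
    return pd.DataFrame.from_records(records)
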