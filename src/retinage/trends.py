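"""Monotone aging-trend screening across ordered donor age stages.

Donors are binned into ordered stages (adult / mid / aging by default).  A
gene is called "up" when its stage means strictly increase along the stage
order, both adjacent log2 fold changes clear ``min_log2fc``, and both
adjacent Wilcoxon rank-sum contrasts are BH-significant at ``alpha`` ("down"
mirrored).  Contrasts are computed on cells pooled within stage; a stricter
donor-level pseudobulk screen is available via
:func:`donor_pseudobulk_means`.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .core import (
    DEFAULT_STAGE_MAP,
    NormalizedMatrix,
    StageMap,
    bh_adjust,
    log2_fold_change,
    pseudobulk,
    wilcoxon_rank_sum,
    _linear_means,
)
from .annotate import CellAnnotation

__all__ = [
    "assign_stage",
    "detect_monotone_genes",
    "celltype_stage_foldchange",
    "donor_pseudobulk_means",
]


def assign_stage(age_years: float, stage_map: StageMap = DEFAULT_STAGE_MAP) -> str:
    """Stage whose age interval contains ``age_years`` (else "unstaged")."""
    return stage_map.assign(age_years)


def _stage_labels(matrix: NormalizedMatrix,
                  stages, stage_map: StageMap) -> np.ndarray:
    if stages is None:
        return stage_map.assign_many(matrix.meta["age_years"].to_numpy())
    stages = np.asarray(pd.Series(stages).loc[list(matrix.cell_ids)]
                        if isinstance(stages, pd.Series) else stages,
                        dtype=object)
    if stages.shape != (matrix.n_cells,):
        raise ValueError("stage labels must align with matrix cells")
    return stages


def detect_monotone_genes(
    matrix: NormalizedMatrix,
    stages: pd.Series | np.ndarray | None = None,
    alpha: float = 0.05,
    min_log2fc: float = 0.25,
    stage_map: StageMap = DEFAULT_STAGE_MAP,
    chunk_size: int = 256,
) -> pd.DataFrame:
    """Call per-gene monotone up/down trends across the ordered stages.

    Returns one row per gene with ``direction`` in {up, down, none}, the
    ordered stage means (linear scale), and the adjacent-contrast log2 fold
    changes and BH FDRs.  ``stages`` defaults to staging each cell by its
    donor age through ``stage_map``.
    """
    labels = _stage_labels(matrix, stages, stage_map)
    order = list(stage_map.stage_names)
    masks = [labels == s for s in order]
    missing = [s for s, m in zip(order, masks) if not m.any()]
    if missing:
        raise ValueError(f"no cells in stage(s) {missing}")
    if len(order) < 3:
        raise ValueError("need at least three ordered stages")

    values = [sp.csr_matrix(matrix.values[:, m]) for m in masks]
    means = np.column_stack([_linear_means(v) for v in values])

    n_genes = matrix.n_genes
    adj_lfc = np.column_stack([
        log2_fold_change(means[:, k + 1], means[:, k])
        for k in range(len(order) - 1)
    ])
    adj_p = np.empty((n_genes, len(order) - 1))
    for k in range(len(order) - 1):
        a, b = values[k], values[k + 1]
        for start in range(0, n_genes, chunk_size):
            rows = slice(start, min(start + chunk_size, n_genes))
            adj_p[rows, k] = wilcoxon_rank_sum(
                np.asarray(a[rows].todense()), np.asarray(b[rows].todense())
            )
    adj_fdr = np.column_stack([bh_adjust(adj_p[:, k])
                               for k in range(adj_p.shape[1])])

    strict_up = np.all(np.diff(means, axis=1) > 0, axis=1)
    strict_down = np.all(np.diff(means, axis=1) < 0, axis=1)
    sig = np.all(adj_fdr <= alpha, axis=1)
    up = strict_up & sig & np.all(adj_lfc >= min_log2fc, axis=1)
    down = strict_down & sig & np.all(adj_lfc <= -min_log2fc, axis=1)
    direction = np.where(up, "up", np.where(down, "down", "none"))

    out = pd.DataFrame({"gene": matrix.gene_ids, "direction": direction})
    for i, s in enumerate(order):
        out[f"mean_{s}"] = means[:, i]
    for k in range(len(order) - 1):
        pair = f"{order[k]}_{order[k + 1]}"
        out[f"log2fc_{pair}"] = adj_lfc[:, k]
        out[f"fdr_{pair}"] = adj_fdr[:, k]
    return out.set_index("gene")


def donor_pseudobulk_means(
    matrix: NormalizedMatrix,
    stage_map: StageMap = DEFAULT_STAGE_MAP,
) -> tuple[pd.DataFrame, pd.Series]:
    """Donor-level pseudobulk profiles and each donor's stage.

    The stricter screening companion to the pooled-cell contrasts: callers
    can require monotonicity of donor means as well.
    """
    pb = pseudobulk(matrix, "donor_id")
    donor_age = matrix.meta.groupby("donor_id")["age_years"].first()
    donor_stage = donor_age.map(stage_map.assign)
    return pb, donor_stage.loc[pb.columns]


def celltype_stage_foldchange(
    matrix: NormalizedMatrix,
    annot: CellAnnotation,
    genes: list[str],
    stages: pd.Series | np.ndarray | None = None,
    stage_map: StageMap = DEFAULT_STAGE_MAP,
    baseline: str | None = None,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """log2 fold change per (gene, cell type, stage) against the baseline stage.

    Rows are a (gene, cell_type) MultiIndex, columns the ordered stages; a
    cell type absent from some stage yields NaN entries there (never a silent
    zero).  The baseline defaults to the first stage in the map.
    """
    labels = _stage_labels(matrix, stages, stage_map)
    order = list(stage_map.stage_names)
    baseline = baseline or order[0]
    if baseline not in order:
        raise ValueError(f"baseline stage {baseline!r} not in stage map")
    rows = matrix.gene_index(genes)
    cell_types = sorted(annot.cells["cell_type"].unique())
    ct = annot.cells["cell_type"].to_numpy()

    index = pd.MultiIndex.from_product([genes, cell_types],
                                       names=["gene", "cell_type"])
    out = pd.DataFrame(np.nan, index=index, columns=order)
    for cell_type in cell_types:
        base_mask = (ct == cell_type) & (labels == baseline)
        if not base_mask.any():
            continue  # no baseline for this type: whole row stays NaN
        base_mean = _linear_means(
            sp.csr_matrix(matrix.values[rows][:, base_mask]))
        for stage in order:
            mask = (ct == cell_type) & (labels == stage)
            if not mask.any():
                continue
            stage_mean = _linear_means(
                sp.csr_matrix(matrix.values[rows][:, mask]))
            lfc = log2_fold_change(stage_mean, base_mean, pseudocount)
            out.loc[(slice(None), cell_type), stage] = lfc
    return out
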