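"""Pseudo-aging scores and score-vs-age trajectories with bootstrap bands.

The per-cell aging score is the mean (optionally weighted) z-scored
expression of the up-regulated genes of a curated aging gene set minus that
of the down-regulated genes, min-max rescaled to [0, 1] over the dataset.
Trajectories are local-linear (Gaussian kernel) smooths of score vs donor
age per region, with 95% percentile-bootstrap bands over cells stratified by
donor.  The fovea-vs-periphery gradient is assessed by a within-donor
region-label permutation test on the mean fitted difference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import DEFAULT_STAGE_MAP, NormalizedMatrix, StageMap
from .annotate import CellAnnotation

__all__ = [
    "AgingGeneSet",
    "ScoreCurve",
    "compute_aging_score",
    "fit_trajectory",
    "region_gradient_test",
    "gene_trajectory",
    "signature_drift",
]


@dataclass
class AgingGeneSet:
    """Aging-related genes with direction (and optional per-gene weights).

    The loader accepts the two-column TSV export convention of aging-gene
    databases (columns ``gene`` and ``direction`` in {up, down}, optional
    ``weight``).
    """

    up_genes: list[str]
    down_genes: list[str]
    weights: dict[str, float] | None = None

    def __post_init__(self) -> None:
        overlap = set(self.up_genes) & set(self.down_genes)
        if overlap:
            raise ValueError(f"genes in both directions: {sorted(overlap)[:5]}")
        if not self.up_genes and not self.down_genes:
            raise ValueError("gene set is empty")
        if self.weights is not None:
            missing = (set(self.up_genes) | set(self.down_genes)) - set(self.weights)
            if missing:
                raise ValueError(
                    f"weights missing for gene(s) {sorted(missing)[:5]}"
                )

    @classmethod
    def from_tsv(cls, path) -> "AgingGeneSet":
        df = pd.read_csv(path, sep="\t")
        df.columns = [c.lower() for c in df.columns]
        if not {"gene", "direction"} <= set(df.columns):
            raise ValueError("gene-set TSV needs 'gene' and 'direction' columns")
        up = df.loc[df["direction"].str.lower() == "up", "gene"].tolist()
        down = df.loc[df["direction"].str.lower() == "down", "gene"].tolist()
        weights = None
        if "weight" in df.columns:
            weights = dict(zip(df["gene"], df["weight"].astype(float)))
        return cls(up_genes=up, down_genes=down, weights=weights)

    def weight_of(self, gene: str) -> float:
        return 1.0 if self.weights is None else float(self.weights[gene])


@dataclass
class ScoreCurve:
    """A fitted score-(or expression-)vs-age trajectory for one region."""

    region: str
    grid_ages: np.ndarray
    fitted: np.ndarray
    band_low: np.ndarray
    band_high: np.ndarray
    per_cell_scores: pd.Series
    cells: pd.DataFrame = field(repr=False, default=None)  # score, age, donor, region
    bandwidth: float = float("nan")

    def __post_init__(self) -> None:
        if np.any(np.diff(self.grid_ages) <= 0):
            raise ValueError("grid ages must be strictly increasing")
        if np.any(self.band_low > self.fitted + 1e-12) or \
                np.any(self.band_high < self.fitted - 1e-12):
            raise ValueError("band must bracket the fitted curve pointwise")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"region": self.region, "age": self.grid_ages, "fit": self.fitted,
             "lo": self.band_low, "hi": self.band_high}
        )


def _zscore_across_cells(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (x - mu) / sd


def compute_aging_score(
    matrix: NormalizedMatrix,
    gene_set: AgingGeneSet,
    rescale: bool = True,
) -> pd.Series:
    """Per-cell aging score in [0, 1].

    Raw score = weighted mean z-expression over up-genes minus that over
    down-genes; min-max rescaled over the dataset (the rescale is
    order-preserving).  Genes absent from the matrix are dropped; an entirely
    absent gene set is an error.
    """
    gene_pool = set(matrix.gene_ids)
    up = [g for g in gene_set.up_genes if g in gene_pool]
    down = [g for g in gene_set.down_genes if g in gene_pool]
    if not up and not down:
        raise ValueError("no gene-set genes present in the matrix")

    def _side_mean(genes: list[str]) -> np.ndarray:
        if not genes:
            return np.zeros(matrix.n_cells)
        z = _zscore_across_cells(matrix.dense(matrix.gene_index(genes)))
        w = np.array([gene_set.weight_of(g) for g in genes])[:, None]
        return (z * w).sum(axis=0) / np.abs(w).sum()

    raw = _side_mean(up) - _side_mean(down)
    if rescale:
        lo, hi = raw.min(), raw.max()
        raw = np.zeros_like(raw) if hi == lo else (raw - lo) / (hi - lo)
    return pd.Series(raw, index=pd.Index(matrix.cell_ids, name="barcode"),
                     name="aging_score")


def _local_linear_fit(ages: np.ndarray, ysums: np.ndarray, counts: np.ndarray,
                      grid: np.ndarray, bandwidth: float) -> np.ndarray:
    """Local-linear smooth from per-unique-age sufficient statistics.

    ``ysums`` may be 2-D (replicates x unique ages) for vectorized bootstrap
    fits.  Mean squared responses are not needed: the fit at each grid point
    only uses kernel-weighted first moments.
    """
    ysums = np.atleast_2d(ysums)
    fitted = np.empty((ysums.shape[0], len(grid)))
    for j, a in enumerate(grid):
        dx = ages - a
        w = np.exp(-0.5 * (dx / bandwidth) ** 2) * counts
        s0 = w.sum()
        s1 = (w * dx).sum()
        s2 = (w * dx * dx).sum()
        t0 = (ysums * (w / np.maximum(counts, 1))).sum(axis=1)
        t1 = (ysums * (w * dx / np.maximum(counts, 1))).sum(axis=1)
        det = s0 * s2 - s1 * s1
        if det <= 1e-12 * max(s0, 1.0) ** 2:
            fitted[:, j] = t0 / s0  # degenerate: kernel-weighted mean
        else:
            fitted[:, j] = (s2 * t0 - s1 * t1) / det
    return fitted


def _suff_stats(ages: np.ndarray, scores: np.ndarray):
    uniq, inv = np.unique(ages, return_inverse=True)
    counts = np.bincount(inv).astype(float)
    ysum = np.bincount(inv, weights=scores)
    return uniq, inv, counts, ysum


def fit_trajectory(
    scores: pd.Series,
    meta: pd.DataFrame,
    region: str,
    n_boot: int = 200,
    seed: int = 0,
    grid_size: int = 25,
    bandwidth_frac: float = 0.5,
    ci: float = 0.95,
) -> ScoreCurve:
    """Local-linear smooth of per-cell score vs donor age within a region.

    Bandwidth = ``bandwidth_frac`` x the age range.  The 95% band is the
    percentile interval over ``n_boot`` bootstrap refits, resampling cells
    with replacement stratified by donor.  Requires >= 3 distinct donor ages.
    """
    cells = meta.loc[scores.index].copy()
    cells["score"] = scores
    cells = cells[cells["region"] == region]
    ages_all = cells["age_years"].to_numpy(dtype=float)
    if len(np.unique(ages_all)) < 3:
        raise ValueError(
            f"need >= 3 distinct donor ages in region {region!r}, "
            f"got {len(np.unique(ages_all))}"
        )
    y = cells["score"].to_numpy(dtype=float)
    lo_age, hi_age = ages_all.min(), ages_all.max()
    bandwidth = bandwidth_frac * (hi_age - lo_age)
    grid = np.linspace(lo_age, hi_age, grid_size)

    uniq, inv, counts, ysum = _suff_stats(ages_all, y)
    fitted = _local_linear_fit(uniq, ysum, counts, grid, bandwidth)[0]

    # bootstrap over cells, stratified by donor (x age, should a donor ever
    # span several ages): per stratum, resample its scores with replacement
    rng = np.random.default_rng(seed)
    boot_ysum = np.zeros((n_boot, len(uniq)))
    donor_arr = cells["donor_id"].to_numpy()
    strata = pd.DataFrame({"donor": donor_arr, "code": inv}).groupby(
        ["donor", "code"], sort=True
    ).indices
    for (_, code), indices in strata.items():
        ya = y[np.asarray(indices)]
        idx = rng.integers(0, len(ya), size=(n_boot, len(ya)))
        boot_ysum[:, code] += ya[idx].sum(axis=1)
    boot_fits = _local_linear_fit(uniq, boot_ysum, counts, grid, bandwidth)
    alpha = (1 - ci) / 2
    band_low = np.quantile(boot_fits, alpha, axis=0)
    band_high = np.quantile(boot_fits, 1 - alpha, axis=0)
    band_low = np.minimum(band_low, fitted)
    band_high = np.maximum(band_high, fitted)

    keep = cells[["donor_id", "age_years", "region", "score"]]
    return ScoreCurve(
        region=region,
        grid_ages=grid,
        fitted=fitted,
        band_low=band_low,
        band_high=band_high,
        per_cell_scores=cells["score"],
        cells=keep,
        bandwidth=bandwidth,
    )


def _point_fit(ages: np.ndarray, scores: np.ndarray, grid: np.ndarray,
               bandwidth: float) -> np.ndarray:
    uniq, _, counts, ysum = _suff_stats(ages, scores)
    return _local_linear_fit(uniq, ysum, counts, grid, bandwidth)[0]


def region_gradient_test(
    curve_fovea: ScoreCurve,
    curve_periphery: ScoreCurve,
    n_perm: int = 200,
    seed: int = 0,
) -> dict[str, float]:
    """Permutation test of the fovea-minus-periphery trajectory gap.

    ``delta`` is the mean fitted fovea - periphery difference over the shared
    age grid; the p-value permutes region labels among cells within each
    donor and refits both curves (two-sided on |delta|).
    """
    if curve_fovea.grid_ages.shape != curve_periphery.grid_ages.shape or \
            not np.allclose(curve_fovea.grid_ages, curve_periphery.grid_ages):
        raise ValueError("curves must share a common age grid")
    grid = curve_fovea.grid_ages
    delta = float(np.mean(curve_fovea.fitted - curve_periphery.fitted))

    pooled = pd.concat([curve_fovea.cells, curve_periphery.cells])
    ages = pooled["age_years"].to_numpy(dtype=float)
    scores = pooled["score"].to_numpy(dtype=float)
    is_fovea = (pooled["region"] == "fovea").to_numpy()
    donors = pooled["donor_id"].to_numpy()
    bw = curve_fovea.bandwidth

    rng = np.random.default_rng(seed)
    donor_groups = {d: np.flatnonzero(donors == d) for d in np.unique(donors)}
    exceed = 0
    for _ in range(n_perm):
        perm = is_fovea.copy()
        for idx in donor_groups.values():
            perm[idx] = perm[idx][rng.permutation(len(idx))]
        fit_f = _point_fit(ages[perm], scores[perm], grid, bw)
        fit_p = _point_fit(ages[~perm], scores[~perm], grid, bw)
        if abs(np.mean(fit_f - fit_p)) >= abs(delta) - 1e-15:
            exceed += 1
    p = (1 + exceed) / (n_perm + 1)
    return {"delta": delta, "p": float(p)}


def gene_trajectory(
    matrix: NormalizedMatrix,
    gene: str,
    region: str,
    n_boot: int = 200,
    seed: int = 0,
    **fit_kwargs,
) -> ScoreCurve:
    """Trajectory of a single gene's normalized expression vs donor age."""
    row = matrix.gene_index([gene])[0]
    expr = pd.Series(
        np.asarray(matrix.values[row].todense()).ravel(),
        index=pd.Index(matrix.cell_ids, name="barcode"),
        name=gene,
    )
    return fit_trajectory(expr, matrix.meta, region, n_boot=n_boot, seed=seed,
                          **fit_kwargs)


def signature_drift(
    matrix: NormalizedMatrix,
    annot: CellAnnotation,
    gene_list: list[str],
    cell_type: str,
    stages: pd.Series | np.ndarray | None = None,
    stage_map: StageMap = DEFAULT_STAGE_MAP,
) -> pd.Series:
    """Mean z-scored signature expression in one cell type, per stage.

    Each gene is z-scored across the cell type's cells (making the result
    invariant to per-gene affine rescaling); the drift value per stage is the
    mean z over genes and cells of that stage.
    """
    if not gene_list:
        raise ValueError("empty gene list")
    mask = (annot.cells["cell_type"] == cell_type).to_numpy()
    if not mask.any():
        raise ValueError(f"no cells of type {cell_type!r}")
    if stages is None:
        labels = stage_map.assign_many(matrix.meta["age_years"].to_numpy())
    else:
        labels = np.asarray(stages, dtype=object)
    labels = labels[mask]
    z = _zscore_across_cells(
        matrix.dense(matrix.gene_index(gene_list), cell_mask=mask)
    )
    sig = z.mean(axis=0)
    order = [s for s in stage_map.stage_names if (labels == s).any()]
    missing = [s for s in stage_map.stage_names if s not in order]
    if missing:
        raise ValueError(f"cell type {cell_type!r} absent in stage(s) {missing}")
    return pd.Series(
        [float(sig[labels == s].mean()) for s in order], index=order,
        name=f"{cell_type}_signature",
    )
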