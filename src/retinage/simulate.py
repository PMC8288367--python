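"""Synthetic retina-atlas generator with ground truth.

Counts follow a negative-binomial model with a log-link mean: a shared
baseline, additive marker elevation for each cell type, per-stage monotone
shifts for planted aging-trend genes, aged-donor shifts for planted
ligand-receptor signals, and a per-cell lognormal depth factor to exercise
normalization.  Rod MYO9A+/- and horizontal-cell H1/H2 mixtures are assigned
with deterministic largest-remainder allocation across donor x region blocks,
so realized fractions equal the configured ones up to integer rounding; the
per-cell count noise (and hence classifier behaviour) remains stochastic.

``default_study_config`` pre-fills the mixture fractions, cell counts and
planted-gene numbers of the primate retina aging atlas this generator
emulates, so that recovery of those quantities can be tested at desk scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
import yaml

from .core import (
    DEFAULT_STAGE_MAP,
    REGIONS,
    SPECIES,
    CellMatrix,
    StageMap,
    write_matrix,
)

__all__ = [
    "CellTypeSpec",
    "Donor",
    "RodSubtypeMix",
    "HCMix",
    "PlantedTrends",
    "LRSignal",
    "GeneratorConfig",
    "GroundTruth",
    "simulate",
    "default_study_config",
    "write_simulation",
]


@dataclass(frozen=True)
class CellTypeSpec:
    """Cell counts per region (split evenly across donors) and marker genes."""

    n_fovea: int
    n_periphery: int
    markers: tuple[str, ...]
    marker_log_fold: float = 3.0


@dataclass(frozen=True)
class Donor:
    donor_id: str
    species: str
    age_years: float


@dataclass(frozen=True)
class RodSubtypeMix:
    """MYO9A- fraction among rods and its regional placement.

    ``frac_neg_in_periphery`` is the fraction of MYO9A- rods placed in the
    peripheral retina.
    """

    frac_myo9a_neg: float = 0.0
    frac_neg_in_periphery: float = 0.5


@dataclass(frozen=True)
class HCMix:
    """Horizontal-cell H1/H2 mixture.

    ``frac_h2_by_stage`` gives the overall H2 fraction among HCs per donor
    stage; ``foveal_frac_h2`` is held fixed across stages (the peripheral
    fraction is derived from the two).
    """

    foveal_frac_h2: float = 0.0
    frac_h2_by_stage: dict[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class PlantedTrends:
    """Genes shifted monotonically (on the log-mean) across ordered stages."""

    n_up: int = 0
    n_down: int = 0
    per_stage_log_fold: float = 1.0


@dataclass(frozen=True)
class LRSignal:
    """A ligand-receptor pair up-shifted in aged donors.

    The ligand gene rises by ``aged_log_fold`` in aged-stage cells of the
    sender type; the receptor likewise in the receiver type.
    """

    ligand: str
    receptor: str
    sender: str
    receiver: str
    aged_log_fold: float = 1.0


@dataclass
class GeneratorConfig:
    n_genes: int
    cell_types: dict[str, CellTypeSpec]
    donors: list[Donor]
    seed: int
    rod_subtype_mix: RodSubtypeMix = field(default_factory=RodSubtypeMix)
    hc_mix: HCMix = field(default_factory=HCMix)
    planted_trends: PlantedTrends = field(default_factory=PlantedTrends)
    lr_signals: list[LRSignal] = field(default_factory=list)
    nb_dispersion: float = 2.0
    base_mean: float = 0.5
    library_sigma: float = 0.3
    # conserved per-gene baseline heterogeneity (lognormal on the mean):
    # drawn from its own seed so that independently seeded datasets share
    # gene-specific expression levels, as orthologous genes do in real data
    gene_baseline_sigma: float = 0.5
    gene_baseline_seed: int = 7777
    myo9a_log_fold: float = 4.8
    subtype_marker_log_fold: float = 4.0
    fovea_up_gene_log_fold: float = 0.0
    stage_map: StageMap = field(default_factory=lambda: DEFAULT_STAGE_MAP)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.nb_dispersion <= 0 or self.base_mean <= 0:
            raise ValueError("nb_dispersion and base_mean must be > 0")
        for frac in (
            self.rod_subtype_mix.frac_myo9a_neg,
            self.rod_subtype_mix.frac_neg_in_periphery,
            self.hc_mix.foveal_frac_h2,
            *self.hc_mix.frac_h2_by_stage.values(),
        ):
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"fraction {frac} outside [0, 1]")
        for name, spec_ in self.cell_types.items():
            if spec_.n_fovea < 0 or spec_.n_periphery < 0:
                raise ValueError(f"negative cell count for {name!r}")
            if spec_.n_fovea + spec_.n_periphery == 0:
                raise ValueError(f"cell type {name!r} has zero cells")
        if not self.donors:
            raise ValueError("at least one donor required")
        if self.planted_trends.n_up < 0 or self.planted_trends.n_down < 0:
            raise ValueError("planted gene counts must be >= 0")
        bad_sp = {d.species for d in self.donors} - set(SPECIES)
        if bad_sp:
            raise ValueError(f"unknown donor species {sorted(bad_sp)}")

    def named_genes(self) -> list[str]:
        names: list[str] = []
        for spec_ in self.cell_types.values():
            names.extend(spec_.markers)
        if "rod" in self.cell_types:
            names.append("MYO9A")
        if "horizontal" in self.cell_types:
            names.extend(["LHX1", "PCP4", "ISL1", "CALB1"])
        for sig in self.lr_signals:
            names.extend([sig.ligand, sig.receptor])
        seen: list[str] = []
        for n in names:
            if n not in seen:
                seen.append(n)
        return seen


@dataclass
class GroundTruth:
    """Generator-side labels for recovery testing."""

    cells: pd.DataFrame  # index barcode: cell_type, subtype, stage
    up_genes: list[str]
    down_genes: list[str]
    lr_pairs: list[LRSignal]
    donor_stage: dict[str, str]


def _largest_remainder(total: int, weights: np.ndarray) -> np.ndarray:
    """Integer allocation of ``total`` proportional to ``weights``."""
    weights = np.asarray(weights, dtype=float)
    if total == 0 or weights.sum() == 0:
        return np.zeros(len(weights), dtype=int)
    quota = total * weights / weights.sum()
    base = np.floor(quota).astype(int)
    short = total - base.sum()
    order = np.argsort(-(quota - base), kind="stable")
    base[order[:short]] += 1
    return base


def _split_counts(total: int, n_parts: int) -> np.ndarray:
    return _largest_remainder(total, np.ones(n_parts))


def _build_cell_table(config: GeneratorConfig) -> pd.DataFrame:
    rows = []
    for cell_type in sorted(config.cell_types):
        spec_ = config.cell_types[cell_type]
        for region, total in (("fovea", spec_.n_fovea),
                              ("periphery", spec_.n_periphery)):
            per_donor = _split_counts(total, len(config.donors))
            for donor, n in zip(config.donors, per_donor):
                rows.extend(
                    {
                        "cell_type": cell_type,
                        "region": region,
                        "donor_id": donor.donor_id,
                        "species": donor.species,
                        "age_years": donor.age_years,
                        "stage": config.stage_map.assign(donor.age_years),
                    }
                    for _ in range(n)
                )
    table = pd.DataFrame(rows)
    table.index = pd.Index(
        [f"CELL{i:06d}" for i in range(len(table))], name="barcode"
    )
    table["subtype"] = pd.array([pd.NA] * len(table), dtype="string")
    return table


def _assign_rod_subtypes(table: pd.DataFrame, mix: RodSubtypeMix) -> None:
    rods = table.index[table["cell_type"] == "rod"]
    if len(rods) == 0:
        return
    n_neg = round(mix.frac_myo9a_neg * len(rods))
    table.loc[rods, "subtype"] = "MYO9A+"
    if n_neg == 0:
        return
    n_neg_region = {
        "periphery": round(mix.frac_neg_in_periphery * n_neg),
    }
    n_neg_region["fovea"] = n_neg - n_neg_region["periphery"]
    for region, n_neg_r in n_neg_region.items():
        pool = table.loc[rods]
        pool = pool.index[pool["region"] == region]
        if n_neg_r > len(pool):
            raise ValueError(
                f"infeasible rod mix: {n_neg_r} MYO9A- rods requested in "
                f"{region} but only {len(pool)} rods there"
            )
        # allocate across donors proportionally, then take leading cells
        donors = table.loc[pool, "donor_id"]
        donor_ids, counts = np.unique(donors, return_counts=True)
        alloc = _largest_remainder(n_neg_r, counts)
        for donor_id, k in zip(donor_ids, alloc):
            cells = pool[donors.to_numpy() == donor_id][:k]
            table.loc[cells, "subtype"] = "MYO9A-"


def _assign_hc_subtypes(table: pd.DataFrame, mix: HCMix) -> None:
    hcs = table.index[table["cell_type"] == "horizontal"]
    if len(hcs) == 0:
        return
    table.loc[hcs, "subtype"] = "H1"
    sub = table.loc[hcs]
    for stage, pool in sub.groupby("stage", sort=True):
        frac = mix.frac_h2_by_stage.get(str(stage))
        if frac is None:
            raise ValueError(
                f"hc_mix.frac_h2_by_stage has no entry for stage {stage!r}"
            )
        n_total_h2 = round(frac * len(pool))
        fovea = pool.index[pool["region"] == "fovea"]
        n_fovea_h2 = min(round(mix.foveal_frac_h2 * len(fovea)), n_total_h2)
        n_periph_h2 = n_total_h2 - n_fovea_h2
        periph = pool.index[pool["region"] == "periphery"]
        if n_periph_h2 > len(periph):
            raise ValueError(
                f"infeasible HC mix at stage {stage!r}: needs {n_periph_h2} "
                f"peripheral H2 cells, only {len(periph)} peripheral HCs"
            )
        for pool_r, k in ((fovea, n_fovea_h2), (periph, n_periph_h2)):
            donors = table.loc[pool_r, "donor_id"]
            donor_ids, counts = np.unique(donors, return_counts=True)
            alloc = _largest_remainder(k, counts)
            for donor_id, kk in zip(donor_ids, alloc):
                cells = pool_r[donors.to_numpy() == donor_id][:kk]
                table.loc[cells, "subtype"] = "H2"


def _gene_universe(config: GeneratorConfig) -> tuple[list[str], list[str], list[str]]:
    named = config.named_genes()
    n_planted = config.planted_trends.n_up + config.planted_trends.n_down
    n_filler = config.n_genes - len(named)
    if n_filler < n_planted:
        raise ValueError(
            f"n_genes={config.n_genes} too small for {len(named)} named genes "
            f"plus {n_planted} planted trend genes"
        )
    fillers = [f"GENE{i:04d}" for i in range(n_filler)]
    up = fillers[: config.planted_trends.n_up]
    down = fillers[config.planted_trends.n_up: n_planted]
    return named + fillers, up, down


def simulate(config: GeneratorConfig) -> tuple[CellMatrix, GroundTruth]:
    """Draw a CellMatrix (and its GroundTruth) from the configured model.

    Fully reproducible from ``config.seed``: cells are laid out in a
    deterministic block order (cell type, region, donor) and all random draws
    come from a single seeded generator.
    """
    rng = np.random.default_rng(config.seed)
    genes, up_genes, down_genes = _gene_universe(config)
    gene_pos = {g: i for i, g in enumerate(genes)}

    table = _build_cell_table(config)
    _assign_rod_subtypes(table, config.rod_subtype_mix)
    _assign_hc_subtypes(table, config.hc_mix)

    stage_order = {name: i for i, name in enumerate(config.stage_map.stage_names)}
    up_idx = np.array([gene_pos[g] for g in up_genes], dtype=int)
    down_idx = np.array([gene_pos[g] for g in down_genes], dtype=int)

    depth = rng.lognormal(mean=0.0, sigma=config.library_sigma, size=len(table))
    base_rng = np.random.default_rng(config.gene_baseline_seed)
    gene_base_log = np.log(config.base_mean) + \
        config.gene_baseline_sigma * base_rng.standard_normal(n_genes_total := len(genes))
    abs_base_log = np.log(config.base_mean)  # reference for absolute subtype levels
    r = config.nb_dispersion

    blocks = table.groupby(
        ["cell_type", "region", "donor_id", "subtype"], sort=True, dropna=False
    ).indices
    n_genes, n_cells = len(genes), len(table)
    block_mats: list[sp.csc_matrix] = []
    block_cols: list[np.ndarray] = []
    for key in sorted(blocks, key=lambda k: tuple("" if pd.isna(x) else str(x) for x in k)):
        cell_type, region, donor_id, subtype = key
        cols = np.sort(blocks[key])
        row0 = table.iloc[cols[0]]
        stage = row0["stage"]
        k_stage = stage_order.get(stage, None)

        log_mu = gene_base_log.copy()
        spec_ = config.cell_types[cell_type]
        for m in spec_.markers:
            log_mu[gene_pos[m]] += spec_.marker_log_fold
        structural_zero = np.zeros(n_genes, dtype=bool)
        # subtype-defining markers sit at an absolute level (relative to the
        # global baseline) so detection-based classification is independent
        # of the gene's conserved baseline draw
        if cell_type == "rod" and not pd.isna(subtype):
            if subtype == "MYO9A+":
                log_mu[gene_pos["MYO9A"]] = abs_base_log + config.myo9a_log_fold
            else:  # MYO9A-: no transcript at all
                structural_zero[gene_pos["MYO9A"]] = True
        if cell_type == "horizontal" and not pd.isna(subtype):
            markers = ("LHX1", "PCP4") if subtype == "H1" else ("ISL1", "CALB1")
            for m in markers:
                log_mu[gene_pos[m]] = abs_base_log + config.subtype_marker_log_fold
        if k_stage is not None and k_stage > 0:
            f = config.planted_trends.per_stage_log_fold
            log_mu[up_idx] += k_stage * f
            log_mu[down_idx] -= k_stage * f
        if stage == "aging":
            for sig in config.lr_signals:
                if sig.sender == cell_type:
                    log_mu[gene_pos[sig.ligand]] += sig.aged_log_fold
                if sig.receiver == cell_type:
                    log_mu[gene_pos[sig.receptor]] += sig.aged_log_fold
        if region == "fovea" and config.fovea_up_gene_log_fold != 0.0:
            log_mu[up_idx] += config.fovea_up_gene_log_fold

        mu = np.exp(log_mu)
        mu[structural_zero] = 0.0
        mu_block = mu[:, None] * depth[cols][None, :]
        p = r / (r + mu_block)
        draws = rng.negative_binomial(r, p)
        block_mats.append(sp.csc_matrix(draws.astype(np.int32)))
        block_cols.append(cols)

    order = np.concatenate(block_cols)
    stacked = sp.hstack(block_mats, format="csc")
    inverse = np.empty_like(order)
    inverse[order] = np.arange(n_cells)
    counts = sp.csr_matrix(stacked[:, inverse])

    meta = table[["donor_id", "species", "age_years", "region"]].copy()
    truth = table[["cell_type", "subtype", "stage"]].copy()
    matrix = CellMatrix(
        counts=counts,
        gene_ids=np.array(genes, dtype=object),
        cell_ids=table.index.to_numpy(),
        meta=meta,
        truth=truth,
    )
    gt = GroundTruth(
        cells=truth,
        up_genes=up_genes,
        down_genes=down_genes,
        lr_pairs=list(config.lr_signals),
        donor_stage={d.donor_id: config.stage_map.assign(d.age_years)
                     for d in config.donors},
    )
    return matrix, gt


# ---------------------------------------------------------------------------
# Study-conditions defaults
# ---------------------------------------------------------------------------

# Printed study quantities the default configs realize:
#   human rods n=16,686, MYO9A- fraction 36.9%;
#   macaque rods n=36,904, MYO9A- fraction 4.7%, 98.6% of them peripheral;
#   human foveal HC H1 92.0% (foveal H2 8%), overall H2 52.3% mid / 14.2% aged;
#   macaque foveal HC H1 60.0%;
#   87 up- and 121 down-trending genes across adult -> mid -> aging.
_HUMAN_DONORS = [
    Donor("H35", "human", 35.0),
    Donor("H52", "human", 52.0),
    Donor("H63", "human", 63.0),
    Donor("H86", "human", 86.0),
    Donor("H87", "human", 87.0),
]
# Macaque donors span the juvenile-to-aged macaque range (years); they fall
# outside the human-year stage map and are treated as unstaged.
_MACAQUE_DONORS = [
    Donor("M02", "macaque", 2.0),
    Donor("M08", "macaque", 8.0),
    Donor("M15", "macaque", 15.0),
    Donor("M20", "macaque", 20.0),
    Donor("M23", "macaque", 23.0),
]

_MARKERS = {
    "rod": ("NRL", "RHO", "GNAT1"),
    "cone": ("ARR3", "PDE6H", "OPN1LW"),
    "bipolar": ("VSX2", "GRM6", "CABP5"),
    "horizontal": ("ONECUT1", "ONECUT2"),
    "muller_glia": ("RLBP1", "GLUL", "SLC1A3"),
    "amacrine": ("GAD1", "TFAP2A", "SLC32A1"),
}

_DEFAULT_LR_SIGNALS = [
    LRSignal("VEGFA", "FLT1", "muller_glia", "rod", 1.5),
    LRSignal("VEGFA", "KDR", "bipolar", "rod", 1.5),
    LRSignal("BDNF", "NTRK2", "muller_glia", "rod", 1.2),
    LRSignal("TGFB1", "TGFBR1", "bipolar", "rod", 1.0),
]


def default_study_config(species: str, seed: int = 0,
                         n_genes: int = 2000) -> GeneratorConfig:
    """Generator config pre-filled with the study's printed proportions."""
    if species == "human":
        cell_types = {
            "rod": CellTypeSpec(2503, 14183, _MARKERS["rod"]),
            "cone": CellTypeSpec(1200, 1800, _MARKERS["cone"]),
            "bipolar": CellTypeSpec(1000, 2000, _MARKERS["bipolar"]),
            "horizontal": CellTypeSpec(1200, 2800, _MARKERS["horizontal"]),
            "muller_glia": CellTypeSpec(1000, 2000, _MARKERS["muller_glia"]),
            "amacrine": CellTypeSpec(500, 1000, _MARKERS["amacrine"]),
        }
        return GeneratorConfig(
            n_genes=n_genes,
            cell_types=cell_types,
            donors=list(_HUMAN_DONORS),
            seed=seed,
            rod_subtype_mix=RodSubtypeMix(
                frac_myo9a_neg=0.369,
                # the study saw similar MYO9A ratios in both human regions, so
                # MYO9A- placement matches the rods' overall regional split
                frac_neg_in_periphery=14183 / 16686,
            ),
            hc_mix=HCMix(
                foveal_frac_h2=0.08,
                # adult overall derived from the printed regional fractions
                # (92% foveal H1, 60% peripheral H2) at the 30/70 HC split
                frac_h2_by_stage={"adult": 0.444, "mid": 0.523, "aging": 0.142},
            ),
            planted_trends=PlantedTrends(n_up=87, n_down=121,
                                         per_stage_log_fold=1.0),
            lr_signals=list(_DEFAULT_LR_SIGNALS),
        )
    if species == "macaque":
        cell_types = {
            "rod": CellTypeSpec(1845, 35059, _MARKERS["rod"]),
            "cone": CellTypeSpec(1000, 1500, _MARKERS["cone"]),
            "bipolar": CellTypeSpec(800, 1600, _MARKERS["bipolar"]),
            "horizontal": CellTypeSpec(2000, 3000, _MARKERS["horizontal"]),
            "muller_glia": CellTypeSpec(800, 1600, _MARKERS["muller_glia"]),
            "amacrine": CellTypeSpec(400, 800, _MARKERS["amacrine"]),
        }
        return GeneratorConfig(
            n_genes=n_genes,
            cell_types=cell_types,
            donors=list(_MACAQUE_DONORS),
            seed=seed,
            rod_subtype_mix=RodSubtypeMix(
                frac_myo9a_neg=0.047,
                frac_neg_in_periphery=0.986,
            ),
            hc_mix=HCMix(
                foveal_frac_h2=0.40,
                # overall = 0.40 * (2000/5000) + 0.60 * (3000/5000); the
                # macaque H2 mix shows no stage trend, so every stage the
                # donor panel reaches carries the same fraction
                frac_h2_by_stage={"unstaged": 0.52, "adult": 0.52},
            ),
            planted_trends=PlantedTrends(n_up=0, n_down=0),
            lr_signals=[],
        )
    raise ValueError(f"unknown species {species!r}; expected one of {SPECIES}")


def write_simulation(config: GeneratorConfig, dir_path: str | Path) -> Path:
    """Simulate and write the MTX/TSV layout plus truth.tsv and config.yaml."""
    matrix, _ = simulate(config)
    out = write_matrix(matrix, dir_path)
    snapshot = asdict(config)
    snapshot["stage_map"] = [list(b) for b in config.stage_map.boundaries]

    def _plain(obj):
        if isinstance(obj, dict):
            return {k: _plain(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [_plain(v) for v in obj]
        if isinstance(obj, np.generic):
            return obj.item()
        return obj

    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(_plain(snapshot), fh, default_flow_style=False)
    return out
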