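"""Shared fixtures: study-scale simulations (session-scoped, reused by the
acceptance tests) and a light six-type simulation for unit tests."""

from types import SimpleNamespace

import numpy as np
import pandas as pd
import pytest

import retinage as ra
from retinage.simulate import (
    CellTypeSpec,
    Donor,
    GeneratorConfig,
    HCMix,
    LRSignal,
    PlantedTrends,
    RodSubtypeMix,
)

MARKERS = {
    "rod": ("NRL", "RHO", "GNAT1"),
    "cone": ("ARR3", "PDE6H", "OPN1LW"),
    "bipolar": ("VSX2", "GRM6", "CABP5"),
    "horizontal": ("ONECUT1", "ONECUT2"),
    "muller_glia": ("RLBP1", "GLUL", "SLC1A3"),
    "amacrine": ("GAD1", "TFAP2A", "SLC32A1"),
}

THREE_STAGE_DONORS = [
    Donor("D30", "human", 30.0),
    Donor("D55", "human", 55.0),
    Donor("D80", "human", 80.0),
]


def truth_annotation(matrix: ra.CellMatrix) -> ra.CellAnnotation:
    """Annotation seeded from generator truth (isolates subtype classifiers
    and downstream stages from clustering noise)."""
    types = matrix.truth["cell_type"]
    codes = pd.factorize(types, sort=True)[0]
    cells = pd.DataFrame(
        {
            "cluster_id": codes,
            "cell_type": types,
            "subtype": pd.array([pd.NA] * matrix.n_cells, dtype="string"),
            "tie_flag": False,
        },
        index=matrix.truth.index,
    )
    return ra.CellAnnotation(cells=cells)


def small_config(seed: int = 7, n_per_type: int = 200, **overrides) -> GeneratorConfig:
    """Six-type retina sim with three staged donors; light enough for units."""
    defaults = dict(
        n_genes=300,
        cell_types={
            t: CellTypeSpec(int(n_per_type * 0.3), int(n_per_type * 0.7), m)
            for t, m in MARKERS.items()
        },
        donors=list(THREE_STAGE_DONORS),
        seed=seed,
        rod_subtype_mix=RodSubtypeMix(0.3, 0.7),
        hc_mix=HCMix(0.1, {"adult": 0.4, "mid": 0.4, "aging": 0.4}),
        planted_trends=PlantedTrends(10, 10, 1.0),
        lr_signals=[LRSignal("VEGFA", "FLT1", "muller_glia", "rod", 1.5)],
        base_mean=2.0,  # deeper libraries: planted down-trends stay
        # detectable at unit-test cell counts even for genes whose conserved
        # baseline draw is low (the study-scale configs get power from cells)
    )
    defaults.update(overrides)
    return GeneratorConfig(**defaults)


def _bundle(config: GeneratorConfig) -> SimpleNamespace:
    matrix, truth = ra.simulate_atlas(config)
    norm = ra.normalize(matrix)
    annot = truth_annotation(matrix)
    return SimpleNamespace(config=config, matrix=matrix, truth=truth,
                           norm=norm, annot=annot)


@pytest.fixture(scope="session")
def small_sim() -> SimpleNamespace:
    return _bundle(small_config())


@pytest.fixture(scope="session")
def human_default() -> SimpleNamespace:
    """The study-conditions human simulation (seed 1), classifiers applied."""
    bundle = _bundle(ra.default_study_config("human", seed=1))
    annot = ra.classify_rod_subtype(bundle.norm, bundle.annot)
    annot = ra.classify_hc_subtype(bundle.norm, annot)
    bundle.annot = annot
    return bundle


@pytest.fixture(scope="session")
def macaque_default() -> SimpleNamespace:
    bundle = _bundle(ra.default_study_config("macaque", seed=1))
    annot = ra.classify_rod_subtype(bundle.norm, bundle.annot)
    annot = ra.classify_hc_subtype(bundle.norm, annot)
    bundle.annot = annot
    return bundle
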