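"""Clustering, marker scoring, subtype classification and proportions."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from sklearn.metrics import adjusted_rand_score

import retinage as ra
from retinage.annotate import DEFAULT_MARKER_PANEL
from retinage.simulate import CellTypeSpec, Donor, GeneratorConfig, RodSubtypeMix, HCMix

from conftest import MARKERS, small_config, truth_annotation


def two_type_config(seed=3):
    return GeneratorConfig(
        n_genes=200,
        cell_types={
            "rod": CellTypeSpec(100, 200, MARKERS["rod"]),
            "cone": CellTypeSpec(100, 200, MARKERS["cone"]),
        },
        donors=[Donor("D1", "human", 40.0)],
        seed=seed,
        rod_subtype_mix=RodSubtypeMix(0.0, 0.5),
    )


class TestClusterCells:
    def test_two_separated_types_recovered(self):
        m, truth = ra.simulate_atlas(two_type_config())
        norm = ra.normalize(m)
        labels = ra.cluster_cells(norm, resolution=0.5, seed=0)
        ari = adjusted_rand_score(truth.cells["cell_type"], labels)
        assert ari >= 0.9

    def test_same_seed_same_partition(self):
        m, _ = ra.simulate_atlas(two_type_config())
        norm = ra.normalize(m)
        a = ra.cluster_cells(norm, seed=4)
        b = ra.cluster_cells(norm, seed=4)
        assert np.array_equal(a, b)

    def test_identical_cells_rejected(self):
        counts = sp.csr_matrix(np.tile([[3], [1], [2]], (1, 60)))
        meta = pd.DataFrame(
            {"donor_id": "D", "species": "human", "age_years": 30.0,
             "region": "fovea"},
            index=pd.Index([f"C{i}" for i in range(60)], name="barcode"),
        )
        m = ra.CellMatrix(counts=counts, gene_ids=["A", "B", "C"],
                          cell_ids=list(meta.index), meta=meta)
        with pytest.raises(ValueError, match="identical"):
            ra.cluster_cells(ra.normalize(m), seed=0)

    def test_too_few_cells(self, small_sim):
        sub = ra.NormalizedMatrix(
            values=small_sim.norm.values[:, :20],
            gene_ids=small_sim.norm.gene_ids,
            cell_ids=small_sim.norm.cell_ids[:20],
            meta=small_sim.norm.meta.iloc[:20],
            scale_total=1e4,
        )
        with pytest.raises(ValueError, match="50 cells"):
            ra.cluster_cells(sub, seed=0)


class TestScoreCellTypes:
    def test_six_type_accuracy(self, small_sim):
        labels = ra.cluster_cells(small_sim.norm, seed=0)
        annot = ra.score_cell_types(small_sim.norm, labels, DEFAULT_MARKER_PANEL)
        acc = (annot.cells["cell_type"].to_numpy()
               == small_sim.truth.cells["cell_type"].to_numpy()).mean()
        assert acc >= 0.9  # clustering-noise floor; truth-cluster case below

    def test_truth_clusters_label_perfectly(self, small_sim):
        codes = pd.factorize(small_sim.truth.cells["cell_type"], sort=True)[0]
        annot = ra.score_cell_types(small_sim.norm, codes, DEFAULT_MARKER_PANEL)
        assert (annot.cells["cell_type"].to_numpy()
                == small_sim.truth.cells["cell_type"].to_numpy()).all()
        # scores argmax consistent with labels where no tie was flagged
        ts = annot.type_scores
        for cid, row in ts.iterrows():
            cells = annot.cells[annot.cells["cluster_id"] == cid]
            if not cells["tie_flag"].any():
                assert row.idxmax() == cells["cell_type"].iloc[0]

    def test_missing_marker_warned_absent_type_fails(self, small_sim):
        panel = ra.MarkerPanel(entries={"rod": ["NRL", "NOT_A_GENE"]})
        codes = np.zeros(small_sim.norm.n_cells, dtype=int)
        with pytest.warns(UserWarning, match="NOT_A_GENE"):
            ra.score_cell_types(small_sim.norm, codes, panel)
        bad = ra.MarkerPanel(entries={"rod": ["NOPE1", "NOPE2"]})
        with pytest.raises(ValueError, match="all markers missing"):
            with pytest.warns(UserWarning):
                ra.score_cell_types(small_sim.norm, codes, bad)

    def test_tie_break_lexicographic_and_flagged(self):
        # two clusters with mirrored marker expression -> equal scores
        counts = np.zeros((2, 8), dtype=int)
        counts[0, :4] = 5
        counts[1, 4:] = 5
        meta = pd.DataFrame(
            {"donor_id": "D", "species": "human", "age_years": 30.0,
             "region": "fovea"},
            index=pd.Index([f"C{i}" for i in range(8)], name="barcode"),
        )
        m = ra.CellMatrix(counts=sp.csr_matrix(counts), gene_ids=["M1", "M2"],
                          cell_ids=list(meta.index), meta=meta)
        panel = ra.MarkerPanel(entries={"alpha": ["M1", "M2"],
                                        "beta": ["M1", "M2"]})
        annot = ra.score_cell_types(ra.normalize(m),
                                    np.repeat([0, 1], 4), panel)
        assert (annot.cells["cell_type"] == "alpha").all()
        assert annot.cells["tie_flag"].all()


class TestRodSubtype:
    def test_zero_count_rod_is_negative(self, small_sim):
        annot = ra.classify_rod_subtype(small_sim.norm, small_sim.annot)
        row = small_sim.norm.gene_index(["MYO9A"])[0]
        detected = np.asarray(small_sim.norm.values[row].todense()).ravel() > 0
        rods = (annot.cells["cell_type"] == "rod").to_numpy()
        sub = annot.cells.loc[rods, "subtype"]
        assert (sub[~detected[rods]] == "MYO9A-").all()
        assert (sub[detected[rods]] == "MYO9A+").all()

    def test_non_rods_untouched(self, small_sim):
        annot = ra.classify_rod_subtype(small_sim.norm, small_sim.annot)
        non_rod = annot.cells["cell_type"] != "rod"
        assert annot.cells.loc[non_rod, "subtype"].isna().all()

    def test_recovers_configured_fraction(self, small_sim):
        annot = ra.classify_rod_subtype(small_sim.norm, small_sim.annot)
        rods = annot.cells["cell_type"] == "rod"
        frac = (annot.cells.loc[rods, "subtype"] == "MYO9A-").mean()
        assert frac == pytest.approx(0.3, abs=0.015)

    def test_dropout_corruption_shifts_by_injected_rate(self, small_sim):
        """Zeroing MYO9A in 30% of MYO9A+ rods misclassifies exactly those."""
        rng = np.random.default_rng(0)
        norm = small_sim.norm
        row = norm.gene_index(["MYO9A"])[0]
        truth_sub = small_sim.truth.cells["subtype"]
        pos = np.flatnonzero(
            (truth_sub == "MYO9A+").fillna(False).to_numpy(dtype=bool))
        corrupt = rng.choice(pos, size=int(0.3 * len(pos)), replace=False)
        values = norm.values.tolil()
        values[row, corrupt] = 0.0
        corrupted = ra.NormalizedMatrix(
            values=values.tocsr(), gene_ids=norm.gene_ids,
            cell_ids=norm.cell_ids, meta=norm.meta, scale_total=1e4,
        )
        annot = ra.classify_rod_subtype(corrupted, small_sim.annot)
        rods = (annot.cells["cell_type"] == "rod").to_numpy()
        mis = (annot.cells["subtype"][rods].to_numpy()
               != truth_sub[rods].to_numpy())
        # misclassified = injected dropout + the generator's own tiny dropout
        n_pos = (truth_sub[rods] == "MYO9A+").sum()
        assert mis.sum() / n_pos == pytest.approx(0.3, abs=0.02)

    def test_absent_gene_errors(self, small_sim):
        with pytest.raises(KeyError):
            ra.classify_rod_subtype(small_sim.norm, small_sim.annot,
                                    gene="NOT_THERE")


class TestHCSubtype:
    def test_pure_marker_cell_goes_to_h1(self, small_sim):
        annot = ra.classify_hc_subtype(small_sim.norm, small_sim.annot)
        hcs = (annot.cells["cell_type"] == "horizontal").to_numpy()
        agree = (annot.cells.loc[hcs, "subtype"].to_numpy()
                 == small_sim.truth.cells.loc[hcs, "subtype"].to_numpy())
        assert agree.mean() >= 0.98

    def test_tie_breaks_to_h1_with_flag(self):
        counts = np.ones((4, 60), dtype=int) * 2  # all four rule genes equal
        meta = pd.DataFrame(
            {"donor_id": "D", "species": "human", "age_years": 30.0,
             "region": "fovea"},
            index=pd.Index([f"C{i}" for i in range(60)], name="barcode"),
        )
        m = ra.CellMatrix(
            counts=sp.csr_matrix(counts),
            gene_ids=["LHX1", "PCP4", "ISL1", "CALB1"],
            cell_ids=list(meta.index), meta=meta,
        )
        cells = pd.DataFrame(
            {"cluster_id": 0, "cell_type": "horizontal",
             "subtype": pd.array([pd.NA] * 60, dtype="string"),
             "tie_flag": False},
            index=meta.index,
        )
        annot = ra.classify_hc_subtype(ra.normalize(m),
                                       ra.CellAnnotation(cells))
        assert (annot.cells["subtype"] == "H1").all()
        assert annot.cells["tie_flag"].all()


class TestProportions:
    def test_single_label_group_ci_is_degenerate(self):
        labels = pd.Series(["rod"] * 50, index=[f"C{i}" for i in range(50)])
        meta = pd.DataFrame({"region": ["fovea"] * 50}, index=labels.index)
        tab = ra.estimate_proportions(labels, meta, ["region"], n_boot=200)
        assert tab.loc[0, "proportion"] == 1.0
        assert tab.loc[0, "ci_low"] == 1.0 and tab.loc[0, "ci_high"] == 1.0

    def test_proportions_sum_to_one_and_ci_brackets(self, small_sim):
        annot = ra.classify_hc_subtype(small_sim.norm, small_sim.annot)
        tab = ra.estimate_proportions(annot, small_sim.matrix.meta,
                                      ["region"], label="cell_type",
                                      n_boot=300, seed=0)
        sums = tab.groupby("region")["proportion"].sum()
        assert np.allclose(sums, 1.0)
        assert (tab["ci_low"] <= tab["proportion"] + 1e-9).all()
        assert (tab["ci_high"] >= tab["proportion"] - 1e-9).all()

    def test_bootstrap_ci_coverage_near_nominal(self):
        """95% CIs cover a true binomial p=0.3 about 95% of the time."""
        rng = np.random.default_rng(42)
        p_true, n, reps = 0.3, 500, 200
        covered = 0
        meta = pd.DataFrame({"g": ["all"] * n},
                            index=[f"C{i}" for i in range(n)])
        for rep in range(reps):
            labels = pd.Series(
                np.where(rng.random(n) < p_true, "pos", "neg"),
                index=meta.index,
            )
            tab = ra.estimate_proportions(labels, meta, ["g"], n_boot=300,
                                          seed=rep)
            row = tab[tab["label"] == "pos"].iloc[0]
            covered += row["ci_low"] <= p_true <= row["ci_high"]
        assert covered / reps == pytest.approx(0.95, abs=0.03)

    def test_empty_group_keys_rejected(self, small_sim):
        with pytest.raises(KeyError, match="nope"):
            ra.estimate_proportions(small_sim.annot, small_sim.matrix.meta,
                                    ["nope"])
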