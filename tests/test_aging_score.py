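"""Aging-score computation, trajectory smoothing, and the region gradient test."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from scipy import stats

import retinage as ra
from retinage import aging

from conftest import small_config


def make_meta(n, ages, regions, donors=None):
    idx = pd.Index([f"C{i}" for i in range(n)], name="barcode")
    return pd.DataFrame(
        {
            "donor_id": donors if donors is not None
            else [f"D{a}" for a in ages],
            "species": "human",
            "age_years": ages,
            "region": regions,
        },
        index=idx,
    )


class TestAgingGeneSet:
    def test_disjoint_directions_enforced(self):
        with pytest.raises(ValueError, match="both directions"):
            aging.AgingGeneSet(up_genes=["A", "B"], down_genes=["B"])

    def test_tsv_round_trip(self, tmp_path):
        path = tmp_path / "geneset.tsv"
        path.write_text("gene\tdirection\tweight\nA\tup\t1.0\nB\tdown\t0.5\n")
        gs = aging.AgingGeneSet.from_tsv(path)
        assert gs.up_genes == ["A"] and gs.down_genes == ["B"]
        assert gs.weight_of("B") == 0.5


class TestComputeAgingScore:
    def test_extremal_cells_score_zero_and_one(self):
        # one cell maximal in all up genes & minimal in down genes, one mirror
        counts = np.array([
            [9, 0, 3],   # up gene
            [9, 0, 3],   # up gene
            [0, 9, 3],   # down gene
            [5, 5, 5],   # filler keeps libraries even
        ])
        meta = make_meta(3, [30.0, 30.0, 30.0], ["fovea"] * 3)
        m = ra.CellMatrix(counts=sp.csr_matrix(counts),
                          gene_ids=["U1", "U2", "DN1", "F"],
                          cell_ids=list(meta.index), meta=meta)
        gs = aging.AgingGeneSet(up_genes=["U1", "U2"], down_genes=["DN1"])
        score = aging.compute_aging_score(ra.normalize(m), gs)
        assert score.iloc[0] == 1.0
        assert score.iloc[1] == 0.0
        assert 0.0 < score.iloc[2] < 1.0

    def test_cell_permutation_equivariance(self, small_sim):
        gs = aging.AgingGeneSet(up_genes=small_sim.truth.up_genes,
                                down_genes=small_sim.truth.down_genes)
        score = aging.compute_aging_score(small_sim.norm, gs)
        rng = np.random.default_rng(1)
        perm = rng.permutation(small_sim.norm.n_cells)
        norm_p = ra.NormalizedMatrix(
            values=small_sim.norm.values[:, perm],
            gene_ids=small_sim.norm.gene_ids,
            cell_ids=small_sim.norm.cell_ids[perm],
            meta=small_sim.norm.meta.iloc[perm],
            scale_total=1e4,
        )
        score_p = aging.compute_aging_score(norm_p, gs)
        assert np.allclose(score.to_numpy()[perm], score_p.to_numpy())

    def test_planted_signal_correlates_with_age(self, small_sim):
        gs = aging.AgingGeneSet(up_genes=small_sim.truth.up_genes,
                                down_genes=small_sim.truth.down_genes)
        score = aging.compute_aging_score(small_sim.norm, gs)
        rho = stats.spearmanr(
            score.to_numpy(), small_sim.norm.meta["age_years"].to_numpy()
        ).statistic
        assert rho >= 0.8

    def test_absent_gene_set_rejected(self, small_sim):
        gs = aging.AgingGeneSet(up_genes=["ZZZ1"], down_genes=["ZZZ2"])
        with pytest.raises(ValueError, match="no gene-set genes"):
            aging.compute_aging_score(small_sim.norm, gs)


class TestFitTrajectory:
    def test_constant_scores_give_flat_curve(self):
        n = 300
        ages = np.repeat([30.0, 55.0, 80.0], n // 3)
        meta = make_meta(n, ages, ["fovea"] * n)
        scores = pd.Series(0.5, index=meta.index)
        curve = aging.fit_trajectory(scores, meta, "fovea", n_boot=200, seed=0)
        assert np.allclose(curve.fitted, 0.5)
        assert np.allclose(curve.band_low, 0.5)
        assert np.allclose(curve.band_high, 0.5)

    def test_same_seed_identical_band(self):
        rng = np.random.default_rng(2)
        n = 300
        ages = np.repeat([30.0, 55.0, 80.0], n // 3)
        meta = make_meta(n, ages, ["fovea"] * n)
        scores = pd.Series(rng.random(n), index=meta.index)
        a = aging.fit_trajectory(scores, meta, "fovea", n_boot=200, seed=5)
        b = aging.fit_trajectory(scores, meta, "fovea", n_boot=200, seed=5)
        assert np.array_equal(a.band_low, b.band_low)
        assert np.array_equal(a.band_high, b.band_high)

    def test_linear_trend_fits_positive_slope_and_band_covers(self):
        """Monotone fit on a linear signal; the 95% band covers the
        generating line in >= 90% of (replicate, grid point) draws."""
        n = 600
        ages = np.repeat([30.0, 45.0, 60.0, 75.0, 90.0], n // 5)
        meta = make_meta(n, ages, ["fovea"] * n)
        covered = []
        for seed in range(30):
            rng = np.random.default_rng(seed)
            scores = pd.Series(0.002 * ages + rng.normal(0, 0.02, n),
                               index=meta.index)
            curve = aging.fit_trajectory(scores, meta, "fovea", n_boot=300,
                                         seed=seed)
            if seed == 0:
                assert np.all(np.diff(curve.fitted) > 0)
            truth_on_grid = 0.002 * curve.grid_ages
            covered.append((curve.band_low <= truth_on_grid)
                           & (truth_on_grid <= curve.band_high))
        assert np.mean(covered) >= 0.9

    def test_too_few_ages_rejected(self):
        meta = make_meta(40, [30.0] * 20 + [60.0] * 20, ["fovea"] * 40)
        scores = pd.Series(0.5, index=meta.index)
        with pytest.raises(ValueError, match="3 distinct donor ages"):
            aging.fit_trajectory(scores, meta, "fovea")


def paired_region_scores(seed, n_per=200, shift=0.0):
    rng = np.random.default_rng(seed)
    ages = np.repeat([30.0, 50.0, 70.0, 90.0], n_per // 2)
    regions = np.tile(["fovea", "periphery"], len(ages) // 2)
    donors = [f"D{int(a)}" for a in ages]
    meta = make_meta(len(ages), ages, regions, donors)
    scores = 0.004 * ages + rng.normal(0, 0.05, len(ages))
    scores = scores + shift * (regions == "fovea")
    return pd.Series(scores, index=meta.index), meta


class TestRegionGradientTest:
    def test_identical_inputs_delta_zero_p_one(self):
        scores, meta = paired_region_scores(0)
        curve = aging.fit_trajectory(scores, meta, "fovea", n_boot=200, seed=0)
        other = aging.ScoreCurve(
            region="periphery", grid_ages=curve.grid_ages,
            fitted=curve.fitted.copy(), band_low=curve.band_low.copy(),
            band_high=curve.band_high.copy(),
            per_cell_scores=curve.per_cell_scores,
            cells=curve.cells.assign(region="periphery"),
            bandwidth=curve.bandwidth,
        )
        res = aging.region_gradient_test(curve, other, n_perm=99, seed=1)
        assert res["delta"] == 0.0
        assert res["p"] == 1.0

    def test_planted_shift_detected(self):
        scores, meta = paired_region_scores(4, shift=0.1)
        cf = aging.fit_trajectory(scores, meta, "fovea", n_boot=200, seed=0)
        cp = aging.fit_trajectory(scores, meta, "periphery", n_boot=200, seed=1)
        res = aging.region_gradient_test(cf, cp, n_perm=199, seed=2)
        assert res["delta"] == pytest.approx(0.1, abs=0.02)
        assert res["p"] < 0.05

    def test_swapping_regions_negates_delta(self):
        scores, meta = paired_region_scores(5, shift=0.07)
        cf = aging.fit_trajectory(scores, meta, "fovea", n_boot=200, seed=0)
        cp = aging.fit_trajectory(scores, meta, "periphery", n_boot=200, seed=1)
        fwd = aging.region_gradient_test(cf, cp, n_perm=99, seed=2)
        rev = aging.region_gradient_test(cp, cf, n_perm=99, seed=2)
        assert fwd["delta"] == pytest.approx(-rev["delta"])

    def test_null_pvalues_uniform(self):
        """Under exchangeable region labels, p-values are uniform (KS)."""
        pvals = []
        for rep in range(60):
            scores, meta = paired_region_scores(100 + rep)
            cf = aging.fit_trajectory(scores, meta, "fovea", n_boot=200,
                                      seed=rep)
            cp = aging.fit_trajectory(scores, meta, "periphery", n_boot=200,
                                      seed=rep + 1)
            res = aging.region_gradient_test(cf, cp, n_perm=199, seed=rep + 2)
            pvals.append(res["p"])
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01


class TestGeneTrajectoryAndDrift:
    def test_planted_up_gene_has_rising_trajectory(self, small_sim):
        curve = aging.gene_trajectory(small_sim.norm,
                                      small_sim.truth.up_genes[0],
                                      "periphery", n_boot=200, seed=0)
        rho = stats.spearmanr(curve.fitted, curve.grid_ages).statistic
        assert rho > 0

    def test_up_and_down_genes_have_opposite_slopes(self, small_sim):
        up = aging.gene_trajectory(small_sim.norm, small_sim.truth.up_genes[0],
                                   "periphery", n_boot=200, seed=0)
        down = aging.gene_trajectory(small_sim.norm,
                                     small_sim.truth.down_genes[0],
                                     "periphery", n_boot=200, seed=0)
        assert up.fitted[-1] > up.fitted[0]
        assert down.fitted[-1] < down.fitted[0]

    def test_all_zero_gene_flat_zero(self, small_sim):
        norm = small_sim.norm
        zero_values = norm.values.tolil()
        row = norm.gene_index([norm.gene_ids[-1]])[0]
        zero_values[row] = 0
        norm_z = ra.NormalizedMatrix(
            values=zero_values.tocsr(), gene_ids=norm.gene_ids,
            cell_ids=norm.cell_ids, meta=norm.meta, scale_total=1e4,
        )
        curve = aging.gene_trajectory(norm_z, norm.gene_ids[-1], "fovea",
                                      n_boot=200, seed=0)
        assert np.allclose(curve.fitted, 0.0)

    def test_planted_decreasing_signature_drifts_down(self, small_sim):
        drift = aging.signature_drift(small_sim.norm, small_sim.annot,
                                      small_sim.truth.down_genes[:5], "rod")
        assert list(drift.index) == ["adult", "mid", "aging"]
        assert np.all(np.diff(drift.to_numpy()) < 0)

    def test_signature_invariant_to_affine_gene_rescale(self, small_sim):
        genes = small_sim.truth.down_genes[:3]
        base = aging.signature_drift(small_sim.norm, small_sim.annot, genes,
                                     "cone")
        norm = small_sim.norm
        rows = norm.gene_index(genes)
        scaled = norm.values.tolil().astype(float)
        for r in rows:
            scaled[r] = scaled[r] * 3.0
        norm_s = ra.NormalizedMatrix(
            values=scaled.tocsr(), gene_ids=norm.gene_ids,
            cell_ids=norm.cell_ids, meta=norm.meta, scale_total=1e4,
        )
        rescaled = aging.signature_drift(norm_s, small_sim.annot, genes, "cone")
        assert np.allclose(base.to_numpy(), rescaled.to_numpy())
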