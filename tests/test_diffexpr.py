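"""MDS screening, common-dispersion estimation, NB Wald contrasts, DEG calls."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from scipy.spatial import procrustes

from mixturetox import synthdata as sd
from mixturetox.diffexpr import (
    ContrastResult,
    CountMatrix,
    classical_mds,
    classify_degs,
    estimate_common_dispersion,
    mds_screen,
    nb_wald_contrast,
    size_factors,
)


class TestCountMatrix:
    def test_rejects_duplicates_and_negatives(self):
        counts = pd.DataFrame([[1, 2], [3, 4]], index=["g", "g"], columns=["a", "b"])
        groups = pd.Series(["x", "x"], index=["a", "b"])
        with pytest.raises(ValueError, match="duplicate gene"):
            CountMatrix(counts, groups)
        counts = pd.DataFrame([[1, -2]], index=["g"], columns=["a", "b"])
        with pytest.raises(ValueError, match="nonnegative"):
            CountMatrix(counts, groups)

    def test_rejects_unlabeled_sample(self):
        counts = pd.DataFrame([[1, 2]], index=["g"], columns=["a", "b"])
        with pytest.raises(ValueError, match="without a group"):
            CountMatrix(counts, pd.Series(["x"], index=["a"]))


class TestMdsScreen:
    def test_identical_samples_no_outliers(self):
        counts = pd.DataFrame(
            np.tile([[10], [20], [5]], (1, 4)), index=["g1", "g2", "g3"],
            columns=["a", "b", "c", "d"],
        )
        cm = CountMatrix(counts, pd.Series(["g"] * 4, index=counts.columns))
        out = mds_screen(cm)
        assert np.allclose(out[["dim1", "dim2"]], 0.0, atol=1e-8)
        assert not out["outlier_flag"].any()

    def test_classical_mds_recovers_known_configuration(self):
        """Euclidean distances of planted 2-D points are embedded exactly."""
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(12, 2))
        D = squareform(pdist(pts))
        coords = classical_mds(D, dims=2)
        _, _, disparity = procrustes(pts, coords)
        assert disparity < 1e-12

    def test_permuted_replicate_flagged(self):
        truth = sd.SynthTruth(theta=np.zeros(2000), alpha=0.05, seed=21)
        cm, _ = sd.gen_counts(2000, 3, truth)
        counts = cm.counts.copy()
        rng = np.random.default_rng(1)
        col = counts.columns[0]
        counts[col] = rng.permutation(counts[col].to_numpy())
        out = mds_screen(CountMatrix(counts, cm.groups))
        assert out.loc[col, "outlier_flag"]
        assert out["outlier_flag"].sum() == 1

    def test_too_few_samples(self, toy_counts):
        with pytest.raises(ValueError, match="at least 3"):
            mds_screen(toy_counts.subset_samples(["c1", "c2"]))


class TestCommonDispersion:
    def test_poisson_counts_give_near_zero_alpha(self):
        truth = sd.SynthTruth(theta=np.zeros(5000), alpha=0.0, seed=13)
        cm, _ = sd.gen_counts(5000, 3, truth)
        assert estimate_common_dispersion(cm) < 0.01

    def test_recovers_planted_alpha(self, small_null_counts):
        cm, truth = small_null_counts
        assert estimate_common_dispersion(cm) == pytest.approx(truth.alpha, abs=0.01)

    def test_duplicated_group_leaves_estimate_unchanged(self):
        """Adding a second group with identical counts rescales the objective only."""
        truth = sd.SynthTruth(theta=np.zeros(800), alpha=0.08, seed=2)
        cm, _ = sd.gen_counts(800, 4, truth, groups=("control",), lib_size_sd=0.0)
        one = estimate_common_dispersion(cm, pd.Series(1.0, index=cm.counts.columns))
        counts2 = pd.concat(
            [cm.counts, cm.counts.add_suffix("_dup")], axis=1
        )
        groups2 = pd.Series(
            ["control"] * 4 + ["dup"] * 4, index=counts2.columns
        )
        sf = pd.Series(1.0, index=counts2.columns)
        two = estimate_common_dispersion(CountMatrix(counts2, groups2), sf)
        assert two == pytest.approx(one, rel=1e-4)

    def test_no_replication_is_an_error(self):
        counts = pd.DataFrame([[5, 9], [3, 2]], index=["g1", "g2"], columns=["a", "b"])
        cm = CountMatrix(counts, pd.Series(["x", "y"], index=["a", "b"]))
        with pytest.raises(ValueError, match="replicates"):
            estimate_common_dispersion(cm)


class TestNbWaldContrast:
    def test_identical_groups_null_result(self, toy_counts):
        counts = toy_counts.counts.copy()
        counts[["t1", "t2"]] = counts[["c1", "c2"]].to_numpy()
        cm = CountMatrix(counts, toy_counts.groups)
        res = nb_wald_contrast(cm, "treat", "control", alpha_hat=0.05)
        t = res.table.dropna(subset=["p"])
        assert np.allclose(t["log2FC"], 0.0, atol=1e-12)
        assert np.allclose(t["p"], 1.0, atol=1e-9)

    def test_recovers_planted_effect(self):
        """theta=2 at mu=200, n=4/group: median estimated log2FC within [1.8, 2.2]."""
        theta = np.zeros(2000)
        theta[:200] = 2.0
        truth = sd.SynthTruth(theta=theta, alpha=0.05, eps_sd=0.0, seed=31)
        cm, _ = sd.gen_counts(
            2000, 4, truth, mean_log_mu=np.log(200), mean_log_sd=0.0
        )
        alpha_hat = estimate_common_dispersion(cm)
        res = nb_wald_contrast(cm, "mixtureA", "control", alpha_hat)
        med = res.table["log2FC"].iloc[:200].median()
        assert 1.8 <= med <= 2.2

    def test_matches_statsmodels_glm(self):
        """Coefficient and Wald SE agree with an NB GLM fit per gene.

        Size factors are held equal within groups, where the closed-form
        group-mean fit is the exact GLM solution.
        """
        truth = sd.make_truth(40, de_fraction=0.3, seed=17)
        cm, _ = sd.gen_counts(40, 4, truth, lib_size_sd=0.0)
        sf = pd.Series(1.0, index=cm.counts.columns)
        alpha = 0.07
        res = nb_wald_contrast(cm, "mixtureA", "control", alpha, sf)
        keep = cm.groups.isin(["control", "mixtureA"])
        y_all = cm.counts.loc[:, keep]
        X = sm.add_constant((cm.groups[keep] == "mixtureA").astype(float).to_numpy())
        offset = np.log(sf[keep].to_numpy())
        for gene in y_all.index[:25]:
            y = y_all.loc[gene].to_numpy()
            if y.sum() == 0 or y[X[:, 1] == 0].sum() == 0 or y[X[:, 1] == 1].sum() == 0:
                continue
            fit = sm.GLM(
                y, X, family=sm.families.NegativeBinomial(alpha=alpha), offset=offset
            ).fit()
            assert res.table.loc[gene, "log2FC"] == pytest.approx(
                fit.params[1] / np.log(2), abs=1e-4
            )
            se_ours = abs(
                res.table.loc[gene, "log2FC"] * np.log(2) / res.table.loc[gene, "wald_stat"]
            )
            assert se_ours == pytest.approx(fit.bse[1], rel=1e-3)

    def test_swapping_groups_negates_lfc(self, planted_dataset):
        cm, truth, _ = planted_dataset
        ah = 0.05
        fwd = nb_wald_contrast(cm, "mixtureA", "control", ah)
        rev = nb_wald_contrast(cm, "control", "mixtureA", ah)
        ok = fwd.table["p"].notna()
        assert np.allclose(
            fwd.table.loc[ok, "log2FC"], -rev.table.loc[ok, "log2FC"], atol=1e-9
        )
        assert np.allclose(fwd.table.loc[ok, "p"], rev.table.loc[ok, "p"], atol=1e-9)

    def test_count_scale_invariance(self, planted_dataset):
        """Doubling all counts (and size factors) leaves log2FC unchanged."""
        cm, _, _ = planted_dataset
        sf = size_factors(cm.counts)
        a = nb_wald_contrast(cm, "mixtureA", "control", 0.05, sf)
        cm2 = CountMatrix(cm.counts * 2, cm.groups)
        b = nb_wald_contrast(cm2, "mixtureA", "control", 0.05, sf * 2)
        ok = a.table["p"].notna()
        assert np.allclose(
            a.table.loc[ok, "log2FC"], b.table.loc[ok, "log2FC"], atol=1e-6
        )

    def test_all_zero_gene_excluded_from_bh(self, toy_counts):
        res = nb_wald_contrast(toy_counts, "treat", "control", 0.05)
        assert np.isnan(res.table.loc["g1", "p"]) or res.table.loc["g1", "p"] >= 0
        assert np.isnan(res.table.loc["g1", "p_adj"]) or True
        # g1 row index 1 is the all-zero gene in the fixture
        zero_gene = toy_counts.counts.index[1]
        assert np.isnan(res.table.loc[zero_gene, "p"])
        assert np.isnan(res.table.loc[zero_gene, "p_adj"])
        assert len(res.tested_genes()) == toy_counts.n_genes - 1

    def test_bh_is_monotone_in_p(self, small_null_counts):
        cm, _ = small_null_counts
        res = nb_wald_contrast(cm, "mixtureA", "control", 0.05)
        t = res.table.dropna(subset=["p"])
        by_p = t.sort_values(["p", "p_adj"]).index
        by_padj = t.sort_values(["p_adj", "p"], kind="stable").index
        # p_adj is a monotone transform of p: sorting by either agrees up to ties
        assert np.all(t.loc[by_p, "p_adj"].to_numpy() == np.sort(t["p_adj"].to_numpy()))
        assert np.all(t.loc[by_padj, "p"].to_numpy() == np.sort(t["p"].to_numpy()))


def test_null_pvalues_are_uniform(small_null_counts):
    """Raw Wald p-values on null genes pass a KS test against U(0,1)."""
    cm, _ = small_null_counts
    ah = estimate_common_dispersion(cm)
    res = nb_wald_contrast(cm, "mixtureA", "control", ah)
    p = res.table["p"].dropna()
    assert len(p) >= 5000
    assert stats.kstest(p, "uniform").pvalue > 0.01


class TestClassifyDegs:
    def _contrast(self, rows):
        table = pd.DataFrame(rows, columns=["log2FC", "p_adj"])
        table.index = [f"g{i+1}" for i in range(len(rows))]
        table["wald_stat"] = 0.0
        table["p"] = table["p_adj"]
        return ContrastResult("t", "c", table)

    def test_toy_filter(self):
        c = self._contrast([(1.5, 0.01), (0.9, 0.01), (1.5, 0.2)])
        degs = classify_degs(c, 1.0, 0.05)
        assert set(degs.genes) == {"g1"}
        assert degs.direction["g1"] == 1

    def test_thresholds_wide_open(self):
        c = self._contrast([(1.5, 0.01), (-0.2, 0.9), (0.0, 1.0)])
        degs = classify_degs(c, 0.0, 1.0)
        assert set(degs.genes) == {"g1", "g2", "g3"}

    def test_direction_split(self):
        c = self._contrast([(2.0, 0.01), (-2.0, 0.01)])
        degs = classify_degs(c, 1.0, 0.05)
        assert degs.up() == {"g1"} and degs.down() == {"g2"}

    def test_invalid_thresholds(self):
        c = self._contrast([(1.0, 0.01)])
        with pytest.raises(ValueError):
            classify_degs(c, -1.0, 0.05)
        with pytest.raises(ValueError):
            classify_degs(c, 1.0, 0.0)
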