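"""Transformation, ordination, distance-based testing, and the volcano
panel, each validated against an independent oracle where one exists."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from otiskit.metabolome import (
    GlogParams,
    canberra_matrix,
    dispersion_homogeneity,
    effect_size_class,
    glog,
    mann_whitney,
    mw_fdr_panel,
    pca_combined,
    permanova,
)


class TestGlog:
    def test_reference_values(self):
        assert glog(0.0) == pytest.approx(0.0)
        assert glog(3.0) == pytest.approx(np.log(3 + np.sqrt(10)))
        assert glog(3.0) == pytest.approx(1.81845, abs=1e-5)

    @given(st.floats(0, 1e6), st.floats(0, 1e6))
    @settings(max_examples=100, deadline=None)
    def test_strictly_increasing(self, a, b):
        lo, hi = sorted((a, b))
        if hi - lo > 1e-9 * (1 + hi):  # resolvable in float64
            assert glog(lo) < glog(hi)

    def test_rejects_negative_and_bad_lambda(self):
        with pytest.raises(ValueError):
            glog(-1.0)
        with pytest.raises(ValueError):
            GlogParams(0.0)


class TestPca:
    def test_two_perfectly_correlated_variables(self, rng):
        x = rng.normal(10, 1, 10)
        panel = pd.DataFrame({"a": x, "b": 2 * x + 1})
        res = pca_combined(panel, np.array(["g"] * 10), transform=False)
        assert res.explained_variance_fraction[0] == pytest.approx(1.0)

    def test_contributions_sum_to_100(self, cohort_small):
        from otiskit.panel import PANEL_COLUMNS

        sub = cohort_small[cohort_small.visit_age.isin([12.0, 18.0])]
        res = pca_combined(sub[list(PANEL_COLUMNS)], sub["group"], sub["visit_age"])
        sums = res.contributions.sum(axis=0)
        assert np.allclose(sums, 100.0, atol=1e-9)
        assert res.expected_mean_contribution == pytest.approx(100 / 52)

    def test_reconstruction_identity(self, rng):
        """Scores times loadings reproduce the centered/scaled matrix."""
        X = rng.normal(size=(20, 6)) ** 2
        res = pca_combined(pd.DataFrame(X), np.array(["g"] * 20))
        Xs = glog(X)
        Xs = (Xs - Xs.mean(0)) / Xs.std(0, ddof=1)
        scores = res.scores[[c for c in res.scores.columns if c.startswith("PC")]]
        # loadings from contributions lose sign; recompute via lstsq instead
        recon = scores.to_numpy() @ np.linalg.lstsq(scores, Xs, rcond=None)[0]
        assert np.allclose(recon, Xs, atol=1e-8)

    def test_matches_sklearn(self, rng):
        from sklearn.decomposition import PCA

        X = np.abs(rng.normal(50, 10, size=(40, 8)))
        res = pca_combined(pd.DataFrame(X), np.array(["g"] * 40), transform=False)
        Xs = (X - X.mean(0)) / X.std(0, ddof=1)
        sk = PCA().fit(Xs)
        ours = res.explained_variance_fraction
        assert np.allclose(ours, sk.explained_variance_ratio_, atol=1e-10)

    def test_constant_variable_dropped_with_warning(self, rng):
        X = pd.DataFrame({"a": rng.normal(5, 1, 10), "b": np.ones(10)})
        with pytest.warns(UserWarning):
            res = pca_combined(X, np.array(["g"] * 10), transform=False)
        assert res.dropped == ["b"]


class TestCanberra:
    def test_unit_vectors(self):
        D = canberra_matrix(np.array([[1.0, 0.0], [0.0, 1.0]]))
        assert D[0, 1] == pytest.approx(2.0)
        assert D[0, 0] == 0.0

    def test_hand_computed_three_points(self):
        X = np.array([[1.0, 2.0, 0.0], [2.0, 2.0, 1.0], [0.0, 1.0, 1.0]])
        D = canberra_matrix(X)
        assert D[0, 1] == pytest.approx(1 / 3 + 0 + 1)
        assert D[0, 2] == pytest.approx(1 + 1 / 3 + 1)
        assert D[1, 2] == pytest.approx(1 + 1 / 3 + 0)
        assert np.allclose(D, D.T)


class TestPermanova:
    def test_perfect_separation_gives_r2_one(self):
        X = np.array([[1.0, 1.0]] * 4 + [[5.0, 5.0]] * 4)
        D = canberra_matrix(X)
        res = permanova(D, ["a"] * 4 + ["b"] * 4, n_perm=99, seed=0)
        assert res.R2 == pytest.approx(1.0)
        assert res.SS_within == pytest.approx(0.0)

    def test_matches_scikit_bio(self, rng):
        from skbio.stats.distance import DistanceMatrix
        from skbio.stats.distance import permanova as sk_permanova

        X = np.abs(rng.normal(5, 1, size=(24, 6)))
        X[:12] *= 1.4
        labels = ["a"] * 12 + ["b"] * 12
        D = canberra_matrix(X)
        ours = permanova(D, labels, n_perm=999, seed=3)
        theirs = sk_permanova(DistanceMatrix(D), labels, permutations=999)
        assert ours.pseudo_F == pytest.approx(theirs["test statistic"], rel=1e-10)
        assert abs(ours.p_perm - theirs["p-value"]) < 0.05

    def test_monte_carlo_agrees_with_exhaustive_relabeling(self, rng):
        """n=8: enumerate all 8!/(4!4!)=70 balanced relabelings and compare
        the exact permutation p with the 999-draw Monte-Carlo p."""
        X = np.abs(rng.normal(3, 1, size=(8, 4)))
        X[:4, 0] += 1.0
        labels = np.array(["a"] * 4 + ["b"] * 4)
        D = canberra_matrix(X)
        obs = permanova(D, labels, n_perm=999, seed=5)
        stats_all = []
        for combo in itertools.combinations(range(8), 4):
            lab = np.array(["b"] * 8)
            lab[list(combo)] = "a"
            stats_all.append(permanova(D, lab, n_perm=1, seed=0).pseudo_F)
        stats_all = np.array(stats_all)
        p_exact = np.mean(stats_all >= obs.pseudo_F - 1e-12)
        mc_se = np.sqrt(p_exact * (1 - p_exact) / 999)
        assert abs(obs.p_perm - p_exact) <= 2 * mc_se + 2 / 1000

    def test_f_invariant_to_distance_rescaling(self, rng):
        X = np.abs(rng.normal(5, 1, size=(20, 5)))
        labels = ["a"] * 10 + ["b"] * 10
        D = canberra_matrix(X)
        r1 = permanova(D, labels, n_perm=9, seed=0)
        r2 = permanova(3.7 * D, labels, n_perm=9, seed=0)
        assert r1.pseudo_F == pytest.approx(r2.pseudo_F)
        assert r1.R2 == pytest.approx(r2.R2)

    def test_r2_invariant_to_sample_reordering(self, rng):
        X = np.abs(rng.normal(5, 1, size=(16, 5)))
        labels = np.array(["a"] * 8 + ["b"] * 8)
        D = canberra_matrix(X)
        perm = rng.permutation(16)
        r1 = permanova(D, labels, n_perm=9, seed=0)
        r2 = permanova(D[np.ix_(perm, perm)], labels[perm], n_perm=9, seed=0)
        assert r1.R2 == pytest.approx(r2.R2)

    def test_p_floor_and_degenerate_grouping(self, rng):
        X = np.abs(rng.normal(5, 1, size=(10, 3)))
        D = canberra_matrix(X)
        res = permanova(D, ["a"] * 5 + ["b"] * 5, n_perm=99, seed=0)
        assert res.p_perm >= 1 / 100
        with pytest.raises(ValueError):
            permanova(D, ["a"] * 9 + ["b"], n_perm=9, seed=0)


class TestDispersion:
    def test_identical_group_geometry(self):
        from scipy.spatial.distance import pdist, squareform

        block = np.array([[0.0, 0], [2, 0], [0, 2], [2, 2]])
        X = np.vstack([block + 1, block + 30])
        D = squareform(pdist(X))  # euclidean: both groups share geometry
        p = dispersion_homogeneity(D, ["a"] * 4 + ["b"] * 4)
        assert p > 0.9

    def test_scaled_group_detected(self, rng):
        base = np.abs(rng.normal(10, 1, size=(15, 4)))
        spread = 10 + (np.abs(rng.normal(10, 1, size=(15, 4))) - 10) * 5
        X = np.vstack([base, np.abs(spread)])
        D = canberra_matrix(X)
        p = dispersion_homogeneity(D, ["a"] * 15 + ["b"] * 15)
        assert p < 0.05

    def test_output_in_unit_interval(self, rng):
        X = np.abs(rng.normal(5, 1, size=(12, 4)))
        p = dispersion_homogeneity(canberra_matrix(X), ["a"] * 6 + ["b"] * 6)
        assert 0.0 <= p <= 1.0


class TestMannWhitneyPanel:
    def test_exact_small_sample(self):
        U, p, z = mann_whitney(np.array([1.0, 2.0]), np.array([3.0, 4.0]), exact=True)
        assert U in (0.0, 4.0)
        assert p == pytest.approx(1 / 3)

    def test_identical_groups(self):
        x = np.array([1.0, 1.0, 1.0])
        U, p, z = mann_whitney(x, x)
        assert p == 1.0 and z == 0.0

    def test_exact_matches_brute_force_enumeration(self, rng):
        """For n1=n2=4 without ties the exact p equals the proportion of
        label assignments with |U - mu| at least as extreme."""
        x = rng.normal(size=4)
        y = rng.normal(size=4) + 0.8
        pooled = np.concatenate([x, y])
        _, p_exact, _ = mann_whitney(x, y, exact=True)
        mu = 8.0
        obs = abs(stats.mannwhitneyu(x, y, alternative="two-sided").statistic - mu)
        count = 0
        combos = list(itertools.combinations(range(8), 4))
        for combo in combos:
            xa = pooled[list(combo)]
            yb = pooled[[i for i in range(8) if i not in combo]]
            u = stats.mannwhitneyu(xa, yb, alternative="two-sided").statistic
            if abs(u - mu) >= obs - 1e-12:
                count += 1
        assert p_exact == pytest.approx(count / len(combos))

    def test_bh_hand_example(self):
        from statsmodels.stats.multitest import multipletests

        q = multipletests([0.01, 0.02, 0.03, 0.04], method="fdr_bh")[1]
        assert np.allclose(q, 0.04)

    def test_rank_tests_invariant_to_glog(self, rng):
        """U tests are rank-based, so transforming concentrations cannot
        change p-values."""
        panel = pd.DataFrame(np.abs(rng.normal(10, 2, size=(30, 5))))
        panel.columns = [f"m{i}" for i in range(5)]
        groups = np.array(["a"] * 15 + ["b"] * 15)
        raw = mw_fdr_panel(panel, groups)
        trans = mw_fdr_panel(pd.DataFrame(glog(panel.to_numpy()), columns=panel.columns), groups)
        assert np.allclose(raw["p_raw"], trans["p_raw"])

    def test_direction_and_classes(self, rng):
        panel = pd.DataFrame({
            "up_in_a": np.concatenate([rng.normal(12, 1, 40), rng.normal(10, 1, 40)]),
            "flat": rng.normal(10, 1, 80),
        })
        groups = np.array(["a"] * 40 + ["b"] * 40)
        res = mw_fdr_panel(panel, groups, group_a="a").set_index("metabolite")
        assert res.loc["up_in_a", "direction"] == "a"
        assert res.loc["up_in_a", "significant"]
        assert effect_size_class(0.2) == "small"
        assert effect_size_class(0.4) == "moderate"
        assert effect_size_class(0.6) == "large"

    def test_all_tied_metabolite(self):
        panel = pd.DataFrame({"const": np.ones(20)})
        res = mw_fdr_panel(panel, np.array(["a"] * 10 + ["b"] * 10))
        assert res["p_raw"][0] == 1.0
        assert res["effect_size_r"][0] == 0.0
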