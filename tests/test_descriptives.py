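"""Descriptives: Ward clustering, Kaiser criterion, minres+varimax EFA,
loading significance, LV-emotion correlation, ANOVA, histograms."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy.linalg import orthogonal_procrustes
from scipy.stats import ttest_ind

from emoplsc.behavior import EmotionCentroids, emotion_centroids
from emoplsc.descriptives import (
    anova_eta_squared,
    efa_varimax,
    kaiser_count,
    loading_significance,
    lv_emotion_correlation,
    rating_histograms,
    varimax,
    ward_cluster,
)
from emoplsc.features import FEATURE_IDS, REFERENCE_LOADINGS
from emoplsc.plsc import PLSCModel


def _centroids(values, categories=None):
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    cats = categories or tuple(f"c{i}" for i in range(n))
    return EmotionCentroids(
        values=values,
        categories=tuple(cats),
        counts=np.ones(n, dtype=int),
        feature_ids=tuple(f"f{j}" for j in range(p)),
    )


from tests_ward_oracle import ward_oracle as _ward_oracle


class TestWard:
    def test_two_tight_pairs_merge_first(self):
        pts = np.array([[0.0, 0.0], [0.1, 0.0], [10.0, 0.0], [10.1, 0.0]])
        tree = ward_cluster(_centroids(pts))
        first_two = tree.linkage_matrix[:2, :2].astype(int)
        merged = {frozenset(row) for row in first_two}
        assert merged == {frozenset({0, 1}), frozenset({2, 3})}

    def test_heights_nondecreasing_and_nine_merges(self, prepared_blocks):
        _, Yz = prepared_blocks
        tree = ward_cluster(emotion_centroids(Yz))
        assert len(tree.linkage_matrix) == 9
        assert (np.diff(tree.heights) >= -1e-12).all()

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            n = int(rng.integers(3, 13))
            X = rng.standard_normal((n, int(rng.integers(2, 6))))
            tree = ward_cluster(_centroids(X))
            oracle = _ward_oracle(X)
            assert np.allclose(np.sort(tree.heights), np.sort(oracle), atol=1e-8)

    def test_valence_split_at_top(self):
        """Centroids planted with opposite-valence means split into the
        positive and negative groups at the top of the tree."""
        rng = np.random.default_rng(0)
        pos = 1.0 + 0.1 * rng.standard_normal((4, 34))
        neg = -1.0 + 0.1 * rng.standard_normal((6, 34))
        cats = ("joy", "satisfaction", "love", "calm",
                "fear", "anxiety", "anger", "sadness", "disgust", "surprise")
        tree = ward_cluster(_centroids(np.vstack([pos, neg]), cats))
        assign = tree.cut(2)
        assert len({assign[c] for c in cats[:4]}) == 1
        assert len({assign[c] for c in cats[4:]}) == 1
        assert assign["joy"] != assign["fear"]

    def test_newick_and_nested_exports(self, prepared_blocks):
        _, Yz = prepared_blocks
        tree = ward_cluster(emotion_centroids(Yz))
        nwk = tree.to_newick()
        assert nwk.endswith(";") and "joy" in nwk
        nested = tree.to_nested()
        assert "children" in nested


class TestKaiser:
    def test_independent_features_count_zero(self):
        rng = np.random.default_rng(1)
        # exactly uncorrelated columns: eigenvalues of identity are all 1
        X = rng.standard_normal((500, 6))
        Q, _ = np.linalg.qr(X - X.mean(axis=0))
        assert kaiser_count(Q) == 0

    def test_one_dominant_factor(self):
        rng = np.random.default_rng(2)
        f = rng.standard_normal(2000)
        X = np.outer(f, np.full(10, 0.9)) + 0.3 * rng.standard_normal((2000, 10))
        assert kaiser_count(X) == 1

    def test_invariant_to_feature_rescaling(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((300, 8)) @ rng.standard_normal((8, 8))
        scales = rng.uniform(0.1, 50, size=8)
        assert kaiser_count(X) == kaiser_count(X * scales)


class TestEFA:
    def test_block_structure_recovered(self):
        """Two disjoint loading blocks are recovered by minres + varimax up
        to column order and sign."""
        rng = np.random.default_rng(4)
        L = np.zeros((10, 2))
        L[:5, 0] = 0.85
        L[5:, 1] = 0.85
        F = rng.standard_normal((4000, 2))
        X = F @ L.T + rng.standard_normal((4000, 10)) * np.sqrt(1 - 0.85**2)
        sol = efa_varimax(X, 2)
        est = np.abs(sol.loadings)
        for k in range(2):
            block = est[:, k] > 0.5
            assert block.sum() == 5
            assert block[:5].all() or block[5:].all()

    def test_varimax_criterion_nondecreasing(self, rng):
        L = rng.standard_normal((12, 3))

        def criterion(A):
            return np.sum(np.var(A**2, axis=0))

        rotated, R = varimax(L)
        assert np.allclose(R.T @ R, np.eye(3), atol=1e-10)
        assert criterion(rotated) >= criterion(L) - 1e-12

    def test_varimax_matches_reference_rotation(self, rng):
        """Cross-check against an independent varimax implementation."""
        from sklearn.decomposition import FactorAnalysis

        rng2 = np.random.default_rng(5)
        L = np.zeros((12, 2))
        L[:6, 0] = rng2.uniform(0.6, 0.9, 6)
        L[6:, 1] = rng2.uniform(0.6, 0.9, 6)
        mix = np.linalg.qr(rng2.standard_normal((2, 2)))[0]
        ours, _ = varimax(L @ mix)
        # same subspace, and same simple structure as the unmixed blocks
        assert np.abs(np.abs(ours) - L).max() < 1e-4

    def test_reference_loading_matrix_recovered(self):
        """Data generated from the published 34 x 6 varimax pattern at
        M = 2,276 is recovered with Tucker congruence > 0.95 per factor and
        mean absolute loading error < 0.1."""
        rng = np.random.default_rng(0)
        L = REFERENCE_LOADINGS
        psi = 1 - (L**2).sum(axis=1)
        F = rng.standard_normal((2276, 6))
        Z = F @ L.T + rng.standard_normal((2276, 34)) * np.sqrt(psi)
        sol = efa_varimax(Z, 6, feature_ids=FEATURE_IDS)
        Q, _ = orthogonal_procrustes(sol.loadings, L)
        A = sol.loadings @ Q
        for k in range(6):
            cong = A[:, k] @ L[:, k] / np.sqrt(
                (A[:, k] ** 2).sum() * (L[:, k] ** 2).sum()
            )
            assert cong > 0.95
        assert np.abs(A - L).mean() < 0.1
        assert kaiser_count(Z) == 6

    def test_rotation_orthogonal_and_communalities_bounded(self, prepared_blocks):
        _, Yz = prepared_blocks
        sol = efa_varimax(Yz.values, 6, feature_ids=Yz.feature_ids)
        assert np.allclose(sol.rotation.T @ sol.rotation, np.eye(6), atol=1e-10)
        assert (sol.communalities <= 1 + 1e-6).all()

    def test_principal_axis_option(self, rng):
        X = rng.standard_normal((400, 8))
        sol = efa_varimax(X, 2, method="principal_axis")
        assert sol.loadings.shape == (8, 2)

    def test_invalid_factor_count_rejected(self, rng):
        X = rng.standard_normal((50, 5))
        with pytest.raises(ValueError):
            efa_varimax(X, 5)


class TestLoadingSignificance:
    def _dataset(self, seed=0, M=1200, n_subjects=12):
        rng = np.random.default_rng(seed)
        L = np.zeros((8, 2))
        L[:4, 0] = 0.8
        L[4:7, 1] = 0.8
        # feature 7 loads on nothing
        F = rng.standard_normal((M, 2))
        X = F @ L.T + rng.standard_normal((M, 8)) * 0.5
        subjects = np.repeat(np.arange(n_subjects), M // n_subjects)
        return X, subjects, L

    def test_planted_structure_flagged(self):
        X, subjects, L = self._dataset()
        sol = efa_varimax(X, 2)
        flags = loading_significance(X, sol, subjects, n_boot=60, seed=1)
        strong = np.abs(sol.loadings) > 0.5
        assert flags[strong].all()

    def test_null_feature_rarely_flagged(self):
        X, subjects, _ = self._dataset(seed=3)
        sol = efa_varimax(X, 2)
        flags = loading_significance(X, sol, subjects, n_boot=60, alpha=0.01, seed=2)
        assert flags[7].sum() <= 1

    def test_flags_monotone_in_loading_magnitude(self):
        X, subjects, _ = self._dataset(seed=4)
        sol = efa_varimax(X, 2)
        flags = loading_significance(X, sol, subjects, n_boot=60, seed=3)
        # the largest-|loading| entry of every flagged column is flagged
        for k in range(2):
            if flags[:, k].any():
                assert flags[np.abs(sol.loadings[:, k]).argmax(), k]


class TestLVEmotionCorrelation:
    def _model(self, U):
        K = U.shape[1]
        return PLSCModel(
            U=U,
            W=np.eye(U.shape[0], K),
            singular_values=np.linspace(K, 1, K),
            covariance_explained=np.full(K, 1 / K),
        )

    def test_proportional_profile_correlates_perfectly(self, rng):
        u = rng.standard_normal(34)
        model = self._model(np.column_stack([u, rng.standard_normal(34)]))
        cents = _centroids((3.0 * u)[None, :], ("joy",))
        table = lv_emotion_correlation(model, cents)
        assert table.loc["joy", "LV1"] == pytest.approx(1.0)

    def test_orthogonal_profile_near_zero(self, rng):
        u = rng.standard_normal(34)
        u -= u.mean()
        v = rng.standard_normal(34)
        v -= v.mean()
        v -= (u @ v) / (u @ u) * u  # orthogonal and both centered
        model = self._model(u[:, None])
        table = lv_emotion_correlation(model, _centroids(v[None, :], ("joy",)))
        assert abs(table.loc["joy", "LV1"]) < 1e-10

    def test_matches_definitional_computation(self, prepared_blocks, rng):
        from emoplsc.plsc import fit_plsc

        Xz, Yz = prepared_blocks
        model = fit_plsc(Xz, Yz)
        cents = emotion_centroids(Yz)
        table = lv_emotion_correlation(model, cents, n_components=6)
        i, k = 4, 2
        prof, u = cents.values[i], model.U[:, k]
        manual = ((prof - prof.mean()) @ (u - u.mean())) / (
            np.sqrt(((prof - prof.mean()) ** 2).sum())
            * np.sqrt(((u - u.mean()) ** 2).sum())
        )
        assert table.iloc[i, k] == pytest.approx(manual, abs=1e-12)


class TestAnova:
    def test_identical_group_means(self):
        vals = np.tile(np.arange(10.0), 4)
        groups = np.repeat(["a", "b", "c", "d"], 10)
        res = anova_eta_squared(vals, groups)
        assert res.F == pytest.approx(0.0, abs=1e-12)
        assert res.eta_squared == pytest.approx(0.0, abs=1e-12)

    def test_ten_groups_df(self, prepared_blocks):
        _, Yz = prepared_blocks
        hr = Yz.values[:, list(Yz.feature_ids).index("heart_rate")]
        res = anova_eta_squared(hr, Yz.index["primary_emotion"].to_numpy())
        assert res.df_between == 9
        assert res.df_within == 2276 - 10
        assert 0 <= res.eta_squared <= 1

    def test_two_groups_equal_squared_t(self, rng):
        a = rng.standard_normal(30) + 0.5
        b = rng.standard_normal(25)
        res = anova_eta_squared(
            np.concatenate([a, b]), np.array(["a"] * 30 + ["b"] * 25)
        )
        t, p = ttest_ind(a, b)
        assert res.F == pytest.approx(t**2, rel=1e-10)
        assert res.p_value == pytest.approx(p, rel=1e-10)


class TestHistograms:
    def test_all_ones_mass_at_level_one(self):
        df = pd.DataFrame({"f": np.ones(20), "primary_emotion": ["joy"] * 20})
        counts, labels, skew = rating_histograms(df, ["f"])
        assert counts.loc["f", 1] == 20
        assert counts.loc["f"].sum() == 20
        assert labels["joy"] == 20

    def test_counts_conserve_totals(self, default_scenario):
        _, _, _, sim, _ = default_scenario
        from emoplsc.features import GRID_FEATURE_IDS

        counts, labels, _ = rating_histograms(sim.ratings, GRID_FEATURE_IDS)
        assert (counts.sum(axis=1) == 2276).all()
        assert labels.sum() == 2276

    def test_uniform_ratings_spread(self):
        rng = np.random.default_rng(8)
        M = 7000
        df = pd.DataFrame({"f": rng.integers(1, 8, M).astype(float)})
        counts, _, _ = rating_histograms(df, ["f"])
        expected = M / 7
        assert (np.abs(counts.loc["f"] - expected) < 4 * np.sqrt(expected)).all()
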