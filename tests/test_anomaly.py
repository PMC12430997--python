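import math

import numpy as np
import pandas as pd
import pytest

from paddyscan.anomaly import (GridSearchSpace, bhattacharyya, embed_2d,
                               fit_ocsvm, silhouette, standardize)
from paddyscan.features import FeatureTable


def make_table(X, names=None):
    names = names or [f"f{j}" for j in range(X.shape[1])]
    df = pd.DataFrame(X, columns=names)
    df.insert(0, "instance_id", np.arange(1, len(X) + 1))
    return FeatureTable(df=df, feature_names=names)


def brute_silhouette(X, labels):
    """O(n²) reference straight from the definition."""
    n = len(X)
    D = np.linalg.norm(X[:, None, :] - X[None, :, :], axis=-1)
    scores = np.zeros(n)
    for i in range(n):
        own = labels == labels[i]
        own[i] = False
        if own.sum() == 0:
            scores[i] = 0.0
            continue
        a = D[i][own].mean()
        b = min(D[i][labels == lab].mean()
                for lab in np.unique(labels) if lab != labels[i])
        scores[i] = (b - a) / max(a, b)
    return scores.mean()


class TestStandardize:
    def test_zscore_column(self):
        table = make_table(np.array([[1.0], [2.0], [3.0]]))
        out = standardize(table)
        np.testing.assert_allclose(out.df["f0"], [-1.2247, 0, 1.2247],
                                   atol=1e-4)
        assert out.scaling_state == "standardized"

    def test_constant_column_passthrough(self):
        X = np.column_stack([np.arange(5.0), np.full(5, 3.0)])
        out = standardize(make_table(X))
        np.testing.assert_array_equal(out.df["f1"], 3.0)
        assert out.column_stats["f1"]["constant"]

    def test_mean_zero_sd_one(self, rng):
        out = standardize(make_table(rng.random((50, 4))))
        M = out.matrix()
        np.testing.assert_allclose(M.mean(axis=0), 0, atol=1e-9)
        np.testing.assert_allclose(M.std(axis=0), 1, atol=1e-9)

    def test_too_few_rows(self):
        with pytest.raises(ValueError):
            standardize(make_table(np.array([[1.0]])))

    def test_double_standardize_rejected(self):
        out = standardize(make_table(np.random.default_rng(0).random((5, 2))))
        with pytest.raises(ValueError):
            standardize(out)


class TestFitOCSVM:
    def _planted(self, seed=0, n_in=95, n_out=5, dist=6.0, spread=0.1):
        """95 standard-Gaussian points plus a tight planted cluster of
        5 at distance 6σ (the 5 most distant points by construction)."""
        rng = np.random.default_rng(seed)
        inliers = rng.standard_normal((n_in, 2))
        angle = rng.uniform(0, 2 * np.pi)
        center = dist * np.array([np.cos(angle), np.sin(angle)])
        outliers = center + spread * rng.standard_normal((n_out, 2))
        X = np.vstack([inliers, outliers])
        truth = np.r_[np.ones(n_in), -np.ones(n_out)]
        return standardize(make_table(X)), truth, X

    def test_planted_outliers_recovered(self):
        """Seeded instance of 95 Gaussian points + a planted cluster of
        5 at 6σ: the planted points are the five most distant (the
        distance oracle) and the silhouette-selected model flags all
        five."""
        table, truth, X = self._planted(seed=0, spread=0.01)
        dist = np.linalg.norm(X - X[truth == 1].mean(axis=0), axis=1)
        assert set(np.argsort(-dist)[:5]) == set(np.where(truth == -1)[0])
        res = fit_ocsvm(table, seed=0)
        assert (res.labels[truth == -1] == -1).all()

    def test_single_combination_grid(self):
        table, _, _ = self._planted(seed=1)
        space = GridSearchSpace(kernels=("rbf",), nus=(0.1,), gammas=(0.1,))
        res = fit_ocsvm(table, space, seed=0)
        assert res.best_params["kernel"] == "rbf"
        assert res.best_params["nu"] == 0.1
        assert res.best_params["gamma"] == 0.1

    def test_replicated_dataset_consistency(self):
        """Duplicating every row leaves the per-copy labels identical."""
        table, _, _ = self._planted(seed=2)
        space = GridSearchSpace(kernels=("rbf", "linear"))
        dbl_tab = FeatureTable(
            df=pd.concat([table.df, table.df], ignore_index=True),
            feature_names=table.feature_names,
            scaling_state="standardized")
        b = fit_ocsvm(dbl_tab, space, seed=0)
        n = table.n
        np.testing.assert_array_equal(b.labels[:n], b.labels[n:])

    def test_nu_bound_every_combination(self):
        table, _, _ = self._planted(seed=3)
        res = fit_ocsvm(table, seed=0)
        n = table.n
        for entry in res.grid_log:
            if not entry["collapsed"]:
                assert entry["n_outliers"] / n <= entry["nu"] + 0.05 + 1e-12

    def test_sign_agreement(self):
        table, _, _ = self._planted(seed=4)
        res = fit_ocsvm(table, seed=0)
        assert (res.decision_values[res.labels == -1] < 0).all()
        assert (res.decision_values[res.labels == 1] >= 0).all()

    def test_linear_gamma_collapsed(self):
        table, _, _ = self._planted(seed=5)
        res = fit_ocsvm(table, seed=0)
        lin = [e for e in res.grid_log if e["kernel"] == "linear"]
        assert sum(e["collapsed"] for e in lin) == len(lin) - len({e["nu"] for e in lin})

    def test_requires_standardized(self):
        with pytest.raises(ValueError):
            fit_ocsvm(make_table(np.random.default_rng(0).random((20, 2))))


class TestBhattacharyya:
    def test_identical_distributions_zero(self, rng):
        x = rng.standard_normal(100)
        X = np.column_stack([np.r_[x, x]])
        labels = np.r_[np.ones(100), -np.ones(100)]
        d = bhattacharyya(make_table(X), labels)
        assert d["distance"].iloc[0] == pytest.approx(0, abs=1e-12)

    def test_unit_variance_mean_shift(self, rng):
        """μ shift 1 with σ₁=σ₂: closed form gives exactly 1/8."""
        a = rng.standard_normal(20000)
        X = np.column_stack([np.r_[a, a + 1.0]])
        labels = np.r_[np.ones(20000), -np.ones(20000)]
        d = bhattacharyya(make_table(X), labels)["distance"].iloc[0]
        assert d == pytest.approx(0.125, abs=0.01)

    def test_closed_form_exact_on_moments(self):
        # construct samples with exactly the target moments
        a = np.array([-1.0, 1.0])            # mean 0, sd 1
        b = np.array([-2.0, 2.0])            # mean 0, sd 2
        X = np.r_[a, b][:, None]
        labels = np.r_[1, 1, -1, -1]
        d = bhattacharyya(make_table(X), labels)["distance"].iloc[0]
        expected = 0.25 * math.log(0.25 * (0.25 + 4 + 2))
        assert d == pytest.approx(expected, abs=1e-12)

    def test_symmetric_in_class_order(self, rng):
        X = rng.random((40, 3))
        labels = np.where(rng.random(40) > 0.4, 1, -1)
        d1 = bhattacharyya(make_table(X), labels)["distance"]
        d2 = bhattacharyya(make_table(X), -labels)["distance"]
        np.testing.assert_allclose(d1, d2, atol=1e-12)

    def test_affine_invariance(self, rng):
        X = rng.random((60, 2))
        labels = np.where(rng.random(60) > 0.5, 1, -1)
        d1 = bhattacharyya(make_table(X), labels)["distance"]
        d2 = bhattacharyya(make_table(3.7 * X - 2.0), labels)["distance"]
        np.testing.assert_allclose(d1, d2, atol=1e-9)

    def test_small_class_flagged(self):
        X = np.arange(10.0)[:, None]
        labels = np.r_[-1, np.ones(9)]
        d = bhattacharyya(make_table(X), labels)
        assert d["undefined"].all()
        assert d["distance"].isna().all()


class TestSilhouette:
    def test_matches_brute_force(self, rng):
        """Implementation equals the O(n²) definitional reference."""
        for n in (6, 17, 50):
            X = rng.random((n, 3))
            labels = np.where(rng.random(n) > 0.5, 1, -1)
            if len(np.unique(labels)) < 2:
                labels[0] = -labels[0]
            table = make_table(X)
            assert silhouette(table, labels) == pytest.approx(
                brute_silhouette(X, labels), abs=1e-9)

    def test_separated_blobs_high(self, rng):
        X = np.vstack([rng.normal(0, 0.05, (20, 2)),
                       rng.normal(10, 0.05, (20, 2))])
        labels = np.r_[np.ones(20), -np.ones(20)]
        assert silhouette(make_table(X), labels) > 0.95

    def test_random_labels_near_zero(self, rng):
        X = rng.standard_normal((200, 2))
        labels = np.where(rng.random(200) > 0.5, 1, -1)
        assert abs(silhouette(make_table(X), labels)) < 0.2

    def test_unit_square_hand_values(self):
        """Two points per class on a unit square: the edge partition
        gives (√2−1)/(√2+1) and the diagonal partition 1−√2 over √2,
        both computable by hand from the three pairwise distances."""
        X = np.array([[0.0, 0], [0, 1], [1, 0], [1, 1]])
        edge = np.array([1, -1, 1, -1])     # clusters are vertical edges
        expected_edge = (math.sqrt(2) - 1) / (math.sqrt(2) + 1)
        assert silhouette(make_table(X), edge) == pytest.approx(
            expected_edge, abs=1e-12)
        diag = np.array([1, -1, -1, 1])     # clusters are the diagonals
        expected_diag = (1 - math.sqrt(2)) / math.sqrt(2)
        assert silhouette(make_table(X), diag) == pytest.approx(
            expected_diag, abs=1e-12)

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            silhouette(make_table(np.random.default_rng(0).random((5, 2))),
                       np.ones(5))


class TestEmbed2D:
    def test_shape_and_determinism(self, rng):
        table = standardize(make_table(rng.random((30, 5))))
        a = embed_2d(table, seed=3)
        b = embed_2d(table, seed=3)
        assert a.shape == (30, 2)
        assert np.isfinite(a).all()
        np.testing.assert_array_equal(a, b)

    def test_too_small_returns_none(self, rng):
        table = standardize(make_table(rng.random((4, 3))))
        with pytest.warns(UserWarning):
            assert embed_2d(table, seed=0) is None

    def test_duplicated_points_stay_close(self, rng):
        X = rng.random((15, 4))
        table = standardize(make_table(np.vstack([X, X])))
        coords = embed_2d(table, seed=0)
        # each duplicated pair must be mutual nearest neighbours
        n = 15
        D = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
        np.fill_diagonal(D, np.inf)
        for i in range(n):
            assert D[i].argmin() == i + n
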