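"""Standardization, k-means fixed points, CCC, and the choice of k."""

import numpy as np
import pandas as pd
import pytest

from t2drisk.clustering import (
    ClusterDiagnostics,
    ClusterModel,
    choose_k,
    cubic_clustering_criterion,
    fit_cluster_model,
    kmeans_partition,
    nested_kmeans,
    standardize,
)


class TestStandardize:
    def test_three_point_closed_form(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0]})
        z, params = standardize(df, ["x"])
        np.testing.assert_allclose(z[:, 0], [-1.0, 0.0, 1.0], atol=1e-12)

    def test_location_invariance(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=50)
        z1, _ = standardize(pd.DataFrame({"x": x}), ["x"])
        z2, _ = standardize(pd.DataFrame({"x": x + 17.3}), ["x"])
        np.testing.assert_allclose(z1, z2, atol=1e-10)

    def test_round_trip_and_unit_moments(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.normal(size=(200, 3)), columns=list("abc"))
        z, params = standardize(df, ["a", "b", "c"])
        assert np.abs(z.mean(axis=0)).max() < 1e-10
        assert np.abs(z.std(axis=0, ddof=1) - 1).max() < 1e-10
        np.testing.assert_allclose(params.inverse(z), df.to_numpy(), atol=1e-10)

    def test_zero_variance_column_named(self):
        df = pd.DataFrame({"ok": [1.0, 2.0], "flat": [3.0, 3.0]})
        with pytest.raises(ValueError, match="flat"):
            standardize(df, ["ok", "flat"])


class TestKMeans:
    def test_two_separated_blobs_recovered(self):
        rng = np.random.default_rng(2)
        x = np.vstack([rng.normal(-10, 0.1, (40, 2)), rng.normal(10, 0.1, (40, 2))])
        labels, centroids, r2 = kmeans_partition(x, 2, seed=0)
        assert r2 > 0.99
        assert len(set(labels[:40])) == 1 and len(set(labels[40:])) == 1
        assert labels[0] != labels[40]

    def test_k_equal_n_gives_perfect_fit(self):
        x = np.arange(6, dtype=float)[:, None] * 3
        _, _, r2 = kmeans_partition(x, 6, seed=0)
        assert r2 == pytest.approx(1.0)

    def test_too_few_distinct_points_rejected(self):
        x = np.array([[1.0], [1.0], [2.0]])
        with pytest.raises(ValueError):
            kmeans_partition(x, 3, seed=0)

    @pytest.mark.parametrize("seed", range(20))
    def test_nested_refinement_makes_r2_monotone(self, seed):
        x = np.random.default_rng(seed).standard_normal((120, 3))
        res = nested_kmeans(x, 6, seed=seed)
        r2s = [res[k][2] for k in sorted(res)]
        assert all(b >= a - 1e-12 for a, b in zip(r2s, r2s[1:]))

    def test_fixed_point_and_variance_decomposition(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal((200, 4))
        labels, centroids, r2 = kmeans_partition(x, 3, seed=1)
        # assignment stability at the fixed point
        d2 = ((x[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        np.testing.assert_array_equal(d2.argmin(axis=1), labels)
        # centroids are member means
        for c in range(3):
            np.testing.assert_allclose(centroids[c], x[labels == c].mean(axis=0),
                                       atol=1e-8)
        # SS_between + SS_within = SS_total
        ss_total = ((x - x.mean(axis=0)) ** 2).sum()
        ss_within = ((x - centroids[labels]) ** 2).sum()
        ss_between = sum((labels == c).sum() * ((centroids[c] - x.mean(axis=0)) ** 2).sum()
                         for c in range(3))
        assert ss_between + ss_within == pytest.approx(ss_total, abs=1e-8)
        assert r2 == pytest.approx(ss_between / ss_total, abs=1e-10)


class TestCCC:
    def test_strong_separation_exceeds_decision_threshold(self):
        rng = np.random.default_rng(4)
        centers = np.array([[0, 0], [12, 0], [0, 12]], dtype=float)
        x = np.vstack([c + rng.normal(0, 0.5, (60, 2)) for c in centers])
        labels, _, _ = kmeans_partition(x, 3, seed=0)
        assert cubic_clustering_criterion(x, labels) > 10

    def test_uniform_null_stays_low_on_average(self):
        rng = np.random.default_rng(5)
        vals = []
        for r in range(50):
            u = rng.random((300, 3))
            labels, _, _ = kmeans_partition(u, 3, seed=r, n_init=2)
            vals.append(cubic_clustering_criterion(u, labels))
        assert np.mean(vals) <= 2.0

    def test_deterministic_for_identical_input(self):
        rng = np.random.default_rng(6)
        x = rng.standard_normal((100, 2))
        labels = (x[:, 0] > 0).astype(int)
        assert cubic_clustering_criterion(x, labels) == \
            cubic_clustering_criterion(x.copy(), labels.copy())

    def test_single_cluster_undefined(self):
        with pytest.raises(ValueError):
            cubic_clustering_criterion(np.random.default_rng(7).random((10, 2)),
                                       np.zeros(10, dtype=int))


class TestChooseK:
    def test_stated_rule_on_worked_example(self):
        diags = [
            ClusterDiagnostics(k=2, r_squared=0.30, ccc=5.0),
            ClusterDiagnostics(k=3, r_squared=0.50, ccc=14.0),
            ClusterDiagnostics(k=4, r_squared=0.55, ccc=12.0),
        ]
        assert choose_k(diags) == 3

    def test_fallback_to_max_ccc_when_none_pass(self, caplog):
        diags = [
            ClusterDiagnostics(k=2, r_squared=0.2, ccc=4.0),
            ClusterDiagnostics(k=3, r_squared=0.3, ccc=2.0),
        ]
        assert choose_k(diags) == 2

    def test_empty_diagnostics_rejected(self):
        with pytest.raises(ValueError):
            choose_k([])


def test_cluster_model_round_trip_and_projection(cohort):
    model = fit_cluster_model(cohort, ["age", "bmi", "tg"], seed=0, k_fixed=3)
    clone = ClusterModel.from_dict(model.to_dict())
    assert clone.to_json() == model.to_json()
    # a subject sitting exactly on a destandardized centroid joins that cluster
    for c in range(3):
        point = model.params.inverse(model.centroids[c])
        df = pd.DataFrame([point], columns=["age", "bmi", "tg"])
        assert model.assign(df)[0] == c
    # every subject assigned exactly once, to its nearest centroid
    assert len(model.assignments) == len(cohort)
    reassigned = model.assign(cohort)
    np.testing.assert_array_equal(reassigned, model.assignments.to_numpy())
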