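"""Clustering algorithms, silhouette, model selection, cluster summaries."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from polytome.clustering import (
    ClusterModel,
    cluster_gmm,
    cluster_hierarchical,
    cluster_kmeans,
    select_best_clustering,
    silhouette_score,
    summarize_clusters,
)
from polytome.errors import ConfigurationError, DataError


def _blobs(centroids, n_per, scale=0.05, seed=0):
    rng = np.random.default_rng(seed)
    rows, labels = [], []
    for i, c in enumerate(centroids):
        rows.append(rng.normal(c, scale, size=(n_per, len(c))))
        labels += [i] * n_per
    M = pd.DataFrame(
        np.vstack(rows),
        index=[f"g{i:03d}" for i in range(len(labels))],
        columns=["mono", "light", "heavy"][: len(centroids[0])],
    )
    return M, np.array(labels)


class TestHierarchical:
    def test_k_equals_n_gives_singletons(self):
        M, _ = _blobs([(0, 0, 0)], 5)
        model = cluster_hierarchical(M, k=5)
        assert model.assignments.nunique() == 5

    def test_separated_blobs_perfect_split(self):
        M, truth = _blobs([(0, 0, 0), (10, 10, 10)], 20, scale=1.0)
        model = cluster_hierarchical(M, k=2)
        assert adjusted_rand_score(truth, model.assignments) == pytest.approx(1.0)

    def test_duplicated_rows_co_cluster(self):
        M, _ = _blobs([(0, 0, 0), (5, 5, 5)], 10, scale=0.3)
        M.iloc[1] = M.iloc[0]
        model = cluster_hierarchical(M, k=2)
        assert model.assignments.iloc[0] == model.assignments.iloc[1]

    def test_k_larger_than_n_rejected(self):
        M, _ = _blobs([(0, 0, 0)], 3)
        with pytest.raises(ConfigurationError):
            cluster_hierarchical(M, k=4)


class TestKmeans:
    def test_k1_centroid_is_mean(self):
        M, _ = _blobs([(1, 2, 3)], 30, scale=0.5)
        model = cluster_kmeans(M, k=1)
        assert np.allclose(model.params["centroids"][0], M.mean(axis=0), atol=1e-9)
        total_ss = ((M - M.mean(axis=0)) ** 2).to_numpy().sum()
        assert model.params["inertia"] == pytest.approx(total_ss)

    def test_one_dimensional_partition_matches_exhaustive_search(self):
        pts = np.array([0.0, 0.1, 10.0, 10.1])
        M = pd.DataFrame({"mono": pts, "light": 0.0, "heavy": 0.0},
                         index=list("abcd"))
        model = cluster_kmeans(M, k=2, seed=0)
        # brute force: best 2-partition by within-cluster SS
        from itertools import combinations

        best, best_wss = None, np.inf
        for r in range(1, 4):
            for left in combinations(range(4), r):
                right = tuple(i for i in range(4) if i not in left)
                wss = sum(
                    ((pts[list(grp)] - pts[list(grp)].mean()) ** 2).sum()
                    for grp in (left, right)
                )
                if wss < best_wss:
                    best, best_wss = (set(left), set(right)), wss
        found = {
            frozenset(np.flatnonzero(model.assignments.to_numpy() == lab))
            for lab in model.assignments.unique()
        }
        assert found == {frozenset(best[0]), frozenset(best[1])}


class TestGmm:
    def test_single_gaussian_selects_k1(self):
        picks = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            M = pd.DataFrame(rng.normal(0, 1, (200, 2)), columns=["light", "heavy"])
            model = cluster_gmm(
                M, k_range=range(1, 5), cov_families=("spherical",), seed=seed, n_init=2
            )
            picks.append(model.k)
        assert np.mean(np.array(picks) == 1) >= 0.95

    def test_six_planted_centroids_recovered(self):
        centroids = [(-1, 1, 1), (0, 1, 1), (1, 1, 0), (0, -1, 0), (0, 0, -1), (-1, 0, 1)]
        M, truth = _blobs(centroids, 40, scale=0.1, seed=3)  # 10 sigma separation
        model = cluster_gmm(M, seed=3)
        assert model.k == 6
        assert adjusted_rand_score(truth, model.assignments) >= 0.9

    def test_em_monotone_loglik(self):
        """EM's lower bound is non-decreasing across iterations."""
        from sklearn.mixture import GaussianMixture

        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(0, 1, (50, 2)), rng.normal(4, 1, (50, 2))])
        gm = GaussianMixture(
            n_components=2, covariance_type="full", max_iter=1, warm_start=True,
            random_state=0, tol=0, reg_covar=1e-6, init_params="random",
        )
        lls = []
        import warnings

        for _ in range(25):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                gm.fit(X)
            lls.append(gm.lower_bound_)
        assert (np.diff(lls) >= -1e-8).all()

    def test_degenerate_singleton_solutions_rejected(self):
        M, _ = _blobs([(0, 0, 0), (3, 3, 3)], 30, scale=0.2, seed=1)
        M.loc["outlier"] = [10.0, -10.0, 10.0]
        model = cluster_gmm(M, k_range=range(2, 5), seed=1)
        assert model.assignments.value_counts().min() >= 2


class TestSilhouette:
    def test_two_tight_pairs(self):
        M = pd.DataFrame(
            [[0, 0, 0], [0.01, 0, 0], [10, 10, 10], [10.01, 10, 10]],
            index=list("abcd"), columns=["mono", "light", "heavy"], dtype=float,
        )
        assign = pd.Series([1, 1, 2, 2], index=list("abcd"))
        _, mean = silhouette_score(M, assign)
        assert mean > 0.95

    def test_identical_points_give_zero(self):
        M = pd.DataFrame(np.zeros((4, 2)), index=list("abcd"), columns=["x", "y"])
        assign = pd.Series([1, 1, 2, 2], index=list("abcd"))
        _, mean = silhouette_score(M, assign)
        assert mean == pytest.approx(0.0)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(4)
        M = pd.DataFrame(rng.normal(0, 1, (10, 3)), index=[f"g{i}" for i in range(10)],
                         columns=["mono", "light", "heavy"])
        assign = pd.Series(rng.integers(0, 3, 10), index=M.index)
        while assign.nunique() < 3:
            assign = pd.Series(rng.integers(0, 3, 10), index=M.index)
        s, mean = silhouette_score(M, assign)
        X = M.to_numpy()
        D = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
        expected = []
        for i in range(10):
            own = assign.iloc[i]
            same = [j for j in range(10) if j != i and assign.iloc[j] == own]
            if not same:
                expected.append(0.0)
                continue
            a = D[i, same].mean()
            b = min(
                D[i, [j for j in range(10) if assign.iloc[j] == other]].mean()
                for other in assign.unique()
                if other != own
            )
            expected.append((b - a) / max(a, b))
        assert np.allclose(s.to_numpy(), expected)
        assert mean == pytest.approx(np.mean(expected))

    def test_single_cluster_rejected(self):
        M = pd.DataFrame(np.ones((4, 2)), index=list("abcd"), columns=["x", "y"])
        with pytest.raises(DataError):
            silhouette_score(M, pd.Series([1, 1, 1, 1], index=list("abcd")))


class TestSelection:
    @staticmethod
    def _model(method, sil):
        return ClusterModel(method=method, k=2,
                            assignments=pd.Series([1, 2]), silhouette=sil)

    def test_single_model_returned(self):
        m = self._model("kmeans", 0.4)
        assert select_best_clustering([m]) is m

    def test_argmax_silhouette(self):
        models = [self._model("hierarchical-ward", 0.2),
                  self._model("kmeans", 0.5),
                  self._model("gmm", 0.4)]
        assert select_best_clustering(models).method == "kmeans"

    def test_tie_prefers_model_based(self):
        models = [self._model("kmeans", 0.5), self._model("gmm", 0.5),
                  self._model("hierarchical-ward", 0.5)]
        assert select_best_clustering(models).method == "gmm"


class TestSummaries:
    def test_patterns(self):
        M, truth = _blobs([(-1, 1, 1), (0, -1, 0), (0, 0, 0)], 20, scale=0.02, seed=5)
        model = cluster_kmeans(M, k=3, seed=0)
        out = summarize_clusters(model, M)
        patterns = set(out["summary"]["pattern"])
        assert "mono->polysome shift" in patterns
        assert "flat" in patterns
        assert any("light↓" in p for p in patterns)
        # heatmap ordering: cluster-major
        order_clusters = model.assignments.loc[out["heatmap_order"]].to_numpy()
        assert (np.diff(order_clusters) >= 0).all()

    def test_canonical_numbering_puts_shift_cluster_first(self):
        M, _ = _blobs([(0, 0, -1), (-1, 1, 1)], 15, scale=0.05, seed=6)
        model = cluster_kmeans(M, k=2, seed=0)
        out = summarize_clusters(model, M)
        assert out["summary"].loc[1, "pattern"] == "mono->polysome shift"


def test_permutation_equivariance():
    centroids = [(-1, 1, 1), (0, -1, 0), (1, 1, 0)]
    M, _ = _blobs(centroids, 25, scale=0.05, seed=8)
    perm = np.random.default_rng(0).permutation(len(M))
    M_shuffled = M.iloc[perm]
    for fn in (
        lambda m: cluster_hierarchical(m, k=3),
        lambda m: cluster_kmeans(m, k=3, seed=0),
        lambda m: cluster_gmm(m, k_range=(3,), seed=0),
    ):
        a = fn(M).assignments
        b = fn(M_shuffled).assignments
        # canonical renumbering makes labels directly comparable
        assert (a.loc[M.index] == b.loc[M.index]).all()
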