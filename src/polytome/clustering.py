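"""Clustering of the DTG log-ratio matrix and model selection by silhouette.

Three algorithms are run on the genes x {mono, light, heavy} log-ratio
matrix: Ward hierarchical clustering (Ward.D2 convention), k-means, and a
Gaussian mixture model fitted by EM over a grid of component counts and
covariance families with the number of components chosen by minimum BIC
(the model-based route).  Each fitted model carries its mean silhouette;
the model with the best silhouette is selected, ties broken in favour of
the model-based fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_samples
from sklearn.mixture import GaussianMixture

from .errors import ConfigurationError, DataError

__all__ = [
    "ClusterModel",
    "cluster_hierarchical",
    "cluster_kmeans",
    "cluster_gmm",
    "silhouette_score",
    "select_best_clustering",
    "summarize_clusters",
    "cluster_log_ratio_matrix",
]

#: tie-break preference when silhouettes are equal (higher wins)
_METHOD_PREFERENCE = {"hierarchical-ward": 0, "kmeans": 1, "gmm": 2}

DEFAULT_K_RANGE = tuple(range(2, 10))
DEFAULT_COV_FAMILIES = ("spherical", "diag", "full", "tied")


@dataclass
class ClusterModel:
    """A fitted clustering of the log-ratio matrix."""

    method: str
    k: int
    assignments: pd.Series  # gene -> cluster label (1-based, canonical order)
    silhouette: float
    params: dict = field(default_factory=dict)
    bic: float | None = None
    seed: int | None = None


def _canonical_renumber(assignments: pd.Series, M: pd.DataFrame) -> pd.Series:
    """Renumber clusters deterministically by behaviour pattern.

    Clusters are ordered by decreasing translation-shift strength
    (mean(light, heavy) - mono of the cluster centroid), then by heavy and
    light means, so the mono->polysome shift cluster is always cluster 1
    and numbering is stable across seeds and algorithms.
    """
    labels = assignments.unique()
    centroids = {
        lab: M.loc[assignments.index[assignments == lab]].mean(axis=0).to_numpy()
        for lab in labels
    }

    def key(lab):
        c = centroids[lab]
        # translation-shift strength: polysome-side mean minus the first
        # (monosome) coordinate, then later coordinates descending
        shift = c[1:].mean() - c[0] if len(c) > 1 else c[0]
        return (-shift, *(-c[::-1]), str(lab))

    order = sorted(labels, key=key)
    mapping = {old: new + 1 for new, old in enumerate(order)}
    return assignments.map(mapping).rename("cluster")


def silhouette_score(M: pd.DataFrame, assignments: pd.Series) -> tuple[pd.Series, float]:
    """Per-gene silhouette s(i) = (b - a)/max(a, b) on Euclidean distances.

    Members of singleton clusters get s = 0.  Returns (per-gene values,
    mean).  Raises if fewer than two clusters are present.
    """
    labels = assignments.loc[M.index].to_numpy()
    n_labels = len(np.unique(labels))
    if n_labels < 2:
        raise DataError("silhouette needs >= 2 clusters")
    if n_labels == len(M):  # all singletons: s = 0 by convention
        vals = np.zeros(len(M))
        return pd.Series(vals, index=M.index, name="silhouette"), 0.0
    vals = silhouette_samples(M.to_numpy(dtype=float), labels, metric="euclidean")
    s = pd.Series(vals, index=M.index, name="silhouette")
    return s, float(vals.mean())


def _finish(method, k, raw_labels, M, params=None, bic=None, seed=None) -> ClusterModel:
    assignments = _canonical_renumber(pd.Series(raw_labels, index=M.index), M)
    if assignments.nunique() >= 2:
        _, sil = silhouette_score(M, assignments)
    else:
        sil = float("nan")
    return ClusterModel(
        method=method,
        k=int(k),
        assignments=assignments,
        silhouette=sil,
        params=params or {},
        bic=bic,
        seed=seed,
    )


def cluster_hierarchical(M: pd.DataFrame, k: int) -> ClusterModel:
    """Ward linkage (squared-distance update) on Euclidean distances, cut at k."""
    if k > len(M):
        raise ConfigurationError(f"k={k} exceeds {len(M)} genes")
    Z = hierarchy.linkage(M.to_numpy(dtype=float), method="ward", metric="euclidean")
    labels = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    return _finish("hierarchical-ward", k, labels, M, params={"linkage": Z})


def cluster_kmeans(M: pd.DataFrame, k: int, n_init: int = 10, seed: int = 0) -> ClusterModel:
    """Lloyd's k-means with k-means++ seeding, best of n_init restarts."""
    if k < 1:
        raise ConfigurationError("k must be >= 1")
    if k > len(M):
        raise ConfigurationError(f"k={k} exceeds {len(M)} genes")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(M.to_numpy(dtype=float))
    params = {"centroids": km.cluster_centers_, "inertia": float(km.inertia_)}
    return _finish("kmeans", k, km.labels_, M, params=params, seed=seed)


def cluster_gmm(
    M: pd.DataFrame,
    k_range=DEFAULT_K_RANGE,
    cov_families=DEFAULT_COV_FAMILIES,
    seed: int = 0,
    n_init: int = 10,
    reg_covar: float = 1e-6,
    tol: float = 1e-6,
    max_iter: int = 500,
    min_component_size: int = 2,
) -> ClusterModel:
    """Gaussian-mixture clustering over a (K, covariance-family) grid.

    Every combination is fitted by EM (``n_init`` restarts); the model with
    the minimum BIC = -2 log L + p log n wins; genes are hard-assigned to
    the component of maximum posterior responsibility.

    Solutions in which a component collapses onto fewer than
    ``min_component_size`` points are spurious likelihood maxima (the
    component variance shrinks to the regularisation ridge, inflating the
    likelihood without bound) and are excluded from the BIC comparison
    unless no other solution exists.
    """
    k_range = [k for k in k_range if k <= len(M)]
    if not k_range:
        raise ConfigurationError("empty K range (fewer genes than every K)")
    X = M.to_numpy(dtype=float)
    best = best_degenerate = None
    for k in k_range:
        for family in cov_families:
            gm = GaussianMixture(
                n_components=k,
                covariance_type=family,
                random_state=seed,
                n_init=n_init,
                reg_covar=reg_covar,
                tol=tol,
                max_iter=max_iter,
            ).fit(X)
            bic = gm.bic(X)
            smallest = np.bincount(gm.predict(X), minlength=k).min()
            if smallest < min_component_size:
                if best_degenerate is None or bic < best_degenerate[0]:
                    best_degenerate = (bic, k, family, gm)
                continue
            if best is None or bic < best[0]:
                best = (bic, k, family, gm)
    if best is None:
        best = best_degenerate
    bic, k, family, gm = best
    params = {
        "cov_family": family,
        "weights": gm.weights_,
        "means": gm.means_,
        "covariances": gm.covariances_,
        "converged": bool(gm.converged_),
    }
    return _finish("gmm", k, gm.predict(X), M, params=params, bic=float(bic), seed=seed)


def select_best_clustering(models: list[ClusterModel]) -> ClusterModel:
    """Highest mean silhouette wins; exact ties prefer gmm > kmeans > Ward."""
    if not models:
        raise ConfigurationError("no models to select from")
    return max(
        models,
        key=lambda m: (
            -np.inf if np.isnan(m.silhouette) else m.silhouette,
            _METHOD_PREFERENCE.get(m.method, -1),
        ),
    )


def summarize_clusters(
    model: ClusterModel, M: pd.DataFrame, dead_zone: float = 0.05
) -> dict[str, pd.DataFrame]:
    """Per-cluster mean log-ratio vector, qualitative pattern, heatmap order.

    A fraction is called up/down when the cluster mean exceeds the
    +-``dead_zone`` band.  Genes are ordered by cluster, then by the
    heavy-fraction ratio within each cluster.
    """
    assign = model.assignments.loc[M.index]
    rows = []
    for lab in sorted(assign.unique()):
        sub = M.loc[assign.index[assign == lab]]
        mean = sub.mean(axis=0)
        signs = {
            f: ("up" if mean[f] > dead_zone else "down" if mean[f] < -dead_zone else "flat")
            for f in M.columns
        }
        if all(v == "flat" for v in signs.values()):
            pattern = "flat"
        elif signs.get("mono") == "down" and signs.get("light") == "up" and signs.get("heavy") == "up":
            pattern = "mono->polysome shift"
        else:
            arrows = {"up": "↑", "down": "↓", "flat": "→"}
            pattern = " ".join(f"{f}{arrows[signs[f]]}" for f in M.columns)
        rows.append(
            {
                "cluster": lab,
                "n_genes": len(sub),
                **{f"mean_{f}": float(mean[f]) for f in M.columns},
                "pattern": pattern,
            }
        )
    summary = pd.DataFrame(rows).set_index("cluster")
    ordering = (
        pd.DataFrame({"cluster": assign, "heavy": M.get("heavy", M.iloc[:, -1])})
        .sort_values(["cluster", "heavy"], ascending=[True, False])
        .index
    )
    return {"summary": summary, "heatmap_order": list(ordering)}


def cluster_log_ratio_matrix(
    M: pd.DataFrame,
    k_range=DEFAULT_K_RANGE,
    cov_families=DEFAULT_COV_FAMILIES,
    seed: int = 0,
) -> dict:
    """The integrative clustering protocol: GMM picks K by BIC, then k-means
    and Ward are fitted at that K, and the three models are compared by mean
    silhouette.  Returns all models plus the selected one."""
    gmm = cluster_gmm(M, k_range=k_range, cov_families=cov_families, seed=seed)
    km = cluster_kmeans(M, k=gmm.k, seed=seed)
    ward = cluster_hierarchical(M, k=gmm.k)
    models = [ward, km, gmm]
    return {"models": models, "selected": select_best_clustering(models)}
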