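"""Subtype clustering of risk loci with iterative silhouette outlier removal.

Loci are clustered on their 4-trait association z-scores (sleep efficiency,
sleep duration, number of sleep bouts, insomnia; all oriented to the
sleepiness-increasing allele) using agglomerative hierarchical clustering on
pairwise Euclidean distances.  Clustering is then iterated: loci with a
negative silhouette coefficient - objects closer on average to the other
cluster than to their own - are removed and the remaining loci reclustered,
until every retained locus has a nonnegative silhouette.  The two final
clusters are labelled by their centroid's sign pattern: a centroid matching
(+efficiency, +duration, -bouts, -insomnia) on at least 3 of 4 traits is the
sleep-propensity subtype, its counterpart the sleep-fragmentation subtype.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from scipy.spatial.distance import pdist, squareform
from sklearn.base import BaseEstimator, ClusterMixin

from .simulate import PROPENSITY_TEMPLATE

__all__ = [
    "pairwise_distance",
    "hierarchical_cluster",
    "silhouette",
    "label_clusters",
    "SubtypeClusterer",
    "iterative_outlier_removal",
]


def pairwise_distance(X) -> np.ndarray:
    """Pairwise Euclidean distance matrix between locus z-score rows."""
    A = np.asarray(X, dtype=float)
    if A.ndim != 2 or A.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 rows")
    if not np.all(np.isfinite(A)):
        raise ValueError("non-finite z-scores")
    return squareform(pdist(A, metric="euclidean"))


def hierarchical_cluster(D: np.ndarray, k: int = 2,
                         method: str = "complete") -> np.ndarray:
    """Cut an agglomerative tree on a precomputed distance matrix into k.

    Returns 0-based labels.  Exactly equal merge distances are broken by
    scipy's deterministic ordering (lowest condensed index first).
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if k > n:
        raise ValueError("k cannot exceed the number of points")
    Z = scipy_linkage(squareform(D, checks=False), method=method)
    return fcluster(Z, t=k, criterion="maxclust") - 1


def silhouette(D: np.ndarray, labels) -> tuple[np.ndarray, float]:
    """Per-point silhouette coefficients and their average.

    s_i = (b_i - a_i) / max(a_i, b_i), where a_i is the mean distance to the
    other members of i's cluster and b_i the smallest mean distance to any
    other cluster.  Members of singleton clusters score 0 by convention.
    """
    D = np.asarray(D, dtype=float)
    labels = np.asarray(labels)
    clusters = np.unique(labels)
    if clusters.size < 2:
        raise ValueError("silhouette requires at least 2 clusters")
    n = D.shape[0]
    s = np.zeros(n)
    for i in range(n):
        own = labels == labels[i]
        if own.sum() == 1:
            continue  # singleton: s_i = 0
        a = D[i, own].sum() / (own.sum() - 1)
        b = min(D[i, labels == c].mean() for c in clusters if c != labels[i])
        s[i] = (b - a) / max(a, b)
    return s, float(s.mean())


def label_clusters(X, labels) -> tuple[dict, dict]:
    """Name the two clusters sleep ``propensity`` vs ``fragmentation``.

    Each cluster centroid's signs are scored against the propensity template
    (+, +, -, -) over (efficiency, duration, bouts, insomnia).  A cluster
    matching at least 3 of 4 signs is ``propensity`` and the other
    ``fragmentation``; if both or neither reach 3/4 the cluster with the
    higher total agreement wins, with a tie flagged.  Returns
    ``(mapping, flags)``.
    """
    A = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    clusters = list(np.unique(labels))
    if len(clusters) != 2:
        raise ValueError("expected exactly 2 clusters")
    flags: dict = {"tie": False, "degenerate": []}
    agree = {}
    for c in clusters:
        centroid = A[labels == c].mean(axis=0)
        if np.all(centroid == 0):
            flags["degenerate"].append(c)
        agree[c] = int(np.sum(np.sign(centroid) == np.sign(PROPENSITY_TEMPLATE)))
    c0, c1 = clusters
    if agree[c0] == agree[c1]:
        flags["tie"] = True
        prop = c0
    else:
        prop = c0 if agree[c0] > agree[c1] else c1
    frag = c1 if prop == c0 else c0
    return {prop: "propensity", frag: "fragmentation"}, flags


class SubtypeClusterer(BaseEstimator, ClusterMixin):
    """Hierarchical subtype clustering with iterative outlier removal.

    Parameters
    ----------
    k : int, default 2
        Number of clusters cut from the tree (the two-subtype model).
    linkage : {'complete', 'average', 'single', 'ward'}, default 'complete'
    max_iter : int, default 10
        Cap on remove-and-recluster iterations.

    Attributes
    ----------
    labels_ : int ndarray over input loci; 0 = propensity, 1 = fragmentation,
        -1 = removed as an outlier.
    subtype_labels_ : Series of 'propensity'/'fragmentation'/'removed'.
    retained_ / removed_ : index of loci kept / dropped.
    history_ : per-iteration audit trail (retained loci, raw cluster labels,
        per-locus silhouettes, average silhouette, removed loci).
    n_iter_ : iterations run; converged_ : all final silhouettes nonnegative.
    silhouette_avg_ / initial_silhouette_avg_ : final and iteration-1 average.
    """

    def __init__(self, k: int = 2, linkage: str = "complete",
                 max_iter: int = 10):
        self.k = k
        self.linkage = linkage
        self.max_iter = max_iter

    def fit(self, X: pd.DataFrame, y=None):
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X, dtype=float))
        if X.index.has_duplicates:
            raise ValueError("duplicate locus IDs")
        if len(X) < 4:
            raise ValueError("need at least 4 loci")
        retained = X.index
        self.history_ = []
        self.converged_ = False
        for it in range(1, self.max_iter + 1):
            if len(retained) < self.k + 1:
                break  # too few loci left: abort with partial result
            D = pairwise_distance(X.loc[retained])
            raw = hierarchical_cluster(D, self.k, self.linkage)
            sil, avg = silhouette(D, raw)
            negative = retained[sil < 0]
            self.history_.append({
                "iteration": it,
                "retained": list(retained),
                "cluster_labels": raw.copy(),
                "silhouettes": pd.Series(sil, index=retained),
                "average_silhouette": avg,
                "removed": list(negative),
            })
            if len(negative) == 0:
                self.converged_ = True
                break
            retained = retained.difference(negative, sort=False)

        last = self.history_[-1]
        retained = pd.Index(last["retained"])
        raw = last["cluster_labels"]
        self.n_iter_ = last["iteration"]
        self.initial_silhouette_avg_ = self.history_[0]["average_silhouette"]
        self.silhouette_avg_ = last["average_silhouette"]
        self.silhouette_values_ = last["silhouettes"]
        self.retained_ = retained
        self.removed_ = X.index.difference(retained, sort=False)

        mapping, self.label_flags_ = (
            label_clusters(X.loc[retained].to_numpy(), raw)
            if self.k == 2 else ({c: f"cluster{c}" for c in np.unique(raw)}, {}))
        named = pd.Series([mapping[c] for c in raw], index=retained)
        self.subtype_labels_ = named.reindex(X.index, fill_value="removed")
        if self.k == 2:
            code = {"propensity": 0, "fragmentation": 1, "removed": -1}
            self.labels_ = self.subtype_labels_.map(code).to_numpy()
        else:
            raw_series = pd.Series(raw, index=retained)
            self.labels_ = raw_series.reindex(X.index, fill_value=-1) \
                .to_numpy(dtype=int)
        self.cluster_sizes_ = named.value_counts().to_dict()
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


def iterative_outlier_removal(X: pd.DataFrame, k: int = 2,
                              linkage: str = "complete",
                              max_iter: int = 10) -> SubtypeClusterer:
    """Run the remove-and-recluster loop; returns the fitted clusterer."""
    return SubtypeClusterer(k=k, linkage=linkage, max_iter=max_iter).fit(X)
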