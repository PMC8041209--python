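"""Multi-start K-means stratification of ZIP codes and patients.

Three stratifications are used downstream: ZIP codes into two socioeconomic
clusters (income + education), ZIP codes into two racial clusters (white % +
African American %), and patients into four clinical clusters on their
per-patient mean (glucose, cholesterol). Because Lloyd's algorithm depends
on its initialisation, each clustering is run from many random starts and
the *most frequent* partition (up to label permutation) is returned, with the
between-SS / total-SS ratio as the quality summary.

Features are standardized to zero mean and unit variance before clustering;
reported centroids are on the original feature scale.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

__all__ = [
    "ClusterAssignment",
    "kmeans_cluster",
    "label_clusters",
    "between_ss_ratio",
    "cluster_zip_socioeconomic",
    "cluster_zip_racial",
    "cluster_patients_clinical",
]


@dataclass
class ClusterAssignment:
    """A labelled partition with quality and stability summaries.

    ``labels`` are 1-based cluster indices; ``centroids`` are per-cluster
    mean vectors on the original feature scale; ``start_agreement`` is the
    mean pairwise fraction of points assigned identically (after
    canonicalisation) across the random starts.
    """

    unit_ids: np.ndarray
    labels: np.ndarray
    k: int
    between_ss_ratio: float
    centroids: pd.DataFrame
    n_starts: int = 1
    start_agreement: float = 1.0
    partition_frequency: float = 1.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"unit_id": self.unit_ids, "cluster": self.labels})


def _zscore(X: np.ndarray) -> np.ndarray:
    sd = X.std(axis=0)
    if np.all(sd == 0):
        raise ValueError("all rows identical: clustering is degenerate")
    sd = np.where(sd == 0, 1.0, sd)
    return (X - X.mean(axis=0)) / sd


def _canonicalize(labels: np.ndarray, Z: np.ndarray, k: int) -> np.ndarray:
    """Relabel clusters 1..k by ascending centroid on the first standardized
    feature (ties broken by the following features), so that partitions can
    be compared across starts irrespective of arbitrary label order."""
    cents = np.vstack([Z[labels == j].mean(axis=0) for j in range(k)])
    order = np.lexsort(tuple(cents[:, c] for c in range(Z.shape[1] - 1, -1, -1)))
    remap = np.empty(k, int)
    remap[order] = np.arange(1, k + 1)
    return remap[labels]


def between_ss_ratio(matrix, labels) -> float:
    """1 - within-SS / total-SS, with total-SS about the grand mean.

    Defined as 0 when the total sum of squares is zero (all points
    identical) or when a single cluster is present.
    """
    X = np.asarray(matrix, float)
    labels = np.asarray(labels)
    total = float(((X - X.mean(axis=0)) ** 2).sum())
    uniq = np.unique(labels)
    if total == 0.0 or len(uniq) < 2:
        if total > 0.0 and len(uniq) < 2:
            return 0.0
        return 0.0
    within = 0.0
    for j in uniq:
        sub = X[labels == j]
        within += float(((sub - sub.mean(axis=0)) ** 2).sum())
    return 1.0 - within / total


def kmeans_cluster(matrix, k: int, n_starts: int = 25, seed: int = 0,
                   unit_ids=None, feature_names=None) -> ClusterAssignment:
    """K-means with the multi-start, most-frequent-partition protocol.

    Runs Lloyd's algorithm from ``n_starts`` random initialisations on
    standardized features, canonicalises each resulting partition up to
    label permutation, and returns the partition seen most often (ties
    broken by lowest within-SS).
    """
    X = np.asarray(matrix, float)
    if isinstance(matrix, pd.DataFrame):
        feature_names = list(matrix.columns)
        if unit_ids is None:
            unit_ids = matrix.index.to_numpy()
    n = X.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"k={k} exceeds the {n} units")
    if unit_ids is None:
        unit_ids = np.arange(n)
    if feature_names is None:
        feature_names = [f"f{j}" for j in range(X.shape[1])]

    if k == 1:
        centroids = pd.DataFrame(X.mean(axis=0, keepdims=True),
                                 index=[1], columns=feature_names)
        return ClusterAssignment(np.asarray(unit_ids), np.ones(n, int), 1,
                                 0.0, centroids, n_starts)

    Z = _zscore(X)
    rng = np.random.default_rng(seed)
    runs = []
    for _ in range(n_starts):
        km = KMeans(n_clusters=k, n_init=1, init="random",
                    random_state=int(rng.integers(2**31 - 1)),
                    algorithm="lloyd").fit(Z)
        if len(np.unique(km.labels_)) < k:
            raise ValueError("empty cluster produced: data degenerate for "
                             f"k={k}")
        labels = _canonicalize(km.labels_, Z, k)
        runs.append((tuple(labels), float(km.inertia_)))

    freq = Counter(key for key, _ in runs)
    best_count = max(freq.values())
    candidates = [key for key, c in freq.items() if c == best_count]
    inertia = {key: min(i for kk, i in runs if kk == key) for key in candidates}
    winner = min(candidates, key=lambda key: (inertia[key], key))
    labels = np.asarray(winner, int)

    # pairwise agreement of canonical labels across starts
    label_mat = np.asarray([r[0] for r in runs])
    agree = []
    for a in range(len(runs)):
        for b in range(a + 1, len(runs)):
            agree.append(float(np.mean(label_mat[a] == label_mat[b])))
    start_agreement = float(np.mean(agree)) if agree else 1.0

    centroids = pd.DataFrame(
        np.vstack([X[labels == j].mean(axis=0) for j in range(1, k + 1)]),
        index=range(1, k + 1), columns=feature_names)
    return ClusterAssignment(
        unit_ids=np.asarray(unit_ids), labels=labels, k=k,
        between_ss_ratio=between_ss_ratio(Z, labels), centroids=centroids,
        n_starts=n_starts, start_agreement=start_agreement,
        partition_frequency=best_count / n_starts)


def label_clusters(assignment: ClusterAssignment, ordering_feature: str,
                   direction: str = "desc") -> ClusterAssignment:
    """Reorder cluster indices by a centroid feature.

    ``direction='desc'`` makes cluster 1 the one with the *highest* centroid
    value (the convention used for income and white %); ``'asc'`` makes
    cluster 1 the lowest (mildest clinical severity first). Exact centroid
    ties are resolved by the next centroid feature.
    """
    cents = assignment.centroids
    if ordering_feature not in cents.columns:
        raise KeyError(f"{ordering_feature!r} not among centroid features "
                       f"{list(cents.columns)}")
    others = [c for c in cents.columns if c != ordering_feature]
    key = cents[[ordering_feature] + others]
    ascending = direction == "asc"
    order = key.sort_values([ordering_feature] + others,
                            ascending=ascending).index.to_numpy()
    remap = {old: new for new, old in enumerate(order, start=1)}
    new_labels = np.asarray([remap[l] for l in assignment.labels], int)
    new_cents = cents.loc[order].set_axis(range(1, assignment.k + 1))
    return ClusterAssignment(
        unit_ids=assignment.unit_ids, labels=new_labels, k=assignment.k,
        between_ss_ratio=assignment.between_ss_ratio, centroids=new_cents,
        n_starts=assignment.n_starts,
        start_agreement=assignment.start_agreement,
        partition_frequency=assignment.partition_frequency)


# ---------------------------------------------------------------------------
# the three study stratifications


def cluster_zip_socioeconomic(zip_table: pd.DataFrame, k: int = 2,
                              n_starts: int = 25, seed: int = 0
                              ) -> ClusterAssignment:
    """ZIP codes on (income, high-school %, college %); cluster 1 = higher
    income."""
    feats = zip_table.set_index("zip_id")[
        ["income", "pct_highschool", "pct_college"]]
    return label_clusters(
        kmeans_cluster(feats, k, n_starts, seed), "income", "desc")


def cluster_zip_racial(zip_table: pd.DataFrame, k: int = 2,
                       n_starts: int = 25, seed: int = 0) -> ClusterAssignment:
    """ZIP codes on (white %, African American %); cluster 1 = higher
    white %."""
    feats = zip_table.set_index("zip_id")[["pct_white", "pct_black"]]
    return label_clusters(
        kmeans_cluster(feats, k, n_starts, seed), "pct_white", "desc")


def cluster_patients_clinical(panel: pd.DataFrame, k: int = 4,
                              n_starts: int = 25, seed: int = 0,
                              per_patient: bool = True) -> ClusterAssignment:
    """Patients on (glucose, cholesterol); cluster 1 = mildest (lowest
    glucose).

    ``per_patient=True`` clusters per-patient means (the default);
    ``False`` clusters patient-period observations directly.
    """
    if per_patient:
        feats = panel.groupby("patient_id")[["glucose", "cholesterol"]].mean()
    else:
        feats = panel.set_index(
            panel["patient_id"].astype(str) + ":" + panel["period"].astype(str)
        )[["glucose", "cholesterol"]]
    return label_clusters(
        kmeans_cluster(feats, k, n_starts, seed), "glucose", "asc")
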