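"""Mixed-type clustering pathways: Gower distance, FAMD embedding, Ward, K-means.

The Gower dissimilarity between patients x and y over m features is

    d_G(x, y) = sum_j w_j f_j(x_j, y_j) / sum_j w_j

with f_j = |x_j - y_j| / r_j for interval features (r_j = cohort range) and
f_j = 1[x_j != y_j] for categorical features.  With unit weights d_G lies in
[0, 1] and is 0 exactly for identical records.  Binary comorbidity flags are
treated as categorical (match/mismatch), so Gower is computed on the
aggregated but *unscaled* features: the per-feature range normalisation makes
prior z-scoring redundant.

The FAMD embedding acts as PCA on quantitative columns and as MCA on
qualitative ones: continuous columns are z-scored; each categorical level
indicator is divided by the square root of its level proportion and centered;
the combined matrix is decomposed by truncated SVD and row principal
coordinates are returned.  Component signs follow the
largest-loading-positive convention so embeddings are reproducible.

Ward clustering on the Gower pathway applies the Lance-Williams Ward update
to the precomputed distance matrix.  Ward's objective is only exact for
Euclidean input, so this is a pragmatic pairing (documented caveat); the FAMD
pathway clusters Euclidean distances in embedding space, where the objective
is exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .errors import ClusteringError
from .preprocessing import FeatureMatrix

METHODS = ("gower_ward", "famd_ward", "famd_kmeans")


@dataclass
class GowerConfig:
    """Feature weights and kinds for the Gower computation.

    ``feature_kinds`` maps feature name -> "interval" | "categorical";
    weights default to 1.  Ranges are computed from the data unless supplied.
    """

    feature_kinds: dict
    feature_weights: dict = field(default_factory=dict)
    ranges: dict = field(default_factory=dict)

    @classmethod
    def from_feature_matrix(cls, matrix: FeatureMatrix) -> "GowerConfig":
        kinds = {c: ("interval" if k == "continuous" else "categorical")
                 for c, k in matrix.column_meta["kind"].items()}
        return cls(feature_kinds=kinds)


@dataclass
class DistanceMatrix:
    """Symmetric n x n Gower distance grid with the patient order."""

    values: np.ndarray
    index: pd.Index

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)


@dataclass
class ClusteringResult:
    """Cluster labels for one (method, k) configuration.

    Labels are integers in 0..k-1, relabelled so cluster 0 is the largest.
    """

    method: str
    k: int
    labels: np.ndarray

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        found = np.unique(self.labels)
        if len(found) != self.k:
            raise ClusteringError(
                f"{self.method}: expected {self.k} non-empty clusters, got {len(found)}"
            )

    @property
    def sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.k)


def _relabel_by_size(labels: np.ndarray) -> np.ndarray:
    """Map raw labels to 0..k-1 ordered by cluster size (desc), ties by first id."""
    ids, counts = np.unique(labels, return_counts=True)
    order = np.lexsort((ids, -counts))
    mapping = {ids[j]: rank for rank, j in enumerate(order)}
    return np.array([mapping[l] for l in labels], dtype=int)


# ---------------------------------------------------------------------------
# Gower distance
# ---------------------------------------------------------------------------

def gower_matrix(matrix: FeatureMatrix | pd.DataFrame,
                 config: GowerConfig | None = None) -> DistanceMatrix:
    """Pairwise Gower distances over mixed interval/categorical features."""
    if isinstance(matrix, FeatureMatrix):
        values = matrix.values
        if config is None:
            config = GowerConfig.from_feature_matrix(matrix)
    else:
        values = matrix
        if config is None:
            raise ClusteringError("a GowerConfig is required for a bare DataFrame")
    if values.isna().any().any():
        raise ClusteringError("Gower input must have no missing cells")

    cols = list(values.columns)
    weights = np.array([float(config.feature_weights.get(c, 1.0)) for c in cols])
    if np.any(weights < 0):
        raise ClusteringError("feature weights must be nonnegative")
    if weights.sum() == 0:
        raise ClusteringError("all feature weights are zero")

    n = len(values)
    acc = np.zeros((n, n))
    for c, w in zip(cols, weights):
        if w == 0:
            continue
        kind = config.feature_kinds.get(c)
        if kind not in ("interval", "categorical"):
            raise ClusteringError(f"unknown feature kind for {c!r}: {kind!r}")
        x = values[c].to_numpy(dtype=float)
        if kind == "interval":
            r = config.ranges.get(c, x.max() - x.min())
            if r <= 0:
                raise ClusteringError(f"zero range on interval feature {c!r}")
            acc += w * (np.abs(x[:, None] - x[None, :]) / r)
        else:
            acc += w * (x[:, None] != x[None, :])
    D = acc / weights.sum()
    np.fill_diagonal(D, 0.0)
    D = (D + D.T) / 2.0  # enforce exact symmetry against float noise
    return DistanceMatrix(values=D, index=values.index)


# ---------------------------------------------------------------------------
# FAMD embedding
# ---------------------------------------------------------------------------

def famd_embed(matrix: FeatureMatrix, n_components: int | None = None,
               min_explained: float = 0.80) -> pd.DataFrame:
    """Row principal coordinates of the factor analysis of mixed data.

    With only continuous columns this reduces exactly to PCA of the z-scored
    matrix; with only categorical columns the coordinates are proportional to
    MCA principal coordinates.  If ``n_components`` is None, the smallest
    count explaining at least ``min_explained`` of total inertia is kept.
    """
    values = matrix.values
    if values.isna().any().any():
        raise ClusteringError("FAMD input must have no missing cells")
    n = len(values)

    blocks = []
    loadings_names = []
    for c in matrix.continuous_columns:
        x = values[c].to_numpy(dtype=float)
        sd = x.std()
        if sd == 0:
            raise ClusteringError(f"zero-variance continuous column {c!r}")
        blocks.append(((x - x.mean()) / sd)[:, None])
        loadings_names.append(c)
    for c in matrix.binary_columns:
        x = values[c].to_numpy(dtype=float)
        for level in (0.0, 1.0):
            ind = (x == level).astype(float)
            p = ind.mean()
            if p == 0:
                continue  # absent level carries no information
            col = ind / np.sqrt(p)
            blocks.append((col - col.mean())[:, None])
            loadings_names.append(f"{c}={int(level)}")
    if not blocks:
        raise ClusteringError("no usable columns for FAMD")
    G = np.hstack(blocks)

    U, S, Vt = np.linalg.svd(G, full_matrices=False)
    rank = int(np.sum(S > S[0] * 1e-10)) if S.size else 0
    if n_components is None:
        inertia = S**2
        frac = np.cumsum(inertia) / inertia.sum()
        n_components = min(int(np.searchsorted(frac, min_explained) + 1), rank)
    if n_components > rank:
        raise ClusteringError(
            f"n_components={n_components} exceeds matrix rank {rank}"
        )
    U, S, Vt = U[:, :n_components], S[:n_components], Vt[:n_components]

    # sign convention: largest-|loading| entry of each component positive
    for j in range(n_components):
        i = np.argmax(np.abs(Vt[j]))
        if Vt[j, i] < 0:
            Vt[j] *= -1
            U[:, j] *= -1

    coords = U * S
    return pd.DataFrame(coords, index=values.index,
                        columns=[f"F{j+1}" for j in range(n_components)])


# ---------------------------------------------------------------------------
# Clustering algorithms
# ---------------------------------------------------------------------------

def ward_cluster(data: DistanceMatrix | pd.DataFrame | np.ndarray,
                 k: int) -> ClusteringResult:
    """Ward agglomeration cut at ``k`` clusters.

    A :class:`DistanceMatrix` is clustered via the precomputed-distance
    Lance-Williams recursion (gower_ward pathway); an embedding is clustered
    on Euclidean distances (famd_ward pathway).
    """
    if isinstance(data, DistanceMatrix):
        n = data.n
        method = "gower_ward"
        y = data.condensed()
    else:
        arr = np.asarray(data, dtype=float)
        n = arr.shape[0]
        method = "famd_ward"
        y = arr
    if k < 1 or k > n:
        raise ClusteringError(f"k={k} out of range for n={n}")
    Z = linkage(y, method="ward")
    raw = fcluster(Z, t=k, criterion="maxclust")
    if len(np.unique(raw)) != k:
        raise ClusteringError(
            f"dendrogram cut produced {len(np.unique(raw))} clusters, wanted {k}"
        )
    return ClusteringResult(method=method, k=k, labels=_relabel_by_size(raw))


def kmeans_cluster(embedding, k: int, seed: int = 0,
                   n_init: int = 10, max_iter: int = 300) -> ClusteringResult:
    """K-means (k-means++ init, best of ``n_init`` restarts) on an embedding."""
    from sklearn.cluster import KMeans

    X = np.asarray(embedding, dtype=float)
    n_distinct = len(np.unique(X, axis=0))
    if k < 1 or k > n_distinct:
        raise ClusteringError(
            f"k={k} exceeds the number of distinct rows ({n_distinct})"
        )
    km = KMeans(n_clusters=k, n_init=n_init, max_iter=max_iter,
                random_state=int(seed) % (2**31))
    raw = km.fit_predict(X)
    return ClusteringResult(method="famd_kmeans", k=k, labels=_relabel_by_size(raw))


def cluster_pathway(method: str, k: int, *, gower: DistanceMatrix | None = None,
                    embedding=None, seed: int = 0) -> ClusteringResult:
    """Dispatch one of the three clustering pathways."""
    if method == "gower_ward":
        if gower is None:
            raise ClusteringError("gower_ward requires a precomputed DistanceMatrix")
        return ward_cluster(gower, k)
    if method == "famd_ward":
        if embedding is None:
            raise ClusteringError("famd_ward requires an FAMD embedding")
        res = ward_cluster(np.asarray(embedding, dtype=float), k)
        return ClusteringResult(method="famd_ward", k=k, labels=res.labels)
    if method == "famd_kmeans":
        if embedding is None:
            raise ClusteringError("famd_kmeans requires an FAMD embedding")
        return kmeans_cluster(embedding, k, seed=seed)
    raise ClusteringError(f"unknown method {method!r}; choose from {METHODS}")
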