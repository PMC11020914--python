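"""Internal validity indices and majority-vote model selection.

Every candidate (method, k) configuration is scored with the Silhouette
score, the Calinski-Harabasz index, and the Davies-Bouldin index.  The
Silhouette is computed on the representation native to each pathway (the
Gower distance matrix for gower_ward, Euclidean embedding distances for the
FAMD pathways).  Calinski-Harabasz and Davies-Bouldin require centroids,
which are undefined under a raw distance matrix, so for the gower_ward
pathway they are computed on the scaled feature matrix (z-scored continuous
plus half-shifted binary columns) — a documented design choice.

The winning configuration is chosen by majority vote: for each index the
best *admissible* configuration wins (higher-better for Silhouette and
Calinski-Harabasz, lower-better for Davies-Bouldin), and the configuration
winning at least two of the three indices is selected.  Admissibility
requires every cluster to exceed a minimum-size floor (default
max(375, 10% of n)), which promotes stable, non-degenerate partitions.
A three-way split raises :class:`~hfclust.errors.NoMajorityError` carrying
the tally; ties are never resolved silently.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn import metrics as _skm

from .clustering import DistanceMatrix, METHODS, cluster_pathway
from .errors import NoMajorityError, SelectionError

INDEX_COLUMNS = ("silhouette", "calinski_harabasz", "davies_bouldin")
#: larger-is-better flags aligned with INDEX_COLUMNS
_HIGHER_BETTER = {"silhouette": True, "calinski_harabasz": True,
                  "davies_bouldin": False}


def _check_labels(n: int, labels) -> np.ndarray:
    labels = np.asarray(labels)
    if len(labels) != n:
        raise SelectionError("label vector length does not match data")
    k = len(np.unique(labels))
    if k < 2:
        raise SelectionError("validity indices require at least 2 clusters")
    return labels


def silhouette_score(data, labels) -> float:
    """Mean silhouette over points; singleton clusters contribute 0.

    ``data`` is either a :class:`DistanceMatrix` (precomputed metric) or a
    numeric representation scored with Euclidean distances.
    """
    if isinstance(data, DistanceMatrix):
        labels = _check_labels(data.n, labels)
        return float(_skm.silhouette_score(data.values, labels, metric="precomputed"))
    X = np.asarray(data, dtype=float)
    labels = _check_labels(X.shape[0], labels)
    return float(_skm.silhouette_score(X, labels, metric="euclidean"))


def calinski_harabasz(X, labels) -> float:
    """Between/within dispersion ratio scaled by degrees of freedom."""
    X = np.asarray(X, dtype=float)
    labels = _check_labels(X.shape[0], labels)
    n, k = X.shape[0], len(np.unique(labels))
    if k == n:
        raise SelectionError("Calinski-Harabasz undefined for k = n")
    within = sum(
        np.sum((X[labels == c] - X[labels == c].mean(axis=0)) ** 2)
        for c in np.unique(labels)
    )
    if within == 0:
        raise SelectionError("zero within-cluster dispersion (coincident points)")
    return float(_skm.calinski_harabasz_score(X, labels))


def davies_bouldin(X, labels) -> float:
    """Mean over clusters of the worst (s_i + s_j) / d_ij similarity ratio."""
    X = np.asarray(X, dtype=float)
    labels = _check_labels(X.shape[0], labels)
    uniq = np.unique(labels)
    centroids = np.stack([X[labels == c].mean(axis=0) for c in uniq])
    d = np.linalg.norm(centroids[:, None] - centroids[None, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    if np.any(d == 0):
        raise SelectionError("duplicate cluster centroids; Davies-Bouldin undefined")
    return float(_skm.davies_bouldin_score(X, labels))


# ---------------------------------------------------------------------------
# Selection report and majority vote
# ---------------------------------------------------------------------------

@dataclass
class SelectionReport:
    """Scores per (method, k) plus per-index winners and the vote outcome."""

    table: pd.DataFrame  # method, k, the 3 indices, min_cluster_size, admissible
    winners: dict | None = None  # index name -> (method, k)
    chosen: tuple | None = None  # (method, k)

    def to_csv(self, path):
        self.table.to_csv(path, index=False)


def resolve_size_floor(n: int, size_floor=None) -> int:
    """Absolute minimum cluster size: int passthrough, fraction of n, or the
    default max(375, 10% of n)."""
    if size_floor is None:
        return max(375, int(np.ceil(0.10 * n)))
    if isinstance(size_floor, float) and 0 < size_floor < 1:
        return int(np.ceil(size_floor * n))
    return int(size_floor)


def evaluate_configurations(*, gower: DistanceMatrix | None = None,
                            embedding=None, index_features=None,
                            methods=METHODS, k_range=range(2, 13),
                            seed: int = 0, size_floor=None) -> SelectionReport:
    """Cluster and score every (method, k) candidate.

    ``index_features`` (the scaled feature matrix) feeds Calinski-Harabasz and
    Davies-Bouldin for the gower_ward pathway; the FAMD pathways use their own
    embedding for all three indices.
    """
    rows = []
    for method in methods:
        if method == "gower_ward":
            if gower is None or index_features is None:
                raise SelectionError(
                    "gower_ward scoring needs the distance matrix and scaled features"
                )
            sil_data, xy = gower, np.asarray(index_features, dtype=float)
        else:
            if embedding is None:
                raise SelectionError(f"{method} scoring needs the FAMD embedding")
            xy = np.asarray(embedding, dtype=float)
            sil_data = xy
        n = xy.shape[0]
        floor = resolve_size_floor(n, size_floor)
        for k in k_range:
            res = cluster_pathway(method, k, gower=gower, embedding=embedding,
                                  seed=seed)
            min_size = int(res.sizes.min())
            rows.append({
                "method": method, "k": k,
                "silhouette": silhouette_score(sil_data, res.labels),
                "calinski_harabasz": calinski_harabasz(xy, res.labels),
                "davies_bouldin": davies_bouldin(xy, res.labels),
                "min_cluster_size": min_size,
                "admissible": min_size > floor,
            })
    return SelectionReport(table=pd.DataFrame(rows))


def majority_vote(report: SelectionReport | pd.DataFrame,
                  size_floor=None, n: int | None = None) -> tuple:
    """Pick the (method, k) winning at least two of the three indices.

    Rows whose smallest cluster does not exceed the size floor are removed
    first.  Within each index, exact ties break deterministically toward
    smaller k, then method name, making the vote invariant to row order.
    Raises :class:`NoMajorityError` (with the tally) on a three-way split and
    :class:`SelectionError` when nothing is admissible.
    """
    table = report.table if isinstance(report, SelectionReport) else report
    table = table.copy()
    if "admissible" in table.columns and size_floor is None:
        admissible = table[table["admissible"]]
    else:
        if n is None:
            raise SelectionError("need n to resolve a fractional size floor")
        floor = resolve_size_floor(n, size_floor)
        admissible = table[table["min_cluster_size"] > floor]
    if admissible.empty:
        raise SelectionError("no admissible configuration (size floor too high?)")

    winners = {}
    for index in INDEX_COLUMNS:
        ordered = admissible.sort_values(
            [index, "k", "method"],
            ascending=[not _HIGHER_BETTER[index], True, True],
            kind="stable",
        )
        best = ordered.iloc[0]
        winners[index] = (best["method"], int(best["k"]))

    tally: dict = {}
    for config in winners.values():
        tally[config] = tally.get(config, 0) + 1
    best_config, votes = max(tally.items(), key=lambda kv: kv[1])
    if votes < 2:
        raise NoMajorityError(
            f"three-way index split, no majority: {winners}", tally=winners
        )
    if isinstance(report, SelectionReport):
        report.winners = winners
        report.chosen = best_config
    return best_config
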