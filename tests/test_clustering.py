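"""Gower distance, FAMD embedding, Ward and K-means pathway checks.

Oracles are deliberately naive re-implementations (double loops, textbook
PCA/MCA, O(n^3) Lance-Williams agglomeration) kept independent of the
library code paths they verify.
"""

import numpy as np
import pandas as pd
import pytest

from hfclust import clustering as cl
from hfclust import preprocessing as pp
from hfclust.errors import ClusteringError

from conftest import random_mixed_table


# -- naive oracles ----------------------------------------------------------

def gower_oracle(values: pd.DataFrame, kinds: dict) -> np.ndarray:
    """Direct double-loop evaluation of the mixed-type dissimilarity."""
    n = len(values)
    cols = list(values.columns)
    ranges = {c: values[c].max() - values[c].min()
              for c in cols if kinds[c] == "interval"}
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            total = 0.0
            for c in cols:
                xi, xj = values[c].iloc[i], values[c].iloc[j]
                if kinds[c] == "interval":
                    total += abs(xi - xj) / ranges[c]
                else:
                    total += float(xi != xj)
            D[i, j] = total / len(cols)
    return D


def naive_ward_partitions(points: np.ndarray) -> dict:
    """O(n^3) Lance-Williams Ward agglomeration; returns partition per k."""
    n = len(points)
    clusters = {i: [i] for i in range(n)}
    d = {}
    for i in range(n):
        for j in range(i + 1, n):
            d[(i, j)] = float(np.linalg.norm(points[i] - points[j]))
    partitions = {n: [list(v) for v in clusters.values()]}
    next_id = n
    while len(clusters) > 1:
        (a, b), dist = min(d.items(), key=lambda kv: kv[1])
        na, nb = len(clusters[a]), len(clusters[b])
        merged = clusters.pop(a) + clusters.pop(b)
        clusters[next_id] = merged
        new_d = {}
        for (i, j), val in d.items():
            if a in (i, j) or b in (i, j):
                continue
            new_d[(i, j)] = val
        for other in clusters:
            if other == next_id:
                continue
            no = len(clusters[other])
            key_a = (min(a, other), max(a, other))
            key_b = (min(b, other), max(b, other))
            dao, dbo, dab = d[key_a], d[key_b], dist
            # Ward update on squared distances
            val2 = ((na + no) * dao**2 + (nb + no) * dbo**2 - no * dab**2) \
                / (na + nb + no)
            new_d[(min(other, next_id), max(other, next_id))] = np.sqrt(val2)
        d = new_d
        partitions[len(clusters)] = [list(v) for v in clusters.values()]
        next_id += 1
    return partitions


def partition_sets(labels):
    out = {}
    for i, l in enumerate(labels):
        out.setdefault(l, set()).add(i)
    return sorted((frozenset(s) for s in out.values()), key=min)


# -- Gower ------------------------------------------------------------------

def test_gower_identical_records_distance_zero():
    df = pd.DataFrame({"a": [1.0, 1.0], "b": [0.0, 0.0]})
    fm = pp.FeatureMatrix.from_cohort(df.assign(a2=[1.0, 2.0]), ["a2"], ["b"])
    D = cl.gower_matrix(fm)
    assert D.values[0, 0] == 0.0
    # duplicate rows across the mixed columns -> 0 distance
    df2 = pd.DataFrame({"x": [3.0, 3.0, 5.0], "f": [1.0, 1.0, 0.0]})
    fm2 = pp.FeatureMatrix.from_cohort(df2, ["x"], ["f"])
    assert cl.gower_matrix(fm2).values[0, 1] == 0.0


def test_gower_maximal_dissimilarity_is_one():
    df = pd.DataFrame({"x": [0.0, 10.0], "cat": [0.0, 1.0]})
    fm = pp.FeatureMatrix.from_cohort(df, ["x"], ["cat"])
    D = cl.gower_matrix(fm)
    assert D.values[0, 1] == pytest.approx(1.0, abs=1e-12)


def test_gower_matches_double_loop_oracle(rng):
    for _ in range(5):
        fm = random_mixed_table(rng)
        kinds = {c: ("interval" if k == "continuous" else "categorical")
                 for c, k in fm.column_meta["kind"].items()}
        expected = gower_oracle(fm.values, kinds)
        got = cl.gower_matrix(fm).values
        np.testing.assert_allclose(got, expected, atol=1e-12)


def test_gower_metric_properties(rng):
    fm = random_mixed_table(rng, n=25)
    D = cl.gower_matrix(fm).values
    assert np.allclose(D, D.T, atol=1e-15)
    assert np.all(np.diag(D) == 0)
    assert D.min() >= 0 and D.max() <= 1 + 1e-12
    # triangle inequality on random triples (holds for the equal-weight metric)
    idx = rng.integers(0, 25, size=(200, 3))
    for i, j, k in idx:
        assert D[i, j] <= D[i, k] + D[k, j] + 1e-12


from hypothesis import given, settings
from hypothesis import strategies as st


@settings(derandomize=True, max_examples=25, deadline=None)
@given(st.lists(st.tuples(st.floats(-50, 50), st.integers(0, 1)),
                min_size=3, max_size=12))
def test_gower_is_a_bounded_semimetric(rows):
    df = pd.DataFrame(rows, columns=["x", "f"]).astype(float)
    if df["x"].max() == df["x"].min():
        df.loc[df.index[0], "x"] += 1.0
    fm = pp.FeatureMatrix.from_cohort(df, ["x"], ["f"])
    D = cl.gower_matrix(fm).values
    assert np.allclose(D, D.T)
    assert np.all(np.diag(D) == 0)
    assert D.min() >= 0 and D.max() <= 1 + 1e-12
    n = len(df)
    for i in range(n):
        for j in range(n):
            for k in range(n):
                assert D[i, j] <= D[i, k] + D[k, j] + 1e-9


def test_gower_zero_range_errors():
    df = pd.DataFrame({"x": [2.0, 2.0, 2.0], "f": [0.0, 1.0, 0.0]})
    fm = pp.FeatureMatrix.from_cohort(df, ["x"], ["f"])
    with pytest.raises(ClusteringError, match="zero range"):
        cl.gower_matrix(fm)


def test_gower_zero_weights_error(rng):
    fm = random_mixed_table(rng, n=6)
    config = cl.GowerConfig.from_feature_matrix(fm)
    config.feature_weights = {c: 0.0 for c in fm.values.columns}
    with pytest.raises(ClusteringError, match="zero"):
        cl.gower_matrix(fm, config)


# -- FAMD -------------------------------------------------------------------

def test_famd_reduces_to_pca_for_continuous(rng):
    X = rng.normal(size=(30, 4))
    df = pd.DataFrame(X, columns=list("abcd"))
    fm = pp.FeatureMatrix.from_cohort(df, list("abcd"), [])
    emb = cl.famd_embed(fm, n_components=3).to_numpy()
    Z = (X - X.mean(0)) / X.std(0)
    U, S, Vt = np.linalg.svd(Z, full_matrices=False)
    scores = (U * S)[:, :3]
    for j in range(3):  # sign-insensitive comparison
        r = np.corrcoef(emb[:, j], scores[:, j])[0, 1]
        assert abs(abs(r) - 1.0) < 1e-8
        np.testing.assert_allclose(np.abs(emb[:, j]), np.abs(scores[:, j]),
                                   atol=1e-8)


def mca_oracle(indicator: np.ndarray, n_components: int) -> np.ndarray:
    """Textbook correspondence analysis row principal coordinates."""
    P = indicator / indicator.sum()
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    S = np.diag(r**-0.5) @ (P - np.outer(r, c)) @ np.diag(c**-0.5)
    U, sv, Vt = np.linalg.svd(S, full_matrices=False)
    return (np.diag(r**-0.5) @ U * sv)[:, :n_components]


def test_famd_proportional_to_mca_for_categorical(rng):
    flags = rng.integers(0, 2, size=(12, 3)).astype(float)
    while len(np.unique(flags, axis=0)) < 4 or flags.std(0).min() == 0:
        flags = rng.integers(0, 2, size=(12, 3)).astype(float)
    df = pd.DataFrame(flags, columns=list("xyz"))
    fm = pp.FeatureMatrix.from_cohort(df, [], list("xyz"))
    emb = cl.famd_embed(fm, n_components=2).to_numpy()
    indicator = np.hstack([(flags == 0).astype(float), (flags == 1).astype(float)])
    coords = mca_oracle(indicator, 2)
    for j in range(2):
        r = np.corrcoef(emb[:, j], coords[:, j])[0, 1]
        assert abs(abs(r) - 1.0) < 1e-8


def test_famd_duplicated_rows_identical_embeddings(rng):
    fm = random_mixed_table(rng, n=10)
    dup = pd.concat([fm.values, fm.values.iloc[[0]]], ignore_index=True)
    fm2 = pp.FeatureMatrix(dup, fm.column_meta.copy())
    emb = cl.famd_embed(fm2, n_components=2).to_numpy()
    np.testing.assert_allclose(emb[0], emb[-1], atol=1e-10)


def test_famd_component_count_exceeding_rank_errors(rng):
    fm = random_mixed_table(rng, n=8, n_interval=2, n_categorical=1)
    with pytest.raises(ClusteringError, match="rank"):
        cl.famd_embed(fm, n_components=10)


# -- Ward -------------------------------------------------------------------

def test_ward_recovers_separated_clouds(rng):
    pts = np.vstack([rng.normal(0, 0.1, size=(10, 2)),
                     rng.normal(50, 0.1, size=(10, 2))])
    res = cl.ward_cluster(pts, 2)
    assert len(set(res.labels[:10])) == 1
    assert len(set(res.labels[10:])) == 1
    assert res.labels[0] != res.labels[-1]


def test_ward_k_equals_n_singletons(rng):
    pts = rng.normal(size=(7, 2))
    res = cl.ward_cluster(pts, 7)
    assert sorted(res.labels) == list(range(7))


def test_ward_k_out_of_range_errors(rng):
    pts = rng.normal(size=(5, 2))
    with pytest.raises(ClusteringError):
        cl.ward_cluster(pts, 6)


def test_ward_merge_sequence_matches_naive_lance_williams(rng):
    """Every dendrogram cut agrees with an O(n^3) Ward agglomeration."""
    pts = np.array([0.0, 0.9, 2.5, 3.1, 7.0, 7.4, 12.0, 12.2])[:, None]
    expected = naive_ward_partitions(pts)
    # precomputed-distance pathway must produce the same partitions
    D = np.abs(pts - pts.T)
    dm = cl.DistanceMatrix(D, index=pd.RangeIndex(8))
    for k in range(2, 8):
        got = partition_sets(cl.ward_cluster(dm, k).labels)
        want = sorted((frozenset(g) for g in expected[k]), key=min)
        assert got == want, f"k={k}"


def test_ward_permutation_equivariance(rng):
    from sklearn.metrics import adjusted_rand_score

    fm = random_mixed_table(rng, n=30)
    D = cl.gower_matrix(fm)
    base = cl.ward_cluster(D, 3).labels
    perm = rng.permutation(30)
    Dp = cl.DistanceMatrix(D.values[np.ix_(perm, perm)], index=D.index[perm])
    permuted = cl.ward_cluster(Dp, 3).labels
    assert adjusted_rand_score(base[perm], permuted) == 1.0


# -- K-means ----------------------------------------------------------------

def test_kmeans_recovers_blobs(rng):
    from sklearn.metrics import adjusted_rand_score

    pts = np.vstack([rng.normal(0, 0.2, size=(20, 3)),
                     rng.normal(8, 0.2, size=(20, 3))])
    truth = np.repeat([0, 1], 20)
    res = cl.kmeans_cluster(pts, 2, seed=0)
    assert adjusted_rand_score(truth, res.labels) == 1.0


def test_kmeans_duplicate_rows_same_cluster(rng):
    pts = rng.normal(size=(15, 2))
    pts = np.vstack([pts, pts[3]])
    res = cl.kmeans_cluster(pts, 3, seed=0)
    assert res.labels[3] == res.labels[-1]


def test_kmeans_beats_random_assignments(rng):
    pts = np.vstack([rng.normal(0, 1, size=(30, 2)),
                     rng.normal(4, 1, size=(30, 2))])

    def inertia(labels):
        return sum(np.sum((pts[labels == c] - pts[labels == c].mean(0)) ** 2)
                   for c in np.unique(labels))

    res = cl.kmeans_cluster(pts, 2, seed=0)
    best = inertia(res.labels)
    for _ in range(50):
        rand = rng.integers(0, 2, size=60)
        if len(np.unique(rand)) < 2:
            continue
        assert best <= inertia(rand) + 1e-9


def test_kmeans_k_exceeding_distinct_rows_errors():
    pts = np.zeros((6, 2))
    with pytest.raises(ClusteringError):
        cl.kmeans_cluster(pts, 2, seed=0)
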