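"""Cluster profiling: summaries, statistical tests, prescriptions, admissions."""

import numpy as np
import pandas as pd
import pytest

from hfclust import profiles as pr
from hfclust.errors import ProfileError


# -- summary conventions ----------------------------------------------------

def test_median_iqr_hand_values():
    med, q1, q3 = pr._median_iqr(np.arange(1.0, 10.0))
    assert (med, q1, q3) == (5.0, 3.0, 7.0)


def test_summarize_clusters_structure_and_values():
    cohort = pd.DataFrame({
        "age": list(range(1, 10)) + [50.0] * 9,
        "HT": [1, 1, 1, 0, 0, 0, 0, 0, 0] * 2,
    })
    labels = np.repeat([0, 1], 9)
    tab = pr.summarize_clusters(cohort, labels, continuous=["age"], binary=["HT"])
    stats = tab.stats
    med = stats[(stats.characteristic == "age") & (stats.cluster == 0)
                & (stats.stat == "median")]["value"].iloc[0]
    assert med == 5.0
    pct = stats[(stats.characteristic == "HT") & (stats.cluster == 0)
                & (stats.stat == "pct")]["value"].iloc[0]
    assert pct == pytest.approx(100 * 3 / 9)


def test_identical_binary_distribution_gives_p_near_one():
    cohort = pd.DataFrame({"HT": [1, 1, 0, 0] * 10})
    labels = np.tile([0, 1, 0, 1], 10)  # each cluster sees the same 50/50 mix
    tab = pr.summarize_clusters(cohort, labels, binary=["HT"])
    p = tab.table.loc[tab.table.characteristic == "HT, %", "p_value"].iloc[0]
    assert p > 0.9


def test_shifted_distributions_detected(rng):
    a = rng.normal(0, 1, 200)
    b = rng.normal(2, 1, 200)
    cohort = pd.DataFrame({"lab": np.concatenate([a, b])})
    labels = np.repeat([0, 1], 200)
    tab = pr.summarize_clusters(cohort, labels, continuous=["lab"])
    assert tab.table["p_value"].iloc[-1] < 0.001


def test_whole_cohort_pct_is_size_weighted_combination(rng):
    cohort = pd.DataFrame({"flag": rng.integers(0, 2, size=300).astype(float)})
    labels = rng.integers(0, 3, size=300)
    tab = pr.summarize_clusters(cohort, labels, binary=["flag"])
    s = tab.stats
    parts = []
    for c in np.unique(labels):
        pct = s[(s.cluster == c) & (s.stat == "pct")]["value"].iloc[0]
        parts.append(pct * (labels == c).mean())
    whole = s[(s.cluster == "all") & (s.stat == "pct")]["value"].iloc[0]
    assert sum(parts) == pytest.approx(whole, abs=1e-9)


def test_label_permutation_equivariance(rng):
    cohort = pd.DataFrame({"lab": rng.normal(size=90),
                           "flag": rng.integers(0, 2, 90).astype(float)})
    labels = rng.integers(0, 3, size=90)
    t1 = pr.summarize_clusters(cohort, labels, ["lab"], ["flag"])
    relabel = np.array([2, 0, 1])[labels]  # rename clusters
    t2 = pr.summarize_clusters(cohort, relabel, ["lab"], ["flag"])
    np.testing.assert_allclose(t1.table["p_value"], t2.table["p_value"],
                               rtol=1e-9, equal_nan=True)
    v1 = t1.stats[(t1.stats.cluster == 0) & (t1.stats.stat == "pct")]["value"]
    v2 = t2.stats[(t2.stats.cluster == 2) & (t2.stats.stat == "pct")]["value"]
    assert v1.iloc[0] == v2.iloc[0]


# -- chi-square -------------------------------------------------------------

def test_chi_square_no_association():
    stat, p = pr.chi_square_test([[10, 10], [10, 10]])
    assert stat == 0.0 and p == pytest.approx(1.0)


def test_chi_square_perfect_association():
    stat, p = pr.chi_square_test([[20, 0], [0, 20]])
    assert stat == pytest.approx(40.0, abs=1e-10)
    assert p < 1e-9


def test_chi_square_matches_direct_formula(rng):
    for _ in range(10):
        obs = rng.integers(1, 40, size=(3, 2)).astype(float)
        stat, _ = pr.chi_square_test(obs)
        total = obs.sum()
        expected = np.outer(obs.sum(1), obs.sum(0)) / total
        direct = ((obs - expected) ** 2 / expected).sum()
        assert stat == pytest.approx(direct, abs=1e-10)


def test_chi_square_zero_margin_errors():
    with pytest.raises(ProfileError):
        pr.chi_square_test([[0, 10], [0, 20]])


# -- Kruskal-Wallis ---------------------------------------------------------

def test_kruskal_wallis_hand_rank_maximum():
    stat, p = pr.kruskal_wallis([[1, 2, 3], [10, 11, 12]])
    # ranks 1..6 split perfectly: H = 12/42 * (36/3 + 225/3) - 21
    assert stat == pytest.approx(12 / 42 * (36 / 3 + 225 / 3) - 21, abs=1e-10)


def test_kruskal_wallis_monotone_invariance(rng):
    g1, g2 = rng.normal(0, 1, 30), rng.normal(1, 1, 30)
    s1, _ = pr.kruskal_wallis([g1, g2])
    s2, _ = pr.kruskal_wallis([np.exp(g1), np.exp(g2)])
    assert s1 == pytest.approx(s2, abs=1e-10)


def test_kruskal_wallis_null_calibration():
    """Permuted identical distributions rarely reach small p-values."""
    rng = np.random.default_rng(99)
    small = 0
    for _ in range(100):
        pooled = rng.normal(size=60)
        rng.shuffle(pooled)
        _, p = pr.kruskal_wallis([pooled[:30], pooled[30:]])
        small += p <= 0.01
    assert small <= 3  # about 1% expected


def test_kruskal_wallis_degenerate_errors():
    with pytest.raises(ProfileError):
        pr.kruskal_wallis([[1.0, 1.0], [1.0, 1.0]])


# -- prescriptions ----------------------------------------------------------

def _labels(n, values):
    return pd.Series(values, index=[f"P{i}" for i in range(n)])


def test_prescription_prevalence_counts_patients_once():
    labels = _labels(10, [0] * 10)
    presc = pd.DataFrame({
        "patient_id": ["P0", "P0", "P1", "P2", "P3"],
        "drug": ["lisinopril", "ramipril", "atorvastatin", "atorvastatin",
                 "simvastatin"],
        "date": pd.to_datetime(["2015-01-01"] * 5),
    })
    tab = pr.summarize_prescriptions(presc, pr.load_drug_group_map(), labels,
                                     observation_years=5.0)
    s = tab.stats
    acei = s[(s.characteristic == "acei_arb") & (s.cluster == 0)]["value"].iloc[0]
    assert acei == pytest.approx(10.0)  # P0 counted once despite two rows
    statin = s[(s.characteristic == "statin") & (s.cluster == 0)]["value"].iloc[0]
    assert statin == pytest.approx(30.0)


def test_prescriptions_forty_percent_example():
    labels = _labels(10, [0] * 10)
    presc = pd.DataFrame({
        "patient_id": ["P0", "P1", "P2", "P3"],
        "drug": ["atorvastatin"] * 4,
        "date": pd.to_datetime(["2015-01-01"] * 4),
    })
    tab = pr.summarize_prescriptions(presc, pr.load_drug_group_map(), labels, 5.0)
    s = tab.stats
    assert s[(s.characteristic == "statin")]["value"].iloc[0] == pytest.approx(40.0)


def test_no_prescriptions_all_zero():
    labels = _labels(6, [0, 0, 0, 1, 1, 1])
    presc = pd.DataFrame(columns=["patient_id", "drug", "date"])
    tab = pr.summarize_prescriptions(presc, pr.load_drug_group_map(), labels, 5.0)
    pct_cols = [c for c in tab.table.columns if c.startswith("cluster")]
    binary_rows = tab.table[tab.table.kind == "binary"]
    assert (binary_rows[pct_cols].to_numpy(dtype=float) == 0).all()


def test_unmapped_drug_warns_and_goes_to_other():
    labels = _labels(4, [0, 0, 1, 1])
    presc = pd.DataFrame({
        "patient_id": ["P0"], "drug": ["mystery-compound"],
        "date": pd.to_datetime(["2015-01-01"]),
    })
    with pytest.warns(UserWarning, match="mystery-compound"):
        tab = pr.summarize_prescriptions(presc, pr.load_drug_group_map(),
                                         labels, 5.0)
    assert "other, %" in tab.table.characteristic.tolist()


# -- admissions -------------------------------------------------------------

def test_admissions_event_windows():
    labels = _labels(4, [0, 0, 1, 1])
    diag = pd.Series(pd.Timestamp("2015-01-01"), index=labels.index)
    end = pd.Series(pd.Timestamp("2020-01-01"), index=labels.index)
    events = pd.DataFrame({
        "patient_id": ["P0", "P0", "P2"],
        "event_type": ["hospitalisation"] * 3,
        "event_date": pd.to_datetime(["2015-07-01", "2016-07-01", "2018-01-01"]),
    })
    tab = pr.summarize_admissions(events, labels, diag, end)
    s = tab.stats
    one_year = s[(s.characteristic == "hospitalisation_within_1y")]
    assert one_year[one_year.cluster == 0]["value"].iloc[0] == pytest.approx(50.0)
    assert one_year[one_year.cluster == 1]["value"].iloc[0] == 0.0
    period = s[s.characteristic == "hospitalisation_within_period"]
    assert period[period.cluster == 1]["value"].iloc[0] == pytest.approx(50.0)


def test_admissions_thirty_five_percent_example():
    n = 100
    labels = _labels(n, [0] * n)
    diag = pd.Series(pd.Timestamp("2015-01-01"), index=labels.index)
    end = pd.Series(pd.Timestamp("2021-01-01"), index=labels.index)
    events = pd.DataFrame({
        "patient_id": [f"P{i}" for i in range(35)],
        "event_type": ["hospitalisation"] * 35,
        "event_date": pd.to_datetime(["2015-06-01"] * 35),
    })
    tab = pr.summarize_admissions(events, labels, diag, end)
    s = tab.stats
    assert s[s.characteristic == "hospitalisation_within_1y"]["value"].iloc[0] \
        == pytest.approx(35.0)


def test_admissions_before_diagnosis_excluded_with_warning():
    labels = _labels(2, [0, 1])
    diag = pd.Series(pd.Timestamp("2015-01-01"), index=labels.index)
    end = pd.Series(pd.Timestamp("2020-01-01"), index=labels.index)
    events = pd.DataFrame({
        "patient_id": ["P0"], "event_type": ["emergency"],
        "event_date": pd.to_datetime(["2014-06-01"]),
    })
    with pytest.warns(UserWarning, match="before"):
        tab = pr.summarize_admissions(events, labels, diag, end)
    s = tab.stats
    assert (s[s.stat == "pct"]["value"] == 0).all()


def test_no_admissions_all_zero():
    labels = _labels(3, [0, 1, 1])
    diag = pd.Series(pd.Timestamp("2015-01-01"), index=labels.index)
    end = pd.Series(pd.Timestamp("2020-01-01"), index=labels.index)
    events = pd.DataFrame(columns=["patient_id", "event_type", "event_date"])
    tab = pr.summarize_admissions(events, labels, diag, end)
    assert tab.stats.empty or (tab.stats[tab.stats.stat == "pct"]["value"] == 0).all()
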