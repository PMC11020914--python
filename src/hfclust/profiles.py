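"""Per-cluster phenotype, prescription and admission profiles.

Each characteristic is summarised per cluster and for the whole cohort:
continuous variables as median (inter-quartile range, linear-interpolation
quantiles), binary variables as percentages.  Across-cluster differences are
tested with Pearson chi-square (categorical, no continuity correction) or
Kruskal-Wallis (continuous, tie-corrected), flagged significant at p < 0.05.
No multiple-testing correction is applied by default, mirroring per-row
significance reporting; a Benjamini-Hochberg switch is available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ProfileError

ALPHA = 0.05


@dataclass
class ProfileTable:
    """Formatted per-cluster table plus the tidy numeric stats behind it.

    ``table``: one row per characteristic, one formatted column per cluster
    plus the whole-cohort column, the test used, its p-value and a
    significance flag.  ``stats``: long-format numeric values
    (characteristic, cluster, stat, value) for programmatic use.
    """

    table: pd.DataFrame
    stats: pd.DataFrame

    def to_csv(self, path):
        self.table.to_csv(path, index=False)


def _median_iqr(x: np.ndarray) -> tuple:
    x = np.asarray(x, dtype=float)
    x = x[~np.isnan(x)]
    if x.size == 0:
        return (np.nan, np.nan, np.nan)
    q1, med, q3 = np.percentile(x, [25, 50, 75])  # type-7 linear interpolation
    return (med, q1, q3)


def _fmt_median_iqr(med, q1, q3) -> str:
    if np.isnan(med):
        return ""
    return f"{med:.1f} ({q1:.1f}-{q3:.1f})"


def chi_square_test(contingency) -> tuple:
    """Pearson chi-square without continuity correction; (statistic, p)."""
    obs = np.asarray(contingency, dtype=float)
    if obs.sum(axis=0).min() == 0 or obs.sum(axis=1).min() == 0:
        raise ProfileError("contingency table has a zero margin")
    stat, p, _, _ = stats.chi2_contingency(obs, correction=False)
    return float(stat), float(p)


def kruskal_wallis(groups) -> tuple:
    """Tie-corrected Kruskal-Wallis H and its chi-square p-value."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    groups = [g[~np.isnan(g)] for g in groups]
    if len(groups) < 2 or any(g.size == 0 for g in groups):
        raise ProfileError("Kruskal-Wallis needs >= 2 non-empty groups")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        raise ProfileError("all values identical; zero rank variance")
    stat, p = stats.kruskal(*groups)
    return float(stat), float(p)


def _binary_test(values: pd.Series, labels: np.ndarray) -> tuple:
    clusters = np.unique(labels)
    table = np.array([
        [(values[labels == c] == 0).sum(), (values[labels == c] == 1).sum()]
        for c in clusters
    ])
    return chi_square_test(table)


def _bh_adjust(pvals: np.ndarray) -> np.ndarray:
    from statsmodels.stats.multitest import multipletests

    return multipletests(pvals, method="fdr_bh")[1]


def summarize_clusters(cohort: pd.DataFrame, labels, continuous=(),
                       binary=(), adjust: bool = False) -> ProfileTable:
    """Table-5-style characterisation of clusters with across-cluster tests."""
    labels = np.asarray(labels)
    if len(labels) != len(cohort):
        raise ProfileError("labels must align with the cohort rows")
    clusters = np.unique(labels)
    for c in clusters:
        if (labels == c).sum() == 0:
            raise ProfileError(f"cluster {c} has zero patients")

    rows, stats_rows = [], []
    sizes = {int(c): int((labels == c).sum()) for c in clusters}
    size_row = {"characteristic": "Number of patients", "kind": "count",
                **{f"cluster{c}": sizes[int(c)] for c in clusters},
                "cohort": len(cohort), "test": "", "p_value": np.nan,
                "significant": ""}
    rows.append(size_row)

    for col in binary:
        vals = cohort[col]
        row = {"characteristic": f"{col}, %", "kind": "binary"}
        for c in clusters:
            pct = 100.0 * vals[labels == c].mean()
            row[f"cluster{c}"] = round(pct, 2)
            stats_rows.append({"characteristic": col, "cluster": int(c),
                               "stat": "pct", "value": pct})
        row["cohort"] = round(100.0 * vals.mean(), 2)
        stats_rows.append({"characteristic": col, "cluster": "all",
                           "stat": "pct", "value": 100.0 * vals.mean()})
        stat, p = _binary_test(vals, labels)
        row.update(test="chi-square", p_value=p)
        rows.append(row)

    for col in continuous:
        vals = cohort[col]
        row = {"characteristic": col, "kind": "continuous"}
        groups = []
        for c in clusters:
            g = vals[labels == c].to_numpy(dtype=float)
            groups.append(g)
            med, q1, q3 = _median_iqr(g)
            row[f"cluster{c}"] = _fmt_median_iqr(med, q1, q3)
            for name, v in [("median", med), ("q1", q1), ("q3", q3)]:
                stats_rows.append({"characteristic": col, "cluster": int(c),
                                   "stat": name, "value": v})
        med, q1, q3 = _median_iqr(vals.to_numpy(dtype=float))
        row["cohort"] = _fmt_median_iqr(med, q1, q3)
        for name, v in [("median", med), ("q1", q1), ("q3", q3)]:
            stats_rows.append({"characteristic": col, "cluster": "all",
                               "stat": name, "value": v})
        stat, p = kruskal_wallis(groups)
        row.update(test="kruskal-wallis", p_value=p)
        rows.append(row)

    table = pd.DataFrame(rows)
    pmask = table["p_value"].notna()
    if adjust and pmask.any():
        table.loc[pmask, "p_value"] = _bh_adjust(table.loc[pmask, "p_value"].to_numpy())
    table["significant"] = np.where(
        pmask, np.where(table["p_value"] < ALPHA, "yes", "no"), ""
    )
    return ProfileTable(table=table, stats=pd.DataFrame(
        stats_rows, columns=["characteristic", "cluster", "stat", "value"]))


# ---------------------------------------------------------------------------
# Prescriptions
# ---------------------------------------------------------------------------

def load_drug_group_map(path=None) -> dict:
    """drug -> pharmacological group mapping; package default or a user CSV."""
    if path is None:
        with resources.files("hfclust.data").joinpath("drug_groups.csv").open() as fh:
            df = pd.read_csv(fh)
    else:
        df = pd.read_csv(path)
    dup = df["drug"][df["drug"].duplicated()]
    if not dup.empty:
        raise ProfileError(f"drugs mapped to multiple groups: {sorted(set(dup))}")
    return dict(zip(df["drug"], df["group"]))


def summarize_prescriptions(prescriptions: pd.DataFrame, drug_map: dict,
                            patient_labels: pd.Series,
                            observation_years: float) -> ProfileTable:
    """Per-cluster prescription profile.

    For each pharmacological group: the percentage of patients with at least
    one prescription, with an across-cluster chi-square; plus the mean of
    per-patient prescriptions/year over all groups.  Unmapped drug
    identifiers are mapped to "other" with a warning.
    """
    if observation_years <= 0:
        raise ProfileError("observation_years must be positive")
    labels = patient_labels  # index = patient_id
    clusters = np.unique(labels.to_numpy())

    presc = prescriptions.copy()
    unmapped = sorted(set(presc["drug"]) - set(drug_map))
    if unmapped:
        warnings.warn(f"unmapped drug identifiers mapped to 'other': {unmapped}")
    presc["group"] = presc["drug"].map(drug_map).fillna("other")
    presc = presc[presc["patient_id"].isin(labels.index)]

    rows, stats_rows = [], []

    # any-prescription prevalence and average prescriptions/year
    counts = presc.groupby("patient_id").size().reindex(labels.index, fill_value=0)
    any_row = {"characteristic": "Patients with drugs prescribed, %",
               "kind": "binary"}
    rate_row = {"characteristic": "Avg prescriptions/year", "kind": "continuous"}
    has_any = (counts > 0).astype(int)
    for c in clusters:
        in_c = labels == c
        pct = 100.0 * has_any[in_c].mean()
        any_row[f"cluster{c}"] = round(pct, 2)
        rate = (counts[in_c] / observation_years).mean()
        rate_row[f"cluster{c}"] = round(rate, 2)
        stats_rows.append({"characteristic": "any_prescription", "cluster": int(c),
                           "stat": "pct", "value": pct})
        stats_rows.append({"characteristic": "prescriptions_per_year",
                           "cluster": int(c), "stat": "mean", "value": rate})
    any_row["cohort"] = round(100.0 * has_any.mean(), 2)
    rate_row["cohort"] = round((counts / observation_years).mean(), 2)
    try:
        stat, p = _binary_test(has_any, labels.to_numpy())
    except ProfileError:  # universal (or absent) exposure: test undefined
        stat, p = np.nan, np.nan
    any_row.update(test="chi-square", p_value=p)
    rate_row.update(test="", p_value=np.nan)
    rows += [any_row, rate_row]

    for group in sorted(presc["group"].unique()):
        gp = presc[presc["group"] == group]
        with_drug = pd.Series(0, index=labels.index)
        with_drug[with_drug.index.isin(gp["patient_id"])] = 1
        row = {"characteristic": f"{group}, %", "kind": "binary"}
        for c in clusters:
            pct = 100.0 * with_drug[labels == c].mean()
            row[f"cluster{c}"] = round(pct, 2)
            stats_rows.append({"characteristic": group, "cluster": int(c),
                               "stat": "pct", "value": pct})
        row["cohort"] = round(100.0 * with_drug.mean(), 2)
        stats_rows.append({"characteristic": group, "cluster": "all",
                           "stat": "pct", "value": 100.0 * with_drug.mean()})
        try:
            stat, p = _binary_test(with_drug, labels.to_numpy())
        except ProfileError:  # e.g. every patient (or none) exposed
            stat, p = np.nan, np.nan
        row.update(test="chi-square", p_value=p)
        rows.append(row)

    table = pd.DataFrame(rows)
    table["significant"] = np.where(
        table["p_value"].notna(),
        np.where(table["p_value"] < ALPHA, "yes", "no"), "",
    )
    return ProfileTable(table=table, stats=pd.DataFrame(
        stats_rows, columns=["characteristic", "cluster", "stat", "value"]))


# ---------------------------------------------------------------------------
# Admissions
# ---------------------------------------------------------------------------

def summarize_admissions(events: pd.DataFrame, patient_labels: pd.Series,
                         diagnosis_dates: pd.Series,
                         period_end: pd.Series | pd.Timestamp) -> ProfileTable:
    """Outcome profile per cluster: events/year and event percentages.

    Per outcome type: median (IQR) events per patient-year (person-years run
    from HF diagnosis to the end of observation), percentage of patients with
    an event within one year of diagnosis, and within the whole observation
    period.  Events dated before diagnosis are excluded with a warning.
    """
    labels = patient_labels
    clusters = np.unique(labels.to_numpy())
    diag = diagnosis_dates.reindex(labels.index)
    if isinstance(period_end, pd.Series):
        end = period_end.reindex(labels.index)
    else:
        end = pd.Series(pd.Timestamp(period_end), index=labels.index)
    years = (end - diag).dt.days / 365.25
    if (years <= 0).any():
        raise ProfileError("observation period ends before diagnosis for some patients")

    ev = events.copy()
    ev = ev[ev["patient_id"].isin(labels.index)]
    ev["event_date"] = pd.to_datetime(ev["event_date"])
    ev_diag = ev["patient_id"].map(diag)
    before = ev["event_date"] < ev_diag
    if before.any():
        warnings.warn(f"excluded {int(before.sum())} events dated before HF diagnosis")
        ev = ev[~before]

    rows, stats_rows = [], []
    for outcome in sorted(ev["event_type"].unique()):
        sub = ev[ev["event_type"] == outcome]
        delta = (sub["event_date"] - sub["patient_id"].map(diag)).dt.days / 365.25
        counts = sub.groupby("patient_id").size().reindex(labels.index, fill_value=0)
        per_year = counts / years
        within_1y = sub.loc[(delta > 0) & (delta <= 1.0), "patient_id"].unique()
        within_period = sub["patient_id"].unique()

        rate_row = {"characteristic": f"{outcome}s/year", "kind": "continuous"}
        one_row = {"characteristic": f"{outcome} within 1 year, %", "kind": "binary"}
        all_row = {"characteristic": f"{outcome} within period, %", "kind": "binary"}
        flag_1y = pd.Series(0, index=labels.index)
        flag_1y[flag_1y.index.isin(within_1y)] = 1
        flag_all = pd.Series(0, index=labels.index)
        flag_all[flag_all.index.isin(within_period)] = 1
        groups = []
        for c in clusters:
            in_c = labels == c
            g = per_year[in_c].to_numpy(dtype=float)
            groups.append(g)
            med, q1, q3 = _median_iqr(g)
            rate_row[f"cluster{c}"] = _fmt_median_iqr(med, q1, q3)
            one_row[f"cluster{c}"] = round(100.0 * flag_1y[in_c].mean(), 2)
            all_row[f"cluster{c}"] = round(100.0 * flag_all[in_c].mean(), 2)
            stats_rows += [
                {"characteristic": f"{outcome}_per_year", "cluster": int(c),
                 "stat": "median", "value": med},
                {"characteristic": f"{outcome}_within_1y", "cluster": int(c),
                 "stat": "pct", "value": 100.0 * flag_1y[in_c].mean()},
                {"characteristic": f"{outcome}_within_period", "cluster": int(c),
                 "stat": "pct", "value": 100.0 * flag_all[in_c].mean()},
            ]
        med, q1, q3 = _median_iqr(per_year.to_numpy(dtype=float))
        rate_row["cohort"] = _fmt_median_iqr(med, q1, q3)
        one_row["cohort"] = round(100.0 * flag_1y.mean(), 2)
        all_row["cohort"] = round(100.0 * flag_all.mean(), 2)
        try:
            _, p_rate = kruskal_wallis(groups)
        except ProfileError:
            p_rate = np.nan
        rate_row.update(test="kruskal-wallis", p_value=p_rate)
        for row, flag in [(one_row, flag_1y), (all_row, flag_all)]:
            try:
                _, p = _binary_test(flag, labels.to_numpy())
            except ProfileError:
                p = np.nan
            row.update(test="chi-square", p_value=p)
        rows += [rate_row, one_row, all_row]

    table = pd.DataFrame(rows)
    if table.empty:
        table = pd.DataFrame(columns=["characteristic", "kind", "cohort",
                                      "test", "p_value", "significant"])
    else:
        table["significant"] = np.where(
            table["p_value"].notna(),
            np.where(table["p_value"] < ALPHA, "yes", "no"), "",
        )
    return ProfileTable(table=table, stats=pd.DataFrame(
        stats_rows, columns=["characteristic", "cluster", "stat", "value"]))
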