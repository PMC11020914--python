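"""Survival stratification of clusters: Kaplan-Meier, log-rank, Cox models.

Patients are aligned at t0 = HF diagnosis.  The duration is the time to the
first qualifying admission event; patients without one are censored at the
end of observation (a single administrative date or a per-patient series).
Cluster risk is compared with the product-limit (Kaplan-Meier) estimator and
the K-group log-rank test, and quantified with three nested Cox
proportional-hazards specifications (Efron tie handling):

* Model 1 — cluster indicators only (unadjusted),
* Model 2 — plus age and gender,
* Model 3 — plus the NT-proBNP laboratory value.

Hazard ratios are reported against the lowest-risk cluster (the cluster with
the lowest percentage of observed outcomes), whose implicit HR is 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

from .errors import SurvivalError

MODEL_COVARIATES = {1: [], 2: ["age", "gender"], 3: ["age", "gender", "nt_probnp"]}


@dataclass
class SurvivalDataset:
    """Per-patient duration (years), event flag, covariates and cluster label."""

    data: pd.DataFrame  # patient_id index; duration, event, cluster, covariates
    outcome_type: str

    def __post_init__(self):
        if (self.data["duration"] <= 0).any():
            raise SurvivalError("durations must be positive")
        if not self.data["event"].isin([0, 1]).all():
            raise SurvivalError("event flags must be 0/1")


@dataclass
class KMCurve:
    """Product-limit curve: event times, at-risk counts, S(t), optional band."""

    times: np.ndarray
    at_risk: np.ndarray
    survival: np.ndarray
    ci_lower: np.ndarray | None = None
    ci_upper: np.ndarray | None = None
    group: object = None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"time": self.times, "at_risk": self.at_risk,
                           "survival": self.survival})
        if self.ci_lower is not None:
            df["ci_lower"] = self.ci_lower
            df["ci_upper"] = self.ci_upper
        return df


@dataclass
class CoxFit:
    """One fitted Cox specification: HRs and 95% CIs per covariate."""

    model_id: int
    outcome_type: str
    reference_cluster: int
    summary: pd.DataFrame  # coef, hr, ci_lower, ci_upper, p per covariate

    def hazard_ratio(self, covariate: str) -> float:
        return float(self.summary.loc[covariate, "hr"])


def build_survival_dataset(patients: pd.DataFrame, events: pd.DataFrame,
                           outcome_type: str, censor_date,
                           labels=None,
                           covariates=("age", "gender", "nt_probnp"),
                           ) -> SurvivalDataset:
    """Durations from HF diagnosis to first qualifying event or censoring.

    ``censor_date`` is a single administrative timestamp or a per-patient
    series (indexed by patient_id).  Events at or before diagnosis are
    excluded.  ``labels`` defaults to the patients' ``true_cluster`` column
    when present (useful for generator-level checks); pass the fitted
    clustering labels for the real pipeline.
    """
    pt = patients.set_index("patient_id") if "patient_id" in patients.columns \
        else patients
    if "hf_diagnosis_date" not in pt.columns:
        raise SurvivalError("patients need an hf_diagnosis_date column")
    diag = pd.to_datetime(pt["hf_diagnosis_date"])

    if isinstance(censor_date, pd.Series):
        censor = pd.to_datetime(censor_date).reindex(pt.index)
    else:
        censor = pd.Series(pd.Timestamp(censor_date), index=pt.index)
    late = censor <= diag
    if late.any():
        raise SurvivalError(
            "censor date not after diagnosis for patients: "
            f"{sorted(pt.index[late])[:10]}"
        )

    ev = events[events["event_type"] == outcome_type].copy()
    ev["event_date"] = pd.to_datetime(ev["event_date"])
    ev = ev[ev["patient_id"].isin(pt.index)]
    ev["diag"] = ev["patient_id"].map(diag)
    ev = ev[ev["event_date"] > ev["diag"]]  # at/before-diagnosis excluded
    first = ev.groupby("patient_id")["event_date"].min()

    event_flag = pt.index.isin(first.index).astype(int)
    end = pd.Series(first.reindex(pt.index))
    end = end.where(event_flag == 1, censor)
    duration = (pd.to_datetime(end) - diag).dt.days / 365.25
    duration = duration.clip(lower=1.0 / 365.25)  # same-day events: floor at 1 day

    if labels is None:
        if "true_cluster" not in pt.columns:
            raise SurvivalError("no labels supplied and no true_cluster column")
        labels = pt["true_cluster"]
    labels = pd.Series(np.asarray(labels), index=pt.index, name="cluster")

    data = pd.DataFrame({"duration": duration, "event": event_flag,
                         "cluster": labels.astype(int)})
    for c in covariates:
        if c in pt.columns:
            data[c] = pd.to_numeric(pt[c], errors="coerce")
    return SurvivalDataset(data=data, outcome_type=outcome_type)


def kaplan_meier(dataset: SurvivalDataset, group=None,
                 confidence: bool = True) -> KMCurve:
    """Product-limit estimator for one cluster (or ``group=None`` for all)."""
    df = dataset.data
    if group is not None:
        df = df[df["cluster"] == group]
        if df.empty:
            raise SurvivalError(f"cluster {group!r} has zero patients")
    kmf = KaplanMeierFitter()
    kmf.fit(df["duration"], df["event"])
    sf = kmf.survival_function_
    times = sf.index.to_numpy(dtype=float)
    at_risk = kmf.event_table["at_risk"].reindex(sf.index).to_numpy(dtype=float)
    curve = KMCurve(times=times, at_risk=at_risk,
                    survival=sf.iloc[:, 0].to_numpy(dtype=float), group=group)
    if confidence:
        ci = kmf.confidence_interval_
        curve.ci_lower = ci.iloc[:, 0].to_numpy(dtype=float)
        curve.ci_upper = ci.iloc[:, 1].to_numpy(dtype=float)
    return curve


def logrank_test(dataset: SurvivalDataset) -> tuple:
    """K-group log-rank chi-square (K-1 df) across clusters; (statistic, p)."""
    df = dataset.data
    groups = df["cluster"].unique()
    if len(groups) < 2:
        raise SurvivalError("log-rank needs at least two clusters")
    for g in groups:
        sub = df[df["cluster"] == g]
        if sub["duration"].sum() <= 0:
            raise SurvivalError(f"cluster {g} has zero at-risk time")
    res = multivariate_logrank_test(df["duration"], df["cluster"], df["event"])
    return float(res.test_statistic), float(res.p_value)


def _reference_cluster(df: pd.DataFrame) -> int:
    """Cluster with the lowest percentage of observed outcomes."""
    rates = df.groupby("cluster")["event"].mean()
    return int(rates.sort_values(kind="stable").index[0])


def cox_models(dataset: SurvivalDataset, models=(1, 2, 3),
               reference: int | None = None) -> list:
    """Fit the nested Cox specifications; HRs relative to the reference cluster.

    The reference defaults to the lowest-event-percentage cluster.  Covariates
    that are identically constant are dropped (with a warning) rather than
    fitted.  Raises :class:`SurvivalError` on non-convergence.
    """
    df = dataset.data.copy()
    if reference is None:
        reference = _reference_cluster(df)
    clusters = sorted(df["cluster"].unique())
    if reference not in clusters:
        raise SurvivalError(f"reference cluster {reference} not present")

    dummies = pd.get_dummies(df["cluster"], prefix="cluster").astype(float)
    dummies = dummies.drop(columns=f"cluster_{reference}")

    fits = []
    for m in models:
        if m not in MODEL_COVARIATES:
            raise SurvivalError(f"unknown model id {m}; expected 1, 2 or 3")
        covs = [c for c in MODEL_COVARIATES[m] if c in df.columns]
        X = pd.concat([df[["duration", "event"]], dummies,
                       df[covs]], axis=1)
        constant = [c for c in X.columns[2:] if X[c].nunique(dropna=True) <= 1]
        if constant:
            warnings.warn(f"dropping constant covariates: {constant}")
            X = X.drop(columns=constant)
        X = X.dropna()
        cph = CoxPHFitter()
        try:
            cph.fit(X, duration_col="duration", event_col="event")
        except Exception as exc:  # convergence / separation failures
            raise SurvivalError(f"Cox model {m} failed to converge: {exc}") from exc
        s = cph.summary
        summary = pd.DataFrame({
            "coef": s["coef"],
            "hr": s["exp(coef)"],
            "ci_lower": s["exp(coef) lower 95%"],
            "ci_upper": s["exp(coef) upper 95%"],
            "p": s["p"],
        })
        fits.append(CoxFit(model_id=m, outcome_type=dataset.outcome_type,
                           reference_cluster=reference, summary=summary))
    return fits
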