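"""Raw patient tables -> clustering feature matrix.

Implements the cohort-identification and preprocessing rules of the workflow:

* HF cohort identification from ICD-9 code prefixes and/or Portuguese
  free-text keywords (diacritic- and case-insensitive).
* Aggregation of longitudinal observations to one row per patient: labs/BMI
  averaged over all observations, age taken at the final observation,
  comorbidity flags ever-present (or restricted to the last observation year).
* Feature filters: binary features with cohort prevalence strictly below 2%
  are removed; any feature with strictly more than 40% missing values is
  removed.  Both thresholds are strict, so features exactly at the boundary
  are kept; every drop is logged in the audit trail.
* Chained-equation imputation of the remaining missing laboratory cells
  (round-robin ridge regressions of each incomplete column on all others).
  Observed cells are never altered.
* Scaling: continuous features z-scored (population sd); binary features
  mapped {0,1} -> {-0.5, +0.5}.
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import PreprocessingError

#: Default ICD-9 prefixes identifying heart failure (stored undotted; input
#: codes are normalised by stripping dots before prefix matching).
DEFAULT_HF_CODES = [
    "428", "39891", "40201", "40291", "40401", "40403", "40411", "40413",
    "40491", "40493", "4254", "4255", "4256", "4257", "4258", "4259",
]

#: Default free-text keywords: the Portuguese name of heart failure, its
#: abbreviations (IC, ICC, and the preserved/reduced ejection-fraction forms),
#: and any NYHA staging mention.
DEFAULT_HF_KEYWORDS = [
    "insuficiência cardíaca", "icfep", "icfer", "ic", "icc", "nyha",
]


def _normalize_text(s: str) -> str:
    """Casefold and strip diacritics (NFD decomposition, drop combining marks)."""
    decomposed = unicodedata.normalize("NFD", str(s))
    return "".join(ch for ch in decomposed if not unicodedata.combining(ch)).casefold()


def _normalize_code(code: str) -> str:
    return str(code).replace(".", "").strip()


@dataclass
class DiagnosisRecord:
    """One raw diagnosis row: ICD-9 code string and/or a free-text field."""

    patient_id: str
    icd9_code: str = ""
    free_text: str = ""


def identify_hf_patients(records, codes=None, keywords=None) -> set:
    """Return patient ids with at least one HF-matching diagnosis record.

    A record matches if its normalised (undotted) ICD-9 code starts with any
    code prefix, or its free text contains any keyword.  Keyword matching is
    case- and diacritic-insensitive and requires word boundaries, so the
    two-letter abbreviation "IC" does not fire inside unrelated words.
    """
    codes = DEFAULT_HF_CODES if codes is None else list(codes)
    keywords = DEFAULT_HF_KEYWORDS if keywords is None else list(keywords)
    if not codes and not keywords:
        raise PreprocessingError("need at least one ICD-9 prefix or keyword")

    prefixes = tuple(_normalize_code(c) for c in codes if str(c).strip())
    patterns = [
        re.compile(r"(?<!\w)" + re.escape(_normalize_text(k)) + r"(?!\w)")
        for k in keywords if str(k).strip()
    ]

    matched = set()
    for rec in records:
        if isinstance(rec, dict):
            rec = DiagnosisRecord(**rec)
        code = _normalize_code(rec.icd9_code or "")
        if code and code.startswith(prefixes):
            matched.add(rec.patient_id)
            continue
        if rec.free_text:
            text = _normalize_text(rec.free_text)
            if any(p.search(text) for p in patterns):
                matched.add(rec.patient_id)
    return matched


# ---------------------------------------------------------------------------
# Feature matrix container
# ---------------------------------------------------------------------------

@dataclass
class FeatureMatrix:
    """Patients x features grid plus per-column metadata and an audit trail.

    ``column_meta`` is indexed by feature name with columns ``kind``
    (continuous | binary), ``scaling`` (none | zscore | halfshift),
    ``prevalence`` (binary columns) and ``missing_frac`` (at construction).
    ``audit`` accumulates one dict per dropped column.
    """

    values: pd.DataFrame
    column_meta: pd.DataFrame
    audit: list = field(default_factory=list)

    @classmethod
    def from_cohort(cls, patients: pd.DataFrame, continuous, binary) -> "FeatureMatrix":
        cols = list(continuous) + list(binary)
        missing = [c for c in cols if c not in patients.columns]
        if missing:
            raise PreprocessingError(f"columns absent from patient table: {missing}")
        values = patients.set_index("patient_id")[cols].astype(float) \
            if "patient_id" in patients.columns else patients[cols].astype(float)
        bad = [c for c in binary
               if not values[c].dropna().isin([0.0, 1.0]).all()]
        if bad:
            raise PreprocessingError(f"binary columns with non-0/1 values: {bad}")
        meta = pd.DataFrame(index=cols)
        meta["kind"] = ["continuous"] * len(continuous) + ["binary"] * len(binary)
        meta["scaling"] = "none"
        meta["missing_frac"] = values.isna().mean()
        meta["prevalence"] = np.nan
        for c in binary:
            meta.loc[c, "prevalence"] = values[c].mean()
        return cls(values=values, column_meta=meta)

    @property
    def continuous_columns(self):
        return list(self.column_meta.index[self.column_meta["kind"] == "continuous"])

    @property
    def binary_columns(self):
        return list(self.column_meta.index[self.column_meta["kind"] == "binary"])

    def copy(self) -> "FeatureMatrix":
        return FeatureMatrix(self.values.copy(), self.column_meta.copy(),
                             list(self.audit))

    def audit_table(self) -> pd.DataFrame:
        return pd.DataFrame(self.audit, columns=["column", "rule", "value"])


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------

def aggregate_patient_features(observations: pd.DataFrame, continuous=(),
                               binary=(), id_col="patient_id",
                               date_col="date", window="ever") -> pd.DataFrame:
    """Collapse longitudinal observations to one row per patient.

    Continuous columns (labs, BMI) become the mean over all observations;
    ``age`` is taken from the chronologically last observation; binary
    comorbidity flags become 1 if present at any time (``window="ever"``,
    default) or within the last year of observation (``window="last-year"``).
    Patients with no observed value for a lab get a missing cell.
    """
    if window not in ("ever", "last-year"):
        raise PreprocessingError("window must be 'ever' or 'last-year'")
    obs = observations.copy()
    if date_col in obs.columns:
        obs[date_col] = pd.to_datetime(obs[date_col])
        obs = obs.sort_values([id_col, date_col], kind="stable")

    out = {}
    grouped = obs.groupby(id_col, sort=True)
    for col in continuous:
        if col == "age":
            out[col] = grouped[col].last()  # value at final observation
        elif col in obs.columns:
            out[col] = grouped[col].mean()
    if window == "last-year" and date_col in obs.columns:
        last = grouped[date_col].transform("max")
        recent = obs[obs[date_col] > last - pd.Timedelta(days=365)]
        rgrouped = recent.groupby(id_col, sort=True)
        for col in binary:
            out[col] = rgrouped[col].max().reindex(grouped.size().index).fillna(0)
    else:
        for col in binary:
            if col in obs.columns:
                out[col] = grouped[col].max()
    result = pd.DataFrame(out)
    result.index.name = id_col
    return result.reset_index()


# ---------------------------------------------------------------------------
# Filters, imputation, scaling
# ---------------------------------------------------------------------------

def filter_features(matrix: FeatureMatrix, prevalence_min: float = 0.02,
                    missing_max: float = 0.40) -> FeatureMatrix:
    """Drop rare binary features, then overly missing features (strict rules).

    A binary feature is dropped iff its prevalence is strictly below
    ``prevalence_min``; any feature is dropped iff its missing fraction is
    strictly above ``missing_max``.  Boundary values are kept.  Drops are
    appended to the audit trail.
    """
    out = matrix.copy()

    drop = []
    for c in out.binary_columns:
        prev = out.values[c].mean()
        if prev < prevalence_min:
            drop.append(c)
            out.audit.append({"column": c, "rule": "prevalence<min", "value": prev})
    out.values = out.values.drop(columns=drop)
    out.column_meta = out.column_meta.drop(index=drop)

    drop = []
    for c in out.values.columns:
        frac = out.values[c].isna().mean()
        if frac > missing_max:
            drop.append(c)
            out.audit.append({"column": c, "rule": "missing>max", "value": frac})
    out.values = out.values.drop(columns=drop)
    out.column_meta = out.column_meta.drop(index=drop)

    if out.values.shape[1] == 0:
        raise PreprocessingError("all feature columns were dropped by the filters")
    return out


def impute_chained(matrix: FeatureMatrix, max_iter: int = 10,
                   seed: int = 0, tol: float = 1e-3) -> FeatureMatrix:
    """Fill missing cells by chained ridge regressions (MICE-style).

    Each incomplete column is regressed round-robin on all other columns,
    iterating until ``max_iter`` sweeps or until the largest absolute change
    falls below ``tol``.  Observed cells are returned bit-identical.
    """
    from sklearn.experimental import enable_iterative_imputer  # noqa: F401
    from sklearn.impute import IterativeImputer
    from sklearn.linear_model import Ridge

    out = matrix.copy()
    values = out.values
    fully_missing = [c for c in values.columns if values[c].isna().all()]
    if fully_missing:
        raise PreprocessingError(
            f"columns entirely missing (should have been filtered): {fully_missing}"
        )
    if not values.isna().any().any():
        return out

    imputer = IterativeImputer(
        estimator=Ridge(alpha=1e-5), max_iter=max_iter, tol=tol,
        random_state=int(seed) % (2**31), sample_posterior=False,
        keep_empty_features=False,
    )
    filled = imputer.fit_transform(values.to_numpy())
    filled_df = pd.DataFrame(filled, index=values.index, columns=values.columns)
    # restore observed cells bit-identically (the imputer should not touch
    # them, but the contract is asserted here rather than trusted)
    mask = values.notna()
    filled_df = filled_df.where(~mask, values)
    out.values = filled_df
    return out


def scale_features(matrix: FeatureMatrix) -> FeatureMatrix:
    """Z-score continuous columns (population sd); map binaries to +-0.5."""
    out = matrix.copy()
    if out.values.isna().any().any():
        raise PreprocessingError("scaling requires a fully imputed matrix")
    for c in out.continuous_columns:
        col = out.values[c].to_numpy(dtype=float)
        sd = col.std()  # population sd (ddof=0)
        if sd == 0:
            raise PreprocessingError(f"zero-variance continuous column: {c!r}")
        out.values[c] = (col - col.mean()) / sd
        out.column_meta.loc[c, "scaling"] = "zscore"
    for c in out.binary_columns:
        col = out.values[c]
        if not col.isin([0.0, 1.0]).all():
            raise PreprocessingError(f"binary column {c!r} has non-0/1 values")
        out.values[c] = col - 0.5
        out.column_meta.loc[c, "scaling"] = "halfshift"
    return out


def preprocess(patients: pd.DataFrame, continuous, binary,
               prevalence_min: float = 0.02, missing_max: float = 0.40,
               max_iter: int = 10, seed: int = 0):
    """Full chain: build -> filter -> impute -> scale.

    Returns ``(imputed, scaled)`` feature matrices; ``imputed`` keeps the
    original units (the Gower pathway range-normalises internally), ``scaled``
    feeds the FAMD-free index computations.
    """
    fm = FeatureMatrix.from_cohort(patients, continuous, binary)
    fm = filter_features(fm, prevalence_min, missing_max)
    imputed = impute_chained(fm, max_iter=max_iter, seed=seed)
    scaled = scale_features(imputed)
    return imputed, scaled
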