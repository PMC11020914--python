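"""Synthetic EHR-like heart-failure cohorts with planted cluster structure.

The generator emulates the structure of a multimorbid HF cohort extracted from
hospital records: binary comorbidity flags with cluster-specific prevalences
and correlated co-occurrence, continuous laboratory values with cluster-shifted
means and configurable missingness, demographics, drug-prescription rows, and
time-to-admission outcomes with cluster-dependent hazards.  Every quantity is
parameterised through :class:`CohortSpec`, so downstream stages (preprocessing,
clustering, disease networks, survival) can be tested against known ground
truth and parameter recovery can be asserted.

Mechanisms
----------
* Comorbidity flags: Gaussian copula — a latent multivariate normal per cluster
  thresholded at each disease's marginal quantile, giving exact Bernoulli
  marginals with controllable pairwise co-occurrence.
* Event times: exponential with rate ``baseline_rate x hazard_multiplier`` of
  the patient's cluster, so the proportional-hazards assumption holds exactly
  and Cox hazard-ratio recovery is a well-posed check.  Patients whose first
  event falls beyond the censoring horizon contribute no event row.
* Missingness: MCAR by default; optional MAR variant where the missingness
  probability is logistic in (standardised) age, rescaled to keep the average
  missing fraction at the configured rate.

All defaults are stand-ins chosen to be clinically plausible; they are study
conditions of this artifact, not estimates from any real cohort.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import SpecError

#: The eleven tracked comorbidities (ischemic cardiomyopathy, other
#: cardiomyopathy, hypertension, diabetes, atrial fibrillation, transient
#: ischemic attack / cerebrovascular disease, valvular disease, chronic kidney
#: disease, anaemia, COPD, obesity).
DEFAULT_COMORBIDITIES = [
    "ICM", "CM", "HT", "Diabetes", "AF", "TIA", "VD", "CKD",
    "Anaemia", "COPD", "Obesity",
]

#: Outcome event types: unplanned hospital admissions.
OUTCOME_TYPES = ("hospitalisation", "emergency")

#: Example drug identifiers per pharmacological group, used when emitting
#: prescription rows so the drug -> group mapping stage is exercised.
DRUG_EXAMPLES = {
    "acei_arb": ["lisinopril", "ramipril", "losartan"],
    "beta_blocker": ["bisoprolol", "carvedilol"],
    "diuretic": ["furosemide", "hydrochlorothiazide"],
    "digoxin": ["digoxin"],
    "mra": ["spironolactone", "eplerenone"],
    "anticoagulant": ["warfarin", "apixaban"],
    "antiplatelet": ["aspirin", "clopidogrel"],
    "statin": ["atorvastatin", "simvastatin"],
    "bronchodilator": ["salbutamol", "tiotropium"],
    "hematinic": ["ferrous-sulfate", "darbepoetin"],
    "anticholinergic": ["oxybutynin"],
}


@dataclass
class LabSpec:
    """Per-cluster (mean, sd) for one continuous feature plus its missing rate."""

    means: tuple
    sds: tuple
    missing_rate: float = 0.0


@dataclass
class CohortSpec:
    """Full parameterisation of a synthetic multimorbid HF cohort."""

    n_patients: int = 2000
    n_clusters: int = 4
    mixing_proportions: tuple = (0.21, 0.23, 0.33, 0.23)
    comorbidity_names: list = field(default_factory=lambda: list(DEFAULT_COMORBIDITIES))
    prevalence_matrix: np.ndarray | None = None  # clusters x diseases
    copula_correlation: np.ndarray | None = None  # clusters x diseases x diseases
    lab_specs: dict = field(default_factory=dict)  # name -> LabSpec
    age_specs: tuple = ((85.0, 6.0), (80.0, 6.0), (83.0, 6.0), (66.0, 7.0))
    female_prob: tuple = (0.37, 0.64, 0.41, 0.74)
    hazard_multipliers: dict = field(
        default_factory=lambda: {
            "hospitalisation": (4.0, 2.5, 2.0, 1.0),
            "emergency": (2.6, 2.0, 1.3, 1.0),
        }
    )
    baseline_rate: dict | float = field(
        default_factory=lambda: {"hospitalisation": 0.12, "emergency": 0.35}
    )
    censor_horizon: float = 5.0  # years
    missing_mechanism: str = "mcar"  # or "mar" (logistic in age)
    prescription_rates: dict = field(
        default_factory=lambda: {g: 0.4 for g in DRUG_EXAMPLES}
    )
    prescription_multipliers: tuple = (2.2, 1.6, 1.0, 0.7)
    diagnosis_window: tuple = ("2012-01-01", "2016-06-30")
    lookback_years: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.prevalence_matrix is None:
            self.prevalence_matrix = _default_prevalence_matrix()
        self.prevalence_matrix = np.asarray(self.prevalence_matrix, dtype=float)
        if self.copula_correlation is None:
            d = len(self.comorbidity_names)
            self.copula_correlation = np.stack(
                [exchangeable_correlation(d, 0.03)] * self.n_clusters
            )
        self.copula_correlation = np.asarray(self.copula_correlation, dtype=float)
        if not self.lab_specs:
            self.lab_specs = _default_lab_specs()

    # -- validation ----------------------------------------------------------

    def validate(self):
        """Raise :class:`SpecError` on any violated invariant."""
        k, d = self.n_clusters, len(self.comorbidity_names)
        if self.n_patients <= 0 or k <= 0:
            raise SpecError("n_patients and n_clusters must be positive")
        pi = np.asarray(self.mixing_proportions, dtype=float)
        if pi.shape != (k,) or np.any(pi < 0) or abs(pi.sum() - 1.0) > 1e-9:
            raise SpecError(
                f"mixing_proportions must be a length-{k} simplex vector "
                f"(got sum {pi.sum()!r})"
            )
        if self.prevalence_matrix.shape != (k, d):
            raise SpecError(
                f"prevalence_matrix must be {k}x{d}, got {self.prevalence_matrix.shape}"
            )
        if np.any((self.prevalence_matrix < 0) | (self.prevalence_matrix > 1)):
            raise SpecError("prevalences must lie in [0, 1]")
        if self.copula_correlation.shape != (k, d, d):
            raise SpecError(
                f"copula_correlation must be {k}x{d}x{d}, "
                f"got {self.copula_correlation.shape}"
            )
        for c in range(k):
            R = self.copula_correlation[c]
            if not np.allclose(R, R.T, atol=1e-10):
                raise SpecError(f"copula correlation for cluster {c} is not symmetric")
            if not np.allclose(np.diag(R), 1.0, atol=1e-10):
                raise SpecError(f"copula correlation for cluster {c} lacks unit diagonal")
            if np.linalg.eigvalsh(R).min() < -1e-8:
                raise SpecError(
                    f"copula correlation for cluster {c} is not positive semi-definite"
                )
        for name, lab in self.lab_specs.items():
            if len(lab.means) != k or len(lab.sds) != k:
                raise SpecError(f"lab {name!r} needs {k} per-cluster (mean, sd) entries")
            if any(s < 0 for s in lab.sds):
                raise SpecError(f"lab {name!r} has a negative sd")
            if not 0.0 <= lab.missing_rate <= 1.0:
                raise SpecError(f"lab {name!r} missing_rate outside [0, 1]")
        if any(not 0.0 <= p <= 1.0 for p in self.female_prob):
            raise SpecError("female_prob entries must lie in [0, 1]")
        for outcome, rate in self._baseline_rates().items():
            if rate <= 0:
                raise SpecError(f"baseline_rate for {outcome!r} must be positive")
        for outcome, mults in self.hazard_multipliers.items():
            if len(mults) != k or any(m < 0 for m in mults):
                raise SpecError(
                    f"hazard_multipliers[{outcome!r}] needs {k} nonnegative entries"
                )
        if self.censor_horizon <= 0:
            raise SpecError("censor_horizon must be positive")
        if self.missing_mechanism not in ("mcar", "mar"):
            raise SpecError("missing_mechanism must be 'mcar' or 'mar'")

    def _baseline_rates(self) -> dict:
        if isinstance(self.baseline_rate, dict):
            return dict(self.baseline_rate)
        return {o: float(self.baseline_rate) for o in self.hazard_multipliers}

    # -- (de)serialisation ---------------------------------------------------

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["prevalence_matrix"] = self.prevalence_matrix.tolist()
        out["copula_correlation"] = self.copula_correlation.tolist()
        out["lab_specs"] = {
            name: {"means": list(l.means), "sds": list(l.sds),
                   "missing_rate": l.missing_rate}
            for name, l in self.lab_specs.items()
        }
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "CohortSpec":
        d = dict(d)
        labs = d.pop("lab_specs", None)
        spec = cls(**d)
        if labs:
            spec.lab_specs = {
                name: LabSpec(tuple(v["means"]), tuple(v["sds"]),
                              float(v.get("missing_rate", 0.0)))
                for name, v in labs.items()
            }
        return spec


def exchangeable_correlation(d: int, rho: float) -> np.ndarray:
    """d x d correlation matrix with constant off-diagonal ``rho``."""
    R = np.full((d, d), rho, dtype=float)
    np.fill_diagonal(R, 1.0)
    return R


def _default_prevalence_matrix() -> np.ndarray:
    """Four qualitative archetypes of multimorbid HF subgroups.

    Rows: (0) high-burden cardio-renal (CKD + anaemia + hypertension),
    (1) hypertension / atrial-fibrillation / obesity, (2) anaemia-dominant,
    (3) low-burden.  Contrasts between clusters are deliberately strong
    (>= 0.6 on the discriminating diseases).
    Columns follow :data:`DEFAULT_COMORBIDITIES`.
    """
    return np.array([
        # ICM    CM    HT   Diab   AF   TIA    VD   CKD   Anae  COPD  Obes
        [0.90, 0.05, 0.95, 0.85, 0.90, 0.10, 0.85, 0.95, 0.95, 0.10, 0.10],
        [0.08, 0.85, 0.97, 0.08, 0.95, 0.08, 0.08, 0.08, 0.05, 0.08, 0.95],
        [0.85, 0.05, 0.10, 0.08, 0.08, 0.70, 0.08, 0.08, 0.97, 0.70, 0.05],
        [0.04, 0.03, 0.04, 0.02, 0.04, 0.03, 0.04, 0.02, 0.02, 0.03, 0.04],
    ])


def _default_lab_specs() -> dict:
    """Cluster-shifted laboratory profiles; discriminating labs shift >= 2 sd."""
    return {
        "bmi": LabSpec((26.0, 31.0, 24.2, 24.5), (2.2, 2.2, 2.0, 2.2), 0.10),
        "sodium": LabSpec((137.0, 140.0, 139.0, 141.0), (2.2,) * 4, 0.10),
        "urea": LabSpec((90.0, 48.0, 62.0, 40.0), (13.0, 9.0, 10.0, 8.0), 0.15),
        "creatinine": LabSpec((1.95, 1.05, 1.30, 0.90), (0.33, 0.20, 0.24, 0.18), 0.15),
        "hemoglobin": LabSpec((10.0, 13.4, 10.8, 14.0), (1.1, 1.1, 1.1, 1.1), 0.10),
        "platelets": LabSpec((180.0, 225.0, 230.0, 262.0), (45.0,) * 4, 0.20),
        "rdw": LabSpec((16.2, 14.2, 15.3, 13.9), (0.85, 0.75, 0.8, 0.7), 0.25),
        "nt_probnp": LabSpec((9500.0, 1600.0, 4800.0, 1300.0),
                             (2200.0, 700.0, 1200.0, 600.0), 0.35),
    }


def default_cohort_spec(n_patients: int = 2000, seed: int = 0, **overrides) -> CohortSpec:
    """The default four-cluster study condition, with optional field overrides."""
    spec = CohortSpec(n_patients=n_patients, seed=seed, **overrides)
    spec.validate()
    return spec


def uniform_cohort_spec(n_patients: int, n_clusters: int = 1, seed: int = 0, *,
                        prevalence_matrix=None, copula_correlation=None,
                        hazard_multipliers=None, baseline_rate=None,
                        lab_missing: float = 0.2,
                        censor_horizon: float = 5.0) -> CohortSpec:
    """A minimal spec with exchangeable clusters, for calibration experiments.

    All clusters share demographics and labs; only the prevalence matrix,
    copula, and hazard multipliers (if given) differ.  Handy for building
    single-cluster or two-cluster designs with known closed-form behaviour.
    """
    k = n_clusters
    d = len(DEFAULT_COMORBIDITIES)
    if prevalence_matrix is None:
        prevalence_matrix = np.full((k, d), 0.3)
    if copula_correlation is None:
        copula_correlation = np.stack([np.eye(d)] * k)
    if hazard_multipliers is None:
        hazard_multipliers = {o: (1.0,) * k for o in OUTCOME_TYPES}
    if baseline_rate is None:
        baseline_rate = {"hospitalisation": 0.12, "emergency": 0.35}
    labs = {
        "bmi": LabSpec((26.0,) * k, (3.0,) * k, lab_missing),
        "hemoglobin": LabSpec((12.5,) * k, (1.3,) * k, lab_missing),
        "nt_probnp": LabSpec((3000.0,) * k, (1500.0,) * k, lab_missing),
    }
    spec = CohortSpec(
        n_patients=n_patients, n_clusters=k,
        mixing_proportions=(1.0 / k,) * k,
        prevalence_matrix=np.asarray(prevalence_matrix, dtype=float),
        copula_correlation=np.asarray(copula_correlation, dtype=float),
        lab_specs=labs, age_specs=((78.0, 8.0),) * k,
        female_prob=(0.5,) * k, hazard_multipliers=hazard_multipliers,
        baseline_rate=baseline_rate, censor_horizon=censor_horizon,
        prescription_multipliers=(1.0,) * k, seed=seed,
    )
    spec.validate()
    return spec


# ---------------------------------------------------------------------------
# Cohort container
# ---------------------------------------------------------------------------

@dataclass
class Cohort:
    """A generated cohort: patients, admission events, prescription rows.

    ``patients`` carries a hidden ``true_cluster`` column (generator ground
    truth) which is excluded from every clustering input.
    """

    patients: pd.DataFrame
    events: pd.DataFrame
    prescriptions: pd.DataFrame
    spec: CohortSpec | None = None

    def write_csv(self, out_dir) -> dict:
        """Write patients/events/prescriptions CSVs; returns {name: path}."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name, df in [("patients", self.patients), ("events", self.events),
                         ("prescriptions", self.prescriptions)]:
            p = out / f"{name}.csv"
            df.to_csv(p, index=False)
            paths[name] = p
        return paths

    @classmethod
    def read_csv(cls, in_dir) -> "Cohort":
        d = Path(in_dir)
        kw = {}
        for name, dates in [("patients", ["hf_diagnosis_date", "observation_end"]),
                            ("events", ["event_date"]),
                            ("prescriptions", ["date"])]:
            df = pd.read_csv(d / f"{name}.csv")
            for col in dates:
                if col in df.columns:
                    df[col] = pd.to_datetime(df[col])
            kw[name] = df
        return cls(**kw)


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def _rng(seed: int, stream: int) -> np.random.Generator:
    # independent streams so generate_events is deterministic regardless of
    # how much randomness generate_cohort consumed
    return np.random.default_rng([int(seed) % (2**31), stream])


def _sample_correlated_binaries(rng, R, probs, n, cluster_id):
    """Gaussian copula: latent MVN(0, R) thresholded at marginal quantiles."""
    from scipy import stats

    d = len(probs)
    vals, vecs = np.linalg.eigh(R)
    if vals.min() < -1e-8:
        raise SpecError(
            f"copula correlation for cluster {cluster_id} is not positive semi-definite"
        )
    L = vecs * np.sqrt(np.clip(vals, 0.0, None))
    z = rng.standard_normal((n, d)) @ L.T
    thresholds = stats.norm.ppf(np.clip(probs, 0.0, 1.0))
    return (z <= thresholds).astype(int)


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Generate the patient table (and prescriptions) for ``spec``.

    Returns a :class:`Cohort` whose ``events`` table is empty; call
    :func:`generate_events` (or :func:`simulate_cohort`) to add admissions.
    """
    spec.validate()
    n, k = spec.n_patients, spec.n_clusters
    rng = _rng(spec.seed, 0)

    cluster = rng.choice(k, size=n, p=np.asarray(spec.mixing_proportions, float))
    patients = pd.DataFrame({
        "patient_id": [f"P{i:06d}" for i in range(n)],
        "true_cluster": cluster,
    })

    age_mu = np.array([spec.age_specs[c][0] for c in cluster])
    age_sd = np.array([spec.age_specs[c][1] for c in cluster])
    patients["age"] = np.clip(rng.normal(age_mu, age_sd), 18.0, 105.0).round(1)
    patients["gender"] = (
        rng.random(n) < np.array([spec.female_prob[c] for c in cluster])
    ).astype(int)  # 1 = female

    # comorbidity flags per cluster via the Gaussian copula
    flags = np.zeros((n, len(spec.comorbidity_names)), dtype=int)
    for c in range(k):
        idx = np.flatnonzero(cluster == c)
        if idx.size == 0:
            continue
        flags[idx] = _sample_correlated_binaries(
            rng, spec.copula_correlation[c], spec.prevalence_matrix[c], idx.size, c
        )
    for j, name in enumerate(spec.comorbidity_names):
        patients[name] = flags[:, j]

    # continuous labs with configured missingness
    age_z = (patients["age"] - patients["age"].mean()) / max(patients["age"].std(), 1e-9)
    for name, lab in spec.lab_specs.items():
        mu = np.array([lab.means[c] for c in cluster])
        sd = np.array([lab.sds[c] for c in cluster])
        vals = rng.normal(mu, sd)
        if lab.missing_rate > 0:
            if spec.missing_mechanism == "mar":
                w = 1.0 / (1.0 + np.exp(-age_z.to_numpy()))
                p = np.clip(lab.missing_rate * w / w.mean(), 0.0, 1.0)
            else:
                p = np.full(n, lab.missing_rate)
            vals[rng.random(n) < p] = np.nan
        patients[name] = np.round(vals, 4)

    # diagnosis dates and per-patient end of observation
    start = pd.Timestamp(spec.diagnosis_window[0])
    end = pd.Timestamp(spec.diagnosis_window[1])
    offsets = rng.integers(0, (end - start).days + 1, size=n)
    diag = start + pd.to_timedelta(offsets, unit="D")
    patients["hf_diagnosis_date"] = diag
    patients["observation_end"] = diag + pd.Timedelta(
        days=int(round(spec.censor_horizon * 365.25))
    )

    prescriptions = _generate_prescriptions(spec, patients, cluster)
    events = pd.DataFrame(columns=["patient_id", "event_type", "event_date"])
    return Cohort(patients=patients, events=events, prescriptions=prescriptions,
                  spec=spec)


def _generate_prescriptions(spec, patients, cluster):
    rng = _rng(spec.seed, 2)
    years = spec.censor_horizon
    rows = []
    mults = np.asarray(spec.prescription_multipliers, float)
    for group, base in spec.prescription_rates.items():
        drugs = DRUG_EXAMPLES.get(group, [group])
        lam = base * mults[cluster] * years
        counts = rng.poisson(lam)
        for i in np.flatnonzero(counts):
            pid = patients["patient_id"].iat[i]
            diag = patients["hf_diagnosis_date"].iat[i]
            span = max(int(round(years * 365.25)), 1)
            for _ in range(counts[i]):
                rows.append({
                    "patient_id": pid,
                    "drug": drugs[rng.integers(len(drugs))],
                    "date": diag + pd.Timedelta(days=int(rng.integers(0, span))),
                })
    cols = ["patient_id", "drug", "date"]
    return pd.DataFrame(rows, columns=cols).sort_values(cols).reset_index(drop=True)


def generate_events(cohort: Cohort, spec: CohortSpec) -> Cohort:
    """Draw first unplanned-admission times per outcome type.

    First-event times are exponential with rate ``baseline_rate x
    hazard_multiplier[true_cluster]``; times beyond ``censor_horizon`` produce
    no event row (administratively censored).  Deterministic given the spec
    seed, independent of :func:`generate_cohort`'s own random stream.
    """
    spec.validate()
    patients = cohort.patients
    if "hf_diagnosis_date" not in patients or "true_cluster" not in patients:
        raise SpecError("cohort lacks hf_diagnosis_date / true_cluster columns")
    rng = _rng(spec.seed, 1)
    cluster = patients["true_cluster"].to_numpy()
    rows = []
    rates = spec._baseline_rates()
    for outcome in spec.hazard_multipliers:
        mult = np.asarray(spec.hazard_multipliers[outcome], float)[cluster]
        rate = rates[outcome] * mult
        # inverse-CDF draw: one uniform per patient
        u = rng.random(len(patients))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(rate > 0, -np.log(u) / rate, np.inf)
        observed = t <= spec.censor_horizon
        for i in np.flatnonzero(observed):
            rows.append({
                "patient_id": patients["patient_id"].iat[i],
                "event_type": outcome,
                "event_date": patients["hf_diagnosis_date"].iat[i]
                + pd.Timedelta(days=int(round(t[i] * 365.25))),
            })
    events = pd.DataFrame(rows, columns=["patient_id", "event_type", "event_date"])
    events = events.sort_values(["patient_id", "event_type"]).reset_index(drop=True)
    return Cohort(patients=patients, events=events,
                  prescriptions=cohort.prescriptions, spec=spec)


def simulate_cohort(spec: CohortSpec) -> Cohort:
    """Convenience: :func:`generate_cohort` followed by :func:`generate_events`."""
    return generate_events(generate_cohort(spec), spec)
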