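"""End-to-end pipeline: simulate/ingest -> preprocess -> cluster -> select ->
network -> profile -> survival.

Each stage reads only the previous stage's on-disk outputs and writes its own
artifacts under the configured output directory, so stages can be rerun in
isolation.  A manifest (``manifest.json``) records the seed, package
versions, and a SHA-256 digest of every artifact; rerunning the same config
and seed reproduces identical digests for the deterministic stages.

One global seed deterministically derives per-stage seeds, so an individual
stage rerun sees the same randomness as a full pipeline run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import clustering, model_selection, network, preprocessing, profiles, survival
from .errors import HfclustError
from .synthetic import Cohort, CohortSpec, default_cohort_spec

log = logging.getLogger("hfclust")

STAGES = ("simulate", "preprocess", "cluster", "select", "network",
          "profile", "survival")


@dataclass
class PipelineConfig:
    """Single configuration object driving every stage."""

    out_dir: str = "hfclust_out"
    seed: int = 0
    input_dir: str | None = None  # pre-existing cohort CSVs; else simulate
    simulate: dict = field(default_factory=dict)  # CohortSpec overrides
    prevalence_min: float = 0.02
    missing_max: float = 0.40
    impute_max_iter: int = 10
    methods: tuple = clustering.METHODS
    k_min: int = 2
    k_max: int = 12
    size_floor: object = None  # None -> max(375, 10% of n)
    famd_components: int | None = None
    pdn_threshold: float = 0.02
    outcomes: tuple = ("hospitalisation", "emergency")
    prefer_k: int | None = None

    def __post_init__(self):
        if self.k_min < 2 or self.k_max < self.k_min:
            raise HfclustError("need 2 <= k_min <= k_max")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            import yaml

            raw = yaml.safe_load(text)
        else:
            raw = json.loads(text)
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["methods"] = list(self.methods)
        d["outcomes"] = list(self.outcomes)
        return d


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    return (int(seed) * 1_000_003 + STAGES.index(stage)) % (2**31)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def stage_simulate(config: PipelineConfig) -> dict:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if config.input_dir:
        cohort = Cohort.read_csv(config.input_dir)
        spec = None
    else:
        overrides = dict(config.simulate)
        overrides.setdefault("seed", stage_seed(config.seed, "simulate"))
        spec = default_cohort_spec(**overrides)
        from .synthetic import simulate_cohort

        cohort = simulate_cohort(spec)
    paths = cohort.write_csv(out)
    continuous = ["age"] + (list(spec.lab_specs) if spec else
                            _infer_continuous(cohort.patients))
    binary = ["gender"] + (list(spec.comorbidity_names) if spec else
                           _infer_binary(cohort.patients))
    columns = {"continuous": continuous, "binary": binary}
    (out / "columns.json").write_text(json.dumps(columns, indent=1))
    paths["columns"] = out / "columns.json"
    return {str(k): Path(v) for k, v in paths.items()}


def _infer_continuous(patients):
    skip = {"patient_id", "true_cluster", "gender", "age"}
    return ["age"] * 0 + [
        c for c in patients.columns
        if c not in skip and patients[c].dtype.kind == "f"
        and not patients[c].dropna().isin([0.0, 1.0]).all()
    ]


def _infer_binary(patients):
    skip = {"patient_id", "true_cluster", "gender"}
    return [c for c in patients.columns
            if c not in skip and patients[c].dropna().isin([0, 1]).all()
            and patients[c].dtype.kind in "if"]


def stage_preprocess(config: PipelineConfig) -> dict:
    out = Path(config.out_dir)
    patients = pd.read_csv(out / "patients.csv")
    columns = json.loads((out / "columns.json").read_text())
    imputed, scaled = preprocessing.preprocess(
        patients, columns["continuous"], columns["binary"],
        prevalence_min=config.prevalence_min, missing_max=config.missing_max,
        max_iter=config.impute_max_iter,
        seed=stage_seed(config.seed, "preprocess"),
    )
    paths = {}
    for name, fm in [("features_imputed", imputed), ("features_scaled", scaled)]:
        p = out / f"{name}.csv"
        fm.values.to_csv(p)
        paths[name] = p
    meta = imputed.column_meta.copy()
    meta.index.name = "feature"
    meta.to_csv(out / "feature_meta.csv")
    imputed.audit_table().to_csv(out / "feature_audit.csv", index=False)
    paths["feature_meta"] = out / "feature_meta.csv"
    paths["feature_audit"] = out / "feature_audit.csv"
    return paths


def _load_feature_matrices(out: Path):
    meta = pd.read_csv(out / "feature_meta.csv", index_col="feature")
    mats = {}
    for name in ("features_imputed", "features_scaled"):
        vals = pd.read_csv(out / f"{name}.csv", index_col=0)
        mats[name] = preprocessing.FeatureMatrix(
            values=vals, column_meta=meta.loc[vals.columns].copy()
        )
    return mats["features_imputed"], mats["features_scaled"]


def stage_cluster(config: PipelineConfig) -> dict:
    out = Path(config.out_dir)
    imputed, scaled = _load_feature_matrices(out)
    seed = stage_seed(config.seed, "cluster")

    gower = clustering.gower_matrix(imputed)
    np.save(out / "gower.npy", gower.values)
    embedding = clustering.famd_embed(imputed, n_components=config.famd_components)
    embedding.to_csv(out / "famd_embedding.csv")

    rows = []
    ks = range(config.k_min, config.k_max + 1)
    for method in config.methods:
        for k in ks:
            res = clustering.cluster_pathway(
                method, k, gower=gower, embedding=embedding, seed=seed)
            for pid, lab in zip(imputed.values.index, res.labels):
                rows.append({"patient_id": pid, "method": method, "k": k,
                             "label": int(lab)})
    labels = pd.DataFrame(rows)
    labels.to_csv(out / "labels.csv", index=False)
    return {"gower": out / "gower.npy", "famd_embedding": out / "famd_embedding.csv",
            "labels": out / "labels.csv"}


def stage_select(config: PipelineConfig) -> dict:
    out = Path(config.out_dir)
    imputed, scaled = _load_feature_matrices(out)
    gower = clustering.DistanceMatrix(np.load(out / "gower.npy"),
                                      index=imputed.values.index)
    embedding = pd.read_csv(out / "famd_embedding.csv", index_col=0)
    report = model_selection.evaluate_configurations(
        gower=gower, embedding=embedding, index_features=scaled.values,
        methods=config.methods, k_range=range(config.k_min, config.k_max + 1),
        seed=stage_seed(config.seed, "cluster"), size_floor=config.size_floor,
    )
    if config.prefer_k is not None:
        admissible = report.table[report.table["admissible"]
                                  & (report.table["k"] == config.prefer_k)]
        if admissible.empty:
            raise HfclustError(f"prefer_k={config.prefer_k} is not admissible")
        best = admissible.sort_values("silhouette", ascending=False).iloc[0]
        chosen = (best["method"], int(best["k"]))
        report.chosen = chosen
    else:
        chosen = model_selection.majority_vote(report)
    report.to_csv(out / "selection_report.csv")
    (out / "chosen.json").write_text(json.dumps(
        {"method": chosen[0], "k": chosen[1],
         "winners": {k: list(v) for k, v in (report.winners or {}).items()}},
        indent=1))

    labels = pd.read_csv(out / "labels.csv")
    sel = labels[(labels["method"] == chosen[0]) & (labels["k"] == chosen[1])]
    sel[["patient_id", "label"]].to_csv(out / "chosen_labels.csv", index=False)
    return {"selection_report": out / "selection_report.csv",
            "chosen": out / "chosen.json",
            "chosen_labels": out / "chosen_labels.csv"}


def _chosen_labels(out: Path) -> pd.Series:
    df = pd.read_csv(out / "chosen_labels.csv")
    return df.set_index("patient_id")["label"]


def stage_network(config: PipelineConfig) -> dict:
    out = Path(config.out_dir)
    patients = pd.read_csv(out / "patients.csv").set_index("patient_id")
    columns = json.loads((out / "columns.json").read_text())
    comorbidities = [c for c in columns["binary"] if c != "gender"]
    labels = _chosen_labels(out).reindex(patients.index)
    flags = patients[comorbidities]

    nets = network.per_cluster_networks(flags, labels.to_numpy(),
                                        edge_threshold=config.pdn_threshold)
    paths, metric_rows = {}, []
    ndir = out / "networks"
    for key, net in nets.items():
        name = "cohort" if key == "all" else f"cluster{key}"
        paths.update({f"{name}_{k}": v for k, v in
                      network.export_network(net, ndir / name).items()})
        metric_rows.append({
            "subset": name,
            "n_patients": net.n_patients,
            "nodes": net.graph.number_of_nodes(),
            "edges": net.graph.number_of_edges(),
            "average_degree": network.average_degree(net),
            "average_clustering": network.average_clustering(net),
        })
    pd.DataFrame(metric_rows).to_csv(out / "network_metrics.csv", index=False)
    paths["network_metrics"] = out / "network_metrics.csv"
    return paths


def stage_profile(config: PipelineConfig) -> dict:
    out = Path(config.out_dir)
    patients = pd.read_csv(out / "patients.csv",
                           parse_dates=["hf_diagnosis_date", "observation_end"]
                           ).set_index("patient_id")
    columns = json.loads((out / "columns.json").read_text())
    labels = _chosen_labels(out).reindex(patients.index)

    prof = profiles.summarize_clusters(
        patients, labels.to_numpy(),
        continuous=columns["continuous"], binary=columns["binary"])
    prof.to_csv(out / "profile_clusters.csv")
    paths = {"profile_clusters": out / "profile_clusters.csv"}

    presc_path = out / "prescriptions.csv"
    if presc_path.exists():
        presc = pd.read_csv(presc_path, parse_dates=["date"])
        years = float(
            ((patients["observation_end"] - patients["hf_diagnosis_date"])
             .dt.days / 365.25).mean()
        )
        ptab = profiles.summarize_prescriptions(
            presc, profiles.load_drug_group_map(), labels, observation_years=years)
        ptab.to_csv(out / "profile_prescriptions.csv")
        paths["profile_prescriptions"] = out / "profile_prescriptions.csv"

    events_path = out / "events.csv"
    if events_path.exists():
        events = pd.read_csv(events_path, parse_dates=["event_date"])
        atab = profiles.summarize_admissions(
            events, labels, patients["hf_diagnosis_date"],
            patients["observation_end"])
        atab.to_csv(out / "profile_admissions.csv")
        paths["profile_admissions"] = out / "profile_admissions.csv"
    return paths


def stage_survival(config: PipelineConfig) -> dict:
    out = Path(config.out_dir)
    patients = pd.read_csv(out / "patients.csv",
                           parse_dates=["hf_diagnosis_date", "observation_end"])
    events = pd.read_csv(out / "events.csv", parse_dates=["event_date"])
    labels = _chosen_labels(out)
    paths = {}
    for outcome in config.outcomes:
        ds = survival.build_survival_dataset(
            patients, events, outcome,
            censor_date=patients.set_index("patient_id")["observation_end"],
            labels=labels.reindex(patients["patient_id"]).to_numpy(),
        )
        curves = []
        for c in sorted(ds.data["cluster"].unique()):
            frame = survival.kaplan_meier(ds, group=c).to_frame()
            frame.insert(0, "cluster", c)
            curves.append(frame)
        km_path = out / f"km_{outcome}.csv"
        pd.concat(curves).to_csv(km_path, index=False)
        paths[f"km_{outcome}"] = km_path

        stat, p = survival.logrank_test(ds)
        fits = survival.cox_models(ds)
        rows = []
        for fit in fits:
            for cov, r in fit.summary.iterrows():
                rows.append({"model": fit.model_id, "covariate": cov,
                             "reference_cluster": fit.reference_cluster,
                             **r.to_dict()})
        cox_path = out / f"cox_{outcome}.csv"
        pd.DataFrame(rows).to_csv(cox_path, index=False)
        paths[f"cox_{outcome}"] = cox_path
        (out / f"logrank_{outcome}.json").write_text(
            json.dumps({"statistic": stat, "p_value": p}, indent=1))
        paths[f"logrank_{outcome}"] = out / f"logrank_{outcome}.json"
    return paths


STAGE_FUNCS = {
    "simulate": stage_simulate,
    "preprocess": stage_preprocess,
    "cluster": stage_cluster,
    "select": stage_select,
    "network": stage_network,
    "profile": stage_profile,
    "survival": stage_survival,
}


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages in order and write ``manifest.json``.

    Any stage error aborts with the stage name; artifacts written by earlier
    stages are retained on disk.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"seed": config.seed, "config": config.to_dict(), "stages": {}}
    import hfclust

    manifest["versions"] = {"hfclust": hfclust.__version__,
                            "numpy": np.__version__, "pandas": pd.__version__}
    for stage in STAGES:
        log.info("running stage %s", stage)
        try:
            paths = STAGE_FUNCS[stage](config)
        except Exception as exc:
            raise HfclustError(f"stage {stage!r} failed: {exc}") from exc
        manifest["stages"][stage] = {
            name: {"path": str(p), "sha256": _sha256(Path(p))}
            for name, p in paths.items()
        }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
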