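"""End-to-end orchestration: cohort -> labels -> risk -> clusters -> tables.

``run_pipeline`` executes every stage on a synthetic or ingested cohort,
writes each intermediate artifact into the run directory together with a
manifest (package/library versions, seeds, config hash) and a structured
log, and returns the in-memory results. Every stochastic stage derives its
seed from the single run seed, so a run is reproducible from its config.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classify import ClassifierEval, evaluate_accuracy_vs_duration
from .cluster import ClusterParams, ClusterResult, order_clusters_by_outcome, \
    spectral_clustering
from .exceptions import ShocktrajError
from .io import read_cohort, write_cohort
from .label import label_cohort, timelines_frame
from .records import GroundTruth, PatientRecord
from .risk import RiskModel, RiskModelConfig, build_training_set, \
    crossfit_risk_models, detect_t_d, select_threshold, train_risk_model
from .strata import cluster_outcome_table, intervention_offset_by_cluster
from .synth import SynthConfig
from .traj import TrajectoryMatrix, align_trajectories

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    synth: SynthConfig | None = None
    input_dir: str | None = None  # cohort CSVs written by write_cohort
    anchor_kind: str = "early_prediction"
    window: tuple[float, float] | None = None
    cluster: ClusterParams = field(default_factory=ClusterParams)
    risk: RiskModelConfig = field(default_factory=RiskModelConfig)
    lenient_map: bool = False
    n_folds: int = 3
    n_boot: int = 1000
    split_fraction: float = 0.7
    knn_k: int = 5
    outdir: str = "run"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.synth is None and self.input_dir is None:
            self.synth = SynthConfig(seed=self.seed)
        # propagate the global seed into stages left at their defaults
        if self.synth is not None and self.synth.seed == 0 and self.seed != 0:
            self.synth = dataclasses.replace(self.synth, seed=self.seed)
        if self.cluster.seed == 0 and self.seed != 0:
            self.cluster = dataclasses.replace(self.cluster, seed=self.seed)
        if self.risk.seed == 0 and self.seed != 0:
            self.risk = dataclasses.replace(self.risk, seed=self.seed)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


@dataclass
class RunResult:
    outdir: Path
    records: list[PatientRecord]
    truth: GroundTruth | None
    timelines: dict
    model: RiskModel
    t_d: dict[str, float | None]
    matrix: TrajectoryMatrix
    clusters: ClusterResult
    outcomes: pd.DataFrame
    table: pd.DataFrame
    offsets: pd.DataFrame
    offset_tests: pd.DataFrame
    classifier: ClassifierEval | None


def _stage(name: str):
    """Decorator-free stage guard: re-raise with the failing stage's name."""
    class _Ctx:
        def __enter__(self):
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise ShocktrajError(f"pipeline stage {name!r} failed: {exc}"
                                     ) from exc
            logger.info("stage %s: done", name)
    return _Ctx()


def assemble_outcomes(records, timelines, t_d, assignments) -> pd.DataFrame:
    """Per-patient outcome frame for the stratification tables."""
    rows = []
    for rec in records:
        pid = rec.patient_id
        if pid not in assignments:
            continue
        tl = timelines[pid]
        rows.append({
            "patient_id": pid, "cluster": assignments[pid],
            "shock": tl.shock_onset is not None, "died": rec.died,
            "t_d": t_d.get(pid) if t_d.get(pid) is not None else np.nan,
            "shock_onset": (tl.shock_onset if tl.shock_onset is not None
                            else np.nan),
            "adequate_resus_time": (tl.adequate_resus_time
                                    if tl.adequate_resus_time is not None
                                    else np.nan),
            "vaso_time": (rec.first_vasopressor_time()
                          if rec.first_vasopressor_time() is not None
                          else np.nan),
            "first_intervention_time": (tl.first_intervention_time
                                        if tl.first_intervention_time is not None
                                        else np.nan),
        })
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig, *, classify: bool = True) -> RunResult:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fh = logging.FileHandler(outdir / "run.log")
    fh.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s "
                                      "%(message)s"))
    root = logging.getLogger("shocktraj")
    root.addHandler(fh)
    root.setLevel(logging.INFO)
    try:
        return _run(config, outdir, classify)
    finally:
        root.removeHandler(fh)
        fh.close()


def _run(config: RunConfig, outdir: Path, classify: bool) -> RunResult:
    with _stage("cohort"):
        if config.input_dir is not None:
            records, truth = read_cohort(config.input_dir)
        else:
            from .synth import generate_cohort
            records, truth = generate_cohort(config.synth)
        write_cohort(records, outdir / "cohort", truth)

    with _stage("label"):
        timelines = label_cohort(records, lenient_map=config.lenient_map)
        timelines_frame(timelines).to_csv(outdir / "timelines.csv", index=False)

    with _stage("risk"):
        X, y, _ = build_training_set(records, timelines)
        model = train_risk_model(X, y, config.risk)
        if config.risk.threshold_rule != "fixed":
            model.threshold = select_threshold(
                model.predict(X), y, config.risk.threshold_rule)
        model.save(outdir / "risk_model.json")
        # per-patient trajectories are scored out of fold (cross-fitting)
        models = crossfit_risk_models(records, timelines, config.risk,
                                      n_folds=config.n_folds)
        for m in models.values():
            m.threshold = model.threshold
        t_d = {rec.patient_id: detect_t_d(
            models[rec.patient_id], rec,
            from_time=timelines[rec.patient_id].sepsis_onset)
            for rec in records
            if timelines[rec.patient_id].sepsis_onset is not None}

    with _stage("traj"):
        if all(v is None for v in t_d.values()):
            raise ShocktrajError("no patient ever crosses the risk threshold")
        anchors: dict[str, float | None]
        if config.anchor_kind == "first_intervention":
            anchors = {p: timelines[p].first_intervention_time for p in t_d}
        else:
            anchors = t_d
        matrix = align_trajectories(models, records, anchors,
                                    anchor_kind=config.anchor_kind,
                                    window=config.window)
        matrix.to_csv(outdir / "trajectories.csv")

    with _stage("cluster"):
        result = spectral_clustering(matrix, config.cluster)
        shock_flags = {p: timelines[p].shock_onset is not None
                       for p in matrix.patient_ids}
        result = order_clusters_by_outcome(result, shock_flags)
        pd.DataFrame({"patient_id": result.patient_ids,
                      "cluster": result.assignments}).to_csv(
            outdir / "assignments.csv", index=False)
        decomp = {"eigenvalues": result.decomposition.eigenvalues[:20].tolist(),
                  "gaps": result.decomposition.gaps[:19].tolist(),
                  "k": result.k, "low_confidence": result.low_confidence,
                  "params": dataclasses.asdict(result.params)}
        (outdir / "decomposition.json").write_text(json.dumps(decomp, indent=1))

    with _stage("strata"):
        outcomes = assemble_outcomes(records, timelines, t_d,
                                     result.assignment_map())
        table = cluster_outcome_table(outcomes)
        table.to_csv(outdir / "stratification.csv")
        offsets, offset_tests = intervention_offset_by_cluster(outcomes)
        offsets.to_csv(outdir / "intervention_offsets.csv")
        offset_tests.to_csv(outdir / "offset_tests.csv", index=False)

    evaluation = None
    if classify:
        with _stage("classify"):
            evaluation = evaluate_accuracy_vs_duration(
                matrix if config.anchor_kind == "early_prediction"
                else matrix.truncated(matrix.window[1]),
                result.assignments,
                np.array([shock_flags[p] for p in matrix.patient_ids]),
                config.cluster, n_boot=config.n_boot,
                fraction=config.split_fraction, k_neighbors=config.knn_k,
                seed=config.seed)
            pd.DataFrame({"duration_h": evaluation.durations_h,
                          "accuracy": evaluation.accuracy,
                          "ci_lower": evaluation.ci_lower,
                          "ci_upper": evaluation.ci_upper}).to_csv(
                outdir / "classifier_accuracy.csv", index=False)

    with _stage("manifest"):
        cfg_json = json.dumps(config.to_dict(), sort_keys=True, default=str)
        numeric = {
            "n_patients": len(records),
            "n_clustered": matrix.n_patients,
            "k": result.k,
            "table": table.round(9).to_dict(),
        }
        manifest = {
            "shocktraj": __version__,
            "python": platform.python_version(),
            "seed": config.seed,
            "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
            "outputs_sha256": hashlib.sha256(
                json.dumps(numeric, sort_keys=True, default=str).encode()
            ).hexdigest(),
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))

    return RunResult(outdir=outdir, records=records, truth=truth,
                     timelines=timelines, model=model, t_d=t_d, matrix=matrix,
                     clusters=result, outcomes=outcomes, table=table,
                     offsets=offsets, offset_tests=offset_tests,
                     classifier=evaluation)
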