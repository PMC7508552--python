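"""Pre-shock risk model and per-patient risk trajectories.

A gradient-boosted tree model is trained to separate the pre-shock window -
observation updates falling in ``(t_shock - 2 h, t_shock - 1 h]`` of patients
who go on to septic shock - from the sepsis-state samples of patients who
never do. Applying the model to last-observation-carried-forward feature
vectors yields a risk score in (0, 1) at any time; the first above-threshold
score defines the time of early prediction ``t_d``, and the early warning
time is EWT = shock onset - t_d.

Missing features are passed to the tree learner as native NaN rather than
imputed, matching the LOCF-with-gaps reality of EHR streams. With logistic
loss and class-balancing the score behaves like a (rebalanced) posterior
probability of being in the pre-shock state.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import xgboost as xgb

from .exceptions import ConfigError, InputError, TrainingSetError
from .features import FEATURE_NAMES
from .label import StateTimeline
from .records import HOUR, PatientRecord


@dataclass
class RiskModelConfig:
    n_estimators: int = 300
    max_depth: int = 6
    learning_rate: float = 0.05
    min_child_weight: float = 100.0
    subsample: float = 0.8
    colsample_bytree: float = 0.8
    gamma: float = 1.0
    objective: str = "binary:logistic"
    balance_classes: bool = True
    threshold: float = 0.15
    threshold_rule: str = "fixed"  # fixed | quantile | target_specificity | youden
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold < 1.0:
            raise ConfigError("threshold: must lie in (0, 1) for logistic risk")
        if self.threshold_rule not in ("fixed", "quantile", "target_specificity",
                                       "youden"):
            raise ConfigError(f"threshold_rule: unknown rule {self.threshold_rule!r}")


# ------------------------------------------------------------------ features
def locf_featurize(record: PatientRecord, t: float,
                   features: Sequence[str] = FEATURE_NAMES) -> np.ndarray:
    """Feature vector at time ``t``: latest value at or before ``t`` per
    feature, NaN where never observed."""
    wide = record.locf_frame()
    out = np.full(len(features), np.nan)
    if not len(wide):
        return out
    times = wide.index.to_numpy(dtype=float)
    idx = np.searchsorted(times, t, side="right") - 1
    if idx < 0:
        return out
    row = wide.iloc[idx]
    for j, name in enumerate(features):
        if name in wide.columns:
            out[j] = row[name]
    return out


def locf_matrix(record: PatientRecord, times: np.ndarray,
                features: Sequence[str] = FEATURE_NAMES) -> np.ndarray:
    """Vectorized LOCF feature matrix at arbitrary query ``times``."""
    wide = record.locf_frame()
    n, p = len(times), len(features)
    out = np.full((n, p), np.nan)
    if not len(wide):
        return out
    obs_t = wide.index.to_numpy(dtype=float)
    idx = np.searchsorted(obs_t, np.asarray(times, dtype=float), side="right") - 1
    valid = idx >= 0
    for j, name in enumerate(features):
        if name in wide.columns:
            col = wide[name].to_numpy(dtype=float)
            out[valid, j] = col[idx[valid]]
    return out


def build_training_set(records: Iterable[PatientRecord],
                       timelines: Mapping[str, StateTimeline],
                       window_h: tuple[float, float] = (2.0, 1.0),
                       features: Sequence[str] = FEATURE_NAMES,
                       ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Assemble the (X, y, patient_ids) training triplet.

    Positive rows: LOCF vectors at observation-update times inside
    ``(t_shock - window_h[0], t_shock - window_h[1]]`` of shock patients.
    Negative rows: update times during the sepsis state (sepsis onset to end
    of record) of patients who never reach septic shock. Identical
    consecutive vectors within a patient are deduplicated.
    """
    lo, hi = window_h
    if not lo > hi:
        raise ConfigError("window_h: expected (earlier, later) with lo > hi")
    xs, ys, pids = [], [], []
    for rec in records:
        tl = timelines.get(rec.patient_id)
        if tl is None or tl.sepsis_onset is None:
            continue
        t_all = rec.update_times()
        if tl.shock_onset is not None:
            t0, t1 = tl.shock_onset - lo * HOUR, tl.shock_onset - hi * HOUR
            times = t_all[(t_all > t0) & (t_all <= t1)]
            label = 1
        else:
            times = t_all[t_all >= tl.sepsis_onset]
            label = 0
        if not times.size:
            continue
        mat = locf_matrix(rec, times, features)
        # drop rows identical to their predecessor (no information update)
        if len(mat) > 1:
            same = np.all((mat[1:] == mat[:-1])
                          | (np.isnan(mat[1:]) & np.isnan(mat[:-1])), axis=1)
            keep = np.concatenate([[True], ~same])
            mat = mat[keep]
        xs.append(mat)
        ys.append(np.full(len(mat), label))
        pids.append(np.full(len(mat), rec.patient_id, dtype=object))
    if not xs:
        raise TrainingSetError("no labeled patients contributed training rows")
    X = np.vstack(xs)
    y = np.concatenate(ys)
    if not (y == 1).any():
        raise TrainingSetError("no shock patients in the training cohort")
    if not (y == 0).any():
        raise TrainingSetError("no never-shock patients in the training cohort")
    return X, y, np.concatenate(pids)


# --------------------------------------------------------------------- model
@dataclass
class RiskModel:
    booster: xgb.Booster
    features: tuple[str, ...]
    config: RiskModelConfig
    threshold: float

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return self.booster.predict(xgb.DMatrix(X, missing=np.nan))

    def save(self, path: str | Path) -> None:
        path = Path(path)
        self.booster.save_model(str(path))
        sidecar = {"features": list(self.features), "threshold": self.threshold,
                   "config": asdict(self.config)}
        path.with_suffix(".meta.json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "RiskModel":
        path = Path(path)
        booster = xgb.Booster()
        booster.load_model(str(path))
        meta = json.loads(path.with_suffix(".meta.json").read_text())
        cfg = RiskModelConfig(**meta["config"])
        return cls(booster=booster, features=tuple(meta["features"]),
                   config=cfg, threshold=meta["threshold"])


def train_risk_model(X: np.ndarray, y: np.ndarray,
                     config: RiskModelConfig | None = None,
                     features: Sequence[str] = FEATURE_NAMES) -> RiskModel:
    """Fit the boosted-tree risk model; deterministic given ``config.seed``."""
    config = config or RiskModelConfig()
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise TrainingSetError("training labels contain a single class")
    params = {
        "objective": config.objective,
        "max_depth": config.max_depth,
        "eta": config.learning_rate,
        "min_child_weight": config.min_child_weight,
        "subsample": config.subsample,
        "colsample_bytree": config.colsample_bytree,
        "gamma": config.gamma,
        "seed": config.seed,
        "tree_method": "hist",
        "nthread": 1,
    }
    if config.balance_classes:
        params["scale_pos_weight"] = float((y == 0).sum() / max((y == 1).sum(), 1))
    dtrain = xgb.DMatrix(np.asarray(X, dtype=float), label=y, missing=np.nan)
    booster = xgb.train(params, dtrain, num_boost_round=config.n_estimators)
    return RiskModel(booster=booster, features=tuple(features), config=config,
                     threshold=config.threshold)


def select_threshold(scores: np.ndarray, labels: np.ndarray, rule: str,
                     *, target_specificity: float = 0.84,
                     quantile: float = 0.84,
                     fixed_value: float = 0.15) -> float:
    """Detection threshold from validation scores under the given rule.

    ``fixed`` returns ``fixed_value``; ``quantile`` the given quantile of the
    negative-class scores; ``target_specificity`` the smallest threshold whose
    specificity reaches the target; ``youden`` maximizes sensitivity +
    specificity - 1 over all cut-points.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if rule == "fixed":
        return float(fixed_value)
    neg, pos = scores[labels == 0], scores[labels == 1]

    def above(base: float) -> float:
        """Place the cut between the negative quantile and the next score up,
        so detection with ``risk >= threshold`` clears the quantile mass."""
        higher = scores[scores > base]
        if higher.size:
            return float((base + higher.min()) / 2.0)
        return float(np.nextafter(base, np.inf))

    if rule == "quantile":
        if not neg.size:
            raise InputError("quantile rule requires negative validation scores")
        return above(float(np.quantile(neg, quantile)))
    if rule == "target_specificity":
        if not neg.size:
            raise InputError("specificity rule requires negative validation scores")
        if not 0.0 <= target_specificity <= 1.0:
            raise ConfigError("target_specificity: must lie in [0, 1]")
        if target_specificity == 1.0:
            return above(float(neg.max()))
        thr = above(float(np.quantile(neg, target_specificity)))
        if np.mean(neg < thr) + 1e-9 < target_specificity:
            raise InputError("requested specificity unattainable on these scores")
        return thr
    if rule == "youden":
        cuts = np.unique(scores)
        best_thr, best_j = cuts[0], -np.inf
        for c in cuts:
            sens = float(np.mean(pos >= c)) if pos.size else 0.0
            spec = float(np.mean(neg < c)) if neg.size else 0.0
            if sens + spec - 1.0 > best_j:
                best_j, best_thr = sens + spec - 1.0, c
        return float(best_thr)
    raise ConfigError(f"threshold_rule: unknown rule {rule!r}")


def crossfit_risk_models(records: Sequence[PatientRecord],
                         timelines: Mapping[str, StateTimeline],
                         config: RiskModelConfig | None = None,
                         n_folds: int = 3,
                         features: Sequence[str] = FEATURE_NAMES,
                         ) -> dict[str, RiskModel]:
    """Patient-level cross-fitted risk models: pid -> out-of-fold model.

    Trajectories in this package are always scored out of sample: each
    patient's risk comes from a model trained on the other folds. Scoring a
    patient with a model that saw their own (slowly sampled, patient-specific)
    laboratory values amounts to patient-identity memorization and inflates
    early threshold crossings.
    """
    config = config or RiskModelConfig()
    records = list(records)
    rng = np.random.default_rng(config.seed)
    pids = np.array([r.patient_id for r in records], dtype=object)
    folds = rng.permutation(len(records)) % n_folds
    out: dict[str, RiskModel] = {}
    for f in range(n_folds):
        train_recs = [r for r, fo in zip(records, folds) if fo != f]
        X, y, _ = build_training_set(train_recs, timelines, features=features)
        model = train_risk_model(X, y, config, features)
        for pid in pids[folds == f]:
            out[str(pid)] = model
    return out


# -------------------------------------------------------------- trajectories
@dataclass
class RiskTrajectory:
    """Risk values on a time grid, with threshold-crossing time and EWT."""

    patient_id: str
    grid_times: np.ndarray  # minutes
    risk: np.ndarray
    t_d: float | None  # time of early prediction (first risk >= threshold)
    ewt: float | None = None  # minutes; shock onset - t_d
    threshold: float = field(default=0.15)

    @property
    def ewt_hours(self) -> float | None:
        return None if self.ewt is None else self.ewt / HOUR


def detect_t_d(model: RiskModel, record: PatientRecord,
               threshold: float | None = None,
               from_time: float | None = None) -> float | None:
    """First observation-update time with risk at or above the threshold.

    ``from_time`` restricts the scan (the pipeline passes sepsis onset: the
    pre-shock risk score is defined for patients in the sepsis state).
    """
    thr = model.threshold if threshold is None else threshold
    times = record.update_times()
    if from_time is not None:
        times = times[times >= from_time]
    if not times.size:
        return None
    risk = model.predict(locf_matrix(record, times, model.features))
    above = np.nonzero(risk >= thr)[0]
    return float(times[above[0]]) if above.size else None


def compute_risk_trajectory(model: RiskModel, record: PatientRecord,
                            grid: np.ndarray | None = None, *,
                            threshold: float | None = None,
                            shock_onset: float | None = None,
                            window_h: int = 12) -> RiskTrajectory:
    """Risk trajectory for one patient.

    ``t_d`` is detected by scanning all observation-update times (not just the
    export grid). When ``grid`` is omitted, an hourly grid over
    ``[t_d, t_d + window_h]`` is used (empty if the threshold is never
    crossed).
    """
    thr = model.threshold if threshold is None else threshold
    t_d = detect_t_d(model, record, thr)
    if grid is None:
        grid = (t_d + np.arange(window_h + 1) * HOUR if t_d is not None
                else np.empty(0))
    grid = np.asarray(grid, dtype=float)
    risk = (model.predict(locf_matrix(record, grid, model.features))
            if grid.size else np.empty(0))
    ewt = None
    if t_d is not None and shock_onset is not None:
        ewt = float(shock_onset - t_d)
    return RiskTrajectory(patient_id=record.patient_id, grid_times=grid,
                          risk=np.asarray(risk, dtype=float), t_d=t_d, ewt=ewt,
                          threshold=thr)
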