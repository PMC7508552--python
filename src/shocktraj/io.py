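"""Reading and writing cohorts as long-format CSV tables.

The on-disk layout mirrors eICU-style extracts: an observations table of
(patient_id, time, feature, value) rows, an events table for fluid boluses
and vasopressor state changes, a statics table of per-patient fields, and -
for synthetic cohorts - a ground-truth table. Times are either numeric
minutes from hospital admission or ISO-8601 timestamps (converted at
ingestion using each patient's hospital admission time).

Duplicate same-timestamp blood-pressure entries are resolved by preferring
invasive over non-invasive readings when a ``modality`` column is present.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import SchemaError
from .records import GroundTruth, PatientRecord

OBS_COLUMNS = ("patient_id", "time", "feature", "value")
EVENT_COLUMNS = ("patient_id", "time", "event_type", "value")
STATIC_COLUMNS = ("patient_id", "weight_kg", "icu_admit", "hospital_admit",
                  "suspected_infection_time", "antibiotic_order_time", "died",
                  "end_time")


def write_cohort(records: Sequence[PatientRecord], outdir: str | Path,
                 truth: GroundTruth | None = None) -> dict[str, Path]:
    """Write a cohort to ``outdir`` (observations/events/statics[/truth])."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    obs_frames, event_rows, static_rows = [], [], []
    for rec in records:
        if len(rec.observations):
            obs = rec.observations.copy()
            obs.insert(0, "patient_id", rec.patient_id)
            obs_frames.append(obs)
        for t, vol in rec.fluid_events:
            event_rows.append((rec.patient_id, t, "fluid", vol))
        for t, flag in rec.vasopressor_events:
            event_rows.append((rec.patient_id, t, "vasopressor", flag))
        static_rows.append({
            "patient_id": rec.patient_id, "weight_kg": rec.weight_kg,
            "icu_admit": rec.icu_admit, "hospital_admit": rec.hospital_admit,
            "suspected_infection_time": rec.suspected_infection_time,
            "antibiotic_order_time": rec.antibiotic_order_time,
            "died": int(rec.died), "end_time": rec.end_time})
    paths = {
        "observations": outdir / "observations.csv",
        "events": outdir / "events.csv",
        "statics": outdir / "statics.csv",
    }
    (pd.concat(obs_frames, ignore_index=True) if obs_frames
     else pd.DataFrame(columns=OBS_COLUMNS)).to_csv(paths["observations"],
                                                    index=False)
    pd.DataFrame(event_rows, columns=EVENT_COLUMNS).to_csv(paths["events"],
                                                           index=False)
    pd.DataFrame(static_rows, columns=STATIC_COLUMNS).to_csv(paths["statics"],
                                                             index=False)
    if truth is not None:
        paths["ground_truth"] = outdir / "ground_truth.csv"
        merged = truth.frame.merge(
            truth.baselines.add_prefix("baseline_").reset_index(),
            on="patient_id", how="left")
        merged.to_csv(paths["ground_truth"], index=False)
    return paths


def _require(df: pd.DataFrame, cols: Iterable[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} table is missing required columns: {missing}")


def _times_to_minutes(df: pd.DataFrame, col: str, admits: pd.Series,
                      what: str) -> pd.Series:
    """Times as float minutes; ISO-8601 converted via hospital admission."""
    ser = df[col]
    if pd.api.types.is_numeric_dtype(ser):
        return ser.astype(float)
    parsed = pd.to_datetime(ser, errors="coerce", format="ISO8601")
    bad = parsed.isna() & ser.notna()
    if bad.any():
        line = int(bad.idxmax()) + 2  # header + 1-based
        raise SchemaError(f"{what} row at line {line}: unparseable timestamp "
                          f"{ser[bad.idxmax()]!r}")
    admit = df["patient_id"].map(admits)
    if admit.isna().any():
        missing = df.loc[admit.isna(), "patient_id"].iloc[0]
        raise SchemaError(f"{what}: no hospital admission time for patient "
                          f"{missing!r} to anchor ISO timestamps")
    return (parsed - pd.to_datetime(admit)).dt.total_seconds() / 60.0


def _apply_invasive_precedence(obs: pd.DataFrame) -> pd.DataFrame:
    if "modality" not in obs.columns:
        return obs
    key = ["patient_id", "time", "feature"]
    invasive = obs.loc[obs["modality"] == "invasive", key]
    inv_keys = set(map(tuple, invasive.to_numpy()))
    drop = obs.apply(lambda r: (r["modality"] != "invasive"
                                and (r["patient_id"], r["time"], r["feature"])
                                in inv_keys), axis=1)
    return obs.loc[~drop].drop(columns=["modality"])


def read_cohort(obs_path: str | Path, events_path: str | Path | None = None,
                statics_path: str | Path | None = None,
                truth_path: str | Path | None = None,
                ) -> tuple[list[PatientRecord], GroundTruth | None]:
    """Read a cohort from long-format CSVs (see module docstring).

    ``obs_path`` may also be a directory produced by :func:`write_cohort`.
    """
    obs_path = Path(obs_path)
    if obs_path.is_dir():
        d = obs_path
        obs_path = d / "observations.csv"
        events_path = events_path or (d / "events.csv")
        statics_path = statics_path or (d / "statics.csv")
        if truth_path is None and (d / "ground_truth.csv").exists():
            truth_path = d / "ground_truth.csv"
    if statics_path is None:
        raise SchemaError("statics table is required (per-patient weight etc.)")
    statics = pd.read_csv(statics_path)
    _require(statics, STATIC_COLUMNS[:2], "statics")
    obs = pd.read_csv(obs_path)
    _require(obs, OBS_COLUMNS, "observations")
    events = (pd.read_csv(events_path) if events_path is not None
              and Path(events_path).exists() else pd.DataFrame(columns=EVENT_COLUMNS))
    if len(events):
        _require(events, EVENT_COLUMNS, "events")

    admits = statics.set_index("patient_id").get(
        "hospital_admit", pd.Series(dtype=float))
    # statics may themselves carry ISO-8601 times: convert them to offset
    # minutes from each patient's hospital admission
    if ("hospital_admit" in statics.columns
            and not pd.api.types.is_numeric_dtype(statics["hospital_admit"])):
        admit_dt = pd.to_datetime(statics["hospital_admit"], errors="coerce",
                                  format="ISO8601")
        if admit_dt.isna().any():
            raise SchemaError("statics: unparseable hospital_admit timestamp")
        statics = statics.copy()
        for col in ("icu_admit", "suspected_infection_time",
                    "antibiotic_order_time", "end_time"):
            if col in statics.columns and not pd.api.types.is_numeric_dtype(
                    statics[col]):
                parsed = pd.to_datetime(statics[col], errors="coerce",
                                        format="ISO8601")
                statics[col] = (parsed - admit_dt).dt.total_seconds() / 60.0
        statics["hospital_admit"] = 0.0
    if len(obs):
        obs = obs.copy()
        obs["time"] = _times_to_minutes(obs, "time", admits, "observations")
        obs = _apply_invasive_precedence(obs)
    if len(events):
        events = events.copy()
        events["time"] = _times_to_minutes(events, "time", admits, "events")

    def opt(row, name):
        v = row.get(name)
        return None if v is None or (isinstance(v, float) and np.isnan(v)) else float(v)

    records = []
    obs_by_pid = dict(tuple(obs.groupby("patient_id"))) if len(obs) else {}
    ev_by_pid = dict(tuple(events.groupby("patient_id"))) if len(events) else {}
    for _, row in statics.iterrows():
        pid = row["patient_id"]
        p_obs = obs_by_pid.get(pid)
        p_obs = (p_obs[["time", "feature", "value"]] if p_obs is not None
                 else pd.DataFrame(columns=["time", "feature", "value"]))
        p_ev = ev_by_pid.get(pid)
        fluid = np.empty((0, 2))
        vaso = np.empty((0, 2))
        if p_ev is not None:
            f = p_ev[p_ev["event_type"] == "fluid"]
            v = p_ev[p_ev["event_type"] == "vasopressor"]
            fluid = f[["time", "value"]].to_numpy(dtype=float)
            vaso = v[["time", "value"]].to_numpy(dtype=float)
        records.append(PatientRecord(
            patient_id=str(pid), weight_kg=float(row["weight_kg"]),
            icu_admit=float(row.get("icu_admit", 0.0) or 0.0),
            hospital_admit=float(row.get("hospital_admit", 0.0) or 0.0),
            suspected_infection_time=opt(row, "suspected_infection_time"),
            observations=p_obs.reset_index(drop=True),
            fluid_events=fluid, vasopressor_events=vaso,
            antibiotic_order_time=opt(row, "antibiotic_order_time"),
            died=bool(row.get("died", False)),
            end_time=opt(row, "end_time")))
    truth = None
    if truth_path is not None:
        tf = pd.read_csv(truth_path)
        base_cols = [c for c in tf.columns if c.startswith("baseline_")]
        baselines = tf[base_cols].rename(columns=lambda c: c[len("baseline_"):])
        baselines.index = pd.Index(tf["patient_id"], name="patient_id")
        truth = GroundTruth(frame=tf.drop(columns=base_cols), baselines=baselines)
    return records, truth
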