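"""Algorithmic Sepsis-3 clinical-state labeling.

Implements the consensus-definition machinery on irregular EHR streams:
SOFA scoring, sepsis onset (suspected infection + SOFA >= 2), adequate fluid
resuscitation per the 2012 Surviving Sepsis Campaign criteria, septic-shock
onset (earliest time at which resuscitation, vasopressor dependence and serum
lactate > 2 mmol/L all co-hold), first intervention, and EGDT compliance.

Design notes
------------
* Missing SOFA inputs score 0 - standard practice for sparse EHR extracts,
  which avoids scoring unobserved organ systems.
* The resuscitation-target criteria (urine output / MAP / CVP) count only at
  or after the first fluid administration: a never-treated patient cannot be
  "adequately resuscitated". Disable with ``require_fluids_first=False``.
* "Vasopressors to maintain MAP >= 65 mmHg" is evaluated as vasopressor
  active AND most-recent MAP >= 65 at the candidate time; ``lenient_map=True``
  drops the MAP condition (the consensus text does not resolve how to handle
  pressor-refractory hypotension).
* LOCF lookback for lactate and MAP at shock evaluation is capped at a 24 h
  staleness horizon.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .exceptions import InputError
from .records import HOUR, PatientRecord

#: Versioned encoding of the standard SOFA criterion table. Each subscore maps
#: value cutoffs to points; cardio combines hypotension and vasopressor use
#: (any vasopressor scores 3 - dose information is not modeled).
SOFA_CRITERIA_VERSION = "sofa-1996-consensus/v1"

_SOFA_SUBSCORES = ("resp", "coag", "liver", "cardio", "nervous", "kidney")


def _score_resp(pao2: float, fio2_pct: float) -> int:
    if np.isnan(pao2) or np.isnan(fio2_pct) or fio2_pct <= 0:
        return 0
    ratio = pao2 / (fio2_pct / 100.0)
    for cut, pts in ((100, 4), (200, 3), (300, 2), (400, 1)):
        if ratio < cut:
            return pts
    return 0


def _score_coag(platelets: float) -> int:
    if np.isnan(platelets):
        return 0
    for cut, pts in ((20, 4), (50, 3), (100, 2), (150, 1)):
        if platelets < cut:
            return pts
    return 0


def _score_liver(bilirubin: float) -> int:
    if np.isnan(bilirubin):
        return 0
    for cut, pts in ((12.0, 4), (6.0, 3), (2.0, 2), (1.2, 1)):
        if bilirubin >= cut:
            return pts
    return 0


def _score_cardio(map_mmhg: float, vasopressor: bool) -> int:
    if vasopressor:
        return 3
    if not np.isnan(map_mmhg) and map_mmhg < 70.0:
        return 1
    return 0


def _score_nervous(gcs: float) -> int:
    if np.isnan(gcs):
        return 0
    if gcs < 6:
        return 4
    if gcs <= 9:
        return 3
    if gcs <= 12:
        return 2
    if gcs <= 14:
        return 1
    return 0


def _score_kidney(creatinine: float) -> int:
    if np.isnan(creatinine):
        return 0
    for cut, pts in ((5.0, 4), (3.5, 3), (2.0, 2), (1.2, 1)):
        if creatinine >= cut:
            return pts
    return 0


@dataclass
class SofaScore:
    timestamp: float
    subscores: dict[str, int]
    total: int


def compute_sofa(snapshot: Mapping[str, float], timestamp: float = 0.0,
                 vasopressor_active: bool | None = None) -> SofaScore:
    """SOFA score from a (possibly incomplete) feature snapshot.

    Missing inputs leave the corresponding subscore at 0. ``vasopressor_active``
    may also be supplied inside the snapshot under that key.
    """
    def get(name: str) -> float:
        v = snapshot.get(name, np.nan)
        if v is None:
            return np.nan
        if isinstance(v, str) or not np.isscalar(v):
            raise InputError(f"non-numeric value for {name!r}: {v!r}")
        return float(v)

    if vasopressor_active is None:
        vasopressor_active = bool(snapshot.get("vasopressor_active", False))
    subscores = {
        "resp": _score_resp(get("pao2"), get("fio2")),
        "coag": _score_coag(get("platelets")),
        "liver": _score_liver(get("bilirubin")),
        "cardio": _score_cardio(get("map"), vasopressor_active),
        "nervous": _score_nervous(get("gcs")),
        "kidney": _score_kidney(get("creatinine")),
    }
    return SofaScore(timestamp=timestamp, subscores=subscores,
                     total=int(sum(subscores.values())))


def sofa_series(record: PatientRecord) -> pd.DataFrame:
    """SOFA total and subscores at every observation-update time (vectorized)."""
    wide = record.locf_frame()
    if not len(wide):
        return pd.DataFrame(columns=["time", *_SOFA_SUBSCORES, "total"])
    t = wide.index.to_numpy(dtype=float)

    def col(name: str) -> np.ndarray:
        if name in wide.columns:
            return wide[name].to_numpy(dtype=float)
        return np.full(len(wide), np.nan)

    pao2, fio2 = col("pao2"), col("fio2")
    ratio = np.where((fio2 > 0) & ~np.isnan(pao2) & ~np.isnan(fio2),
                     pao2 / np.where(fio2 > 0, fio2 / 100.0, 1.0), np.nan)
    resp = np.select([ratio < 100, ratio < 200, ratio < 300, ratio < 400],
                     [4, 3, 2, 1], default=0)
    plt_ = col("platelets")
    coag = np.select([plt_ < 20, plt_ < 50, plt_ < 100, plt_ < 150],
                     [4, 3, 2, 1], default=0)
    bili = col("bilirubin")
    liver = np.select([bili >= 12, bili >= 6, bili >= 2, bili >= 1.2],
                      [4, 3, 2, 1], default=0)
    vaso = np.asarray(record.vasopressor_active_at(t), dtype=bool)
    map_ = col("map")
    cardio = np.where(vaso, 3, np.where(map_ < 70, 1, 0))
    gcs = col("gcs")
    nervous = np.select([gcs < 6, gcs <= 9, gcs <= 12, gcs <= 14],
                        [4, 3, 2, 1], default=0)
    creat = col("creatinine")
    kidney = np.select([creat >= 5, creat >= 3.5, creat >= 2, creat >= 1.2],
                       [4, 3, 2, 1], default=0)
    out = pd.DataFrame({"time": t, "resp": resp, "coag": coag, "liver": liver,
                        "cardio": cardio, "nervous": nervous, "kidney": kidney})
    out["total"] = out[list(_SOFA_SUBSCORES)].sum(axis=1)
    return out


# ------------------------------------------------------------------- labeling
def label_sepsis_onset(record: PatientRecord,
                       sofa: pd.DataFrame | None = None) -> float | None:
    """Earliest time with suspected infection present and SOFA >= 2."""
    if record.suspected_infection_time is None:
        return None
    if sofa is None:
        sofa = sofa_series(record)
    ok = sofa[(sofa["total"] >= 2)
              & (sofa["time"] >= record.suspected_infection_time)]
    return float(ok["time"].iloc[0]) if len(ok) else None


def detect_adequate_fluid_resuscitation(
        record: PatientRecord, *, require_fluids_first: bool = True,
        target_ml_per_kg: float = 30.0,
        urine_rate_ml_kg_h: float = 0.5) -> float | None:
    """Earliest time the 2012 SSC adequate-resuscitation criteria hold.

    Criteria (any one suffices): cumulative fluids >= 30 mL/kg; urine output
    > 0.5 mL/kg/hr; MAP >= 65 mmHg; CVP in [8, 12] mmHg. Urine observations
    are hourly-rate readings (mL over the trailing hour), so the rate is the
    reading normalized by body weight.
    """
    if not record.weight_kg or not np.isfinite(record.weight_kg):
        raise InputError(f"weight missing for patient {record.patient_id}")
    w = record.weight_kg
    candidates: list[float] = []

    if record.fluid_events.size:
        cum = np.cumsum(record.fluid_events[:, 1])
        hit = np.nonzero(cum >= target_ml_per_kg * w)[0]
        if hit.size:
            candidates.append(float(record.fluid_events[hit[0], 0]))
        first_fluid = float(record.fluid_events[0, 0])
    else:
        first_fluid = None

    if first_fluid is not None or not require_fluids_first:
        gate = first_fluid if require_fluids_first else -np.inf
        wide = record.locf_frame()
        if len(wide):
            t = wide.index.to_numpy(dtype=float)
            ok = np.zeros(len(wide), dtype=bool)
            if "urine_output" in wide.columns:
                ok |= (wide["urine_output"].to_numpy(dtype=float) / w
                       > urine_rate_ml_kg_h)
            if "map" in wide.columns:
                ok |= wide["map"].to_numpy(dtype=float) >= 65.0
            if "cvp" in wide.columns:
                cvp = wide["cvp"].to_numpy(dtype=float)
                ok |= (cvp >= 8.0) & (cvp <= 12.0)
            ok &= t >= gate
            if ok.any():
                candidates.append(float(t[np.argmax(ok)]))
    return min(candidates) if candidates else None


def label_septic_shock_onset(record: PatientRecord, sepsis_onset: float | None,
                             resus_time: float | None, *,
                             lenient_map: bool = False,
                             staleness_h: float = 24.0) -> float | None:
    """Earliest time all septic-shock criteria co-hold.

    Requires sepsis onset and adequate resuscitation, an active vasopressor,
    most-recent lactate > 2 mmol/L (strict inequality) and - unless
    ``lenient_map`` - most-recent MAP >= 65 mmHg, evaluating candidates at
    every observation/event time from ``max(sepsis_onset, resus_time)`` on.
    """
    if sepsis_onset is None or resus_time is None:
        return None
    if not record.vasopressor_events.size:
        return None
    stale = staleness_h * HOUR
    obs = record.observations
    times = [obs.loc[obs["feature"] == "lactate", "time"].to_numpy(dtype=float),
             record.vasopressor_events[:, 0],
             np.array([sepsis_onset, resus_time])]
    if not lenient_map:
        times.append(obs.loc[obs["feature"] == "map", "time"].to_numpy(dtype=float))
    cand = np.unique(np.concatenate(times))
    cand = cand[cand >= max(sepsis_onset, resus_time)]
    for t in cand:
        if not record.vasopressor_active_at(t):
            continue
        lact = record.feature_at("lactate", t, staleness_min=stale)
        if not lact > 2.0:
            continue
        if not lenient_map:
            map_v = record.feature_at("map", t, staleness_min=stale)
            if not map_v >= 65.0:
                continue
        return float(t)
    return None


def first_intervention_time(record: PatientRecord,
                            resus_time: float | None = "auto") -> float | None:
    """Earliest of antibiotic order, vasopressor start, adequate resuscitation."""
    if resus_time == "auto":
        resus_time = detect_adequate_fluid_resuscitation(record)
    times = [t for t in (record.antibiotic_order_time,
                         record.first_vasopressor_time(), resus_time)
             if t is not None]
    return float(min(times)) if times else None


def egdt_compliance(record: PatientRecord, resus_time: float | None,
                    icu_admit: float | None = None) -> bool:
    """Adequate resuscitation achieved within 6 h after ICU admission."""
    if icu_admit is None:
        icu_admit = record.icu_admit
    if icu_admit is None:
        raise InputError(f"icu_admit missing for patient {record.patient_id}")
    if resus_time is None:
        return False
    return icu_admit < resus_time <= icu_admit + 6.0 * HOUR


@dataclass
class StateTimeline:
    """Per-patient clinical-state labels and onset times (minutes)."""

    patient_id: str
    sepsis_onset: float | None
    adequate_resus_time: float | None
    shock_onset: float | None
    first_intervention_time: float | None
    egdt_compliant: bool

    @property
    def state_series(self) -> list[tuple[float, str]]:
        out: list[tuple[float, str]] = [(0.0, "none")]
        if self.sepsis_onset is not None:
            out.append((self.sepsis_onset, "sepsis"))
        if self.shock_onset is not None:
            out.append((self.shock_onset, "septic_shock"))
        return out


def label_patient(record: PatientRecord, *, lenient_map: bool = False,
                  require_fluids_first: bool = True) -> StateTimeline:
    sepsis = label_sepsis_onset(record)
    resus = detect_adequate_fluid_resuscitation(
        record, require_fluids_first=require_fluids_first)
    shock = label_septic_shock_onset(record, sepsis, resus,
                                     lenient_map=lenient_map)
    first_iv = first_intervention_time(record, resus_time=resus)
    return StateTimeline(
        patient_id=record.patient_id, sepsis_onset=sepsis,
        adequate_resus_time=resus, shock_onset=shock,
        first_intervention_time=first_iv,
        egdt_compliant=egdt_compliance(record, resus))


def label_cohort(records: Iterable[PatientRecord],
                 **kwargs) -> dict[str, StateTimeline]:
    return {r.patient_id: label_patient(r, **kwargs) for r in records}


def timelines_frame(timelines: Mapping[str, StateTimeline]) -> pd.DataFrame:
    """One row per patient with onset columns (minutes; NaN when absent)."""
    rows = []
    for tl in timelines.values():
        rows.append({
            "patient_id": tl.patient_id,
            "sepsis_onset": np.nan if tl.sepsis_onset is None else tl.sepsis_onset,
            "adequate_resus_time": (np.nan if tl.adequate_resus_time is None
                                    else tl.adequate_resus_time),
            "shock_onset": np.nan if tl.shock_onset is None else tl.shock_onset,
            "first_intervention_time": (np.nan if tl.first_intervention_time is None
                                        else tl.first_intervention_time),
            "egdt_compliant": tl.egdt_compliant,
        })
    return pd.DataFrame(rows)
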