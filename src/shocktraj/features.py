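"""Clinical feature schema shared by the generator, the labeler and the risk model.

The risk model operates on 28 routinely collected ICU variables (vital signs,
blood gases, chemistry, hematology, urine output, ...). For each feature the
schema records the unit, a plausible between-patient baseline distribution for
a sepsis cohort, the measurement noise, the mean inter-observation interval
(hours) of a typical ICU charting workflow, a physiologic clipping range, and
the latent deterioration shift applied at full severity when a patient crosses
the sepsis -> pre-shock transition (lactate and heart rate rise, blood
pressures fall, ...).

Observation intervals follow the familiar ICU cadence: continuous vitals are
charted roughly hourly, blood gases every ~8 h, chemistries every ~12 h and
lactate roughly every 11 h, the median inter-observation interval reported for
large multi-center ICU EHR extracts.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class FeatureSpec:
    name: str
    unit: str
    baseline_mean: float
    baseline_sd: float  # between-patient spread of the pre-transition baseline
    noise_sd: float  # within-patient measurement noise
    interval_h: float  # mean inter-observation interval (homogeneous Poisson)
    lo: float
    hi: float
    shift: float  # latent change at full severity (severity = 1.0)


#: The 28 model features. ``shift`` is scaled by the patient's archetype
#: severity in the synthetic generator; a severity of 0 leaves the latent
#: curve at its stationary baseline.
FEATURES: tuple[FeatureSpec, ...] = (
    FeatureSpec("heart_rate", "bpm", 88.0, 5.0, 4.0, 1.0, 40.0, 200.0, 32.0),
    FeatureSpec("sbp", "mmHg", 118.0, 6.0, 5.0, 1.0, 50.0, 250.0, -35.0),
    FeatureSpec("dbp", "mmHg", 66.0, 4.0, 4.0, 1.0, 30.0, 150.0, -18.0),
    FeatureSpec("map", "mmHg", 78.0, 4.5, 4.0, 1.0, 35.0, 180.0, -22.0),
    FeatureSpec("resp_rate", "bpm", 20.0, 2.0, 2.0, 1.0, 6.0, 60.0, 6.0),
    FeatureSpec("temperature", "degC", 37.3, 0.4, 0.2, 4.0, 33.0, 42.0, 0.8),
    FeatureSpec("spo2", "%", 96.0, 1.2, 1.0, 1.0, 70.0, 100.0, -4.0),
    FeatureSpec("fio2", "%", 45.0, 6.0, 3.0, 4.0, 21.0, 100.0, 22.0),
    FeatureSpec("gcs", "points", 14.0, 0.8, 0.5, 4.0, 3.0, 15.0, -3.0),
    FeatureSpec("lactate", "mmol/L", 1.3, 0.2, 0.15, 11.0, 0.3, 20.0, 3.6),
    FeatureSpec("wbc", "k/uL", 13.0, 3.0, 1.0, 6.0, 0.5, 80.0, 6.0),
    FeatureSpec("platelets", "k/uL", 180.0, 40.0, 10.0, 12.0, 5.0, 1000.0, -60.0),
    FeatureSpec("creatinine", "mg/dL", 1.4, 0.35, 0.1, 12.0, 0.2, 15.0, 1.2),
    FeatureSpec("bun", "mg/dL", 28.0, 8.0, 2.0, 12.0, 2.0, 150.0, 10.0),
    FeatureSpec("bilirubin", "mg/dL", 0.9, 0.3, 0.1, 12.0, 0.1, 30.0, 0.8),
    FeatureSpec("ph", "pH", 7.38, 0.03, 0.02, 8.0, 6.8, 7.8, -0.10),
    FeatureSpec("paco2", "mmHg", 40.0, 4.0, 2.0, 8.0, 10.0, 120.0, 2.0),
    FeatureSpec("pao2", "mmHg", 95.0, 12.0, 6.0, 8.0, 30.0, 500.0, -20.0),
    FeatureSpec("bicarbonate", "mEq/L", 24.0, 2.5, 1.0, 12.0, 5.0, 50.0, -5.0),
    FeatureSpec("hemoglobin", "g/dL", 10.8, 1.2, 0.4, 12.0, 3.0, 20.0, 0.5),
    FeatureSpec("hematocrit", "%", 33.0, 3.5, 1.2, 12.0, 10.0, 60.0, 1.5),
    FeatureSpec("urine_output", "mL/hr", 55.0, 10.0, 10.0, 2.0, 0.0, 1000.0, -35.0),
    FeatureSpec("cvp", "mmHg", 7.0, 1.5, 1.5, 4.0, 0.0, 30.0, 6.0),
    FeatureSpec("glucose", "mg/dL", 135.0, 25.0, 15.0, 6.0, 30.0, 1000.0, 40.0),
    FeatureSpec("sodium", "mEq/L", 138.0, 3.0, 1.5, 12.0, 110.0, 175.0, 2.0),
    FeatureSpec("potassium", "mEq/L", 4.1, 0.4, 0.2, 12.0, 1.5, 9.0, 0.4),
    FeatureSpec("chloride", "mEq/L", 103.0, 3.0, 1.5, 12.0, 70.0, 140.0, 4.0),
    FeatureSpec("albumin", "g/dL", 3.1, 0.4, 0.15, 24.0, 0.5, 6.0, -0.4),
)

FEATURE_NAMES: tuple[str, ...] = tuple(f.name for f in FEATURES)
FEATURE_BY_NAME: dict[str, FeatureSpec] = {f.name: f for f in FEATURES}

#: Blood-pressure channels whose latent deterioration partially reverses once
#: vasopressors are running (that is what vasopressors do).
PRESSOR_RESPONSIVE: frozenset[str] = frozenset({"sbp", "dbp", "map"})
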