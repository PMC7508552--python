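"""Per-patient containers.

All timestamps in this package are float minutes from hospital admission,
mirroring the offset convention of eICU-style EHR extracts. Helpers that
present results to the user convert to hours.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .exceptions import InputError

#: Minutes per hour; timestamps are minutes from hospital admission.
HOUR = 60.0


@dataclass
class PatientRecord:
    """One patient's static fields, observation stream and intervention events.

    Parameters
    ----------
    observations
        Long-format frame with columns ``time`` (minutes), ``feature``, ``value``.
    fluid_events
        ``(n, 2)`` array of ``(time, volume_mL)`` bolus administrations.
    vasopressor_events
        ``(n, 2)`` array of ``(time, active_flag)`` state changes; a flag of 1
        starts an infusion, 0 stops it.
    """

    patient_id: str
    weight_kg: float
    icu_admit: float = 0.0
    hospital_admit: float = 0.0
    suspected_infection_time: float | None = None
    observations: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["time", "feature", "value"]))
    fluid_events: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))
    vasopressor_events: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))
    antibiotic_order_time: float | None = None
    died: bool = False
    end_time: float | None = None
    _locf_cache: pd.DataFrame | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self.weight_kg > 0:
            raise InputError(f"weight_kg must be > 0 for patient {self.patient_id}")
        self.fluid_events = np.asarray(self.fluid_events, dtype=float).reshape(-1, 2)
        self.vasopressor_events = np.asarray(
            self.vasopressor_events, dtype=float).reshape(-1, 2)
        if self.fluid_events.size and (self.fluid_events[:, 1] < 0).any():
            raise InputError(f"negative fluid volume for patient {self.patient_id}")
        obs = self.observations
        if len(obs) and not pd.api.types.is_numeric_dtype(obs["value"]):
            raise InputError(f"non-numeric observation values for {self.patient_id}")
        # sort internally so labeling is invariant to input row order
        self.observations = obs.sort_values(["time", "feature"], kind="stable")
        self.observations = self.observations.reset_index(drop=True)
        if self.fluid_events.size:
            self.fluid_events = self.fluid_events[np.argsort(self.fluid_events[:, 0],
                                                             kind="stable")]
        if self.vasopressor_events.size:
            order = np.argsort(self.vasopressor_events[:, 0], kind="stable")
            self.vasopressor_events = self.vasopressor_events[order]
        if self.end_time is None:
            self.end_time = float(self.observations["time"].max()) if len(obs) else 0.0

    # ------------------------------------------------------------------ LOCF
    def locf_frame(self) -> pd.DataFrame:
        """Wide last-observation-carried-forward frame.

        Index: the sorted unique observation times (the "update times");
        columns: feature names; entries: latest observed value at or before
        the row time, NaN where a feature has never been observed.
        """
        if self._locf_cache is None:
            if not len(self.observations):
                self._locf_cache = pd.DataFrame()
            else:
                wide = self.observations.pivot_table(
                    index="time", columns="feature", values="value",
                    aggfunc="last", sort=True)
                self._locf_cache = wide.ffill()
        return self._locf_cache

    def update_times(self) -> np.ndarray:
        """Sorted unique observation times (minutes)."""
        if not len(self.observations):
            return np.empty(0)
        return self.locf_frame().index.to_numpy(dtype=float)

    def feature_at(self, feature: str, t: float,
                   staleness_min: float | None = None) -> float:
        """LOCF lookup of one feature at time ``t`` (NaN if never observed).

        ``staleness_min`` discards observations older than the given horizon.
        """
        obs = self.observations
        sel = obs[(obs["feature"] == feature) & (obs["time"] <= t)]
        if staleness_min is not None:
            sel = sel[sel["time"] >= t - staleness_min]
        if not len(sel):
            return float("nan")
        return float(sel["value"].iloc[-1])

    # ---------------------------------------------------------------- events
    def vasopressor_active_at(self, t: float | np.ndarray) -> np.ndarray | bool:
        """Whether a vasopressor infusion is running at time(s) ``t``."""
        t_arr = np.atleast_1d(np.asarray(t, dtype=float))
        if not self.vasopressor_events.size:
            out = np.zeros(t_arr.shape, dtype=bool)
        else:
            idx = np.searchsorted(self.vasopressor_events[:, 0], t_arr, side="right")
            out = np.where(idx > 0, self.vasopressor_events[
                np.clip(idx - 1, 0, None), 1] > 0, False)
        return bool(out[0]) if np.isscalar(t) or np.ndim(t) == 0 else out

    def first_vasopressor_time(self) -> float | None:
        ev = self.vasopressor_events
        starts = ev[ev[:, 1] > 0, 0] if ev.size else np.empty(0)
        return float(starts.min()) if starts.size else None

    def cumulative_fluids_at(self, t: float) -> float:
        """Total administered fluid volume (mL) at or before ``t``."""
        if not self.fluid_events.size:
            return 0.0
        mask = self.fluid_events[:, 0] <= t
        return float(self.fluid_events[mask, 1].sum())


@dataclass
class GroundTruth:
    """Generator-side truth for a synthetic cohort (the test oracle).

    ``frame`` has one row per patient: ``patient_id``, ``archetype``,
    ``severity``, ``transition_time``, ``jump_width`` (minutes), ``shock``,
    ``died``, ``true_shock_onset`` (NaN for non-shock patients).
    ``baselines`` holds the latent pre-transition baseline of each feature.
    """

    frame: pd.DataFrame
    baselines: pd.DataFrame

    def archetypes(self) -> pd.Series:
        return self.frame.set_index("patient_id")["archetype"]

    def row(self, patient_id: str) -> pd.Series:
        sel = self.frame[self.frame["patient_id"] == patient_id]
        if not len(sel):
            raise KeyError(patient_id)
        return sel.iloc[0]


def cohort_observation_counts(records: Iterable[PatientRecord]) -> pd.Series:
    """Observations per feature across a cohort (useful sanity check)."""
    frames = [r.observations for r in records if len(r.observations)]
    if not frames:
        return pd.Series(dtype=int)
    return pd.concat(frames)["feature"].value_counts()
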