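"""Alignment of risk trajectories into a fixed-length matrix for clustering.

Trajectories are aligned about an anchor - the time of early prediction
(threshold crossing) or the time of first intervention - and evaluated by
LOCF risk scoring on an evenly spaced grid of offsets. Patients without the
anchor are excluded and logged; patients whose record ends inside the window
are extended by LOCF (their latest observations keep being carried forward)
and flagged incomplete.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .exceptions import InputError
from .records import HOUR, PatientRecord

logger = logging.getLogger(__name__)

ANCHOR_KINDS = ("early_prediction", "first_intervention", "latent_transition")


@dataclass
class TrajectoryMatrix:
    patient_ids: list[str]
    anchor_kind: str
    relative_times_h: np.ndarray
    values: np.ndarray  # patients x timepoints
    window: tuple[float, float]
    step_h: float = 1.0
    complete: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=bool))
    exclusions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size and not np.isfinite(self.values).all():
            raise InputError("trajectory matrix contains non-finite entries")
        if 0.0 not in np.round(self.relative_times_h, 9):
            raise InputError("relative time grid must include the anchor (0)")

    @property
    def n_patients(self) -> int:
        return len(self.patient_ids)

    def truncated(self, max_offset_h: float) -> "TrajectoryMatrix":
        """Restrict to grid offsets in [window start, max_offset_h]."""
        if max_offset_h > self.window[1] + 1e-9:
            raise InputError(f"duration {max_offset_h} h exceeds window "
                             f"{self.window}")
        keep = self.relative_times_h <= max_offset_h + 1e-9
        return TrajectoryMatrix(
            patient_ids=list(self.patient_ids), anchor_kind=self.anchor_kind,
            relative_times_h=self.relative_times_h[keep],
            values=self.values[:, keep],
            window=(self.window[0], max_offset_h), step_h=self.step_h,
            complete=self.complete, exclusions=dict(self.exclusions))

    # ------------------------------------------------------------------- io
    def to_csv(self, path: str | Path) -> None:
        path = Path(path)
        cols = [f"h{h:+g}" for h in self.relative_times_h]
        df = pd.DataFrame(self.values, index=self.patient_ids, columns=cols)
        df.index.name = "patient_id"
        df.to_csv(path)
        meta = {"anchor_kind": self.anchor_kind, "window": list(self.window),
                "step_h": self.step_h, "exclusions": self.exclusions,
                "complete": [bool(c) for c in self.complete]}
        path.with_suffix(".meta.json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def from_csv(cls, path: str | Path) -> "TrajectoryMatrix":
        path = Path(path)
        df = pd.read_csv(path, index_col="patient_id")
        meta = json.loads(path.with_suffix(".meta.json").read_text())
        rel = np.array([float(c[1:]) for c in df.columns])
        return cls(patient_ids=[str(i) for i in df.index],
                   anchor_kind=meta["anchor_kind"], relative_times_h=rel,
                   values=df.to_numpy(dtype=float),
                   window=tuple(meta["window"]), step_h=meta["step_h"],
                   complete=np.asarray(meta["complete"], dtype=bool),
                   exclusions=meta["exclusions"])


def align_trajectories(model, records: Iterable[PatientRecord],
                       anchors: Mapping[str, float | None],
                       anchor_kind: str = "early_prediction",
                       window: tuple[float, float] | None = None,
                       step_h: float = 1.0) -> TrajectoryMatrix:
    """Assemble the aligned risk matrix.

    ``anchors`` maps patient id to anchor time in minutes (None/NaN excludes
    the patient). ``model`` is either one risk model or a mapping patient id
    -> model (cross-fitted scoring). Default windows: [0, +12] h about the
    early prediction, [-6, +12] h about the first intervention.
    """
    from .risk import locf_matrix  # deferred: risk imports records only

    if anchor_kind not in ANCHOR_KINDS:
        raise InputError(f"unknown anchor_kind {anchor_kind!r}")
    if window is None:
        window = (0.0, 12.0) if anchor_kind == "early_prediction" else (-6.0, 12.0)
    rel = np.arange(window[0], window[1] + step_h / 2, step_h)
    ids, rows, complete = [], [], []
    exclusions: dict[str, str] = {}
    for rec in records:
        anchor = anchors.get(rec.patient_id)
        if anchor is None or (isinstance(anchor, float) and np.isnan(anchor)):
            exclusions[rec.patient_id] = f"no {anchor_kind} anchor"
            logger.info("excluding %s: no %s anchor", rec.patient_id, anchor_kind)
            continue
        grid = float(anchor) + rel * HOUR
        mdl = model[rec.patient_id] if isinstance(model, Mapping) else model
        risk = mdl.predict(locf_matrix(rec, grid, mdl.features))
        ids.append(rec.patient_id)
        rows.append(risk)
        complete.append(bool(rec.end_time is None or grid[-1] <= rec.end_time))
    values = np.vstack(rows) if rows else np.empty((0, rel.size))
    return TrajectoryMatrix(patient_ids=ids, anchor_kind=anchor_kind,
                            relative_times_h=rel, values=values, window=window,
                            step_h=step_h,
                            complete=np.asarray(complete, dtype=bool),
                            exclusions=exclusions)
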