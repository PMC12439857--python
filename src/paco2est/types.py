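"""Domain containers shared across pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from paco2est.config import CHANNEL_UNITS


@dataclass
class CaseRecord:
    """One surgical case's clinical information and pulmonary function tests."""

    case_id: str
    age: float                      # years, study inclusion 18-80
    sex: str                        # "male" | "female"
    height: float                   # cm
    weight: float                   # kg
    asa_class: int                  # ASA physical status 1-5
    surgery_type: str
    surgical_approach: str
    fev1_fvc_ratio: Optional[float] = None   # dimensionless, (0, 1]
    fvc_pct_predicted: Optional[float] = None  # percent of predicted

    def __post_init__(self) -> None:
        if not 18 <= self.age <= 80:
            raise ValueError(f"{self.case_id}: age {self.age} outside [18, 80]")
        if self.height <= 0 or self.weight <= 0:
            raise ValueError(f"{self.case_id}: nonpositive height/weight")
        if not 1 <= self.asa_class <= 5:
            raise ValueError(f"{self.case_id}: ASA class {self.asa_class}")
        if self.fev1_fvc_ratio is not None and not 0 < self.fev1_fvc_ratio <= 1:
            raise ValueError(f"{self.case_id}: FEV1/FVC {self.fev1_fvc_ratio}")
        if self.fvc_pct_predicted is not None and self.fvc_pct_predicted <= 0:
            raise ValueError(f"{self.case_id}: FVC% {self.fvc_pct_predicted}")


@dataclass
class BiosignalTrace:
    """One channel's timestamped samples for one case.

    ``times`` are seconds from case start, strictly increasing; ``values``
    may contain NaN for explicitly missing samples.
    """

    case_id: str
    channel: str
    times: np.ndarray
    values: np.ndarray
    units: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.channel not in CHANNEL_UNITS:
            raise ValueError(f"unknown channel {self.channel!r}")
        if not self.units:
            self.units = CHANNEL_UNITS[self.channel]
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal length")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError(
                f"{self.case_id}/{self.channel}: sample times not strictly increasing")

    @property
    def span(self) -> tuple[float, float]:
        return float(self.times[0]), float(self.times[-1])


@dataclass
class AbgaEvent:
    """One PaCO2 measurement with its database-recorded timestamp.

    For synthetic data the hidden true draw time and surge flag are carried
    along solely to score alignment; the estimation pipeline never reads them.
    """

    case_id: str
    recorded_time_s: float
    paco2: float
    true_draw_time_s: Optional[float] = None
    surge_present: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.paco2 <= 0:
            raise ValueError(f"{self.case_id}: nonpositive PaCO2")
        if (self.true_draw_time_s is not None
                and self.recorded_time_s < self.true_draw_time_s):
            raise ValueError(
                f"{self.case_id}: recorded time precedes true draw time")


@dataclass
class Cohort:
    """A full synthetic cohort: clinical table, traces, and ABGA events."""

    cases: list[CaseRecord]
    traces: list[BiosignalTrace]
    abga: list[AbgaEvent]

    _trace_index: dict[tuple[str, str], BiosignalTrace] = field(
        default_factory=dict, repr=False)

    def trace(self, case_id: str, channel: str) -> Optional[BiosignalTrace]:
        if not self._trace_index:
            self._trace_index = {(t.case_id, t.channel): t for t in self.traces}
        return self._trace_index.get((case_id, channel))

    def clinical_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.cases:
            rows.append({
                "case_id": c.case_id, "age": c.age, "sex": c.sex,
                "height": c.height, "weight": c.weight,
                "asa_class": c.asa_class, "surgery_type": c.surgery_type,
                "surgical_approach": c.surgical_approach,
                "fev1_fvc_ratio": np.nan if c.fev1_fvc_ratio is None else c.fev1_fvc_ratio,
                "fvc_pct_predicted": np.nan if c.fvc_pct_predicted is None else c.fvc_pct_predicted,
            })
        return pd.DataFrame(rows)

    def signals_frame(self) -> pd.DataFrame:
        parts = []
        for t in self.traces:
            parts.append(pd.DataFrame({
                "case_id": t.case_id, "channel": t.channel,
                "time_s": t.times, "value": t.values,
            }))
        return pd.concat(parts, ignore_index=True)

    def abga_frame(self, include_hidden: bool = True) -> pd.DataFrame:
        rows = []
        for e in self.abga:
            row = {"case_id": e.case_id, "recorded_time_s": e.recorded_time_s,
                   "paco2": e.paco2}
            if include_hidden:
                row["true_draw_time_s"] = (
                    np.nan if e.true_draw_time_s is None else e.true_draw_time_s)
                row["surge_present"] = e.surge_present
            rows.append(row)
        return pd.DataFrame(rows)

    @classmethod
    def from_frames(cls, clinical: pd.DataFrame, signals: pd.DataFrame,
                    abga: pd.DataFrame) -> "Cohort":
        cases = [CaseRecord(
            case_id=str(r.case_id), age=float(r.age), sex=str(r.sex),
            height=float(r.height), weight=float(r.weight),
            asa_class=int(r.asa_class), surgery_type=str(r.surgery_type),
            surgical_approach=str(r.surgical_approach),
            fev1_fvc_ratio=None if pd.isna(r.fev1_fvc_ratio) else float(r.fev1_fvc_ratio),
            fvc_pct_predicted=None if pd.isna(r.fvc_pct_predicted) else float(r.fvc_pct_predicted),
        ) for r in clinical.itertuples()]
        traces = []
        for (cid, ch), grp in signals.groupby(["case_id", "channel"], sort=True):
            traces.append(BiosignalTrace(
                case_id=str(cid), channel=str(ch),
                times=grp["time_s"].to_numpy(dtype=float),
                values=grp["value"].to_numpy(dtype=float)))
        events = []
        for r in abga.itertuples():
            events.append(AbgaEvent(
                case_id=str(r.case_id),
                recorded_time_s=float(r.recorded_time_s),
                paco2=float(r.paco2),
                true_draw_time_s=(float(r.true_draw_time_s)
                                  if hasattr(r, "true_draw_time_s")
                                  and not pd.isna(r.true_draw_time_s) else None),
                surge_present=(bool(r.surge_present)
                               if hasattr(r, "surge_present")
                               and not pd.isna(r.surge_present) else None)))
        return cls(cases=cases, traces=traces, abga=events)
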