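"""Event-timestamp refinement from MAP pressure surges.

The database timestamp of an arterial blood gas record marks result entry,
not the draw itself.  Drawing blood through the arterial line transiently
occludes it and raises the measured mean arterial pressure, so the draw
moment is recovered by z-score outlier detection on the MAP trace in the
20-minute interval preceding the recorded timestamp: maximal runs of
samples whose z score (against the lookback window's own mean and sample
SD) exceeds the threshold form abnormal periods, and the period nearest the
recorded time gives the estimated draw.  Events with no detectable surge in
the lookback are excluded as unreliably timed.

The feature trigger is then placed a fixed interval before the estimated
draw, and the observation window ends a (configurable, default zero)
blackout before the trigger.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from paco2est.config import AlignmentConfig
from paco2est.types import AbgaEvent, BiosignalTrace, Cohort

STATUS_ALIGNED = "aligned"
STATUS_NO_SURGE = "excluded_no_surge"
STATUS_MISSING = "excluded_missing_features"


@dataclass
class AbnormalPeriod:
    """A maximal run of consecutive samples above the z threshold."""

    start_s: float
    end_s: float
    peak_time_s: float   # time of the maximum z within the run
    peak_z: float

    def distance_to(self, t: float) -> float:
        """Time distance from ``t`` to the period (0 if inside)."""
        if t < self.start_s:
            return self.start_s - t
        if t > self.end_s:
            return t - self.end_s
        return 0.0


@dataclass
class EventPoint:
    """An aligned (or excluded) estimation event."""

    case_id: str
    recorded_time_s: float
    status: str
    estimated_draw_time_s: Optional[float] = None
    trigger_time_s: Optional[float] = None
    window_start_s: Optional[float] = None
    window_end_s: Optional[float] = None
    target_paco2: Optional[float] = None
    features: dict = field(default_factory=dict)


def compute_window_zscores(values: np.ndarray) -> np.ndarray:
    """Z scores of MAP samples against the lookback window's own statistics.

    Uses the window mean and sample SD (ddof=1).  A zero-variance window
    yields all-zero z (nothing can be abnormal relative to it).  NaNs stay
    NaN and never exceed any threshold.
    """
    values = np.asarray(values, dtype=float)
    finite = np.isfinite(values)
    n = int(finite.sum())
    if n < 2:
        return np.zeros_like(values)
    mean = values[finite].mean()
    sd = values[finite].std(ddof=1)
    if sd == 0:
        z = np.zeros_like(values)
        z[~finite] = np.nan
        return z
    return (values - mean) / sd


def find_abnormal_periods(times: np.ndarray, z: np.ndarray,
                          z_threshold: float) -> list[AbnormalPeriod]:
    """Maximal runs of consecutive samples with z strictly above threshold.

    One-sided: only positive excursions count, since a blood draw raises
    MAP.  Periods are returned in time order.
    """
    times = np.asarray(times, dtype=float)
    z = np.asarray(z, dtype=float)
    above = np.zeros(z.size, dtype=bool)
    finite = np.isfinite(z)
    above[finite] = z[finite] > z_threshold
    if not above.any():
        return []
    # run boundaries from the transition points
    padded = np.concatenate([[False], above, [False]])
    starts = np.flatnonzero(padded[1:] & ~padded[:-1])
    ends = np.flatnonzero(~padded[1:] & padded[:-1])  # exclusive index
    periods = []
    for s, e in zip(starts, ends):
        seg = slice(s, e)
        k = s + int(np.argmax(z[seg]))
        periods.append(AbnormalPeriod(start_s=float(times[s]),
                                      end_s=float(times[e - 1]),
                                      peak_time_s=float(times[k]),
                                      peak_z=float(z[k])))
    return periods


def estimate_draw_time(map_trace: BiosignalTrace, recorded_time_s: float,
                       config: AlignmentConfig) -> Optional[float]:
    """Estimated draw time from the nearest abnormal MAP period, or None.

    Only samples in ``[recorded - lookback, recorded]`` are inspected (no
    lookahead past the recorded timestamp).  Among the abnormal periods the
    one whose boundary is nearest the recorded time is chosen; ties go to
    the later period (closer to data entry).  The returned time is the
    moment of maximum z within the chosen period.
    """
    t0 = recorded_time_s - config.lookback_s
    mask = (map_trace.times >= t0) & (map_trace.times <= recorded_time_s)
    vals = map_trace.values[mask]
    if int(np.isfinite(vals).sum()) < config.min_window_samples:
        return None
    z = compute_window_zscores(vals)
    periods = find_abnormal_periods(map_trace.times[mask], z, config.z_threshold)
    if not periods:
        return None
    # nearest boundary; ties resolved toward the later period
    best = min(periods,
               key=lambda p: (p.distance_to(recorded_time_s), -p.start_s))
    return best.peak_time_s


def build_event_point(abga: AbgaEvent, draw_time_s: Optional[float],
                      config: AlignmentConfig,
                      case_start_s: float = 0.0) -> EventPoint:
    """Attach trigger time and observation window to one ABGA event.

    trigger = draw - pre_trigger; window = [trigger - blackout - window_s,
    trigger - blackout).  Events whose window would begin before the case
    start are excluded for insufficient history.
    """
    ep = EventPoint(case_id=abga.case_id, recorded_time_s=abga.recorded_time_s,
                    status=STATUS_NO_SURGE, target_paco2=abga.paco2)
    if draw_time_s is None:
        return ep
    trigger = draw_time_s - config.pre_trigger_s
    w_end = trigger - config.blackout_s
    w_start = w_end - config.window_s
    if w_start < case_start_s:
        return ep
    ep.status = STATUS_ALIGNED
    ep.estimated_draw_time_s = draw_time_s
    ep.trigger_time_s = trigger
    ep.window_start_s = w_start
    ep.window_end_s = w_end
    return ep


def align_events(cohort: Cohort, config: AlignmentConfig) -> list[EventPoint]:
    """Align every ABGA event in a cohort against its case's MAP trace."""
    config.validate()
    out = []
    for abga in cohort.abga:
        trace = cohort.trace(abga.case_id, "MAP")
        if trace is None:
            raise KeyError(f"no MAP trace for case {abga.case_id}")
        draw = estimate_draw_time(trace, abga.recorded_time_s, config)
        out.append(build_event_point(abga, draw, config,
                                     case_start_s=trace.span[0]))
    return out


def events_frame(events: list[EventPoint]) -> pd.DataFrame:
    """Tabular view of event points (one row per ABGA event)."""
    rows = []
    for i, e in enumerate(events):
        rows.append({
            "event_id": i, "case_id": e.case_id,
            "recorded_time_s": e.recorded_time_s, "status": e.status,
            "estimated_draw_time_s": e.estimated_draw_time_s,
            "trigger_time_s": e.trigger_time_s,
            "window_start_s": e.window_start_s,
            "window_end_s": e.window_end_s,
            "target_paco2": e.target_paco2,
        })
    return pd.DataFrame(rows)
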