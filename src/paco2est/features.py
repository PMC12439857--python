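"""Windowed feature extraction and the model-ready event table.

For each aligned event the 60-second observation window of every biosignal
is sliced, cleaned (clinical plausibility bounds first, then a 3x-IQR
outlier fence), and summarized by its median.  Engineered features add
recognized physiological indices — tidal volume per ideal body weight,
SpO2/FiO2, PEEP/FiO2, respiratory-system compliance and the rapid shallow
breathing index — plus a pulmonary-function-test grade.  Events missing any
predictor are dropped (listwise deletion) with per-reason accounting, and
continuous features are robust-scaled (median/IQR) with state fitted on
training rows only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from paco2est.align import STATUS_ALIGNED, STATUS_MISSING, EventPoint
from paco2est.config import FeatureConfig
from paco2est.types import Cohort

#: biosignal channels summarized by their window median
BIOSIGNAL_FEATURES = ("BT", "HR", "SPO2", "MV", "PEEP", "PIP", "PPLAT",
                      "MAWP", "RR", "TV", "FIO2", "ETCO2")
OPTIONAL_FEATURES = ("CO",)
ENGINEERED_FEATURES = ("tv_ibw", "sf_ratio", "peep_fio2", "crs", "rsbi")
CLINICAL_CONTINUOUS = ("age", "height", "weight")
CATEGORICAL_FEATURES = ("sex", "surgery_type", "surgical_approach",
                        "asa_class", "pft_grade")
TARGET = "paco2"


def continuous_features(include_co: bool = True) -> tuple[str, ...]:
    cols = tuple(ch.lower() for ch in BIOSIGNAL_FEATURES)
    if include_co:
        cols = cols + tuple(ch.lower() for ch in OPTIONAL_FEATURES)
    return cols + ENGINEERED_FEATURES + CLINICAL_CONTINUOUS


def slice_window(times: np.ndarray, values: np.ndarray,
                 start: float, end: float) -> np.ndarray:
    """Samples with start <= t < end (half-open window), order preserved."""
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    m = (times >= start) & (times < end)
    return values[m]


def filter_plausibility(values: np.ndarray,
                        bounds: tuple[float, float]) -> np.ndarray:
    """Drop values outside the physiologic [min, max] range (and NaNs)."""
    values = np.asarray(values, dtype=float)
    lo, hi = bounds
    keep = np.isfinite(values) & (values >= lo) & (values <= hi)
    return values[keep]


def filter_outliers_iqr(values: np.ndarray, k: float = 3.0) -> np.ndarray:
    """Keep values within [Q1 - k*IQR, Q3 + k*IQR].

    Quartiles use linear interpolation.  With IQR 0 the fence collapses to
    the quartiles, so identical values all survive.
    """
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size == 0:
        return values
    q1, q3 = np.percentile(values, [25.0, 75.0])
    iqr = q3 - q1
    lo, hi = q1 - k * iqr, q3 + k * iqr
    return values[(values >= lo) & (values <= hi)]


def window_median(values: np.ndarray) -> float:
    """Sample median; NaN marks a missing summary for an empty window."""
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size == 0:
        return float("nan")
    return float(np.median(values))


def ideal_body_weight(height_cm: float, sex: str) -> float:
    """Devine ideal body weight (kg), floored at 30 kg for short statures."""
    if height_cm <= 0:
        raise ValueError("height must be positive")
    inches = height_cm / 2.54
    base = 50.0 if sex == "male" else 45.5
    return max(30.0, base + 2.3 * (inches - 60.0))


def respiratory_compliance(tv_mL: float, pplat_cmH2O: float,
                           peep_cmH2O: float) -> float:
    """Static compliance TV/(Pplat - PEEP) in mL/cmH2O.

    A nonpositive driving pressure is physically invalid and returns NaN,
    which listwise deletion later removes.
    """
    driving = pplat_cmH2O - peep_cmH2O
    if not np.isfinite(driving) or driving <= 0 or not np.isfinite(tv_mL):
        return float("nan")
    return tv_mL / driving


def engineered_ratios(spo2_pct: float, fio2_frac: float, peep: float,
                      rr: float, tv_mL: float) -> tuple[float, float, float]:
    """(SpO2/FiO2, PEEP/FiO2, RSBI) from window medians.

    RSBI is respiratory rate over tidal volume in liters
    (breaths/min/L); a zero tidal volume leaves it missing.
    """
    sf = spo2_pct / fio2_frac
    peep_fio2 = peep / fio2_frac
    rsbi = rr / (tv_mL / 1000.0) if tv_mL > 0 else float("nan")
    return sf, peep_fio2, rsbi


def classify_pft(fev1_fvc_ratio, fvc_pct_predicted) -> str:
    """Grade a pulmonary function test: none/obstructive/restrictive/mixed.

    Spirometric cutoffs: obstruction at FEV1/FVC < 0.70, restriction at
    FVC < 80% predicted; both together grade as mixed; absent values grade
    as none.
    """
    if fev1_fvc_ratio is None or fvc_pct_predicted is None:
        return "none"
    if isinstance(fev1_fvc_ratio, float) and np.isnan(fev1_fvc_ratio):
        return "none"
    if isinstance(fvc_pct_predicted, float) and np.isnan(fvc_pct_predicted):
        return "none"
    obstructive = fev1_fvc_ratio < 0.70
    restrictive = fvc_pct_predicted < 80.0
    if obstructive and restrictive:
        return "mixed"
    if obstructive:
        return "obstructive"
    if restrictive:
        return "restrictive"
    return "none"


def _window_summary(cohort: Cohort, event: EventPoint, channel: str,
                    config: FeatureConfig) -> float:
    trace = cohort.trace(event.case_id, channel)
    if trace is None:
        return float("nan")
    vals = slice_window(trace.times, trace.values,
                        event.window_start_s, event.window_end_s)
    bounds = config.plausibility.get(channel)
    if bounds is not None:
        vals = filter_plausibility(vals, bounds)
    vals = filter_outliers_iqr(vals, k=config.iqr_k)
    return window_median(vals)


def assemble_feature_table(events: list[EventPoint], cohort: Cohort,
                           config: FeatureConfig
                           ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Build the model-ready table plus an exclusion log.

    Per aligned event: slice each channel's window, apply plausibility then
    IQR filtering, take the median, derive engineered features, and join the
    case's clinical fields.  Events with any missing predictor are marked
    ``excluded_missing_features``; the log has one row per exclusion reason.
    Raises for an event whose case is unknown.
    """
    config.validate()
    case_map = {c.case_id: c for c in cohort.cases}
    has_co = config.include_co and any(t.channel == "CO" for t in cohort.traces)

    rows, excl = [], []
    for i, ev in enumerate(events):
        if ev.case_id not in case_map:
            raise KeyError(f"event references unknown case {ev.case_id}")
        if ev.status != STATUS_ALIGNED:
            excl.append({"event_id": i, "case_id": ev.case_id,
                         "reason": ev.status})
            continue
        case = case_map[ev.case_id]
        feats: dict[str, object] = {"event_id": i, "case_id": ev.case_id,
                                    "trigger_time_s": ev.trigger_time_s}
        missing = []
        channels = BIOSIGNAL_FEATURES + (OPTIONAL_FEATURES if has_co else ())
        for ch in channels:
            v = _window_summary(cohort, ev, ch, config)
            feats[ch.lower()] = v
            if not np.isfinite(v):
                missing.append(ch)

        ibw = ideal_body_weight(case.height, case.sex)
        tv, pplat, peep = feats["tv"], feats["pplat"], feats["peep"]
        spo2, fio2, rr = feats["spo2"], feats["fio2"], feats["rr"]
        feats["tv_ibw"] = tv / ibw if np.isfinite(tv) else float("nan")
        crs = respiratory_compliance(tv, pplat, peep)
        feats["crs"] = crs
        if np.isfinite(spo2) and np.isfinite(fio2) and np.isfinite(rr) \
                and np.isfinite(tv) and np.isfinite(peep):
            sf, pf, rsbi = engineered_ratios(spo2, fio2, peep, rr, tv)
        else:
            sf = pf = rsbi = float("nan")
        feats["sf_ratio"], feats["peep_fio2"], feats["rsbi"] = sf, pf, rsbi
        if not np.isfinite(crs):
            missing.append("PPLAT/CRS" if "PPLAT" not in missing else "CRS")
        if not np.isfinite(rsbi) and "RSBI" not in missing:
            missing.append("RSBI")

        feats["age"] = case.age
        feats["height"] = case.height
        feats["weight"] = case.weight
        feats["sex"] = case.sex
        feats["surgery_type"] = case.surgery_type
        feats["surgical_approach"] = case.surgical_approach
        feats["asa_class"] = case.asa_class
        feats["pft_grade"] = classify_pft(case.fev1_fvc_ratio,
                                          case.fvc_pct_predicted)
        feats[TARGET] = ev.target_paco2

        predictors = [c for c in continuous_features(has_co) if c in feats]
        if missing or any(not np.isfinite(feats[c]) for c in predictors):
            ev.status = STATUS_MISSING
            excl.append({"event_id": i, "case_id": ev.case_id,
                         "reason": "missing: " + ",".join(sorted(set(missing)))})
            continue
        ev.features = {k: v for k, v in feats.items()
                       if k not in ("event_id", "case_id", "trigger_time_s")}
        rows.append(feats)

    features = pd.DataFrame(rows)
    exclusions = pd.DataFrame(excl, columns=["event_id", "case_id", "reason"])
    return features, exclusions


@dataclass
class ScalerState:
    """Per-feature robust-scaling state: center (median) and scale (IQR).

    Degenerate IQR falls back to scale 1 and flags the feature constant.
    """

    columns: list[str]
    center: dict[str, float]
    scale: dict[str, float]
    constant: list[str]


def robust_scale_fit(frame: pd.DataFrame, columns: list[str]) -> ScalerState:
    """Fit median/IQR scaling on training rows only."""
    center, scale, constant = {}, {}, []
    for c in columns:
        x = frame[c].to_numpy(dtype=float)
        med = float(np.median(x))
        q1, q3 = np.percentile(x, [25.0, 75.0])
        iqr = float(q3 - q1)
        if iqr == 0.0:
            iqr = 1.0
            constant.append(c)
        center[c], scale[c] = med, iqr
    return ScalerState(columns=list(columns), center=center, scale=scale,
                       constant=constant)


def robust_scale_apply(state: ScalerState, frame: pd.DataFrame) -> pd.DataFrame:
    """Apply stored scaling state; never recomputes statistics."""
    out = frame.copy()
    for c in state.columns:
        out[c] = (frame[c].to_numpy(dtype=float) - state.center[c]) / state.scale[c]
    return out


def robust_scale_invert(state: ScalerState, frame: pd.DataFrame) -> pd.DataFrame:
    out = frame.copy()
    for c in state.columns:
        out[c] = frame[c].to_numpy(dtype=float) * state.scale[c] + state.center[c]
    return out
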