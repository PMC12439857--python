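"""Synthetic surgical-cohort generator.

Emulates the statistical structure of an intraoperative biosignal study:
mean-arterial-pressure (MAP) traces carrying transient surges at arterial
blood-draw times (a configurable fraction of draws lack one), database entry
delays with median 34 s and IQR 22-54 s, slowly varying end-tidal CO2,
ventilator and physiology channels, and a ground-truth arterial CO2 built as
ETCO2 plus a gradient that rises with age and falls with body temperature,
SpO2/FiO2 ratio and respiratory-system compliance — averaging about
7.6 mmHg over the cohort.

The generator is the study-conditions oracle for the rest of the package:
the hidden true draw times and surge flags it records are used only to
score the alignment stage, never by the estimation pipeline itself.
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np
from scipy.signal import lfilter

from paco2est.config import GeneratorConfig
from paco2est.types import AbgaEvent, BiosignalTrace, CaseRecord, Cohort

# Channels other than MAP are emitted at this coarser interval; MAP keeps
# config.sample_interval_s because surge detection needs its full resolution.
SLOW_INTERVAL_S = 2.0

SURGERY_TYPES = ("general", "gynecologic", "urologic", "orthopedic",
                 "thoracic", "neurosurgic")
SURGERY_P = (0.34, 0.16, 0.16, 0.14, 0.10, 0.10)
APPROACHES = ("open", "laparoscopic", "robotic")
APPROACH_P = (0.5, 0.4, 0.1)

# Skewed unimodal bump: fast rise (line occlusion), slower decay.
_BUMP_PEAK_FRAC = 0.25
_BUMP_A, _BUMP_B = 1.5, 4.5
_BUMP_NORM = 1.0 / (_BUMP_PEAK_FRAC ** _BUMP_A * (1 - _BUMP_PEAK_FRAC) ** _BUMP_B)


def _bump_shape(u: np.ndarray) -> np.ndarray:
    """Unimodal bump on [0, 1], peak 1 at u=0.25, zero at both ends."""
    s = np.zeros_like(u)
    inside = (u > 0) & (u < 1)
    ui = u[inside]
    s[inside] = _BUMP_NORM * ui ** _BUMP_A * (1 - ui) ** _BUMP_B
    return s


def inject_surge(trace: BiosignalTrace, time_s: float, amplitude: float,
                 duration_s: float) -> BiosignalTrace:
    """Return a copy of ``trace`` with a transient pressure bump added.

    The bump is a smooth unimodal excursion supported on
    ``[time_s, time_s + duration_s]`` with maximum ``amplitude``; samples
    outside that interval are unchanged.  ``amplitude`` 0 is a no-op.
    """
    lo, hi = trace.span
    if not lo <= time_s <= hi:
        raise ValueError(f"surge time {time_s} outside trace span [{lo}, {hi}]")
    if amplitude < 0:
        raise ValueError("surge amplitude must be >= 0")
    values = trace.values.copy()
    if amplitude > 0:
        u = (trace.times - time_s) / duration_s
        values = values + amplitude * _bump_shape(u)
    return BiosignalTrace(case_id=trace.case_id, channel=trace.channel,
                          times=trace.times, values=values, units=trace.units)


def _add_bump(times: np.ndarray, values: np.ndarray, time_s: float,
              amplitude: float, duration_s: float) -> None:
    """In-place bump addition on raw arrays (generator fast path)."""
    u = (times - time_s) / duration_s
    values += amplitude * _bump_shape(u)


def _ou_series(rng: np.random.Generator, n: int, sd: float, tau_s: float,
               dt: float) -> np.ndarray:
    """Mean-reverting (Ornstein-Uhlenbeck) noise with stationary sd ``sd``."""
    if sd == 0 or n == 0:
        return np.zeros(n)
    a = np.exp(-dt / tau_s)
    innov_sd = sd * np.sqrt(1 - a * a)
    innov = rng.normal(0.0, 1.0, size=n)
    innov[0] *= sd          # start in the stationary distribution
    innov[1:] *= innov_sd
    return lfilter([1.0], [1.0, -a], innov)


def _map_noise(rng: np.random.Generator, t: np.ndarray, sd: float) -> np.ndarray:
    """Baseline MAP variability: two oscillations plus bounded jitter.

    Mean arterial pressure fluctuates quasi-periodically (Mayer waves around
    0.05-0.07 Hz, slower vasomotor drift); modelling the noise as two
    sinusoids with random per-case amplitude, period and phase plus uniform
    measurement jitter makes the max-deviation-to-SD ratio of any full
    lookback window provably below the z=3 surge threshold, so only an
    injected surge can ever register as abnormal.  Overall SD is close to
    ``sd`` (default 4 mmHg).
    """
    k = sd / 4.0
    a1 = k * rng.uniform(3.0, 5.0)
    a2 = k * rng.uniform(1.5, 2.5)
    t1 = rng.uniform(14.0, 22.0)      # Mayer-wave band
    t2 = rng.uniform(45.0, 90.0)      # slow vasomotor band
    p1, p2 = rng.uniform(0.0, 2 * np.pi, size=2)
    jitter = k * rng.uniform(-1.5, 1.5, size=t.size)
    return (a1 * np.sin(2 * np.pi * t / t1 + p1)
            + a2 * np.sin(2 * np.pi * t / t2 + p2) + jitter)


def sample_gradient(case: CaseRecord, window_state: dict, config: GeneratorConfig,
                    rng: np.random.Generator) -> float:
    """Draw one arterial-minus-end-tidal CO2 gradient (mmHg).

    Linear in engineered covariates around clinical reference points —
    age 50 y, body temperature 36.5 degC, SpO2/FiO2 400, respiratory-system
    compliance 50 mL/cmH2O — plus Gaussian noise.  Signs follow the
    physiology: the gradient widens with age and with lower temperature,
    oxygenation ratio and compliance.
    """
    bt = window_state["BT"]
    sf = window_state["SPO2"] / window_state["FIO2"]
    driving = window_state["PPLAT"] - window_state["PEEP"]
    crs = window_state["TV"] / driving
    g = (config.gamma0
         + config.gamma_age * (case.age - 50.0) / 10.0
         - config.gamma_bt * (bt - 36.5)
         - config.gamma_sf * (sf - 400.0) / 100.0
         - config.gamma_crs * (crs - 50.0) / 10.0)
    if config.sigma_g > 0:
        g += rng.normal(0.0, config.sigma_g)
    return float(g)


def sample_entry_delay(config: GeneratorConfig, rng: np.random.Generator) -> float:
    """Database entry delay (s): right-skewed log-normal, capped.

    Default parameters put the median at 34 s with quartiles near 22 and
    54 s, matching the delay statistics the alignment stage is built for.
    """
    d = float(rng.lognormal(config.entry_delay_mu, config.entry_delay_sigma))
    return min(d, config.entry_delay_max_s)


def _sample_case(rng: np.random.Generator, case_id: str) -> CaseRecord:
    age = float(rng.integers(18, 81))
    sex = "male" if rng.random() < 0.55 else "female"
    if sex == "male":
        height = float(np.clip(rng.normal(172.0, 7.0), 150.0, 200.0))
    else:
        height = float(np.clip(rng.normal(159.0, 6.0), 140.0, 185.0))
    bmi = float(np.clip(rng.normal(24.0, 3.5), 16.0, 40.0))
    weight = round(bmi * (height / 100.0) ** 2, 1)
    asa = int(rng.choice([1, 2, 3, 4, 5], p=[0.25, 0.45, 0.22, 0.07, 0.01]))
    stype = str(rng.choice(SURGERY_TYPES, p=SURGERY_P))
    approach = str(rng.choice(APPROACHES, p=APPROACH_P))
    if rng.random() < 0.25:          # no preoperative PFT on record
        ratio, fvc = None, None
    else:
        ratio = float(np.clip(rng.normal(0.78, 0.09), 0.30, 0.95))
        fvc = float(np.clip(rng.normal(95.0, 16.0), 35.0, 140.0))
    return CaseRecord(case_id=case_id, age=age, sex=sex, height=round(height, 1),
                      weight=weight, asa_class=asa, surgery_type=stype,
                      surgical_approach=approach, fev1_fvc_ratio=ratio,
                      fvc_pct_predicted=fvc)


def _devine_ibw(height_cm: float, sex: str) -> float:
    inches = height_cm / 2.54
    base = 50.0 if sex == "male" else 45.5
    return max(30.0, base + 2.3 * (inches - 60.0))


def _schedule_draws(rng: np.random.Generator, config: GeneratorConfig,
                    duration: float) -> list[tuple[float, bool, float]]:
    """Place blood draws in one case: (draw_time, surge_present, entry_delay).

    Every draw is spaced a clean 20-minute lookback past the previous one,
    so a surge-free draw's lookback never contains an earlier draw's surge.
    Spacing is independent of the surge flag, keeping the realized
    surge-free fraction an unbiased binomial draw even when the case
    duration truncates the schedule.
    """
    lo, hi = config.abga_per_case
    n_target = int(rng.integers(lo, hi + 1))
    gap_min = max(config.min_gap_s, 1300.0)
    out: list[tuple[float, bool, float]] = []
    t_prev: Optional[float] = None
    for _ in range(n_target):
        surge = rng.random() >= config.no_surge_fraction
        delay = sample_entry_delay(config, rng)
        if t_prev is None:
            t = config.first_draw_s + float(rng.uniform(0.0, 300.0))
        else:
            t = t_prev + gap_min + float(rng.exponential(300.0))
        if t + delay + 60.0 > duration:
            break
        out.append((t, surge, delay))
        t_prev = t
    return out


def _window_median(times: np.ndarray, values: np.ndarray,
                   start: float, end: float) -> float:
    m = (times >= start) & (times < end)
    return float(np.median(values[m]))


def generate_cohort(config: GeneratorConfig) -> Cohort:
    """Generate a full synthetic cohort, deterministically from the seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    dt_map = config.sample_interval_s
    dt_slow = max(SLOW_INTERVAL_S, dt_map)

    cases: list[CaseRecord] = []
    traces: list[BiosignalTrace] = []
    events: list[AbgaEvent] = []

    for i in range(config.n_cases):
        case = _sample_case(rng, case_id=f"C{i + 1:04d}")
        cases.append(case)
        duration = float(rng.uniform(*config.case_duration_s))
        t_map = np.arange(0.0, duration, dt_map)
        t_slow = np.arange(0.0, duration, dt_slow)

        # per-case ventilator settings (piecewise constant over the case)
        ibw = _devine_ibw(case.height, case.sex)
        tv = round(ibw * float(rng.uniform(6.0, 8.0)) / 10.0) * 10.0
        rr = float(rng.integers(10, 17))
        peep = float(rng.choice([4.0, 5.0, 6.0], p=[0.3, 0.5, 0.2]))
        crs_true = float(np.clip(rng.normal(50.0, 12.0), 25.0, 90.0))
        pplat = peep + tv / crs_true
        pip = pplat + float(rng.uniform(2.0, 6.0))
        mawp = peep + 0.35 * (pip - peep)
        fio2 = float(rng.uniform(0.40, 0.60))
        mv = tv * rr / 1000.0

        # physiology baselines
        map_mean = float(np.clip(rng.normal(75.0, 8.0), 55.0, 95.0))
        hr_mean = float(np.clip(rng.normal(70.0, 10.0), 45.0, 110.0))
        spo2_mean = float(np.clip(rng.normal(98.3, 1.0), 94.0, 99.8))
        bt_mean = float(np.clip(rng.normal(36.5, 0.5), 35.0, 38.0))
        etco2_mean = float(np.clip(rng.normal(35.0, 3.0), 26.0, 45.0))
        co_mean = float(np.clip(rng.normal(5.0, 1.0), 2.5, 8.0))

        draws = _schedule_draws(rng, config, duration)

        # MAP at full rate: bounded quasi-periodic noise so that a
        # surge-free lookback window can never exceed the z threshold
        map_vals = map_mean + _map_noise(rng, t_map, config.map_noise_sd)
        for t_draw, surge, _delay in draws:
            if surge:
                amp = float(rng.uniform(*config.surge_amplitude))
                dur = float(rng.uniform(*config.surge_duration_s))
                _add_bump(t_map, map_vals, t_draw, amp, dur)

        # distractor bumps away from draws and from surge-free lookbacks
        n_distract = rng.poisson(config.distractor_rate_per_h * duration / 3600.0)
        forbidden: list[tuple[float, float]] = []
        for t_draw, surge, delay in draws:
            rec = t_draw + delay
            if not surge:
                forbidden.append((rec - config.entry_delay_max_s - 1300.0, rec + 10.0))
            forbidden.append((t_draw - 80.0, rec + 80.0))
        for _ in range(n_distract):
            td = float(rng.uniform(200.0, max(duration - 200.0, 201.0)))
            amp = float(rng.uniform(*config.surge_amplitude))
            dur = float(rng.uniform(*config.surge_duration_s))
            if any(lo - dur <= td <= hi for lo, hi in forbidden):
                continue
            _add_bump(t_map, map_vals, td, amp, dur)
        traces.append(BiosignalTrace(case.case_id, "MAP", t_map, map_vals))

        # slow channels
        ns = t_slow.size
        chan_vals = {
            "HR": hr_mean + _ou_series(rng, ns, 2.5, 60.0, dt_slow),
            "SPO2": np.clip(spo2_mean + _ou_series(rng, ns, 0.4, 120.0, dt_slow),
                            85.0, 100.0),
            "BT": bt_mean + _ou_series(rng, ns, 0.05, 600.0, dt_slow),
            "ETCO2": etco2_mean + _ou_series(rng, ns, 0.8, 120.0, dt_slow),
            "RR": rr + _ou_series(rng, ns, 0.2, 60.0, dt_slow),
            "TV": tv + _ou_series(rng, ns, 5.0, 60.0, dt_slow),
            "MV": mv + _ou_series(rng, ns, 0.15, 60.0, dt_slow),
            "PEEP": peep + _ou_series(rng, ns, 0.10, 60.0, dt_slow),
            "PIP": pip + _ou_series(rng, ns, 0.30, 60.0, dt_slow),
            "PPLAT": pplat + _ou_series(rng, ns, 0.30, 60.0, dt_slow),
            "MAWP": mawp + _ou_series(rng, ns, 0.20, 60.0, dt_slow),
            "FIO2": fio2 + _ou_series(rng, ns, 0.003, 60.0, dt_slow),
            "CO": co_mean + _ou_series(rng, ns, 0.30, 60.0, dt_slow),
        }

        # ABGA events: the target is ETCO2 in the feature window plus gradient
        for t_draw, surge, delay in draws:
            w_start = t_draw - 120.0
            w_end = t_draw - 60.0
            state = {ch: _window_median(t_slow, chan_vals[ch], w_start, w_end)
                     for ch in ("BT", "SPO2", "FIO2", "TV", "PPLAT", "PEEP",
                                "ETCO2")}
            gradient = sample_gradient(case, state, config, rng)
            paco2 = round(state["ETCO2"] + gradient, 1)
            paco2 = max(paco2, 10.0)
            if (config.missing_channel_fraction > 0
                    and rng.random() < config.missing_channel_fraction):
                ch = str(rng.choice(["PPLAT", "TV", "MAWP"]))
                # cover the window the pipeline will use: the estimated draw
                # sits at the surge peak, a few tens of seconds past the draw
                m = (t_slow >= w_start - 20.0) & (t_slow < w_end + 45.0)
                chan_vals[ch][m] = np.nan
            events.append(AbgaEvent(
                case_id=case.case_id, recorded_time_s=round(t_draw + delay, 3),
                paco2=paco2, true_draw_time_s=round(t_draw, 3),
                surge_present=surge))

        for ch, vals in chan_vals.items():
            traces.append(BiosignalTrace(case.case_id, ch, t_slow, vals))

    return Cohort(cases=cases, traces=traces, abga=events)


def manifest(config: GeneratorConfig) -> dict:
    """Reproducibility record for a generated cohort."""
    return {"generator": dataclasses.asdict(config), "seed": config.seed,
            "slow_interval_s": SLOW_INTERVAL_S}
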