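"""Synthetic CGM cohort generation.

Builds cohorts of continuous glucose monitoring (CGM) traces with the
statistical structure the downstream analysis assumes: a patient-specific
glycemic baseline, a 24-h circadian oscillation, post-prandial excursions,
AR(1) sensor noise, irregular recording gaps, and severe-hypoglycemia (SH)
events of two phenotypes (deep/long vs shallow/short nadir) preceded by a
descending glucose trajectory.

Every random draw flows from a single integer seed, so identical configs
produce bitwise-identical cohorts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as _signal

from .io import GlucoseTrace, SHEvent

GLUCOSE_MIN = 20.0
GLUCOSE_MAX = 500.0

#: threshold defining SH onset (first instant below this is the onset)
SH_ONSET_MGDL = 54.0
#: deep-phenotype events must dip below this
DEEP_NADIR_MGDL = 45.0

_EPOCH = pd.Timestamp("2023-01-01 00:00:00")


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of the simulated cohort.

    Defaults are calibrated to the pediatric type-1-diabetes population the
    package targets: per-patient glycemic means of 170.9 +/- 33.3 mg/dL, and
    SH events whose nadirs/durations follow the two observed phenotypes
    (deep: nadir 40.3 +/- 10.3 mg/dL, ~161.3 min below 54 mg/dL; shallow:
    nadir 53.0 +/- 7.2 mg/dL, ~106.1 min).
    """

    n_patients: int = 50
    days_per_patient: float = 60.0
    sample_period_native: float = 5.0            # minutes
    baseline_mean_mean: float = 170.9            # mg/dL
    baseline_mean_sd: float = 33.3               # mg/dL
    circadian_amplitude: float = 15.0            # mg/dL
    meal_events_per_day: float = 3.0
    meal_excursion_amplitude: float = 45.0       # mg/dL
    noise_ar1_rho: float = 0.8
    noise_sd: float = 12.0                       # mg/dL (marginal)
    gap_rate_per_day: float = 0.25
    gap_duration_range: tuple[float, float] = (30.0, 300.0)  # minutes
    hypo_dips_per_day: float = 0.5               # non-severe hypoglycemic dips
    dip_nadir_range: tuple[float, float] = (55.0, 80.0)  # mg/dL
    sh_events_per_patient: float = 1.0
    p_deep_event: float = 26.0 / 41.0
    deep_nadir_mean: float = 40.3                # mg/dL
    deep_nadir_sd: float = 10.3                  # mg/dL
    shallow_nadir_mean: float = 53.0             # mg/dL
    shallow_nadir_sd: float = 7.2                # mg/dL
    deep_duration_mean: float = 161.3            # minutes below 54
    deep_duration_sd: float = 118.9
    shallow_duration_mean: float = 106.1
    shallow_duration_sd: float = 87.2
    pre_event_descent_minutes: float = 150.0
    recovery_minutes: float = 90.0
    seed: int = 0

    def validate(self) -> None:
        numeric = {k: v for k, v in asdict(self).items()
                   if isinstance(v, (int, float))}
        for name, value in numeric.items():
            if not math.isfinite(value):
                raise ValueError(f"config field {name!r} is not finite")
        lo, hi = self.gap_duration_range
        if not (math.isfinite(lo) and math.isfinite(hi) and 0 <= lo <= hi):
            raise ValueError("gap_duration_range must be finite with lo <= hi")
        if self.n_patients < 0:
            raise ValueError("n_patients must be >= 0")
        d_lo, d_hi = self.dip_nadir_range
        if not (SH_ONSET_MGDL < d_lo <= d_hi):
            raise ValueError("dip_nadir_range must stay above 54 mg/dL")
        for name in ("baseline_mean_sd", "noise_sd", "meal_events_per_day",
                     "gap_rate_per_day", "sh_events_per_patient",
                     "hypo_dips_per_day",
                     "deep_nadir_sd", "shallow_nadir_sd",
                     "deep_duration_sd", "shallow_duration_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.p_deep_event <= 1.0:
            raise ValueError("p_deep_event must be a probability")
        if not 0.0 <= self.noise_ar1_rho < 1.0:
            raise ValueError("noise_ar1_rho must be in [0, 1)")
        if not self.deep_nadir_mean < self.shallow_nadir_mean:
            raise ValueError("deep_nadir_mean must be < shallow_nadir_mean")


@dataclass
class SyntheticEvent:
    """Ground truth for one injected SH event."""

    patient_id: str
    onset: pd.Timestamp
    phenotype: str          # "deep" | "shallow"
    nadir: float            # mg/dL, exactly the spliced plateau value
    duration_below54: float  # minutes, exactly the spliced below-54 time
    window_start: pd.Timestamp
    window_end: pd.Timestamp

    def to_sh_event(self) -> SHEvent:
        return SHEvent(patient_id=self.patient_id, onset=self.onset)


@dataclass
class SyntheticCohort:
    traces: list[GlucoseTrace]
    events: list[SyntheticEvent]
    demographics: pd.DataFrame   # patient_id, age_years, sex, age_at_diagnosis_years
    config: CohortConfig = field(repr=False, default=None)

    @property
    def sh_events(self) -> list[SHEvent]:
        return [e.to_sh_event() for e in self.events]


def _sample_deep_nadir(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Nadir for the deep phenotype: a beta distribution rescaled to the
    admissible band [20, 45) mg/dL, moment-matched to the requested
    mean/sd.

    With every nadir confined to (20, 45) the dispersion has a hard ceiling
    (Bhatia-Davis: sd^2 <= (45-mean)(mean-20)); a requested sd beyond ~95%
    of that ceiling is capped there, which for the default 40.3 +/- 10.3
    target yields an sd near 9, the largest the support allows.
    """
    lo, hi = GLUCOSE_MIN, DEEP_NADIR_MGDL
    if not lo < mean < hi:
        return float(np.clip(mean, lo + 0.5, hi - 0.1))
    if sd == 0:
        return float(mean)
    span = hi - lo
    m = (mean - lo) / span
    sd_x = min(sd / span, 0.95 * math.sqrt(m * (1.0 - m)))
    nu = m * (1.0 - m) / (sd_x * sd_x) - 1.0
    nu = max(nu, 0.05)
    draw = rng.beta(m * nu, (1.0 - m) * nu)
    return float(np.clip(lo + span * draw, lo + 0.5, hi - 0.1))


def _sample_shallow_nadir(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Nadir for the shallow phenotype, truncated to (52, 54) mg/dL so the
    event both triggers the onset rule (< 54) and satisfies the group-2
    definition (> 52)."""
    if sd == 0:
        return float(np.clip(mean, 52.05, 53.95))
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if 52.05 <= x <= 53.95:
            return float(x)
    return float(np.clip(mean, 52.05, 53.95))


def _sample_duration(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Below-54 duration in minutes: gamma-distributed, floored at 20 min so
    the plateau spans at least one 15-min grid step."""
    if sd == 0:
        return max(mean, 20.0)
    shape = (mean / sd) ** 2
    scale = sd * sd / mean
    return float(max(rng.gamma(shape, scale), 20.0))


def _ar1_noise(rng: np.random.Generator, n: int, rho: float, sd: float) -> np.ndarray:
    if sd == 0 or n == 0:
        return np.zeros(n)
    innov = rng.normal(0.0, sd * math.sqrt(1.0 - rho * rho), size=n)
    innov[0] = rng.normal(0.0, sd)  # stationary start
    return _signal.lfilter([1.0], [1.0, -rho], innov)


def _background_trace(rng: np.random.Generator, cfg: CohortConfig,
                      t_min: np.ndarray) -> tuple[np.ndarray, float]:
    """Deterministic baseline + circadian + meals + AR(1) noise on the native
    grid (`t_min` in minutes from trace start). Returns (values, baseline)."""
    baseline = rng.normal(cfg.baseline_mean_mean, cfg.baseline_mean_sd)
    baseline = float(np.clip(baseline, 80.0, 350.0))
    values = np.full(t_min.shape, baseline)

    phase = rng.uniform(0.0, 24.0)
    if cfg.circadian_amplitude > 0:
        values = values + cfg.circadian_amplitude * np.sin(
            2.0 * np.pi * (t_min / 60.0 - phase) / 24.0)

    n_meals = rng.poisson(cfg.meal_events_per_day * cfg.days_per_patient)
    total_min = float(t_min[-1]) if t_min.size else 0.0
    for _ in range(n_meals):
        center = rng.uniform(0.0, total_min)
        amp = cfg.meal_excursion_amplitude * rng.uniform(0.5, 1.5)
        width = rng.uniform(20.0, 45.0)
        lo = np.searchsorted(t_min, center - 4 * width)
        hi = np.searchsorted(t_min, center + 4 * width)
        seg = t_min[lo:hi]
        values[lo:hi] += amp * np.exp(-0.5 * ((seg - center) / width) ** 2)

    values = values + _ar1_noise(rng, t_min.size, cfg.noise_ar1_rho, cfg.noise_sd)
    return values, baseline


def _splice_event(values: np.ndarray, t_min: np.ndarray, rng: np.random.Generator,
                  cfg: CohortConfig, t_start: float, phenotype: str,
                  ) -> tuple[float, float, float, float] | None:
    """Replace the background with an SH excursion starting at `t_start` min.

    Shape (piecewise linear): pre-event level -> 54 over the configured
    descent time, then a symmetric trapezoid below 54 (down to the sampled
    nadir, plateau, back up) whose total below-54 time equals the sampled
    duration, then recovery to a peak above the pre-event level and a blend
    back into the background. The splice *replaces* the background so the
    recorded nadir/duration are exactly the sampled ones.

    Returns (onset_minutes, nadir, duration, window_end_minutes), or None if
    the event does not fit in the trace.
    """
    if phenotype == "deep":
        nadir = _sample_deep_nadir(rng, cfg.deep_nadir_mean, cfg.deep_nadir_sd)
        duration = _sample_duration(rng, cfg.deep_duration_mean, cfg.deep_duration_sd)
    else:
        nadir = _sample_shallow_nadir(rng, cfg.shallow_nadir_mean, cfg.shallow_nadir_sd)
        duration = _sample_duration(rng, cfg.shallow_duration_mean,
                                    cfg.shallow_duration_sd)

    t_cross = t_start + cfg.pre_event_descent_minutes
    t_peak = t_cross + duration + cfg.recovery_minutes
    t_end = t_peak + 60.0
    if t_end >= t_min[-1]:
        return None

    i_start = int(np.searchsorted(t_min, t_start))
    pre_level = max(float(values[i_start]), 90.0)
    peak_level = max(pre_level + 15.0, 90.0)
    i_end = int(np.searchsorted(t_min, t_end, side="right"))
    bg_after = float(values[min(i_end, values.size - 1)])

    knots_t = np.array([
        t_start,
        t_cross,
        t_cross + 0.25 * duration,
        t_cross + 0.75 * duration,
        t_cross + duration,
        t_peak,
        t_end,
    ])
    knots_v = np.array([pre_level, SH_ONSET_MGDL, nadir, nadir,
                        SH_ONSET_MGDL, peak_level, bg_after])

    sl = slice(i_start, i_end)
    values[sl] = np.interp(t_min[sl], knots_t, knots_v)

    below = np.nonzero(values[sl] < SH_ONSET_MGDL)[0]
    if below.size == 0:
        return None
    onset_min = float(t_min[sl][below[0]])
    return onset_min, nadir, duration, t_end


def _splice_dips(values: np.ndarray, t_min: np.ndarray,
                 rng: np.random.Generator, cfg: CohortConfig,
                 forbidden: list[tuple[float, float]]) -> None:
    """Non-severe hypoglycemic dips: descents to 55-80 mg/dL that recover
    without crossing the SH threshold. These are the clinical near-misses
    that make negative segments end low and descending — the substrate of
    false-positive predictions."""
    n = rng.poisson(cfg.hypo_dips_per_day * cfg.days_per_patient)
    total_min = float(t_min[-1]) if t_min.size else 0.0
    lo, hi = cfg.dip_nadir_range
    for _ in range(n):
        for _attempt in range(50):
            t_start = rng.uniform(0.0, total_min - 400.0)
            descent = rng.uniform(60.0, 150.0)
            plateau = rng.uniform(10.0, 40.0)
            recovery = rng.uniform(45.0, 120.0)
            t_end = t_start + descent + plateau + recovery
            if all(t_end < f0 or t_start > f1 for f0, f1 in forbidden):
                break
        else:
            continue
        i0 = int(np.searchsorted(t_min, t_start))
        i1 = int(np.searchsorted(t_min, t_end, side="right"))
        if i1 - i0 < 3 or i1 >= values.size:
            continue
        nadir = rng.uniform(lo, hi)
        pre = max(float(values[i0]), nadir + 10.0)
        post = max(float(values[min(i1, values.size - 1)]), nadir + 10.0)
        knots_t = np.array([t_start, t_start + descent,
                            t_start + descent + plateau, t_end])
        knots_v = np.array([pre, nadir, nadir, post])
        sl = slice(i0, i1)
        values[sl] = np.interp(t_min[sl], knots_t, knots_v)


def _place_events(rng: np.random.Generator, cfg: CohortConfig,
                  total_min: float) -> list[float]:
    """Event descent-start times (minutes), kept >= 5 days + descent from the
    trace start (so a full history window exists) and non-overlapping."""
    n = rng.poisson(cfg.sh_events_per_patient)
    lead = 5.0 * 1440.0 + cfg.pre_event_descent_minutes
    tail = 24.0 * 60.0
    width = cfg.pre_event_descent_minutes + cfg.deep_duration_mean + \
        cfg.recovery_minutes + 60.0
    min_sep = max(2.0 * 1440.0, width)
    if total_min - tail <= lead:
        return []
    starts: list[float] = []
    for _ in range(n):
        for _attempt in range(200):
            t = rng.uniform(lead, total_min - tail)
            if all(abs(t - s) >= min_sep for s in starts):
                starts.append(t)
                break
    return sorted(starts)


def _make_gaps(rng: np.random.Generator, cfg: CohortConfig, total_min: float,
               protected: list[tuple[float, float]]) -> list[tuple[float, float]]:
    """Recording gaps (start, end) in minutes, drawn uniformly over the trace
    but kept out of SH-event neighbourhoods so injected events stay usable."""
    n = rng.poisson(cfg.gap_rate_per_day * cfg.days_per_patient)
    gaps: list[tuple[float, float]] = []
    lo, hi = cfg.gap_duration_range
    for _ in range(n):
        for _attempt in range(100):
            start = rng.uniform(0.0, total_min)
            dur = rng.uniform(lo, hi)
            end = start + dur
            if all(end < p0 or start > p1 for p0, p1 in protected) and \
                    all(end < g0 or start > g1 for g0, g1 in gaps):
                gaps.append((start, end))
                break
    return sorted(gaps)


def _make_demographics(rng: np.random.Generator, patient_ids: list[str]) -> pd.DataFrame:
    rows = []
    for pid in patient_ids:
        age = float(np.clip(rng.normal(13.3, 3.7), 2.0, 18.0))
        dur = float(np.clip(rng.normal(6.3, 4.6), 0.5, age - 0.5))
        sex = "F" if rng.uniform() < 0.46 else "M"
        rows.append({"patient_id": pid, "age_years": round(age, 1),
                     "sex": sex,
                     "age_at_diagnosis_years": round(age - dur, 1)})
    df = pd.DataFrame(rows, columns=["patient_id", "age_years", "sex",
                                     "age_at_diagnosis_years"])
    return df


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Simulate a full cohort: traces, ground-truth SH events, demographics."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    traces: list[GlucoseTrace] = []
    events: list[SyntheticEvent] = []
    patient_ids = [f"P{i:03d}" for i in range(config.n_patients)]

    total_min = config.days_per_patient * 1440.0
    for pid in patient_ids:
        # stagger trace starts so grid anchoring is exercised per patient
        start_offset = float(rng.integers(0, 24 * 12)) * 5.0
        t0 = _EPOCH + pd.Timedelta(minutes=start_offset)
        n_samples = int(total_min // config.sample_period_native) + 1
        t_min = np.arange(n_samples) * config.sample_period_native

        values, _baseline = _background_trace(rng, config, t_min)

        protected: list[tuple[float, float]] = []
        splice_windows: list[tuple[float, float]] = []
        for t_start in _place_events(rng, config, total_min):
            phen = "deep" if rng.uniform() < config.p_deep_event else "shallow"
            spliced = _splice_event(values, t_min, rng, config, t_start, phen)
            if spliced is None:
                continue
            onset_min, nadir, duration, t_end = spliced
            protected.append((t_start - 5.0 * 1440.0, t_end + 60.0))
            splice_windows.append((t_start - 60.0, t_end + 60.0))
            events.append(SyntheticEvent(
                patient_id=pid,
                onset=t0 + pd.Timedelta(minutes=onset_min),
                phenotype=phen,
                nadir=nadir,
                duration_below54=duration,
                window_start=t0 + pd.Timedelta(minutes=t_start),
                window_end=t0 + pd.Timedelta(minutes=t_end),
            ))

        _splice_dips(values, t_min, rng, config, splice_windows)
        values = np.clip(values, GLUCOSE_MIN, GLUCOSE_MAX)

        keep = np.ones(t_min.size, dtype=bool)
        for g0, g1 in _make_gaps(rng, config, total_min, protected):
            keep &= ~((t_min > g0) & (t_min < g1))

        readings = pd.DataFrame({
            "timestamp": t0 + pd.to_timedelta(t_min[keep], unit="m"),
            "glucose": values[keep],
            "source": "sim-cgm",
        })
        traces.append(GlucoseTrace(patient_id=pid, readings=readings))

    demographics = _make_demographics(rng, patient_ids)
    return SyntheticCohort(traces=traces, events=events,
                           demographics=demographics, config=config)


# ---------------------------------------------------------------------------
# CSV export

DIALECTS = ("generic", "libre-like", "dexcom-like")


def export_cgm_csv(cohort: SyntheticCohort, out_dir: str | Path,
                   dialect: str = "generic") -> list[Path]:
    """Write one CGM CSV per patient plus an events CSV and a demographics
    CSV, in the chosen vendor column convention. Round-trips through the
    readers in :mod:`shpred.io`."""
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    for trace in cohort.traces:
        path = out_dir / f"{trace.patient_id}_cgm.csv"
        df = trace.readings
        if dialect == "generic":
            out = pd.DataFrame({
                "patient_id": trace.patient_id,
                "timestamp": df["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S"),
                "glucose_mgdl": df["glucose"].map(lambda v: format(v, ".6f")),
                "source": df["source"],
            })
        elif dialect == "libre-like":
            out = pd.DataFrame({
                "Serial Number": trace.patient_id,
                "Device Timestamp": df["timestamp"].dt.strftime("%d-%m-%Y %H:%M"),
                "Record Type": 0,
                "Historic Glucose mg/dL": df["glucose"].map(lambda v: format(v, ".6f")),
            })
        else:  # dexcom-like
            out = pd.DataFrame({
                "Timestamp (YYYY-MM-DDThh:mm:ss)":
                    df["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S"),
                "Event Type": "EGV",
                "Glucose Value (mg/dL)": df["glucose"].map(lambda v: format(v, ".6f")),
                "Source Device ID": df["source"],
            })
        out.to_csv(path, index=False)
        written.append(path)

    events_path = out_dir / "events.csv"
    pd.DataFrame({
        "patient_id": [e.patient_id for e in cohort.events],
        "onset_timestamp": [e.onset.strftime("%Y-%m-%dT%H:%M:%S")
                            for e in cohort.events],
    }).to_csv(events_path, index=False)
    written.append(events_path)

    demo_path = out_dir / "demographics.csv"
    cohort.demographics.to_csv(demo_path, index=False)
    written.append(demo_path)
    return written
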