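"""Characterization of severe-hypoglycemia events on the uniform grid.

Each event is analysed within a window running from the start of the
glucose decline preceding the onset to the first glycemic peak after the
episode. From that window we compute the time spent below 54 mg/dL (with
threshold crossings located by linear interpolation), the glucose deficit
area under 54 mg/dL (trapezoidal, in mg.min/dL), the nadir, and the value
at the window end. Events stratify into two phenotypes by nadir: group 1
(nadir < 45 mg/dL, deep/long) and group 2 (nadir > 52 mg/dL,
shallow/short); nadirs in between are left unassigned.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import UniformRun, SHEvent, GRID_MINUTES

log = logging.getLogger(__name__)

SH_THRESHOLD = 54.0
GROUP1_NADIR = 45.0     # deep phenotype: nadir strictly below
GROUP2_NADIR = 52.0     # shallow phenotype: nadir strictly above
PEAK_MIN = 70.0         # a recovery peak must exceed this


@dataclass
class EventProfile:
    patient_id: str
    onset: pd.Timestamp
    window_start: pd.Timestamp
    window_end: pd.Timestamp
    duration_below54: float     # minutes
    deficit_area: float         # mg.min/dL
    nadir: float                # mg/dL
    recovery_peak: float        # mg/dL (value at window end)
    group: str = "unassigned"   # "group1" | "group2" | "unassigned"
    truncated: bool = False     # window clipped at a run boundary


def extract_event_window(run: UniformRun, event: SHEvent) -> tuple[int, int, bool]:
    """Index window (start, end, truncated) of one event inside a run.

    Start: walk back from the onset while each preceding sample is >= its
    successor (a monotone non-increasing descent; plateaus count), stopping
    at the first rise. End: the first sample after the nadir that is a local
    maximum (>= both neighbours) above 70 mg/dL; capped at the run end.
    """
    if event.patient_id != run.patient_id:
        raise ValueError("event and run belong to different patients")
    offset = (event.onset - run.start) / run.sample_period
    k = int(round(offset))
    if abs(offset - k) > 1e-9 or k < 0 or k >= len(run):
        raise ValueError("event onset does not fall on the run grid")

    v = run.values
    start = k
    while start > 0 and v[start - 1] >= v[start]:
        start -= 1

    # forward to the nadir, then to the first qualifying local max
    truncated = False
    i = k
    while i + 1 < len(v) and v[i + 1] <= v[i]:
        i += 1
    end = None
    for j in range(i, len(v)):
        if v[j] > PEAK_MIN:
            left_ok = j == 0 or v[j] >= v[j - 1]
            right_ok = j == len(v) - 1 or v[j] >= v[j + 1]
            if left_ok and right_ok:
                end = j
                break
    if end is None:
        end = len(v) - 1
        truncated = True
        log.info("event at %s: no recovery peak before run end, window truncated",
                 event.onset)
    if start == k and k == 0:
        truncated = True
    return start, end, truncated


def characterize(window_values: np.ndarray,
                 sample_minutes: float = float(GRID_MINUTES),
                 ) -> tuple[float, float, float, float]:
    """(duration_below54, deficit_area, nadir, recovery_peak) for a window.

    Crossings of the 54 mg/dL threshold are located by linear interpolation
    between samples; the duration is the total time strictly below the
    threshold and the deficit area is the trapezoidal integral of
    (54 - glucose) over the below-threshold intervals.
    """
    v = np.asarray(window_values, dtype=float)
    if v.size < 2:
        raise ValueError("window needs at least 2 samples")
    if not np.any(v < SH_THRESHOLD):
        raise ValueError("window never drops below 54 mg/dL: not an SH window")

    t = np.arange(v.size) * sample_minutes
    deficit = np.maximum(SH_THRESHOLD - v, 0.0)

    duration = 0.0
    area = 0.0
    for i in range(v.size - 1):
        a, b = v[i], v[i + 1]
        dt = sample_minutes
        if a < SH_THRESHOLD and b < SH_THRESHOLD:
            duration += dt
            area += 0.5 * (deficit[i] + deficit[i + 1]) * dt
        elif a < SH_THRESHOLD <= b:
            frac = (SH_THRESHOLD - a) / (b - a)      # up-crossing
            duration += frac * dt
            area += 0.5 * deficit[i] * frac * dt
        elif b < SH_THRESHOLD <= a:
            frac = (SH_THRESHOLD - a) / (b - a)      # down-crossing
            duration += (1.0 - frac) * dt
            area += 0.5 * deficit[i + 1] * (1.0 - frac) * dt
        # both >= threshold: contributes nothing
    del t
    return duration, area, float(v.min()), float(v[-1])


def profile_event(run: UniformRun, event: SHEvent) -> EventProfile:
    start, end, truncated = extract_event_window(run, event)
    window = run.values[start:end + 1]
    duration, area, nadir, peak = characterize(window)
    return EventProfile(
        patient_id=event.patient_id, onset=event.onset,
        window_start=run.times[start], window_end=run.times[end],
        duration_below54=duration, deficit_area=area,
        nadir=nadir, recovery_peak=peak, truncated=truncated)


def profile_events(runs: list[UniformRun],
                   events: list[SHEvent]) -> list[EventProfile]:
    """Profile every event that falls inside some uniform run."""
    profiles: list[EventProfile] = []
    for ev in events:
        for run in runs:
            if run.patient_id != ev.patient_id:
                continue
            offset = (ev.onset - run.start) / run.sample_period
            k = int(round(offset))
            if 0 <= k < len(run) and abs(offset - k) <= 1.0:
                snapped = SHEvent(patient_id=ev.patient_id, onset=run.times[k])
                try:
                    profiles.append(profile_event(run, snapped))
                except ValueError as exc:
                    log.info("event at %s skipped: %s", ev.onset, exc)
                break
    return profiles


def stratify(profiles: list[EventProfile]) -> list[EventProfile]:
    """Assign each profile its phenotype group by nadir (in place)."""
    n_unassigned = 0
    for p in profiles:
        if p.nadir < GROUP1_NADIR:
            p.group = "group1"
        elif p.nadir > GROUP2_NADIR:
            p.group = "group2"
        else:
            p.group = "unassigned"
            n_unassigned += 1
    if n_unassigned:
        log.info("%d events with nadir in [45, 52] mg/dL left unassigned",
                 n_unassigned)
    return profiles


def compare_groups(profiles: list[EventProfile]) -> pd.DataFrame:
    """Group-wise descriptives and a two-sided Mann-Whitney test per metric
    (duration, deficit area, nadir). With fewer than 2 events in a group the
    p-value is omitted."""
    metrics = {"duration_below54": "duration_below54",
               "deficit_area": "deficit_area",
               "nadir": "nadir"}
    g1 = [p for p in profiles if p.group == "group1"]
    g2 = [p for p in profiles if p.group == "group2"]
    if not g1 or not g2:
        raise ValueError("both groups must be non-empty")
    rows = []
    for name, attr in metrics.items():
        x1 = np.array([getattr(p, attr) for p in g1])
        x2 = np.array([getattr(p, attr) for p in g2])
        row = {"metric": name,
               "group1_n": x1.size, "group2_n": x2.size,
               "group1_mean": x1.mean(), "group1_sd": x1.std(ddof=1) if x1.size > 1 else np.nan,
               "group2_mean": x2.mean(), "group2_sd": x2.std(ddof=1) if x2.size > 1 else np.nan}
        if x1.size >= 2 and x2.size >= 2:
            row["p_value"] = float(stats.mannwhitneyu(
                x1, x2, alternative="two-sided").pvalue)
        else:
            row["p_value"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def profiles_to_frame(profiles: list[EventProfile]) -> pd.DataFrame:
    return pd.DataFrame([{
        "patient_id": p.patient_id,
        "onset": p.onset,
        "window_start": p.window_start,
        "window_end": p.window_end,
        "duration_below54_min": p.duration_below54,
        "deficit_area_mgmin_dl": p.deficit_area,
        "nadir_mgdl": p.nadir,
        "recovery_peak_mgdl": p.recovery_peak,
        "group": p.group,
        "truncated": p.truncated,
    } for p in profiles])
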