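"""CGM ingestion, merging, uniform resampling and 5-day segmentation.

The preprocessing contract: all of a patient's device exports are pooled into
one trace; the trace is resampled onto a uniform 15-min grid anchored at the
first reading, with linear interpolation across raw gaps of at most two
hours; longer gaps split the trace into separate uniform runs; runs are cut
into 5-day segments of exactly 480 samples, labeled positive iff the final
sample falls on a severe-hypoglycemia (SH) onset. This module is fully
deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

GRID_MINUTES = 15
MAX_GAP_MINUTES = 120          # raw gaps longer than this are eliminated
SEGMENT_SAMPLES = 480          # 5 days x 96 samples/day
EVENT_SNAP_MINUTES = 15        # events farther than one grid step are unusable

LABEL_SH = "SH"
LABEL_NON_SH = "non-SH"


@dataclass
class GlucoseTrace:
    """One patient's timestamped glucose series.

    ``readings`` has columns ``timestamp`` (datetime64), ``glucose`` (mg/dL)
    and ``source`` (device label). After :func:`merge_sources` the timestamps
    are strictly increasing.
    """

    patient_id: str
    readings: pd.DataFrame

    def __len__(self) -> int:
        return len(self.readings)


@dataclass(frozen=True)
class SHEvent:
    patient_id: str
    onset: pd.Timestamp


@dataclass
class UniformRun:
    """A gap-free stretch of 15-min samples (interpolation already applied)."""

    patient_id: str
    start: pd.Timestamp
    values: np.ndarray
    sample_period: pd.Timedelta = field(
        default_factory=lambda: pd.Timedelta(minutes=GRID_MINUTES))

    @property
    def times(self) -> pd.DatetimeIndex:
        return pd.DatetimeIndex(
            self.start + self.sample_period * np.arange(len(self.values)))

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class Segment:
    """A 5-day window of 480 uniform samples; positive iff it ends at an SH
    onset (the onset sample is the last point)."""

    patient_id: str
    end_time: pd.Timestamp
    values: np.ndarray
    label: str

    def __post_init__(self) -> None:
        if len(self.values) != SEGMENT_SAMPLES:
            raise ValueError(
                f"segment must have {SEGMENT_SAMPLES} samples, got {len(self.values)}")


# ---------------------------------------------------------------------------
# Readers

_DIALECT_COLUMNS = {
    "generic": {"timestamp": "timestamp", "glucose": "glucose_mgdl",
                "source": "source", "patient": "patient_id",
                "fmt": None},
    "libre-like": {"timestamp": "Device Timestamp",
                   "glucose": "Historic Glucose mg/dL",
                   "source": None, "patient": "Serial Number",
                   "fmt": "%d-%m-%Y %H:%M"},
    "dexcom-like": {"timestamp": "Timestamp (YYYY-MM-DDThh:mm:ss)",
                    "glucose": "Glucose Value (mg/dL)",
                    "source": "Source Device ID", "patient": None,
                    "fmt": "%Y-%m-%dT%H:%M:%S"},
}


def read_cgm(path: str | Path, dialect: str = "generic",
             patient_id: str | None = None) -> GlucoseTrace:
    """Read one CGM export. Rows with unparseable timestamps or non-positive
    glucose are dropped (count logged). ``patient_id`` overrides / supplies
    the patient identifier for dialects that do not carry one."""
    if dialect not in _DIALECT_COLUMNS:
        raise ValueError(f"unknown dialect {dialect!r}")
    cols = _DIALECT_COLUMNS[dialect]
    path = Path(path)
    df = pd.read_csv(path)

    for key in ("timestamp", "glucose"):
        if cols[key] not in df.columns:
            raise ValueError(
                f"{path.name}: missing required column {cols[key]!r} "
                f"for dialect {dialect!r}")

    ts = pd.to_datetime(df[cols["timestamp"]], format=cols["fmt"], errors="coerce")
    glucose = pd.to_numeric(df[cols["glucose"]], errors="coerce")
    valid = ts.notna() & glucose.notna() & np.isfinite(glucose) & (glucose > 0)
    n_dropped = int((~valid).sum())
    if n_dropped:
        log.info("%s: dropped %d unparseable/non-positive rows", path.name, n_dropped)

    if patient_id is None:
        if cols["patient"] is not None and cols["patient"] in df.columns and valid.any():
            patient_id = str(df.loc[valid, cols["patient"]].iloc[0])
        else:
            patient_id = path.stem.removesuffix("_cgm")

    source = (df[cols["source"]].astype(str)
              if cols["source"] and cols["source"] in df.columns
              else pd.Series(dialect, index=df.index))
    readings = pd.DataFrame({
        "timestamp": ts[valid],
        "glucose": glucose[valid].astype(float),
        "source": source[valid],
    }).reset_index(drop=True)
    return GlucoseTrace(patient_id=patient_id, readings=readings)


def read_events(path: str | Path) -> list[SHEvent]:
    df = pd.read_csv(path)
    for col in ("patient_id", "onset_timestamp"):
        if col not in df.columns:
            raise ValueError(f"events file missing required column {col!r}")
    onsets = pd.to_datetime(df["onset_timestamp"], errors="coerce")
    valid = onsets.notna()
    if (~valid).sum():
        log.info("events: dropped %d rows with unparseable onsets",
                 int((~valid).sum()))
    return [SHEvent(patient_id=str(pid), onset=ts)
            for pid, ts in zip(df.loc[valid, "patient_id"], onsets[valid])]


def read_demographics(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = ("patient_id", "age_years", "sex", "age_at_diagnosis_years")
    for col in required:
        if col not in df.columns:
            raise ValueError(f"demographics file missing required column {col!r}")
    df = df.copy()
    df["patient_id"] = df["patient_id"].astype(str)
    return df


# ---------------------------------------------------------------------------
# Merge / resample / segment

def merge_sources(traces: list[GlucoseTrace]) -> GlucoseTrace:
    """Pool all of one patient's sources into a single time-sorted trace.
    Readings at exactly the same instant are collapsed to their mean."""
    if not traces:
        raise ValueError("no traces to merge")
    pids = {t.patient_id for t in traces}
    if len(pids) != 1:
        raise ValueError(f"cannot merge traces from different patients: {sorted(pids)}")
    pooled = pd.concat([t.readings for t in traces], ignore_index=True)
    pooled = pooled.sort_values("timestamp", kind="mergesort")
    merged = (pooled.groupby("timestamp", as_index=False)
              .agg(glucose=("glucose", "mean"), source=("source", "first")))
    return GlucoseTrace(patient_id=traces[0].patient_id,
                        readings=merged[["timestamp", "glucose", "source"]])


def resample_uniform(trace: GlucoseTrace) -> list[UniformRun]:
    """Resample a merged trace to the 15-min grid anchored at its first
    reading. Grid values inside raw gaps <= 120 min are linearly
    interpolated; longer raw gaps split the output into separate runs. No
    extrapolation beyond the first/last reading; runs need >= 2 grid points.
    """
    df = trace.readings
    if len(df) < 2:
        return []
    raw_t = df["timestamp"].to_numpy(dtype="datetime64[s]").astype(np.int64)
    raw_v = df["glucose"].to_numpy(dtype=float)
    if not np.all(np.diff(raw_t) > 0):
        raise ValueError("trace timestamps must be strictly increasing (merge first)")

    step = GRID_MINUTES * 60
    n_grid = int((raw_t[-1] - raw_t[0]) // step) + 1
    grid_t = raw_t[0] + step * np.arange(n_grid, dtype=np.int64)

    idx = np.searchsorted(raw_t, grid_t, side="right") - 1
    idx = np.clip(idx, 0, len(raw_t) - 1)
    on_reading = raw_t[idx] == grid_t
    idx_next = np.clip(idx + 1, 0, len(raw_t) - 1)
    gap_ok = (raw_t[idx_next] - raw_t[idx]) <= MAX_GAP_MINUTES * 60
    valid = on_reading | (gap_ok & (idx_next > idx))

    values = np.interp(grid_t, raw_t, raw_v)

    runs: list[UniformRun] = []
    start = None
    for i in range(n_grid + 1):
        if i < n_grid and valid[i]:
            if start is None:
                start = i
        else:
            if start is not None and i - start >= 2:
                runs.append(UniformRun(
                    patient_id=trace.patient_id,
                    start=pd.Timestamp(grid_t[start], unit="s"),
                    values=values[start:i].copy()))
            start = None
    return runs


def segment_runs(runs: list[UniformRun], events: list[SHEvent]) -> list[Segment]:
    """Cut uniform runs into labeled 5-day segments.

    For each SH event inside a run (onset snapped to the nearest grid point
    within one grid step): emit the 480 samples ending at the onset as a
    positive segment when the run provides a full 5-day history that does not
    overlap an earlier event's excised window; then excise that window.
    Remaining stretches are partitioned left-to-right into non-overlapping
    480-sample negative segments; leftovers shorter than 5 days are dropped.
    """
    segments: list[Segment] = []
    events_sorted = sorted(events, key=lambda e: (e.patient_id, e.onset))

    for run in runs:
        n = len(run)
        times = run.times
        excised: list[tuple[int, int]] = []   # inclusive index windows

        for ev in events_sorted:
            if ev.patient_id != run.patient_id:
                continue
            offset = (ev.onset - run.start) / run.sample_period
            k = int(round(offset))
            if k < 0 or k >= n:
                continue
            snap_err = abs(ev.onset - times[k])
            if snap_err > pd.Timedelta(minutes=EVENT_SNAP_MINUTES):
                log.info("event at %s for %s: %s from grid, unusable",
                         ev.onset, ev.patient_id, snap_err)
                continue
            lo = k - (SEGMENT_SAMPLES - 1)
            if lo < 0:
                log.info("event at %s for %s: insufficient history, skipped",
                         ev.onset, ev.patient_id)
                continue
            if any(not (k < a or lo > b) for a, b in excised):
                log.info("event at %s for %s: overlaps an earlier event window,"
                         " skipped", ev.onset, ev.patient_id)
                continue
            segments.append(Segment(
                patient_id=run.patient_id, end_time=times[k],
                values=run.values[lo:k + 1].copy(), label=LABEL_SH))
            excised.append((lo, k))

        excised.sort()
        stretches: list[tuple[int, int]] = []   # half-open [a, b)
        cursor = 0
        for a, b in excised:
            if a > cursor:
                stretches.append((cursor, a))
            cursor = b + 1
        if cursor < n:
            stretches.append((cursor, n))

        for a, b in stretches:
            pos = a
            while pos + SEGMENT_SAMPLES <= b:
                end = pos + SEGMENT_SAMPLES - 1
                segments.append(Segment(
                    patient_id=run.patient_id, end_time=times[end],
                    values=run.values[pos:end + 1].copy(), label=LABEL_NON_SH))
                pos += SEGMENT_SAMPLES

    return segments


# ---------------------------------------------------------------------------
# Tabular round-trip for segments (CSV interface)

def segments_to_frame(segments: list[Segment]) -> pd.DataFrame:
    cols = [f"v{i + 1:03d}" for i in range(SEGMENT_SAMPLES)]
    rows = []
    for s in segments:
        row = {"patient_id": s.patient_id,
               "end_time": s.end_time.strftime("%Y-%m-%dT%H:%M:%S"),
               "label": s.label}
        row.update(dict(zip(cols, s.values)))
        rows.append(row)
    return pd.DataFrame(rows, columns=["patient_id", "end_time", "label"] + cols)


def frame_to_segments(df: pd.DataFrame) -> list[Segment]:
    cols = [f"v{i + 1:03d}" for i in range(SEGMENT_SAMPLES)]
    return [Segment(patient_id=str(r["patient_id"]),
                    end_time=pd.Timestamp(r["end_time"]),
                    values=np.asarray([r[c] for c in cols], dtype=float),
                    label=str(r["label"]))
            for _, r in df.iterrows()]


def preprocess_patient(traces: list[GlucoseTrace],
                       events: list[SHEvent]) -> list[Segment]:
    """Convenience: merge -> resample -> segment for one patient."""
    merged = merge_sources(traces)
    runs = resample_uniform(merged)
    return segment_runs(runs, [e for e in events
                               if e.patient_id == merged.patient_id])
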