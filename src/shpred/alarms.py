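"""Deployment simulation: leave-one-patient-out false-alarm spacing.

For each patient, a model is trained on all other patients (with fold-
internal PCA and normalization) and applied to every segment of the
held-out patient in time order. Each positive prediction is an alarm,
marked false when the segment does not end at an SH onset. The headline
statistic is the cohort median of the per-patient mean days between
successive false alarms (patients with fewer than two false alarms are
excluded).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from . import evaluation as ev
from . import features as ft
from .io import Segment, LABEL_SH

log = logging.getLogger(__name__)


def loo_deploy(segments: list[Segment], demographics: pd.DataFrame,
               config: ev.EvalConfig) -> pd.DataFrame:
    """Leave-one-patient-out scoring of every segment.

    Returns a frame with columns ``patient_id, alarm_time, truth, score``
    holding one row per positive prediction (alarm), sorted by patient then
    time. ``truth`` is ``true_alarm`` for segments that end at an SH onset,
    ``false_alarm`` otherwise.
    """
    patients = sorted({s.patient_id for s in segments})
    if len(patients) < 3:
        raise ValueError("leave-one-patient-out needs at least 3 patients")
    rng = np.random.default_rng(config.seed)

    rows = []
    for held_out in patients:
        train_segs = [s for s in segments if s.patient_id != held_out]
        test_segs = sorted((s for s in segments if s.patient_id == held_out),
                           key=lambda s: s.end_time)
        y_train = ft.labels_binary(train_segs)
        if len(np.unique(y_train)) < 2:
            log.info("patient %s: single-class training set, skipped", held_out)
            continue

        basis_full, basis_last = ft.fit_bases(train_segs)
        train_df = ft.featurize_segments(train_segs, basis_full, basis_last,
                                         demographics)
        test_df = ft.featurize_segments(test_segs, basis_full, basis_last,
                                        demographics)
        X_train = train_df[list(ft.FEATURE_NAMES)].to_numpy(dtype=float)
        X_test = test_df[list(ft.FEATURE_NAMES)].to_numpy(dtype=float)
        params = ev.robust_normalize_fit(X_train)
        X_train = ev.robust_normalize_apply(params, X_train)
        X_test = ev.robust_normalize_apply(params, X_test)

        scores = ev.train_and_score(X_train, y_train, X_test, config, rng)
        threshold = (0.0 if config.decision_threshold == "bcr"
                     else float(config.decision_threshold))
        for seg, score in zip(test_segs, scores):
            if score > threshold:
                rows.append({
                    "patient_id": held_out,
                    "alarm_time": seg.end_time,
                    "truth": ("true_alarm" if seg.label == LABEL_SH
                              else "false_alarm"),
                    "score": float(score),
                })
    df = pd.DataFrame(rows, columns=["patient_id", "alarm_time", "truth",
                                     "score"])
    return df.sort_values(["patient_id", "alarm_time"]).reset_index(drop=True)


def coalesce_alarms(records: pd.DataFrame, hours: float) -> pd.DataFrame:
    """Merge runs of alarms closer than ``hours`` into their first alarm
    (per patient and truth status)."""
    kept = []
    for (_pid, _truth), grp in records.groupby(["patient_id", "truth"],
                                               sort=False):
        grp = grp.sort_values("alarm_time")
        last_time = None
        for _, row in grp.iterrows():
            if last_time is None or \
                    (row["alarm_time"] - last_time) > pd.Timedelta(hours=hours):
                kept.append(row)
                last_time = row["alarm_time"]
    return (pd.DataFrame(kept).sort_values(["patient_id", "alarm_time"])
            .reset_index(drop=True) if kept
            else records.iloc[0:0])


def inter_alarm_delays(records: pd.DataFrame,
                       truth: str = "false_alarm") -> tuple[pd.DataFrame, float]:
    """Per-patient mean delay (days) between successive alarms and the
    cohort median of those means.

    Patients with fewer than two alarms of the requested kind are excluded
    from the median; with no eligible patient the statistic is NaN (logged).
    """
    sub = records[records["truth"] == truth]
    rows = []
    for pid, grp in sub.groupby("patient_id"):
        times = grp.sort_values("alarm_time")["alarm_time"].to_numpy()
        n = len(times)
        if n < 2:
            rows.append({"patient_id": pid, "n_alarms": n,
                         "mean_delay_days": np.nan})
            continue
        deltas = np.diff(times).astype("timedelta64[s]").astype(float) / 86400.0
        rows.append({"patient_id": pid, "n_alarms": n,
                     "mean_delay_days": float(np.mean(deltas))})
    per_patient = pd.DataFrame(rows, columns=["patient_id", "n_alarms",
                                              "mean_delay_days"])
    eligible = per_patient["mean_delay_days"].dropna()
    if eligible.empty:
        log.info("no patient with >= 2 %s records; median delay undefined", truth)
        return per_patient, float("nan")
    return per_patient, float(np.median(eligible))
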