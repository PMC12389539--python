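"""The 21-feature representation of a 5-day CGM segment.

Each segment first has its final sample removed (so every feature describes
the curve up to 15 min before the labeled endpoint — the prediction
horizon). The predictors are then:

1.  glycemic mean (mg/dL)
2.  variability, defined as mean / sample-SD (inverse coefficient of
    variation)
3.  frequency of grade-1 hypoglycemia: number of maximal runs of consecutive
    samples < 60 mg/dL
4-6. time below / in / above range as percentages of samples (< 60,
    [60, 160], > 160 mg/dL)
7-11.  scores on the first five principal components of the whole curve
12-16. scores on the first five principal components of the last five hours
17. whether the curve is descending over the last 45 min (strict)
18. whether the last point is below 54 mg/dL (strict)
19-21. age (years), sex (F=1/M=0), age at diagnosis (years)

Both PCA bases are fitted on training segments only and applied to held-out
segments, keeping patient-level cross-validation leak-free.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .io import Segment, SEGMENT_SAMPLES, LABEL_SH

TRUNCATED_SAMPLES = SEGMENT_SAMPLES - 1      # 479
LAST5H_SAMPLES = 20                          # 5 h at 15-min spacing
N_PCA = 5

HYPO_MGDL = 60.0
TIR_LOW, TIR_HIGH = 60.0, 160.0
ENDPOINT_MGDL = 54.0
TREND_STEPS = 3                              # 45 min at 15-min spacing
SD_FLOOR = 1e-6

FEATURE_NAMES: tuple[str, ...] = (
    "gly_mean", "variability", "hypo_freq", "tbr60", "tir60_160", "tar160",
    "pca_full_1", "pca_full_2", "pca_full_3", "pca_full_4", "pca_full_5",
    "pca_last5h_1", "pca_last5h_2", "pca_last5h_3", "pca_last5h_4",
    "pca_last5h_5",
    "descending_45min", "end_below_54",
    "age", "sex", "age_at_diagnosis",
)

BOOLEAN_FEATURES: tuple[str, ...] = ("descending_45min", "end_below_54", "sex")


def truncate_for_prediction(segment: Segment) -> np.ndarray:
    """Drop the final sample (the labeled instant) before any featurization."""
    if len(segment.values) != SEGMENT_SAMPLES:
        raise ValueError(
            f"expected a {SEGMENT_SAMPLES}-sample segment, got {len(segment.values)}")
    return segment.values[:-1]


def glycemic_stats(values: np.ndarray) -> tuple[float, float, int, float, float, float]:
    """(mean, mean/SD, hypo-episode count, %TBR<60, %TIR60-160, %TAR>160).

    Band percentages are by sample counting; 60 and 160 belong to the
    in-range band. The hypo frequency counts maximal runs below 60, not
    samples. SD is floored at 1e-6 mg/dL so the variability ratio stays
    finite on constant segments.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("glycemic_stats needs at least 2 samples")
    mean = float(values.mean())
    sd = max(float(values.std(ddof=1)), SD_FLOOR)
    variability = mean / sd

    below = values < HYPO_MGDL
    hypo_freq = int(np.count_nonzero(below[1:] & ~below[:-1]) + int(below[0]))

    n = values.size
    tbr = 100.0 * np.count_nonzero(below) / n
    tar = 100.0 * np.count_nonzero(values > TIR_HIGH) / n
    tir = 100.0 * np.count_nonzero((values >= TIR_LOW) & (values <= TIR_HIGH)) / n
    return mean, variability, hypo_freq, tbr, tir, tar


def trend_flag(values: np.ndarray) -> bool:
    """True iff the curve is descending over the last 45 min: last value
    strictly below the value three grid steps earlier."""
    values = np.asarray(values, dtype=float)
    if values.size < TREND_STEPS + 1:
        raise ValueError("trend_flag needs at least 4 samples")
    return bool(values[-1] < values[-1 - TREND_STEPS])


def endpoint_flag(values: np.ndarray) -> bool:
    """True iff the final available sample is strictly below 54 mg/dL."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("endpoint_flag needs a non-empty input")
    return bool(values[-1] < ENDPOINT_MGDL)


@dataclass
class PCABasis:
    """Mean curve + 5 orthonormal loading vectors for one window choice."""

    window: str                   # "full" | "last5h"
    mean_curve: np.ndarray
    components: np.ndarray        # (5, window length)
    explained_variance: np.ndarray

    @property
    def length(self) -> int:
        return self.mean_curve.size


def _window_matrix(truncated: list[np.ndarray] | np.ndarray, window: str) -> np.ndarray:
    X = np.asarray(truncated, dtype=float)
    if X.ndim != 2 or X.shape[1] != TRUNCATED_SAMPLES:
        raise ValueError(
            f"expected truncated segments of length {TRUNCATED_SAMPLES}")
    if window == "full":
        return X
    if window == "last5h":
        return X[:, -LAST5H_SAMPLES:]
    raise ValueError(f"unknown window {window!r}")


def fit_pca(truncated_segments: list[np.ndarray] | np.ndarray,
            window: str) -> PCABasis:
    """Fit a 5-component PCA on the requested window of the training curves.

    Sign convention: each component's largest-magnitude loading is positive,
    which makes the basis deterministic across SVD implementations.
    """
    X = _window_matrix(truncated_segments, window)
    if X.shape[0] < N_PCA + 1:
        raise ValueError(f"need at least {N_PCA + 1} training segments, "
                         f"got {X.shape[0]}")
    pca = PCA(n_components=N_PCA, svd_solver="full")
    pca.fit(X)
    components = pca.components_.copy()
    for i in range(N_PCA):
        j = int(np.argmax(np.abs(components[i])))
        if components[i, j] < 0:
            components[i] = -components[i]
    return PCABasis(window=window, mean_curve=pca.mean_.copy(),
                    components=components,
                    explained_variance=pca.explained_variance_.copy())


def project_pca(basis: PCABasis, truncated: np.ndarray) -> np.ndarray:
    """Scores of one truncated segment on the basis (inner products with the
    loadings after mean-centering)."""
    truncated = np.asarray(truncated, dtype=float)
    if truncated.size == TRUNCATED_SAMPLES:
        window = truncated if basis.window == "full" \
            else truncated[-LAST5H_SAMPLES:]
    elif truncated.size == basis.length:
        window = truncated
    else:
        raise ValueError(
            f"segment length {truncated.size} incompatible with "
            f"{basis.window!r} basis of length {basis.length}")
    return basis.components @ (window - basis.mean_curve)


def assemble_features(segment: Segment, basis_full: PCABasis,
                      basis_last5h: PCABasis,
                      demographics: pd.DataFrame) -> np.ndarray:
    """The 21-vector for one segment, in :data:`FEATURE_NAMES` order.

    Sex is encoded F=1 / M=0. Raises if the patient has no demographics row.
    """
    demo = demographics.loc[demographics["patient_id"] == segment.patient_id]
    if demo.empty:
        raise ValueError(f"no demographics for patient {segment.patient_id!r}")
    row = demo.iloc[0]

    values = truncate_for_prediction(segment)
    mean, variability, hypo_freq, tbr, tir, tar = glycemic_stats(values)
    scores_full = project_pca(basis_full, values)
    scores_last = project_pca(basis_last5h, values)

    sex = row["sex"]
    sex_code = 1.0 if str(sex).upper().startswith("F") else 0.0
    vec = np.array([
        mean, variability, float(hypo_freq), tbr, tir, tar,
        *scores_full, *scores_last,
        float(trend_flag(values)), float(endpoint_flag(values)),
        float(row["age_years"]), sex_code,
        float(row["age_at_diagnosis_years"]),
    ])
    assert vec.size == len(FEATURE_NAMES)
    return vec


def featurize_segments(segments: list[Segment], basis_full: PCABasis,
                       basis_last5h: PCABasis,
                       demographics: pd.DataFrame) -> pd.DataFrame:
    """Feature table for many segments: patient_id, end_time, label + the 21
    named predictor columns."""
    rows = []
    for seg in segments:
        vec = assemble_features(seg, basis_full, basis_last5h, demographics)
        row = {"patient_id": seg.patient_id, "end_time": seg.end_time,
               "label": seg.label}
        row.update(dict(zip(FEATURE_NAMES, vec)))
        rows.append(row)
    df = pd.DataFrame(rows, columns=["patient_id", "end_time", "label",
                                     *FEATURE_NAMES])
    return df


def fit_bases(segments: list[Segment]) -> tuple[PCABasis, PCABasis]:
    """Fit both PCA bases (whole curve and last 5 h) on training segments."""
    truncated = [truncate_for_prediction(s) for s in segments]
    return fit_pca(truncated, "full"), fit_pca(truncated, "last5h")


def labels_binary(segments_or_frame) -> np.ndarray:
    """0/1 label vector (1 = segment ends at an SH onset)."""
    if isinstance(segments_or_frame, pd.DataFrame):
        lab = segments_or_frame["label"]
    else:
        lab = pd.Series([s.label for s in segments_or_frame])
    return (lab == LABEL_SH).to_numpy().astype(int)
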