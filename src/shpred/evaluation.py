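"""Patient-level repeated cross-validation of SH classifiers.

The pipeline repeats k times: draw 80% of *patients* for training (every
segment follows its patient, so the model is only ever evaluated on unseen
patients), fit the two PCA bases and assemble features on the training fold,
robust-normalize (median/IQR from the training fold), optionally rank
features and keep a consensus signature of size s, fit a class-weighted
classifier (linear SVM or random forest), and score the held-out patients'
segments. Per-split confusion matrices and metrics (sensitivity,
specificity, PPV, BCR, AUC) are aggregated as medians with IQRs, and the
stability of the selected signatures is summarized by the Kuncheva index.

A univariate screen (Kruskal-Wallis for numeric features, Fisher's exact
test for booleans, Benjamini-Hochberg correction) is provided alongside.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.svm import SVC
from statsmodels.stats.multitest import multipletests

from . import features as ft
from .io import Segment

log = logging.getLogger(__name__)

N_FEATURES = len(ft.FEATURE_NAMES)

RANKING_METHODS = ("svm", "random_forest", "wilcoxon_consensus")
CLASSIFIERS = ("svm", "random_forest")


@dataclass(frozen=True)
class EvalConfig:
    k: int = 200                       # resampling count
    train_fraction: float = 0.8
    ranking_method: str = "svm"
    classifier: str = "svm"
    signature_size: int = N_FEATURES   # s; 21 = use all features, no selection
    subsample_models: int = 200        # subsamples for consensus selection
    subsample_fraction: float = 0.8
    seed: int = 0
    decision_threshold: float | str = 0.0   # score cutoff, or "bcr"
    svm_kernel: str = "linear"
    svm_C: float = 1.0
    rf_n_estimators: int = 200

    def validate(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")
        if not 1 <= self.signature_size <= N_FEATURES:
            raise ValueError(f"signature_size must be in [1, {N_FEATURES}]")
        if self.ranking_method not in RANKING_METHODS:
            raise ValueError(f"unknown ranking method {self.ranking_method!r}")
        if self.classifier not in CLASSIFIERS:
            raise ValueError(f"unknown classifier {self.classifier!r}")
        if self.k < 1:
            raise ValueError("k must be >= 1")


@dataclass
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class MetricSet:
    sensitivity: float
    specificity: float
    ppv: float          # NaN when no positives were predicted
    bcr: float
    auc: float          # NaN when the test set is single-class


@dataclass
class ResamplingResult:
    split_id: int
    test_patients: list[str]
    selected_features: list[str]
    confusion: ConfusionMatrix
    metrics: MetricSet
    threshold: float = 0.0


# ---------------------------------------------------------------------------
# Splits

def make_patient_splits(patient_ids: list[str], config: EvalConfig,
                        ) -> list[tuple[list[str], list[str]]]:
    """k seeded draws of floor(train_fraction * P) training patients."""
    patients = sorted(set(patient_ids))
    if len(patients) < 5:
        raise ValueError("need at least 5 patients for patient-level splits")
    n_train = int(np.floor(config.train_fraction * len(patients)))
    rng = np.random.default_rng(config.seed)
    splits = []
    for _ in range(config.k):
        train = list(rng.choice(patients, size=n_train, replace=False))
        test = [p for p in patients if p not in set(train)]
        splits.append((sorted(train), test))
    return splits


# ---------------------------------------------------------------------------
# Robust normalization

def robust_normalize_fit(train: np.ndarray,
                         feature_names: tuple[str, ...] = ft.FEATURE_NAMES,
                         ) -> dict:
    """Median/IQR per feature (linear-interpolation quantiles). Boolean
    features pass through unscaled; zero IQR falls back to 1."""
    train = np.asarray(train, dtype=float)
    median = np.median(train, axis=0)
    q1 = np.percentile(train, 25, axis=0)
    q3 = np.percentile(train, 75, axis=0)
    iqr = q3 - q1
    iqr[iqr == 0] = 1.0
    boolean = np.array([name in ft.BOOLEAN_FEATURES for name in feature_names])
    median = np.where(boolean, 0.0, median)
    iqr = np.where(boolean, 1.0, iqr)
    return {"median": median, "iqr": iqr}


def robust_normalize_apply(params: dict, X: np.ndarray) -> np.ndarray:
    return (np.asarray(X, dtype=float) - params["median"]) / params["iqr"]


# ---------------------------------------------------------------------------
# Feature ranking and consensus selection

def _svm_rfe_ranking(X: np.ndarray, y: np.ndarray, config: EvalConfig,
                     ) -> list[int]:
    """Recursive feature elimination driven by the squared weights of a
    linear maximum-margin classifier: repeatedly drop the feature with the
    smallest squared weight. Returns indices best-first."""
    remaining = list(range(X.shape[1]))
    eliminated: list[int] = []
    while len(remaining) > 1:
        clf = SVC(kernel="linear", C=config.svm_C, class_weight="balanced")
        clf.fit(X[:, remaining], y)
        w2 = np.ravel(clf.coef_) ** 2
        worst = int(np.argmin(w2))   # ties -> lowest index (fixed feature order)
        eliminated.append(remaining.pop(worst))
    return remaining + eliminated[::-1]


def _rf_ranking(X: np.ndarray, y: np.ndarray, config: EvalConfig,
                rng: np.random.Generator) -> list[int]:
    clf = RandomForestClassifier(
        n_estimators=config.rf_n_estimators, class_weight="balanced",
        random_state=int(rng.integers(2 ** 31)))
    clf.fit(X, y)
    imp = clf.feature_importances_
    # stable sort descending: ties broken by fixed feature order
    return list(np.argsort(-imp, kind="stable"))


def _wilcoxon_pvalues(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    pos, neg = X[y == 1], X[y == 0]
    pvals = np.ones(X.shape[1])
    for j in range(X.shape[1]):
        a, b = pos[:, j], neg[:, j]
        if np.ptp(np.concatenate([a, b])) == 0:
            pvals[j] = 1.0
        else:
            pvals[j] = stats.mannwhitneyu(a, b, alternative="two-sided").pvalue
    return pvals


def rank_features(X: np.ndarray, y: np.ndarray, method: str,
                  config: EvalConfig, rng: np.random.Generator) -> list[int]:
    """Order feature indices best-first with the requested method.

    ``wilcoxon_consensus`` ranks features by the median rank of their
    two-sample rank-test p-values across random row subsamples.
    """
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("ranking needs both classes in the training set")
    if method == "svm":
        return _svm_rfe_ranking(X, y, config)
    if method == "random_forest":
        return _rf_ranking(X, y, config, rng)
    if method == "wilcoxon_consensus":
        n = X.shape[0]
        m = max(2, int(round(config.subsample_fraction * n)))
        rank_mat = []
        for _ in range(config.subsample_models):
            idx = rng.choice(n, size=m, replace=False)
            ys = y[idx]
            if len(np.unique(ys)) < 2:
                continue
            p = _wilcoxon_pvalues(X[idx], ys)
            rank_mat.append(stats.rankdata(p, method="ordinal"))
        if not rank_mat:
            raise ValueError("no subsample contained both classes")
        med = np.median(np.asarray(rank_mat), axis=0)
        return list(np.argsort(med, kind="stable"))
    raise ValueError(f"unknown ranking method {method!r}")


def consensus_select(rankings: list[list[int]], s: int,
                     n_features: int = N_FEATURES) -> list[int]:
    """Features scored by how often they appear in the top-s of each
    subsample ranking; the s most frequent win, ties broken by mean rank and
    then by fixed feature order."""
    if s > n_features:
        raise ValueError(f"signature size {s} exceeds {n_features} features")
    if len(rankings) < 1:
        raise ValueError("need at least one ranking")
    freq = np.zeros(n_features)
    rank_sum = np.zeros(n_features)
    for ranking in rankings:
        for pos, f in enumerate(ranking):
            rank_sum[f] += pos
            if pos < s:
                freq[f] += 1
    mean_rank = rank_sum / len(rankings)
    order = sorted(range(n_features), key=lambda f: (-freq[f], mean_rank[f], f))
    return sorted(order[:s])


# ---------------------------------------------------------------------------
# Classifiers and metrics

def train_and_score(X_train: np.ndarray, y_train: np.ndarray,
                    X_test: np.ndarray, config: EvalConfig,
                    rng: np.random.Generator) -> np.ndarray:
    """Fit the configured classifier with class weights inversely
    proportional to class frequency and return continuous scores for the
    test rows (positive score => SH under the default zero threshold)."""
    if len(np.unique(y_train)) < 2:
        raise ValueError("training set must contain both classes")
    if config.classifier == "svm":
        clf = SVC(kernel=config.svm_kernel, C=config.svm_C,
                  class_weight="balanced")
        clf.fit(X_train, y_train)
        return clf.decision_function(X_test)
    clf = RandomForestClassifier(
        n_estimators=config.rf_n_estimators, class_weight="balanced",
        random_state=int(rng.integers(2 ** 31)))
    clf.fit(X_train, y_train)
    return clf.predict_proba(X_test)[:, 1] - 0.5


def compute_metrics(cm: ConfusionMatrix) -> MetricSet:
    sens = cm.tp / (cm.tp + cm.fn) if cm.tp + cm.fn else np.nan
    spec = cm.tn / (cm.tn + cm.fp) if cm.tn + cm.fp else np.nan
    ppv = cm.tp / (cm.tp + cm.fp) if cm.tp + cm.fp else np.nan
    bcr = (sens + spec) / 2.0
    return MetricSet(sensitivity=sens, specificity=spec, ppv=ppv, bcr=bcr,
                     auc=np.nan)


def compute_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC by the rank (Mann-Whitney) formulation; tied scores count 1/2.
    NaN when the labels are single-class."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == 0))
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    ranks = stats.rankdata(scores)
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def confusion_from_scores(scores: np.ndarray, labels: np.ndarray,
                          threshold: float) -> ConfusionMatrix:
    pred = np.asarray(scores) > threshold
    labels = np.asarray(labels).astype(bool)
    return ConfusionMatrix(
        tp=int(np.sum(pred & labels)), fp=int(np.sum(pred & ~labels)),
        tn=int(np.sum(~pred & ~labels)), fn=int(np.sum(~pred & labels)))


def bcr_optimal_threshold(scores: np.ndarray, labels: np.ndarray) -> float:
    """Score cutoff maximizing the balanced classification rate, chosen
    midway between consecutive distinct scores."""
    scores = np.asarray(scores, dtype=float)
    uniq = np.unique(scores)
    cands = np.concatenate([[uniq[0] - 1.0], (uniq[:-1] + uniq[1:]) / 2.0]) \
        if uniq.size > 1 else np.array([uniq[0] - 1.0])
    best_t, best_bcr = cands[0], -np.inf
    for t in cands:
        m = compute_metrics(confusion_from_scores(scores, labels, t))
        if np.isfinite(m.bcr) and m.bcr > best_bcr:
            best_bcr, best_t = m.bcr, t
    return float(best_t)


# ---------------------------------------------------------------------------
# Stability

def kuncheva_stability(selected_sets: list[set | list], s: int,
                       n_features: int = N_FEATURES) -> float:
    """Chance-corrected average pairwise overlap of size-s feature sets:
    K(A,B) = (|A & B| - s^2/N) / (s - s^2/N), averaged over all pairs."""
    if s <= 0 or s >= n_features:
        raise ValueError("Kuncheva index undefined for s = 0 or s = N")
    sets = [set(x) for x in selected_sets]
    if any(len(x) != s for x in sets):
        raise ValueError("all selected sets must have size s")
    expected = s * s / n_features
    vals = []
    for i in range(len(sets)):
        for j in range(i + 1, len(sets)):
            vals.append((len(sets[i] & sets[j]) - expected) / (s - expected))
    if not vals:
        raise ValueError("need at least two sets")
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# Full pipeline

def _segments_by_patients(segments: list[Segment],
                          patients: set[str]) -> list[Segment]:
    return [s for s in segments if s.patient_id in patients]


def run_pipeline(segments: list[Segment], demographics: pd.DataFrame,
                 config: EvalConfig,
                 ) -> tuple[list[ResamplingResult], dict]:
    """Execute the full split -> featurize (fold-wise PCA) -> normalize ->
    rank/select -> train -> score -> metric loop, and aggregate.

    Returns the per-split results and an aggregate dict with median and IQR
    of each metric plus the Kuncheva stability of the selected signatures
    (NaN when s equals the full feature count, where the index is undefined).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    patient_ids = [s.patient_id for s in segments]
    splits = make_patient_splits(patient_ids, config)

    results: list[ResamplingResult] = []
    for split_id, (train_p, test_p) in enumerate(splits):
        try:
            result = _run_split(split_id, segments, demographics, config,
                                set(train_p), set(test_p), rng)
        except ValueError as exc:
            log.info("split %d skipped: %s", split_id, exc)
            continue
        if result is not None:
            results.append(result)

    aggregate = aggregate_results(results, config)
    return results, aggregate


def _run_split(split_id: int, segments: list[Segment],
               demographics: pd.DataFrame, config: EvalConfig,
               train_p: set[str], test_p: set[str],
               rng: np.random.Generator) -> ResamplingResult | None:
    train_segs = _segments_by_patients(segments, train_p)
    test_segs = _segments_by_patients(segments, test_p)
    if not train_segs or not test_segs:
        raise ValueError("empty train or test fold")

    y_train = ft.labels_binary(train_segs)
    y_test = ft.labels_binary(test_segs)
    if len(np.unique(y_train)) < 2:
        raise ValueError("single-class training fold")

    basis_full, basis_last = ft.fit_bases(train_segs)
    train_df = ft.featurize_segments(train_segs, basis_full, basis_last,
                                     demographics)
    test_df = ft.featurize_segments(test_segs, basis_full, basis_last,
                                    demographics)
    X_train = train_df[list(ft.FEATURE_NAMES)].to_numpy(dtype=float)
    X_test = test_df[list(ft.FEATURE_NAMES)].to_numpy(dtype=float)

    params = robust_normalize_fit(X_train)
    X_train = robust_normalize_apply(params, X_train)
    X_test = robust_normalize_apply(params, X_test)

    s = config.signature_size
    if s >= N_FEATURES:
        selected = list(range(N_FEATURES))
    else:
        rankings = []
        n = X_train.shape[0]
        m = max(2, int(round(config.subsample_fraction * n)))
        for _ in range(config.subsample_models):
            idx = rng.choice(n, size=m, replace=False)
            if len(np.unique(y_train[idx])) < 2:
                continue
            rankings.append(rank_features(X_train[idx], y_train[idx],
                                          config.ranking_method, config, rng))
        if not rankings:
            raise ValueError("no subsample contained both classes")
        selected = consensus_select(rankings, s)

    scores = train_and_score(X_train[:, selected], y_train,
                             X_test[:, selected], config, rng)

    if config.decision_threshold == "bcr":
        if len(np.unique(y_test)) < 2:
            threshold = 0.0
        else:
            threshold = bcr_optimal_threshold(scores, y_test)
    else:
        threshold = float(config.decision_threshold)

    cm = confusion_from_scores(scores, y_test, threshold)
    metrics = compute_metrics(cm)
    metrics.auc = compute_auc(scores, y_test)
    return ResamplingResult(
        split_id=split_id, test_patients=sorted(test_p),
        selected_features=[ft.FEATURE_NAMES[i] for i in selected],
        confusion=cm, metrics=metrics, threshold=threshold)


def results_to_frame(results: list[ResamplingResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "split_id": r.split_id,
        "test_patients": ";".join(r.test_patients),
        "selected_features": ";".join(r.selected_features),
        "tp": r.confusion.tp, "fp": r.confusion.fp,
        "tn": r.confusion.tn, "fn": r.confusion.fn,
        "threshold": r.threshold,
        "sensitivity": r.metrics.sensitivity,
        "specificity": r.metrics.specificity,
        "ppv": r.metrics.ppv, "bcr": r.metrics.bcr, "auc": r.metrics.auc,
    } for r in results])


def aggregate_results(results: list[ResamplingResult],
                      config: EvalConfig) -> dict:
    """Median and IQR of each metric over splits (NaN-aware: undefined PPVs
    and AUCs are excluded rather than imputed), plus signature stability."""
    agg: dict = {"n_splits": len(results)}
    if not results:
        return agg
    df = results_to_frame(results)
    for metric in ("auc", "bcr", "sensitivity", "specificity", "ppv"):
        x = df[metric].dropna().to_numpy()
        if x.size:
            agg[f"median_{metric}"] = float(np.median(x))
            agg[f"iqr_{metric}"] = (float(np.percentile(x, 25)),
                                    float(np.percentile(x, 75)))
            agg[f"mean_{metric}"] = float(np.mean(x))
        else:
            agg[f"median_{metric}"] = float("nan")
    s = config.signature_size
    if 0 < s < N_FEATURES and len(results) >= 2:
        agg["kuncheva_stability"] = kuncheva_stability(
            [r.selected_features for r in results], s=s)
    else:
        agg["kuncheva_stability"] = float("nan")
    return agg


# ---------------------------------------------------------------------------
# Univariate screen

def univariate_screen(feature_df: pd.DataFrame) -> pd.DataFrame:
    """Per-feature two-group test against the segment label: Kruskal-Wallis
    for numeric features, Fisher's exact test for booleans, with
    Benjamini-Hochberg adjustment across all features."""
    y = ft.labels_binary(feature_df)
    rows = []
    for name in ft.FEATURE_NAMES:
        x = feature_df[name].to_numpy(dtype=float)
        if name in ft.BOOLEAN_FEATURES:
            tbl = np.array([
                [np.sum((x == 1) & (y == 1)), np.sum((x == 1) & (y == 0))],
                [np.sum((x == 0) & (y == 1)), np.sum((x == 0) & (y == 0))],
            ])
            p = float(stats.fisher_exact(tbl, alternative="two-sided")[1])
            test = "fisher"
        else:
            if np.ptp(x) == 0:
                p, test = 1.0, "kruskal (constant)"
            else:
                p = float(stats.kruskal(x[y == 1], x[y == 0]).pvalue)
            test = test if np.ptp(x) == 0 else "kruskal"
        rows.append({"feature": name, "test": test, "p_raw": p})
    df = pd.DataFrame(rows)
    df["p_adj"] = multipletests(df["p_raw"], method="fdr_bh")[1]
    return df
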