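"""Shapley-value attributions for individual predictions.

Attributions are computed on the classifier's continuous score. A feature's
value function marginalizes absent features by substituting them from a
background set (the training-fold feature table in practice), so for a
coalition S the payoff is the background-averaged score of the instance
with only the features in S fixed. With few features the Shapley values are
computed exactly by enumerating all coalitions; otherwise a Monte-Carlo
permutation estimator is used, whose error shrinks as 1/sqrt(n_permutations).
By construction baseline + sum(contributions) equals the model score
(exactly under enumeration, to sampling error otherwise).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import factorial
from typing import Callable, Sequence

import numpy as np
import pandas as pd

ScoreFn = Callable[[np.ndarray], np.ndarray]   # (n, d) -> (n,) scores

EXACT_MAX_FEATURES = 16


@dataclass
class Explanation:
    segment_id: str
    baseline: float
    contributions: np.ndarray           # signed, one per feature
    prediction: float
    feature_names: tuple[str, ...] | None = None

    @property
    def additivity_gap(self) -> float:
        return float(self.prediction - self.baseline - self.contributions.sum())


def _coalition_value(score_fn: ScoreFn, instance: np.ndarray,
                     background: np.ndarray, members: Sequence[int]) -> float:
    X = background.copy()
    if len(members):
        X[:, list(members)] = instance[list(members)]
    return float(np.mean(score_fn(X)))


def shap_values_exact(score_fn: ScoreFn, instance: np.ndarray,
                      background: np.ndarray,
                      segment_id: str = "") -> Explanation:
    """Exact Shapley values by enumeration over all feature coalitions.

    Cost is O(2^d) model evaluations over the background set; limited to
    small d.
    """
    instance = np.asarray(instance, dtype=float)
    background = np.atleast_2d(np.asarray(background, dtype=float))
    if background.size == 0:
        raise ValueError("background set must be non-empty")
    d = instance.size
    if d > EXACT_MAX_FEATURES:
        raise ValueError(f"exact enumeration limited to {EXACT_MAX_FEATURES} "
                         f"features, got {d}")

    values: dict[frozenset, float] = {}
    for r in range(d + 1):
        for S in combinations(range(d), r):
            values[frozenset(S)] = _coalition_value(
                score_fn, instance, background, S)

    contrib = np.zeros(d)
    fact = [factorial(i) for i in range(d + 1)]
    for i in range(d):
        others = [j for j in range(d) if j != i]
        for r in range(d):
            w = fact[r] * fact[d - r - 1] / fact[d]
            for S in combinations(others, r):
                fs = frozenset(S)
                contrib[i] += w * (values[fs | {i}] - values[fs])

    baseline = values[frozenset()]
    prediction = values[frozenset(range(d))]
    return Explanation(segment_id=segment_id, baseline=baseline,
                       contributions=contrib, prediction=prediction)


def shap_values_mc(score_fn: ScoreFn, instance: np.ndarray,
                   background: np.ndarray, n_permutations: int,
                   seed: int = 0, segment_id: str = "") -> Explanation:
    """Monte-Carlo permutation estimate of the Shapley values.

    Each iteration draws a random feature order and a random background row,
    then walks the order switching features from background to instance
    values, crediting each feature with the induced score change.
    """
    instance = np.asarray(instance, dtype=float)
    background = np.atleast_2d(np.asarray(background, dtype=float))
    if background.size == 0:
        raise ValueError("background set must be non-empty")
    rng = np.random.default_rng(seed)
    d = instance.size
    contrib = np.zeros(d)
    for _ in range(n_permutations):
        order = rng.permutation(d)
        b = background[rng.integers(background.shape[0])]
        x = b.copy()
        prev = float(score_fn(x[None, :])[0])
        for i in order:
            x[i] = instance[i]
            cur = float(score_fn(x[None, :])[0])
            contrib[i] += cur - prev
            prev = cur
    contrib /= n_permutations
    baseline = float(np.mean(score_fn(background)))
    prediction = float(score_fn(instance[None, :])[0])
    return Explanation(segment_id=segment_id, baseline=baseline,
                       contributions=contrib, prediction=prediction)


def shap_values(score_fn: ScoreFn, instance: np.ndarray,
                background: np.ndarray,
                n_permutations: int | str = 200, seed: int = 0,
                segment_id: str = "") -> Explanation:
    """Shapley attribution of one prediction.

    ``n_permutations="exhaustive"`` requests exact enumeration (small
    feature counts only); an integer requests the Monte-Carlo estimator.
    """
    if n_permutations == "exhaustive":
        return shap_values_exact(score_fn, instance, background, segment_id)
    return shap_values_mc(score_fn, instance, background,
                          int(n_permutations), seed, segment_id)


# ---------------------------------------------------------------------------
# Waterfall output

def waterfall_table(explanation: Explanation,
                    feature_names: Sequence[str] | None = None,
                    group_last5h: bool = False) -> pd.DataFrame:
    """Waterfall-ready table: features sorted by |contribution| descending
    with the running cumulative score from the baseline.

    ``group_last5h=True`` aggregates the last-5-h PCA component
    contributions into a single "last-5h shape" row (Shapley values are
    additive, so the grouped contribution is their exact sum).
    """
    contrib = explanation.contributions
    if feature_names is None:
        feature_names = explanation.feature_names or \
            tuple(f"f{i + 1}" for i in range(contrib.size))
    names = list(feature_names)

    if group_last5h:
        grouped_idx = [i for i, n in enumerate(names)
                       if n.startswith("pca_last5h")]
        if grouped_idx:
            keep = [i for i in range(len(names)) if i not in grouped_idx]
            names = [names[i] for i in keep] + ["last_5h_shape"]
            contrib = np.concatenate([contrib[keep],
                                      [contrib[grouped_idx].sum()]])

    order = np.argsort(-np.abs(contrib), kind="stable")
    rows = []
    running = explanation.baseline
    for i in order:
        running += contrib[i]
        rows.append({"feature": names[i], "contribution": float(contrib[i]),
                     "cumulative": float(running)})
    df = pd.DataFrame(rows, columns=["feature", "contribution", "cumulative"])
    df.attrs["baseline"] = explanation.baseline
    df.attrs["prediction"] = explanation.prediction
    return df


# ---------------------------------------------------------------------------
# False-positive curve profile

def false_positive_profile(segments_values: np.ndarray) -> dict:
    """Mean curve and pointwise 95% band over false-positive segments.

    Returns per grid position the mean and mean +/- 1.96 SE across the
    segments, plus the distribution of each segment's final glucose value.
    With fewer than 2 segments only the mean is reported.
    """
    X = np.atleast_2d(np.asarray(segments_values, dtype=float))
    n = X.shape[0]
    out = {"n": n, "mean": X.mean(axis=0), "final_values": X[:, -1].copy()}
    if n >= 2:
        se = X.std(axis=0, ddof=1) / np.sqrt(n)
        out["lower95"] = out["mean"] - 1.96 * se
        out["upper95"] = out["mean"] + 1.96 * se
    return out
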