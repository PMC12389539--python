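"""Splits, normalization, ranking, metrics, stability and the univariate
screen."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from shpred import evaluation as ev
from shpred import features as ft


# ---------------------------------------------------------------------------
# Splits

def test_split_sizes_and_disjointness():
    cfg = ev.EvalConfig(k=20, seed=0)
    pids = [f"P{i}" for i in range(10)]
    splits = ev.make_patient_splits(pids, cfg)
    assert len(splits) == 20
    for train, test in splits:
        assert len(train) == 8 and len(test) == 2
        assert not set(train) & set(test)
        assert set(train) | set(test) == set(pids)


def test_split_seed_reproducibility():
    pids = [f"P{i}" for i in range(10)]
    a = ev.make_patient_splits(pids, ev.EvalConfig(k=5, seed=3))
    b = ev.make_patient_splits(pids, ev.EvalConfig(k=5, seed=3))
    assert a == b
    c = ev.make_patient_splits(pids, ev.EvalConfig(k=5, seed=4))
    assert a != c


def test_every_patient_eventually_tested():
    pids = [f"P{i}" for i in range(10)]
    splits = ev.make_patient_splits(pids, ev.EvalConfig(k=200, seed=0))
    tested = set().union(*(set(test) for _, test in splits))
    assert tested == set(pids)


def test_split_too_few_patients():
    with pytest.raises(ValueError):
        ev.make_patient_splits(["P1", "P2"], ev.EvalConfig(k=1))


# ---------------------------------------------------------------------------
# Robust normalization

def test_robust_normalize_hand_example():
    names = ("a",)
    train = np.array([[1.0], [2.0], [3.0], [4.0], [5.0]])
    params = ev.robust_normalize_fit(train, names)
    assert params["median"][0] == 3.0 and params["iqr"][0] == 2.0
    assert ev.robust_normalize_apply(params, np.array([[5.0]]))[0, 0] == 1.0
    assert ev.robust_normalize_apply(params, np.array([[3.0]]))[0, 0] == 0.0


def test_robust_normalize_constant_feature():
    train = np.full((10, 1), 7.0)
    params = ev.robust_normalize_fit(train, ("a",))
    out = ev.robust_normalize_apply(params, train)
    np.testing.assert_array_equal(out, 0.0)


def test_robust_normalize_booleans_passthrough():
    train = np.column_stack([np.arange(10.0),
                             np.array([0, 1] * 5, dtype=float)])
    params = ev.robust_normalize_fit(train, ("gly_mean", "sex"))
    out = ev.robust_normalize_apply(params, train)
    np.testing.assert_array_equal(out[:, 1], train[:, 1])


# ---------------------------------------------------------------------------
# Metrics

def test_confusion_metrics_hand_arithmetic():
    m = ev.compute_metrics(ev.ConfusionMatrix(tp=3, fp=22, tn=100, fn=1))
    assert m.ppv == pytest.approx(0.12)
    assert m.sensitivity == pytest.approx(0.75)
    assert m.bcr == pytest.approx((0.75 + 100 / 122) / 2)


def test_bcr_identity():
    m = ev.compute_metrics(ev.ConfusionMatrix(tp=8, fp=1, tn=9, fn=2))
    assert m.bcr == (m.sensitivity + m.specificity) / 2


def test_auc_degenerate_orderings():
    assert ev.compute_auc([0.9, 0.8, 0.3], [1, 1, 0]) == 1.0
    assert ev.compute_auc([0.5, 0.5, 0.5], [1, 0, 1]) == 0.5
    assert np.isnan(ev.compute_auc([0.1, 0.2], [1, 1]))


def brute_force_auc(scores, labels):
    scores, labels = np.asarray(scores), np.asarray(labels)
    pos, neg = scores[labels == 1], scores[labels == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (pos.size * neg.size)


def test_auc_matches_brute_force_pair_ordering():
    rng = np.random.default_rng(0)
    for _ in range(50):
        n = rng.integers(4, 30)
        scores = np.round(rng.normal(size=n), 1)   # induce ties
        labels = rng.integers(0, 2, size=n)
        if labels.min() == labels.max():
            continue
        assert ev.compute_auc(scores, labels) == \
            pytest.approx(brute_force_auc(scores, labels), abs=1e-12)


def test_threshold_and_confusion_sizes():
    scores = np.array([-1.0, 0.5, 2.0, -0.2])
    labels = np.array([0, 1, 1, 0])
    cm = ev.confusion_from_scores(scores, labels, 0.0)
    assert (cm.tp, cm.fp, cm.tn, cm.fn) == (2, 0, 2, 0)
    assert cm.n == 4


def test_bcr_optimal_threshold_separable():
    scores = np.array([-2.0, -1.0, 1.0, 2.0])
    labels = np.array([0, 0, 1, 1])
    t = ev.bcr_optimal_threshold(scores, labels)
    cm = ev.confusion_from_scores(scores, labels, t)
    assert ev.compute_metrics(cm).bcr == 1.0


# ---------------------------------------------------------------------------
# Kuncheva stability

def test_kuncheva_identical_sets():
    sets = [{0, 1, 2}] * 4
    assert ev.kuncheva_stability(sets, 3, 21) == pytest.approx(1.0)


def test_kuncheva_disjoint_half():
    assert ev.kuncheva_stability([set(range(5)), set(range(5, 10))],
                                 5, 10) == pytest.approx(-1.0)


def test_kuncheva_null_mean_near_zero():
    rng = np.random.default_rng(0)
    vals = []
    for _ in range(5000):
        a = set(rng.choice(21, 10, replace=False))
        b = set(rng.choice(21, 10, replace=False))
        vals.append(ev.kuncheva_stability([a, b], 10, 21))
    assert abs(np.mean(vals)) < 0.02


def test_kuncheva_undefined_cases():
    with pytest.raises(ValueError):
        ev.kuncheva_stability([{1}], 0, 21)
    with pytest.raises(ValueError):
        ev.kuncheva_stability([set(range(21))], 21, 21)


# ---------------------------------------------------------------------------
# Ranking and consensus

def _informative_dataset(rng, n=400, n_noise=19):
    y = rng.integers(0, 2, n)
    X = rng.normal(size=(n, 2 + n_noise))
    X[:, 0] += 2.5 * y
    X[:, 1] -= 2.5 * y
    return X, y


@pytest.mark.parametrize("method", ev.RANKING_METHODS)
def test_informative_features_ranked_high(method):
    rng = np.random.default_rng(1)
    X, y = _informative_dataset(rng)
    cfg = ev.EvalConfig(subsample_models=20, rf_n_estimators=100)
    ranking = ev.rank_features(X, y, method, cfg, np.random.default_rng(1))
    assert {0, 1} <= set(ranking[:5])


def test_ranking_rejects_single_class():
    rng = np.random.default_rng(2)
    X = rng.normal(size=(20, 5))
    with pytest.raises(ValueError):
        ev.rank_features(X, np.zeros(20, dtype=int), "svm",
                         ev.EvalConfig(), rng)


def test_wilcoxon_null_no_systematic_winner():
    rng = np.random.default_rng(3)
    winners = []
    cfg = ev.EvalConfig(subsample_models=10)
    for rep in range(12):
        X = rng.normal(size=(60, 6))
        y = np.array([0, 1] * 30)
        ranking = ev.rank_features(X, y, "wilcoxon_consensus", cfg,
                                   np.random.default_rng(rep))
        winners.append(ranking[0])
    assert len(set(winners)) > 2  # no feature systematically wins under the null


def test_consensus_select_rules():
    r = [list(range(21))] * 3
    assert ev.consensus_select(r, 4) == [0, 1, 2, 3]
    assert ev.consensus_select(r, 21) == list(range(21))
    rankings = [[0] + list(range(1, 21)),
                [0] + list(range(1, 21)),
                [5, 0] + [i for i in range(1, 21) if i != 5]]
    assert ev.consensus_select(rankings, 1) == [0]   # top-1 twice: majority
    with pytest.raises(ValueError):
        ev.consensus_select(r, 22)


def test_train_and_score_separable_and_deterministic():
    rng = np.random.default_rng(4)
    y = rng.integers(0, 2, 200)
    X = np.column_stack([4.0 * y + rng.uniform(-1, 1, 200),
                         -4.0 * y + rng.uniform(-1, 1, 200)])
    cfg = ev.EvalConfig(classifier="svm")
    s1 = ev.train_and_score(X, y, X, cfg, np.random.default_rng(0))
    s2 = ev.train_and_score(X, y, X, cfg, np.random.default_rng(0))
    np.testing.assert_array_equal(s1, s2)
    assert np.mean((s1 > 0) == y) == 1.0
    cfg_rf = ev.EvalConfig(classifier="random_forest")
    s_rf = ev.train_and_score(X, y, X, cfg_rf, np.random.default_rng(0))
    assert np.mean((s_rf > 0) == y) == 1.0   # memorizable training set
    with pytest.raises(ValueError):
        ev.train_and_score(X, np.zeros_like(y), X, cfg, rng)


# ---------------------------------------------------------------------------
# Pipeline on synthetic segments

def test_run_pipeline_k1_single_holdout(small_segments, small_cohort):
    cfg = ev.EvalConfig(k=1, seed=2)
    results, agg = ev.run_pipeline(small_segments, small_cohort.demographics,
                                   cfg)
    assert agg["n_splits"] == len(results) <= 1
    if results:
        assert agg["median_auc"] == results[0].metrics.auc
        # test patients never appear in training
        train = {s.patient_id for s in small_segments} - \
            set(results[0].test_patients)
        assert not set(results[0].test_patients) & train


def test_run_pipeline_aggregate_consistency(small_segments, small_cohort):
    cfg = ev.EvalConfig(k=8, seed=5)
    results, agg = ev.run_pipeline(small_segments, small_cohort.demographics,
                                   cfg)
    df = ev.results_to_frame(results)
    for r in results:
        assert r.metrics.bcr == pytest.approx(
            (r.metrics.sensitivity + r.metrics.specificity) / 2)
    assert agg["median_auc"] == pytest.approx(
        np.median(df["auc"].dropna()))


def test_run_pipeline_signature_selection(small_segments, small_cohort):
    cfg = ev.EvalConfig(k=3, seed=6, signature_size=5, subsample_models=8,
                        ranking_method="wilcoxon_consensus")
    results, agg = ev.run_pipeline(small_segments, small_cohort.demographics,
                                   cfg)
    for r in results:
        assert len(r.selected_features) == 5
    assert np.isfinite(agg["kuncheva_stability"])


# ---------------------------------------------------------------------------
# Univariate screen

def test_bh_adjustment_hand_case():
    df = pd.DataFrame({"feature": ["a", "b", "c"],
                       "p_raw": [0.01, 0.02, 0.04]})
    from statsmodels.stats.multitest import multipletests
    adj = multipletests(df["p_raw"], method="fdr_bh")[1]
    np.testing.assert_allclose(adj, [0.03, 0.03, 0.04])


def test_fisher_exact_hand_case():
    assert stats.fisher_exact([[2, 0], [0, 2]])[1] == pytest.approx(1 / 3)


def test_univariate_screen_shapes(small_segments, small_cohort):
    bf, bl = ft.fit_bases(small_segments)
    fdf = ft.featurize_segments(small_segments, bf, bl,
                                small_cohort.demographics)
    out = ev.univariate_screen(fdf)
    assert len(out) == 21
    assert (out["p_adj"] >= out["p_raw"] - 1e-12).all()
    assert set(out.loc[out["feature"] == "sex", "test"]) == {"fisher"}


def test_univariate_screen_fdr_under_null():
    rng = np.random.default_rng(9)
    rows = []
    sig_frac = []
    for rep in range(10):
        n = 200
        df = pd.DataFrame(rng.normal(size=(n, 18)),
                          columns=[f for f in ft.FEATURE_NAMES
                                   if f not in ft.BOOLEAN_FEATURES])
        for b in ft.BOOLEAN_FEATURES:
            df[b] = rng.integers(0, 2, n).astype(float)
        df["label"] = np.where(rng.integers(0, 2, n) == 1, "SH", "non-SH")
        out = ev.univariate_screen(df)
        sig_frac.append(np.mean(out["p_adj"] < 0.05))
    assert np.mean(sig_frac) <= 0.05
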