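"""Feature extraction: glycemic statistics, trend/endpoint flags, curve PCA
and the 21-vector assembly."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from shpred import features as ft
from shpred import io as sio


def _segment(values, patient_id="P0", label=sio.LABEL_NON_SH):
    return sio.Segment(patient_id=patient_id,
                       end_time=pd.Timestamp("2023-01-06"),
                       values=np.asarray(values, dtype=float), label=label)


DEMO = pd.DataFrame({"patient_id": ["P0"], "age_years": [12.5], "sex": ["F"],
                     "age_at_diagnosis_years": [6.0]})


def test_truncate_removes_final_point():
    seg = _segment(np.arange(480.0))
    out = ft.truncate_for_prediction(seg)
    assert out.size == 479 and out[-1] == 478.0


def test_truncate_rejects_wrong_length():
    seg = _segment(np.arange(480.0))
    short = ft.truncate_for_prediction(seg)
    # applying truncation twice is a length error (479 != 480)
    fake = sio.Segment.__new__(sio.Segment)
    fake.patient_id, fake.end_time, fake.label = "P0", seg.end_time, "non-SH"
    fake.values = short
    with pytest.raises(ValueError):
        ft.truncate_for_prediction(fake)
    with pytest.raises(ValueError):
        ft.glycemic_stats(short[:1])  # stats precondition: >= 2 samples


def test_glycemic_stats_constant():
    mean, var, hypo, tbr, tir, tar = ft.glycemic_stats(np.full(100, 120.0))
    assert mean == 120.0 and hypo == 0
    assert (tbr, tir, tar) == (0.0, 100.0, 0.0)
    assert var == 120.0 / 1e-6  # SD floor engaged


def test_glycemic_stats_band_boundaries():
    _, _, _, tbr, tir, tar = ft.glycemic_stats([59, 60, 160, 161])
    assert (tbr, tir, tar) == (25.0, 50.0, 25.0)


def test_hypo_episode_run_counting():
    stats = ft.glycemic_stats([58, 57, 65, 59, 61, 55])
    assert stats[2] == 3


@settings(max_examples=50, derandomize=True)
@given(st.lists(st.floats(min_value=20, max_value=500), min_size=2,
                max_size=200))
def test_band_percentages_sum_to_100(values):
    _, _, hypo, tbr, tir, tar = ft.glycemic_stats(values)
    assert tbr + tir + tar == pytest.approx(100.0, abs=1e-9)
    assert (hypo == 0) == (tbr == 0.0)


@pytest.mark.parametrize("tail,expected", [
    ([100, 95, 90, 85], True),
    ([85, 90, 95, 100], False),
    ([90, 80, 95, 90], False),   # tie: strict comparison
])
def test_trend_flag(tail, expected):
    assert ft.trend_flag(np.asarray(tail, dtype=float)) is expected
    with pytest.raises(ValueError):
        ft.trend_flag(np.array([1.0, 2.0]))


@pytest.mark.parametrize("last,expected", [(53.9, True), (54.0, False),
                                           (300.0, False)])
def test_endpoint_flag(last, expected):
    assert ft.endpoint_flag(np.array([100.0, last])) is expected


# ---------------------------------------------------------------------------
# PCA

def _random_curves(n, rng):
    t = np.linspace(0, 4 * np.pi, ft.TRUNCATED_SAMPLES)
    return np.array([150 + rng.normal(0, 20) * np.sin(t + rng.uniform(0, np.pi))
                     + rng.normal(0, 5, t.size) for _ in range(n)])


def test_pca_orthonormal_and_variance_ordered():
    rng = np.random.default_rng(0)
    basis = ft.fit_pca(_random_curves(30, rng), "full")
    gram = basis.components @ basis.components.T
    np.testing.assert_allclose(gram, np.eye(5), atol=1e-8)
    assert np.all(np.diff(basis.explained_variance) <= 1e-9)
    # deterministic sign convention
    for comp in basis.components:
        assert comp[np.argmax(np.abs(comp))] > 0


def test_pca_rank_deficiency():
    rng = np.random.default_rng(1)
    base = _random_curves(2, rng)
    coeffs = rng.normal(size=(12, 2))
    X = 150 + coeffs @ (base - 150)      # 2-D affine subspace
    basis = ft.fit_pca(X, "full")
    np.testing.assert_allclose(basis.explained_variance[2:], 0, atol=1e-8)


def test_pca_projection_properties():
    rng = np.random.default_rng(2)
    X = _random_curves(12, rng)
    basis = ft.fit_pca(X, "full")
    # mean curve projects to zero
    np.testing.assert_allclose(ft.project_pca(basis, basis.mean_curve),
                               0, atol=1e-8)
    # mean + c1 * component1 -> (c1, 0, 0, 0, 0)
    probe = basis.mean_curve + 3.7 * basis.components[0]
    np.testing.assert_allclose(ft.project_pca(basis, probe),
                               [3.7, 0, 0, 0, 0], atol=1e-8)
    # isometry bound: score norm never exceeds centered-curve norm
    for row in X:
        scores = ft.project_pca(basis, row)
        assert np.linalg.norm(scores) <= \
            np.linalg.norm(row - basis.mean_curve) + 1e-9


def test_pca_reconstruction_monotone():
    rng = np.random.default_rng(3)
    X = _random_curves(6, rng)
    basis = ft.fit_pca(X, "full")
    x = X[0]
    centered = x - basis.mean_curve
    errs = []
    for k in range(6):
        recon = basis.components[:k].T @ (basis.components[:k] @ centered)
        errs.append(np.linalg.norm(centered - recon))
    assert all(a >= b - 1e-9 for a, b in zip(errs, errs[1:]))
    # 6 curves lie in a <=5-D affine subspace: full reconstruction is exact
    np.testing.assert_allclose(errs[-1], 0, atol=1e-6)


def test_fit_pca_too_few_segments():
    rng = np.random.default_rng(4)
    with pytest.raises(ValueError):
        ft.fit_pca(_random_curves(5, rng), "full")


def test_project_length_mismatch():
    rng = np.random.default_rng(5)
    basis = ft.fit_pca(_random_curves(8, rng), "last5h")
    with pytest.raises(ValueError):
        ft.project_pca(basis, np.zeros(33))


# ---------------------------------------------------------------------------
# Assembly

def _training_segments(rng, n=10):
    return [_segment(150 + rng.normal(0, 10, 480)) for _ in range(n)]


def test_assemble_has_21_features_and_is_deterministic():
    rng = np.random.default_rng(6)
    segs = _training_segments(rng)
    bf, bl = ft.fit_bases(segs)
    v1 = ft.assemble_features(segs[0], bf, bl, DEMO)
    v2 = ft.assemble_features(segs[0], bf, bl, DEMO)
    assert v1.size == 21 == len(ft.FEATURE_NAMES)
    np.testing.assert_array_equal(v1, v2)
    assert v1[ft.FEATURE_NAMES.index("sex")] == 1.0       # F -> 1
    assert v1[ft.FEATURE_NAMES.index("age")] == 12.5


def test_assemble_missing_demographics_names_patient():
    rng = np.random.default_rng(7)
    segs = _training_segments(rng)
    bf, bl = ft.fit_bases(segs)
    with pytest.raises(ValueError, match="P0"):
        ft.assemble_features(segs[0], bf, bl, DEMO.assign(patient_id="P9"))


def test_assemble_descending_low_ending_segment():
    rng = np.random.default_rng(8)
    segs = _training_segments(rng)
    bf, bl = ft.fit_bases(segs)
    values = np.full(480, 150.0)
    values[-30:] = np.linspace(150, 45, 30)   # monotone fall to 45
    seg = _segment(values)
    vec = ft.assemble_features(seg, bf, bl, DEMO)
    assert vec[ft.FEATURE_NAMES.index("end_below_54")] == 1.0
    assert vec[ft.FEATURE_NAMES.index("descending_45min")] == 1.0
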