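"""Portrayed-emotion models: preprocessing parity, shared variance, CCA, CV."""

import numpy as np
import pytest

from emomap.attribution import (
    AttributionModel,
    cca_align,
    crossval_encoding_comparison,
    preprocess_attribution,
    shared_variance,
)
from emomap.encoding import DesignMatrix, fit_encoding
from emomap.ratings import RatingTimeseries, preprocess_ratings
from emomap.synthetic import gen_bold

from conftest import ar1_series

ATTR_LABELS = tuple(f"cat_{i}" for i in range(18)) + (
    "happiness",
    "fear",
    "sadness",
    "anger",
)


def test_preprocessing_parity_with_subjective_path(rng):
    col = np.clip(50 + 15 * ar1_series(rng, 2000, phi=0.9), 0, 100)
    as_rating = RatingTimeseries(col[:, None], rate=10.0, emotion_labels=("e",))
    as_attr = AttributionModel(
        col[:, None], labels=("e",), direction="other_directed", rate=10.0
    )
    pre_r = preprocess_ratings(as_rating, tr=2, lag=2, window=10)
    pre_a = preprocess_attribution(as_attr, tr=2, lag=2, window=10)
    assert np.allclose(pre_a.values[:, 0], pre_r.values[:, 0], atol=1e-9)


def test_constant_columns_preserved():
    vals = np.column_stack([np.full(2000, 7.0), np.full(2000, 0.0)])
    attr = AttributionModel(vals, labels=("a", "b"), direction="self_directed", rate=10.0)
    pre = preprocess_attribution(attr)
    assert np.allclose(pre.values[:, 0], 7.0)
    assert np.allclose(pre.values[:, 1], 0.0)


def test_shared_variance_identical_models_is_100(rng):
    vals = np.clip(50 + 15 * ar1_series(rng, 300, n=6, phi=0.8), 0, 100)
    subj = RatingTimeseries(vals, rate=0.5)
    attr_vals = np.abs(ar1_series(rng, 300, n=22, phi=0.8))
    for c in ("happiness", "fear", "sadness", "anger"):
        attr_vals[:, ATTR_LABELS.index(c)] = vals[:, subj.emotion_labels.index(c)]
    attr = AttributionModel(attr_vals, labels=ATTR_LABELS, direction="other_directed")
    res = shared_variance(subj, attr)
    assert all(np.isclose(v, 100.0) for v in res["per_category"].values())
    assert len(res["per_category"]) == 4


def test_shared_variance_independent_series_near_zero(rng):
    vals = np.clip(50 + 15 * ar1_series(rng, 500, n=6, phi=0.3), 0, 100)
    subj = RatingTimeseries(vals, rate=0.5)
    attr = AttributionModel(
        np.abs(ar1_series(rng, 500, n=22, phi=0.3)),
        labels=ATTR_LABELS,
        direction="other_directed",
    )
    res = shared_variance(subj, attr)
    assert res["mean"] < 5.0


def test_shared_variance_missing_category_rejected(rng):
    subj = RatingTimeseries(
        np.clip(50 + ar1_series(rng, 100, n=6, phi=0.3), 0, 100), rate=0.5
    )
    attr = AttributionModel(
        np.abs(ar1_series(rng, 100, n=3, phi=0.3)),
        labels=("x", "y", "z"),
        direction="self_directed",
    )
    with pytest.raises(ValueError, match="missing"):
        shared_variance(subj, attr)


# ---------------------------------------------------------------------------
# CCA


def test_exact_transform_gives_unit_correlations(rng):
    subj = rng.standard_normal((400, 6))
    attr = subj @ rng.standard_normal((6, 22))
    cca = cca_align(attr, subj)
    assert np.allclose(cca.canonical_correlations, 1.0, atol=1e-8)
    # reconstructed components mutually uncorrelated
    c = np.corrcoef(cca.reconstructed.T)
    assert np.allclose(c - np.diag(np.diag(c)), 0.0, atol=1e-6)


def test_correlations_invariant_to_invertible_transforms(rng):
    subj = rng.standard_normal((500, 6))
    attr = rng.standard_normal((500, 22)) + subj @ rng.standard_normal((6, 22))
    base = cca_align(attr, subj).canonical_correlations
    t1 = cca_align(attr @ _invertible(rng, 22), subj).canonical_correlations
    t2 = cca_align(attr, subj @ _invertible(rng, 6)).canonical_correlations
    assert np.allclose(base, t1, atol=1e-8)
    assert np.allclose(base, t2, atol=1e-8)


def _invertible(rng, n):
    m = rng.standard_normal((n, n))
    return m + n * np.eye(n)


def test_independent_blocks_small_correlations_vs_shift_null(rng):
    t = 600
    subj = ar1_series(rng, t, n=6, phi=0.5)
    attr = ar1_series(rng, t, n=22, phi=0.5)
    observed = cca_align(attr, subj).canonical_correlations[0]
    null = []
    for shift in (97, 199, 301, 403, 505):
        null.append(
            cca_align(np.roll(attr, shift, axis=0), subj).canonical_correlations[0]
        )
    # observed top correlation is of the same order as the circular-shift null
    assert observed < max(null) + 0.15


def test_cca_requires_sufficient_t(rng):
    with pytest.raises(ValueError, match="T"):
        cca_align(rng.standard_normal((20, 22)), rng.standard_normal((20, 6)))


# ---------------------------------------------------------------------------
# cross-validated model comparison


def test_generating_model_wins_crossvalidation(rng):
    t = 400
    runs = np.repeat(np.arange(4), t // 4)
    x_true = ar1_series(rng, t, n=4, phi=0.7)
    x_other = ar1_series(rng, t, n=4, phi=0.7)
    beta = rng.standard_normal((15, 4))
    activity = gen_bold(beta, x_true, 0.0, seed=0)
    models = {
        "true": DesignMatrix(x_true, tuple("abcd")),
        "mismatched": DesignMatrix(x_other, tuple("wxyz")),
    }
    res = crossval_encoding_comparison(activity, models, runs)
    assert res["true"]["r2_corr"] > 0.99
    assert res["true"]["r2_corr"] > res["mismatched"]["r2_corr"] + 0.5


def test_pure_noise_has_near_zero_cv_r2(rng):
    t = 400
    runs = np.repeat(np.arange(4), t // 4)
    activity = rng.standard_normal((15, t))
    models = {"m": DesignMatrix(ar1_series(rng, t, n=4, phi=0.7), tuple("abcd"))}
    res = crossval_encoding_comparison(activity, models, runs)
    assert res["m"]["r2_corr"] < 0.1
    assert res["m"]["r2_raw"] < 0.1


def test_cv_r2_below_in_sample_r2_in_expectation(rng):
    t, v, p = 80, 5, 3
    runs = np.repeat(np.arange(2), t // 2)
    cv, ins = [], []
    for sim in range(100):
        r = np.random.default_rng(sim)
        x = ar1_series(r, t, n=p, phi=0.5)
        beta = r.standard_normal((v, p))
        activity = gen_bold(beta, x, 4.0, seed=sim)
        design = DesignMatrix(x, tuple("abc"))
        ins.append(float(np.nanmean(fit_encoding(activity, design).r2)))
        cv.append(
            crossval_encoding_comparison(activity, {"m": design}, runs)["m"]["r2_raw"]
        )
    assert np.mean(cv) < np.mean(ins)


def test_crossval_requires_multiple_runs(rng):
    activity = rng.standard_normal((3, 100))
    design = DesignMatrix(ar1_series(rng, 100, n=2, phi=0.5), ("a", "b"))
    with pytest.raises(ValueError, match="2 runs"):
        crossval_encoding_comparison(activity, {"m": design}, np.zeros(100, int))
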