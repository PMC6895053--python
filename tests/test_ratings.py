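"""Rating preprocessing, agreement, PCA dimensions, clustering."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from emomap.ratings import (
    RatingTimeseries,
    cluster_affective_states,
    loo_pc_consistency,
    pairwise_agreement,
    pca_dimensions,
    preprocess_ratings,
    procrustes_rotation,
    rating_surrogates,
)

from conftest import ar1_series


# ---------------------------------------------------------------------------
# preprocessing


@settings(max_examples=10, deadline=None, derandomize=True)
@given(hst.floats(min_value=0, max_value=100))
def test_constant_input_gives_constant_output(value):
    raw = RatingTimeseries(np.full((2000, 6), value), rate=10.0)
    pre = preprocess_ratings(raw, tr=2, lag=2, window=10)
    assert np.allclose(pre.values, value)


def test_usable_samples_match_full_scan_geometry(rng):
    """A 10 Hz series covering a 3599-volume TR-2s scan yields 3595 usable
    samples after 2 s lag and 10 s centered smoothing with edge trimming."""
    raw = RatingTimeseries(
        np.clip(50 + 10 * rng.standard_normal((3599 * 20, 6)), 0, 100), rate=10.0
    )
    pre = preprocess_ratings(raw, tr=2, lag=2, window=10)
    values, volumes = pre.align_to_scan(3599)
    assert values.shape[0] == 3595
    assert volumes[0] == 3 and volumes[-1] == 3597


def test_lag_shifts_impulse_by_one_volume():
    imp = np.zeros((400, 1))
    imp[200] = 100.0
    raw = RatingTimeseries(imp, rate=10.0, emotion_labels=("e",))
    on_axis = {}
    for lag in (0.0, 2.0):
        pre = preprocess_ratings(raw, tr=2, lag=lag, window=10)
        axis = np.zeros(60)
        axis[pre.volume_indices] = pre.values[:, 0]
        on_axis[lag] = axis
    assert on_axis[2.0].argmax() == on_axis[0.0].argmax() + 1


def test_downsampling_is_block_mean():
    v = np.arange(40, dtype=float).reshape(-1, 1)  # 0..39 at 10 Hz
    raw = RatingTimeseries(v, rate=10.0, emotion_labels=("e",))
    pre = preprocess_ratings(raw, tr=2, lag=0, window=2, trim_edges=False)
    assert np.allclose(pre.values[:, 0], [9.5, 29.5])


@pytest.mark.parametrize(
    "kwargs,match",
    [
        (dict(window=1.0), "window"),
        (dict(lag=-2.0), "lag"),
        (dict(lag=3.0), "multiple"),
    ],
)
def test_preprocess_rejects_bad_parameters(kwargs, match):
    raw = RatingTimeseries(np.full((200, 6), 50.0), rate=10.0)
    with pytest.raises(ValueError, match=match):
        preprocess_ratings(raw, tr=2, **kwargs)


# ---------------------------------------------------------------------------
# PCA dimensions


def test_pca_reconstructs_centered_ratings(small_panel):
    group = small_panel["group"]
    dims = small_panel["dims"]
    centered = group.values - group.values.mean(axis=0)
    assert np.allclose(centered, dims.scores @ dims.loadings.T, atol=1e-10)
    assert np.isclose(dims.explained_variance.sum(), 1.0)
    assert np.all(np.diff(dims.explained_variance) <= 1e-12)
    # loadings orthonormal
    assert np.allclose(dims.loadings.T @ dims.loadings, np.eye(6), atol=1e-10)


def test_pca_six_emotions_give_six_components(small_panel):
    assert small_panel["dims"].loadings.shape == (6, 6)
    assert len(small_panel["dims"].component_labels) == 6


def test_pca_perfectly_anticorrelated_pair():
    rng = np.random.default_rng(0)
    a = np.clip(50 + 20 * rng.standard_normal(500), 0, 100)
    x = np.column_stack([a, 100 - a])
    rt = RatingTimeseries(x, rate=0.5, emotion_labels=("up", "down"))
    dims = pca_dimensions(rt)
    # closed form: covariance [[v,-v],[-v,v]] has eigenvalues (2v, 0)
    assert np.isclose(dims.explained_variance[0], 1.0)
    assert dims.loadings[0, 0] * dims.loadings[1, 0] < 0
    assert dims.degenerate[1]


def test_pca_sign_convention_largest_loading_positive(small_panel):
    loadings = small_panel["dims"].loadings
    for c in range(loadings.shape[1]):
        assert loadings[np.abs(loadings[:, c]).argmax(), c] > 0


def test_pca_uncorrelated_inputs_give_identity_like_loadings():
    rng = np.random.default_rng(1)
    t = 4096
    x = rng.standard_normal((t, 4))
    # exactly uncorrelated columns with distinct variances, offset into range
    q, _ = np.linalg.qr(x - x.mean(axis=0))
    scales = np.array([300.0, 240.0, 180.0, 120.0])
    vals = 50 + q * scales
    assert vals.min() >= 0 and vals.max() <= 100  # no clipping distortion
    rt = RatingTimeseries(vals, rate=0.5, emotion_labels=tuple("abcd"))
    dims = pca_dimensions(rt)
    # loadings form a signed permutation of the identity (here: identity)
    perm = np.abs(dims.loadings) > 0.99
    assert perm.sum() == 4
    assert np.all(perm.sum(axis=0) == 1) and np.all(perm.sum(axis=1) == 1)


# ---------------------------------------------------------------------------
# agreement


def test_identical_subjects_have_unit_agreement(rng):
    base = np.clip(50 + 15 * ar1_series(rng, 300, n=6, phi=0.8), 0, 100)
    panel = [RatingTimeseries(base.copy(), rate=0.5) for _ in range(4)]
    group = panel[0]
    null = rating_surrogates(group, n=30, seed=3, max_iter=20)
    res = pairwise_agreement(panel, null)
    assert res.n_pairs == 6
    for label in group.emotion_labels:
        assert np.allclose(res.pairwise_rho[label], 1.0)


def test_twelve_subjects_give_66_pairs(small_panel):
    group = small_panel["group"]
    null = rating_surrogates(group, n=20, seed=4, max_iter=10)
    res = pairwise_agreement(small_panel["panel"], null)
    assert res.n_pairs == 66
    for label in group.emotion_labels:
        assert res.pairwise_rho[label].shape == (66,)


def test_zero_variance_subject_recorded_as_missing(rng):
    base = np.clip(50 + 15 * ar1_series(rng, 300, n=6, phi=0.8), 0, 100)
    flat = base.copy()
    flat[:, 0] = 42.0
    panel = [
        RatingTimeseries(base, rate=0.5),
        RatingTimeseries(flat, rate=0.5),
        RatingTimeseries(base.copy(), rate=0.5),
    ]
    group = panel[0]
    null = rating_surrogates(group, n=20, seed=5, max_iter=10)
    res = pairwise_agreement(panel, null)
    label = group.emotion_labels[0]
    assert np.isnan(res.pairwise_rho[label]).sum() == 2  # the two pairs with flat
    assert not res.consistent[label]


# ---------------------------------------------------------------------------
# Procrustes consistency


def test_procrustes_recovers_known_rotation(rng):
    from scipy.stats import special_ortho_group

    g = rng.standard_normal((200, 6)) * np.array([8, 6, 5, 4, 3, 2])
    g -= g.mean(axis=0)
    q = special_ortho_group.rvs(6, random_state=np.random.default_rng(0))
    rotated = g @ q
    r = procrustes_rotation(rotated, g)
    back = rotated @ r
    for c in range(6):
        num = np.corrcoef(back[:, c], g[:, c])[0, 1]
        assert num > 1 - 1e-6


def test_procrustes_flags_rank_deficiency(rng):
    a = rng.standard_normal((100, 3))
    b = a.copy()
    b[:, 2] = 0.0
    with pytest.raises(ValueError, match="rank-deficient"):
        procrustes_rotation(a, b)


def test_loo_consistency_requires_three_subjects(small_panel):
    with pytest.raises(ValueError, match="3 subjects"):
        loo_pc_consistency(small_panel["panel"][:2])


def test_identical_subjects_yield_unit_component_agreement(rng):
    base = np.clip(50 + 15 * ar1_series(rng, 300, n=6, phi=0.8), 0, 100)
    panel = [RatingTimeseries(base.copy(), rate=0.5) for _ in range(4)]
    res = loo_pc_consistency(panel)
    for label, rhos in res.pairwise_rho.items():
        assert np.allclose(rhos, 1.0, atol=1e-9), label


# ---------------------------------------------------------------------------
# affective-state clustering


def test_clustering_rejects_too_few_kept_points():
    rng = np.random.default_rng(0)
    vals = np.clip(50 + rng.standard_normal((100, 6)), 0, 100)
    group = RatingTimeseries(vals, rate=0.5)
    with pytest.raises(ValueError, match="perplexity"):
        cluster_affective_states(group, perplexity=30)


def test_clustering_rejects_degenerate_kept_set():
    vals = np.zeros((400, 6))
    vals[200:] = 80.0  # kept half is constant
    group = RatingTimeseries(vals, rate=0.5)
    with pytest.raises(ValueError, match="degenerate"):
        cluster_affective_states(group, perplexity=30)


def test_clustering_labels_and_reproducibility(rng):
    centers = np.array([[70, 10, 5, 5, 5, 5], [5, 5, 60, 50, 10, 10]], dtype=float)
    pts = np.vstack(
        [
            centers[0] + rng.standard_normal((150, 6)) * 3,
            centers[1] + rng.standard_normal((150, 6)) * 3,
            np.abs(rng.standard_normal((300, 6))) * 2,
        ]
    )
    group = RatingTimeseries(np.clip(pts, 0, 100), rate=0.5)
    a = cluster_affective_states(group, seed=9)
    b = cluster_affective_states(group, seed=9)
    assert a.k == b.k
    assert np.array_equal(a.labels, b.labels)
    assert a.labels.min() == 1 and a.labels.max() == a.k
    assert a.k == max(a.silhouette_by_k, key=a.silhouette_by_k.get)
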