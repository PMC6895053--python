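"""Gaussian tuning estimation (pRF) and NMF tuning decomposition."""

import numpy as np
import pytest

from emomap.prf import (
    build_tuning_grid,
    filter_predictor,
    fit_prf,
    grid_t_values,
    nmf_tuning_components,
    tuning_vs_gradient,
)
from emomap.synthetic import gen_tuned_activity

from conftest import ar1_series


@pytest.fixture(scope="module")
def scores():
    rng = np.random.default_rng(3)
    return 20.0 * ar1_series(rng, 250, phi=0.8)


# ---------------------------------------------------------------------------
# grid construction and filtering


def test_grid_defaults_match_reference_spec(scores):
    grid = build_tuning_grid(scores)
    assert np.isclose(grid.mu_values[1] - grid.mu_values[0], 0.5)
    assert np.isclose(grid.sigma_values[0], 1.0)
    assert np.isclose(grid.sigma_values[-1], 12.0)
    assert np.isclose(grid.sigma_values[1] - grid.sigma_values[0], 0.25)
    lo, hi = np.percentile(scores, [5, 95])
    assert grid.mu_values[0] >= lo - 1e-9
    assert grid.mu_values[-1] <= hi + 1e-9


def test_grid_spans_percentiles_for_uniform_scores():
    s = np.linspace(0, 100, 10_001)
    grid = build_tuning_grid(s)
    assert np.isclose(grid.mu_values[0], 5.0, atol=0.02)
    assert grid.mu_values[-1] <= 95.0 + 1e-9
    assert grid.mu_values[-1] > 94.4


def test_grid_rejects_constant_scores():
    with pytest.raises(ValueError, match="constant"):
        build_tuning_grid(np.full(100, 3.0))


def test_filter_predictor_contract(scores):
    assert np.allclose(filter_predictor(np.full(50, 2.0), 2.0, 1.0), 1.0)
    wide = filter_predictor(scores, 0.0, 1e6)
    assert np.ptp(wide) < 1e-6  # flat-tuning limit
    pts = np.array([-1.0, 0.5, 2.0, 3.5, 7.0])
    expect = np.exp(-((pts - 2.0) ** 2) / (2 * 1.5**2))
    assert np.allclose(filter_predictor(pts, 2.0, 1.5), expect)
    with pytest.raises(ValueError, match="sigma"):
        filter_predictor(pts, 0.0, -1.0)


# ---------------------------------------------------------------------------
# grid search


def test_noiseless_tuning_recovered_within_one_step(scores):
    grid = build_tuning_grid(scores)
    tp = np.array([[5.0, 2.0], [-8.0, 4.0], [0.0, 3.0]])
    activity, _ = gen_tuned_activity(scores, tp, amplitude=1.0, noise_sd=0.0, seed=0)
    est = fit_prf(activity, scores, grid)
    assert np.all(np.abs(est.mu - tp[:, 0]) <= 0.5 + 1e-9)
    assert np.all(np.abs(est.sigma - tp[:, 1]) <= 0.5 + 1e-9)


def test_t_statistic_invariant_to_affine_voxel_rescaling(scores):
    grid = build_tuning_grid(scores)
    tp = np.array([[3.0, 2.5]])
    activity, _ = gen_tuned_activity(scores, tp, amplitude=1.0, noise_sd=0.5, seed=1)
    t1 = grid_t_values(activity, scores, grid)
    t2 = grid_t_values(7.0 * activity + 40.0, scores, grid)
    assert np.allclose(t1, t2, atol=1e-8)


def test_tie_break_prefers_smallest_sigma_then_mu(scores):
    grid = build_tuning_grid(scores, mu_step=5.0, sigma_range=(2.0, 4.0), sigma_step=1.0)
    combos = grid.combinations()
    # sigma-major ordering encodes the tie-break
    assert np.all(np.diff(combos[:, 1]) >= 0)
    first_sigma = combos[combos[:, 1] == combos[0, 1]]
    assert np.all(np.diff(first_sigma[:, 0]) > 0)


def test_all_nan_voxel_flagged_and_skipped(scores):
    grid = build_tuning_grid(scores)
    tp = np.array([[5.0, 2.0]])
    activity, _ = gen_tuned_activity(scores, tp, amplitude=1.0, noise_sd=0.0, seed=0)
    full = np.vstack([activity, np.full_like(activity, np.nan)])
    est = fit_prf(full, scores, grid)
    assert not est.flat_flag[0] and est.flat_flag[1]
    assert np.isnan(est.mu[1]) and np.isnan(est.t[1])


# ---------------------------------------------------------------------------
# tuning vs gradient


def test_monotone_mu_beta_relation_gives_rho_one(rng):
    mu = rng.standard_normal(60)
    beta = np.exp(mu)  # monotone transform
    rho, p = tuning_vs_gradient(mu, beta)
    assert np.isclose(rho, 1.0)
    assert p is None


def test_independent_maps_not_significant(rng):
    mu = rng.standard_normal(80)
    beta = rng.standard_normal(80)
    nulls = rng.standard_normal((200, 80))
    rho, p = tuning_vs_gradient(mu, beta, nulls)
    assert abs(rho) < 0.5
    assert p > 0.01


def test_constant_map_degenerate(rng):
    with pytest.raises(ValueError, match="degenerate"):
        tuning_vs_gradient(np.ones(30), rng.standard_normal(30))


# ---------------------------------------------------------------------------
# NMF decomposition


def test_rank_one_matrix_recovered(scores):
    grid = build_tuning_grid(scores, mu_step=2.0, sigma_range=(1, 3), sigma_step=1.0)
    k = grid.n_combinations
    rng = np.random.default_rng(5)
    w = np.abs(rng.standard_normal(40))
    h = np.abs(rng.standard_normal(k))
    x = np.outer(w, h)
    basis = nmf_tuning_components(x, grid, rank=1, seed=0)
    assert basis.variance_explained[0] > 0.99
    assert basis.total_retained > 0.999
    assert np.all(basis.components >= 0) and np.all(basis.weights >= 0)


def test_reconstruction_error_nonincreasing_in_rank(scores):
    grid = build_tuning_grid(scores, mu_step=2.0, sigma_range=(1, 3), sigma_step=1.0)
    rng = np.random.default_rng(6)
    x = np.abs(rng.standard_normal((30, grid.n_combinations)))
    retained = [
        nmf_tuning_components(x, grid, rank=r, seed=1).total_retained
        for r in (2, 4, 8)
    ]
    assert retained[0] <= retained[1] + 1e-6 <= retained[2] + 2e-6


def test_tuning_curves_only_for_large_components(scores):
    grid = build_tuning_grid(scores, mu_step=2.0, sigma_range=(1, 3), sigma_step=1.0)
    rng = np.random.default_rng(7)
    w = np.abs(rng.standard_normal(40))
    h = np.abs(rng.standard_normal(grid.n_combinations))
    x = np.outer(w, h) + 0.001 * np.abs(rng.standard_normal((40, grid.n_combinations)))
    basis = nmf_tuning_components(x, grid, rank=3, seed=2)
    assert 0 in basis.tuning_curves  # dominant component kept
    assert all(
        basis.variance_explained[i] >= 0.05 for i in basis.tuning_curves
    )
    assert basis.tuning_curves[0].shape == (len(grid.mu_values),)


def test_nmf_input_contracts(scores):
    grid = build_tuning_grid(scores, mu_step=2.0, sigma_range=(1, 3), sigma_step=1.0)
    with pytest.raises(ValueError, match="all-zero"):
        nmf_tuning_components(np.zeros((10, grid.n_combinations)), grid, rank=2)
    with pytest.raises(ValueError, match="rank"):
        nmf_tuning_components(
            np.abs(np.random.default_rng(0).standard_normal((4, grid.n_combinations))),
            grid,
            rank=10,
        )
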