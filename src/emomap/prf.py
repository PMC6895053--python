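"""Population receptive field tuning of voxels along emotion dimensions.

Parallel to sensory topographies, a voxel may respond maximally around a
preferred value of an emotion-dimension score. Each voxel's tuning curve
is modeled as a Gaussian over the score with preferred value mu and width
sigma: the score series is passed through every Gaussian of a regular
(mu, sigma) grid, each filtered regressor is fit to the voxel by simple
linear regression, and the grid point with the highest t-value (beta /
SE(beta)) wins. The default grid follows the reference analysis: mu from
the 5th to the 95th percentile of the scores in steps of 0.5, sigma from
1 to 12 in steps of 0.25 (~5k combinations).

Voxels whose best t does not exceed a surrogate-based null threshold are
flagged as flat (no meaningful preference). Prototypical tunings across
voxels are extracted by non-negative matrix factorization of the t-value
grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import NMF

from ._stats import pearson_rows, rank_rows, spearman

__all__ = [
    "TuningGrid",
    "TuningEstimate",
    "TuningBasis",
    "build_tuning_grid",
    "filter_predictor",
    "grid_t_values",
    "fit_prf",
    "tuning_vs_gradient",
    "nmf_tuning_components",
]


@dataclass(frozen=True)
class TuningGrid:
    """Regular grid of candidate (mu, sigma) tuning parameters."""

    mu_values: np.ndarray  # ascending, score units
    sigma_values: np.ndarray  # ascending, strictly positive, score units
    percentile_bounds: tuple[float, float] = (5.0, 95.0)

    def __post_init__(self) -> None:
        if len(self.mu_values) < 1 or len(self.sigma_values) < 1:
            raise ValueError("empty tuning grid")
        if np.any(np.asarray(self.sigma_values) <= 0):
            raise ValueError("sigma grid must be strictly positive")

    @property
    def n_combinations(self) -> int:
        return len(self.mu_values) * len(self.sigma_values)

    def combinations(self) -> np.ndarray:
        """(K, 2) rows of (mu, sigma), sigma-major ascending then mu.

        The ordering encodes the tie-break: on equal t the first (i.e.
        smallest sigma, then smallest mu) grid point wins — the most
        specific tuning.
        """
        s, m = np.meshgrid(self.sigma_values, self.mu_values, indexing="ij")
        return np.column_stack([m.ravel(), s.ravel()])


@dataclass
class TuningEstimate:
    """Per-voxel preferred score, width, and best-fit statistic."""

    mu: np.ndarray  # (V,)
    sigma: np.ndarray  # (V,)
    t: np.ndarray  # (V,) best t = beta / SE(beta)
    flat_flag: np.ndarray  # (V,) bool: no tuning beyond the null threshold
    null_t95: np.ndarray | None = None  # per-voxel null 95th percentile


@dataclass
class TuningBasis:
    """NMF decomposition of the voxel x (mu, sigma) t-value matrix."""

    components: np.ndarray  # (rank, K) non-negative basis tunings
    weights: np.ndarray  # (V, rank) non-negative voxel weights
    variance_explained: np.ndarray  # (rank,) fractions, descending
    total_retained: float
    tuning_curves: dict[int, np.ndarray]  # component -> curve over mu (sigma-avg)
    mu_values: np.ndarray


def build_tuning_grid(
    scores: np.ndarray,
    mu_step: float = 0.5,
    sigma_range: tuple[float, float] = (1.0, 12.0),
    sigma_step: float = 0.25,
    percentile_bounds: tuple[float, float] = (5.0, 95.0),
) -> TuningGrid:
    """Grid of plausible tunings spanning the observed score range.

    mu spans the (5th, 95th) score percentiles at `mu_step`; sigma spans
    `sigma_range` at `sigma_step`.
    """
    scores = np.asarray(scores, dtype=float).ravel()
    if np.ptp(scores) == 0:
        raise ValueError("constant scores: tuning grid undefined")
    lo, hi = np.percentile(scores, percentile_bounds)
    if hi - lo <= 0:
        raise ValueError("degenerate percentile range for the mu grid")
    n_mu = int(np.floor((hi - lo) / mu_step + 1e-9)) + 1
    mu = lo + mu_step * np.arange(n_mu)
    s_lo, s_hi = sigma_range
    n_s = int(np.floor((s_hi - s_lo) / sigma_step + 1e-9)) + 1
    sigma = s_lo + sigma_step * np.arange(n_s)
    return TuningGrid(
        mu_values=mu, sigma_values=sigma, percentile_bounds=percentile_bounds
    )


def filter_predictor(scores: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    """Gaussian-filtered regressor ``exp(-(score - mu)^2 / (2 sigma^2))``."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    scores = np.asarray(scores, dtype=float)
    return np.exp(-((scores - mu) ** 2) / (2.0 * sigma**2))


def grid_t_values(
    activity: np.ndarray, scores: np.ndarray, grid: TuningGrid
) -> np.ndarray:
    """t-value of each (voxel, grid point) simple-regression slope, (V, K).

    For regressor g and voxel y (intercept included):
    ``t = b / SE(b)`` with ``b = Sxy / Sxx`` and
    ``SE(b)^2 = (Syy - Sxy^2/Sxx) / ((T - 2) Sxx)``. Vectorized over the
    full grid. Degenerate regressors (constant over the observed scores)
    give t = 0.
    """
    activity = np.atleast_2d(np.asarray(activity, dtype=float))
    scores = np.asarray(scores, dtype=float).ravel()
    t_len = scores.shape[0]
    if activity.shape[1] != t_len:
        raise ValueError("activity and scores differ in T")
    if t_len <= 3:
        raise ValueError("need more than 3 timepoints for a tuning fit")

    combos = grid.combinations()  # (K, 2)
    # regressors (K, T)
    g = np.exp(
        -((scores[None, :] - combos[:, 0:1]) ** 2) / (2.0 * combos[:, 1:2] ** 2)
    )
    gc = g - g.mean(axis=1, keepdims=True)
    sxx = (gc * gc).sum(axis=1)  # (K,)
    ac = activity - activity.mean(axis=1, keepdims=True)
    syy = (ac * ac).sum(axis=1)  # (V,)
    sxy = ac @ gc.T  # (V, K)
    dof = t_len - 2
    with np.errstate(invalid="ignore", divide="ignore"):
        se2 = (syy[:, None] - sxy**2 / sxx[None, :]) / (dof * sxx[None, :])
        se2 = np.maximum(se2, 0.0)
        t = (sxy / sxx[None, :]) / np.sqrt(se2)
    t[:, sxx <= 1e-300] = 0.0  # flat regressor: no tuning information
    t[~np.isfinite(t)] = 0.0
    return t


def fit_prf(
    activity: np.ndarray,
    scores: np.ndarray,
    grid: TuningGrid,
    n_null: int = 0,
    seed: int | None = None,
    null_quantile: float = 95.0,
    surrogate_max_iter: int = 50,
) -> TuningEstimate:
    """Best Gaussian tuning per voxel by exhaustive grid search.

    The winning (mu, sigma) maximizes the regression t-value over the
    grid; exact ties resolve to the smallest sigma, then the smallest mu.
    With ``n_null > 0``, the score series is IAAFT-surrogated `n_null`
    times, the grid search repeated, and a voxel is flagged flat when its
    best t does not exceed the `null_quantile` percentile of its own null
    best-t distribution. All-NaN voxels are flagged flat and skipped.
    """
    from .surrogates import iaaft_surrogate

    activity = np.atleast_2d(np.asarray(activity, dtype=float))
    v = activity.shape[0]
    nan_voxels = ~np.isfinite(activity).all(axis=1)
    work = activity.copy()
    work[nan_voxels] = 0.0

    t = grid_t_values(work, scores, grid)
    best = t.argmax(axis=1)  # first max -> smallest sigma, then mu
    combos = grid.combinations()
    mu = combos[best, 0]
    sigma = combos[best, 1]
    best_t = t[np.arange(v), best]

    null_t95 = None
    flat = np.zeros(v, dtype=bool)
    if n_null > 0:
        ens = iaaft_surrogate(
            np.asarray(scores, dtype=float).ravel(),
            n=n_null,
            seed=seed,
            max_iter=surrogate_max_iter,
        )
        null_best = np.empty((n_null, v))
        for i in range(n_null):
            tn = grid_t_values(work, ens.surrogates[i], grid)
            null_best[i] = tn.max(axis=1)
        null_t95 = np.percentile(null_best, null_quantile, axis=0)
        flat = best_t <= null_t95
    flat |= nan_voxels
    mu[nan_voxels] = np.nan
    sigma[nan_voxels] = np.nan
    best_t[nan_voxels] = np.nan
    return TuningEstimate(
        mu=mu, sigma=sigma, t=best_t, flat_flag=flat, null_t95=null_t95
    )


def tuning_vs_gradient(
    mu_map: np.ndarray,
    beta_map: np.ndarray,
    null_betas: np.ndarray | None = None,
) -> tuple[float, float | None]:
    """Spearman similarity between preferred scores and gradient coefficients.

    Correlates the per-voxel pRF mu map with the per-voxel encoding beta
    map across the ROI; significance against a null ensemble of beta maps
    (surrogate-refit coefficients), (n_null, V). Returns (rho, p).
    """
    mu_map = np.asarray(mu_map, dtype=float).ravel()
    beta_map = np.asarray(beta_map, dtype=float).ravel()
    if mu_map.shape != beta_map.shape:
        raise ValueError("mu and beta maps differ in voxel count")
    if np.ptp(mu_map[np.isfinite(mu_map)]) == 0 or np.ptp(beta_map) == 0:
        raise ValueError("constant map: association degenerate")
    ok = np.isfinite(mu_map)
    rho = spearman(mu_map[ok], beta_map[ok])
    p = None
    if null_betas is not None:
        null_betas = np.atleast_2d(np.asarray(null_betas, dtype=float))[:, ok]
        mu_ranks = rank_rows(mu_map[ok])
        null_rhos = pearson_rows(rank_rows(null_betas), mu_ranks)
        p = float((1 + np.sum(np.abs(null_rhos) >= abs(rho))) / (null_rhos.size + 1))
    return rho, p


def nmf_tuning_components(
    t_matrix: np.ndarray,
    grid: TuningGrid,
    rank: int = 10,
    min_component_variance: float = 0.05,
    min_total_retained: float = 0.90,
    seed: int | None = None,
    n_restarts: int = 10,
    max_iter: int = 500,
) -> TuningBasis:
    """Prototypical voxel tunings by non-negative matrix factorization.

    The (V, K) t-value matrix (negative t clipped to zero — "no response"
    stays zero, preserving the parts-based reading) is factored as W @ H
    with multiplicative updates from seeded random non-negative starts;
    `n_restarts` restarts keep the lowest reconstruction error.
    Components are ordered by variance explained; those below
    `min_component_variance` are excluded from the per-mu tuning curves
    (curves average the basis over all sigma at each mu).
    """
    x = np.atleast_2d(np.asarray(t_matrix, dtype=float))
    x = np.clip(x, 0.0, None)
    if not np.any(x > 0):
        raise ValueError("all-zero t matrix: nothing to factor")
    if rank >= min(x.shape):
        raise ValueError("NMF rank must be below both matrix dimensions")

    streams = np.random.SeedSequence(seed).spawn(n_restarts)
    best = None
    for ss in streams:
        model = NMF(
            n_components=rank,
            init="random",
            solver="mu",
            max_iter=max_iter,
            random_state=int(ss.generate_state(1)[0] % (2**31)),
        )
        w = model.fit_transform(x)
        if best is None or model.reconstruction_err_ < best[0]:
            best = (model.reconstruction_err_, w, model.components_)
    _, w, h = best

    total_ss = float((x**2).sum())
    comp_var = np.array(
        [float((np.outer(w[:, i], h[i]) ** 2).sum()) / total_ss for i in range(rank)]
    )
    order = np.argsort(comp_var)[::-1]
    w, h, comp_var = w[:, order], h[order], comp_var[order]
    resid = x - w @ h
    total_retained = 1.0 - float((resid**2).sum()) / total_ss
    if total_retained < min_total_retained:
        import warnings

        warnings.warn(
            f"NMF rank {rank} retains {total_retained:.1%} < "
            f"{min_total_retained:.0%} of the total variance; consider a "
            "higher rank"
        )

    n_sigma = len(grid.sigma_values)
    n_mu = len(grid.mu_values)
    curves: dict[int, np.ndarray] = {}
    for i in range(rank):
        if comp_var[i] >= min_component_variance:
            curves[i] = h[i].reshape(n_sigma, n_mu).mean(axis=0)
    return TuningBasis(
        components=h,
        weights=w,
        variance_explained=comp_var,
        total_retained=total_retained,
        tuning_curves=curves,
        mu_values=np.asarray(grid.mu_values),
    )
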