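"""Voxelwise linear encoding of emotion ratings in brain activity.

Each voxel's time series is regressed (ordinary least squares, intercept
always included) on a T x P design of emotion predictors — basic-emotion
ratings, their principal components, or attribution models. The full-
model R^2 is invariant under any invertible recombination of predictors,
so the basic-emotion and emotion-dimension designs fit identically even
though individual coefficients differ.

Inference: the observed R^2 is compared per voxel to null encoding models
in which every predictor column is replaced by an IAAFT surrogate
(preserving each column's spectrum and autocorrelation while destroying
its relation to the activity), with Benjamini-Hochberg FDR across voxels.
R^2 standard errors come from a circular block bootstrap of timepoints,
and a leave-one-subject-out noise ceiling bounds the variance any model
could explain given between-subject reliability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ._stats import bh_fdr
from .surrogates import surrogate_matrix

__all__ = [
    "DesignMatrix",
    "EncodingResult",
    "NoiseCeiling",
    "fit_encoding",
    "permutation_null_r2",
    "bootstrap_r2_se",
    "noise_ceiling",
]

_COND_WARN = 1e8


@dataclass
class DesignMatrix:
    """T x P predictor matrix (intercept is added at fit time, never counted)."""

    values: np.ndarray
    predictor_labels: tuple[str, ...]
    basis: str = "custom"  # basic_emotions | principal_components | attribution | custom

    def __post_init__(self) -> None:
        v = np.atleast_2d(np.asarray(self.values, dtype=float))
        if v.shape[1] != len(self.predictor_labels):
            raise ValueError("label count does not match predictor columns")
        if not np.all(np.isfinite(v)):
            raise ValueError("design contains non-finite values")
        if np.any(np.all(v == 0, axis=0)):
            raise ValueError("design contains an all-zero predictor column")
        self.values = v

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_predictors(self) -> int:
        return self.values.shape[1]


@dataclass
class EncodingResult:
    """Per-voxel OLS fit: coefficients, R^2, and (optionally) inference."""

    beta: np.ndarray  # (V, P)
    r2: np.ndarray  # (V,), NaN for zero-variance voxels
    predictor_labels: tuple[str, ...]
    intercept: np.ndarray | None = None  # (V,)
    p: np.ndarray | None = None  # permutation p per voxel
    q: np.ndarray | None = None  # BH-FDR adjusted
    r2_se: np.ndarray | None = None  # bootstrap SE per voxel
    zero_variance: np.ndarray | None = None  # bool flags


@dataclass
class NoiseCeiling:
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.lower) and np.isfinite(self.upper)):
            raise ValueError("non-finite noise ceiling")


def _design_with_intercept(
    design: DesignMatrix, zscore_predictors: bool
) -> np.ndarray:
    x = design.values
    if zscore_predictors:
        sd = x.std(axis=0, ddof=0)
        if np.any(sd == 0):
            # constant (nonzero) columns carry no signal beyond the intercept
            raise ValueError("design contains a constant predictor column")
        x = (x - x.mean(axis=0)) / sd
    return np.column_stack([np.ones(x.shape[0]), x])


def _r2_from_fit(activity: np.ndarray, x: np.ndarray, b: np.ndarray) -> np.ndarray:
    """activity (V, T), x (T, P+1), b (P+1, V) -> R^2 per voxel (NaN if flat)."""
    resid = activity.T - x @ b  # (T, V)
    ss_res = (resid**2).sum(axis=0)
    centered = activity.T - activity.T.mean(axis=0)
    ss_tot = (centered**2).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = 1.0 - ss_res / ss_tot
    r2[ss_tot == 0] = np.nan
    return np.clip(r2, 0.0, 1.0, out=r2, where=np.isfinite(r2))


def fit_encoding(
    activity: np.ndarray,
    design: DesignMatrix,
    zscore_predictors: bool = True,
) -> EncodingResult:
    """OLS encoding fit of every voxel (rows of `activity`, V x T).

    Predictors are z-scored by default so coefficient magnitudes are
    comparable across dimensions (required by the topography analyses);
    this rescaling never changes the full-model R^2. An ill-conditioned
    design triggers a warning; an exactly singular one is rejected.
    """
    activity = np.atleast_2d(np.asarray(activity, dtype=float))
    t, p = design.n_timepoints, design.n_predictors
    if activity.shape[1] != t:
        raise ValueError(
            f"activity has {activity.shape[1]} timepoints, design has {t}"
        )
    if t <= p + 1:
        raise ValueError("need T > P + 1 timepoints to fit the encoding model")

    x = _design_with_intercept(design, zscore_predictors)
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise np.linalg.LinAlgError("singular design matrix")
    cond = np.linalg.cond(x)
    if cond > _COND_WARN:
        warnings.warn(
            f"design condition number {cond:.3g} exceeds {_COND_WARN:.0e}: "
            "coefficients are unreliable"
        )
    b, *_ = np.linalg.lstsq(x, activity.T, rcond=None)
    r2 = _r2_from_fit(activity, x, b)
    return EncodingResult(
        beta=b[1:].T,
        r2=r2,
        predictor_labels=design.predictor_labels,
        intercept=b[0],
        zero_variance=~np.isfinite(r2),
    )


def permutation_null_r2(
    activity: np.ndarray,
    design: DesignMatrix,
    n_perm: int = 1000,
    seed: int | None = None,
    alpha: float = 0.01,
    zscore_predictors: bool = True,
    surrogate_max_iter: int = 50,
    return_null: bool = False,
):
    """Permutation p-values of the full-model R^2 via surrogate designs.

    Each of the `n_perm` null models replaces *all* predictor columns
    jointly by independent IAAFT surrogates and refits; for each voxel
    ``p = (1 + #{null R^2 >= observed R^2}) / (n_perm + 1)`` and q is the
    BH-FDR adjustment across voxels (report q < `alpha`). The reference
    analysis used n_perm = 10,000; desk-scale calibration runs use less.

    Returns an :class:`EncodingResult` with `p` and `q` filled in (plus
    the (n_perm, V) null R^2 matrix when `return_null`).
    """
    if n_perm < 100:
        raise ValueError("n_perm < 100 gives meaninglessly coarse p-values")
    activity = np.atleast_2d(np.asarray(activity, dtype=float))
    observed = fit_encoding(activity, design, zscore_predictors)
    x_cols = design.values
    streams = np.random.SeedSequence(seed).spawn(n_perm)
    null_r2 = np.empty((n_perm, activity.shape[0]))
    for i, ss in enumerate(streams):
        sur = surrogate_matrix(
            x_cols,
            seed=int(ss.generate_state(1)[0] % (2**31)),
            max_iter=surrogate_max_iter,
        )
        null_design = DesignMatrix(
            sur, design.predictor_labels, basis=design.basis
        )
        xn = _design_with_intercept(null_design, zscore_predictors)
        b, *_ = np.linalg.lstsq(xn, activity.T, rcond=None)
        null_r2[i] = _r2_from_fit(activity, xn, b)

    v = activity.shape[0]
    p = np.full(v, np.nan)
    ok = np.isfinite(observed.r2)
    exceed = np.sum(null_r2[:, ok] >= observed.r2[ok], axis=0)
    p[ok] = (1 + exceed) / (n_perm + 1)
    observed.p = p
    observed.q = bh_fdr(p)
    if return_null:
        return observed, null_r2
    return observed


def bootstrap_r2_se(
    activity: np.ndarray,
    design: DesignMatrix,
    n_boot: int = 1000,
    seed: int | None = None,
    block_length: int | None = None,
    zscore_predictors: bool = True,
) -> np.ndarray:
    """Standard error of R^2 by circular block bootstrap of timepoints.

    Blocks of ~sqrt(T) consecutive timepoints (wrapping at the end) are
    resampled jointly in activity and design, respecting temporal
    autocorrelation; the SE is the standard deviation of R^2 over
    `n_boot` refits.
    """
    if n_boot < 100:
        raise ValueError("n_boot < 100 gives unreliable standard errors")
    activity = np.atleast_2d(np.asarray(activity, dtype=float))
    t = design.n_timepoints
    if block_length is None:
        block_length = max(1, int(round(np.sqrt(t))))
    if block_length > t:
        raise ValueError("block length exceeds the series length")
    n_blocks = int(np.ceil(t / block_length))
    rng = np.random.default_rng(seed)
    r2s = np.empty((n_boot, activity.shape[0]))
    base = np.arange(block_length)
    for i in range(n_boot):
        starts = rng.integers(0, t, n_blocks)
        idx = ((starts[:, None] + base[None, :]) % t).ravel()[:t]
        boot_design = DesignMatrix(
            design.values[idx], design.predictor_labels, basis=design.basis
        )
        r2s[i] = fit_encoding(
            activity[:, idx], boot_design, zscore_predictors
        ).r2
    return r2s.std(axis=0, ddof=1)


def noise_ceiling(
    per_subject_activity: np.ndarray,
    design: DesignMatrix,
    zscore_predictors: bool = True,
) -> NoiseCeiling:
    """Leave-one-subject-out bounds on explainable variance.

    Lower bound: for each subject, the encoding model is fit on the mean
    activity of the *other* subjects and evaluated (squared Pearson
    correlation between prediction and the subject's activity, averaged
    over voxels). Upper bound: the same with the subject included in the
    mean. A model's true R^2 is expected to fall inside [lower, upper].
    """
    a = np.asarray(per_subject_activity, dtype=float)
    if a.ndim != 3:
        raise ValueError("expected (subjects, voxels, T) activity")
    s = a.shape[0]
    if s < 3:
        raise ValueError("noise ceiling needs at least 3 subjects")
    if a.shape[2] != design.n_timepoints:
        raise ValueError("subjects and design differ in T")

    x = _design_with_intercept(design, zscore_predictors)

    def _pred_r2(train_mean: np.ndarray, test: np.ndarray) -> float:
        b, *_ = np.linalg.lstsq(x, train_mean.T, rcond=None)
        pred = x @ b  # (T, V)
        pc = pred - pred.mean(axis=0)
        tc = test.T - test.T.mean(axis=0)
        num = (pc * tc).sum(axis=0)
        den = np.sqrt((pc**2).sum(axis=0) * (tc**2).sum(axis=0))
        with np.errstate(invalid="ignore", divide="ignore"):
            r = num / den
        return float(np.nanmean(r**2))

    lowers, uppers = [], []
    all_mean = a.mean(axis=0)
    for i in range(s):
        others_mean = np.delete(a, i, axis=0).mean(axis=0)
        lowers.append(_pred_r2(others_mean, a[i]))
        uppers.append(_pred_r2(all_mean, a[i]))
    return NoiseCeiling(lower=float(np.mean(lowers)), upper=float(np.mean(uppers)))
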