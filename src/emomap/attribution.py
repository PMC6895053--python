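"""Third-person (portrayed-emotion) models and their link to subjective ratings.

Observers who tag the emotions portrayed by movie characters — self- or
other-directed, over a larger category set (22 in the reference data) —
provide an alternative description of the same stimulus. This module
gives those series preprocessing parity with the subjective ratings,
quantifies the variance the two descriptions share on their four common
categories (happiness, fear, sadness, anger), aligns the attribution
space to the subjective-dimension space by canonical correlation
analysis, and compares encoding models of different dimensionality by
half-run-split cross-validation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._stats import spearman
from .encoding import DesignMatrix, _design_with_intercept
from .ratings import PreprocessedRatings, RatingTimeseries, preprocess_ratings

__all__ = [
    "AttributionModel",
    "CCAAlignment",
    "SHARED_CATEGORIES",
    "preprocess_attribution",
    "shared_variance",
    "cca_align",
    "crossval_encoding_comparison",
]

SHARED_CATEGORIES = ("happiness", "fear", "sadness", "anger")


@dataclass
class AttributionModel:
    """T x C portrayed-emotion intensity series with a direction flag."""

    values: np.ndarray
    labels: tuple[str, ...]
    direction: str  # self_directed | other_directed
    rate: float = 0.5

    def __post_init__(self) -> None:
        v = np.atleast_2d(np.asarray(self.values, dtype=float))
        if v.shape[1] != len(self.labels):
            raise ValueError("label count does not match columns")
        if not np.all(np.isfinite(v)):
            raise ValueError("attribution series contain missing values")
        if v.min() < 0:
            raise ValueError("attribution intensities must be non-negative")
        if self.direction not in ("self_directed", "other_directed"):
            raise ValueError("direction must be self_directed or other_directed")
        self.values = v

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]


def preprocess_attribution(
    raw: AttributionModel,
    tr: float = 2.0,
    lag: float = 2.0,
    window: float = 10.0,
    trim_edges: bool = True,
) -> AttributionModel:
    """Exact same lagging/smoothing pipeline as the subjective ratings.

    Delegates column-wise to :func:`emomap.ratings.preprocess_ratings`
    (code-path parity by construction); values are rescaled into [0, 100]
    range checks by clipping only at 0 since attribution tags are
    non-negative counts/intensities on their own scale.
    """
    scale = max(raw.values.max(), 1e-12)
    as_ratings = RatingTimeseries(
        values=raw.values / scale * 100.0,
        rate=raw.rate,
        emotion_labels=raw.labels,
        subject_id=f"attribution:{raw.direction}",
    )
    pre: PreprocessedRatings = preprocess_ratings(
        as_ratings, tr=tr, lag=lag, window=window, trim_edges=trim_edges
    )
    return AttributionModel(
        values=pre.values * scale / 100.0,
        labels=raw.labels,
        direction=raw.direction,
        rate=1.0 / tr,
    )


def shared_variance(
    subjective: RatingTimeseries,
    attribution: AttributionModel,
    categories: tuple[str, ...] = SHARED_CATEGORIES,
) -> dict[str, float | dict[str, float]]:
    """Variance shared between first- and third-person descriptions.

    For each category present in both models the shared variance is
    ``100 * rho^2`` (squared Spearman correlation, in percent); the
    summary is the mean +- sd across categories.
    """
    missing = [
        c
        for c in categories
        if c not in subjective.emotion_labels or c not in attribution.labels
    ]
    if missing:
        raise ValueError(f"categories missing from one model: {missing}")
    t = min(subjective.n_timepoints, attribution.n_timepoints)
    if subjective.n_timepoints != attribution.n_timepoints:
        raise ValueError("models differ in T; preprocess them identically first")
    per_category: dict[str, float] = {}
    for c in categories:
        a = subjective.values[:t, subjective.emotion_labels.index(c)]
        b = attribution.values[:t, attribution.labels.index(c)]
        rho = spearman(a, b)
        per_category[c] = 100.0 * rho**2
    vals = np.array(list(per_category.values()))
    return {
        "per_category": per_category,
        "mean": float(vals.mean()),
        "sd": float(vals.std(ddof=1)),
    }


@dataclass
class CCAAlignment:
    """Canonical alignment of the attribution space to the subjective space."""

    weights_attribution: np.ndarray  # (C_attr, C)
    weights_subjective: np.ndarray  # (C_subj, C)
    canonical_correlations: np.ndarray  # (C,) in [0, 1], non-increasing
    reconstructed: np.ndarray  # (T, C) attribution-side canonical variates
    subjective_variates: np.ndarray  # (T, C)


def _whitener(x: np.ndarray, rcond: float, ridge: float) -> np.ndarray:
    """Inverse symmetric square root of cov(x), truncated at rcond."""
    c = x.T @ x / (x.shape[0] - 1)
    if ridge > 0:
        c = c + ridge * np.trace(c) / c.shape[0] * np.eye(c.shape[0])
    w, v = np.linalg.eigh(c)
    keep = w > rcond * w.max()
    return v[:, keep] / np.sqrt(w[keep])


def cca_align(
    attribution: np.ndarray,
    subjective: np.ndarray,
    rcond: float = 1e-10,
    ridge: float = 0.0,
) -> CCAAlignment:
    """Canonical correlation analysis via whitening + SVD.

    Both blocks are centered; each is whitened by the truncated inverse
    square root of its covariance (rank-deficient blocks lose their null
    space rather than exploding — set `ridge` for an explicit shrinkage
    fallback). The SVD of the whitened cross-covariance yields up to
    ``min(rank_x, rank_y)`` canonical pairs with non-increasing
    correlations; the attribution-side variates ("reconstructed"
    dimensions) are mutually uncorrelated and unit-variance.
    """
    x = np.atleast_2d(np.asarray(attribution, dtype=float))
    y = np.atleast_2d(np.asarray(subjective, dtype=float))
    if x.shape[0] != y.shape[0]:
        raise ValueError("blocks differ in T")
    t = x.shape[0]
    if t <= max(x.shape[1], y.shape[1]) + 1:
        raise ValueError("need T well above both block dimensionalities")
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    wx = _whitener(xc, rcond, ridge)  # (Cx, rx)
    wy = _whitener(yc, rcond, ridge)  # (Cy, ry)
    k = (wx.T @ (xc.T @ yc) @ wy) / (t - 1)  # (rx, ry)
    u, s, vt = np.linalg.svd(k, full_matrices=False)
    corrs = np.clip(s, 0.0, 1.0)
    a = wx @ u  # attribution weights (Cx, C)
    b = wy @ vt.T  # subjective weights (Cy, C)
    return CCAAlignment(
        weights_attribution=a,
        weights_subjective=b,
        canonical_correlations=corrs,
        reconstructed=xc @ a,
        subjective_variates=yc @ b,
    )


def crossval_encoding_comparison(
    activity: np.ndarray,
    models: dict[str, DesignMatrix],
    run_ids: np.ndarray,
    zscore_predictors: bool = True,
) -> dict[str, dict[str, float]]:
    """Half-run-split cross-validated R^2 for competing encoding models.

    Runs are split into two halves (first half of the run list vs the
    rest); each model is fit on one half and evaluated on the other, and
    the two directions are averaged. Two out-of-sample metrics are
    reported per model, averaged over voxels:

    * ``r2_corr`` — squared Pearson correlation between prediction and
      observation (non-negative; comparable across models of different
      dimensionality);
    * ``r2_raw`` — 1 - SSE/SST (can be negative when a model predicts
      worse than the test-half mean).
    """
    activity = np.atleast_2d(np.asarray(activity, dtype=float))
    run_ids = np.asarray(run_ids)
    if run_ids.shape[0] != activity.shape[1]:
        raise ValueError("run_ids must label every timepoint")
    runs = list(dict.fromkeys(run_ids.tolist()))  # preserve order
    if len(runs) < 2:
        raise ValueError("half-run split needs at least 2 runs")
    half_a = set(runs[: len(runs) // 2 + len(runs) % 2])
    mask_a = np.isin(run_ids, list(half_a))
    splits = [(mask_a, ~mask_a), (~mask_a, mask_a)]

    out: dict[str, dict[str, float]] = {}
    for name, design in models.items():
        if design.n_timepoints != activity.shape[1]:
            raise ValueError(f"model {name!r} does not match activity T")
        r2c, r2r = [], []
        for train, test in splits:
            if train.sum() <= design.n_predictors + 1:
                raise ValueError("a half-split has T <= P: too few timepoints")
            xt = _design_with_intercept(
                DesignMatrix(
                    design.values[train], design.predictor_labels, design.basis
                ),
                zscore_predictors,
            )
            b, *_ = np.linalg.lstsq(xt, activity[:, train].T, rcond=None)
            # apply the training-half normalization to the test half
            tr = design.values[train]
            te = design.values[test]
            if zscore_predictors:
                te = (te - tr.mean(axis=0)) / tr.std(axis=0, ddof=0)
            xe = np.column_stack([np.ones(te.shape[0]), te])
            pred = xe @ b  # (T_test, V)
            obs = activity[:, test].T
            pc = pred - pred.mean(axis=0)
            oc = obs - obs.mean(axis=0)
            den = np.sqrt((pc**2).sum(axis=0) * (oc**2).sum(axis=0))
            with np.errstate(invalid="ignore", divide="ignore"):
                r = (pc * oc).sum(axis=0) / den
            r2c.append(float(np.nanmean(r**2)))
            sse = ((obs - pred) ** 2).sum(axis=0)
            sst = (oc**2).sum(axis=0)
            with np.errstate(invalid="ignore", divide="ignore"):
                raw = 1.0 - sse / sst
            r2r.append(float(np.nanmean(raw)))
        out[name] = {
            "r2_corr": float(np.mean(r2c)),
            "r2_raw": float(np.mean(r2r)),
        }
    return out
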