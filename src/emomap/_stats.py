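"""Small numerical helpers shared across modules (ranks, correlations)."""

from __future__ import annotations

import numpy as np
from scipy.stats import rankdata

__all__ = ["spearman", "rank_rows", "pearson_rows", "bh_fdr"]


def spearman(a: np.ndarray, b: np.ndarray) -> float:
    """Spearman rank correlation with midrank tie handling."""
    ra = rankdata(a)
    rb = rankdata(b)
    ra = ra - ra.mean()
    rb = rb - rb.mean()
    denom = np.sqrt((ra @ ra) * (rb @ rb))
    if denom == 0:
        return np.nan
    return float((ra @ rb) / denom)


def rank_rows(a: np.ndarray) -> np.ndarray:
    """Ordinal ranks along the last axis (vectorized over leading axes).

    Ties are broken by position, which is immaterial for the continuous
    distance vectors this is applied to (ties have measure zero); the
    headline statistics use :func:`spearman`, which handles ties by
    midranks.
    """
    a = np.asarray(a, dtype=float)
    order = np.argsort(a, axis=-1)
    ranks = np.empty_like(a)
    np.put_along_axis(
        ranks,
        order,
        np.broadcast_to(
            np.arange(1, a.shape[-1] + 1, dtype=float), a.shape
        ).copy(),
        axis=-1,
    )
    return ranks


def pearson_rows(rows: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson correlation of each row of `rows` with the vector `b`."""
    rows = rows - rows.mean(axis=-1, keepdims=True)
    b = b - b.mean()
    denom = np.sqrt((rows * rows).sum(axis=-1) * (b @ b))
    with np.errstate(invalid="ignore", divide="ignore"):
        return (rows @ b) / denom


def bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted values (NaN-aware wrapper)."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p, dtype=float)
    q = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q
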