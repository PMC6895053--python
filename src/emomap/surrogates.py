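"""Autocorrelation-preserving surrogate time series (IAAFT).

The Iterative Amplitude Adjusted Fourier Transform produces randomized
versions of a series that keep its amplitude distribution *exactly* (the
final step is a rank remap onto the sorted original values) and match its
power spectrum — hence its linear autocorrelation — to high accuracy.
These surrogates are the null model for every permutation test in this
package: inter-rater agreement, voxelwise encoding significance, and the
anatomo-functional topography statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SurrogateEnsemble", "iaaft_surrogate", "surrogate_matrix"]


@dataclass
class SurrogateEnsemble:
    """A set of IAAFT surrogates of a single source series.

    Attributes
    ----------
    surrogates : (n, T) array
        Each row has exactly the source's sorted values.
    source : (T,) array
        The original series.
    n_iterations_used : (n,) int array
        Iterations consumed by each surrogate before convergence.
    spectrum_mismatch : (n,) array
        Final relative RMS mismatch between each surrogate's amplitude
        spectrum and the source's.
    seed : int | None
    """

    surrogates: np.ndarray
    source: np.ndarray
    n_iterations_used: np.ndarray
    spectrum_mismatch: np.ndarray
    seed: int | None = None
    source_length: int = field(init=False)

    def __post_init__(self) -> None:
        self.source_length = int(self.source.shape[0])

    @property
    def n(self) -> int:
        return self.surrogates.shape[0]


def _one_surrogate(
    x: np.ndarray,
    sorted_x: np.ndarray,
    target_amp: np.ndarray,
    rng: np.random.Generator,
    max_iter: int,
    tol: float,
) -> tuple[np.ndarray, int, float]:
    amp_norm = float(np.linalg.norm(target_amp))
    s = rng.permutation(x)
    best = s
    best_err = np.inf
    n_iter = 0
    for it in range(1, max_iter + 1):
        n_iter = it
        # spectrum step: impose the target amplitude spectrum, keep phases
        ft = np.fft.rfft(s)
        phase = np.angle(ft)
        s = np.fft.irfft(target_amp * np.exp(1j * phase), n=x.shape[0])
        # distribution step: remap onto the source's sorted values
        ranks = np.argsort(np.argsort(s, kind="stable"), kind="stable")
        s = sorted_x[ranks]
        err = float(np.linalg.norm(np.abs(np.fft.rfft(s)) - target_amp)) / amp_norm
        if err < best_err - tol:
            best, best_err = s, err
        else:
            # no further improvement: fixed point (up to tol) reached
            if err < best_err:
                best, best_err = s, err
            break
    return best, n_iter, best_err


def iaaft_surrogate(
    x: np.ndarray,
    n: int = 1000,
    seed: int | None = None,
    max_iter: int = 200,
    tol: float = 1e-12,
) -> SurrogateEnsemble:
    """Generate `n` IAAFT surrogates of the 1-D series `x`.

    Each surrogate is produced from an independent random substream
    (spawned from `seed`), iterating the amplitude-spectrum adjustment and
    the rank remap until the spectral mismatch stops decreasing by more
    than `tol` or `max_iter` is hit. The last applied step is always the
    rank remap, so ``sorted(surrogate) == sorted(x)`` holds exactly.

    Raises
    ------
    ValueError
        If the series is shorter than 16 samples or constant (the
        spectrum carries no information beyond DC).
    """
    x = np.asarray(x, dtype=float).ravel()
    if x.shape[0] < 16:
        raise ValueError(f"series too short for IAAFT: T={x.shape[0]} < 16")
    if np.ptp(x) == 0:
        raise ValueError("constant series: IAAFT surrogate undefined")
    if n < 1:
        raise ValueError("need n >= 1 surrogates")

    sorted_x = np.sort(x)
    target_amp = np.abs(np.fft.rfft(x))
    streams = np.random.SeedSequence(seed).spawn(n)

    surrogates = np.empty((n, x.shape[0]))
    iters = np.empty(n, dtype=int)
    errs = np.empty(n)
    for i, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        surrogates[i], iters[i], errs[i] = _one_surrogate(
            x, sorted_x, target_amp, rng, max_iter, tol
        )
    return SurrogateEnsemble(
        surrogates=surrogates,
        source=x,
        n_iterations_used=iters,
        spectrum_mismatch=errs,
        seed=seed,
    )


def surrogate_matrix(
    columns: np.ndarray,
    seed: int | None = None,
    max_iter: int = 100,
    tol: float = 1e-12,
) -> np.ndarray:
    """Jointly surrogate every column of a (T, P) matrix.

    Each column gets one independent IAAFT surrogate from its own
    substream: the columns' individual spectra and distributions are
    preserved while their mutual (and any external) relationship is
    destroyed. Used to build null design matrices.
    """
    columns = np.asarray(columns, dtype=float)
    if columns.ndim != 2:
        raise ValueError("expected a (T, P) matrix")
    streams = np.random.SeedSequence(seed).spawn(columns.shape[1])
    out = np.empty_like(columns)
    for j, ss in enumerate(streams):
        col = columns[:, j]
        if col.shape[0] < 16:
            raise ValueError(f"series too short for IAAFT: T={col.shape[0]} < 16")
        if np.ptp(col) == 0:
            raise ValueError(f"column {j} is constant: IAAFT surrogate undefined")
        rng = np.random.default_rng(ss)
        out[:, j], _, _ = _one_surrogate(
            col, np.sort(col), np.abs(np.fft.rfft(col)), rng, max_iter, tol
        )
    return out
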