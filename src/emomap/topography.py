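"""Anatomo-functional topography of voxel response profiles.

The central question this module answers: are voxels with similar
functional profiles (similar encoding-model coefficients) also close to
each other on the cortex? A gradient-like ("topographic") organization
predicts a positive association between inter-voxel anatomical distance
and inter-voxel functional distance.

The statistic is the Spearman correlation between the condensed upper
triangles of two dissimilarity matrices over the voxels of a spherical
region of interest (ROI): Euclidean distance of voxel-center coordinates
(or geodesic distance along a cortical mesh) on one side, Euclidean
distance of per-voxel coefficient vectors on the other. Significance is
assessed against coefficient ensembles refit from autocorrelation-
preserving surrogate predictors, which inherit the data's spatial
structure — a spatially naive permutation would be anticonservative.

Also here: the per-voxel numerical gradient field and its summed
direction, the radius sweep used to pick the ROI scale, the rotated-
solution analysis that asks whether the chosen component axes are the
ones that best explain the topography, and mesh geodesics (Dijkstra).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra as _csgraph_dijkstra
from scipy.spatial.distance import pdist, squareform
from scipy.spatial.transform import Rotation
from scipy.stats import rankdata

from ._stats import pearson_rows, rank_rows, spearman

__all__ = [
    "VoxelGrid",
    "VoxelROI",
    "DistanceMatrix",
    "TopographyStat",
    "GradientField",
    "Mesh",
    "RadiusSweepResult",
    "RotationAnalysis",
    "grid_for_sphere",
    "sphere_roi",
    "anatomical_distance",
    "functional_distance",
    "topography_stat",
    "per_dimension_topography",
    "radius_sweep",
    "gradient_direction",
    "rotation_analysis",
    "geodesic_distance",
]

_BOUNDARY_RTOL = 1e-9  # inclusive sphere boundary, robust to mm rounding


# ---------------------------------------------------------------------------
# voxel grids and ROIs


@dataclass(frozen=True)
class VoxelGrid:
    """Axis-aligned isotropic voxel grid; coordinates are voxel centers in mm."""

    shape: tuple[int, int, int]
    voxel_size: float = 3.0
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if any(s < 1 for s in self.shape):
            raise ValueError(f"non-positive grid shape {self.shape}")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be > 0")

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    def coords(self) -> np.ndarray:
        """(N, 3) voxel-center coordinates in C (row-major) index order."""
        axes = [
            self.origin[d] + self.voxel_size * np.arange(self.shape[d])
            for d in range(3)
        ]
        mesh = np.meshgrid(*axes, indexing="ij")
        return np.stack([m.ravel() for m in mesh], axis=1)

    def bounding_box(self) -> tuple[np.ndarray, np.ndarray]:
        lo = np.asarray(self.origin, dtype=float)
        hi = lo + self.voxel_size * (np.asarray(self.shape) - 1)
        return lo, hi


@dataclass
class VoxelROI:
    """Voxels of a parent grid within `radius` mm of `center` (inclusive)."""

    coords: np.ndarray  # (N, 3) mm
    center: np.ndarray  # (3,) mm
    radius: float
    voxel_ids: np.ndarray  # indices into the parent grid, ascending

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.center = np.asarray(self.center, dtype=float)
        d = np.linalg.norm(self.coords - self.center, axis=1)
        if np.any(d > self.radius * (1 + _BOUNDARY_RTOL) + 1e-9):
            raise ValueError("ROI contains coordinates outside its radius")

    @property
    def n_voxels(self) -> int:
        return self.coords.shape[0]


def grid_for_sphere(
    center: np.ndarray, radius: float, voxel_size: float = 3.0
) -> VoxelGrid:
    """Smallest grid covering the sphere with a voxel center exactly at `center`."""
    center = np.asarray(center, dtype=float)
    half = int(np.ceil(radius / voxel_size))
    origin = center - half * voxel_size
    n = 2 * half + 1
    return VoxelGrid(shape=(n, n, n), voxel_size=voxel_size, origin=tuple(origin))


def sphere_roi(center: np.ndarray, radius: float, grid: VoxelGrid) -> VoxelROI:
    """Spherical ROI: voxel centers within `radius` of `center` (boundary inclusive).

    Voxels are returned in ascending parent-grid index order, so the ROI is
    deterministic for a given grid.
    """
    center = np.asarray(center, dtype=float)
    lo, hi = grid.bounding_box()
    if np.any(center < lo - grid.voxel_size / 2) or np.any(
        center > hi + grid.voxel_size / 2
    ):
        raise ValueError("sphere center outside the grid bounding box")
    coords = grid.coords()
    d2 = ((coords - center) ** 2).sum(axis=1)
    inside = d2 <= radius**2 * (1 + _BOUNDARY_RTOL) + 1e-9
    ids = np.flatnonzero(inside)
    if ids.size == 0:
        raise ValueError("empty ROI: no voxel center within the sphere")
    return VoxelROI(coords=coords[ids], center=center, radius=radius, voxel_ids=ids)


# ---------------------------------------------------------------------------
# dissimilarity matrices


@dataclass
class DistanceMatrix:
    """Symmetric pairwise dissimilarities with zero diagonal."""

    values: np.ndarray  # (N, N)
    metric: str  # euclidean | geodesic | beta_euclidean
    disconnected: bool = False  # geodesic only: some pairs unreachable (inf)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.allclose(v, v.T, equal_nan=True):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("distance matrix must have a zero diagonal")
        finite = v[np.isfinite(v)]
        if np.any(finite < 0):
            raise ValueError("distances must be non-negative")
        self.values = v

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def condensed(self) -> np.ndarray:
        """Upper triangle (diagonal excluded), scipy condensed order."""
        return squareform(self.values, checks=False)


def anatomical_distance(roi: VoxelROI) -> DistanceMatrix:
    """Pairwise Euclidean distance between voxel-center coordinates (mm)."""
    return DistanceMatrix(squareform(pdist(roi.coords)), metric="euclidean")


def functional_distance(beta: np.ndarray) -> DistanceMatrix:
    """Pairwise Euclidean distance between per-voxel coefficient vectors.

    A single column gives |delta beta| distances.
    """
    beta = np.asarray(beta, dtype=float)
    if beta.ndim == 1:
        beta = beta[:, None]
    if beta.shape[1] < 1:
        raise ValueError("need at least one coefficient per voxel")
    if not np.all(np.isfinite(beta)):
        raise ValueError("NaN/inf coefficients in functional profile")
    return DistanceMatrix(squareform(pdist(beta)), metric="beta_euclidean")


# ---------------------------------------------------------------------------
# the topography statistic


@dataclass
class TopographyStat:
    """Spearman association between anatomical and functional dissimilarity.

    `p` is a one-sided permutation p against `null_rhos`; `ci` the
    voxel-bootstrap percentile interval of `rho`. `degenerate` marks a
    statistic that is undefined (zero-variance distance vector) — it is
    reported explicitly rather than coerced to 0.
    """

    rho: float
    p: float | None = None
    ci: tuple[float, float] | None = None
    null_rhos: np.ndarray | None = None
    degenerate: bool = False
    n_voxels: int = 0


def _null_rhos_from_betas(
    anat_ranks: np.ndarray, null_betas: np.ndarray
) -> np.ndarray:
    """Spearman rho of each null beta ensemble member against anatomy."""
    null_betas = np.asarray(null_betas, dtype=float)
    if null_betas.ndim == 2:  # (n_null, N) single-dimension ensemble
        null_betas = null_betas[:, :, None]
    n_null, n, p = null_betas.shape
    m = n * (n - 1) // 2
    # bound peak memory: condensed matrices for large ROIs are huge
    block = max(1, int(2e7 // max(m, 1)))
    iu, ju = (np.triu_indices(n, k=1) if p == 1 else (None, None))
    out = np.empty(n_null)
    for start in range(0, n_null, block):
        stop = min(start + block, n_null)
        if p == 1:  # |delta beta|, vectorized over the block
            cond = np.abs(null_betas[start:stop, iu, 0] - null_betas[start:stop, ju, 0])
        else:
            cond = np.stack(
                [pdist(null_betas[i]) for i in range(start, stop)], axis=0
            )
        out[start:stop] = pearson_rows(rank_rows(cond), anat_ranks)
    return out


def topography_stat(
    anat: DistanceMatrix,
    func: DistanceMatrix,
    null_betas: np.ndarray | None = None,
    n_boot: int = 1000,
    seed: int | None = None,
) -> TopographyStat:
    """Test the anatomo-functional association over one ROI.

    Parameters
    ----------
    anat, func : DistanceMatrix
        Matching (N, N) dissimilarity matrices (N >= 4).
    null_betas : (n_null, N, P) array, optional
        Null coefficient ensemble, typically obtained by refitting the
        encoding model with IAAFT-surrogate predictors on the *real*
        activity so the null inherits the data's spatial autocorrelation.
        When given, ``p = (1 + #{null rho >= rho}) / (n_null + 1)``.
    n_boot : int
        Voxel-resampling bootstrap iterations for the 2.5-97.5 percentile
        confidence interval (0 disables it).
    """
    if anat.n != func.n:
        raise ValueError("anatomical and functional matrices differ in size")
    if anat.n < 4:
        raise ValueError("topography test needs at least 4 voxels")
    av = anat.condensed()
    fv = func.condensed()
    if np.ptp(av) == 0 or np.ptp(fv) == 0:
        return TopographyStat(rho=np.nan, degenerate=True, n_voxels=anat.n)

    rho = spearman(av, fv)
    anat_ranks = rankdata(av)  # midranks: lattice anatomy has exact ties

    p = None
    null_rhos = None
    if null_betas is not None:
        null_rhos = _null_rhos_from_betas(anat_ranks, null_betas)
        n_null = null_rhos.shape[0]
        p = float((1 + np.sum(null_rhos >= rho)) / (n_null + 1))

    ci = None
    if n_boot and n_boot > 0:
        rng = np.random.default_rng(seed)
        n = anat.n
        boot = np.empty(n_boot)
        A, F = anat.values, func.values
        iu = np.triu_indices(n, k=1)
        for b in range(n_boot):
            idx = rng.integers(0, n, n)
            asub = A[np.ix_(idx, idx)][iu]
            fsub = F[np.ix_(idx, idx)][iu]
            boot[b] = spearman(asub, fsub)
        boot = boot[np.isfinite(boot)]
        if boot.size:
            ci = (float(np.percentile(boot, 2.5)), float(np.percentile(boot, 97.5)))

    return TopographyStat(
        rho=rho, p=p, ci=ci, null_rhos=null_rhos, degenerate=False, n_voxels=anat.n
    )


def per_dimension_topography(
    anat: DistanceMatrix,
    beta_column: np.ndarray,
    null_beta_columns: np.ndarray | None = None,
    n_boot: int = 1000,
    seed: int | None = None,
) -> TopographyStat:
    """Topography test for a single emotion dimension (P = 1)."""
    beta_column = np.asarray(beta_column, dtype=float).reshape(-1, 1)
    func = functional_distance(beta_column)
    return topography_stat(
        anat, func, null_betas=null_beta_columns, n_boot=n_boot, seed=seed
    )


# ---------------------------------------------------------------------------
# radius sweep


@dataclass
class RadiusSweepResult:
    stats: dict[float, TopographyStat]
    selected_radius: float | None  # None when no radius is significant


def radius_sweep(
    center: np.ndarray,
    radii: list[float],
    grid: VoxelGrid,
    beta_provider,
    null_provider=None,
    alpha: float = 0.05,
    n_boot: int = 0,
    seed: int | None = None,
) -> RadiusSweepResult:
    """Test a range of ROI radii and select the best-supported scale.

    `beta_provider(roi)` must return the (N, P) coefficient matrix for the
    ROI's voxels; `null_provider(roi)` the matching (n_null, N, P) null
    ensemble. Selection: the significant radius (p < alpha) with the
    highest rho, ties broken toward the smaller radius. All per-radius
    statistics are returned regardless.
    """
    if len(radii) < 2:
        raise ValueError("radius sweep needs at least 2 radii")
    stats: dict[float, TopographyStat] = {}
    best: tuple[float, float] | None = None  # (rho, radius)
    for radius in sorted(radii):
        roi = sphere_roi(center, radius, grid)
        beta = np.asarray(beta_provider(roi), dtype=float)
        nulls = None if null_provider is None else null_provider(roi)
        stat = topography_stat(
            anatomical_distance(roi),
            functional_distance(beta),
            null_betas=nulls,
            n_boot=n_boot,
            seed=seed,
        )
        stats[radius] = stat
        if stat.degenerate or stat.p is None or not stat.p < alpha:
            continue
        if best is None or stat.rho > best[0]:  # strict: ties keep smaller radius
            best = (stat.rho, radius)
    return RadiusSweepResult(stats=stats, selected_radius=None if best is None else best[1])


# ---------------------------------------------------------------------------
# gradient field direction


@dataclass
class GradientField:
    """Numerical spatial gradient of a coefficient map over an ROI.

    `vectors[i]` estimates (d beta/dx, d beta/dy, d beta/dz) at voxel i in
    coefficient units per mm (NaN where no neighbor exists along an axis).
    `principal_direction` is the normalized vector sum — the main direction
    of a linear gradient — or None (`null_flag`) when the sum vanishes.
    """

    vectors: np.ndarray
    principal_direction: np.ndarray | None
    magnitude: float
    null_flag: bool = False


def gradient_direction(
    roi: VoxelROI, beta_column: np.ndarray, voxel_size: float | None = None
) -> GradientField:
    """Estimate the gradient field of a single-dimension beta map.

    Central differences where both axis neighbors are in the ROI,
    one-sided differences at the ROI boundary. The ROI must be a subset of
    an axis-aligned isotropic grid.
    """
    beta_column = np.asarray(beta_column, dtype=float).ravel()
    if beta_column.shape[0] != roi.n_voxels:
        raise ValueError("beta length does not match ROI voxel count")

    coords = roi.coords
    if voxel_size is None:
        gaps = []
        for d in range(3):
            u = np.unique(coords[:, d])
            if u.size > 1:
                gaps.append(np.diff(u).min())
        if not gaps:
            raise ValueError("ROI has a single voxel: gradient undefined")
        voxel_size = float(min(gaps))

    lo = coords.min(axis=0)
    idx = np.rint((coords - lo) / voxel_size).astype(int)
    if not np.allclose(idx * voxel_size + lo, coords, atol=1e-6):
        raise ValueError("ROI coordinates are not on an isotropic grid")
    shape = idx.max(axis=0) + 1
    if np.all(shape < 2):
        raise ValueError("ROI needs >= 2 voxels along at least one axis")

    vol = np.full(shape, np.nan)
    vol[tuple(idx.T)] = beta_column

    vectors = np.full((roi.n_voxels, 3), np.nan)
    for d in range(3):
        if shape[d] < 2:
            continue
        fwd_idx = idx.copy()
        fwd_idx[:, d] += 1
        bwd_idx = idx.copy()
        bwd_idx[:, d] -= 1
        fwd_ok = fwd_idx[:, d] < shape[d]
        bwd_ok = bwd_idx[:, d] >= 0
        fwd = np.full(roi.n_voxels, np.nan)
        bwd = np.full(roi.n_voxels, np.nan)
        fwd[fwd_ok] = vol[tuple(fwd_idx[fwd_ok].T)]
        bwd[bwd_ok] = vol[tuple(bwd_idx[bwd_ok].T)]
        has_f = np.isfinite(fwd)
        has_b = np.isfinite(bwd)
        both = has_f & has_b
        vectors[both, d] = (fwd[both] - bwd[both]) / (2 * voxel_size)
        only_f = has_f & ~has_b
        vectors[only_f, d] = (fwd[only_f] - beta_column[only_f]) / voxel_size
        only_b = has_b & ~has_f
        vectors[only_b, d] = (beta_column[only_b] - bwd[only_b]) / voxel_size

    total = np.nansum(vectors, axis=0)
    magnitude = float(np.linalg.norm(total))
    scale = np.nanmax(np.abs(vectors)) if np.isfinite(vectors).any() else 0.0
    if magnitude <= 1e-12 * max(scale, 1.0) * roi.n_voxels or magnitude == 0.0:
        return GradientField(
            vectors=vectors, principal_direction=None, magnitude=magnitude,
            null_flag=True,
        )
    return GradientField(
        vectors=vectors,
        principal_direction=total / magnitude,
        magnitude=magnitude,
        null_flag=False,
    )


# ---------------------------------------------------------------------------
# rotated-solution analysis


@dataclass
class RotationAnalysis:
    """Per-dimension topography of randomly rotated component solutions.

    `identity_rank` is the 1-based rank of the unrotated solution's mean
    per-dimension rho among all `n_rotations + 1` solutions (identity
    included); rank 1 = best.
    """

    rhos: np.ndarray  # (n_rotations, 3)
    mean_rhos: np.ndarray  # (n_rotations,)
    identity_rhos: np.ndarray  # (3,)
    identity_mean: float
    identity_rank: int
    n_rotations: int

    @property
    def identity_rank_fraction(self) -> float:
        return self.identity_rank / (self.n_rotations + 1)


def rotation_analysis(
    beta: np.ndarray,
    anat: DistanceMatrix,
    n_rotations: int = 2000,
    seed: int | None = None,
    chunk: int = 64,
) -> RotationAnalysis:
    """Ask whether the three given component axes best explain the topography.

    Rotations are sampled uniformly over SO(3) (proper rotations only,
    quaternion sampling). For each rotation the (N, 3) coefficient matrix
    is post-multiplied by it and the per-dimension topography rho is
    recomputed; the unrotated solution is ranked by mean per-dimension rho.
    """
    beta = np.asarray(beta, dtype=float)
    if beta.ndim != 2 or beta.shape[1] != 3:
        raise ValueError("rotation analysis expects an (N, 3) coefficient matrix")
    if n_rotations < 10:
        raise ValueError("need at least 10 rotations")
    if anat.n != beta.shape[0]:
        raise ValueError("anatomical matrix does not match beta")

    anat_ranks = rankdata(anat.condensed())
    n = beta.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    pair_diff = beta[iu] - beta[ju]  # (M, 3); |pair_diff @ r| = condensed |drho|

    def _dim_rhos(columns: np.ndarray) -> np.ndarray:
        """columns: (3, K) rotated axes -> (K,) spearman rho per axis."""
        cond = np.abs(pair_diff @ columns)  # (M, K)
        # midranks: planted maps on a lattice produce exactly tied distances
        ranks = rankdata(cond.T, axis=-1)  # (K, M)
        return pearson_rows(ranks, anat_ranks)

    identity_rhos = _dim_rhos(np.eye(3))

    rng = np.random.default_rng(seed)
    mats = Rotation.random(n_rotations, random_state=rng).as_matrix()  # (R, 3, 3)
    rhos = np.empty((n_rotations, 3))
    for start in range(0, n_rotations, chunk):
        block = mats[start : start + chunk]  # (B, 3, 3)
        cols = np.concatenate([m for m in block], axis=1)  # (3, 3B)
        r = _dim_rhos(cols)
        rhos[start : start + block.shape[0]] = r.reshape(block.shape[0], 3)

    mean_rhos = rhos.mean(axis=1)
    identity_mean = float(identity_rhos.mean())
    identity_rank = int(1 + np.sum(mean_rhos > identity_mean))
    return RotationAnalysis(
        rhos=rhos,
        mean_rhos=mean_rhos,
        identity_rhos=identity_rhos,
        identity_mean=identity_mean,
        identity_rank=identity_rank,
        n_rotations=n_rotations,
    )


# ---------------------------------------------------------------------------
# meshes and geodesic distance


@dataclass
class Mesh:
    """Triangulated surface: vertices in mm, triangles as vertex index triples."""

    vertices: np.ndarray  # (V, 3)
    triangles: np.ndarray  # (F, 3) int

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.triangles = np.asarray(self.triangles, dtype=int)
        if self.triangles.size and (
            self.triangles.min() < 0 or self.triangles.max() >= len(self.vertices)
        ):
            raise ValueError("triangle indices out of range")
        e = self.edges()
        lengths = np.linalg.norm(
            self.vertices[e[:, 0]] - self.vertices[e[:, 1]], axis=1
        )
        if np.any(lengths <= 0):
            raise ValueError("mesh contains zero-length edges")

    @property
    def n_vertices(self) -> int:
        return self.vertices.shape[0]

    def edges(self) -> np.ndarray:
        """Unique undirected edges (E, 2), each with i < j."""
        t = self.triangles
        pairs = np.concatenate([t[:, [0, 1]], t[:, [1, 2]], t[:, [2, 0]]], axis=0)
        pairs = np.sort(pairs, axis=1)
        return np.unique(pairs, axis=0)


def geodesic_distance(mesh: Mesh, node_ids: np.ndarray | None = None) -> DistanceMatrix:
    """Shortest-path distances over the edge-length-weighted mesh graph.

    Dijkstra on the undirected graph whose edge weights are Euclidean edge
    lengths — the standard, computationally efficient approximation of
    cortical distance respecting folding. Unreachable pairs get +inf and
    set the `disconnected` flag.
    """
    e = mesh.edges()
    w = np.linalg.norm(mesh.vertices[e[:, 0]] - mesh.vertices[e[:, 1]], axis=1)
    v = mesh.n_vertices
    graph = coo_matrix(
        (np.concatenate([w, w]), (np.concatenate([e[:, 0], e[:, 1]]),
                                  np.concatenate([e[:, 1], e[:, 0]]))),
        shape=(v, v),
    ).tocsr()
    if node_ids is None:
        node_ids = np.arange(v)
    node_ids = np.asarray(node_ids, dtype=int)
    d = _csgraph_dijkstra(graph, directed=False, indices=node_ids)[:, node_ids]
    d = (d + d.T) / 2  # exact symmetry despite float summation order
    np.fill_diagonal(d, 0.0)
    disconnected = bool(np.isinf(d).any())
    if disconnected:
        warnings.warn("mesh nodes span multiple components: infinite distances")
    return DistanceMatrix(d, metric="geodesic", disconnected=disconnected)
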