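"""Reading and writing the pipeline's on-disk formats.

Ratings and attribution series travel as TSV (a `time_s` column plus one
column per emotion); coefficient and statistic maps as NIfTI volumes on
the voxel grid (one volume per predictor, 4-D for activity); meshes as
ASCII OFF; ground truth and result summaries as JSON sidecars.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .ratings import RatingTimeseries
from .synthetic import GroundTruth
from .topography import Mesh, VoxelGrid

__all__ = [
    "write_ratings_tsv",
    "read_ratings_tsv",
    "write_voxel_map_nifti",
    "read_voxel_map_nifti",
    "write_mesh_off",
    "read_mesh_off",
    "write_ground_truth_json",
]


def write_ratings_tsv(path: str | Path, ratings: RatingTimeseries) -> Path:
    path = Path(path)
    t = np.arange(ratings.n_timepoints) / ratings.rate
    df = pd.DataFrame(ratings.values, columns=list(ratings.emotion_labels))
    df.insert(0, "time_s", t)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
    return path


def read_ratings_tsv(
    path: str | Path, rate: float | None = None, subject_id: str = "group"
) -> RatingTimeseries:
    df = pd.read_csv(path, sep="\t")
    if "time_s" not in df.columns:
        raise ValueError("ratings TSV must have a time_s column")
    t = df.pop("time_s").to_numpy()
    if rate is None:
        if len(t) < 2:
            raise ValueError("cannot infer rate from a single sample")
        dt = np.diff(t)
        if np.ptp(dt) > 1e-6 * dt.mean():
            raise ValueError("irregular time axis: pass rate explicitly")
        rate = 1.0 / dt.mean()
    return RatingTimeseries(
        values=df.to_numpy(dtype=float),
        rate=float(rate),
        emotion_labels=tuple(df.columns),
        subject_id=subject_id,
    )


def _grid_affine(grid: VoxelGrid) -> np.ndarray:
    affine = np.eye(4)
    affine[:3, :3] *= grid.voxel_size
    affine[:3, 3] = grid.origin
    return affine


def write_voxel_map_nifti(
    path: str | Path,
    grid: VoxelGrid,
    voxel_ids: np.ndarray,
    values: np.ndarray,
    fill: float = np.nan,
) -> Path:
    """Write per-voxel values (N,) or (N, P) as a 3-D/4-D NIfTI on `grid`."""
    path = Path(path)
    values = np.asarray(values, dtype=float)
    if values.ndim == 1:
        values = values[:, None]
    vol = np.full((grid.n_voxels, values.shape[1]), fill)
    vol[np.asarray(voxel_ids, dtype=int)] = values
    data = vol.reshape(*grid.shape, values.shape[1])
    if data.shape[-1] == 1:
        data = data[..., 0]
    img = nib.Nifti1Image(data, _grid_affine(grid))
    nib.save(img, str(path))
    return path


def read_voxel_map_nifti(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Return (data array, affine)."""
    img = nib.load(str(path))
    return np.asarray(img.get_fdata()), img.affine


def write_mesh_off(path: str | Path, mesh: Mesh) -> Path:
    path = Path(path)
    lines = ["OFF", f"{mesh.n_vertices} {len(mesh.triangles)} 0"]
    for v in mesh.vertices:
        lines.append(f"{v[0]:.9g} {v[1]:.9g} {v[2]:.9g}")
    for t in mesh.triangles:
        lines.append(f"3 {t[0]} {t[1]} {t[2]}")
    path.write_text("\n".join(lines) + "\n")
    return path


def read_mesh_off(path: str | Path) -> Mesh:
    tokens = Path(path).read_text().split()
    if tokens[0] != "OFF":
        raise ValueError("not an OFF file")
    nv, nf = int(tokens[1]), int(tokens[2])
    pos = 4
    vertices = np.array(tokens[pos : pos + 3 * nv], dtype=float).reshape(nv, 3)
    pos += 3 * nv
    triangles = []
    for _ in range(nf):
        k = int(tokens[pos])
        if k != 3:
            raise ValueError("only triangle meshes are supported")
        triangles.append([int(x) for x in tokens[pos + 1 : pos + 4]])
        pos += k + 1
    return Mesh(vertices=vertices, triangles=np.asarray(triangles))


def write_ground_truth_json(path: str | Path, gt: GroundTruth) -> Path:
    path = Path(path)
    path.write_text(json.dumps(gt.to_dict(), indent=2, default=_jsonify))
    return path


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")
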