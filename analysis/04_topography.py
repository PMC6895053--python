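"""Emotion gradients: topography tests, radius sweep, directions, rotations.

Refits coefficients from the weak-signal activity of a planted-gradient
ROI, runs the per-dimension anatomo-functional topography test with
surrogate-refit null ensembles and bootstrap CIs, sweeps the ROI radius,
estimates gradient-field directions, and ranks the unrotated dimension
solution among random rotations. Tables go to results/topography/.
"""

import argparse
import json
import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "src"))

from emomap.encoding import DesignMatrix, fit_encoding
from emomap.studies import _ar1_columns, null_beta_ensemble
from emomap.synthetic import PlantedGradientSpec, gen_bold, gen_voxel_roi, planted_beta
from emomap.topography import (
    anatomical_distance,
    functional_distance,
    gradient_direction,
    per_dimension_topography,
    radius_sweep,
    rotation_analysis,
    topography_stat,
)
from emomap.topography import grid_for_sphere

AXES = ((1.0, 0.0, 0.0), (0.0, 1.0, 0.0), (0.0, 0.0, 1.0))


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-null", type=int, default=200)
    ap.add_argument("--n-boot", type=int, default=200)
    ap.add_argument("--n-rotations", type=int, default=2000)
    ap.add_argument("--noise-sd", type=float, default=60.0)
    ap.add_argument("--out", type=Path, default=Path("results/topography"))
    args = ap.parse_args()
    rng = np.random.default_rng(args.seed)
    labels = ("dim1", "dim2", "dim3")

    spec = PlantedGradientSpec(
        directions=AXES, slopes=(1.0, 1.0, 1.0), offsets=(0.0, 0.0, 0.0)
    )
    roi, beta_true, _ = gen_voxel_roi(np.zeros(3), 15.0, 3.0, spec, seed=args.seed)
    design = DesignMatrix(_ar1_columns(rng, 300, (0.85,) * 3), labels)
    activity = gen_bold(beta_true, design.values, args.noise_sd, seed=args.seed + 1)
    fit = fit_encoding(activity, design)
    nulls = null_beta_ensemble(activity, design, args.n_null, args.seed + 2)
    anat = anatomical_distance(roi)

    rows = []
    for d, name in enumerate(labels):
        stat = per_dimension_topography(
            anat, fit.beta[:, d], nulls[:, :, d], n_boot=args.n_boot,
            seed=args.seed + d,
        )
        gf = gradient_direction(roi, fit.beta[:, d])
        angle = np.degrees(
            np.arccos(np.clip(abs(gf.principal_direction @ np.array(AXES[d])), -1, 1))
        )
        rows.append(
            {
                "dimension": name,
                "rho": stat.rho,
                "p": stat.p,
                "ci_low": stat.ci[0],
                "ci_high": stat.ci[1],
                "direction_x": gf.principal_direction[0],
                "direction_y": gf.principal_direction[1],
                "direction_z": gf.principal_direction[2],
                "angle_error_deg": angle,
            }
        )
    per_dim = pd.DataFrame(rows)

    # full-profile topography and radius sweep (9-27 mm)
    full = topography_stat(
        anat, functional_distance(fit.beta), nulls, n_boot=args.n_boot,
        seed=args.seed,
    )
    grid = grid_for_sphere(np.zeros(3), 27.0, 3.0)

    def beta_provider(r):
        sub_design = design
        act = gen_bold(
            planted_beta(r.coords, spec), sub_design.values, args.noise_sd,
            seed=args.seed + 1,
        )
        return fit_encoding(act, sub_design).beta

    def null_provider(r):
        act = gen_bold(
            planted_beta(r.coords, spec), design.values, args.noise_sd,
            seed=args.seed + 1,
        )
        return null_beta_ensemble(act, design, 100, args.seed + 3)

    sweep = radius_sweep(
        np.zeros(3), list(range(9, 28, 3)), grid, beta_provider, null_provider
    )
    sweep_rows = [
        {"radius_mm": r, "rho": s.rho, "p": s.p, "n_voxels": s.n_voxels}
        for r, s in sweep.stats.items()
    ]

    ra = rotation_analysis(
        fit.beta, anat, n_rotations=args.n_rotations, seed=args.seed
    )

    args.out.mkdir(parents=True, exist_ok=True)
    per_dim.to_csv(args.out / "per_dimension.tsv", sep="\t", index=False)
    pd.DataFrame(sweep_rows).to_csv(args.out / "radius_sweep.tsv", sep="\t", index=False)
    summary = {
        "full_profile_rho": full.rho,
        "full_profile_p": full.p,
        "full_profile_ci": list(full.ci),
        "selected_radius_mm": sweep.selected_radius,
        "rotation_identity_rank": ra.identity_rank,
        "rotation_identity_rank_fraction": ra.identity_rank_fraction,
        "n_null": args.n_null,
        "n_rotations": args.n_rotations,
    }
    (args.out / "summary.json").write_text(json.dumps(summary, indent=2))

    print(f"ROI: {roi.n_voxels} voxels (15 mm, 3 mm iso)")
    print(
        f"full-profile topography rho = {full.rho:.3f}, p = {full.p:.3f}, "
        f"95% CI [{full.ci[0]:.3f}, {full.ci[1]:.3f}]"
    )
    for r in rows:
        print(
            f"  {r['dimension']}: rho = {r['rho']:.3f}, p = {r['p']:.3f}, "
            f"direction error {r['angle_error_deg']:.1f} deg"
        )
    print(f"radius sweep selected {sweep.selected_radius} mm")
    print(
        f"identity rotation rank {ra.identity_rank}/{args.n_rotations + 1} "
        f"({100 * ra.identity_rank_fraction:.2f}% — note: with *linear* planted "
        "gradients rotated solutions are near-equivalent by construction)"
    )
    print(f"tables in {args.out}/")


if __name__ == "__main__":
    main()
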