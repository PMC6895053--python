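"""Voxel tuning along an emotion dimension: pRF grid fit + NMF prototypes.

Simulates Gaussian-tuned voxels along a dimension-score series, fits the
(mu, sigma) tuning grid per voxel, flags flat voxels with a surrogate
null, compares the recovered mu map to a planted gradient map, and
extracts prototypical tunings by NMF. Tables go to results/prf/.
"""

import argparse
import json
import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "src"))

from emomap.prf import (
    build_tuning_grid,
    filter_predictor,
    fit_prf,
    grid_t_values,
    nmf_tuning_components,
    tuning_vs_gradient,
)
from emomap.studies import _ar1_columns, _sub_seed


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-voxels", type=int, default=200)
    ap.add_argument("--snr", type=float, default=2.0)
    ap.add_argument("--n-null", type=int, default=19)
    ap.add_argument("--out", type=Path, default=Path("results/prf"))
    args = ap.parse_args()

    rng = np.random.default_rng(_sub_seed(args.seed, "scores"))
    scores = 20.0 * _ar1_columns(rng, 300, (0.8,))[:, 0]
    grid = build_tuning_grid(scores)

    gen = np.random.default_rng(_sub_seed(args.seed, "tunings"))
    mu_lo, mu_hi = np.percentile(scores, [10, 90])
    mus = gen.uniform(mu_lo, mu_hi, args.n_voxels)
    sigmas = gen.uniform(2.0, 6.0, args.n_voxels)
    responses = np.empty((args.n_voxels, scores.shape[0]))
    for i in range(args.n_voxels):
        resp = filter_predictor(scores, mus[i], sigmas[i])
        responses[i] = args.snr / resp.std() * resp
    noise = np.random.default_rng(_sub_seed(args.seed, "noise"))
    activity = responses + noise.standard_normal(responses.shape)

    est = fit_prf(
        activity, scores, grid, n_null=args.n_null, seed=_sub_seed(args.seed, "null")
    )
    mu_step = grid.mu_values[1] - grid.mu_values[0]
    recovery = float((np.abs(est.mu - mus) <= mu_step + 1e-9).mean())

    # tuning-map vs gradient-map similarity: the planted mu map itself is
    # the gradient ground truth here, so compare recovered mu against it
    rho, p = tuning_vs_gradient(
        est.mu,
        mus,
        null_betas=np.random.default_rng(_sub_seed(args.seed, "nullmaps"))
        .standard_normal((1000, args.n_voxels)),
    )

    t_matrix = grid_t_values(activity, scores, grid)
    basis = nmf_tuning_components(t_matrix, grid, rank=10, seed=args.seed)

    args.out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {
            "mu_true": mus,
            "sigma_true": sigmas,
            "mu_est": est.mu,
            "sigma_est": est.sigma,
            "t": est.t,
            "flat": est.flat_flag,
        }
    ).to_csv(args.out / "tuning_estimates.tsv", sep="\t", index=False)
    curves = pd.DataFrame({"mu": grid.mu_values})
    for i, c in basis.tuning_curves.items():
        curves[f"component_{i + 1}"] = c
    curves.to_csv(args.out / "tuning_curves.tsv", sep="\t", index=False)
    summary = {
        "grid_combinations": grid.n_combinations,
        "mu_recovery_rate": recovery,
        "flat_flag_rate": float(est.flat_flag.mean()),
        "tuning_vs_gradient_rho": rho,
        "tuning_vs_gradient_p": p,
        "nmf_variance_explained": basis.variance_explained.round(4).tolist(),
        "nmf_total_retained": basis.total_retained,
        "nmf_curves_kept": sorted(int(i) for i in basis.tuning_curves),
    }
    (args.out / "summary.json").write_text(json.dumps(summary, indent=2))

    print(
        f"{args.n_voxels} tuned voxels, SNR {args.snr:.1f}, grid "
        f"{len(grid.mu_values)} mu x {len(grid.sigma_values)} sigma "
        f"= {grid.n_combinations} combinations"
    )
    print(f"mu recovered within one grid step: {recovery:.1%}")
    print(f"tuning-vs-gradient rho = {rho:.3f} (p = {p:.3f})")
    print(
        f"NMF rank 10 retains {basis.total_retained:.1%} of variance; "
        f"{len(basis.tuning_curves)} components above the 5% curve threshold"
    )
    print(f"tables in {args.out}/")


if __name__ == "__main__":
    main()
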