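"""Behavioral analysis: agreement, emotion dimensions, affective states.

Reads the simulated preprocessed ratings (analysis/01), quantifies
inter-rater agreement against the IAAFT surrogate null, extracts emotion
dimensions by PCA, checks their leave-one-subject-out Procrustes
consistency, and clusters high-intensity timepoints into affective
states. Tables go to results/behavior/.
"""

import argparse
import json
import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "src"))

from emomap.io import read_ratings_tsv
from emomap.ratings import (
    RatingTimeseries,
    cluster_affective_states,
    loo_pc_consistency,
    null_component_scores,
    pairwise_agreement,
    pca_dimensions,
    rating_surrogates,
)


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--ratings-dir", type=Path, default=Path("results/ratings"))
    ap.add_argument("--n-surrogates", type=int, default=200)
    ap.add_argument("--out", type=Path, default=Path("results/behavior"))
    args = ap.parse_args()

    paths = sorted(args.ratings_dir.glob("sub-*_preprocessed.tsv"))
    if not paths:
        raise SystemExit("no preprocessed ratings found; run analysis/01 first")
    panel = [
        read_ratings_tsv(p, subject_id=p.stem.split("_")[0]) for p in paths
    ]
    group = RatingTimeseries(
        np.mean([r.values for r in panel], axis=0),
        rate=panel[0].rate,
        emotion_labels=panel[0].emotion_labels,
    )
    args.out.mkdir(parents=True, exist_ok=True)

    # agreement of the basic emotions vs surrogate null
    null = rating_surrogates(group, n=args.n_surrogates, seed=args.seed)
    agree = pairwise_agreement(panel, null)
    rows = [
        {
            "emotion": e,
            "mean_rho": float(np.nanmean(agree.pairwise_rho[e])),
            "sd_rho": float(np.nanstd(agree.pairwise_rho[e])),
            "null_p95": agree.null_p95[e],
            "consistent_all_pairs": agree.consistent[e],
            "group_p": agree.group_p[e],
        }
        for e in group.emotion_labels
    ]
    pd.DataFrame(rows).to_csv(args.out / "agreement.tsv", sep="\t", index=False)

    # emotion dimensions
    dims = pca_dimensions(group)
    pd.DataFrame(
        dims.loadings, index=group.emotion_labels, columns=dims.component_labels
    ).to_csv(args.out / "pca_loadings.tsv", sep="\t")
    pd.DataFrame(dims.scores, columns=dims.component_labels).to_csv(
        args.out / "pca_scores.tsv", sep="\t", index=False
    )

    # leave-one-out Procrustes consistency of the components
    null_scores = null_component_scores(
        group, n=args.n_surrogates, seed=args.seed + 1
    )
    consist = loo_pc_consistency(panel, null_scores)
    rows = [
        {
            "component": c,
            "mean_rho": float(np.nanmean(consist.pairwise_rho[c])),
            "null_p95": consist.null_p95[c],
            "consistent_all_pairs": consist.consistent[c],
            "group_p": consist.group_p[c],
        }
        for c in consist.pairwise_rho
    ]
    pd.DataFrame(rows).to_csv(args.out / "pc_consistency.tsv", sep="\t", index=False)

    # affective states
    clust = cluster_affective_states(group, seed=args.seed)
    pd.DataFrame(
        {
            "timepoint": clust.kept_timepoints,
            "tsne_x": clust.embedding[:, 0],
            "tsne_y": clust.embedding[:, 1],
            "cluster": clust.labels,
        }
    ).to_csv(args.out / "affective_states.tsv", sep="\t", index=False)
    summary = {
        "n_subjects": len(panel),
        "n_pairs": agree.n_pairs,
        "explained_variance_pct": (100 * dims.explained_variance).round(1).tolist(),
        "n_affective_states": clust.k,
        "silhouette_by_k": clust.silhouette_by_k,
    }
    (args.out / "summary.json").write_text(json.dumps(summary, indent=2))

    ev = 100 * dims.explained_variance
    consistent = [e for e in group.emotion_labels if agree.consistent[e]]
    print(f"{len(panel)} raters, {agree.n_pairs} pairs")
    print(f"emotions consistent across all pairs: {', '.join(consistent)}")
    print(
        "PC explained variance (%): "
        + ", ".join(f"{v:.0f}" for v in ev)
        + f"  (first three: {ev[:3].sum():.0f}%)"
    )
    print(f"affective states selected by silhouette: k = {clust.k}")
    print(f"tables in {args.out}/")


if __name__ == "__main__":
    main()
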