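"""Simulate the behavioral experiment: 12 raters, 6 emotions, shared latents.

Generates a panel of continuous emotion-rating time series (10 Hz native,
0-100 scale) driven by three smooth latent components plus independent
per-rater noise, preprocesses them to the fMRI temporal resolution
(TR 2 s, 2 s lag, 10 s moving average), and writes everything under
results/ratings/.
"""

import argparse
import sys
from pathlib import Path


sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "src"))

from emomap.io import write_ground_truth_json, write_ratings_tsv
from emomap.ratings import RatingTimeseries, preprocess_ratings
from emomap.studies import default_latent_spec
from emomap.synthetic import gen_rating_panel


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-subjects", type=int, default=12)
    ap.add_argument("--minutes", type=float, default=20.0)
    ap.add_argument("--out", type=Path, default=Path("results/ratings"))
    args = ap.parse_args()

    n_native = int(args.minutes * 60 * 10)  # 10 Hz
    spec = default_latent_spec()
    panel, gt = gen_rating_panel(args.n_subjects, n_native, 10.0, spec, args.seed)

    args.out.mkdir(parents=True, exist_ok=True)
    for ratings in panel:
        write_ratings_tsv(args.out / f"{ratings.subject_id}_native.tsv", ratings)
        pre = preprocess_ratings(ratings, tr=2.0, lag=2.0, window=10.0)
        write_ratings_tsv(
            args.out / f"{ratings.subject_id}_preprocessed.tsv",
            RatingTimeseries(
                pre.values, pre.rate, pre.emotion_labels, pre.subject_id
            ),
        )
    write_ground_truth_json(args.out / "ground_truth.json", gt)

    clip = gt.extras["clipped_fraction"]
    pre_len = preprocess_ratings(panel[0]).values.shape[0]
    print(
        f"simulated {args.n_subjects} raters x {n_native} samples "
        f"({args.minutes:.0f} min at 10 Hz), seed {args.seed}"
    )
    print(
        f"preprocessed to {pre_len} usable TRs; "
        f"clipped fraction {clip.mean():.3%} (max {clip.max():.3%})"
    )
    print(f"wrote TSVs and ground truth to {args.out}/")


if __name__ == "__main__":
    main()
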