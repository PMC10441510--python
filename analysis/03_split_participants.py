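#!/usr/bin/env python
"""Partition participants into training / linear-correction / test
subdivisions (77 / 8.5 / 14.5 %) and lay out the 3-fold CV with the 30/70
bias/evaluation subsplit inside each held-out fold.

Splits are at the participant level; rare-modality carriers fill the
held-out test set first so unseen modalities are evaluated there.
"""

import argparse
from pathlib import Path

from brainpad import cohort, splits


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--predictions", type=Path,
                        default=Path("results/predictions.tsv"))
    parser.add_argument("--out", type=Path, default=Path("results"))
    args = parser.parse_args()

    table = cohort.read_prediction_table(args.predictions)
    split = splits.assign_subdivisions(table, seed=args.seed)
    folds = splits.make_cv_folds(split[split["subdivision"] == "train"],
                                 k=3, subsplit=(0.30, 0.70),
                                 seed=args.seed + 1)

    args.out.mkdir(parents=True, exist_ok=True)
    split.to_csv(args.out / "split.tsv", sep="\t", index=False)
    folds.to_csv(args.out / "cv_folds.tsv", sep="\t", index=False)

    print("subdivision sizes (participants):")
    print(split["subdivision"].value_counts().to_string())
    print("CV roles per iteration (participants):")
    print(folds.groupby(["iteration", "role"]).size().unstack().to_string())
    print(f"wrote {args.out / 'split.tsv'} and {args.out / 'cv_folds.tsv'}")


if __name__ == "__main__":
    main()
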