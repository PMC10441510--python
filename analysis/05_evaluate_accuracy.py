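#!/usr/bin/env python
"""Accuracy of the corrected predictions on the held-out test set.

Repeated-measures bootstrap (one random repetition per participant per
replicate, participants resampled with replacement) of MAE, correlation and
the constrained R² per modality and pooled, with 95% percentile CIs.
"""

import argparse
from pathlib import Path

import pandas as pd

from brainpad import accuracy


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--corrected-test", type=Path,
                        default=Path("results/corrected_test.tsv"))
    parser.add_argument("--n-boot-factor", type=int, default=10_000,
                        help="multiplier for N_r (x N_m pooled) replicates; "
                             "lower it for a quick look")
    parser.add_argument("--out", type=Path, default=Path("results"))
    args = parser.parse_args()

    table = pd.read_csv(args.corrected_test, sep="\t")
    report = accuracy.bootstrap_accuracy(
        table, value_col="corrected_brain_age_years",
        n_boot_factor=args.n_boot_factor, seed=args.seed)

    args.out.mkdir(parents=True, exist_ok=True)
    report.table.to_csv(args.out / "accuracy.tsv", sep="\t", index=False,
                        float_format="%.6f")
    cols = ["cell", "n_participants", "mae", "mae_lo", "mae_hi",
            "correlation", "r2"]
    print(report.table[cols].round(3).to_string(index=False))
    print(f"replicates used: {report.n_boot}")
    print(f"wrote {args.out / 'accuracy.tsv'}")


if __name__ == "__main__":
    main()
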