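#!/usr/bin/env python
"""Repeated-measures model of |corrected brain-PAD| on the test set.

Fits |brain-PAD| ~ modality + subject (+ random subject intercept) by REML
and reports the within-subject modality contrasts against the reference
modality and the model-based "population" MAE per modality and in total.
"""

import argparse
from pathlib import Path

import pandas as pd

from brainpad import groupmodels


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--corrected-test", type=Path,
                        default=Path("results/corrected_test.tsv"))
    parser.add_argument("--reference", default="MPRAGE")
    parser.add_argument("--path", default="fixed_and_random",
                        choices=groupmodels.PATHS)
    parser.add_argument("--out", type=Path, default=Path("results"))
    args = parser.parse_args()

    table = pd.read_csv(args.corrected_test, sep="\t")
    fit = groupmodels.fit_abs_pad_model(table, reference=args.reference,
                                        path=args.path)
    contrasts = groupmodels.modality_contrasts(fit)
    pop = groupmodels.population_mae(fit)

    args.out.mkdir(parents=True, exist_ok=True)
    contrasts.to_csv(args.out / "modality_contrasts.tsv", sep="\t",
                     index=False, float_format="%.6f")
    pop.to_csv(args.out / "population_mae.tsv", sep="\t", index=False,
               float_format="%.6f")

    if fit.random_intercept_sd is not None:
        print(f"random-intercept sd: {fit.random_intercept_sd:.2f} y")
    print(f"modality contrasts vs {args.reference} (years of |brain-PAD|):")
    print(contrasts.round(3).to_string(index=False))
    print("population MAE estimates (years):")
    print(pop.round(3).to_string(index=False))
    print(f"wrote {args.out / 'modality_contrasts.tsv'} and "
          f"{args.out / 'population_mae.tsv'}")


if __name__ == "__main__":
    main()
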