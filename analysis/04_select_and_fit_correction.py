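#!/usr/bin/env python
"""Select the bias-correction model by cross-validated corrected MAE and
fit the final correction on the linear-correction subdivision.

For each CV iteration the four candidate forms (age, age*modality,
age*scanner, age*modality*scanner) are fitted on the cv_bias participants
and scored by corrected MAE on cv_eval; the winner (ties to the simpler
form) is re-fitted on the held-aside linear-correction set and applied to
the test set, whose corrected table is written for the evaluation scripts.
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from brainpad import cohort, correction


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--predictions", type=Path,
                        default=Path("results/predictions.tsv"))
    parser.add_argument("--split", type=Path, default=Path("results/split.tsv"))
    parser.add_argument("--cv-folds", type=Path,
                        default=Path("results/cv_folds.tsv"))
    parser.add_argument("--out", type=Path, default=Path("results"))
    args = parser.parse_args()

    table = cohort.read_prediction_table(args.predictions)
    split = pd.read_csv(args.split, sep="\t")
    folds = pd.read_csv(args.cv_folds, sep="\t")
    merged = table.merge(split[["participant_id", "subdivision"]],
                         on="participant_id")

    rows = []
    for it, roles in folds.groupby("iteration"):
        by_role = {role: set(sub["participant_id"])
                   for role, sub in roles.groupby("role")}
        fit_tab = merged[merged["participant_id"].isin(by_role["cv_bias"])]
        eval_tab = merged[merged["participant_id"].isin(by_role["cv_eval"])]
        for kind in correction.CANDIDATE_KINDS:
            try:
                model = correction.fit_correction(fit_tab, kind)
                out = correction.apply_correction(eval_tab, model)
                mae = float(out["corrected_pad_years"].abs().mean())
            except ValueError:
                mae = np.inf  # unfit in this fold; cannot win selection
            rows.append({"iteration": it, "fold": it, "formula_kind": kind,
                         "corrected_mae": mae})
    cv_results = pd.DataFrame(rows)
    selected = correction.select_correction_model(cv_results)

    corr_tab = merged[merged["subdivision"] == "linear_correction"]
    final = correction.fit_correction(corr_tab, selected)
    test_tab = merged[merged["subdivision"] == "test"]
    corrected_test = correction.apply_correction(test_tab, final)

    args.out.mkdir(parents=True, exist_ok=True)
    cv_results.to_csv(args.out / "cv_results.tsv", sep="\t", index=False,
                      float_format="%.6f")
    corrected_test.to_csv(args.out / "corrected_test.tsv", sep="\t",
                          index=False, float_format="%.6f")
    (args.out / "correction_model.json").write_text(json.dumps({
        "selected": selected,
        "coefficients": {k: float(v) for k, v in final.coefficients.items()},
        "n_fit": final.n_fit}, indent=2))

    print("fold-averaged corrected MAE by candidate:")
    print(cv_results.groupby("formula_kind")["corrected_mae"].mean()
          .round(3).to_string())
    print(f"selected model: {selected}")
    if selected == "age":
        print(f"intercept {final.intercept:.2f} y, slope {final.slope:.3f}")
    raw_pad = (corrected_test["brain_age_years"]
               - corrected_test["age_years"]).mean()
    print(f"test-set mean PAD: raw {raw_pad:+.2f} y -> corrected "
          f"{corrected_test['corrected_pad_years'].mean():+.2f} y")


if __name__ == "__main__":
    main()
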