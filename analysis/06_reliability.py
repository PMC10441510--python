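#!/usr/bin/env python
"""Internal consistency of corrected brain-PADs on the test set.

Builds the participants x (modality, repetition) item matrix, computes
Cronbach's alpha with pairwise-deletion covariance and its F-based CI, and
the within-subject mean absolute deviation of corrected brain-PADs (also
after excluding the worst-performing unseen modality).
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from brainpad import reliability


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--corrected-test", type=Path,
                        default=Path("results/corrected_test.tsv"))
    parser.add_argument("--exclude-modality", action="append", default=[],
                        help="repeatable; e.g. --exclude-modality T2wGRE")
    parser.add_argument("--out", type=Path, default=Path("results"))
    args = parser.parse_args()

    table = pd.read_csv(args.corrected_test, sep="\t")
    item = reliability.build_item_matrix(table)
    item = reliability.ensure_pairwise_support(item)
    alpha = reliability.cronbach_alpha(item)
    lo, hi = reliability.alpha_confidence_interval(alpha, item.n_obs, item.k)

    mad_all = reliability.within_subject_mad(table, seed=args.seed)
    out = {"alpha": alpha, "alpha_ci": [lo, hi], "k_items": item.k,
           "n_participants": item.n_obs,
           "within_subject_mad": mad_all}
    print(f"Cronbach's alpha: {alpha:.3f} [{lo:.3f}, {hi:.3f}] "
          f"({item.n_obs} participants x {item.k} items)")
    m = mad_all
    print(f"within-subject MAD: {m['mean']:.2f} y "
          f"[{m['ci'][0]:.2f}, {m['ci'][1]:.2f}] over {m['n_participants']} "
          "participants")
    if args.exclude_modality:
        mad_ex = reliability.within_subject_mad(
            table, exclude_modalities=args.exclude_modality, seed=args.seed)
        out["within_subject_mad_excluding"] = {
            "modalities": args.exclude_modality, **mad_ex}
        print(f"excluding {args.exclude_modality}: {mad_ex['mean']:.2f} y "
              f"[{mad_ex['ci'][0]:.2f}, {mad_ex['ci'][1]:.2f}]")

    args.out.mkdir(parents=True, exist_ok=True)
    (args.out / "reliability.json").write_text(json.dumps(out, indent=2))
    print(f"wrote {args.out / 'reliability.json'}")


if __name__ == "__main__":
    main()
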