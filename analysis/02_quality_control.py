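#!/usr/bin/env python
"""Image quality control on toy volumes.

Generates template-like volumes for a subset of scans (a few deliberately
corrupted), scores each against the template by normalized mutual
information, proposes the Tukey lower-fence review threshold, and reports
how the flags line up with the ground-truth corruption manifest.
"""

import argparse
from pathlib import Path

import pandas as pd

from brainpad import cohort, qc


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--n-volumes", type=int, default=24)
    parser.add_argument("--n-corrupted", type=int, default=4)
    parser.add_argument("--shape", type=int, nargs=3, default=(48, 48, 48))
    parser.add_argument("--predictions", type=Path,
                        default=Path("results/predictions.tsv"))
    parser.add_argument("--out", type=Path, default=Path("results"))
    args = parser.parse_args()

    table = cohort.read_prediction_table(args.predictions)
    sub = table.head(args.n_volumes)
    volumes, manifest = cohort.generate_volumes(
        sub, seed=args.seed, shape=tuple(args.shape),
        n_corrupted=args.n_corrupted)
    template = cohort.make_template(tuple(args.shape))
    nmis = [qc.normalized_mutual_information(v, template) for v in volumes]
    threshold, flags = qc.propose_qc_threshold(nmis)

    report = manifest.assign(nmi=nmis, flag=flags, threshold=threshold)
    args.out.mkdir(parents=True, exist_ok=True)
    report.to_csv(args.out / "qc.tsv", sep="\t", index=False,
                  float_format="%.6f")

    agreement = pd.crosstab(report["corrupted"], report["flag"])
    print(f"NMI range: [{min(nmis):.3f}, {max(nmis):.3f}]  "
          f"review threshold: {threshold:.3f}")
    print("ground truth vs flag:")
    print(agreement.to_string())
    print(f"wrote {args.out / 'qc.tsv'}")


if __name__ == "__main__":
    main()
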