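#!/usr/bin/env python
"""Generate the default synthetic three-group study and summarise it.

The scenario plants a nodal-strength effect on the left calcarine's
incident edges in the amyloid-positive group and links the recall z-score
to the right middle cingulum's regional efficiency (partial r = 0.5) in
that group. Matrices and metadata are written under scratch/ (they are
bulky intermediate data); a cohort summary goes to results/.
"""

import argparse
from pathlib import Path

from lldnet.io import write_study
from lldnet.simulate import default_paper_like_config, simulate_study


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--study-dir", type=Path, default=Path("scratch/synthetic_study"))
    parser.add_argument("--out", type=Path, default=Path("results"))
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    config = default_paper_like_config()
    study = simulate_study(config, seed=args.seed)
    write_study(study, args.study_dir)

    summary = study.subjects.groupby("group")[["age", "sex", "education"]].agg(
        ["mean", "std"]
    ).round(2)
    summary.to_csv(args.out / "synthetic_cohort_summary.tsv", sep="\t")
    print(study.subjects["group"].value_counts().to_string())
    print(summary.to_string())
    print(f"edge clip rate: {study.ledger['clip_rate']:.4%}")
    print(f"planted effects: {study.ledger['effects']}")
    print(f"planted partial correlations: {study.ledger['planted_partial_r']}")
    print(f"study written to {args.study_dir}/, summary to {args.out}/")


if __name__ == "__main__":
    main()
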