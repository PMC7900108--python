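#!/usr/bin/env python
"""Partial correlations between network measures and cognitive scores.

Runs the per-group covariate-controlled correlation analysis on the
synthetic cohort and checks recovery of the planted link (recall z-score
vs. right middle cingulum regional efficiency, partial r = 0.5 in the
amyloid-positive group). Also writes the descriptive Fisher-z group
contrasts.
"""

import argparse
from pathlib import Path

from lldnet.association import compare_group_correlations, run_correlation_analysis
from lldnet.metrics import compute_metric_tables
from lldnet.simulate import default_paper_like_config, simulate_study


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--out", type=Path, default=Path("results"))
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    study = simulate_study(default_paper_like_config(), seed=args.seed)
    nodal, global_df = compute_metric_tables(study.connectomes)
    res = run_correlation_analysis(
        nodal, global_df, study.scores, study.design
    )
    res.to_csv(args.out / "correlations.tsv", sep="\t", index=False)
    contrasts = compare_group_correlations(res[res["scope"] == "nodal"])
    contrasts.to_csv(
        args.out / "correlation_group_contrasts.tsv", sep="\t", index=False
    )

    planted = res[
        (res["group"] == "LLD-MCI-A+")
        & (res["score"] == "word_list_recall_z")
        & (res["measure"] == "efficiency")
    ].set_index("node_label")
    cell = planted.loc["Cingulum_Mid_R"]
    print(f"planted link (target partial r = 0.5): estimated "
          f"r = {cell['r']:.3f}, p = {cell['p']:.4f}, "
          f"p_fdr = {cell['p_fdr']:.4f}, n = {int(cell['n_effective'])}")
    rank = int((planted["r"].abs() > abs(cell["r"])).sum()) + 1
    print(f"planted node's |r| rank within its 90-node family: {rank}")
    n_cells = len(res)
    n_sig = int((res["p_fdr"].dropna() < 0.05).sum())
    print(f"{n_cells} correlation cells; {n_sig} nodal cells FDR-significant")
    if n_sig:
        fams = (
            res[res["p_fdr"] < 0.05]
            .groupby(["group", "score", "measure"])
            .size()
        )
        print("discoveries concentrate in whole node families — nodal "
              "measures share a per-subject global scaling component, so "
              "a family lights up together when that component chances to "
              "track a score:")
        print(fams.to_string())
    print(f"tables written to {args.out}/")


if __name__ == "__main__":
    main()
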