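#!/usr/bin/env python
"""Permutation-ANCOVA group comparison on the synthetic cohort.

Runs the omnibus Freedman-Lane permutation ANCOVA per node per measure
(FDR across 90 nodes), the uncorrected global-measure comparison, and the
covariate-adjusted group means at the planted node. Reports whether the
planted left-calcarine strength effect is detected.
"""

import argparse
from pathlib import Path

from lldnet.inference import adjusted_group_means, run_global_group_analysis, run_nodal_group_analysis
from lldnet.metrics import compute_metric_tables
from lldnet.simulate import default_paper_like_config, simulate_study


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--n-perm", type=int, default=2000)
    parser.add_argument("--out", type=Path, default=Path("results"))
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    study = simulate_study(default_paper_like_config(), seed=args.seed)
    nodal, global_df = compute_metric_tables(study.connectomes)
    design = study.design

    res = run_nodal_group_analysis(
        nodal, design, n_perm=args.n_perm, seed=args.seed, posthoc="survivors"
    )
    res.to_csv(args.out / "nodal_group_comparison.tsv", sep="\t", index=False)
    gres = run_global_group_analysis(
        global_df, design, n_perm=args.n_perm, seed=args.seed
    )
    gres.to_csv(args.out / "global_group_comparison.tsv", sep="\t", index=False)

    strength = res[res["measure"] == "strength"].sort_values("f", ascending=False)
    top = strength.iloc[0]
    print(f"top node by strength F: {top['node_label']} "
          f"(F={top['f']:.2f}, p_perm={top['p_perm']:.4f}, "
          f"p_fdr={top['p_fdr']:.4f})")
    print("planted node was Calcarine_L -> "
          + ("DETECTED" if top["node_label"] == "Calcarine_L" else "MISSED"))
    n_sig = int((res["p_fdr"] < 0.05).sum())
    print(f"{n_sig} (measure, node) pairs FDR-significant at q=0.05")
    print("global measures (uncorrected):")
    print(gres.round(4).to_string(index=False))

    am = adjusted_group_means(nodal["strength"]["Calcarine_L"].to_numpy(), design)
    am.table.round(1).to_csv(
        args.out / "calcarine_adjusted_means.tsv", sep="\t", index=False
    )
    print("covariate-adjusted mean strength at Calcarine_L (95% CI):")
    print(am.table.round(1).to_string(index=False))


if __name__ == "__main__":
    main()
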