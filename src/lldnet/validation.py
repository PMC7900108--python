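"""Validation experiments: calibration, exactness and parameter recovery.

The imaging-derived results of a clinical connectome study cannot be
reproduced without the subject-level matrices, which are not deposited.
What *can* be established is that every inferential component behaves
correctly on data whose ground truth is known. This module bundles those
experiments so tests, scripts and reports run the same code:

* graph-measure equivalence against brute-force oracles on small graphs;
* exactness of the permutation p-value against exhaustive enumeration;
* type-I error calibration of the Freedman-Lane permutation ANCOVA under
  covariate confounding;
* recovery of planted nodal-strength group effects and planted partial
  correlations from synthetic cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from . import metrics as mx
from .connectome import Connectome
from .inference import CohortDesign, permutation_pvalue, run_nodal_group_analysis
from .association import partial_correlation
from .simulate import (
    ScoreLink,
    SimulationConfig,
    default_paper_like_config,
    generate_cohort,
    generate_connectomes,
    generate_scores,
    measure_vector,
    simulate_study,
)

__all__ = [
    "max_graph_oracle_error", "permutation_exactness_gap",
    "type_i_error_rate", "planted_node_recovery", "recover_planted_r",
]


def _random_small_connectome(rng: np.random.Generator) -> Connectome:
    n = int(rng.integers(2, 7))
    w = np.zeros((n, n))
    iu = np.triu_indices(n, 1)
    present = rng.random(len(iu[0])) < rng.uniform(0.2, 0.95)
    w[iu[0][present], iu[1][present]] = rng.uniform(0.05, 10.0, int(present.sum()))
    return Connectome(w + w.T, tuple(f"n{i}" for i in range(n)))


def _floyd_warshall(weights: np.ndarray) -> np.ndarray:
    n = weights.shape[0]
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    nz = weights > 0
    d[nz] = 1.0 / weights[nz]
    np.fill_diagonal(d, 0.0)
    for k in range(n):
        d = np.minimum(d, d[:, [k]] + d[[k], :])
    return d


def _onnela_enumeration(weights: np.ndarray) -> np.ndarray:
    n = weights.shape[0]
    k = (weights > 0).sum(axis=1)
    out = np.zeros(n)
    for i in range(n):
        if k[i] < 2:
            continue
        acc = sum(
            (weights[i, j] * weights[i, h] * weights[j, h]) ** (1 / 3)
            for j in range(n) for h in range(n)
            if j != i and h != i and j != h
        )
        out[i] = acc / (k[i] * (k[i] - 1))
    return out


def max_graph_oracle_error(n_graphs: int = 200, seed: int = 0) -> dict[str, float]:
    """Largest deviation of the production metrics from brute-force oracles
    over random graphs with at most 6 nodes."""
    rng = np.random.default_rng(seed)
    worst_dist = worst_clust = 0.0
    for _ in range(n_graphs):
        conn = _random_small_connectome(rng)
        d = mx.shortest_path_matrix(conn)
        ref = _floyd_warshall(conn.weights)
        both = np.isfinite(d) & np.isfinite(ref)
        if not np.array_equal(np.isfinite(d), np.isfinite(ref)):
            worst_dist = np.inf
        if both.any():
            worst_dist = max(worst_dist, float(np.abs(d[both] - ref[both]).max()))
        worst_clust = max(
            worst_clust,
            float(np.abs(
                mx.nodal_clustering(conn) - _onnela_enumeration(conn.weights)
            ).max()),
        )
    return {"distance": worst_dist, "clustering": worst_clust}


def permutation_exactness_gap(seed: int = 0) -> float:
    """|permutation p - exhaustive enumeration p| on a 6-subject two-group
    problem without covariates (20 possible assignments)."""
    rng = np.random.default_rng(seed)
    y = rng.normal(size=6)
    design = CohortDesign(
        pd.Series(["HOA"] * 3 + ["LLD-MCI-A+"] * 3),
        pd.DataFrame(index=range(6)),
    )
    _, p = permutation_pvalue(y, design, exhaustive=True)

    # independent oracle: enumerate assignments, textbook one-way F
    def oneway_f(a: np.ndarray, b: np.ndarray) -> float:
        grand = np.concatenate([a, b]).mean()
        ssb = len(a) * (a.mean() - grand) ** 2 + len(b) * (b.mean() - grand) ** 2
        ssw = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
        return ssb / (ssw / 4)

    f_obs = oneway_f(y[:3], y[3:])
    hits = total = 0
    for idx in combinations(range(6), 3):
        sel = np.zeros(6, bool)
        sel[list(idx)] = True
        total += 1
        hits += oneway_f(y[sel], y[~sel]) >= f_obs - 1e-12
    return abs(p - hits / total)


def _confounded_null_design(rng: np.random.Generator) -> tuple[CohortDesign, np.ndarray]:
    """A 74-subject null cohort whose covariates differ by group, plus an
    outcome driven by covariates only (no group effect)."""
    cohort = generate_cohort(SimulationConfig(), rng.integers(2**31))
    design = cohort.design
    z = design.covariates.to_numpy(float)
    y = 0.6 * z[:, 0] - 0.8 * z[:, 2] + rng.normal(size=len(z))
    return design, y


def type_i_error_rate(
    n_reps: int = 500, n_perm: int = 500, seed: int = 0, alpha: float = 0.05,
    scheme: str = "freedman-lane",
) -> float:
    """Null rejection rate of the permutation ANCOVA under confounding."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_reps):
        design, y = _confounded_null_design(rng)
        _, p = permutation_pvalue(
            y, design, n_perm=n_perm, seed=int(rng.integers(2**31)),
            scheme=scheme,
        )
        rejections += p <= alpha
    return rejections / n_reps


@dataclass
class RecoveryResult:
    top1_rate: float
    n_seeds: int
    ranks: list[int]


def planted_node_recovery(
    n_seeds: int = 20, n_perm: int = 1000, seed: int = 0,
    effect_size: float = 6.0,
) -> RecoveryResult:
    """How often the planted strength-effect node ranks first by omnibus F.

    Runs the full nodal group analysis on the default synthetic scenario
    (effect on the left calcarine's incident edges in the amyloid-positive
    group) for ``n_seeds`` independent cohorts.
    """
    config = default_paper_like_config(effect_size=effect_size)
    ranks = []
    for k in range(n_seeds):
        study = simulate_study(config, seed=seed + k)
        nodal, _ = mx.compute_metric_tables(study.connectomes)
        res = run_nodal_group_analysis(
            {"strength": nodal["strength"]}, study.design,
            n_perm=n_perm, seed=seed + k, posthoc="survivors",
        )
        order = res.sort_values("f", ascending=False)["node_label"].tolist()
        ranks.append(order.index("Calcarine_L") + 1)
    top1 = sum(r == 1 for r in ranks) / n_seeds
    return RecoveryResult(top1, n_seeds, ranks)


def recover_planted_r(
    n_subjects: int = 2000, target_r: float = 0.6, seed: int = 0
) -> float:
    """Estimated partial correlation of a score linked at ``target_r``.

    Uses a large synthetic cohort (equal thirds per group) with the score
    linked to one node's strength across all groups, then estimates the
    partial correlation controlling age, sex and education.
    """
    third = n_subjects // 3
    sizes = (third, third, n_subjects - 2 * third)
    config = SimulationConfig(
        group_sizes=sizes,
        score_links=(
            ScoreLink("linked_score", "strength", "Calcarine_L", target_r),
        ),
    )
    ss = np.random.SeedSequence(seed)
    s1, s2, s3 = ss.spawn(3)
    cohort = generate_cohort(config, s1)
    cohort = generate_connectomes(cohort, config, s2)
    cohort = generate_scores(cohort, config, s3)
    m = measure_vector(cohort.connectomes, "strength", "Calcarine_L")
    z = cohort.subjects[["age", "sex", "education"]].to_numpy(float)
    return partial_correlation(
        cohort.scores["linked_score"].to_numpy(), m, z
    )
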