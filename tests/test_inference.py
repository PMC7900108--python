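"""Permutation ANCOVA, FDR and adjusted-means correctness."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from lldnet.inference import (
    CohortDesign,
    adjusted_group_means,
    ancova_f,
    fdr_bh,
    permutation_pvalue,
    posthoc_pairwise,
    run_global_group_analysis,
    run_nodal_group_analysis,
)
from lldnet.cohort import oneway_anova_f


def two_group_design(n1, n2, covariates=None):
    group = pd.Series(["HOA"] * n1 + ["LLD-MCI-A+"] * n2)
    cov = pd.DataFrame(index=range(n1 + n2)) if covariates is None else covariates
    return CohortDesign(group, cov)


# ------------------------------------------------------------- ancova_f

def test_equal_group_means_give_zero_f():
    design = two_group_design(3, 3)
    assert ancova_f(np.array([1, 2, 3, 1, 2, 3.0]), design) == pytest.approx(0)


def test_no_covariates_reduces_to_oneway_anova(rng):
    y = rng.normal(size=12)
    group = pd.Series(["HOA"] * 4 + ["LLD-MCI-A+"] * 4 + ["LLD-MCI-A-"] * 4)
    design = CohortDesign(group, pd.DataFrame(index=range(12)))
    f = ancova_f(y, design)
    assert f == pytest.approx(oneway_anova_f([y[:4], y[4:8], y[8:]]))
    assert f == pytest.approx(stats.f_oneway(y[:4], y[4:8], y[8:]).statistic)


def test_ancova_f_matches_statsmodels_oracle(rng):
    """12-subject fixture with one covariate against the OLS partial F."""
    z = rng.normal(size=12)
    y = rng.normal(size=12) + 0.7 * z
    design = two_group_design(6, 6, pd.DataFrame({"z": z}))
    g = np.r_[np.zeros(6), np.ones(6)]
    full = sm.OLS(y, sm.add_constant(np.column_stack([g, z]))).fit()
    reduced = sm.OLS(y, sm.add_constant(z)).fit()
    f_oracle = (
        (reduced.ssr - full.ssr) / 1
    ) / (full.ssr / full.df_resid)
    assert ancova_f(y, design) == pytest.approx(f_oracle, rel=1e-10)


def test_too_small_or_rank_deficient_designs_error(rng):
    design = two_group_design(
        2, 2, pd.DataFrame({"z": [1.0, 2, 3, 4], "w": [4.0, 1, 3, 2]})
    )
    with pytest.raises(ValueError, match="too few"):
        ancova_f(np.zeros(4), design)
    dup = pd.DataFrame({"a": [1.0, 2, 3, 4, 5, 6], "b": [2.0, 4, 6, 8, 10, 12]})
    with pytest.raises(ValueError, match="rank deficient"):
        two_group_design(3, 3, dup)


def test_sex_coding_invariance(small_design):
    """Flipping the 0/1 sex code leaves the partial F unchanged."""
    rng = np.random.default_rng(7)
    y = rng.normal(size=15)
    flipped = CohortDesign(
        small_design.group,
        small_design.covariates.assign(sex=1 - small_design.covariates["sex"]),
    )
    assert ancova_f(y, small_design) == pytest.approx(ancova_f(y, flipped))


# ---------------------------------------------------- permutation p-value

def brute_force_two_group_p(y, n1):
    """Exhaustive enumeration oracle over group assignments (no covariates)."""
    n = len(y)
    f_obs = stats.f_oneway(y[:n1], y[n1:]).statistic
    hits = total = 0
    for idx in combinations(range(n), n1):
        a = np.array([k in idx for k in range(n)])
        f = stats.f_oneway(y[a], y[~a]).statistic
        total += 1
        hits += f >= f_obs - 1e-12
    return hits / total


def test_exhaustive_mode_matches_enumeration_oracle(rng):
    y = rng.normal(size=6)
    design = two_group_design(3, 3)
    _, p = permutation_pvalue(y, design, exhaustive=True)
    assert p == pytest.approx(brute_force_two_group_p(y, 3))
    assert p >= 1 / 20


def test_pvalue_bounds_and_reproducibility(small_design):
    rng = np.random.default_rng(11)
    y = rng.normal(size=15)
    f1, p1 = permutation_pvalue(y, small_design, n_perm=199, seed=5)
    f2, p2 = permutation_pvalue(y, small_design, n_perm=199, seed=5)
    assert (f1, p1) == (f2, p2)
    assert 1 / 200 <= p1 <= 1
    # a different seed gives a different (but close) estimate
    _, p3 = permutation_pvalue(y, small_design, n_perm=199, seed=6)
    assert p3 == pytest.approx(p1, abs=0.35)


def test_label_scheme_runs(small_design):
    rng = np.random.default_rng(3)
    y = rng.normal(size=15)
    _, p = permutation_pvalue(y, small_design, n_perm=99, seed=1, scheme="labels")
    assert 0.01 <= p <= 1


def test_planted_effect_increases_power(small_design):
    """Mean permutation p decreases along a three-point effect grid."""
    rng = np.random.default_rng(21)
    base = rng.normal(size=15)
    bump = (small_design.group == "LLD-MCI-A+").to_numpy(float)
    mean_p = []
    for effect in (0.0, 1.5, 3.0):
        ps = [
            permutation_pvalue(
                base + effect * bump, small_design, n_perm=300, seed=s
            )[1]
            for s in range(5)
        ]
        mean_p.append(np.mean(ps))
    assert mean_p[0] > mean_p[1] > mean_p[2]


# ------------------------------------------------------------------ FDR

def test_fdr_bh_hand_examples():
    np.testing.assert_allclose(fdr_bh([0.2]), [0.2])
    np.testing.assert_allclose(
        fdr_bh([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
    )
    np.testing.assert_allclose(fdr_bh([0.3, 0.3, 0.3]), [0.3, 0.3, 0.3])
    np.testing.assert_allclose(
        fdr_bh([0.002, 0.9, 0.95]), [0.006, 0.95, 0.95]
    )


def test_fdr_bh_matches_statsmodels(rng):
    p = rng.uniform(0.001, 1, 40)
    np.testing.assert_allclose(
        fdr_bh(p), multipletests(p, method="fdr_bh")[1], atol=1e-12
    )


def test_fdr_bh_properties(rng):
    p = rng.uniform(0.001, 1, 25)
    adj = fdr_bh(p)
    assert np.all(adj >= p)
    order = np.argsort(p)
    assert np.all(np.diff(adj[order]) >= -1e-15)
    with pytest.raises(ValueError, match=r"\(0, 1\]"):
        fdr_bh([0.0, 0.5])


# -------------------------------------------------------------- post hoc

def test_posthoc_three_contrasts(small_design):
    rng = np.random.default_rng(2)
    y = rng.normal(size=15)
    ph = posthoc_pairwise(y, small_design, n_perm=99, seed=0)
    assert len(ph) == 3
    np.testing.assert_allclose(
        ph["p_fdr"], fdr_bh(ph["p_perm"].to_numpy())
    )


def test_posthoc_planted_contrast_ranks_first(small_design):
    """An effect confined to one group drives its two contrasts' p down."""
    rng = np.random.default_rng(4)
    y = rng.normal(size=15) + 4.0 * (small_design.group == "HOA").to_numpy(float)
    ph = posthoc_pairwise(y, small_design, n_perm=499, seed=0)
    involving = ph["contrast"].str.contains("HOA")
    assert ph.loc[involving, "p_perm"].max() < ph.loc[~involving, "p_perm"].min()


# -------------------------------------------------------- adjusted means

def test_adjusted_equal_raw_when_covariates_balanced():
    """Identical covariate values across groups mean no adjustment."""
    group = pd.Series(["HOA"] * 3 + ["LLD-MCI-A+"] * 3 + ["LLD-MCI-A-"] * 3)
    cov = pd.DataFrame({"age": [60.0, 70, 80] * 3})
    design = CohortDesign(group, cov)
    y = np.array([1.0, 2, 3, 4, 5, 6, 7, 8, 9])
    am = adjusted_group_means(y, design)
    np.testing.assert_allclose(am.table["mean"], [2.0, 5.0, 8.0])
    assert (am.table["ci_low"] <= am.table["mean"]).all()
    assert (am.table["mean"] <= am.table["ci_high"]).all()


def test_pure_covariate_outcome_equalises_groups(small_design):
    y = 2.0 * small_design.covariates["age"].to_numpy() - 5
    am = adjusted_group_means(y, small_design)
    np.testing.assert_allclose(
        am.table["mean"], [am.table["mean"].iloc[0]] * 3, rtol=1e-8
    )


def test_adjusted_means_match_statsmodels(small_design):
    """Estimate and CI against OLS prediction at covariate grand means."""
    rng = np.random.default_rng(9)
    y = rng.normal(size=15) + 0.1 * small_design.covariates["age"].to_numpy()
    am = adjusted_group_means(y, small_design)
    z = small_design.covariates.to_numpy(float)
    dummies = np.column_stack(
        [(small_design.group == lv).to_numpy(float)
         for lv in small_design.levels[1:]]
    )
    x = sm.add_constant(np.column_stack([dummies, z]))
    fit = sm.OLS(y, x).fit()
    for i, lv in enumerate(small_design.levels):
        x0 = np.zeros(x.shape[1])
        x0[0] = 1
        if i > 0:
            x0[i] = 1
        x0[3:] = z.mean(axis=0)
        pred = fit.get_prediction(x0)
        row = am.table.loc[am.table["group"] == lv].iloc[0]
        assert row["mean"] == pytest.approx(pred.predicted_mean[0])
        lo, hi = pred.conf_int()[0]
        assert row["ci_low"] == pytest.approx(lo)
        assert row["ci_high"] == pytest.approx(hi)


# ------------------------------------------------------------ full runs

def test_nodal_run_shapes_and_fdr_family(small_design, rng):
    nodal = {
        "strength": pd.DataFrame(
            rng.normal(size=(15, 6)), columns=[f"n{i}" for i in range(6)]
        )
    }
    res = run_nodal_group_analysis(
        nodal, small_design, n_perm=99, seed=0, posthoc="all"
    )
    assert len(res) == 6
    np.testing.assert_allclose(
        res["p_fdr"], fdr_bh(res["p_perm"].to_numpy())
    )
    assert res.filter(like="_vs_").notna().all().all()


def test_degenerate_feature_skipped_not_crashed(small_design, rng):
    nodal = {
        "strength": pd.DataFrame(
            {"live": rng.normal(size=15), "flat": np.ones(15)}
        )
    }
    res = run_nodal_group_analysis(nodal, small_design, n_perm=49, seed=0)
    flat = res.set_index("node_label").loc["flat"]
    assert np.isnan(flat["f"]) and np.isnan(flat["p_fdr"])
    assert np.isfinite(res.set_index("node_label").loc["live", "p_perm"])


def test_global_run_has_no_fdr_column(small_design, rng):
    gdf = pd.DataFrame(
        rng.normal(size=(15, 5)),
        columns=["edge_density", "total_strength", "clustering_coefficient",
                 "characteristic_path_length", "small_worldness"],
    )
    res = run_global_group_analysis(gdf, small_design, n_perm=99, seed=0)
    assert list(res.columns) == ["measure", "f", "p_perm"]
    assert len(res) == 5


def test_misaligned_tables_error(small_design, rng):
    nodal = {"strength": pd.DataFrame(rng.normal(size=(10, 3)))}
    with pytest.raises(ValueError, match="rows"):
        run_nodal_group_analysis(nodal, small_design, n_perm=9)
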