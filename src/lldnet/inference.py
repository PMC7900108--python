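"""Permutation-based ANCOVA group comparison with two-level FDR.

The omnibus test compares a network measure across groups while controlling
for age, sex and education through a linear model: the observed statistic is
the partial F for the group factor (full model: intercept + group indicators
+ covariates; reduced model: intercept + covariates). Its null distribution
is built by permutation. Two schemes are available:

``freedman-lane`` (default)
    Residuals of the reduced (covariates-only) model are permuted and the
    covariate fit added back before recomputing F. This stays calibrated
    when covariates are confounded with group membership — which is the
    situation in cohorts where the control group is younger and more
    educated than the patient groups.
``labels``
    Naive shuffling of group labels, provided for comparison only; it is
    known to drift from nominal size under confounding.

Nodal measures are tested per node with Benjamini-Hochberg FDR across the
node family; post-hoc pairwise permutation ANCOVAs are FDR-corrected across
the three group contrasts. Global measures are tested without any
across-feature correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "CohortDesign", "PermAncovaResult", "AdjustedMeans",
    "ancova_f", "permutation_pvalue", "fdr_bh", "posthoc_pairwise",
    "adjusted_group_means", "run_nodal_group_analysis",
    "run_global_group_analysis",
]

#: Canonical group labels for the three-arm design.
GROUPS = ("HOA", "LLD-MCI-A+", "LLD-MCI-A-")

# tolerance for counting permuted F >= observed F despite float jitter
_F_TIE_TOL = 1e-12


@dataclass
class CohortDesign:
    """Group membership and nuisance covariates, aligned to subject order.

    ``covariates`` columns are typically age (years), sex (0/1 code) and
    education (years); any numeric columns are accepted and all are treated
    as nuisance terms.
    """

    group: pd.Series
    covariates: pd.DataFrame

    def __post_init__(self) -> None:
        self.group = pd.Series(self.group).reset_index(drop=True)
        self.covariates = pd.DataFrame(self.covariates).reset_index(drop=True)
        if len(self.group) != len(self.covariates):
            raise ValueError("group and covariates have different lengths")
        counts = self.group.value_counts()
        if (counts < 2).any():
            small = counts[counts < 2].index.tolist()
            raise ValueError(f"groups with fewer than 2 subjects: {small}")
        z = self.covariates.to_numpy(dtype=float)
        if not np.all(np.isfinite(z)):
            raise ValueError("non-finite covariate values")
        x = np.column_stack([np.ones(len(z)), z])
        if np.linalg.matrix_rank(x) < x.shape[1]:
            raise ValueError("covariate matrix is rank deficient with intercept")

    @property
    def levels(self) -> tuple[str, ...]:
        return tuple(pd.unique(self.group))

    @property
    def n_subjects(self) -> int:
        return len(self.group)

    def subset(self, levels: tuple[str, ...]) -> tuple["CohortDesign", np.ndarray]:
        """Design restricted to ``levels``, plus the row mask used."""
        mask = self.group.isin(levels).to_numpy()
        return (
            CohortDesign(self.group[mask], self.covariates[mask]),
            mask,
        )


@dataclass
class PermAncovaResult:
    """Omnibus permutation-ANCOVA result for one feature."""

    feature: str
    f_obs: float
    p_perm: float
    n_perm: int
    seed: int | None = None
    p_fdr: float = np.nan
    posthoc: pd.DataFrame | None = None


@dataclass
class AdjustedMeans:
    """Covariate-adjusted group means with confidence intervals."""

    table: pd.DataFrame  # columns: group, mean, ci_low, ci_high
    conf_level: float = 0.95


def _design_matrices(
    design: CohortDesign, levels: tuple[str, ...] | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray, int, int]:
    """Full/reduced design matrices and subject mask for selected levels.

    Returns (X_full, X_reduced, mask, g, q). Group enters as g-1 indicator
    columns against the first level as reference; F is invariant to the
    coding choice.
    """
    levels = tuple(levels) if levels is not None else design.levels
    if len(levels) < 2:
        raise ValueError("need at least two groups to compare")
    mask = design.group.isin(levels).to_numpy()
    grp = design.group[mask].to_numpy()
    z = design.covariates[mask].to_numpy(dtype=float)
    n, q = z.shape
    g = len(levels)
    dummies = np.column_stack([(grp == lv).astype(float) for lv in levels[1:]])
    intercept = np.ones((n, 1))
    x_full = np.column_stack([intercept, dummies, z])
    x_red = np.column_stack([intercept, z])
    if n <= g + q:
        raise ValueError(f"too few subjects (n={n}) for g={g} groups, q={q} covariates")
    if np.linalg.matrix_rank(x_full) < x_full.shape[1]:
        raise ValueError("rank-deficient full design matrix")
    return x_full, x_red, mask, g, q


def _residual_projector(x: np.ndarray) -> np.ndarray:
    """M = I - X (X'X)^-1 X', the residual-maker of a full-rank design."""
    q, _ = np.linalg.qr(x)
    return np.eye(x.shape[0]) - q @ q.T


def _partial_f(
    m_full: np.ndarray, m_red: np.ndarray, y: np.ndarray, dfn: int, dfd: int
) -> np.ndarray:
    """Partial F for the group factor, columnwise over outcome matrix y."""
    rf = m_full @ y
    rr = m_red @ y
    rss_f = (rf * rf).sum(axis=0)
    rss_r = (rr * rr).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = ((rss_r - rss_f) / dfn) / (rss_f / dfd)
    return f


def ancova_f(
    y: np.ndarray,
    design: CohortDesign,
    levels: tuple[str, ...] | None = None,
) -> float:
    """Observed partial F for the group factor, controlling covariates.

    With no covariates this reduces exactly to the one-way ANOVA F.
    """
    x_full, x_red, mask, g, q = _design_matrices(design, levels)
    yv = np.asarray(y, dtype=float)[mask][:, None]
    n = x_full.shape[0]
    f = _partial_f(
        _residual_projector(x_full), _residual_projector(x_red), yv,
        dfn=g - 1, dfd=n - g - q,
    )
    return float(f[0])


def _permutation_matrix(
    n: int, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """n x n_perm array of row permutations."""
    return np.argsort(rng.random((n, n_perm)), axis=0)


def permutation_pvalue(
    y: np.ndarray,
    design: CohortDesign,
    levels: tuple[str, ...] | None = None,
    n_perm: int = 10_000,
    seed: int | None = 0,
    scheme: str = "freedman-lane",
    exhaustive: bool = False,
) -> tuple[float, float]:
    """Permutation p-value for the group partial F.

    Returns ``(f_obs, p_perm)`` with p = (1 + #{F_perm >= F_obs}) /
    (1 + n_perm), so p is never zero. ``exhaustive=True`` enumerates every
    distinct assignment of subjects to two groups of the observed sizes
    (label semantics; intended for small two-group problems) and returns
    the exact proportion of assignments with F >= F_obs.
    """
    x_full, x_red, mask, g, q = _design_matrices(design, levels)
    yv = np.asarray(y, dtype=float)[mask]
    n = x_full.shape[0]
    dfn, dfd = g - 1, n - g - q
    m_full = _residual_projector(x_full)
    m_red = _residual_projector(x_red)
    f_obs = float(_partial_f(m_full, m_red, yv[:, None], dfn, dfd)[0])

    if exhaustive:
        if g != 2:
            raise ValueError("exhaustive enumeration supports two groups only")
        lv = tuple(levels) if levels is not None else design.levels
        grp = design.group[mask].to_numpy()
        n1 = int((grp == lv[1]).sum())
        z = design.covariates[mask].to_numpy(dtype=float)
        hits = total = 0
        for idx in combinations(range(n), n1):
            dummy = np.zeros(n)
            dummy[list(idx)] = 1.0
            xf = np.column_stack([np.ones(n), dummy, z])
            f = _partial_f(
                _residual_projector(xf), m_red, yv[:, None], dfn, dfd
            )[0]
            total += 1
            hits += f >= f_obs - _F_TIE_TOL
        return f_obs, hits / total

    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    perms = _permutation_matrix(n, n_perm, rng)
    if scheme == "freedman-lane":
        # permute reduced-model residuals, add the covariate fit back
        e = m_red @ yv
        yhat = yv - e
        ystar = yhat[:, None] + e[perms]
        f_perm = _partial_f(m_full, m_red, ystar, dfn, dfd)
    elif scheme == "labels":
        # shuffle group labels only: permute the dummy block of X_full
        grp_cols = x_full[:, 1:g]
        f_perm = np.empty(n_perm)
        for b in range(n_perm):
            xf = x_full.copy()
            xf[:, 1:g] = grp_cols[perms[:, b]]
            f_perm[b] = _partial_f(
                _residual_projector(xf), m_red, yv[:, None], dfn, dfd
            )[0]
    else:
        raise ValueError(f"unknown permutation scheme {scheme!r}")
    n_ge = int((f_perm >= f_obs - _F_TIE_TOL).sum())
    return f_obs, (1 + n_ge) / (1 + n_perm)


def fdr_bh(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    adj_(i) = min_{j >= i} p_(j) * m / j over the ascending order
    statistics, capped at 1 and returned in the original order.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("pvals must be a non-empty 1-D array")
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(scaled[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def posthoc_pairwise(
    y: np.ndarray,
    design: CohortDesign,
    n_perm: int = 10_000,
    seed: int | None = 0,
    scheme: str = "freedman-lane",
) -> pd.DataFrame:
    """Pairwise permutation ANCOVAs with FDR across the three contrasts.

    Each pair of groups is tested on its own subject subset; the three
    permutation p-values are then Benjamini-Hochberg adjusted together.
    """
    levels = design.levels
    rows = []
    pairs = list(combinations(levels, 2))
    for k, pair in enumerate(pairs):
        sub_seed = None if seed is None else seed + k
        f, p = permutation_pvalue(
            y, design, levels=pair, n_perm=n_perm, seed=sub_seed, scheme=scheme
        )
        rows.append({"contrast": f"{pair[0]} vs {pair[1]}", "f": f, "p_perm": p})
    out = pd.DataFrame(rows)
    out["p_fdr"] = fdr_bh(out["p_perm"].to_numpy())
    return out


def adjusted_group_means(
    y: np.ndarray,
    design: CohortDesign,
    conf_level: float = 0.95,
) -> AdjustedMeans:
    """Covariate-adjusted group means: model predictions at covariate grand means.

    CI = estimate +/- t_{1-alpha/2, n-g-q} * SE of the prediction contrast.
    When covariate distributions are identical across groups these equal
    the raw group means.
    """
    x_full, x_red, mask, g, q = _design_matrices(design)
    yv = np.asarray(y, dtype=float)[mask]
    n = x_full.shape[0]
    df = n - g - q
    beta, *_ = np.linalg.lstsq(x_full, yv, rcond=None)
    resid = yv - x_full @ beta
    sigma2 = float(resid @ resid) / df
    xtx_inv = np.linalg.inv(x_full.T @ x_full)
    zbar = design.covariates[mask].to_numpy(dtype=float).mean(axis=0)
    tcrit = stats.t.ppf(0.5 + conf_level / 2, df)
    rows = []
    for i, lv in enumerate(design.levels):
        x0 = np.zeros(x_full.shape[1])
        x0[0] = 1.0
        if i > 0:
            x0[i] = 1.0  # indicator column for this level
        x0[g:] = zbar
        est = float(x0 @ beta)
        se = float(np.sqrt(sigma2 * x0 @ xtx_inv @ x0))
        rows.append(
            {"group": lv, "mean": est,
             "ci_low": est - tcrit * se, "ci_high": est + tcrit * se}
        )
    return AdjustedMeans(pd.DataFrame(rows), conf_level)


def _feature_pvalues(
    y_matrix: np.ndarray,
    design: CohortDesign,
    n_perm: int,
    seed: int | None,
    scheme: str,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Omnibus F and permutation p for each column of ``y_matrix``.

    All columns share one set of permutations (the standard choice for a
    family of features on the same subjects). Zero-variance columns are
    skipped with NaN results. Returns (f_obs, p_perm, degenerate_mask).
    """
    if scheme != "freedman-lane":
        # fall back to per-feature calls for the comparison scheme
        f_obs = np.empty(y_matrix.shape[1])
        p = np.empty(y_matrix.shape[1])
        degenerate = np.zeros(y_matrix.shape[1], bool)
        for j in range(y_matrix.shape[1]):
            col = y_matrix[:, j]
            if np.ptp(col) == 0:
                degenerate[j] = True
                f_obs[j] = p[j] = np.nan
                continue
            f_obs[j], p[j] = permutation_pvalue(
                col, design, n_perm=n_perm, seed=seed, scheme=scheme
            )
        return f_obs, p, degenerate

    x_full, x_red, mask, g, q = _design_matrices(design)
    y = np.asarray(y_matrix, dtype=float)[mask]
    n = x_full.shape[0]
    dfn, dfd = g - 1, n - g - q
    m_full = _residual_projector(x_full)
    m_red = _residual_projector(x_red)
    degenerate = np.ptp(y, axis=0) == 0
    f_obs = _partial_f(m_full, m_red, y, dfn, dfd)
    rng = np.random.default_rng(seed)
    perms = _permutation_matrix(n, n_perm, rng)
    e = m_red @ y
    yhat = y - e
    n_ge = np.zeros(y.shape[1])
    for b in range(n_perm):
        f_b = _partial_f(m_full, m_red, yhat + e[perms[:, b]], dfn, dfd)
        n_ge += f_b >= f_obs - _F_TIE_TOL
    p = (1 + n_ge) / (1 + n_perm)
    f_obs = np.where(degenerate, np.nan, f_obs)
    p = np.where(degenerate, np.nan, p)
    if degenerate.any():
        logger.warning("%d zero-variance features skipped", int(degenerate.sum()))
    return f_obs, p, degenerate


def run_nodal_group_analysis(
    nodal: dict[str, pd.DataFrame],
    design: CohortDesign,
    n_perm: int = 10_000,
    seed: int | None = 0,
    scheme: str = "freedman-lane",
    posthoc: str = "all",
    fdr_q: float = 0.05,
) -> pd.DataFrame:
    """Omnibus permutation ANCOVA per node per measure, FDR across nodes.

    ``posthoc`` is ``"all"`` (pairwise contrasts at every node) or
    ``"survivors"`` (only nodes with FDR-adjusted omnibus p below
    ``fdr_q``). Returns a long table with one row per (measure, node),
    including per-contrast pairwise F / p / FDR-adjusted p columns.
    """
    frames = []
    for mi, (measure, table) in enumerate(nodal.items()):
        if len(table) != design.n_subjects:
            raise ValueError(
                f"{measure}: table has {len(table)} rows for "
                f"{design.n_subjects} subjects"
            )
        m_seed = None if seed is None else seed + 1000 * mi
        f_obs, p_perm, degenerate = _feature_pvalues(
            table.to_numpy(dtype=float), design, n_perm, m_seed, scheme
        )
        res = pd.DataFrame(
            {"measure": measure, "node_label": table.columns,
             "f": f_obs, "p_perm": p_perm}
        )
        res["p_fdr"] = np.nan
        ok = ~np.isnan(p_perm)
        if ok.any():
            res.loc[ok, "p_fdr"] = fdr_bh(p_perm[ok])
        run_ph = np.zeros(len(res), bool)
        if posthoc == "all":
            run_ph[:] = ok
        elif posthoc == "survivors":
            run_ph[:] = ok & (res["p_fdr"].to_numpy() < fdr_q)
        else:
            raise ValueError(f"unknown posthoc mode {posthoc!r}")
        pairs = list(combinations(design.levels, 2))
        for pair in pairs:
            tag = f"{pair[0]}_vs_{pair[1]}"
            for col in ("f", "p_perm", "p_fdr"):
                res[f"{tag}:{col}"] = np.nan
        for j in np.flatnonzero(run_ph):
            ph = posthoc_pairwise(
                table.iloc[:, j].to_numpy(dtype=float), design,
                n_perm=n_perm, seed=None if m_seed is None else m_seed + j,
                scheme=scheme,
            )
            for _, row in ph.iterrows():
                tag = row["contrast"].replace(" vs ", "_vs_")
                res.loc[res.index[j], f"{tag}:f"] = row["f"]
                res.loc[res.index[j], f"{tag}:p_perm"] = row["p_perm"]
                res.loc[res.index[j], f"{tag}:p_fdr"] = row["p_fdr"]
        frames.append(res)
    return pd.concat(frames, ignore_index=True)


def run_global_group_analysis(
    global_df: pd.DataFrame,
    design: CohortDesign,
    n_perm: int = 10_000,
    seed: int | None = 0,
    scheme: str = "freedman-lane",
) -> pd.DataFrame:
    """Permutation ANCOVA for each global measure, reported uncorrected.

    The five global measures form a small, heterogeneous family; p-values
    are reported raw (no across-feature FDR).
    """
    if len(global_df) != design.n_subjects:
        raise ValueError("global table not aligned with design")
    f_obs, p_perm, _ = _feature_pvalues(
        global_df.to_numpy(dtype=float), design, n_perm, seed, scheme
    )
    return pd.DataFrame(
        {"measure": global_df.columns, "f": f_obs, "p_perm": p_perm}
    )
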