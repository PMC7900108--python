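"""Partial-correlation mapping of network measures onto cognitive scores.

For each patient group separately, Pearson partial correlations between a
network measure (per node, or global) and a cognitive test score are
computed controlling for age, sex and education: both variables are
residualised on the covariates by least squares and the residuals are
correlated. Nodal families (the 90 nodes within one group x score x
measure) are Benjamini-Hochberg adjusted; global measures are reported with
raw p-values. Missing scores are handled pairwise complete-case, with the
effective n recorded per cell.
"""

from __future__ import annotations

import logging
import warnings
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .inference import CohortDesign, fdr_bh

logger = logging.getLogger(__name__)

__all__ = [
    "partial_correlation", "partial_corr_pvalue", "fisher_z_contrast",
    "run_correlation_analysis", "compare_group_correlations",
]

#: Cognitive-domain assignment of the analysed scores.
DEFAULT_DOMAIN_MAP = {
    "digit_span_forward": "attention",
    "digit_span_backward": "attention",
    "trail_making_a_z": "attention",
    "trail_making_a_seconds": "attention",
    "cowat_animal": "executive",
    "cowat_market": "executive",
    "cowat_market_z": "executive",
    "cowat_lexical_g": "executive",
    "cowat_lexical_o": "executive",
    "cowat_lexical_s": "executive",
    "word_list_learning": "learning",
    "word_list_learning_z": "learning",
    "word_list_recall": "recall-recognition",
    "word_list_recall_z": "recall-recognition",
    "word_list_recognition": "recall-recognition",
    "word_list_recognition_z": "recall-recognition",
    "constructional_praxis": "visuospatial",
    "constructional_praxis_z": "visuospatial",
    "constructional_praxis_recall": "visuospatial",
    "boston_naming": "language",
    "boston_naming_z": "language",
}


class DegenerateDataError(ValueError):
    """Residual vector is constant; the correlation is undefined."""


def _residualize(v: np.ndarray, covariates: np.ndarray | None) -> np.ndarray:
    if covariates is None or covariates.size == 0:
        x = np.ones((v.size, 1))
    else:
        x = np.column_stack([np.ones(v.size), covariates])
    beta, *_ = np.linalg.lstsq(x, v, rcond=None)
    return v - x @ beta


def partial_correlation(
    x: np.ndarray, y: np.ndarray, covariates: np.ndarray | None = None
) -> float:
    """Pearson correlation of x and y after removing covariate effects.

    With no covariates this is the plain Pearson r (residualisation then
    only centres the data).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and equally long")
    z = None if covariates is None else np.atleast_2d(
        np.asarray(covariates, dtype=float)
    ).reshape(x.size, -1)
    q = 0 if z is None else z.shape[1]
    if x.size <= q + 2:
        raise ValueError(f"need n > q + 2 (n={x.size}, q={q})")
    rx = _residualize(x, z)
    ry = _residualize(y, z)
    sx = float(rx @ rx)
    sy = float(ry @ ry)
    # residuals that are zero up to lstsq round-off are degenerate
    tiny_x = 1e-20 * max(1.0, float(x @ x))
    tiny_y = 1e-20 * max(1.0, float(y @ y))
    if sx <= tiny_x or sy <= tiny_y:
        raise DegenerateDataError("constant residual vector")
    r = float(rx @ ry / np.sqrt(sx * sy))
    return float(np.clip(r, -1.0, 1.0))


def partial_corr_pvalue(r: float, n: int, q: int) -> float:
    """Two-sided p-value for a partial correlation via the t transform.

    t = r sqrt((n - 2 - q) / (1 - r^2)) on n - 2 - q degrees of freedom.
    """
    if n <= q + 2:
        raise ValueError(f"need n > q + 2 (n={n}, q={q})")
    if abs(r) > 1:
        raise ValueError("|r| cannot exceed 1")
    df = n - 2 - q
    if abs(r) == 1:
        warnings.warn("|r| = 1: p-value at the zero limit", stacklevel=2)
        return float(np.nextafter(0, 1))
    t = r * np.sqrt(df / (1 - r * r))
    return float(2 * stats.t.sf(abs(t), df))


def fisher_z_contrast(
    r1: float, n1: int, r2: float, n2: int, q: int = 0
) -> tuple[float, float]:
    """Fisher z test comparing two independent (partial) correlations.

    Effective sample sizes are reduced by the number of covariates q.
    Returns (z, two-sided p). Intended as a descriptive contrast for small
    groups; interpret with caution.
    """
    for n in (n1, n2):
        if n - q - 3 <= 0:
            raise ValueError("groups too small for the Fisher z contrast")
    z1, z2 = np.arctanh(r1), np.arctanh(r2)
    se = np.sqrt(1 / (n1 - q - 3) + 1 / (n2 - q - 3))
    z = float((z1 - z2) / se)
    return z, float(2 * stats.norm.sf(abs(z)))


def _cell(
    x: np.ndarray, y: np.ndarray, z: np.ndarray
) -> tuple[float, float, int] | None:
    """Complete-case partial correlation for one (score, feature) pair."""
    keep = np.isfinite(x) & np.isfinite(y)
    q = z.shape[1]
    if keep.sum() <= q + 2:
        return None
    try:
        r = partial_correlation(x[keep], y[keep], z[keep])
    except DegenerateDataError:
        return None
    return r, partial_corr_pvalue(r, int(keep.sum()), q), int(keep.sum())


def run_correlation_analysis(
    nodal: dict[str, pd.DataFrame],
    global_df: pd.DataFrame,
    scores: pd.DataFrame,
    design: CohortDesign,
    groups: tuple[str, ...] = ("LLD-MCI-A+", "LLD-MCI-A-"),
    score_names: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Partial correlations of every measure with every score, per group.

    The patient groups are analysed separately (controls are excluded by
    default). FDR is applied across the node family within each
    (group, score, nodal measure) triple; global-measure p-values are
    reported unadjusted. Returns a long table with columns group, score,
    scope, measure, node_label, r, p, p_fdr, n_effective.
    """
    if len(scores) != design.n_subjects or len(global_df) != design.n_subjects:
        raise ValueError("tables not aligned with design")
    score_names = tuple(score_names) if score_names is not None else tuple(
        c for c in scores.columns if c != "subject_id"
    )
    rows = []
    for group in groups:
        mask = (design.group == group).to_numpy()
        z = design.covariates[mask].to_numpy(dtype=float)
        for score in score_names:
            s = scores.loc[mask, score].to_numpy(dtype=float)
            for measure, table in nodal.items():
                fam: list[dict] = []
                n_skipped = 0
                for node in table.columns:
                    got = _cell(s, table.loc[mask, node].to_numpy(dtype=float), z)
                    if got is None:
                        n_skipped += 1
                        continue
                    r, p, n_eff = got
                    fam.append(
                        {"group": group, "score": score, "scope": "nodal",
                         "measure": measure, "node_label": node,
                         "r": r, "p": p, "n_effective": n_eff}
                    )
                if n_skipped:
                    logger.warning(
                        "%s/%s/%s: %d of %d nodes skipped (too few "
                        "complete cases or degenerate)",
                        group, score, measure, n_skipped, len(table.columns),
                    )
                if fam:
                    adj = fdr_bh([c["p"] for c in fam])
                    for c, a in zip(fam, adj):
                        c["p_fdr"] = a
                    rows.extend(fam)
            for measure in global_df.columns:
                got = _cell(
                    s, global_df.loc[mask, measure].to_numpy(dtype=float), z
                )
                if got is None:
                    continue
                r, p, n_eff = got
                rows.append(
                    {"group": group, "score": score, "scope": "global",
                     "measure": measure, "node_label": "", "r": r, "p": p,
                     "p_fdr": np.nan, "n_effective": n_eff}
                )
    cols = ["group", "score", "scope", "measure", "node_label",
            "r", "p", "p_fdr", "n_effective"]
    return pd.DataFrame(rows, columns=cols)


def compare_group_correlations(
    results: pd.DataFrame, q: int = 3
) -> pd.DataFrame:
    """Descriptive Fisher z contrasts of each correlation across group pairs."""
    keys = ["score", "scope", "measure", "node_label"]
    out = []
    for key, cell in results.groupby(keys, sort=False):
        for (_, a), (_, b) in combinations(cell.iterrows(), 2):
            z, p = fisher_z_contrast(
                a["r"], int(a["n_effective"]), b["r"], int(b["n_effective"]), q
            )
            out.append(
                dict(zip(keys, key))
                | {"group_1": a["group"], "group_2": b["group"],
                   "r_1": a["r"], "r_2": b["r"], "z": z, "p": p}
            )
    return pd.DataFrame(out)
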