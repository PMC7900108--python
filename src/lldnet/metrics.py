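"""Weighted graph-theoretic measures on structural connectomes.

Four nodal measures (degree, strength, Onnela clustering, regional
efficiency) and five global measures (edge density, total strength, network
clustering coefficient, characteristic path length, small-worldness) for
undirected, nonnegatively weighted brain networks.

Shortest paths are computed on edge *lengths* l_ij = 1 / w_ij, the standard
mapping for streamline-count weights: stronger connections are shorter.
Small-worldness is defined as the plain ratio C / L of the network
clustering coefficient to the characteristic path length; no random-network
normalisation is applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import dijkstra

from .connectome import Connectome

__all__ = [
    "NodalMetrics", "GlobalMetrics", "NODAL_MEASURES", "GLOBAL_MEASURES",
    "nodal_degree", "nodal_strength", "edge_density", "total_strength",
    "nodal_clustering", "global_clustering", "shortest_path_matrix",
    "characteristic_path_length", "small_worldness", "regional_efficiency",
    "compute_all_metrics", "compute_metric_tables", "metrics_long_table",
]

NODAL_MEASURES = ("degree", "strength", "clustering", "efficiency")
GLOBAL_MEASURES = (
    "edge_density", "total_strength", "clustering_coefficient",
    "characteristic_path_length", "small_worldness",
)


@dataclass(frozen=True)
class NodalMetrics:
    """Per-node measures, each a length-N vector aligned with node order."""

    degree: np.ndarray
    strength: np.ndarray
    clustering: np.ndarray
    efficiency: np.ndarray


@dataclass(frozen=True)
class GlobalMetrics:
    """Whole-network measures."""

    edge_density: float
    total_strength: float
    clustering_coefficient: float
    characteristic_path_length: float
    small_worldness: float


def nodal_degree(conn: Connectome) -> np.ndarray:
    """Number of neighbours of each node (edges with positive weight)."""
    return (conn.weights > 0).sum(axis=1).astype(int)


def nodal_strength(conn: Connectome) -> np.ndarray:
    """Sum of edge weights incident to each node."""
    return conn.weights.sum(axis=1)


def edge_density(conn: Connectome) -> float:
    """Fraction of the N(N-1)/2 possible node pairs that are connected."""
    n = conn.n_nodes
    if n < 2:
        raise ValueError("edge density undefined for fewer than 2 nodes")
    n_edges = int(np.count_nonzero(np.triu(conn.weights, 1)))
    return n_edges / (n * (n - 1) / 2)


def total_strength(conn: Connectome) -> float:
    """Sum of all edge weights, each undirected edge counted once."""
    return float(np.triu(conn.weights, 1).sum())


def nodal_clustering(
    conn: Connectome, normalize_weights: bool = False
) -> np.ndarray:
    """Onnela weighted clustering coefficient of each node.

    C_i = sum_{j,h} (w_ij w_ih w_jh)^(1/3) / (k_i (k_i - 1)), with C_i = 0
    for nodes of degree < 2. When ``normalize_weights`` is set, weights are
    first divided by the network maximum so that C_i lies in [0, 1]; by
    default raw streamline-count weights are used, matching toolbox output
    on unnormalised count matrices (values may then exceed 1).
    """
    w = conn.weights
    if normalize_weights and w.max() > 0:
        w = w / w.max()
    cbrt = np.cbrt(w)
    # diag of cbrt(W)^3 counts closed weighted triangles through each node
    triangles = np.diag(cbrt @ cbrt @ cbrt)
    k = nodal_degree(conn)
    denom = k * (k - 1)
    out = np.zeros(conn.n_nodes)
    np.divide(triangles, denom, out=out, where=denom > 0)
    return out


def global_clustering(conn: Connectome, normalize_weights: bool = False) -> float:
    """Network clustering coefficient: mean of the nodal values.

    Nodes with fewer than two neighbours contribute zero.
    """
    return float(nodal_clustering(conn, normalize_weights).mean())


def shortest_path_matrix(conn: Connectome) -> np.ndarray:
    """All-pairs shortest-path distances on edge lengths 1/weight.

    Unreachable pairs are ``np.inf``; the diagonal is zero.
    """
    with np.errstate(divide="ignore"):
        lengths = np.where(conn.weights > 0, 1.0 / conn.weights, 0.0)
    return dijkstra(lengths, directed=False)


def characteristic_path_length(
    conn: Connectome, distances: np.ndarray | None = None
) -> float:
    """Mean shortest-path distance over all reachable node pairs.

    Unreachable pairs are excluded with a warning (tractography networks
    are near-fully connected, so exclusion only trims isolated fragments);
    a network with no reachable pair at all is an error.
    """
    d = shortest_path_matrix(conn) if distances is None else distances
    iu = np.triu_indices_from(d, 1)
    pairs = d[iu]
    finite = np.isfinite(pairs)
    if not finite.any():
        raise ValueError(
            f"{conn.subject_id}: no reachable node pairs; "
            "characteristic path length undefined"
        )
    if not finite.all():
        warnings.warn(
            f"{conn.subject_id}: {int((~finite).sum())} unreachable node "
            "pairs excluded from characteristic path length",
            stacklevel=2,
        )
    return float(pairs[finite].mean())


def small_worldness(conn: Connectome, normalize_weights: bool = False) -> float:
    """Ratio of the network clustering coefficient to the CPL."""
    return global_clustering(conn, normalize_weights) / characteristic_path_length(conn)


def regional_efficiency(
    conn: Connectome, distances: np.ndarray | None = None
) -> np.ndarray:
    """Mean inverse shortest-path distance from each node to all others.

    E_i = (1/(N-1)) sum_{j != i} 1/d_ij, with 1/inf = 0, so isolated nodes
    score zero. On a complete unit-weight network every node scores 1.
    """
    d = shortest_path_matrix(conn) if distances is None else distances
    n = conn.n_nodes
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(d) & (d > 0), 1.0 / d, 0.0)
    np.fill_diagonal(inv, 0.0)
    return inv.sum(axis=1) / (n - 1)


def compute_all_metrics(
    conn: Connectome, normalize_weights: bool = False
) -> tuple[NodalMetrics, GlobalMetrics]:
    """Compute all nodal and global measures for one connectome.

    A single shortest-path solve is shared by the path-based measures, so
    the bundle agrees exactly with the individual calls.
    """
    d = shortest_path_matrix(conn)
    clustering = nodal_clustering(conn, normalize_weights)
    c = float(clustering.mean())
    cpl = characteristic_path_length(conn, distances=d)
    nodal = NodalMetrics(
        degree=nodal_degree(conn),
        strength=nodal_strength(conn),
        clustering=clustering,
        efficiency=regional_efficiency(conn, distances=d),
    )
    global_ = GlobalMetrics(
        edge_density=edge_density(conn),
        total_strength=total_strength(conn),
        clustering_coefficient=c,
        characteristic_path_length=cpl,
        small_worldness=c / cpl,
    )
    return nodal, global_


def compute_metric_tables(
    connectomes: list[Connectome], normalize_weights: bool = False
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Stack per-subject measures into analysis-ready tables.

    Returns ``(nodal, global_df)`` where ``nodal`` maps each nodal measure
    name to a subjects x nodes DataFrame (columns are node labels) and
    ``global_df`` is subjects x 5 global measures.
    """
    if not connectomes:
        raise ValueError("no connectomes given")
    labels = connectomes[0].node_labels
    ids = [c.subject_id for c in connectomes]
    nodal_rows: dict[str, list[np.ndarray]] = {m: [] for m in NODAL_MEASURES}
    global_rows = []
    for conn in connectomes:
        if conn.node_labels != labels:
            raise ValueError(
                f"{conn.subject_id}: node labels differ from first subject"
            )
        nm, gm = compute_all_metrics(conn, normalize_weights)
        nodal_rows["degree"].append(nm.degree)
        nodal_rows["strength"].append(nm.strength)
        nodal_rows["clustering"].append(nm.clustering)
        nodal_rows["efficiency"].append(nm.efficiency)
        global_rows.append([getattr(gm, g) for g in GLOBAL_MEASURES])
    nodal = {
        m: pd.DataFrame(np.vstack(rows), index=ids, columns=list(labels))
        for m, rows in nodal_rows.items()
    }
    global_df = pd.DataFrame(global_rows, index=ids, columns=list(GLOBAL_MEASURES))
    return nodal, global_df


def metrics_long_table(
    nodal: dict[str, pd.DataFrame], global_df: pd.DataFrame
) -> pd.DataFrame:
    """Long-format table: subject_id, scope, measure, node_label, value."""
    frames = []
    for measure, df in nodal.items():
        long = df.reset_index(names="subject_id").melt(
            id_vars="subject_id", var_name="node_label", value_name="value"
        )
        long.insert(1, "scope", "nodal")
        long.insert(2, "measure", measure)
        frames.append(long)
    glong = global_df.reset_index(names="subject_id").melt(
        id_vars="subject_id", var_name="measure", value_name="value"
    )
    glong.insert(1, "scope", "global")
    glong["node_label"] = ""
    frames.append(glong[["subject_id", "scope", "measure", "node_label", "value"]])
    return pd.concat(frames, ignore_index=True)
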