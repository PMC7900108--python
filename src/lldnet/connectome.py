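"""Subject-level structural connectome container and file I/O.

A connectome here is an undirected, weighted brain network: nodes are
parcellated grey-matter regions (by default the 90 cortical + subcortical
regions of the AAL atlas) and edge weights are streamline counts from
tractography, i.e. nonnegative reals on a count-like scale. The analysis
pipeline starts from these matrices; image processing and tractography are
upstream of this package.
"""

from __future__ import annotations

import csv
import io
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

# Relative tolerance under which a numerically asymmetric matrix is
# repaired by mirroring the upper triangle; beyond it, asymmetry is an error.
SYMMETRY_RTOL = 1e-8

#: AAL atlas node labels, 78 cortical + 12 subcortical regions, in the
#: conventional left/right interleaved atlas order.
AAL90_LABELS: tuple[str, ...] = tuple(
    f"{name}_{side}"
    for name in (
        "Precentral", "Frontal_Sup", "Frontal_Sup_Orb", "Frontal_Mid",
        "Frontal_Mid_Orb", "Frontal_Inf_Oper", "Frontal_Inf_Tri",
        "Frontal_Inf_Orb", "Rolandic_Oper", "Supp_Motor_Area", "Olfactory",
        "Frontal_Sup_Medial", "Frontal_Med_Orb", "Rectus", "Insula",
        "Cingulum_Ant", "Cingulum_Mid", "Cingulum_Post", "Hippocampus",
        "ParaHippocampal", "Amygdala", "Calcarine", "Cuneus", "Lingual",
        "Occipital_Sup", "Occipital_Mid", "Occipital_Inf", "Fusiform",
        "Postcentral", "Parietal_Sup", "Parietal_Inf", "SupraMarginal",
        "Angular", "Precuneus", "Paracentral_Lobule", "Caudate", "Putamen",
        "Pallidum", "Thalamus", "Heschl", "Temporal_Sup",
        "Temporal_Pole_Sup", "Temporal_Mid", "Temporal_Pole_Mid",
        "Temporal_Inf",
    )
    for side in ("L", "R")
)


class ConnectomeError(ValueError):
    """Raised when a connectivity matrix violates a structural invariant."""


@dataclass
class Connectome:
    """A single subject's weighted, undirected connectivity matrix.

    Parameters
    ----------
    weights
        N x N symmetric matrix of nonnegative edge weights (streamline-count
        scale); the diagonal must be zero.
    node_labels
        Ordered region names, one per node. Order defines the node index.
    subject_id
        Identifier used in result tables and error messages.
    """

    weights: np.ndarray
    node_labels: tuple[str, ...] = field(default=AAL90_LABELS)
    subject_id: str = "subject"

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.node_labels = tuple(self.node_labels)
        self._validate()

    def _validate(self) -> None:
        w = self.weights
        sid = self.subject_id
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ConnectomeError(
                f"{sid}: weight matrix must be square, got shape {w.shape}"
            )
        if len(self.node_labels) != w.shape[0]:
            raise ConnectomeError(
                f"{sid}: {len(self.node_labels)} node labels for "
                f"{w.shape[0]} nodes"
            )
        if not np.all(np.isfinite(w)):
            i, j = np.argwhere(~np.isfinite(w))[0]
            raise ConnectomeError(f"{sid}: non-finite weight at ({i}, {j})")
        if np.any(w < 0):
            i, j = np.argwhere(w < 0)[0]
            raise ConnectomeError(
                f"{sid}: negative weight {w[i, j]!r} at ({i}, {j})"
            )
        if np.any(np.diag(w) != 0):
            i = int(np.flatnonzero(np.diag(w))[0])
            raise ConnectomeError(
                f"{sid}: nonzero diagonal entry at node {i} "
                f"({self.node_labels[i]})"
            )
        scale = max(np.abs(w).max(), 1.0)
        asym = np.abs(w - w.T)
        if asym.max() > SYMMETRY_RTOL * scale:
            i, j = np.unravel_index(np.argmax(asym), asym.shape)
            raise ConnectomeError(
                f"{sid}: asymmetric weights at ({i}, {j}): "
                f"{w[i, j]!r} vs {w[j, i]!r}"
            )
        if asym.max() > 0:
            # numerically asymmetric within tolerance: mirror upper triangle
            logger.warning(
                "%s: mirroring upper triangle (max asymmetry %.3g)",
                sid, asym.max(),
            )
            w = np.triu(w, 1)
            self.weights = w + w.T

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]


def _sniff_delimiter(text: str) -> str | None:
    """Guess the column delimiter of a numeric matrix file.

    Returns None for whitespace-delimited content (numpy's default split).
    """
    sample = "\n".join(text.splitlines()[:5])
    try:
        return csv.Sniffer().sniff(sample, delimiters=",\t;").delimiter
    except csv.Error:
        return None


def read_matrix(
    path: str | Path,
    node_labels: tuple[str, ...] | None = None,
    subject_id: str | None = None,
) -> Connectome:
    """Read a square connectivity matrix from CSV/TSV/whitespace text.

    An optional single header row of node labels is detected (a first row
    that does not parse as numbers). Explicit ``node_labels`` override any
    header labels.
    """
    path = Path(path)
    text = path.read_text()
    delim = _sniff_delimiter(text)
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise ConnectomeError(f"{path}: empty matrix file")

    def _split(line: str) -> list[str]:
        return line.split(delim) if delim else line.split()

    header: tuple[str, ...] | None = None
    try:
        [float(tok) for tok in _split(lines[0])]
    except ValueError:
        header = tuple(tok.strip() for tok in _split(lines[0]))
        lines = lines[1:]
    rows = [[float(tok) for tok in _split(ln)] for ln in lines]
    weights = np.asarray(rows, dtype=float)
    labels = node_labels or header or tuple(
        f"node_{i}" for i in range(weights.shape[0] if weights.ndim == 2 else 0)
    )
    return Connectome(weights, labels, subject_id or path.stem)


def read_node_labels(path: str | Path) -> tuple[str, ...]:
    """Read one region label per line; line order defines node index."""
    lines = Path(path).read_text().splitlines()
    return tuple(ln.strip() for ln in lines if ln.strip())


def write_matrix(conn: Connectome, path: str | Path) -> None:
    """Write a connectome as CSV with a node-label header row."""
    buf = io.StringIO()
    buf.write(",".join(conn.node_labels) + "\n")
    np.savetxt(buf, conn.weights, delimiter=",", fmt="%.10g")
    Path(path).write_text(buf.getvalue())
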