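"""Study loading, run configuration, and result writers.

A study on disk is a directory of per-subject matrix files named
``<subject_id>.csv``, a metadata CSV (``subject_id, group, age, sex,
education`` plus optional score columns), and an optional node-label file
(one label per line). Every analysis run writes its fully resolved
configuration next to its outputs so results are self-describing and
re-runnable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict, field
from pathlib import Path

import pandas as pd

from .connectome import Connectome, read_matrix, read_node_labels, write_matrix
from .inference import GROUPS, CohortDesign

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "load_study", "write_study", "write_run_config"]

COVARIATE_COLUMNS = ("age", "sex", "education")
METADATA_COLUMNS = ("subject_id", "group") + COVARIATE_COLUMNS


@dataclass
class RunConfig:
    """Resolved options of one analysis run; round-trips via key=value text."""

    matrix_dir: str = ""
    metadata: str = ""
    labels: str = ""
    output_dir: str = "results"
    n_perm: int = 10_000
    seed: int = 0
    scheme: str = "freedman-lane"
    normalize_clustering: bool = False
    fdr_q: float = 0.05
    conf_level: float = 0.95
    posthoc: str = "all"
    correlate_groups: tuple[str, ...] = ("LLD-MCI-A+", "LLD-MCI-A-")

    def to_file(self, path: str | Path) -> None:
        lines = []
        for key, value in asdict(self).items():
            if isinstance(value, tuple):
                value = ",".join(map(str, value))
            lines.append(f"{key}={value}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        kwargs: dict = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, raw = line.partition("=")
            key = key.strip()
            raw = raw.strip()
            if key not in cls.__dataclass_fields__:
                raise ValueError(f"unknown config key {key!r}")
            kind = cls.__dataclass_fields__[key].type
            if key == "correlate_groups":
                kwargs[key] = tuple(t for t in raw.split(",") if t)
            elif kind == "int":
                kwargs[key] = int(raw)
            elif kind == "float":
                kwargs[key] = float(raw)
            elif kind == "bool":
                kwargs[key] = raw.lower() in ("1", "true", "yes", "on")
            else:
                kwargs[key] = raw
        return cls(**kwargs)


def load_study(
    matrix_dir: str | Path,
    metadata: str | Path,
    labels: str | Path | None = None,
) -> tuple[list[Connectome], CohortDesign, pd.DataFrame]:
    """Load matrices plus metadata, aligned in canonical subject order.

    Subjects are ordered by group (canonical group order, then subject id)
    so that downstream results do not depend on metadata row order.
    Validation problems are aggregated and reported together with subject
    ids. Returns (connectomes, design, scores) where ``scores`` holds any
    metadata columns beyond the design columns.
    """
    matrix_dir = Path(matrix_dir)
    meta = pd.read_csv(metadata)
    missing_cols = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing_cols:
        raise ValueError(f"metadata is missing columns: {missing_cols}")
    unknown = sorted(set(meta["group"]) - set(GROUPS))
    if unknown:
        raise ValueError(
            f"unknown group labels {unknown}; expected one of {list(GROUPS)}"
        )
    order = {g: i for i, g in enumerate(GROUPS)}
    meta = meta.sort_values(
        ["group", "subject_id"], key=lambda s: s.map(order).fillna(s)
    ).reset_index(drop=True)

    node_labels = read_node_labels(labels) if labels else None
    problems: list[str] = []
    conns: list[Connectome] = []
    for sid in meta["subject_id"]:
        path = matrix_dir / f"{sid}.csv"
        if not path.exists():
            problems.append(f"{sid}: missing matrix file {path}")
            continue
        try:
            conns.append(read_matrix(path, node_labels, subject_id=sid))
        except ValueError as err:
            problems.append(str(err))
    if not problems and len({c.n_nodes for c in conns}) > 1:
        problems.append("matrices have differing node counts")
    if problems:
        raise ValueError(
            "study validation failed:\n  " + "\n  ".join(problems)
        )
    design = CohortDesign(meta["group"], meta[list(COVARIATE_COLUMNS)])
    score_cols = [c for c in meta.columns if c not in METADATA_COLUMNS]
    scores = meta[["subject_id"] + score_cols]
    return conns, design, scores


def write_study(cohort, out_dir: str | Path) -> Path:
    """Write a synthetic cohort as a loadable study directory."""
    out = Path(out_dir)
    (out / "matrices").mkdir(parents=True, exist_ok=True)
    meta = cohort.subjects.copy()
    if cohort.scores is not None:
        meta = meta.merge(cohort.scores, on="subject_id")
    meta.to_csv(out / "metadata.csv", index=False)
    for conn in cohort.connectomes or ():
        write_matrix(conn, out / "matrices" / f"{conn.subject_id}.csv")
    if cohort.connectomes:
        (out / "node_labels.txt").write_text(
            "\n".join(cohort.connectomes[0].node_labels) + "\n"
        )
    lines = []
    for key, value in cohort.ledger.items():
        lines.append(f"{key}={value!r}")
    (out / "ground_truth.txt").write_text("\n".join(lines) + "\n")
    return out


def write_run_config(config: RunConfig, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_file(out / "run_config.txt")
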