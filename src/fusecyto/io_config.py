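"""Expression-matrix I/O, run configuration, and structured reports.

Input is the universal interchange format for segmented-cytometry tables:
delimited text (comma or tab, auto-detected) with one header row of marker
names and one row per cell, optionally carrying a per-cell annotation column
of manually curated cell-type labels. No normalization or transformation is
applied on load — preprocessing is the caller's responsibility, matching
the convention that each dataset is clustered exactly as processed by its
source study. Rows with missing entries are rejected, not imputed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .evaluation import Partition
from .metrics import ALL_METRICS

REPORT_SCHEMA_VERSION = 1


class ValidationError(ValueError):
    pass


@dataclass
class ExpressionMatrix:
    """N cells x M markers of nonnegative intensities with ids and optional labels."""

    values: np.ndarray
    cell_ids: list[str]
    marker_names: list[str]
    annotations: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n, m = self.values.shape
        if n < 2 or m < 2:
            raise ValidationError("need at least 2 cells and 2 markers")
        if np.isnan(self.values).any():
            raise ValidationError("missing values are rejected, not imputed")
        if len(self.cell_ids) != n:
            raise ValidationError("cell_ids length mismatch")
        if len(set(self.cell_ids)) != n:
            raise ValidationError("cell_ids must be unique")
        if len(self.marker_names) != m:
            raise ValidationError("marker_names length mismatch")
        if len(set(self.marker_names)) != m:
            raise ValidationError("duplicate marker names")
        if self.annotations is not None and len(self.annotations) != n:
            raise ValidationError("annotations must have one entry per cell")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_markers(self) -> int:
        return self.values.shape[1]

    def subset(self, rows: np.ndarray) -> "ExpressionMatrix":
        rows = np.asarray(rows)
        return ExpressionMatrix(
            values=self.values[rows],
            cell_ids=[self.cell_ids[i] for i in rows],
            marker_names=list(self.marker_names),
            annotations=(
                [self.annotations[i] for i in rows] if self.annotations else None
            ),
        )


@dataclass
class RunConfig:
    """Configuration of one clustering run.

    Defaults reproduce the reference configuration: the fused view set
    (pearson, spearman, cosine, euclidean), data-driven square grid, 20K-cell
    subsamples, five repeats, alpha = 0.05.
    """

    metric_set: list[str] = field(
        default_factory=lambda: ["pearson", "spearman", "cosine", "euclidean"]
    )
    k: int | None = None
    grid_side: int | None = None
    seed: int = 42
    subsample_size: int = 20000
    n_repeats: int = 5
    alpha: float = 0.05
    som_epochs: int = 10
    min_grid_side: int = 5

    def __post_init__(self) -> None:
        bad = [m for m in self.metric_set if m not in ALL_METRICS]
        if bad:
            raise ValidationError(f"unknown metric names: {bad}")
        if not self.metric_set:
            raise ValidationError("metric_set must be nonempty")
        if self.k is not None and self.k < 1:
            raise ValidationError("k must be positive")
        if self.grid_side is not None and self.grid_side < 2:
            raise ValidationError("grid_side must be >= 2")
        if self.subsample_size < 1 or self.n_repeats < 1:
            raise ValidationError("subsample_size and n_repeats must be positive")
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must be in (0, 1)")


def _detect_sep(path: Path) -> str:
    header = path.open().readline()
    return "\t" if header.count("\t") >= header.count(",") and "\t" in header else ","


def read_expression_matrix(
    path, annotation_column: str | None = None
) -> ExpressionMatrix:
    """Load a delimited cell-by-marker table; header row holds marker names.

    ``annotation_column``, when given, is split out of the numeric block as
    per-cell labels. Nonnumeric entries in marker columns and duplicate
    marker names are errors.
    """
    path = Path(path)
    sep = _detect_sep(path)
    header = path.open().readline().rstrip("\n").split(sep)
    seen = set()
    for name in header:  # pandas silently renames duplicates, so check raw
        if name in seen:
            raise ValidationError(f"duplicate marker name {name!r} in header")
        seen.add(name)
    df = pd.read_csv(path, sep=sep, dtype=str)

    annotations = None
    if annotation_column is not None:
        if annotation_column not in df.columns:
            raise ValidationError(
                f"annotation column {annotation_column!r} not found in header"
            )
        annotations = df[annotation_column].astype(str).tolist()
        df = df.drop(columns=[annotation_column])

    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        try:
            values[:, j] = pd.to_numeric(df[col], errors="raise")
        except (ValueError, TypeError) as exc:
            bad = pd.to_numeric(df[col], errors="coerce")
            row = int(np.where(bad.isna() & df[col].notna())[0][0]) if bad.isna().any() else -1
            raise ValidationError(
                f"nonnumeric entry in marker column {col!r}, data row {row}"
            ) from exc
    cell_ids = [str(i) for i in range(values.shape[0])]
    return ExpressionMatrix(
        values=values,
        cell_ids=cell_ids,
        marker_names=[str(c) for c in df.columns],
        annotations=annotations,
    )


def write_expression_matrix(data: ExpressionMatrix, path, truth_path=None) -> None:
    """Write a matrix as CSV; annotations go to ``truth_path`` when given."""
    df = pd.DataFrame(data.values, columns=data.marker_names)
    df.to_csv(path, index=False)
    if truth_path is not None and data.annotations is not None:
        pd.DataFrame(
            {"cell_id": data.cell_ids, "annotation": data.annotations}
        ).to_csv(truth_path, index=False)


def write_partition(partition: Partition, path, cell_ids=None) -> None:
    """Two-column CSV (cell_id, cluster_label); round-trips losslessly."""
    if len(partition) == 0:
        raise ValidationError("cannot write an empty partition")
    ids = cell_ids or [str(i) for i in range(len(partition))]
    pd.DataFrame({"cell_id": ids, "cluster_label": partition.labels}).to_csv(
        path, index=False
    )


def read_partition(path, method: str = "", seed: int = 0) -> Partition:
    df = pd.read_csv(path, dtype={"cell_id": str})
    if "cluster_label" not in df.columns:
        raise ValidationError("partition file must have a cluster_label column")
    return Partition(labels=df["cluster_label"].to_numpy(), method=method, seed=seed)


def write_report(report: dict, path) -> None:
    """Schema-versioned JSON report of scores keyed by method/metric/repeat."""
    if "seed" not in report:
        raise ValidationError("report must carry the seed it was produced with")
    payload = {"schema_version": REPORT_SCHEMA_VERSION, **report}
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def read_report(path) -> dict:
    payload = json.loads(Path(path).read_text())
    if payload.get("schema_version") != REPORT_SCHEMA_VERSION:
        raise ValidationError("unsupported report schema version")
    return payload


def load_config(path) -> RunConfig:
    """Read a YAML-style key/value config file into a RunConfig."""
    import yaml

    raw = yaml.safe_load(Path(path).read_text()) or {}
    if "metric_set" in raw and isinstance(raw["metric_set"], str):
        raw["metric_set"] = [m.strip() for m in raw["metric_set"].split(",")]
    return RunConfig(**raw)
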