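"""Matrix containers shared by all pipeline stages.

Every matrix is region-major in the canonical atlas order; construction
validates shape, missingness and (for connectomes) symmetry so that later
stages can assume clean inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .atlas import Atlas

METRIC_NAMES = ("SV", "ReHo", "NS", "NS_short", "NS_long", "CT", "FA", "MD")


@dataclass
class MetricMatrix:
    """Subjects x regions values for one named metric."""

    metric_name: str
    values: np.ndarray
    subject_ids: list[str]
    region_ids: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, float)
        self.region_ids = np.asarray(self.region_ids, int)
        if self.metric_name not in METRIC_NAMES:
            raise ValueError(f"unknown metric name {self.metric_name!r}")
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (subjects x regions)")
        if self.values.shape != (len(self.subject_ids), len(self.region_ids)):
            raise ValueError("values shape does not match subject/region ids")
        if np.isnan(self.values).any():
            subj, reg = np.nonzero(np.isnan(self.values))
            cells = [(self.subject_ids[s], int(self.region_ids[r]))
                     for s, r in zip(subj[:5], reg[:5])]
            raise ValueError(f"NaN values at (subject, region): {cells}")

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=pd.Index(self.subject_ids, name="subject_id"),
                            columns=self.region_ids)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    def align_to(self, atlas: Atlas) -> "MetricMatrix":
        """Reorder columns to the canonical atlas region order."""
        order = [list(self.region_ids).index(r) for r in atlas.region_ids]
        return MetricMatrix(self.metric_name, self.values[:, order],
                            self.subject_ids, atlas.region_ids)


@dataclass
class Connectome:
    """Weighted symmetric structural connectivity (zero diagonal)."""

    weights: np.ndarray
    region_ids: np.ndarray

    def __post_init__(self):
        w = np.asarray(self.weights, float)
        self.region_ids = np.asarray(self.region_ids, int)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("connectome must be square")
        if w.shape[0] != len(self.region_ids):
            raise ValueError("connectome size does not match region ids")
        if np.isnan(w).any():
            raise ValueError("connectome contains NaN")
        if not np.allclose(w, w.T, atol=1e-10):
            raise ValueError("connectome must be symmetric")
        if (w < 0).any():
            raise ValueError("connectome weights must be nonnegative")
        if np.abs(np.diag(w)).max() > 1e-12:
            raise ValueError("connectome diagonal must be zero")
        self.weights = 0.5 * (w + w.T)
        np.fill_diagonal(self.weights, 0.0)

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.weights, index=self.region_ids,
                     columns=self.region_ids).to_csv(path, sep="\t")


@dataclass
class VertexData:
    """Per-subject vertex-level BOLD time series with region map and adjacency."""

    timeseries: np.ndarray          # vertices x T
    vertex_region: np.ndarray       # vertex -> region_id
    vertex_neighbors: list = field(default_factory=list)

    def __post_init__(self):
        self.timeseries = np.asarray(self.timeseries, float)
        self.vertex_region = np.asarray(self.vertex_region, int)
        if self.timeseries.ndim != 2:
            raise ValueError("timeseries must be vertices x T")
        if self.timeseries.shape[1] < 3:
            raise ValueError("need at least 3 time points")
        if len(self.vertex_region) != self.timeseries.shape[0]:
            raise ValueError("vertex_region length mismatch")
        if len(self.vertex_neighbors) != self.timeseries.shape[0]:
            raise ValueError("vertex_neighbors length mismatch")
        for v, nbrs in enumerate(self.vertex_neighbors):
            for u in nbrs:
                if u == v:
                    raise ValueError(f"vertex {v} adjacent to itself")
                if v not in self.vertex_neighbors[u]:
                    raise ValueError("vertex adjacency must be symmetric")

    @property
    def n_vertices(self) -> int:
        return self.timeseries.shape[0]

    @property
    def T(self) -> int:
        return self.timeseries.shape[1]


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------

def read_matrix(path, kind: str, atlas: Atlas, metric_name: str | None = None):
    """Read a TSV matrix and validate it against the atlas.

    ``kind`` is ``"metric"`` (subjects x regions, index column = subject id)
    or ``"connectome"`` (square, region ids on both axes).  Columns are
    harmonized to the canonical atlas order.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.columns = df.columns.astype(int)
    cols = df.columns.to_numpy()
    if set(cols) != set(atlas.region_ids):
        raise ValueError(f"{path}: region columns do not match atlas")
    if kind == "connectome":
        if df.shape[0] != df.shape[1]:
            raise ValueError(f"{path}: connectome file must be square")
        df.index = df.index.astype(int)
        df = df.loc[atlas.region_ids, :]
        df = df[atlas.region_ids]
        return Connectome(df.to_numpy(float), atlas.region_ids)
    if kind == "metric":
        if metric_name is None:
            raise ValueError("metric_name required for kind='metric'")
        df = df[atlas.region_ids]
        vals = df.to_numpy(float)
        if np.isnan(vals).any():
            subj, reg = np.nonzero(np.isnan(vals))
            cells = [(df.index[s], int(atlas.region_ids[r]))
                     for s, r in zip(subj[:5], reg[:5])]
            raise ValueError(f"{path}: NaN at (subject, region): {cells}")
        return MetricMatrix(metric_name, vals, list(df.index.astype(str)), atlas.region_ids)
    raise ValueError(f"unknown matrix kind {kind!r}")


def write_matrix(obj, path) -> None:
    obj.to_tsv(path)


def write_vertex_data(directory, subject_id: str, vd: VertexData) -> None:
    """Write one subject's vertex series plus (shared) region map/adjacency.

    Layout: ``<sid>_timeseries.tsv`` (vertices x T, no header),
    ``vertex_region.tsv`` (one region id per line) and
    ``vertex_neighbors.tsv`` (comma-separated neighbour ids per line).
    """
    from pathlib import Path
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    np.savetxt(d / f"{subject_id}_timeseries.tsv", vd.timeseries, delimiter="\t")
    np.savetxt(d / "vertex_region.tsv", vd.vertex_region, fmt="%d")
    with open(d / "vertex_neighbors.tsv", "w") as fh:
        for nbrs in vd.vertex_neighbors:
            fh.write(",".join(map(str, nbrs)) + "\n")


def read_vertex_data(directory, subject_id: str) -> VertexData:
    from pathlib import Path
    d = Path(directory)
    ts = np.loadtxt(d / f"{subject_id}_timeseries.tsv", delimiter="\t", ndmin=2)
    region = np.loadtxt(d / "vertex_region.tsv", dtype=int, ndmin=1)
    neighbors = []
    with open(d / "vertex_neighbors.tsv") as fh:
        for line in fh:
            line = line.strip()
            neighbors.append([int(x) for x in line.split(",")] if line else [])
    return VertexData(ts, region, neighbors)
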