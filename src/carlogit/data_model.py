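"""Crash records, severity coding, segment adjacency, and dataset I/O.

The modelling unit is a *crash* with an ordered three-level severity outcome
(1 = light, 2 = medium, 3 = severe), a propensity covariate vector ``x`` and a
threshold covariate vector ``z`` (both carrying a leading constant 1), and the
index of the roadway segment it occurred on.  Segments carry a symmetric
binary first-order proximity structure; on a linear freeway corridor the
natural default is a chain (path) graph over consecutive segments.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "GraphError",
    "SeverityCoding",
    "DEFAULT_CODING",
    "CrashRecord",
    "SegmentGraph",
    "CrashDataset",
    "collapse_severity",
    "chain_graph",
    "load_dataset",
    "write_dataset",
]


class SchemaError(ValueError):
    """A required column or mapping is missing or malformed."""


class GraphError(ValueError):
    """The adjacency structure is inconsistent with the segment set."""


@dataclass(frozen=True)
class SeverityCoding:
    """Mapping from raw severity labels to the modelled ordinal levels.

    The administrative classification distinguishes four ordered levels; the
    two most severe are so rare that they are collapsed into a single top
    level, giving the modelled coding 1 = light, 2 = medium, 3 = severe.
    """

    raw_levels: tuple[str, ...] = ("light", "medium", "severe", "very_severe")
    collapse_map: Mapping[str, int] = field(
        default_factory=lambda: {
            "light": 1,
            "medium": 2,
            "severe": 3,
            "very_severe": 3,
        }
    )

    def __post_init__(self) -> None:
        levels = [self.collapse_map[r] for r in self.raw_levels]
        if levels != sorted(levels):
            raise ValueError("collapse_map must be order-preserving")
        if set(levels) != {1, 2, 3}:
            raise ValueError("collapsed levels must be exactly {1, 2, 3}")

    def encode(self, label: object) -> int:
        """Map a raw label (or an already-coded 1/2/3 integer) to a level."""
        if isinstance(label, (int, np.integer)) and not isinstance(label, bool):
            if int(label) not in (1, 2, 3):
                raise ValueError(f"severity level {label!r} outside {{1,2,3}}")
            return int(label)
        key = str(label)
        if key not in self.collapse_map:
            raise ValueError(f"unknown severity label {label!r}")
        return int(self.collapse_map[key])


DEFAULT_CODING = SeverityCoding()


@dataclass(frozen=True)
class CrashRecord:
    """One crash: severity level, covariates, and segment index (1-based)."""

    severity: int
    x: np.ndarray
    z: np.ndarray
    segment: int

    def __post_init__(self) -> None:
        if self.severity not in (1, 2, 3):
            raise ValueError("severity must be in {1, 2, 3}")
        if self.x[0] != 1.0 or self.z[0] != 1.0:
            raise ValueError("x and z must carry a leading constant 1")
        if self.segment < 1:
            raise ValueError("segment indices are 1-based")


@dataclass(frozen=True)
class SegmentGraph:
    """Symmetric binary proximity over ``n_segments`` roadway segments.

    Edges are stored as unordered 1-based pairs; ω(m,n) ∈ {0,1}, ω(m,m) = 0.
    """

    n_segments: int
    edges: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.n_segments < 1:
            raise GraphError("need at least one segment")
        seen = set()
        for a, b in self.edges:
            if a == b:
                raise GraphError(f"self-loop on segment {a}")
            if not (1 <= a <= self.n_segments and 1 <= b <= self.n_segments):
                raise GraphError(
                    f"edge ({a},{b}) references a segment outside 1..{self.n_segments}"
                )
            key = (min(a, b), max(a, b))
            if key in seen:
                raise GraphError(f"duplicate edge {key}")
            seen.add(key)
        object.__setattr__(
            self, "edges", tuple(sorted((min(a, b), max(a, b)) for a, b in self.edges))
        )

    # -- derived structure ------------------------------------------------
    def edge_array(self) -> np.ndarray:
        """(E, 2) int array of 0-based endpoint indices."""
        if not self.edges:
            return np.empty((0, 2), dtype=np.intp)
        return np.asarray(self.edges, dtype=np.intp) - 1

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_segments, dtype=np.intp)
        for a, b in self.edges:
            deg[a - 1] += 1
            deg[b - 1] += 1
        return deg

    def neighbors(self, m: int) -> tuple[int, ...]:
        """1-based neighbours of 1-based segment ``m``."""
        out = []
        for a, b in self.edges:
            if a == m:
                out.append(b)
            elif b == m:
                out.append(a)
        return tuple(sorted(out))

    def islands(self) -> np.ndarray:
        """0-based indices of degree-0 segments."""
        return np.flatnonzero(self.degrees() == 0)

    @property
    def n_islands(self) -> int:
        return int(self.islands().size)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(1, self.n_segments + 1))
        g.add_edges_from(self.edges)
        return g

    def components(self) -> list[np.ndarray]:
        """Connected components with ≥2 nodes, as 0-based index arrays."""
        comps = []
        for comp in nx.connected_components(self.to_networkx()):
            if len(comp) > 1:
                comps.append(np.asarray(sorted(comp), dtype=np.intp) - 1)
        return comps

    @property
    def df_prior(self) -> int:
        """Degrees of freedom of the intrinsic CAR field: Σ_c (|c| − 1).

        Islands are excluded (their effect is pinned at 0), and each connected
        component loses one degree of freedom to the flat direction.
        """
        return sum(len(c) - 1 for c in self.components())

    def laplacian(self) -> np.ndarray:
        """Dense graph Laplacian D − W (0-based ordering)."""
        L = np.diag(self.degrees().astype(float))
        for a, b in self.edges:
            L[a - 1, b - 1] -= 1.0
            L[b - 1, a - 1] -= 1.0
        return L


def chain_graph(n_segments: int) -> SegmentGraph:
    """Path adjacency over consecutive segments of a linear corridor."""
    if n_segments < 1:
        raise ValueError("n_segments must be >= 1")
    edges = tuple((m, m + 1) for m in range(1, n_segments))
    return SegmentGraph(n_segments=n_segments, edges=edges)


def collapse_severity(
    counts_by_raw_level: Sequence[int],
) -> tuple[tuple[int, int, int], tuple[float, float, float]]:
    """Collapse four raw severity counts to the modelled three levels.

    Returns ``(counts, shares)`` where shares are percentages of the total.
    The two most severe raw levels are pooled into the modelled top level.
    """
    if len(counts_by_raw_level) != 4:
        raise ValueError("expected four raw-level counts")
    counts = [int(c) for c in counts_by_raw_level]
    if any(c < 0 for c in counts):
        raise ValueError("counts must be nonnegative")
    light, medium, severe, very_severe = counts
    collapsed = (light, medium, severe + very_severe)
    total = sum(collapsed)
    if total == 0:
        raise ValueError("at least one crash required")
    shares = tuple(100.0 * c / total for c in collapsed)
    return collapsed, shares  # type: ignore[return-value]


@dataclass(frozen=True)
class CrashDataset:
    """A crash table in design-matrix form plus the segment graph.

    ``X`` (propensity side) and ``Z`` (threshold side) both carry a leading
    constant column; the same source column may appear on both sides.
    ``segments`` are 1-based and every index must exist in ``graph``.
    """

    y: np.ndarray
    X: np.ndarray
    Z: np.ndarray
    segments: np.ndarray
    x_names: tuple[str, ...]
    z_names: tuple[str, ...]
    graph: SegmentGraph

    def __post_init__(self) -> None:
        y = np.asarray(self.y, dtype=np.intp)
        X = np.asarray(self.X, dtype=float)
        Z = np.asarray(self.Z, dtype=float)
        seg = np.asarray(self.segments, dtype=np.intp)
        n = y.shape[0]
        if X.shape != (n, len(self.x_names)) or Z.shape != (n, len(self.z_names)):
            raise SchemaError("design-matrix shapes do not match covariate names")
        if seg.shape != (n,):
            raise SchemaError("segments must be one index per crash")
        if n:
            if not np.isin(y, (1, 2, 3)).all():
                raise ValueError("severity levels must be in {1, 2, 3}")
            if not (np.all(X[:, 0] == 1.0) and np.all(Z[:, 0] == 1.0)):
                raise SchemaError("first column of X and Z must be the constant 1")
            if not (np.isfinite(X).all() and np.isfinite(Z).all()):
                raise ValueError("covariates contain missing or non-finite values")
            if seg.min() < 1 or seg.max() > self.graph.n_segments:
                raise GraphError("crash assigned to a segment outside the graph")
        if len(set(self.x_names)) != len(self.x_names) or len(set(self.z_names)) != len(
            self.z_names
        ):
            raise SchemaError("covariate names must be unique within each side")
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "Z", Z)
        object.__setattr__(self, "segments", seg)

    @property
    def n_crashes(self) -> int:
        return int(self.y.shape[0])

    @property
    def n_segments(self) -> int:
        return self.graph.n_segments

    def record(self, i: int) -> CrashRecord:
        return CrashRecord(
            severity=int(self.y[i]),
            x=self.X[i].copy(),
            z=self.Z[i].copy(),
            segment=int(self.segments[i]),
        )

    def __iter__(self) -> Iterable[CrashRecord]:
        return (self.record(i) for i in range(self.n_crashes))

    def severity_shares(self) -> tuple[float, float, float]:
        """Percentage of crashes at each modelled level."""
        n = max(self.n_crashes, 1)
        return tuple(100.0 * float((self.y == j).sum()) / n for j in (1, 2, 3))  # type: ignore[return-value]

    def to_frame(self) -> pd.DataFrame:
        """Flat table: severity, segment, and the union of covariate columns."""
        cols: dict[str, np.ndarray] = {
            "severity": self.y,
            "segment": self.segments,
        }
        for j, name in enumerate(self.x_names):
            if name != "constant":
                cols[name] = self.X[:, j]
        for j, name in enumerate(self.z_names):
            if name != "constant" and name not in cols:
                cols[name] = self.Z[:, j]
        return pd.DataFrame(cols)


def _build_design(
    frame: pd.DataFrame, columns: Sequence[str], side: str
) -> tuple[np.ndarray, tuple[str, ...]]:
    missing = [c for c in columns if c not in frame.columns]
    if missing:
        raise SchemaError(f"{side} covariate column(s) missing: {missing}")
    n = len(frame)
    mat = np.ones((n, len(columns) + 1))
    for j, c in enumerate(columns):
        mat[:, j + 1] = pd.to_numeric(frame[c], errors="raise").to_numpy(dtype=float)
    return mat, ("constant", *columns)


def load_dataset(
    crash_table: str | Path | pd.DataFrame,
    edge_list: str | Path | pd.DataFrame | None = None,
    schema: Mapping[str, object] | str | Path | None = None,
    *,
    n_segments: int | None = None,
    coding: SeverityCoding = DEFAULT_CODING,
) -> CrashDataset:
    """Assemble a validated :class:`CrashDataset` from tabular inputs.

    Parameters
    ----------
    crash_table
        CSV path or DataFrame with columns ``severity``, ``segment`` and the
        covariates named by ``schema``.
    edge_list
        Two-column CSV/DataFrame of 1-based segment pairs.  If omitted, a
        chain graph over ``n_segments`` (default: the largest observed
        segment index) is used — the natural adjacency for consecutive
        segments of a linear corridor.
    schema
        Mapping (or JSON file) with keys ``propensity`` and ``threshold``
        listing covariate column names, and optionally ``severity_map``
        (label → raw level name understood by ``coding``).
    """
    if isinstance(schema, (str, Path)):
        schema = json.loads(Path(schema).read_text())
    if schema is None or "propensity" not in schema or "threshold" not in schema:
        raise SchemaError("schema must declare 'propensity' and 'threshold' columns")

    frame = (
        pd.read_csv(crash_table) if isinstance(crash_table, (str, Path)) else crash_table
    )
    for required in ("severity", "segment"):
        if required not in frame.columns:
            raise SchemaError(f"crash table lacks required column {required!r}")

    label_map = dict(schema.get("severity_map", {}))  # type: ignore[union-attr]
    y = np.array(
        [
            coding.encode(label_map.get(str(v), v) if label_map else v)
            for v in frame["severity"]
        ],
        dtype=np.intp,
    )
    segments = frame["segment"].to_numpy(dtype=np.intp)
    if len(segments) and segments.min() < 1:
        raise GraphError("segment indices are 1-based")

    if edge_list is not None:
        etab = (
            pd.read_csv(edge_list) if isinstance(edge_list, (str, Path)) else edge_list
        )
        if etab.shape[1] < 2:
            raise GraphError("edge list needs two columns")
        pairs = [tuple(map(int, row[:2])) for row in etab.itertuples(index=False)]
        M = n_segments or max(
            [max(p) for p in pairs] + ([int(segments.max())] if len(segments) else [1])
        )
        graph = SegmentGraph(n_segments=M, edges=tuple(pairs))
    else:
        M = n_segments or (int(segments.max()) if len(segments) else 1)
        graph = chain_graph(M)

    X, x_names = _build_design(frame, list(schema["propensity"]), "propensity")  # type: ignore[index]
    Z, z_names = _build_design(frame, list(schema["threshold"]), "threshold")  # type: ignore[index]
    return CrashDataset(
        y=y, X=X, Z=Z, segments=segments, x_names=x_names, z_names=z_names, graph=graph
    )


def write_dataset(
    dataset: CrashDataset, crash_path: str | Path, edge_path: str | Path
) -> None:
    """Write the crash table and edge list as CSV (1-based segment indices)."""
    dataset.to_frame().to_csv(crash_path, index=False)
    edges = pd.DataFrame(dataset.graph.edges, columns=["segment_a", "segment_b"])
    edges.to_csv(edge_path, index=False)


def dataset_schema(dataset: CrashDataset) -> dict[str, list[str]]:
    """Schema mapping that round-trips ``dataset`` through :func:`load_dataset`."""
    return {
        "propensity": [c for c in dataset.x_names if c != "constant"],
        "threshold": [c for c in dataset.z_names if c != "constant"],
    }
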