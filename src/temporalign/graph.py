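"""Temporal graphs, cumulative snapshots and the exponentially decayed
temporal influence matrix.

A temporal graph is a timestamped edge list over a fixed node registry
(growing networks only; node removal is unsupported).  The time axis is cut
into T equal-width slices; in cumulative mode snapshot t holds every edge
formed up to the upper boundary of slice t, so snapshot supports nest.  The
temporal influence matrix discounts each edge by the exponential of its age
relative to a reference time, and adds decayed self-loops so isolated nodes
still propagate their own features.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TemporalEdge",
    "TemporalGraph",
    "SnapshotSeries",
    "DecayConfig",
    "read_edge_list",
    "write_edge_list",
    "read_feature_table",
    "build_snapshots",
    "temporal_influence",
]


@dataclass(frozen=True)
class TemporalEdge:
    """One timestamped interaction; weight defaults to 1."""

    source: object
    target: object
    time: float
    weight: float = 1.0

    def __post_init__(self):
        if not np.isfinite(self.time):
            raise ValueError(f"edge timestamp must be finite, got {self.time}")
        if self.weight < 0:
            raise ValueError(f"edge weight must be nonnegative, got {self.weight}")


class TemporalGraph:
    """Timestamped edge list with a dense, first-appearance node registry.

    Node indices are 0-based, assigned in order of first appearance in the
    edge list and frozen for the lifetime of the object.
    """

    def __init__(self, edges: Sequence[TemporalEdge], directed: bool = False,
                 nodes: Optional[Dict[object, int]] = None):
        if nodes is None:
            nodes = {}
            for e in edges:
                for u in (e.source, e.target):
                    if u not in nodes:
                        nodes[u] = len(nodes)
        else:
            for e in edges:
                if e.source not in nodes or e.target not in nodes:
                    raise ValueError(
                        f"edge ({e.source}, {e.target}) references an "
                        f"unregistered node")
        self.nodes: Dict[object, int] = dict(nodes)
        self.edges: List[TemporalEdge] = list(edges)
        self.directed = bool(directed)
        times = [e.time for e in self.edges]
        self.t_min = min(times) if times else 0.0
        self.t_max = max(times) if times else 0.0

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def index_of(self, node) -> int:
        return self.nodes[node]

    def node_labels(self) -> list:
        """Node ids ordered by dense index."""
        inv = sorted(self.nodes, key=self.nodes.get)
        return inv

    def subgraph_until(self, t: float) -> "TemporalGraph":
        """Edges with timestamp <= t, keeping the full node registry."""
        kept = [e for e in self.edges if e.time <= t]
        return TemporalGraph(kept, directed=self.directed, nodes=self.nodes)

    def __repr__(self):
        kind = "directed" if self.directed else "undirected"
        return (f"TemporalGraph({self.n_nodes} nodes, {self.n_edges} edges, "
                f"{kind}, t in [{self.t_min}, {self.t_max}])")


@dataclass
class SnapshotSeries:
    """Per-slice adjacency matrices with per-entry latest edge times.

    ``A[t]`` is the (weighted) adjacency at slice t; ``edge_time[t]`` holds
    the most recent creation time of the corresponding entry (NaN where no
    edge), restricted to the edges present in ``A[t]``.  ``boundaries`` are
    the T+1 time cut points; slices are half-open [lo, hi) except the last,
    which is closed, so every edge lands in exactly one slice.
    """

    A: List[np.ndarray]
    edge_time: List[np.ndarray]
    boundaries: np.ndarray
    cumulative: bool = True
    directed: bool = False

    @property
    def T(self) -> int:
        return len(self.A)

    @property
    def n(self) -> int:
        return self.A[0].shape[0]

    def slice_index(self, time) -> np.ndarray:
        """Map raw timestamps to slice indices 0..T-1."""
        idx = np.searchsorted(self.boundaries, np.asarray(time), side="right") - 1
        return np.clip(idx, 0, self.T - 1)


@dataclass
class DecayConfig:
    """Parameters of the exponential temporal decay.

    epsilon      small positive offset keeping fresh edges strictly below 1
    mode         "per_edge": each entry decays by its own edge age;
                 "snapshot_scalar": one scalar factor per snapshot
    t_now        reference time; default is the index of the snapshot being
                 embedded (the latest information available at that step)
    time_rescale map raw timestamps to slice indices 0..T-1 before
                 exponentiation (raw second-scale gaps would underflow)
    """

    epsilon: float = 1e-5
    mode: str = "per_edge"
    t_now: Optional[float] = None
    time_rescale: bool = True

    def __post_init__(self):
        if self.epsilon <= 0:
            raise ValueError(f"epsilon must be positive, got {self.epsilon}")
        if self.mode not in ("per_edge", "snapshot_scalar"):
            raise ValueError(f"unknown decay mode {self.mode!r}")


# ---------------------------------------------------------------------------
# I/O

def read_edge_list(path, delimiter: Optional[str] = None,
                   directed: bool = False) -> TemporalGraph:
    """Read a temporal edge list: source, target, timestamp[, weight].

    Whitespace- or comma-delimited; lines starting with '#' are skipped.
    Malformed rows raise a ValueError naming the 1-based line number.
    """
    edges = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if delimiter is not None:
                parts = [p for p in line.split(delimiter) if p != ""]
            elif "," in line:
                parts = [p.strip() for p in line.split(",") if p.strip()]
            else:
                parts = line.split()
            if len(parts) < 3:
                raise ValueError(
                    f"{path}: line {lineno}: expected at least 3 columns "
                    f"(source, target, time), got {len(parts)}: {line!r}")
            try:
                t = float(parts[2])
                w = float(parts[3]) if len(parts) >= 4 else 1.0
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from None
            edges.append(TemporalEdge(parts[0], parts[1], t, w))
    if not edges:
        raise ValueError(f"{path}: no edges found")
    return TemporalGraph(edges, directed=directed)


def write_edge_list(g: TemporalGraph, path, delimiter: str = "\t") -> None:
    """Write the edge list in the format `read_edge_list` accepts."""
    with open(path, "w") as fh:
        for e in g.edges:
            fh.write(delimiter.join(
                [str(e.source), str(e.target), repr(e.time), repr(e.weight)]))
            fh.write("\n")


def read_feature_table(path, delimiter: Optional[str] = None) -> pd.DataFrame:
    """Node feature table: first column node id, remaining columns real."""
    df = pd.read_csv(path, sep=delimiter if delimiter else r"\s+|,",
                     engine="python", header=None, comment="#")
    df = df.set_index(0)
    df.index = df.index.astype(str)
    return df.astype(float)


# ---------------------------------------------------------------------------
# Snapshots

def build_snapshots(g: TemporalGraph, T: int, cumulative: bool = True,
                    t_range: Optional[tuple] = None) -> SnapshotSeries:
    """Cut the time range into T equal slices and build adjacencies.

    The range defaults to [t_min, t_max] of the graph; pass ``t_range`` to
    slice against an external window (slices outside the data are empty).
    Duplicate (i, j) occurrences sum their weights; the stored per-entry
    time is the latest occurrence.  Undirected edges are mirrored into both
    triangles.
    """
    if T < 2:
        raise ValueError(f"T must be >= 2, got {T} (a single snapshot has "
                         f"no temporal structure)")
    if g.n_edges == 0:
        raise ValueError("graph has no edges")
    lo, hi = t_range if t_range is not None else (g.t_min, g.t_max)
    if lo == hi:
        raise ValueError("all edges share one timestamp; slicing into T >= 2 "
                         "snapshots is unsupported for a single-time graph")

    n = g.n_nodes
    boundaries = np.linspace(lo, hi, T + 1)
    slice_of = lambda t: int(np.clip(
        np.searchsorted(boundaries, t, side="right") - 1, 0, T - 1))

    A = [np.zeros((n, n)) for _ in range(T)]
    E = [np.full((n, n), np.nan) for _ in range(T)]
    per_slice: List[List[TemporalEdge]] = [[] for _ in range(T)]
    for e in g.edges:
        per_slice[slice_of(e.time)].append(e)

    acc_w = np.zeros((n, n))
    acc_t = np.full((n, n), np.nan)
    for t in range(T):
        if not cumulative:
            acc_w = np.zeros((n, n))
            acc_t = np.full((n, n), np.nan)
        for e in per_slice[t]:
            i, j = g.nodes[e.source], g.nodes[e.target]
            pairs = [(i, j)] if g.directed or i == j else [(i, j), (j, i)]
            for a, b in pairs:
                acc_w[a, b] += e.weight
                prev = acc_t[a, b]
                acc_t[a, b] = e.time if np.isnan(prev) else max(prev, e.time)
        A[t] = acc_w.copy()
        E[t] = acc_t.copy()
    return SnapshotSeries(A=A, edge_time=E, boundaries=boundaries,
                          cumulative=cumulative, directed=g.directed)


def temporal_influence(s: SnapshotSeries, t: int,
                       cfg: Optional[DecayConfig] = None) -> np.ndarray:
    """Exponentially decayed adjacency-plus-self-loop matrix at step t.

    snapshot_scalar mode scales (A_t + I) by one factor exp(t - t_now - eps).
    per_edge mode decays each entry by its own edge age, with self-loops
    treated as formed at t_now (diagonal exp(-eps)).  Ages are measured on
    the slice-index axis when ``cfg.time_rescale`` (the default).
    """
    cfg = cfg or DecayConfig()
    if not 0 <= t < s.T:
        raise ValueError(f"step index {t} out of range [0, {s.T})")
    At = s.A[t]
    t_now = float(t if cfg.t_now is None else cfg.t_now)

    if cfg.mode == "snapshot_scalar":
        t_val = float(t) if cfg.time_rescale else float(s.boundaries[t + 1])
        return np.exp(t_val - (t_now + cfg.epsilon)) * (At + np.eye(s.n))

    ages = s.edge_time[t]
    if cfg.time_rescale:
        with np.errstate(invalid="ignore"):
            ages = np.where(np.isnan(ages), np.nan,
                            s.slice_index(np.nan_to_num(ages, nan=s.boundaries[0])))
    decay = np.zeros_like(At)
    mask = ~np.isnan(ages) & (At != 0)
    decay[mask] = At[mask] * np.exp(ages[mask] - (t_now + cfg.epsilon))
    decay[np.diag_indices(s.n)] += np.exp(-cfg.epsilon)
    return decay
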