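"""Synthetic growing temporal graphs with planted structure.

Two generators cover the regimes the pipeline is exercised on:

* ``simulate_dynamic_sbm`` — a growing planted-partition (stochastic block
  model) graph: communities are fixed, and at each time step new edges
  appear among the not-yet-connected pairs with higher probability inside
  communities than between them.  Edges are never removed, emulating
  weighted, timestamped interaction data (e.g. dynamic protein-interaction
  releases) with a known link-prediction signal.
* ``simulate_preferential`` — degree-proportional attachment, one arriving
  node per event, giving a heavy-tailed growing network.

Optionally, nodes carry explicit features (noisy community indicators) so
the feature-initialized embedding path is testable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from .graph import TemporalEdge, TemporalGraph, write_edge_list

__all__ = ["SimConfig", "simulate_dynamic_sbm", "simulate_preferential",
           "write_fixture", "community_labels"]


@dataclass
class SimConfig:
    """Generator parameters.

    Defaults (n=200, k=4, T=8, p_in=0.05, p_out=0.005) give a planted
    community signal large enough to train the recurrent predictor yet
    small enough for minutes-scale runs.
    """

    n: int = 200
    k: int = 4
    T: int = 8
    p_in: float = 0.05
    p_out: float = 0.005
    growth: int = 2
    weighted: bool = True
    feature_dim: Optional[int] = None
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.p_out < self.p_in <= 1):
            raise ValueError(
                f"need 0 <= p_out < p_in <= 1, got p_in={self.p_in}, "
                f"p_out={self.p_out}")
        if not (self.n >= self.k >= 1):
            raise ValueError(f"need n >= k >= 1, got n={self.n}, k={self.k}")
        if self.T < 2:
            raise ValueError(f"need T >= 2, got {self.T}")


def community_labels(cfg: SimConfig) -> np.ndarray:
    """Fixed community assignment: contiguous blocks of ~n/k nodes."""
    return np.repeat(np.arange(cfg.k), int(np.ceil(cfg.n / cfg.k)))[: cfg.n]


def simulate_dynamic_sbm(cfg: SimConfig) -> TemporalGraph:
    """Growing planted-partition graph; reproducible from cfg.seed.

    At each step t = 1..T, every not-yet-connected pair gains an edge with
    probability p_in (same community) or p_out (different), timestamped t,
    with weight ~ Uniform(0.1, 1) when weighted.
    """
    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 0)))
    comm = community_labels(cfg)
    iu, ju = np.triu_indices(cfg.n, k=1)
    same = comm[iu] == comm[ju]
    p = np.where(same, cfg.p_in, cfg.p_out)
    connected = np.zeros(iu.size, dtype=bool)

    edges = []
    for t in range(1, cfg.T + 1):
        draw = rng.random(iu.size) < p
        new = draw & ~connected
        connected |= new
        idx = np.flatnonzero(new)
        w = (rng.uniform(0.1, 1.0, size=idx.size) if cfg.weighted
             else np.ones(idx.size))
        for pos, wt in zip(idx, w):
            edges.append(TemporalEdge(int(iu[pos]), int(ju[pos]),
                                      float(t), float(wt)))
    if not edges:
        raise ValueError("no edges generated; densities are infeasible for "
                         "this n/T (increase p_in or T)")
    # register all n nodes up front so isolated nodes keep dense indices
    nodes = {i: i for i in range(cfg.n)}
    return TemporalGraph(edges, directed=False, nodes=nodes)


def node_features(cfg: SimConfig) -> Optional[pd.DataFrame]:
    """Noisy community-indicator features (None unless feature_dim set)."""
    if cfg.feature_dim is None:
        return None
    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 1)))
    comm = community_labels(cfg)
    F = rng.normal(0.0, 0.5, size=(cfg.n, cfg.feature_dim))
    for c in range(cfg.k):
        F[comm == c, c % cfg.feature_dim] += 1.0
    return pd.DataFrame(F, index=[str(i) for i in range(cfg.n)])


def simulate_preferential(cfg: SimConfig) -> TemporalGraph:
    """Degree-proportional attachment; one arriving node per event.

    Starts from a triangle at t = 0; node v (3 <= v < n) arrives at t = v-2
    and attaches to `growth` distinct existing nodes chosen with
    probability proportional to degree.
    """
    if cfg.n < 3:
        raise ValueError(f"preferential attachment needs n >= 3, got {cfg.n}")
    m = max(int(cfg.growth), 1)
    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 2)))
    deg = np.zeros(cfg.n)
    edges = [TemporalEdge(0, 1, 0.0), TemporalEdge(1, 2, 0.0),
             TemporalEdge(0, 2, 0.0)]
    deg[:3] = 2
    for v in range(3, cfg.n):
        t = float(v - 2)
        n_existing = v
        probs = deg[:n_existing] / deg[:n_existing].sum()
        k = min(m, n_existing)
        targets = rng.choice(n_existing, size=k, replace=False, p=probs)
        for u in targets:
            w = float(rng.uniform(0.1, 1.0)) if cfg.weighted else 1.0
            edges.append(TemporalEdge(int(u), v, t, w))
            deg[u] += 1
            deg[v] += 1
    nodes = {i: i for i in range(cfg.n)}
    return TemporalGraph(edges, directed=False, nodes=nodes)


def write_fixture(g: TemporalGraph, path, features: Optional[pd.DataFrame] = None,
                  feature_path=None, delimiter: str = "\t") -> None:
    """Write an edge list (and optional feature table) round-trippable
    through `read_edge_list` / `read_feature_table`."""
    write_edge_list(g, path, delimiter=delimiter)
    if features is not None:
        if feature_path is None:
            feature_path = str(path) + ".features"
        features.to_csv(feature_path, sep=delimiter, header=False)
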