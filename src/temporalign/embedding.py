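"""Untrained multi-layer graph propagation producing per-step static
latent-position matrices.

At every time step the decayed adjacency is pushed through a shallow stack
of random linear layers — no degree normalization, no nonlinearity in the
plain variant, and no training whatsoever.  Each step draws its own weights
by default, so consecutive embeddings live in unrelated bases; recovering a
common orientation is the job of the alignment module.  The "plusplus"
variant inserts a row-wise softmax nonlinearity in each layer and
concatenates a fixed cosine time encoding to every row.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, List, Optional

import numpy as np
import pandas as pd

from .graph import DecayConfig, SnapshotSeries, TemporalGraph, temporal_influence

__all__ = [
    "EmbedConfig",
    "LayerStack",
    "StaticEmbeddingSeries",
    "init_features",
    "sample_weights",
    "gnn_forward_layer",
    "static_embed_step",
    "embed_series",
    "time_encode",
    "embedding_dispersion",
]


def _default_hidden(n: int) -> int:
    return max(n // 2, 1)


@dataclass
class EmbedConfig:
    """Configuration of the untrained propagation stack.

    d                   embedding dimension (width of the final layer)
    n_layers            number of propagation layers; 3 keeps the model
                        shallow enough to avoid over-smoothing
    hidden_dim_rule     width of the intermediate layers as a function of
                        the node count; default floor(n/2)
    variant             "plain" (linear) or "plusplus" (softmax layers plus
                        a concatenated time encoding)
    weight_seed_base    base entropy for the per-layer weight draws
    fresh_weights_per_step  draw new weights at every step (default), so
                        each step is an independent embedding session
    time_enc_dim        width of the cosine time encoding (plusplus only)
    """

    d: int = 128
    n_layers: int = 3
    hidden_dim_rule: Callable[[int], int] = field(default=_default_hidden)
    variant: str = "plain"
    weight_seed_base: int = 0
    fresh_weights_per_step: bool = True
    time_enc_dim: int = 16

    def __post_init__(self):
        if self.d < 1:
            raise ValueError(f"embedding dimension must be >= 1, got {self.d}")
        if self.n_layers < 1:
            raise ValueError(f"n_layers must be >= 1, got {self.n_layers}")
        if self.variant not in ("plain", "plusplus"):
            raise ValueError(f"unknown variant {self.variant!r}")

    def layer_widths(self, n: int, f0: int) -> List[tuple]:
        """(fan_in, fan_out) per layer: f0 -> h -> ... -> h -> d."""
        h = max(int(self.hidden_dim_rule(n)), 1)
        ins = [f0] + [h] * (self.n_layers - 1)
        outs = [h] * (self.n_layers - 1) + [self.d]
        return list(zip(ins, outs))


@dataclass
class LayerStack:
    """Random weight matrices plus the initial representation."""

    W: List[np.ndarray]
    R0: np.ndarray

    def __post_init__(self):
        dim = self.R0.shape[1]
        for l, w in enumerate(self.W):
            if w.shape[0] != dim:
                raise ValueError(
                    f"layer {l}: fan-in {w.shape[0]} does not chain with "
                    f"previous width {dim}")
            dim = w.shape[1]


@dataclass
class StaticEmbeddingSeries:
    """One latent-position matrix per time step, plus provenance."""

    X: List[np.ndarray]
    variant: str = "plain"
    provenance: dict = field(default_factory=dict)

    @property
    def T(self) -> int:
        return len(self.X)

    @property
    def width(self) -> int:
        return self.X[0].shape[1]

    def save(self, directory) -> None:
        """One whitespace-delimited matrix per step + a JSON sidecar."""
        import pathlib

        directory = pathlib.Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for t, X in enumerate(self.X):
            np.savetxt(directory / f"step_{t:03d}.tsv", X, delimiter="\t")
        sidecar = {"variant": self.variant, "T": self.T,
                   "shape": list(self.X[0].shape),
                   "provenance": self.provenance}
        (directory / "series.json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, directory) -> "StaticEmbeddingSeries":
        import pathlib

        directory = pathlib.Path(directory)
        meta = json.loads((directory / "series.json").read_text())
        X = [np.loadtxt(directory / f"step_{t:03d}.tsv", delimiter="\t",
                        ndmin=2)
             for t in range(meta["T"])]
        return cls(X=X, variant=meta["variant"],
                   provenance=meta.get("provenance", {}))


# ---------------------------------------------------------------------------

def init_features(g: TemporalGraph,
                  features: Optional[pd.DataFrame] = None) -> np.ndarray:
    """Initial representation R0: one-hot identity, or explicit features.

    When a feature table is given, rows are aligned to the node registry
    order; a node missing from the table is an error.
    """
    n = g.n_nodes
    if features is None:
        return np.eye(n)
    labels = g.node_labels()
    idx = features.index
    rows = []
    for lab in labels:
        key = lab if lab in idx else str(lab)
        if key not in idx:
            raise ValueError(f"feature table is missing node {lab!r}")
        rows.append(features.loc[key].to_numpy(dtype=float))
    return np.vstack(rows)


def sample_weights(cfg: EmbedConfig, n: int, f0: int, t: int) -> "LayerStack":
    """Draw the random layer weights for step t, reproducibly.

    Entries are i.i.d. Gaussian with standard deviation 1/sqrt(fan_in),
    which keeps the activation scale stable across layers without degree
    normalization.  The seed mixes (base, step, layer) when weights are
    fresh per step, else (base, layer).
    """
    Ws = []
    for l, (fin, fout) in enumerate(cfg.layer_widths(n, f0)):
        if cfg.fresh_weights_per_step:
            entropy = (int(cfg.weight_seed_base), int(t), l)
        else:
            entropy = (int(cfg.weight_seed_base), l)
        rng = np.random.default_rng(np.random.SeedSequence(entropy))
        Ws.append(rng.normal(0.0, 1.0 / np.sqrt(fin), size=(fin, fout)))
    return LayerStack(W=Ws, R0=np.eye(n) if f0 == n else np.empty((n, f0)))


def _row_softmax(M: np.ndarray) -> np.ndarray:
    Z = M - M.max(axis=1, keepdims=True)
    E = np.exp(Z)
    return E / E.sum(axis=1, keepdims=True)


def gnn_forward_layer(A_hat: np.ndarray, R: np.ndarray, W: np.ndarray,
                      variant: str = "plain") -> np.ndarray:
    """One propagation layer.

    plain:     A_hat @ R @ W           (purely linear)
    plusplus:  A_hat @ softmax(R @ W)  (row-wise softmax nonlinearity)
    """
    if A_hat.shape[1] != R.shape[0] or R.shape[1] != W.shape[0]:
        raise ValueError(
            f"non-conformable shapes: A_hat {A_hat.shape}, R {R.shape}, "
            f"W {W.shape}")
    if variant == "plain":
        return A_hat @ R @ W
    if variant == "plusplus":
        return A_hat @ _row_softmax(R @ W)
    raise ValueError(f"unknown variant {variant!r}")


def time_encode(t: float, dim: int) -> np.ndarray:
    """Fixed cosine time encoding with geometric frequencies.

    z_k(t) = cos(omega_k * t), omega_k = 10^(-2k/dim), k = 0..dim-1.
    Deterministic, parameter-free, values in [-1, 1].
    """
    if dim < 1:
        raise ValueError(f"time encoding dimension must be >= 1, got {dim}")
    k = np.arange(dim)
    omega = 10.0 ** (-(2.0 * k) / dim)
    return np.cos(omega * float(t))


def static_embed_step(s: SnapshotSeries, t: int, cfg: EmbedConfig,
                      dcfg: Optional[DecayConfig] = None,
                      features: Optional[np.ndarray] = None) -> np.ndarray:
    """Embed one snapshot: decayed adjacency through the layer stack.

    `features`, when given, is the already-aligned R0 matrix (n x f0); by
    default the one-hot identity is used.  Returns an (n, d) matrix, or
    (n, d + time_enc_dim) for the plusplus variant.
    """
    A_hat = temporal_influence(s, t, dcfg)
    n = s.n
    R = np.eye(n) if features is None else np.asarray(features, dtype=float)
    stack = sample_weights(cfg, n, R.shape[1], t)
    for W in stack.W:
        R = gnn_forward_layer(A_hat, R, W, variant=cfg.variant)
    if cfg.variant == "plusplus":
        enc = time_encode(t, cfg.time_enc_dim)
        R = np.hstack([R, np.broadcast_to(enc, (n, cfg.time_enc_dim))])
    return R


def embed_series(s: SnapshotSeries, cfg: EmbedConfig,
                 dcfg: Optional[DecayConfig] = None,
                 features: Optional[np.ndarray] = None
                 ) -> StaticEmbeddingSeries:
    """Embed every snapshot independently."""
    X = [static_embed_step(s, t, cfg, dcfg, features) for t in range(s.T)]
    prov = {"d": cfg.d, "n_layers": cfg.n_layers, "variant": cfg.variant,
            "weight_seed_base": cfg.weight_seed_base,
            "fresh_weights_per_step": cfg.fresh_weights_per_step}
    return StaticEmbeddingSeries(X=X, variant=cfg.variant, provenance=prov)


def embedding_dispersion(X: np.ndarray, rng=None,
                         max_pairs: int = 20000) -> float:
    """Scale-invariant mean pairwise distance between embedding rows.

    Rows are first scaled by the RMS row norm so the statistic measures
    geometry (how distinguishable nodes are), not the raw propagation
    scale, which grows with depth.  Used to quantify over-smoothing.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    scale = np.sqrt(np.mean(np.sum(X * X, axis=1)))
    if scale == 0:
        return 0.0
    Xs = X / scale
    n_pairs = n * (n - 1) // 2
    if n_pairs <= max_pairs:
        from scipy.spatial.distance import pdist

        return float(pdist(Xs).mean())
    rng = np.random.default_rng(rng)
    i = rng.integers(0, n, size=max_pairs)
    j = rng.integers(0, n, size=max_pairs)
    keep = i != j
    return float(np.linalg.norm(Xs[i[keep]] - Xs[j[keep]], axis=1).mean())
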