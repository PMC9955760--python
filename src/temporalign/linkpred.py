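"""Temporal link prediction as binary classification.

Edges are split at a pivot time (~80% of edges at/before it form the
training positives, the rest the test positives); negatives are sampled
non-edges with counts matched to the positives.  Each node's sequence of
aligned embeddings runs through the tanh orientation recursion and a GRU;
the final hidden states of a candidate pair are concatenated and scored by
an affine + logistic decoder.  Orientation matrices, GRU and decoder are
trained jointly with Adam on mean binary cross-entropy.

Ranking metrics (AUROC by trapezoidal integration of the ROC curve, AUPR
over the precision-recall curve) and threshold-0.5 confusion counts are
reported together in an :class:`EvalReport`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from sklearn.metrics import precision_recall_curve, roc_curve

from ._autodiff import Adam, Tensor, concat, gather_rows
from .embedding import StaticEmbeddingSeries
from .graph import TemporalGraph

__all__ = [
    "SplitSpec",
    "TrainConfig",
    "LinkPredictor",
    "EvalReport",
    "temporal_split",
    "pair_feature",
    "bce_loss",
    "train",
    "predict_scores",
    "evaluate",
    "auroc_score",
    "aupr_score",
    "confusion_report",
    "degree_product_auroc",
]

Pair = Tuple[int, int]


@dataclass
class SplitSpec:
    """Pivot-time split with matched negative samples.

    Positives/negatives are canonical (u < v) node-index pairs for
    undirected graphs.  Train negatives are unconnected at the pivot; test
    negatives are never connected; no pair appears in two buckets.
    """

    pivot_time: float
    pivot_fraction: float
    train_pos: List[Pair]
    test_pos: List[Pair]
    train_neg: List[Pair]
    test_neg: List[Pair]
    seed: int = 0

    def __post_init__(self):
        if len(self.train_neg) != len(self.train_pos):
            raise ValueError("train negatives must match train positives")
        if len(self.test_neg) != len(self.test_pos):
            raise ValueError("test negatives must match test positives")
        buckets = [set(self.train_pos), set(self.test_pos),
                   set(self.train_neg), set(self.test_neg)]
        for i in range(4):
            for j in range(i + 1, 4):
                if buckets[i] & buckets[j]:
                    raise ValueError("a pair appears in two split buckets")


def _canonical_pairs(g: TemporalGraph) -> Dict[Pair, float]:
    """Map each canonical node-index pair to its earliest edge time."""
    first: Dict[Pair, float] = {}
    for e in g.edges:
        i, j = g.nodes[e.source], g.nodes[e.target]
        if i == j:
            continue
        if not g.directed and i > j:
            i, j = j, i
        key = (i, j)
        if key not in first or e.time < first[key]:
            first[key] = e.time
    return first


def temporal_split(g: TemporalGraph, pivot_fraction: float = 0.8,
                   seed: int = 0) -> SplitSpec:
    """Split edges at the pivot time closest to the requested fraction.

    Train positives are pairs first connected at/before the pivot, test
    positives after it.  Equal numbers of negatives are sampled uniformly
    without replacement: train negatives from pairs unconnected at pivot
    time, test negatives from pairs never connected (both kept disjoint
    from every other bucket).
    """
    if g.n_edges < 5:
        raise ValueError(f"need at least 5 edges to split, got {g.n_edges}")
    first = _canonical_pairs(g)
    pairs = np.array(sorted(first), dtype=np.int64)
    times = np.array([first[tuple(p)] for p in pairs])
    uniq = np.unique(times)
    fracs = np.array([(times <= t).mean() for t in uniq])
    pivot = float(uniq[np.argmin(np.abs(fracs - pivot_fraction))])

    train_mask = times <= pivot
    train_pos = [tuple(p) for p in pairs[train_mask]]
    test_pos = [tuple(p) for p in pairs[~train_mask]]
    if not train_pos or not test_pos:
        raise ValueError("pivot split left an empty positive bucket; the "
                         "time distribution is too concentrated")

    n = g.n_nodes
    iu, ju = np.triu_indices(n, k=1)
    all_keys = iu.astype(np.int64) * n + ju
    ever = {i * n + j for (i, j) in first}
    at_pivot = {i * n + j for (i, j) in train_pos}
    rng = np.random.default_rng(np.random.SeedSequence((seed, 17)))

    # test negatives: never connected
    never_mask = np.array([k not in ever for k in all_keys])
    never_keys = all_keys[never_mask]
    if never_keys.size < len(test_pos):
        raise ValueError(
            f"cannot sample {len(test_pos)} test negatives: only "
            f"{never_keys.size} never-connected pairs exist")
    test_neg_keys = rng.choice(never_keys, size=len(test_pos), replace=False)
    test_neg = [(int(k) // n, int(k) % n) for k in test_neg_keys]

    # train negatives: unconnected at pivot, excluding every other bucket
    used = at_pivot | set(int(k) for k in test_neg_keys) | {
        i * n + j for (i, j) in test_pos}
    cand_mask = np.array([k not in used for k in all_keys])
    cand = all_keys[cand_mask]
    if cand.size < len(train_pos):
        raise ValueError(
            f"cannot sample {len(train_pos)} train negatives: only "
            f"{cand.size} candidate non-edges remain")
    train_neg_keys = rng.choice(cand, size=len(train_pos), replace=False)
    train_neg = [(int(k) // n, int(k) % n) for k in train_neg_keys]

    return SplitSpec(pivot_time=pivot, pivot_fraction=pivot_fraction,
                     train_pos=train_pos, test_pos=test_pos,
                     train_neg=train_neg, test_neg=test_neg, seed=seed)


def pair_feature(z_u: np.ndarray, z_v: np.ndarray) -> np.ndarray:
    """Concatenated pair representation [z_u ; z_v]."""
    z_u = np.asarray(z_u)
    z_v = np.asarray(z_v)
    if z_u.shape != z_v.shape:
        raise ValueError(f"length mismatch: {z_u.shape} vs {z_v.shape}")
    return np.concatenate([z_u, z_v])


def bce_loss(p: float, p_hat: float) -> float:
    """Binary cross-entropy with the prediction clipped to [1e-7, 1-1e-7]."""
    q = min(max(float(p_hat), 1e-7), 1.0 - 1e-7)
    return float(-p * np.log(q) - (1.0 - p) * np.log(1.0 - q))


# ---------------------------------------------------------------------------
# Model

@dataclass
class TrainConfig:
    """Training hyperparameters (all logged in the report)."""

    epochs: int = 100
    lr: float = 1e-3
    seed: int = 0
    hidden: Optional[int] = None      # GRU hidden width; default = input width
    patience: int = 15                # early stop after this many epochs
    min_delta: float = 1e-5           # ... without at least this improvement


class LinkPredictor:
    """Orientation recursion + GRU encoder + concatenation decoder.

    Parameters (all trained jointly):
      A, B        d x d orientation matrices of the tanh recursion
      W*, U*, b*  GRU gate weights (input d, hidden h)
      w_out, b_out  affine decoder on the concatenated pair state (2h -> 1)
    """

    def __init__(self, d: int, hidden: Optional[int] = None, seed: int = 0):
        h = hidden or d
        self.d, self.h = d, h
        rng = np.random.default_rng(np.random.SeedSequence((seed, 29)))

        def mat(fin, fout):
            return Tensor(rng.normal(0, 1.0 / np.sqrt(fin), (fin, fout)),
                          requires_grad=True)

        def vec(k):
            return Tensor(np.zeros((1, k)), requires_grad=True)

        self.params: Dict[str, Tensor] = {
            "A": mat(d, d), "B": mat(d, d),
            "W_r": mat(d, h), "U_r": mat(h, h), "b_r": vec(h),
            "W_z": mat(d, h), "U_z": mat(h, h), "b_z": vec(h),
            "W_n": mat(d, h), "U_n": mat(h, h), "b_n": vec(h),
            "w_out": mat(2 * h, 1), "b_out": vec(1),
        }
        self.loss_history: List[float] = []
        self.train_config: Optional[TrainConfig] = None

    @property
    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.params.values())

    # ---- forward pieces -------------------------------------------------

    def node_states(self, series: StaticEmbeddingSeries) -> Tensor:
        """Final per-node GRU state from the orientation-recursion sequence.

        The series is expected to be aligned already (the per-step
        orthogonal operators are absorbed into its matrices), so the
        recursion consumes the aligned rows directly.
        """
        P = self.params
        n = series.X[0].shape[0]
        l = Tensor(np.zeros((n, self.d)))
        hid = Tensor(np.zeros((n, self.h)))
        for t in range(series.T):
            x = Tensor(series.X[t])
            l = (l @ P["A"] + x @ P["B"]).tanh()
            rgate = (l @ P["W_r"] + hid @ P["U_r"] + P["b_r"]).sigmoid()
            zgate = (l @ P["W_z"] + hid @ P["U_z"] + P["b_z"]).sigmoid()
            cand = (l @ P["W_n"] + (rgate * hid) @ P["U_n"] + P["b_n"]).tanh()
            hid = (1.0 - zgate) * hid + zgate * cand
        return hid

    def pair_scores(self, states: Tensor, pairs: Sequence[Pair]) -> Tensor:
        """Logistic link probabilities for the given node pairs."""
        u = [p[0] for p in pairs]
        v = [p[1] for p in pairs]
        feat = concat([gather_rows(states, u), gather_rows(states, v)], axis=1)
        return (feat @ self.params["w_out"] + self.params["b_out"]).sigmoid()

    def scores(self, series: StaticEmbeddingSeries,
               pairs: Sequence[Pair]) -> np.ndarray:
        return self.pair_scores(self.node_states(series), pairs).data.ravel()


def _bce_mean(p_hat: Tensor, labels: np.ndarray) -> Tensor:
    y = Tensor(labels.reshape(-1, 1))
    q = p_hat.clip(1e-7, 1.0 - 1e-7)
    return (-(y * q.log() + (1.0 - y) * (1.0 - q).log())).mean()


def train(series: StaticEmbeddingSeries, split: SplitSpec,
          config: Optional[TrainConfig] = None) -> LinkPredictor:
    """Fit the predictor on the training pairs with Adam.

    Full-batch gradient steps on mean binary cross-entropy; early stop when
    the loss plateaus.  Deterministic given config.seed.  Raises on NaN
    loss (divergence).
    """
    config = config or TrainConfig()
    d = series.width
    model = LinkPredictor(d, hidden=config.hidden, seed=config.seed)
    model.train_config = config
    pairs = list(split.train_pos) + list(split.train_neg)
    labels = np.concatenate([np.ones(len(split.train_pos)),
                             np.zeros(len(split.train_neg))])
    opt = Adam(model.params.values(), lr=config.lr)
    best, since_best = np.inf, 0
    for epoch in range(config.epochs):
        opt.zero_grad()
        states = model.node_states(series)
        p_hat = model.pair_scores(states, pairs)
        loss = _bce_mean(p_hat, labels)
        value = float(loss.data)
        if not np.isfinite(value):
            raise FloatingPointError(
                f"training diverged at epoch {epoch} (loss={value}); "
                f"lr={config.lr}, d={d}")
        model.loss_history.append(value)
        loss.backward()
        opt.step()
        if value < best - config.min_delta:
            best, since_best = value, 0
        else:
            since_best += 1
            if since_best >= config.patience:
                break
    return model


def predict_scores(model: LinkPredictor, series: StaticEmbeddingSeries,
                   pairs: Sequence[Pair]) -> np.ndarray:
    """Link probabilities for arbitrary node pairs (no training)."""
    return model.scores(series, pairs)


# ---------------------------------------------------------------------------
# Metrics

@dataclass
class EvalReport:
    """Confusion counts at threshold 0.5 plus ranking metrics."""

    tp: int
    fp: int
    fn: int
    tn: int
    precision: float
    recall: float
    fpr: float
    auroc: float
    aupr: float
    threshold: float = 0.5
    precision_defined: bool = True

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("tp", "fp", "fn", "tn", "precision", "recall", "fpr",
                 "auroc", "aupr", "threshold", "precision_defined")}


def confusion_report(tp: int, fp: int, fn: int, tn: int) -> dict:
    """Precision, recall and FPR from confusion counts (0 when undefined)."""
    precision = tp / (tp + fp) if (tp + fp) > 0 else 0.0
    recall = tp / (tp + fn) if (tp + fn) > 0 else 0.0
    fpr = fp / (tn + fp) if (tn + fp) > 0 else 0.0
    return {"precision": precision, "recall": recall, "fpr": fpr,
            "precision_defined": (tp + fp) > 0}


def auroc_score(labels: np.ndarray, scores: np.ndarray) -> float:
    """Area under the ROC curve by trapezoidal integration over all
    thresholds (equals the tie-averaged rank statistic)."""
    fpr, tpr, _ = roc_curve(labels, scores)
    return float(np.trapezoid(tpr, fpr))


def aupr_score(labels: np.ndarray, scores: np.ndarray) -> float:
    """Area under the precision-recall curve, trapezoidal over thresholds."""
    precision, recall, _ = precision_recall_curve(labels, scores)
    # integrate along the threshold-ordered path (recall non-increasing);
    # re-sorting would scramble tied-recall points
    return float(abs(np.trapezoid(precision, recall)))


def evaluate(model: LinkPredictor, split: SplitSpec,
             series: StaticEmbeddingSeries,
             threshold: float = 0.5) -> EvalReport:
    """Score the held-out pairs and assemble the evaluation report."""
    if not split.test_pos:
        raise ValueError("empty test set")
    pairs = list(split.test_pos) + list(split.test_neg)
    labels = np.concatenate([np.ones(len(split.test_pos)),
                             np.zeros(len(split.test_neg))])
    scores = model.scores(series, pairs)
    pred = scores >= threshold
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    tn = int(np.sum(~pred & (labels == 0)))
    cm = confusion_report(tp, fp, fn, tn)
    return EvalReport(tp=tp, fp=fp, fn=fn, tn=tn,
                      precision=cm["precision"], recall=cm["recall"],
                      fpr=cm["fpr"],
                      auroc=auroc_score(labels, scores),
                      aupr=aupr_score(labels, scores),
                      threshold=threshold,
                      precision_defined=cm["precision_defined"])


def degree_product_auroc(g: TemporalGraph, split: SplitSpec) -> float:
    """Degree-product heuristic baseline on the same test pairs.

    Degrees are counted on edges at/before the pivot only, so the baseline
    sees exactly the information available to the model.
    """
    n = g.n_nodes
    deg = np.zeros(n)
    for e in g.edges:
        if e.time <= split.pivot_time:
            deg[g.nodes[e.source]] += 1
            deg[g.nodes[e.target]] += 1
    pairs = list(split.test_pos) + list(split.test_neg)
    labels = np.concatenate([np.ones(len(split.test_pos)),
                             np.zeros(len(split.test_neg))])
    scores = np.array([deg[u] * deg[v] for (u, v) in pairs], dtype=float)
    return auroc_score(labels, scores)
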