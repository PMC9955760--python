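# temporalign

Temporal network embedding with orthogonal alignment and GRU-based link
prediction for growing dynamic graphs.

Many real interaction networks — dynamic protein–protein interaction maps,
e-mail exchanges, physical-contact logs — are streams of timestamped edges.
Predicting which pairs of nodes will connect next requires node
representations that track how the graph evolves. `temporalign` is for
researchers working with such timestamped edge lists who want a simple,
fully reproducible temporal embedding pipeline: no trained encoder, a
shallow untrained graph propagation per time step, an explicit orthogonal
alignment between steps, and a small recurrent head that is the only
trained component.

## Method

A timestamped edge list over nodes `V` (|V| = n) is cut into `T`
equal-width time slices; the cumulative snapshot `A_t` (n×n, weighted)
holds every edge formed up to slice `t`. Each snapshot is turned into a
**temporal influence matrix** that discounts edges by their age relative
to the reference time `t_now` (default: the slice being embedded), with
decayed self-loops added:

    Â_t[i,j] = A_t[i,j] · exp(time(i,j) − (t_now + ε)),   Â_t[i,i] = exp(−ε)

with `ε = 1e-5` (a snapshot-scalar variant `exp(t − t_now − ε)(A_t + I)`
is also provided). A **static embedding** `X_t` (n×d, default d = 128) is
produced at every step by three untrained propagation layers

    R_{l+1} = Â_t R_l W_l        (widths  n → ⌊n/2⌋ → ⌊n/2⌋ → d)

with `R_0` the one-hot identity (or explicit node features) and `W_l`
random Gaussian matrices — no degree normalization, no nonlinearity, no
training. A `plusplus` variant applies a row-wise softmax inside each
layer and concatenates a fixed cosine time encoding.

Because each step draws fresh weights, consecutive `X_t` live in unrelated
bases. Two orthogonal **alignment** operators relate step `t+1` to `t`:

* *Procrustes*: `Q = argmin_{QᵀQ=I} ‖X_{t+1}Q − X_t‖_F`, closed form
  `Q = UVᵀ` from the SVD of `X_{t+1}ᵀX_t`;
* *Givens/QR*: per-(node, feature) rotation cosines `(cos α, cos β)`
  collected into Θ-matrices, contracted to `C = Θ_{cosβ}ᵀ Θ_{cosα}`, with
  the orthogonal factor of `C = QR` as the operator.

**Link prediction** is binary classification: edges are split at a pivot
time (80 % train), negatives are sampled non-edges matched in count. Each
node's aligned sequence runs through the orientation recursion
`l_{t+1}(v) = tanh(A l_t(v) + B x_t(v))` and a GRU; the final states of a
pair are concatenated and scored by an affine + logistic decoder. The
orientation matrices, GRU and decoder are trained jointly with Adam on
cross-entropy. Training runs on a compact numpy reverse-mode autodiff
engine included in the package. Reported metrics: AUROC, AUPR,
precision/recall/FPR at threshold 0.5.

## Worked example

`examples/04_link_prediction.py` runs the full pipeline on a growing
planted-partition graph (n = 200 nodes in k = 4 communities, T = 8 steps,
within/between edge probabilities 0.05 / 0.005 per step):

```
$ python examples/04_link_prediction.py
[load] TemporalGraph(200 nodes, 2234 edges, undirected, t in [1.0, 8.0])
[split] 1732 train / 502 test positives, pivot=6.0
[embed] T=8, shape=(200, 32)
[align] method=givens_qr, operators=7
[train] 100 epochs, final loss 0.5190, 8353 parameters

test AUROC     0.727   (1.0 = perfect ranking, 0.5 = chance)
test AUPR      0.704
precision      0.706 at threshold 0.5
recall         0.659
degree-product baseline AUROC 0.471
training loss  0.704 -> 0.519 over 100 epochs
```

The model ranks held-out future edges (mostly within-community pairs)
well above never-connected pairs, while the degree-product heuristic sits
at chance — the planted community signal, not node popularity, is what
the embedding captures. The other examples walk through simulation and
snapshots (`01`), the untrained embedding and its over-smoothing with
depth (`02`), and the two alignment operators (`03`).

The same pipeline is available from the shell:

```
temporalign simulate --n 200 --k 4 --steps 8 --seed 1 --out graph.tsv
temporalign run --edges graph.tsv --steps 8 --dim 32 --seed 1 --out-dir out/
temporalign replay --manifest out/manifest.json   # bitwise-identical rerun
```

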