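# Methods

This note records the model as implemented, the choices made where the
design was genuinely open, and what the synthetic fixtures do and do not
demonstrate. Nothing here states an empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## Temporal graph and snapshots

A temporal graph is a list of `(source, target, timestamp[, weight])`
edges over a dense node registry frozen at read time in first-appearance
order. Only growing networks are supported: edges are added, never
removed, and the node set never shrinks. The time range is cut into `T`
equal-width slices, half-open `[lo, hi)` except the last slice, which is
closed, so every edge lands in exactly one slice. Cumulative snapshots
(the default) nest: the support of `A_t` is contained in that of
`A_{t+1}`. Duplicate occurrences of the same pair sum their weights and
keep the latest timestamp — repeated interactions strengthen ties in
contact and e-mail data, and recency is what the decay should see. The
per-entry edge times are stored per snapshot, so an edge that re-occurs
late never leaks a future timestamp into an earlier snapshot.

## Temporal influence

Two decay modes are implemented. The per-edge mode (default) discounts
each entry by its own age, `A_t[i,j]·exp(time(i,j) − (t_now + ε))`, with
self-loops treated as formed at `t_now` (diagonal `exp(−ε)`); the
snapshot-scalar mode applies one factor `exp(t − t_now − ε)` to
`A_t + I`. The per-edge form is the default because cumulative snapshots
make per-edge age meaningful: in a cumulative snapshot most edges are old,
and a single scalar cannot distinguish them.

Raw timestamps are mapped to slice indices `0..T−1` before
exponentiation (`time_rescale`, default on). With raw Unix-second
differences the exponential underflows to zero for everything but the
newest edges; on the index axis the decay spans `e^0 … e^{-(T-1)}`, a
usable dynamic range for any input granularity. `t_now` defaults to the
index of the snapshot being embedded — the latest information available
at that step. `ε = 1e-5` keeps fresh binary edges strictly below 1.

## Static embedding

Each step is embedded independently by `n_layers = 3` untrained layers
`R_{l+1} = Â_t R_l W_l` with widths `f0 → ⌊n/2⌋ → ⌊n/2⌋ → d`
(`d = 128` by default; `f0 = n` for one-hot initialization, or the
feature-table width). There is deliberately no degree normalization and
no nonlinearity in the plain variant. Open choices resolved here:

* **Weight distribution.** Unspecified by the method; entries are i.i.d.
  Gaussian with standard deviation `1/√fan_in`, which keeps the
  activation scale stable across layers in the absence of normalization.
  Seeds mix `(base, step, layer)`, so every draw is bit-reproducible.
* **Fresh weights per step** (default). Embedding sessions at different
  steps are independent by construction; this is precisely what creates
  the basis drift the alignment stage corrects, and it can be switched
  off (`fresh_weights_per_step=False`) for shared weights.
* **Softmax placement (`plusplus`).** The nonlinear variant computes
  `Â_t · rowsoftmax(R_l W_l)` — the softmax acts on the feature
  dimension before the adjacency product, turning each node's
  representation into a distribution.
* **Time encoding (`plusplus`).** A fixed cosine basis
  `z_k(t) = cos(10^{−2k/dim}·t)`, `k = 0..dim−1`, `dim = 16` by default,
  concatenated to every row. Deterministic with zero extra parameters;
  geometric frequencies cover slow and fast temporal variation.

### Over-smoothing measurement

Depth sweeps use a scale-invariant dispersion: the mean pairwise distance
between embedding rows after dividing by the RMS row norm. Raw distances
confound geometry with the propagation scale (each layer multiplies by an
unnormalized `Â`, so norms grow with depth); after scaling, the statistic
isolates how distinguishable nodes remain. On a fixed connected graph the
seed-averaged dispersion decreases monotonically as depth sweeps 3 → 8 —
the over-smoothing trend that motivates the shallow default.

## Alignment

* **Procrustes.** `Q = argmin ‖X_{t+1}Q − X_t‖_F` over orthogonal `Q`,
  via the SVD of `X_{t+1}ᵀX_t`. The operator multiplies from the right:
  a `d×d` matrix can only act on the feature axis of an `n×d` embedding.
* **Givens/QR.** For every (node, feature) scalar pair `(a, b) =
  (X_t[v,i], X_{t+1}[v,i])` the rotation cosines are computed with the
  numerically safe branch on the dominant scalar; the normalization
  `1/√(1+tmp²)` is used because it is the only form under which
  `cos²α + cos²β = 1`, the defining property of a Givens rotation. The
  angle matrices are contracted to `C = Θ_{cosβ}ᵀΘ_{cosα}` and
  QR-factorized with the sign convention `diag(R) ≥ 0`, which makes `Q`
  unique and runs reproducible. The `b = 0` branch also absorbs
  `a = b = 0`, returning `(1, 0)` — an entry absent from both steps
  contributes the identity rotation.
* **Chaining.** `X'_1 = X_1`; `Q_{t+1}` aligns `X_{t+1}` to the
  already-aligned `X'_t`, and `X'_{t+1} = X_{t+1}Q_{t+1}`, so all steps
  end up in the basis of the first.

The operator fed to the downstream recursion is whichever method is
configured (`givens_qr` by default). Measured on the synthetic fixtures,
the two methods give downstream AUROC within noise of each other (the
comparison harness `compare_alignment_methods` computes this); the
Givens/QR operator is not a least-squares drift minimizer, so only
Procrustes provably reduces the consecutive-step Frobenius drift.

## Link prediction

* **Split.** The pivot is the edge timestamp whose cumulative edge
  fraction is closest to 0.8. Train positives are pairs first connected
  at/before the pivot; test positives after it. Train negatives are
  sampled uniformly without replacement from pairs unconnected at the
  pivot, test negatives from pairs never connected; all four buckets are
  disjoint and negatives are count-matched to positives. Pairs are
  canonicalized `u < v` for undirected graphs; self-pairs are excluded.
* **Leakage control.** Snapshots and embeddings are built from edges at
  or before the pivot only — held-out edges never enter the adjacency
  the model sees.
* **Model.** Orientation recursion `l_{t+1}(v) = tanh(A l_t(v) + B x_t(v))`
  (`l_0 = 0`, aligned rows as input, the orthogonal operators already
  absorbed into the series), a single-layer GRU with hidden width equal
  to the embedding width, and an affine + logistic decoder on the
  concatenated pair states. All parameters — `A`, `B`, GRU gates,
  decoder — train jointly.
* **Training.** Full-batch Adam (learning rate `1e-3`), mean binary
  cross-entropy with predictions clipped to `[1e-7, 1−1e-7]`, up to 100
  epochs with early stop after 15 epochs without `1e-5` improvement.
  NaN loss aborts with a diagnostic. Gradients come from a compact
  reverse-mode autodiff engine on numpy arrays written for this package
  and verified against central finite differences in the test suite.
* **Metrics.** AUROC by trapezoidal integration of the ROC curve
  (equivalent to the tie-averaged Mann–Whitney statistic, which the
  tests use as an independent oracle); AUPR integrated along the
  threshold-ordered precision-recall path — re-sorting by recall would
  scramble tied-recall points and underestimate the area. Precision is
  reported as 0 with a flag when no pair is predicted positive.

## Synthetic fixtures

The generator emulates weighted, timestamped, optionally node-featured
interaction data. The planted-partition fixture (defaults n = 200, k = 4,
T = 8, p_in = 0.05, p_out = 0.005, weights Uniform(0.1, 1)) fixes
community assignments and wires previously unconnected pairs each step —
a growing network with a known link-prediction signal, large enough to
train the recurrent head in minutes on one CPU. A degree-proportional
attachment generator provides heavy-tailed growth for structural tests.

What the fixtures do **not** emulate: the biological co-expression
dynamics behind real dynamic protein-interaction releases, bursty or
periodic activity of contact networks, node-level churn, and
assortativity beyond the planted blocks. Passing the end-to-end tests
shows the pipeline recovers a planted community signal under temporal
growth; it does not certify performance on any real dataset.

Two regimes of the end-to-end fixture behave differently, and both are
exercised: at d = 128 the final cumulative snapshot alone nearly
determines the outcome and alignment is immaterial; at d = 8 each step is
a lossy random sketch, and only with coherent (aligned) bases can the
shared recurrence average information across steps — this is the regime
where the aligned-vs-unaligned ablation is measured.

## Known limitations

* Dense `n×n` adjacency and one-hot initialization make the embedding
  stage O(n²·d); the implementation targets desk-scale graphs (up to a
  few thousand nodes), not the largest interaction maps.
* Node or edge removal is unsupported by design (growing networks only).
* The GRU trains full-batch; no mini-batching or GPU path.
* The Givens/QR operator's downstream advantage over Procrustes does not
  manifest on these synthetic fixtures; the package exposes both and
  defaults to Givens/QR.
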