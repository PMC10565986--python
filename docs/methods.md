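# Methods

## Model

### Knowledge graph

A knowledge graph is a typed directed multigraph `G = (V, E)` with a finite
relation vocabulary `R`; an edge is a triple `(u, r, v)`. Relations are
namespaced by source (`pathway_commons` for 3-column SIF interaction data,
`cancer_pathway` for the normalized 5-column pathway edge TSV, `synthetic`
for generated graphs). Merging requires disjoint namespaces: nodes unify by
their verbatim identifier string (gene symbols shared between sources
collapse to one node; no synonym resolution is attempted), while relation
vocabularies and edge sets are disjoint unions, so relation and edge counts
are exactly additive. Self-loops are kept; reciprocal pairs
`(u, r, v)`/`(v, r, u)` are both retained. Nodes, relations and edges are
stored canonically sorted, which makes every downstream computation
independent of input line order and bit-reproducible.

### Graph encoder

Every node has a trainable embedding `z⁰ ∈ R^C`, refined by `L`
relation-stratified GIN blocks

    z^(ℓ+1) = relu( Σ_r  W_(r) · relu( GINConv(z^ℓ, G_(r)) ) + b_(r) ),

where `G_(r)` keeps only edges with relation `r` (over the full node set, so
tables stay aligned) and GINConv is `MLP((1+ε)·z_v + Σ_{u∈N(v)} z_u)` with a
2-layer `C→C→C` rectifier MLP shared across relations within a layer and
`ε = 0` fixed. Message passing treats each relation subgraph as undirected
(`N(v)` = in- ∪ out-neighbors, as a set); a directed mode is available via
`GnnConfig.undirected=False`. The outputs of all layers including `z⁰` are
concatenated — `(L+1)·C` columns — and linearly projected back to `C`, making
the final embedding a literal `z_u ∈ R^C` while letting it see every depth.
Design choices that were genuinely open: `L = 2` by default (two hops cover
pathway neighborhoods without oversmoothing small graphs); rectifiers for the
block nonlinearities, reserving the logistic function for link scores; a
learned projection rather than truncation for the concatenation block.

### Link-prediction pretraining

For each positive edge `(u, r, v)` one corrupted example `(u, r, v′)` is
drawn with `v′` uniform over `V` — unfiltered, so `v′` may coincide with a
true neighbor. The loss is the mean over pairs of
`softplus(−s⁺) + softplus(s⁻)`, the numerically stable form of
`−log σ(s⁺) − log σ(−s⁻)`; it equals `2·ln 2` exactly at zero logits.
The score is the dot product `z_u·z_v`, replaced by `z_uᵀ diag(w_r) z_v`
when the graph has more than one relation (per-relation diagonal weights,
initialized at ones). Optimization is Adam; one epoch sweeps the shuffled
edge set, minibatched at 512 only when the edge count exceeds 10⁵. The loss
is averaged (not summed) over a batch. Training, including negative
sampling, is fully determined by `GnnConfig.seed`.

All of this runs on a small reverse-mode automatic-differentiation engine
(`drivernet.autodiff`) written on numpy/scipy — dense/sparse matmul, gather/
scatter, ReLU, softplus, reductions, Adam — whose gradients are verified
against central finite differences in the test suite.

**Learning-rate scaling.** The reference setting (rate 1e-4, 50 epochs) is
calibrated for graphs with millions of edges, i.e. thousands of optimizer
steps per epoch. The synthetic study graphs here have a few hundred edges —
one optimizer step per epoch — so runs whose purpose is *skill* (held-out
edge scoring, the with/without-graph comparison) use rate 0.01 as the
step-count-faithful analogue; the monotone loss-decrease property is still
exercised at the reference rate. Both are plain `GnnConfig` settings.

### Training-set sampling

Per-variant labels are driver / passenger / unknown, keyed by
`(gene, protein change)`. The three-step sampler corrects the double
imbalance of driver corpora:

1. per gene, keep at most `cap` drivers and at most `cap` passengers,
   uniformly at random; `cap` defaults to the median per-gene driver count
   over genes with ≥ 1 driver (lower middle for even counts, keeping the cap
   an integer; an all-genes median would be 0);
2. every surviving passenger in a gene that still has a driver is included
   unconditionally — this stops the classifier from keying on gene identity;
3. passengers from driver-free genes are sampled so the passenger total is
   exactly `ratio × drivers` (default 4), with step-2 passengers counting
   toward the total.

Totals are seed-invariant; only membership varies. If step-2 passengers
already exceed the target the sampler raises rather than silently dropping
mandated records; likewise when the capped driver-free pool cannot cover the
shortfall, with counts in the message. Note the cap binds driver-free genes
too, so feasibility at ratio 4 requires drivers confined to a small fraction
of genes — the regime real corpora are in (see synthetic data below).

### Feature assembly and classification

The design matrix is 91 variant columns (schema: 88 sequence/structure
columns plus `pvalue_w0/w5/w10` hotspot p-values, validated on load) followed
by `C` graph columns `graph_feature_0..C−1` joined by gene — width 123 at
`C = 32`, 107 at `C = 16`. Missing variant cells are imputed with column
means fitted on the training rows only and reusable on validation/benchmark
data (no leakage); genes absent from the graph receive a zero embedding and
are logged rather than dropped. The classifier is a random forest tuned by
exhaustive grid search (default grid: trees {100, 300, 500} × depth
{∞, 10, 20} × features-per-split {sqrt, 0.3}) with stratified 3-fold inner
CV maximizing ROC-AUC, refit on all rows. No class weighting: the 4:1
sampling already controls imbalance. Benchmark records sharing a variant key
with training data are removed before evaluation.

### Evaluation

ROC-AUC is the Mann–Whitney pairwise concordance (ties ½); PR-AUC is the
step-wise area of the precision–recall curve swept in descending score order
(no interpolation — stated because small-n values differ between
conventions). The cross-validation harness runs `trials` independently
seeded stratified k-fold partitions (trial seeds derived from a master
seed), imputes within folds, and reports per-fold AUCs, their means, and a
Youden threshold per trial computed on the pooled out-of-fold scores; the
decision threshold is the across-trial average, and thresholded
accuracy/precision/recall/F1 are computed per trial at that averaged cutoff
and then averaged (the metric is averaged, not the scores). Youden
candidates are the minimum score plus midpoints of adjacent distinct scores,
prediction is positive at `score ≥ t`, ties break toward the lower threshold
(higher sensitivity), and a degenerate all-equal score vector returns that
score with a warning. The harness's default hyperparameter grid is a single
standard combination (300 trees, unlimited depth, sqrt features) to keep
k × trials tractable; pass the full grid explicitly to nest the search.

### Interpretation

Shapley values for the driver probability are computed by the
polynomial-time path-dependent tree-traversal algorithm for tree ensembles,
implemented directly over the fitted sklearn tree arrays and validated
against exhaustive coalition enumeration on small forests; local accuracy
(baseline + attributions = prediction, tolerance 1e-6 per row) is enforced
in tests. The graph feature importance rate is, per variant,
`Σ|attr| over graph columns / Σ|attr| over all columns`. Absolute values are
used in both numerator and denominator — signed sums could leave [0, 1] and
break the rate's reading as a proportion; top-feature rankings likewise use
mean absolute attribution (deterministic name tie-break). Rows with all-zero
attributions have an undefined rate and are reported as NaN.

## Synthetic data

`simulate_graph` draws a stochastic-block multigraph: unordered gene pairs
get an edge with probability `p_within` (same block) or `p_between`, each
edge receiving one of `n_relations` relations uniformly. `simulate_variants`
designates driver genes clustered in the leading block(s) and draws each
variant's label from a logistic model

    logit p = logit(base rate) + β_g·(±1 driver/non-driver gene) + β_v·s + ε,

with latent variant signal `s ~ N(0,1)` written into the first
`n_signal_columns` feature columns (as `expit(−s)` for p-value columns, so
small p-values track driver-ness and respect [0, 1]); remaining columns are
independent noise, and cells are masked at `missing_rate`. The graph term is
coded ±β_g so that large β_g drives labels to pure block membership while
β_g = 0 leaves prevalence at the base rate.

Two condition sets are used. The **default** (60 genes, 2 blocks,
`p_within = 0.3`, `p_between = 0.02`, 2 relations, 15 driver genes, ~8
variants/gene at 25% base rate, `β_g = 1.5`, `β_v = 1.0`, noise 0.5) is the
compact block-graph regime used for encoder properties and for the
with/without-graph comparison. The **imbalanced corpus**
(`synth.imbalanced_corpus`: 120 genes, 10% driver genes, ~12 variants/gene
at ~8% base rate, `β_g = 4` so drivers land almost exclusively in driver
genes) reproduces the shape real corpora have — drivers confined to few
genes over a deep passenger pool — which is the regime the three-step
sampler requires: under the default conditions the per-gene cap throttles
the driver-free passenger pool below 4× the drivers, and the sampler
correctly refuses.

What passing tests on these generators shows — and does not. They exercise
every contract end to end (schemas, determinism, the exact ratio identity,
signal recoverability, the direction of the graph's contribution). They do
not emulate mutation-rate heterogeneity, trinucleotide context, real
feature correlations, or database-scale graphs, so measured AUCs
characterize the synthetic conditions only, not expected performance on
real tumor data.

## Numerical choices and degenerate inputs

- Embeddings initialize i.i.d. standard normal; weight matrices at scale
  `1/√C`; biases zero; relation-score diagonals at ones (pure dot product
  before training). Identical seeds give bit-identical parameters, traces
  and embeddings.
- `link_loss` uses `log1p`-stable softplus; NaN logits raise immediately;
  a non-finite training loss aborts with the epoch in the message.
- Negative sampling is unfiltered by design; on a single-node graph the
  only possible corruption is the node itself, which is accepted.
- Duplicate variant keys are rejected at load; labels normalize
  case-insensitively.
- Zero predicted positives make precision undefined; it is reported as 0
  with an explicit flag.
- Columns with no observed values impute to 0 and are recorded in the
  imputation sidecar.

## Problem sizes

Tests and the acceptance script run at desk scale, chosen to exercise every
code path with comfortable statistical margins: graphs of 60–120 nodes
(~300–900 edges), corpora of ~500–1500 variants, forests of 50–300 trees,
5-fold × 1–3-trial cross-validation, Shapley attribution over ≤ 40 rows ×
100 trees, and 3–5 seed replicates for stochastic properties.

## Known limitations

- The graph part and prediction part are trained independently; per-node
  contributions to a specific prediction are not interpretable beyond the
  embedding columns' Shapley values.
- Path-dependent Shapley values use tree cover distributions, not an
  interventional background set; attributions for strongly correlated
  features inherit that convention.
- The encoder offers GIN only (no GCN/GAT alternatives), CPU only; the
  hand-rolled autodiff engine supports exactly the ops the encoder needs.
- No identifier mapping: graphs merge on verbatim symbols; externally
  sourced files with inconsistent naming will silently fail to collapse.
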