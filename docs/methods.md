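# Methods

## The model

`ghnn` implements a transductive node classifier for gene prioritization
on a protein–protein interaction (PPI) network enriched with biological
pathway membership. The inputs are a triple — an undirected gene graph
G, a pathway hypergraph HG (one hyperedge per pathway), and a node
feature matrix V of multiomics attributes — aligned on one node ordering.
Two deep encoders run in parallel:

    E_graph = DeepEncoder_graph(G, V)
    E_hyper = DeepEncoder_hyper(HG, V)
    E_merge = concat(E_graph, E_hyper)
    p(node is pan-cancer related) = sigmoid(CLS-head(E_merge))

Each encoder stacks residual blocks of three spectral-style convolution
layers. The propagation operators are

* graph channel: `S = D^{-1/2} (A + I) D^{-1/2}` with A the 0/1
  adjacency and D the degree of A + I;
* hypergraph channel: `S = D_v^{-1/2} H W D_e^{-1} H^T D_v^{-1/2}` with
  H the node-by-hyperedge incidence, W diagonal hyperedge weights
  (default 1), `D_v = diag(HW1)`, `D_e = diag(1ᵀH)`.

Zero degrees map through the convention `0^{-1/2} -> 0`, so genes absent
from every pathway simply receive a zero hypergraph row rather than an
error; partial pathway coverage is the normal case in real data. One
layer computes `act(S X W + b)` with ReLU activation on the first two
layers of each block and input dropout (rate 0.1) in training mode.

A block adds its skip (identity, or a learned linear projection in the
first block where the width changes) to the third layer's
*pre-activation* output and applies a final ReLU. The addition point is
a design choice: adding before the closing nonlinearity lets the
residual branch learn a pure correction. The default encoder has 9
blocks = 27 convolution layers per channel; the depth grid
{1, 3, 6, 9, 12} blocks is supported throughout for depth sweeps.

The classifier is a feature-tokenizer transformer: every scalar of the
merged embedding becomes a token via a per-feature affine map
(`token_i = x_i * w_i + b_i`, token dimension 16), a learned CLS token
is prepended, and a 4-layer, 4-head pre-norm self-attention encoder
(attention and feed-forward dropout 0.1, feed-forward width 4× the token
dimension) processes the sequence. Feature tokens carry no positional
encoding — the feature set is unordered — so predictions are invariant
to permuting non-CLS tokens. The CLS position's final representation
passes through a linear head and a sigmoid. A plain affine + sigmoid
head is available as the `linear_head` ablation through the same
interface.

### Embedding standardization before the head

The merged embedding of a deep residual stack rides on a large
node-constant offset (residual accumulation plus ReLU asymmetry). Fed
raw into the tokenizer, that offset dominates every token and the CLS
logit collapses towards zero scale. The head therefore consumes the
embedding standardized per dimension across nodes, with the mean and
standard deviation treated as constants of the current forward pass
(stop-gradient), exactly as numeric features entering a feature
tokenizer are conventionally standardized. The flag
`TrainConfig.emerge_norm` (default on) controls this.

## Training

Training is full batch and transductive: both encoders run on the whole
graph every epoch and the mean binary cross-entropy over train-mask
nodes is minimized with Adam. The published configuration is the
default: hidden width 64, learning rate 1e-4, decay rate 1e-5, dropout
0.1, 3000 epochs, token dimension 16, 4 transformer layers and heads.
"Decay rate" is implemented as decoupled weight decay — each step
multiplies parameters by (1 − decay) independent of the learning rate —
so with learning rate 0 parameters decay geometrically, a closed form
the test suite checks. An optional positive-class re-weighting flag
exists and defaults off, and an optional best-validation-AUPRC
checkpoint (`select_best_val`) replaces final-epoch parameters with the
best-validation ones; the experiment protocols below enable it, plain
`train` does not.

Because the transformer treats nodes independently, the classifier head
runs in node chunks (sized so the attention tensors stay within a fixed
memory cap) with exact gradient accumulation into a
detached copy of the merged embedding; the encoders backpropagate once
from the accumulated gradient. This bounds the memory of the
token-by-token attention tensors without changing any gradient (the
equality chunked = unchunked is asserted in the test suite at 1e-10).
Model arithmetic is float32; the operator constructors and their
correctness contracts are float64.

All randomness — initialization (Glorot-uniform weights, zero biases)
and dropout — derives from `TrainConfig.seed` through a seed sequence,
so a (bundle, config, seed) triple reproduces every logged number
bitwise.

## Synthetic benchmarks

The generator plants the two kinds of structure the architecture
claims to exploit; everything is a deterministic function of
`BenchmarkSpec.seed`.

1. Graph: a planted-partition (community) or preferential-attachment
   model.
2. Hyperedges: random gene sets; a designated fraction are *signal*
   hyperedges whose members carry elevated risk.
3. Seed nodes: planted sources whose influence diffuses along edges with
   per-hop decay (default 0.5) out to `graph_signal_radius` hops.
4. Features: `n_signal_features` columns report the *local* risk sources
   (a private feature latent, the seed indicator, signal-hyperedge
   membership count) plus Gaussian noise; remaining columns are pure
   noise; all columns are z-scored. Reporting the seed indicator rather
   than the post-diffusion risk is deliberate — labels at hop distance
   ≥ 2 from a seed are then unrecoverable without propagation, which is
   what makes depth testable.
5. Latent risk: the signal-mix-weighted sum of the three standardized
   sources; labels are the top `positive_rate` quantile of risk, then
   independent flips with probability `label_noise` (default 0.02).
6. Split: stratified 60/20/20 train/validation/test.

The default condition is 600 nodes, 32 features (8 signal), 60
hyperedges, mixed signal weights (0.3, 0.4, 0.3). `bayes_reference`
scores nodes by the true latent risk: with zero label noise it attains
AUPRC 1 on the test mask, and it upper-bounds any trained model up to
noise.

What the generator does **not** emulate: real multiomics marginals
(methylation fractions, expression dynamic range), degree-correlated
pathway annotation bias, and label curation artefacts. Passing the
planted-signal tests therefore demonstrates that the architecture can
exploit hyperedge membership and multi-hop structure when they carry
signal — not that it attains any particular performance on real
pan-cancer data.

### Named study conditions

* `hyperedge_dominant_spec` — labels driven by signal-hyperedge
  membership (mix 0.15/0/0.85), with feature noise high enough that
  pathway membership, visible only through the incidence structure,
  carries most of the learnable signal. Used to show the full model
  beating the `no_hypergraph` ablation.
* `graph_depth_spec` — labels driven by radius-4 diffusion from a small
  seed set (mix 0.1/0.9/0); features mark the seeds only. A one-block
  (3-hop) encoder cannot see most of the positive set; a nine-block
  encoder can. Used to show deep beating shallow.

## Desk-scale experiment protocol

The experiments in `ghnn.experiments` run the published architecture
shape — 9 residual blocks (27 conv layers) per channel, the 4-layer
4-head tokenizer transformer — at reduced width and length so the
five-seed protocols complete in CPU minutes: hidden width 16, 300
epochs, learning rate 3e-3, best-validation checkpointing on with
validation every 5 epochs. These are package choices for the synthetic
benchmarks, documented here once; the `TrainConfig` defaults remain the
published values. Comparisons use the five-seed protocol (default seeds
0–4) with a two-sided Welch t-test at significance 0.05 on per-seed test
AUROC for the hyperedge condition (on 60-node test masks average
precision hangs on a few top-ranked genes; AUROC integrates the whole
ranking) and per-seed test AUPRC for the depth condition. Welch rather
than pooled-variance is deliberate and the null calibration (5% ± 2
points) is part of the test suite.

The gradient-health experiment trains the 27-layer model twice for 100
epochs on the default 600-node bundle — skips on and off — recording
each convolution layer's mean absolute weight gradient per epoch.
"Gradient" here means the mean absolute entry of the layer weight
matrix's gradient: the only monotone, sign-free summary that supports
vanishing/recovery statements. The head-input standardization is
disabled for this diagnostic — dividing by the collapsing embedding
standard deviation would adaptively rescale gradients and mask the
vanishing. Without skips the early layers' (1–10) gradients collapse by
orders of magnitude; with skips every layer stays trainable.

## Numerical choices and degenerate inputs

* Zero-degree nodes: `0^{-1/2} -> 0`; isolated nodes propagate nothing.
* ReLU subgradient at exactly 0 is 0 (the PyTorch convention); with
  zero-initialized biases some pre-activations sit exactly on the kink,
  where two-sided finite differences legitimately disagree — gradient
  tests jitter biases first.
* BCE is computed from logits with the stable
  `max(z,0) − zy + log(1 + e^{−|z|})` form.
* Average precision is the step-sum of precision increments
  (scikit-learn's `average_precision_score`); AUROC is the Mann–Whitney
  rank statistic with tie midpoints; both are cross-checked against
  independent brute-force implementations.
* Welch p-value when both groups have zero variance: 1 if means are
  equal, else 0.
* Empty hyperedges are dropped at construction; hyperedge members
  outside the graph's node set are dropped at bundle assembly; nodes
  without features get zero rows; nodes without labels join no mask.
* Model selection: final-epoch parameters by default; no early
  stopping.

## Known limitations

* CPU-only; the numpy implementation is practical to a few thousand
  nodes at the published width, not to PCNet-scale graphs.
* The transductive protocol gives no inductive (unseen-node) path.
* The hypergraph treats pathways as flat sets; within-pathway topology
  is ignored.
* The desk-scale protocol's reduced width/epochs trade absolute AUPRC
  for runtime; the synthetic comparisons are meaningful relative to each
  other, not as projections of real-data performance.
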