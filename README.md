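# ghnn — deep graph + hypergraph neural networks for gene prioritization

`ghnn` is a node-classification toolkit for pan-cancer related gene
prediction. Genes are nodes of a protein–protein interaction (PPI)
network carrying multiomics feature vectors; biological pathways enter
as hyperedges of a second, hypergraph view of the same genes. Two deep
residual convolutional encoders — one over the normalized adjacency
`D^{-1/2}(A+I)D^{-1/2}`, one over the incidence-based hypergraph operator
`D_v^{-1/2} H W D_e^{-1} H^T D_v^{-1/2}` — embed every gene in parallel:

    E_graph = DeepEncoder(G, V)      E_hyper = DeepEncoder(HG, V)
    E_merge = concat(E_graph, E_hyper)
    Pred    = sigmoid(TokenizerTransformer(E_merge))

Each encoder is a stack of residual blocks (three convolution layers +
skip connection; default 9 blocks = 27 layers per channel), and the
classifier is a feature-tokenizer transformer: every scalar of the merged
embedding becomes a 16-dimensional token, a CLS token is prepended, and a
4-layer, 4-head self-attention encoder produces the per-gene probability
of being pan-cancer related.

The package is aimed at method developers: besides the model it ships a
planted-signal synthetic benchmark generator, so the architecture's three
structural claims — pathway hyperedges help, depth helps, and skip
connections keep 27-layer stacks trainable — are each testable in CPU
minutes without downloading any multiomics dataset. Loaders for the
standard flat formats (edge-list TSV, GMT gene sets, feature/label TSV,
an HDF5 bundle cache) are included for real data.

The whole stack — convolutions, residual encoders, transformer, Adam,
backpropagation — is implemented in numpy/scipy with a small reverse-mode
autodiff; there is no deep-learning framework dependency.

## Worked example

Generate a 300-gene benchmark whose labels are driven by membership in
"signal" pathways, train the full model and its no-hypergraph ablation,
and compare:

```python
import ghnn
from ghnn.training import desk_config

bundle, truth = ghnn.generate(ghnn.hyperedge_dominant_spec(seed=0))
print(ghnn.bayes_reference(truth, bundle).auprc)   # ceiling given noise

model, log = ghnn.train(bundle, desk_config(variant="full", seed=0),
                        val_every=5)
pred = model.predict(bundle)
report = ghnn.evaluate(pred, bundle.label_set, bundle.label_set.test_mask)
print(report.auprc, report.auroc)
```

Output:

```
0.973...
0.455...  0.740...
```

The Bayes reference (scoring by the true planted risk) gives the AUPRC
ceiling ≈ 0.97 under 2% label noise; the trained full model's AUROC of
0.74 sits far above chance (0.5) at a 0.22 positive rate, while the same
protocol with `variant="no_hypergraph"` drops to ≈ 0.6 mean AUROC — the
gap is the hypergraph channel's contribution, and
`ghnn.experiments.hyperedge_signal_experiment()` runs the full five-seed
Welch-tested comparison.

The same interfaces drive the other experiments:

```python
from ghnn.experiments import (gradient_health_experiment,
                              depth_signal_experiment)

g = gradient_health_experiment()         # 27-layer gradients, skips on/off
print(g["early_layer_ratio"])            # >> 10: skips cure vanishing grads

d = depth_signal_experiment()            # 9-block vs 1-block, 5 seeds
print(d["full"].auprc, d["shallow"].auprc,
      d["comparison_auprc"].p_value)
```

A CLI mirrors the library: `ghnn simulate`, `ghnn train`, `ghnn ablate`,
`ghnn gradtrace`, `ghnn sweep`, `ghnn evaluate` (see `ghnn --help`).

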