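"""Full node-classification model: two deep encoders plus a classifier head.

The full architecture runs the node feature matrix through a deep residual
graph encoder and a deep residual hypergraph encoder in parallel,
concatenates the two 64-dimensional embeddings, and classifies each node
with the feature-tokenizer transformer.  Named ablation variants rewire
this assembly:

* ``full``          — both channels, tokenizer + transformer head
* ``linear_head``   — both channels, affine + sigmoid head
* ``no_hypergraph`` — graph channel only
* ``no_graph``      — hypergraph channel only
* ``shallow``       — one residual block (3 conv layers) per channel
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .encoder import EncoderParams, EmbeddingMatrix, encode, merge
from .netio import DatasetBundle
from .operators import PropagationOperator, graph_operator, \
    hypergraph_operator
from .tokenformer import (LinearHeadParams, PredictionVector,
                          TokenizerParams, TransformerParams,
                          linear_head_logits, tokenize, transformer_logits)

__all__ = ["TrainConfig", "PanCancerGeneModel", "VARIANTS"]

VARIANTS = ("full", "linear_head", "no_hypergraph", "no_graph", "shallow")


@dataclass
class TrainConfig:
    """Hyperparameters; defaults follow the published configuration."""

    hidden_dim: int = 64
    learning_rate: float = 1e-4
    weight_decay: float = 1e-5
    dropout: float = 0.1
    epochs: int = 3000
    n_blocks: int = 9
    token_dim: int = 16
    transformer_layers: int = 4
    transformer_heads: int = 4
    attn_ffn_dropout: float = 0.1
    seed: int = 0
    variant: str = "full"
    skip_connections: bool = True
    emerge_norm: bool = True        # standardize embedding entering the head
    select_best_val: bool = False   # evaluate best-val-AUPRC checkpoint
    grad_trace_epochs: int = 0      # record per-layer gradients this long
    class_weighting: bool = False   # optional positive-class reweighting
    weighted_graph: bool = False
    hypergraph_self_loops: bool = False

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; choose "
                             f"one of {VARIANTS}")
        for name in ("hidden_dim", "epochs", "n_blocks", "token_dim",
                     "transformer_layers", "transformer_heads"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("dropout", "attn_ffn_dropout"):
            if not (0.0 <= getattr(self, name) < 1.0):
                raise ValueError(f"{name} must be in [0,1)")


@dataclass
class PanCancerGeneModel:
    """Parameters and forward pass for one architecture variant."""

    config: TrainConfig
    graph_encoder: EncoderParams | None
    hyper_encoder: EncoderParams | None
    tokenizer: TokenizerParams | None
    transformer: TransformerParams | None
    linear_head: LinearHeadParams | None
    n_features: int = field(default=0)

    @classmethod
    def init(cls, n_features: int, config: TrainConfig,
             rng: np.random.Generator) -> "PanCancerGeneModel":
        use_graph = config.variant != "no_graph"
        use_hyper = config.variant != "no_hypergraph"
        n_blocks = 1 if config.variant == "shallow" else config.n_blocks
        g_enc = EncoderParams.init(
            n_features, rng, n_blocks=n_blocks, hidden_dim=config.hidden_dim,
            dropout_rate=config.dropout) if use_graph else None
        h_enc = EncoderParams.init(
            n_features, rng, n_blocks=n_blocks, hidden_dim=config.hidden_dim,
            dropout_rate=config.dropout) if use_hyper else None
        merged_dim = config.hidden_dim * (int(use_graph) + int(use_hyper))
        if config.variant == "linear_head":
            tok, trans, lin = None, None, LinearHeadParams.init(merged_dim,
                                                                rng)
        else:
            tok = TokenizerParams.init(merged_dim, rng,
                                       token_dim=config.token_dim)
            trans = TransformerParams.init(
                rng, token_dim=config.token_dim,
                n_layers=config.transformer_layers,
                n_heads=config.transformer_heads,
                attn_dropout=config.attn_ffn_dropout,
                ffn_dropout=config.attn_ffn_dropout)
            lin = None
        model = cls(config, g_enc, h_enc, tok, trans, lin, n_features)
        # the model runs in float32: halves the memory traffic of the
        # attention tensors with no effect at the metric scale
        for p in model.parameters():
            p.data = p.data.astype(np.float32)
        return model

    @property
    def dtype(self):
        return self.parameters()[0].data.dtype

    # -- bookkeeping -------------------------------------------------------

    def parameters(self) -> list[ad.Tensor]:
        ps: list[ad.Tensor] = []
        for enc in (self.graph_encoder, self.hyper_encoder):
            if enc is not None:
                ps += enc.parameters()
        if self.tokenizer is not None:
            ps += self.tokenizer.parameters()
        if self.transformer is not None:
            ps += self.transformer.parameters()
        if self.linear_head is not None:
            ps += self.linear_head.parameters()
        return ps

    @property
    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def operators(self, bundle: DatasetBundle
                  ) -> tuple[PropagationOperator | None,
                             PropagationOperator | None]:
        cfg = self.config
        P_g = graph_operator(bundle.graph, add_self_loops=True,
                             weighted=cfg.weighted_graph) \
            if self.graph_encoder is not None else None
        P_h = hypergraph_operator(
            bundle.hypergraph, add_self_loops=cfg.hypergraph_self_loops) \
            if self.hyper_encoder is not None else None
        for op in (P_g, P_h):  # cast after the f64 symmetry validation
            if op is not None:
                op.matrix.data = op.matrix.data.astype(self.dtype)
        return P_g, P_h

    # -- forward -----------------------------------------------------------

    def embed_tensor(self, X, P_g, P_h, train_mode: bool = False,
                     rng: np.random.Generator | None = None) -> ad.Tensor:
        """Merged embedding for every node as an autodiff tensor."""
        cfg = self.config
        x = X if isinstance(X, ad.Tensor) \
            else ad.Tensor(np.asarray(X, dtype=self.dtype))
        parts = []
        if self.graph_encoder is not None:
            parts.append(encode(x, P_g, self.graph_encoder,
                                train_mode=train_mode, rng=rng,
                                use_skip=cfg.skip_connections))
        if self.hyper_encoder is not None:
            parts.append(encode(x, P_h, self.hyper_encoder,
                                train_mode=train_mode, rng=rng,
                                use_skip=cfg.skip_connections))
        return parts[0] if len(parts) == 1 else ad.concat(parts, axis=1)

    def head_logits(self, emerge: ad.Tensor, train_mode: bool = False,
                    rng: np.random.Generator | None = None) -> ad.Tensor:
        """Classifier head on an (already merged) embedding tensor."""
        if self.linear_head is not None:
            return linear_head_logits(emerge, self.linear_head)
        tokens = tokenize(emerge, self.tokenizer)
        return transformer_logits(tokens, self.transformer,
                                  train_mode=train_mode, rng=rng)

    def emerge_scale(self, emerge_data: np.ndarray
                     ) -> tuple[np.ndarray, np.ndarray]:
        """Per-dimension (mean, std) over nodes for head standardization.

        The merged embedding of a deep residual stack rides on a large
        node-constant background that would drown the tokenizer; the head
        therefore consumes the embedding standardized across nodes, with
        the statistics treated as constants (stop-gradient), as numeric
        features entering a feature tokenizer normally are.
        """
        if not self.config.emerge_norm:
            return (np.zeros(emerge_data.shape[1], emerge_data.dtype),
                    np.ones(emerge_data.shape[1], emerge_data.dtype))
        mu = emerge_data.mean(axis=0)
        sd = emerge_data.std(axis=0) + np.asarray(1e-6, emerge_data.dtype)
        return mu, sd

    def logits(self, X, P_g, P_h, node_idx=None, train_mode: bool = False,
               rng: np.random.Generator | None = None) -> ad.Tensor:
        """Per-node logit; ``node_idx`` restricts the classifier head
        (the encoders always run on the whole graph — training is
        transductive).  Builds one unchunked graph; for large node sets
        prefer the chunked paths in :mod:`ghnn.training`."""
        emerge = self.embed_tensor(X, P_g, P_h, train_mode=train_mode,
                                   rng=rng)
        mu, sd = self.emerge_scale(emerge.data)
        emerge = (emerge - mu) * (1.0 / sd)
        if node_idx is not None:
            emerge = emerge[np.asarray(node_idx)]
        return self.head_logits(emerge, train_mode=train_mode, rng=rng)

    def embed(self, bundle: DatasetBundle) -> EmbeddingMatrix:
        """Eval-mode merged embedding for every node."""
        P_g, P_h = self.operators(bundle)
        X = bundle.features.matrix
        e_g = encode(X, P_g, self.graph_encoder,
                     use_skip=self.config.skip_connections) \
            if self.graph_encoder is not None else None
        e_h = encode(X, P_h, self.hyper_encoder,
                     use_skip=self.config.skip_connections) \
            if self.hyper_encoder is not None else None
        return merge(e_g, e_h)

    def predict(self, bundle: DatasetBundle,
                chunk_size: int | None = None) -> PredictionVector:
        """Eval-mode probabilities for every node in the bundle.

        The transformer head treats nodes independently, so it runs in
        chunks to bound the memory of the attention tensors.
        """
        emerge = self.embed(bundle).matrix
        if chunk_size is None:
            from .training import _head_chunk_size
            chunk_size = _head_chunk_size(emerge.shape[1])
        mu, sd = self.emerge_scale(emerge)
        emerge = (emerge - mu) / sd
        n = emerge.shape[0]
        probs = np.empty(n)
        for lo in range(0, n, chunk_size):
            sel = ad.Tensor(emerge[lo:lo + chunk_size])
            probs[lo:lo + chunk_size] = ad.sigmoid(
                self.head_logits(sel)).data
        return PredictionVector(probs)
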