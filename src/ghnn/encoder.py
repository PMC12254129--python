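"""Deep residual graph/hypergraph encoders.

An encoder stacks residual blocks, each a three-layer convolution with a
skip connection: the skip (identity, or a learned linear projection when
the block changes width) is added to the third layer's pre-activation
output, followed by a final ReLU.  The default depth of nine blocks gives
27 convolution layers per channel; residual shortcuts keep every layer
trainable at that depth.  The graph and hypergraph embeddings are fused by
column-wise concatenation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .operators import ConvLayerParams, PropagationOperator, conv_layer

__all__ = ["ResidualBlockParams", "EncoderParams", "EmbeddingMatrix",
           "residual_block", "encode", "merge"]

HIDDEN_DIM_DEFAULT = 64


@dataclass
class ResidualBlockParams:
    """Three chained conv layers plus an optional linear skip projection."""

    layer1: ConvLayerParams
    layer2: ConvLayerParams
    layer3: ConvLayerParams
    skip_projection: ad.Tensor | None = None

    def __post_init__(self):
        if self.layer1.out_dim != self.layer2.in_dim or \
           self.layer2.out_dim != self.layer3.in_dim:
            raise ValueError("conv layer dimensions do not chain")
        needs_proj = self.in_dim != self.out_dim
        if needs_proj and self.skip_projection is None:
            raise ValueError("dimension-changing block needs skip_projection")
        if not needs_proj and self.skip_projection is not None:
            raise ValueError("square block must use an identity skip")

    @property
    def in_dim(self) -> int:
        return self.layer1.in_dim

    @property
    def out_dim(self) -> int:
        return self.layer3.out_dim

    @classmethod
    def init(cls, in_dim: int, out_dim: int, rng: np.random.Generator,
             dropout_rate: float = 0.1) -> "ResidualBlockParams":
        l1 = ConvLayerParams.init(in_dim, out_dim, rng, dropout_rate)
        l2 = ConvLayerParams.init(out_dim, out_dim, rng, dropout_rate)
        l3 = ConvLayerParams.init(out_dim, out_dim, rng, dropout_rate)
        proj = None
        if in_dim != out_dim:
            limit = np.sqrt(6.0 / (in_dim + out_dim))
            proj = ad.Parameter(rng.uniform(-limit, limit,
                                            size=(in_dim, out_dim)))
        return cls(l1, l2, l3, proj)

    def parameters(self) -> list[ad.Tensor]:
        ps = [self.layer1.weight, self.layer1.bias,
              self.layer2.weight, self.layer2.bias,
              self.layer3.weight, self.layer3.bias]
        if self.skip_projection is not None:
            ps.append(self.skip_projection)
        return ps

    def conv_layers(self) -> list[ConvLayerParams]:
        return [self.layer1, self.layer2, self.layer3]


@dataclass
class EncoderParams:
    """Ordered residual blocks; default 9 blocks of hidden width 64."""

    blocks: list[ResidualBlockParams]
    hidden_dim: int = HIDDEN_DIM_DEFAULT

    def __post_init__(self):
        if not self.blocks:
            raise ValueError("encoder needs at least one block")
        for prev, nxt in zip(self.blocks, self.blocks[1:]):
            if prev.out_dim != nxt.in_dim:
                raise ValueError("block dimensions do not chain")
        for blk in self.blocks[1:]:
            if blk.in_dim != self.hidden_dim or blk.out_dim != self.hidden_dim:
                raise ValueError("non-first blocks must be hidden -> hidden")

    @classmethod
    def init(cls, in_dim: int, rng: np.random.Generator, n_blocks: int = 9,
             hidden_dim: int = HIDDEN_DIM_DEFAULT,
             dropout_rate: float = 0.1) -> "EncoderParams":
        dims = [in_dim] + [hidden_dim] * n_blocks
        blocks = [ResidualBlockParams.init(dims[i], dims[i + 1], rng,
                                           dropout_rate)
                  for i in range(n_blocks)]
        return cls(blocks, hidden_dim)

    def parameters(self) -> list[ad.Tensor]:
        return [p for blk in self.blocks for p in blk.parameters()]

    def conv_layers(self) -> list[ConvLayerParams]:
        """All conv layers in forward order (layer 1 nearest the input)."""
        return [l for blk in self.blocks for l in blk.conv_layers()]

    @property
    def n_layers(self) -> int:
        return 3 * len(self.blocks)


@dataclass
class EmbeddingMatrix:
    """Node-by-dimension embedding tagged with its producing channel."""

    matrix: np.ndarray
    source: str  # "graph" | "hypergraph" | "merged"

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix)
        if self.source not in ("graph", "hypergraph", "merged"):
            raise ValueError(f"unknown embedding source {self.source!r}")
        if not np.isfinite(self.matrix).all():
            raise ValueError("embedding has non-finite entries")

    @property
    def n_nodes(self) -> int:
        return self.matrix.shape[0]

    @property
    def dim(self) -> int:
        return self.matrix.shape[1]


def residual_block(X, P: PropagationOperator, params: ResidualBlockParams,
                   train_mode: bool = False,
                   rng: np.random.Generator | None = None,
                   use_skip: bool = True):
    """One block: ReLU(conv3(conv2(conv1(X))) + skip(X)).

    The first two conv layers are ReLU-activated, the third is linear so
    the skip adds to a pre-activation value.  ``use_skip=False`` yields the
    ablated (plain deep) block used in gradient-health experiments.
    """
    was_array = not isinstance(X, ad.Tensor)
    x = ad.as_float_tensor(X) if was_array else X
    h = conv_layer(x, P, params.layer1, activate=True,
                   train_mode=train_mode, rng=rng)
    h = conv_layer(h, P, params.layer2, activate=True,
                   train_mode=train_mode, rng=rng)
    h = conv_layer(h, P, params.layer3, activate=False,
                   train_mode=train_mode, rng=rng)
    if use_skip:
        skip = x if params.skip_projection is None \
            else x @ params.skip_projection
        h = h + skip
    out = ad.relu(h)
    return out.data if was_array else out


def encode(X, P: PropagationOperator, params: EncoderParams,
           train_mode: bool = False,
           rng: np.random.Generator | None = None,
           use_skip: bool = True):
    """Apply all residual blocks in sequence.

    Returns an :class:`EmbeddingMatrix` for array input, or the raw
    autodiff Tensor when called inside a training graph.
    """
    was_array = not isinstance(X, ad.Tensor)
    h = ad.as_float_tensor(X) if was_array else X
    for blk in params.blocks:
        h = residual_block(h, P, blk, train_mode=train_mode, rng=rng,
                           use_skip=use_skip)
    if was_array:
        return EmbeddingMatrix(h.data, P.kind)
    return h


def merge(e_graph: EmbeddingMatrix | None,
          e_hyper: EmbeddingMatrix | None) -> EmbeddingMatrix:
    """Column-wise concatenation, graph columns first.

    Either argument may be None or zero-width (the channel-ablation paths),
    in which case the other embedding passes through.
    """
    parts = []
    if e_graph is not None and e_graph.dim > 0:
        if e_graph.source != "graph":
            raise ValueError("first argument must come from the graph "
                             "channel")
        parts.append(e_graph.matrix)
    if e_hyper is not None and e_hyper.dim > 0:
        if e_hyper.source != "hypergraph":
            raise ValueError("second argument must come from the hypergraph "
                             "channel")
        parts.append(e_hyper.matrix)
    if not parts:
        raise ValueError("nothing to merge")
    if len(parts) == 2 and parts[0].shape[0] != parts[1].shape[0]:
        raise ValueError(f"node count mismatch: {parts[0].shape[0]} vs "
                         f"{parts[1].shape[0]}")
    return EmbeddingMatrix(np.concatenate(parts, axis=1), "merged")
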