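"""Feature-tokenizer + transformer classification head.

Each scalar of the merged node embedding becomes one token through a
per-feature affine map (token_i = x_i * w_i + b_i); a learned CLS token is
prepended and a small pre-norm multi-head self-attention encoder mixes the
tokens.  The CLS position's final representation passes through a linear
head and a sigmoid to give a per-node probability of being a pan-cancer
related gene.  Feature tokens carry no positional encoding — the feature
set is unordered and the CLS token marks the readout position — so the
output is invariant to permuting the non-CLS tokens.

A plain affine + sigmoid head (:func:`linear_classifier`) is provided as
the linear-head ablation through the same prediction interface.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .encoder import EmbeddingMatrix

__all__ = ["TokenizerParams", "TransformerParams", "LinearHeadParams",
           "PredictionVector", "tokenize", "classify", "transformer_logits",
           "linear_classifier"]

TOKEN_DIM_DEFAULT = 16


def _glorot(rng, shape):
    limit = np.sqrt(6.0 / (shape[0] + shape[-1]))
    return rng.uniform(-limit, limit, size=shape)


@dataclass
class TokenizerParams:
    """Per-feature affine token embeddings plus the CLS token."""

    per_feature_weight: ad.Tensor  # (n_features, token_dim)
    per_feature_bias: ad.Tensor    # (n_features, token_dim)
    cls_token: ad.Tensor           # (token_dim,)

    @property
    def n_features(self) -> int:
        return self.per_feature_weight.shape[0]

    @property
    def token_dim(self) -> int:
        return self.per_feature_weight.shape[1]

    @classmethod
    def init(cls, n_features: int, rng: np.random.Generator,
             token_dim: int = TOKEN_DIM_DEFAULT) -> "TokenizerParams":
        return cls(
            ad.Parameter(_glorot(rng, (n_features, token_dim))),
            ad.Parameter(np.zeros((n_features, token_dim))),
            ad.Parameter(rng.normal(0.0, 0.02, size=token_dim)),
        )

    def parameters(self) -> list[ad.Tensor]:
        return [self.per_feature_weight, self.per_feature_bias,
                self.cls_token]


@dataclass
class _AttnBlockParams:
    """One pre-norm transformer layer: LN -> MHSA -> add, LN -> FFN -> add."""

    ln1_gamma: ad.Tensor
    ln1_beta: ad.Tensor
    wq: ad.Tensor
    wk: ad.Tensor
    wv: ad.Tensor
    wo: ad.Tensor
    bq: ad.Tensor
    bk: ad.Tensor
    bv: ad.Tensor
    bo: ad.Tensor
    ln2_gamma: ad.Tensor
    ln2_beta: ad.Tensor
    ffn_w1: ad.Tensor
    ffn_b1: ad.Tensor
    ffn_w2: ad.Tensor
    ffn_b2: ad.Tensor

    @classmethod
    def init(cls, d: int, ffn_hidden: int, rng: np.random.Generator):
        z = np.zeros
        return cls(
            ad.Parameter(np.ones(d)), ad.Parameter(z(d)),
            ad.Parameter(_glorot(rng, (d, d))),
            ad.Parameter(_glorot(rng, (d, d))),
            ad.Parameter(_glorot(rng, (d, d))),
            ad.Parameter(_glorot(rng, (d, d))),
            ad.Parameter(z(d)), ad.Parameter(z(d)),
            ad.Parameter(z(d)), ad.Parameter(z(d)),
            ad.Parameter(np.ones(d)), ad.Parameter(z(d)),
            ad.Parameter(_glorot(rng, (d, ffn_hidden))),
            ad.Parameter(z(ffn_hidden)),
            ad.Parameter(_glorot(rng, (ffn_hidden, d))),
            ad.Parameter(z(d)),
        )

    def parameters(self) -> list[ad.Tensor]:
        return [self.ln1_gamma, self.ln1_beta, self.wq, self.wk, self.wv,
                self.wo, self.bq, self.bk, self.bv, self.bo,
                self.ln2_gamma, self.ln2_beta,
                self.ffn_w1, self.ffn_b1, self.ffn_w2, self.ffn_b2]


@dataclass
class TransformerParams:
    """Depth-4, 4-head pre-norm transformer encoder plus the sigmoid head."""

    layers: list[_AttnBlockParams]
    n_heads: int
    attn_dropout: float
    ffn_dropout: float
    lnf_gamma: ad.Tensor
    lnf_beta: ad.Tensor
    head_weight: ad.Tensor  # (token_dim, 1)
    head_bias: ad.Tensor    # (1,)
    token_dim: int = TOKEN_DIM_DEFAULT

    def __post_init__(self):
        if self.token_dim % self.n_heads != 0:
            raise ValueError(f"token_dim {self.token_dim} not divisible by "
                             f"n_heads {self.n_heads}")
        for r in (self.attn_dropout, self.ffn_dropout):
            if not (0.0 <= r < 1.0):
                raise ValueError(f"dropout {r} not in [0,1)")

    @classmethod
    def init(cls, rng: np.random.Generator,
             token_dim: int = TOKEN_DIM_DEFAULT, n_layers: int = 4,
             n_heads: int = 4, attn_dropout: float = 0.1,
             ffn_dropout: float = 0.1,
             ffn_hidden: int | None = None) -> "TransformerParams":
        if token_dim % n_heads != 0:
            raise ValueError(f"token_dim {token_dim} not divisible by "
                             f"n_heads {n_heads}")
        ffn_hidden = ffn_hidden or 4 * token_dim
        layers = [_AttnBlockParams.init(token_dim, ffn_hidden, rng)
                  for _ in range(n_layers)]
        return cls(layers, n_heads, attn_dropout, ffn_dropout,
                   ad.Parameter(np.ones(token_dim)),
                   ad.Parameter(np.zeros(token_dim)),
                   ad.Parameter(_glorot(rng, (token_dim, 1))),
                   ad.Parameter(np.zeros(1)), token_dim)

    def parameters(self) -> list[ad.Tensor]:
        ps = [p for layer in self.layers for p in layer.parameters()]
        ps += [self.lnf_gamma, self.lnf_beta, self.head_weight,
               self.head_bias]
        return ps


@dataclass
class LinearHeadParams:
    """Affine + sigmoid replacement classifier (linear-head ablation)."""

    weight: ad.Tensor  # (n_features, 1)
    bias: ad.Tensor    # (1,)

    @classmethod
    def init(cls, n_features: int,
             rng: np.random.Generator) -> "LinearHeadParams":
        return cls(ad.Parameter(_glorot(rng, (n_features, 1))),
                   ad.Parameter(np.zeros(1)))

    def parameters(self) -> list[ad.Tensor]:
        return [self.weight, self.bias]


@dataclass
class PredictionVector:
    """Per-node probability of the positive (pan-cancer related) class."""

    probabilities: np.ndarray = field()

    def __post_init__(self):
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        if self.probabilities.ndim != 1:
            raise ValueError("probabilities must be one-dimensional")
        if ((self.probabilities < 0) | (self.probabilities > 1)).any():
            raise ValueError("probabilities outside [0,1]")

    def __len__(self):
        return len(self.probabilities)


# ---------------------------------------------------------------------------
# Forward passes
# ---------------------------------------------------------------------------

def tokenize(emerge, params: TokenizerParams):
    """Embed each scalar feature as a token and prepend CLS.

    Input: node-by-feature matrix (or :class:`EmbeddingMatrix`); output has
    shape (n_nodes, n_features + 1, token_dim) with CLS at position 0.
    """
    if isinstance(emerge, EmbeddingMatrix):
        emerge = emerge.matrix
    was_array = not isinstance(emerge, ad.Tensor)
    x = ad.as_float_tensor(emerge) if was_array else emerge
    n, m = x.shape
    if m != params.n_features:
        raise ValueError(f"embedding dim {m} != tokenizer feature count "
                         f"{params.n_features}")
    d = params.token_dim
    tok = x.reshape(n, m, 1) * params.per_feature_weight \
        + params.per_feature_bias
    ones = ad.Tensor(np.ones((n, 1, 1), dtype=tok.data.dtype))
    cls = ones * params.cls_token.reshape(1, 1, d)
    seq = ad.concat([cls, tok], axis=1)
    return seq.data if was_array else seq


def _mhsa(x: ad.Tensor, p: _AttnBlockParams, n_heads: int, attn_dropout,
          train_mode, rng) -> ad.Tensor:
    n, L, d = x.shape
    dh = d // n_heads

    def heads(t):
        return t.reshape(n, L, n_heads, dh).transpose(0, 2, 1, 3)

    # scale folded into q (cheaper than scaling the L x L score tensor)
    q = heads((x @ p.wq + p.bq) * np.asarray(1.0 / np.sqrt(dh),
                                             dtype=x.data.dtype))
    k = heads(x @ p.wk + p.bk)
    v = heads(x @ p.wv + p.bv)
    scores = q @ k.transpose(0, 1, 3, 2)
    probs = ad.softmax(scores, axis=-1)
    probs = ad.dropout(probs, attn_dropout, rng, train_mode) \
        if train_mode else probs
    out = (probs @ v).transpose(0, 2, 1, 3).reshape(n, L, d)
    return out @ p.wo + p.bo


def transformer_logits(tokens, params: TransformerParams,
                       train_mode: bool = False,
                       rng: np.random.Generator | None = None) -> ad.Tensor:
    """Run the encoder and return the CLS logit per node (autodiff Tensor)."""
    x = ad.as_float_tensor(tokens)
    if x.shape[-1] != params.token_dim:
        raise ValueError(f"token dim {x.shape[-1]} != transformer width "
                         f"{params.token_dim}")
    if train_mode and rng is None:
        raise ValueError("train_mode requires an rng for dropout")
    for layer in params.layers:
        h = ad.layer_norm(x, layer.ln1_gamma, layer.ln1_beta)
        x = x + _mhsa(h, layer, params.n_heads, params.attn_dropout,
                      train_mode, rng)
        h = ad.layer_norm(x, layer.ln2_gamma, layer.ln2_beta)
        h = ad.relu(h @ layer.ffn_w1 + layer.ffn_b1)
        h = ad.dropout(h, params.ffn_dropout, rng, train_mode) \
            if train_mode else h
        x = x + (h @ layer.ffn_w2 + layer.ffn_b2)
    cls = ad.layer_norm(x, params.lnf_gamma, params.lnf_beta)[:, 0, :]
    logit = cls @ params.head_weight + params.head_bias
    return logit.reshape(x.shape[0])


def classify(tokens, params: TransformerParams,
             train_mode: bool = False,
             rng: np.random.Generator | None = None) -> PredictionVector:
    """Transformer + sigmoid head over token sequences."""
    logits = transformer_logits(tokens, params, train_mode, rng)
    return PredictionVector(ad.sigmoid(logits).data)


def linear_head_logits(emerge, params: LinearHeadParams) -> ad.Tensor:
    if isinstance(emerge, EmbeddingMatrix):
        emerge = emerge.matrix
    x = ad.as_float_tensor(emerge)
    return (x @ params.weight + params.bias).reshape(x.shape[0])


def linear_classifier(emerge, params: LinearHeadParams) -> PredictionVector:
    """Affine map + sigmoid: the linear-head ablation classifier."""
    return PredictionVector(ad.sigmoid(linear_head_logits(emerge,
                                                          params)).data)
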