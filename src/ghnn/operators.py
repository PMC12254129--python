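"""Propagation operators and single convolution layers.

Two symmetric, nonnegative propagation operators drive feature smoothing:

* graph channel:      S = D^{-1/2} (A + I) D^{-1/2}
* hypergraph channel: S = D_v^{-1/2} H W D_e^{-1} H^T D_v^{-1/2}

where A is the 0/1 adjacency, H the node-by-hyperedge incidence, W the
diagonal hyperedge weights, D the degree of (A+I), D_v = diag(H W 1) and
D_e = diag(1^T H).  Zero degrees follow the convention 0^{-1/2} -> 0, so
isolated nodes propagate nothing instead of producing infinities.

One convolution layer computes act(S X W + b) with dropout on the layer
input during training.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from . import autodiff as ad
from .netio import GeneGraph, PathwayHypergraph

__all__ = ["PropagationOperator", "ConvLayerParams", "graph_operator",
           "hypergraph_operator", "conv_layer"]


@dataclass
class PropagationOperator:
    """A sparse symmetric node-by-node propagation matrix."""

    matrix: sp.csr_matrix
    kind: str  # "graph" | "hypergraph"

    def __post_init__(self):
        if self.kind not in ("graph", "hypergraph"):
            raise ValueError(f"unknown operator kind {self.kind!r}")
        self.matrix = sp.csr_matrix(self.matrix)
        if not np.isfinite(self.matrix.data).all():
            raise ValueError("operator has non-finite entries")
        asym = abs(self.matrix - self.matrix.T)
        if asym.nnz and asym.max() > 1e-9:
            raise ValueError("operator is not symmetric")

    @property
    def n_nodes(self) -> int:
        return self.matrix.shape[0]

    def dense(self) -> np.ndarray:
        return self.matrix.toarray()


def _inv_sqrt(d: np.ndarray) -> np.ndarray:
    """Elementwise d^{-1/2} with the 0 -> 0 convention."""
    out = np.zeros_like(d, dtype=float)
    pos = d > 0
    out[pos] = 1.0 / np.sqrt(d[pos])
    return out


def graph_operator(graph: GeneGraph, add_self_loops: bool = True,
                   weighted: bool = False) -> PropagationOperator:
    """Symmetric-normalized adjacency D^{-1/2}(A+I)D^{-1/2}.

    The adjacency is 0/1 by default; ``weighted=True`` uses stored edge
    weights instead.  ``add_self_loops`` adds the identity before
    normalization (the default, matching common GCN practice).
    """
    n = graph.n_nodes
    if n == 0:
        raise ValueError("empty graph")
    rows, cols, vals = [], [], []
    for (i, j) in graph.edges:
        w = graph.weight((i, j)) if weighted else 1.0
        rows += [i, j]
        cols += [j, i]
        vals += [w, w]
    A = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
    if add_self_loops:
        A = A + sp.identity(n, format="csr")
    d = np.asarray(A.sum(axis=1)).ravel()
    Dinv = sp.diags(_inv_sqrt(d))
    S = Dinv @ A @ Dinv
    return PropagationOperator(S.tocsr(), "graph")


def hypergraph_operator(hg: PathwayHypergraph, add_self_loops: bool = False,
                        ) -> PropagationOperator:
    """Incidence-normalized hypergraph operator.

    With ``add_self_loops`` each node additionally joins a singleton
    hyperedge of weight 1, guaranteeing a nonzero diagonal even for nodes
    with no pathway membership.
    """
    n = hg.n_nodes
    if n == 0:
        raise ValueError("empty hypergraph")
    rows, cols, weights = [], [], []
    for j, (_, members) in enumerate(hg.hyperedges):
        assert len(members) > 0, "empty hyperedge escaped construction"
        for m in members:
            rows.append(m)
            cols.append(j)
        weights.append(hg.hyperedge_weight[j])
    m_edges = len(hg.hyperedges)
    if add_self_loops:
        for i in range(n):
            rows.append(i)
            cols.append(m_edges + i)
            weights.append(1.0)
        m_edges += n
    H = sp.csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, m_edges))
    W = np.asarray(weights, dtype=float)
    d_v = np.asarray(H @ W).ravel()
    d_e = np.asarray(H.sum(axis=0)).ravel()
    inv_de = np.zeros_like(d_e)
    pos = d_e > 0
    inv_de[pos] = 1.0 / d_e[pos]
    Dv = sp.diags(_inv_sqrt(d_v))
    S = Dv @ H @ sp.diags(W * inv_de) @ H.T @ Dv
    return PropagationOperator(S.tocsr(), "hypergraph")


@dataclass
class ConvLayerParams:
    """Weights of one convolution layer: X -> act(S X W + b)."""

    weight: ad.Tensor
    bias: ad.Tensor
    dropout_rate: float = 0.1

    def __post_init__(self):
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValueError(f"dropout_rate {self.dropout_rate} not in [0,1)")

    @property
    def in_dim(self) -> int:
        return self.weight.shape[0]

    @property
    def out_dim(self) -> int:
        return self.weight.shape[1]

    @classmethod
    def init(cls, in_dim: int, out_dim: int, rng: np.random.Generator,
             dropout_rate: float = 0.1) -> "ConvLayerParams":
        """Glorot-uniform weight, zero bias."""
        limit = np.sqrt(6.0 / (in_dim + out_dim))
        w = rng.uniform(-limit, limit, size=(in_dim, out_dim))
        return cls(ad.Parameter(w), ad.Parameter(np.zeros(out_dim)),
                   dropout_rate)


def conv_layer(X, P: PropagationOperator, params: ConvLayerParams,
               activate: bool = True, train_mode: bool = False,
               rng: np.random.Generator | None = None):
    """One graph/hypergraph convolution: act(P X W + b).

    ``X`` may be a numpy array or an autodiff Tensor; the return type
    follows the input.  Dropout is applied to the layer input only in
    train mode (``rng`` required then).
    """
    was_array = not isinstance(X, ad.Tensor)
    x = ad.as_float_tensor(X) if was_array else X
    if x.shape[0] != P.n_nodes:
        raise ValueError(f"node count mismatch: features {x.shape} vs "
                         f"operator {P.matrix.shape}")
    if x.shape[1] != params.in_dim:
        raise ValueError(f"feature dim mismatch: features {x.shape} vs "
                         f"weight {params.weight.shape}")
    if train_mode:
        if rng is None:
            raise ValueError("train_mode requires an rng for dropout")
        x = ad.dropout(x, params.dropout_rate, rng, True)
    h = ad.sparse_matmul(P.matrix, x) @ params.weight + params.bias
    if activate:
        h = ad.relu(h)
    return h.data if was_array else h
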