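"""Readers, writers and assembly of aligned graph/hypergraph datasets.

A dataset bundles four components on one shared node ordering: a gene
interaction graph (e.g. a protein-protein interaction network), a pathway
hypergraph (gene sets, one hyperedge per pathway), a node-by-feature
multiomics matrix, and binary labels with train/validation/test masks.
The graph's node set is the reference universe; the other components are
projected onto it during assembly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import h5py
import numpy as np

logger = logging.getLogger("ghnn")

__all__ = [
    "GeneGraph", "PathwayHypergraph", "OmicsFeatures", "LabelSet",
    "DatasetBundle", "read_edge_list", "write_edge_list", "read_gene_sets",
    "read_feature_table", "read_label_table", "assemble_bundle",
    "save_bundle", "load_bundle",
]


class ParseError(ValueError):
    """Raised for malformed input files, naming the offending line."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class GeneGraph:
    """Undirected gene interaction graph.

    Edges are stored as unordered index pairs (i < j); self-loops are never
    stored.  ``edge_weight`` defaults to 1 for every edge.
    """

    node_ids: list[str]
    edges: set[tuple[int, int]]
    edge_weight: dict[tuple[int, int], float] = field(default_factory=dict)

    def __post_init__(self):
        n = len(self.node_ids)
        norm = set()
        for a, b in self.edges:
            if a == b:
                raise ValueError(f"self-loop on node index {a}")
            if not (0 <= a < n and 0 <= b < n):
                raise ValueError(f"edge ({a},{b}) out of range for {n} nodes")
            norm.add((min(a, b), max(a, b)))
        self.edges = norm
        self.edge_weight = {(min(a, b), max(a, b)): w
                            for (a, b), w in self.edge_weight.items()}

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    def weight(self, edge: tuple[int, int]) -> float:
        a, b = edge
        return self.edge_weight.get((min(a, b), max(a, b)), 1.0)


@dataclass
class PathwayHypergraph:
    """Pathway membership hypergraph: each hyperedge is a gene set."""

    node_ids: list[str]
    hyperedges: list[tuple[str, frozenset[int]]]
    hyperedge_weight: list[float] = field(default_factory=list)

    def __post_init__(self):
        n = len(self.node_ids)
        kept, weights = [], []
        for k, (name, members) in enumerate(self.hyperedges):
            members = frozenset(members)
            if not members:
                continue  # empty hyperedges are dropped at construction
            bad = [m for m in members if not (0 <= m < n)]
            if bad:
                raise ValueError(f"hyperedge {name!r} has invalid member "
                                 f"indices {bad}")
            kept.append((name, members))
            weights.append(self.hyperedge_weight[k]
                           if self.hyperedge_weight else 1.0)
        self.hyperedges = kept
        self.hyperedge_weight = weights

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def n_hyperedges(self) -> int:
        return len(self.hyperedges)

    def incidence(self) -> np.ndarray:
        """Dense 0/1 node-by-hyperedge incidence matrix."""
        H = np.zeros((self.n_nodes, self.n_hyperedges))
        for j, (_, members) in enumerate(self.hyperedges):
            H[list(members), j] = 1.0
        return H


@dataclass
class OmicsFeatures:
    """Node-by-feature numeric matrix (multiomics attributes per gene)."""

    node_ids: list[str]
    matrix: np.ndarray
    feature_names: list[str]

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (len(self.node_ids), len(self.feature_names)):
            raise ValueError(
                f"feature matrix shape {self.matrix.shape} does not match "
                f"{len(self.node_ids)} nodes x {len(self.feature_names)} "
                "features")
        if not np.isfinite(self.matrix).all():
            raise ValueError("feature matrix contains non-finite entries")


@dataclass
class LabelSet:
    """Binary node labels (1 = pan-cancer related) plus disjoint split masks.

    ``labels`` uses -1 for unknown; masked nodes must have known labels.
    """

    labels: np.ndarray
    train_mask: np.ndarray
    val_mask: np.ndarray
    test_mask: np.ndarray

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        for name in ("train_mask", "val_mask", "test_mask"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=bool))
        if (self.train_mask & self.val_mask).any() or \
           (self.train_mask & self.test_mask).any() or \
           (self.val_mask & self.test_mask).any():
            raise ValueError("split masks overlap")
        masked = self.train_mask | self.val_mask | self.test_mask
        if (self.labels[masked] < 0).any():
            raise ValueError("masked node with unknown label")
        tr = self.labels[self.train_mask]
        if tr.size and not ((tr == 1).any() and (tr == 0).any()):
            raise ValueError("train mask needs at least one node per class")

    @property
    def n_nodes(self) -> int:
        return len(self.labels)


@dataclass
class DatasetBundle:
    """Graph, hypergraph, features and labels on one shared node ordering."""

    graph: GeneGraph
    hypergraph: PathwayHypergraph
    features: OmicsFeatures
    label_set: LabelSet

    def __post_init__(self):
        ids = self.graph.node_ids
        if self.hypergraph.node_ids != ids or self.features.node_ids != ids \
                or self.label_set.n_nodes != len(ids):
            raise ValueError("bundle components disagree on node ordering")

    @property
    def n_nodes(self) -> int:
        return self.graph.n_nodes

    @property
    def node_ids(self) -> list[str]:
        return self.graph.node_ids


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def _split_line(line: str, dialect: str) -> list[str]:
    if dialect == "csv":
        return [f.strip() for f in line.split(",")]
    return line.split()


def read_edge_list(path, dialect: str = "tsv") -> GeneGraph:
    """Read an undirected edge list (two node columns, optional weight).

    Lines starting with ``#`` are ignored.  Duplicate edges (in either
    orientation) are deduplicated; self-loop lines are dropped and counted.
    """
    node_index: dict[str, int] = {}
    edges: set[tuple[int, int]] = set()
    weights: dict[tuple[int, int], float] = {}
    n_self_loops = 0
    n_lines = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = _split_line(line, dialect)
            if len(fields) < 2:
                raise ParseError(f"{path}:{lineno}: expected at least two "
                                 f"columns, got {len(fields)}")
            a, b = fields[0], fields[1]
            w = 1.0
            if len(fields) >= 3:
                try:
                    w = float(fields[2])
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: non-numeric weight "
                                     f"{fields[2]!r}") from exc
                if w < 0:
                    raise ParseError(f"{path}:{lineno}: negative weight {w}")
            n_lines += 1
            for name in (a, b):
                if name not in node_index:
                    node_index[name] = len(node_index)
            if a == b:
                n_self_loops += 1
                continue
            i, j = node_index[a], node_index[b]
            key = (min(i, j), max(i, j))
            edges.add(key)
            weights[key] = w
    if n_lines == 0:
        raise ParseError(f"{path}: no edges found")
    if n_self_loops:
        logger.info("read_edge_list: dropped %d self-loop line(s) from %s",
                    n_self_loops, path)
    return GeneGraph(list(node_index), edges, weights)


def write_edge_list(graph: GeneGraph, path) -> None:
    with open(path, "w") as fh:
        for i, j in sorted(graph.edges):
            fh.write(f"{graph.node_ids[i]}\t{graph.node_ids[j]}\t"
                     f"{graph.weight((i, j))}\n")


def read_gene_sets(path) -> PathwayHypergraph:
    """Read gene sets in GMT format: name, description, member genes.

    The hypergraph's node universe is the union of all members in
    first-appearance order; restriction to a graph's nodes happens in
    :func:`assemble_bundle`.
    """
    node_index: dict[str, int] = {}
    hyperedges: list[tuple[str, frozenset[int]]] = []
    n_dropped = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: GMT line needs >=3 "
                                 f"tab-separated fields, got {len(fields)}")
            name, members = fields[0], []
            seen = set()
            for gene in fields[2:]:
                gene = gene.strip()
                if not gene or gene in seen:
                    continue
                seen.add(gene)
                if gene not in node_index:
                    node_index[gene] = len(node_index)
                members.append(node_index[gene])
            if not members:
                n_dropped += 1
                continue
            hyperedges.append((name, frozenset(members)))
    if n_dropped:
        logger.info("read_gene_sets: dropped %d empty gene set(s) from %s",
                    n_dropped, path)
    return PathwayHypergraph(list(node_index), hyperedges)


def read_feature_table(path, impute: str = "zero") -> OmicsFeatures:
    """Read a TSV feature table (header row; first column is the node id).

    Empty cells are imputed: ``"zero"`` fills 0.0, ``"mean"`` fills the
    column mean over observed values (0.0 if a column is all-missing).
    """
    if impute not in ("zero", "mean"):
        raise ValueError(f"unknown imputation rule {impute!r}")
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header.strip():
            raise ParseError(f"{path}: empty file")
        feature_names = header.split("\t")[1:]
        node_ids: list[str] = []
        rows: list[list[float]] = []
        for lineno, raw in enumerate(fh, start=2):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != len(feature_names) + 1:
                raise ParseError(f"{path}:{lineno}: expected "
                                 f"{len(feature_names) + 1} columns, got "
                                 f"{len(fields)}")
            node_ids.append(fields[0])
            row = []
            for col, cell in enumerate(fields[1:]):
                cell = cell.strip()
                if cell == "":
                    row.append(np.nan)
                    continue
                try:
                    row.append(float(cell))
                except ValueError as exc:
                    raise ParseError(
                        f"{path}:{lineno}: non-numeric value {cell!r} in "
                        f"column {feature_names[col]!r}") from exc
            rows.append(row)
    matrix = np.array(rows, dtype=float).reshape(len(node_ids),
                                                 len(feature_names))
    missing = np.isnan(matrix)
    if missing.any():
        if impute == "zero":
            matrix[missing] = 0.0
        else:
            observed = np.maximum((~missing).sum(axis=0), 1)
            col_mean = np.where(missing, 0.0, matrix).sum(axis=0) / observed
            matrix[missing] = np.broadcast_to(col_mean, matrix.shape)[missing]
    return OmicsFeatures(node_ids, matrix, feature_names)


def read_label_table(path) -> tuple[list[str], np.ndarray, list[str]]:
    """Read labels: TSV with header ``node<TAB>label<TAB>split``.

    Returns (node_ids, labels, split_tags); split tags are
    ``train``/``val``/``test`` or empty for unlabeled use.
    """
    node_ids, labels, splits = [], [], []
    with open(path) as fh:
        header = fh.readline()
        if not header.strip():
            raise ParseError(f"{path}: empty file")
        for lineno, raw in enumerate(fh, start=2):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ParseError(f"{path}:{lineno}: expected node, label"
                                 "[, split]")
            node_ids.append(fields[0])
            try:
                labels.append(int(fields[1]))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer label "
                                 f"{fields[1]!r}") from exc
            splits.append(fields[2].strip() if len(fields) > 2 else "")
    return node_ids, np.array(labels, dtype=int), splits


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------

def assemble_bundle(graph: GeneGraph,
                    hypergraph: PathwayHypergraph,
                    features: OmicsFeatures,
                    labels: tuple[list[str], np.ndarray, list[str]],
                    ) -> DatasetBundle:
    """Align all components onto the graph's node ordering.

    The graph defines the node universe.  Hyperedge members outside it are
    dropped (empty hyperedges vanish); nodes without feature rows get zero
    rows; nodes without labels are unlabeled and excluded from every mask.
    """
    ids = graph.node_ids
    index = {name: i for i, name in enumerate(ids)}
    n = len(ids)

    # hypergraph restriction
    new_edges, new_weights = [], []
    for k, (name, members) in enumerate(hypergraph.hyperedges):
        kept = frozenset(index[hypergraph.node_ids[m]] for m in members
                         if hypergraph.node_ids[m] in index)
        if kept:
            new_edges.append((name, kept))
            new_weights.append(hypergraph.hyperedge_weight[k])
    hg = PathwayHypergraph(list(ids), new_edges, new_weights)

    # feature projection
    fmat = np.zeros((n, len(features.feature_names)))
    n_missing = 0
    feat_index = {name: i for i, name in enumerate(features.node_ids)}
    for i, name in enumerate(ids):
        j = feat_index.get(name)
        if j is None:
            n_missing += 1
        else:
            fmat[i] = features.matrix[j]
    if n_missing:
        logger.info("assemble_bundle: %d node(s) without features got zero "
                    "rows", n_missing)
    feats = OmicsFeatures(list(ids), fmat, list(features.feature_names))

    # labels and masks
    lab_ids, lab_values, lab_splits = labels
    lab = np.full(n, -1, dtype=int)
    masks = {"train": np.zeros(n, bool), "val": np.zeros(n, bool),
             "test": np.zeros(n, bool)}
    for name, value, split in zip(lab_ids, lab_values, lab_splits):
        i = index.get(name)
        if i is None:
            continue
        lab[i] = value
        if split in masks:
            masks[split][i] = True
    if (lab >= 0).sum() == 0:
        raise ValueError("no labeled node intersects the graph's node set")
    label_set = LabelSet(lab, masks["train"], masks["val"], masks["test"])
    return DatasetBundle(graph, hg, feats, label_set)


# ---------------------------------------------------------------------------
# Bundle cache (HDF5)
# ---------------------------------------------------------------------------

def save_bundle(bundle: DatasetBundle, path) -> None:
    """Write a bundle to one HDF5 container, bit-stably."""
    g = bundle.graph
    adj = np.array(sorted(g.edges), dtype=np.int64).reshape(-1, 2)
    adj_w = np.array([g.weight(tuple(e)) for e in adj], dtype=float)
    inc_pairs = []
    for j, (_, members) in enumerate(bundle.hypergraph.hyperedges):
        for m in sorted(members):
            inc_pairs.append((m, j))
    inc = np.array(inc_pairs, dtype=np.int64).reshape(-1, 2)
    ls = bundle.label_set
    with h5py.File(path, "w") as f:
        f.create_dataset("node_ids",
                         data=np.array(bundle.node_ids, dtype="S"))
        f.create_dataset("adjacency_indices", data=adj)
        f.create_dataset("adjacency_weights", data=adj_w)
        f.create_dataset("incidence_indices", data=inc)
        f.create_dataset("hyperedge_names", data=np.array(
            [name for name, _ in bundle.hypergraph.hyperedges], dtype="S"))
        f.create_dataset("hyperedge_weights",
                         data=np.asarray(bundle.hypergraph.hyperedge_weight,
                                         dtype=float))
        f.create_dataset("features", data=bundle.features.matrix)
        f.create_dataset("feature_names", data=np.array(
            bundle.features.feature_names, dtype="S"))
        f.create_dataset("labels", data=ls.labels)
        f.create_dataset("mask_train", data=ls.train_mask)
        f.create_dataset("mask_val", data=ls.val_mask)
        f.create_dataset("mask_test", data=ls.test_mask)


def load_bundle(path) -> DatasetBundle:
    with h5py.File(path, "r") as f:
        node_ids = [s.decode() for s in f["node_ids"][()]]
        adj = f["adjacency_indices"][()]
        adj_w = f["adjacency_weights"][()]
        inc = f["incidence_indices"][()]
        he_names = [s.decode() for s in f["hyperedge_names"][()]]
        he_w = list(f["hyperedge_weights"][()])
        feats = f["features"][()]
        feat_names = [s.decode() for s in f["feature_names"][()]]
        labels = f["labels"][()]
        masks = {k: f[f"mask_{k}"][()] for k in ("train", "val", "test")}
    edges = {(int(a), int(b)) for a, b in adj}
    weights = {(int(a), int(b)): float(w) for (a, b), w in zip(adj, adj_w)}
    graph = GeneGraph(node_ids, edges, weights)
    members: dict[int, set[int]] = {}
    for m, j in inc:
        members.setdefault(int(j), set()).add(int(m))
    hyperedges = [(he_names[j], frozenset(members.get(j, set())))
                  for j in range(len(he_names))]
    hg = PathwayHypergraph(list(node_ids), hyperedges, he_w)
    features = OmicsFeatures(list(node_ids), feats, feat_names)
    label_set = LabelSet(labels, masks["train"], masks["val"], masks["test"])
    return DatasetBundle(graph, hg, features, label_set)
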