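"""File readers, bundle assembly and the HDF5 cache."""

import numpy as np
import pytest

from ghnn import netio
from ghnn.netio import ParseError


def write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadEdgeList:
    def test_dedup_and_self_loop_drop(self, tmp_path):
        p = write(tmp_path, "e.tsv", "A\tB\nB\tA\nA\tA\n")
        g = netio.read_edge_list(p)
        assert g.n_nodes == 2
        assert g.edges == {(0, 1)}

    def test_line_and_node_counts(self, tmp_path):
        p = write(tmp_path, "e.tsv", "A\tB\nB\tC\n")
        g = netio.read_edge_list(p)
        assert g.node_ids == ["A", "B", "C"]
        assert len(g.edges) == 2

    def test_random_file_matches_set_oracle(self, tmp_path, rng):
        names = [f"g{i}" for i in range(12)]
        lines, oracle = [], set()
        for _ in range(100):
            a, b = rng.choice(names, size=2)
            lines.append(f"{a}\t{b}")
            if a != b:
                oracle.add(frozenset((a, b)))
        p = write(tmp_path, "e.tsv", "\n".join(lines) + "\n")
        g = netio.read_edge_list(p)
        got = {frozenset((g.node_ids[i], g.node_ids[j])) for i, j in g.edges}
        assert got == oracle

    def test_comments_weights_and_errors(self, tmp_path):
        p = write(tmp_path, "e.tsv", "# header\nA\tB\t2.5\n")
        g = netio.read_edge_list(p)
        assert g.weight((0, 1)) == 2.5
        with pytest.raises(ParseError, match="2"):
            netio.read_edge_list(write(tmp_path, "bad.tsv", "A\tB\nC\n"))
        with pytest.raises(ParseError):
            netio.read_edge_list(write(tmp_path, "empty.tsv", "\n"))
        with pytest.raises(ParseError, match="weight"):
            netio.read_edge_list(write(tmp_path, "w.tsv", "A\tB\tx\n"))

    def test_round_trip(self, tmp_path, rng):
        from conftest import random_graph
        g = random_graph(rng, n=9)
        out = tmp_path / "rt.tsv"
        netio.write_edge_list(g, out)
        g2 = netio.read_edge_list(out)
        orig = {frozenset((g.node_ids[i], g.node_ids[j]))
                for i, j in g.edges}
        back = {frozenset((g2.node_ids[i], g2.node_ids[j]))
                for i, j in g2.edges}
        assert orig == back


class TestReadGeneSets:
    def test_basic_parse(self, tmp_path):
        p = write(tmp_path, "s.gmt", "P1\tdesc\tA\tB\nP2\tdesc\tB\tC\tD\n")
        hg = netio.read_gene_sets(p)
        assert hg.n_hyperedges == 2
        assert sorted(len(m) for _, m in hg.hyperedges) == [2, 3]
        assert set(hg.node_ids) == {"A", "B", "C", "D"}

    def test_member_dedup(self, tmp_path):
        p = write(tmp_path, "s.gmt", "P1\tdesc\tA\tA\tB\n")
        hg = netio.read_gene_sets(p)
        assert len(hg.hyperedges[0][1]) == 2

    def test_short_line_error(self, tmp_path):
        with pytest.raises(ParseError):
            netio.read_gene_sets(write(tmp_path, "bad.gmt", "P1\tdesc\n"))

    def test_random_gmt_incidence_sums_match_oracle(self, tmp_path, rng):
        lines, oracle = [], []
        for k in range(50):
            members = list(dict.fromkeys(
                f"g{rng.integers(30)}" for _ in range(rng.integers(2, 9))))
            oracle.append(len(members))
            lines.append("\t".join([f"S{k}", "d"] + members))
        p = write(tmp_path, "r.gmt", "\n".join(lines) + "\n")
        hg = netio.read_gene_sets(p)
        assert list(hg.incidence().sum(axis=0).astype(int)) == oracle


class TestReadFeatureTable:
    def test_zero_impute(self, tmp_path):
        p = write(tmp_path, "f.tsv", "id\tf1\tf2\nA\t1.0\t\nB\t2.0\t3.0\nC\t\t4.0\n")
        f = netio.read_feature_table(p, impute="zero")
        assert f.matrix[0, 1] == 0.0 and f.matrix[2, 0] == 0.0

    def test_exact_values_without_missing(self, tmp_path):
        p = write(tmp_path, "f.tsv", "id\tx\ty\nA\t1.5\t-2\nB\t0\t7\n")
        f = netio.read_feature_table(p)
        assert np.array_equal(f.matrix, [[1.5, -2.0], [0.0, 7.0]])
        assert f.feature_names == ["x", "y"]

    def test_mean_impute(self, tmp_path):
        p = write(tmp_path, "f.tsv", "id\tx\nA\t1.0\nB\t\nC\t3.0\n")
        f = netio.read_feature_table(p, impute="mean")
        assert f.matrix[1, 0] == pytest.approx(2.0)

    def test_non_numeric_cell_errors(self, tmp_path):
        p = write(tmp_path, "f.tsv", "id\tx\nA\toops\n")
        with pytest.raises(ParseError, match="oops"):
            netio.read_feature_table(p)


class TestAssembleBundle:
    def _parts(self, tmp_path):
        graph = netio.GeneGraph(["A", "B", "C"], {(0, 1), (1, 2)})
        hg = netio.PathwayHypergraph(
            ["B", "C", "D"], [("P1", frozenset({0, 1, 2}))])
        feats = netio.OmicsFeatures(["A", "B"],
                                    np.array([[1.0, 2.0], [3.0, 4.0]]),
                                    ["f1", "f2"])
        labels = (["A", "B", "C"], np.array([1, 0, 1]),
                  ["train", "train", "test"])
        return graph, hg, feats, labels

    def test_restriction_zero_fill_and_alignment(self, tmp_path):
        graph, hg, feats, labels = self._parts(tmp_path)
        bundle = netio.assemble_bundle(graph, hg, feats, labels)
        assert bundle.node_ids == ["A", "B", "C"]
        # hyperedge {B,C,D} restricted to graph nodes {B,C}
        assert bundle.hypergraph.hyperedges[0][1] == frozenset({1, 2})
        # C had no features -> zero row
        assert np.array_equal(bundle.features.matrix[2], [0.0, 0.0])
        assert bundle.hypergraph.n_nodes == bundle.features.matrix.shape[0] \
            == bundle.label_set.n_nodes == 3

    def test_idempotent(self, tmp_path):
        graph, hg, feats, labels = self._parts(tmp_path)
        b1 = netio.assemble_bundle(graph, hg, feats, labels)
        b2 = netio.assemble_bundle(
            b1.graph, b1.hypergraph, b1.features,
            (b1.node_ids, b1.label_set.labels,
             ["train" if b1.label_set.train_mask[i] else
              "val" if b1.label_set.val_mask[i] else
              "test" if b1.label_set.test_mask[i] else ""
              for i in range(3)]))
        assert b2.hypergraph.hyperedges == b1.hypergraph.hyperedges
        assert np.array_equal(b2.features.matrix, b1.features.matrix)
        assert np.array_equal(b2.label_set.labels, b1.label_set.labels)

    def test_no_labeled_overlap_errors(self, tmp_path):
        graph, hg, feats, _ = self._parts(tmp_path)
        with pytest.raises(ValueError):
            netio.assemble_bundle(graph, hg, feats,
                                  (["Z"], np.array([1]), ["train"]))


class TestLabelSet:
    def test_mask_overlap_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            netio.LabelSet(np.array([1, 0]), np.array([True, True]),
                           np.array([True, False]), np.array([False, False]))

    def test_masked_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            netio.LabelSet(np.array([-1, 1]), np.array([True, False]),
                           np.array([False, False]), np.array([False, True]))


class TestBundleCache:
    def test_hdf5_round_trip_bit_stable(self, tmp_path, tiny_bundle):
        bundle, _ = tiny_bundle
        path = tmp_path / "bundle.h5"
        netio.save_bundle(bundle, path)
        back = netio.load_bundle(path)
        assert back.node_ids == bundle.node_ids
        assert back.graph.edges == bundle.graph.edges
        assert [m for _, m in back.hypergraph.hyperedges] == \
            [m for _, m in bundle.hypergraph.hyperedges]
        assert np.array_equal(back.features.matrix, bundle.features.matrix)
        assert np.array_equal(back.label_set.labels, bundle.label_set.labels)
        for name in ("train_mask", "val_mask", "test_mask"):
            assert np.array_equal(getattr(back.label_set, name),
                                  getattr(bundle.label_set, name))
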