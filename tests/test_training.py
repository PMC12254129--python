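"""Training loop, metrics, statistics and experiment protocols."""

import dataclasses

import numpy as np
import pytest
from scipy import stats

import ghnn
from ghnn.model import TrainConfig
from ghnn.training import (ComparisonResult, MetricsReport, compare_runs,
                           desk_config, evaluate)


def brute_force_average_precision(y, s):
    """Sum of (recall increment) x (precision) over descending unique
    score thresholds; samples sharing a score form one threshold group."""
    y = np.asarray(y)
    s = np.asarray(s, dtype=float)
    tp = fp = 0
    ap = 0.0
    for t in np.unique(s)[::-1]:
        grp = s == t
        tp += int(y[grp].sum())
        fp += int((1 - y[grp]).sum())
        ap += y[grp].sum() * tp / (tp + fp)
    return ap / y.sum()


def mann_whitney_auroc(y, s):
    """Rank-statistic AUROC with tie-midpoint correction."""
    y = np.asarray(y)
    ranks = stats.rankdata(s)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2
    return u / (n_pos * n_neg)


def toy_config(**kw):
    base = dict(hidden_dim=8, epochs=40, n_blocks=2, token_dim=8,
                transformer_layers=1, transformer_heads=2,
                learning_rate=3e-3, seed=0)
    base.update(kw)
    return TrainConfig(**base)


@pytest.fixture(scope="module")
def toy_bundle():
    bundle, _ = ghnn.generate(ghnn.default_spec(
        n_nodes=40, n_features=6, n_signal_features=3, n_hyperedges=8,
        signal_mix=(1.0, 0.0, 0.0), feature_noise=0.5, label_noise=0.0,
        seed=2))
    return bundle


class TestEvaluate:
    def test_perfect_ranking(self):
        ls = _label_set([1, 1, 0, 0])
        rep = evaluate(np.array([0.9, 0.8, 0.2, 0.1]), ls,
                       np.ones(4, bool))
        assert rep.auprc == 1.0 and rep.auroc == 1.0

    def test_hand_computed_alternating_example(self):
        # descending scores with labels 1,0,1,0: AP = (1 + 2/3)/2
        ls = _label_set([1, 0, 1, 0])
        rep = evaluate(np.array([0.9, 0.8, 0.7, 0.6]), ls, np.ones(4, bool))
        assert rep.auprc == pytest.approx((1 + 2 / 3) / 2)

    def test_reversed_ranking_flips_auroc(self, rng):
        y = rng.integers(0, 2, size=30)
        y[:2] = [0, 1]
        s = rng.random(30)
        ls = _label_set(y)
        fwd = evaluate(s, ls, np.ones(30, bool)).auroc
        rev = evaluate(-s, ls, np.ones(30, bool)).auroc
        assert fwd == pytest.approx(1.0 - rev, abs=1e-12)

    def test_matches_brute_force_oracles_on_random_vectors(self, rng):
        for _ in range(200):
            n = int(rng.integers(5, 40))
            y = rng.integers(0, 2, size=n)
            if y.sum() in (0, n):
                y[0], y[1] = 0, 1
            s = np.round(rng.random(n), 2)  # coarse scores force ties
            ls = _label_set(y)
            rep = evaluate(s, ls, np.ones(n, bool))
            assert abs(rep.auprc
                       - brute_force_average_precision(y, s)) < 1e-10
            assert abs(rep.auroc - mann_whitney_auroc(y, s)) < 1e-10

    def test_single_class_mask_rejected(self):
        ls = _label_set([1, 1, 1, 0])
        with pytest.raises(ValueError, match="single class"):
            evaluate(np.ones(4) * 0.5, ls, np.array([1, 1, 1, 0], bool))


def _label_set(y):
    y = np.asarray(y, dtype=int)
    return ghnn.LabelSet(y, np.zeros(len(y), bool), np.zeros(len(y), bool),
                         np.ones(len(y), bool))


class TestTrain:
    def test_loss_decreases_on_separable_toy(self, toy_bundle):
        _, log = ghnn.train(toy_bundle, toy_config(epochs=60), val_every=0)
        assert log.loss[-1] < log.loss[0]

    def test_same_seed_gives_bitwise_identical_curves(self, toy_bundle):
        _, log_a = ghnn.train(toy_bundle, toy_config(epochs=15))
        _, log_b = ghnn.train(toy_bundle, toy_config(epochs=15))
        assert np.array_equal(log_a.loss, log_b.loss)
        assert np.array_equal(log_a.val_auprc, log_b.val_auprc,
                              equal_nan=True)

    def test_overfits_separable_features_to_perfect_train_auprc(
            self, toy_bundle):
        model, _ = ghnn.train(toy_bundle, toy_config(epochs=400),
                              val_every=0)
        pred = model.predict(toy_bundle)
        rep = evaluate(pred, toy_bundle.label_set,
                       toy_bundle.label_set.train_mask)
        assert rep.auprc == pytest.approx(1.0)

    def test_loss_invariant_to_node_permutation(self, toy_bundle, rng):
        perm = rng.permutation(toy_bundle.n_nodes)
        inv = np.argsort(perm)
        g = toy_bundle.graph
        edges_p = {(min(inv[i], inv[j]), max(inv[i], inv[j]))
                   for i, j in g.edges}
        ids = [g.node_ids[i] for i in perm]
        graph_p = ghnn.GeneGraph(ids, edges_p)
        hyperedges_p = [(name, frozenset(int(inv[m]) for m in members))
                        for name, members in toy_bundle.hypergraph.hyperedges]
        hg_p = ghnn.PathwayHypergraph(ids, hyperedges_p,
                                      toy_bundle.hypergraph.hyperedge_weight)
        feats_p = ghnn.OmicsFeatures(ids, toy_bundle.features.matrix[perm],
                                     toy_bundle.features.feature_names)
        ls = toy_bundle.label_set
        ls_p = ghnn.LabelSet(ls.labels[perm], ls.train_mask[perm],
                             ls.val_mask[perm], ls.test_mask[perm])
        bundle_p = ghnn.DatasetBundle(graph_p, hg_p, feats_p, ls_p)
        # one epoch without dropout: identical initial loss either way
        cfg = toy_config(epochs=1, dropout=0.0, attn_ffn_dropout=0.0)
        _, log_a = ghnn.train(toy_bundle, cfg, val_every=0)
        _, log_b = ghnn.train(bundle_p, cfg, val_every=0)
        assert log_a.loss[0] == pytest.approx(log_b.loss[0], rel=1e-5)

    def test_weight_decay_closed_form_at_zero_learning_rate(self, rng):
        from ghnn.optim import Adam
        from ghnn import autodiff as ad
        p = ad.Parameter(rng.normal(size=(3, 3)))
        initial = p.data.copy()
        opt = Adam([p], lr=0.0, weight_decay=0.01)
        for _ in range(25):
            opt.zero_grad()
            p.grad = rng.normal(size=(3, 3))
            opt.step()
        assert np.allclose(p.data, initial * (1 - 0.01) ** 25, rtol=1e-10)


class TestCompareRuns:
    def test_identical_lists_not_significant(self):
        res = compare_runs([0.5, 0.5, 0.5], [0.5, 0.5, 0.5])
        assert res.p_value == 1.0 and not res.significant

    def test_separated_lists_significant(self):
        res = compare_runs([0.9, 0.901, 0.899], [0.1, 0.099, 0.101])
        assert res.p_value < 1e-3 and res.significant

    def test_type_i_error_calibrated_under_null(self):
        rng = np.random.default_rng(2024)
        rejections = 0
        reps = 1000
        for _ in range(reps):
            a = rng.normal(0.5, 0.05, size=5)
            b = rng.normal(0.5, 0.05, size=5)
            if compare_runs(a, b).significant:
                rejections += 1
        assert abs(rejections / reps - 0.05) <= 0.02

    def test_short_lists_rejected(self):
        with pytest.raises(ValueError):
            compare_runs([0.5], [0.4, 0.6])


class TestProtocols:
    def test_run_ablation_bookkeeping_and_param_counts(self, toy_bundle):
        cfg = toy_config(epochs=3)
        results = ghnn.run_ablation(toy_bundle, cfg,
                                    variants=("full", "shallow"),
                                    seeds=(0, 1))
        assert set(results) == {"full", "shallow"}
        for rep in results.values():
            assert len(rep.auprc_values) == 2
            assert 0.0 <= rep.auprc <= 1.0
        from ghnn.model import PanCancerGeneModel
        full = PanCancerGeneModel.init(6, dataclasses.replace(
            cfg, variant="full"), np.random.default_rng(0))
        shallow = PanCancerGeneModel.init(6, dataclasses.replace(
            cfg, variant="shallow"), np.random.default_rng(0))
        assert shallow.n_parameters < full.n_parameters

    def test_unknown_variant_rejected(self, toy_bundle):
        with pytest.raises(ValueError, match="variant"):
            ghnn.run_ablation(toy_bundle, toy_config(epochs=2),
                              variants=("bogus",), seeds=(0, 1))
        with pytest.raises(ValueError):
            TrainConfig(variant="nope")

    def test_depth_sweep_rows_and_grid_one_matches_shallow_path(
            self, toy_bundle):
        rows = ghnn.depth_sweep(toy_bundle, blocks_grid=(1, 2),
                                seeds=(0, 1), base_config=toy_config(
                                    epochs=3))
        assert len(rows) == 4
        assert {r["n_blocks"] for r in rows} == {1, 2}
        assert all(r["seconds"] > 0 for r in rows)
        assert all(r["n_layers"] == 3 * r["n_blocks"] for r in rows)

    def test_variant_wiring_dimensions(self, toy_bundle):
        from ghnn.model import PanCancerGeneModel
        for variant, g, h in [("full", True, True),
                              ("no_hypergraph", True, False),
                              ("no_graph", False, True)]:
            m = PanCancerGeneModel.init(
                6, toy_config(variant=variant), np.random.default_rng(0))
            assert (m.graph_encoder is not None) == g
            assert (m.hyper_encoder is not None) == h
            pred = m.predict(toy_bundle)
            assert len(pred) == toy_bundle.n_nodes
        lin = PanCancerGeneModel.init(
            6, toy_config(variant="linear_head"), np.random.default_rng(0))
        assert lin.transformer is None and lin.linear_head is not None
        shallow = PanCancerGeneModel.init(
            6, toy_config(variant="shallow"), np.random.default_rng(0))
        assert len(shallow.graph_encoder.blocks) == 1


class TestWritePredictions:
    def test_tsv_format_and_threshold(self, tmp_path, toy_bundle):
        from ghnn.tokenformer import PredictionVector
        from ghnn.training import write_predictions
        n = toy_bundle.n_nodes
        probs = np.linspace(0.01, 0.99, n)
        write_predictions(tmp_path / "pred.tsv", toy_bundle.node_ids,
                          PredictionVector(probs), toy_bundle.label_set)
        lines = (tmp_path / "pred.tsv").read_text().strip().split("\n")
        assert lines[0] == "node_id\tprobability\tpredicted_label\tsplit"
        assert len(lines) == n + 1
        first = lines[1].split("\t")
        assert first[2] == "0" and first[3] in ("train", "val", "test", "")


class TestMetricsReport:
    def test_aggregation_mean_and_std(self):
        reps = [MetricsReport(a, r) for a, r in
                [(0.8, 0.9), (0.6, 0.7), (0.7, 0.8)]]
        agg = MetricsReport.from_runs(reps)
        assert agg.auprc == pytest.approx(0.7)
        assert agg.auprc_std == pytest.approx(np.std([0.8, 0.6, 0.7],
                                                     ddof=1))
        assert agg.auprc_values == (0.8, 0.6, 0.7)

    def test_range_validation(self):
        with pytest.raises(ValueError):
            MetricsReport(1.2, 0.5)
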