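import numpy as np
import pytest
from sklearn.metrics import accuracy_score, f1_score, precision_score, recall_score

from mhamfd.hetero import build_hetero_graph
from mhamfd.relations import build_all_relation_graphs
from mhamfd.synth import SynthConfig, generate_claims, generate_features
from mhamfd.training import (
    TrainConfig,
    evaluate,
    fraud_lift_analysis,
    split_nodes,
    train_model,
)

from conftest import record


@pytest.fixture(scope="module")
def tiny_population():
    """Small planted-ring population shared by the training tests."""
    cfg = SynthConfig(
        n_fraud=12, n_normal=24, ring_size=4, n_departments=12, n_dates=30,
        n_medicines=30, seed=5,
    )
    claims, labels = generate_claims(cfg)
    g = build_hetero_graph(claims, generate_features(labels, cfg))
    adjs = build_all_relation_graphs(g)
    return g, adjs


class TestSplitNodes:
    def test_stratified_sizes_1_1_3(self):
        labels = np.array([1] * 20 + [0] * 40)
        tr, va, te = split_nodes(labels, (1, 1, 3), seed=0)
        assert (tr.sum(), va.sum(), te.sum()) == (12, 12, 36)
        assert (labels[tr] == 1).sum() == 4
        assert (labels[va] == 1).sum() == 4
        assert (labels[te] == 1).sum() == 12

    def test_sizes_3_1_1_on_fifty(self):
        labels = np.array([1] * 10 + [0] * 40)
        tr, va, te = split_nodes(labels, (3, 1, 1), seed=1)
        assert (tr.sum(), va.sum(), te.sum()) == (30, 10, 10)

    def test_masks_disjoint_and_exclude_unlabelled(self):
        labels = np.array([1, 0, -1, 1, 0, 0, -1, 1, 0, 0])
        tr, va, te = split_nodes(labels, (1, 1, 1), seed=2)
        assert not np.any(tr & va) and not np.any(va & te) and not np.any(tr & te)
        assert not np.any((tr | va | te) & (labels == -1))
        assert (tr | va | te).sum() == (labels >= 0).sum()

    def test_deterministic_under_seed(self):
        labels = np.array([1] * 15 + [0] * 30)
        a = split_nodes(labels, (3, 1, 1), seed=7)
        b = split_nodes(labels, (3, 1, 1), seed=7)
        for ma, mb in zip(a, b):
            np.testing.assert_array_equal(ma, mb)

    def test_class_starvation_raises(self):
        labels = np.array([1, 1, 0, 0, 0, 0])
        with pytest.raises(ValueError, match="coarser"):
            split_nodes(labels, (1, 1, 3), seed=0)

    def test_missing_class_raises(self):
        with pytest.raises(ValueError, match="class 1"):
            split_nodes(np.zeros(10, dtype=int), (1, 1, 1), seed=0)


class TestEvaluate:
    def test_perfect_predictions(self):
        labels = np.array([1, 0, 1, 0])
        logits = np.eye(2)[labels][:, ::-1][:, ::-1]  # one-hot rows
        m = evaluate(np.eye(2)[labels] * 10 - 5, labels, np.arange(4))
        assert m.accuracy == 1.0 and m.f1 == 1.0

    def test_all_negative_predictions_on_1_2_mask(self):
        labels = np.array([1, 0, 0] * 4)
        logits = np.tile([5.0, -5.0], (12, 1))
        m = evaluate(logits, labels, np.arange(12))
        assert m.accuracy == pytest.approx(2 / 3)
        assert m.recall == 0.0 and m.f1 == 0.0
        assert m.warnings

    def test_confusion_fixture_matches_hand_computation(self):
        y = np.array([1] * 10 + [0] * 20)
        pred = np.array([1] * 8 + [0] * 2 + [1] * 2 + [0] * 18)
        logits = np.column_stack([1 - pred, pred]).astype(float)
        m = evaluate(logits, y, np.arange(30))
        assert (m.tp, m.fp, m.fn, m.tn) == (8, 2, 2, 18)
        assert m.precision == pytest.approx(0.8)
        assert m.recall == pytest.approx(0.8)
        assert m.f1 == pytest.approx(0.8)
        assert m.accuracy == pytest.approx(26 / 30)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_sklearn_on_random_fixtures(self, seed):
        rng = np.random.default_rng(seed)
        y = rng.integers(0, 2, 40)
        y[:2] = [0, 1]
        pred = rng.integers(0, 2, 40)
        logits = np.column_stack([1.0 - pred, pred.astype(float)])
        m = evaluate(logits, y, np.arange(40))
        assert m.accuracy == pytest.approx(accuracy_score(y, pred))
        assert m.precision == pytest.approx(precision_score(y, pred, zero_division=0))
        assert m.recall == pytest.approx(recall_score(y, pred, zero_division=0))
        assert m.f1 == pytest.approx(f1_score(y, pred, zero_division=0))

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            evaluate(np.zeros((3, 2)), np.array([0, 1, 0]), np.array([], dtype=int))


class TestTrainModel:
    def config(self, **kw):
        base = dict(max_epochs=12, patience=50, split_ratio=(2, 1, 1), seed=0)
        base.update(kw)
        return TrainConfig(**base)

    def test_training_loss_decreases_early(self):
        # default planted-ring population; deterministic-forward loss trend
        cfg = SynthConfig()
        claims, labels = generate_claims(cfg)
        g = build_hetero_graph(claims, generate_features(labels, cfg))
        adjs = build_all_relation_graphs(g)
        drops = 0
        for seed in range(5):
            tc = TrainConfig(max_epochs=5, patience=50, split_ratio=(3, 1, 1), seed=seed)
            _, hist = train_model(g.features.values, adjs, g.labels, tc)
            drops += hist["train_loss_eval"].iloc[4] < hist["train_loss_eval"].iloc[0]
        assert drops >= 4

    def test_same_seed_identical_history(self, tiny_population):
        g, adjs = tiny_population
        _, h1 = train_model(g.features.values, adjs, g.labels, self.config(seed=3))
        _, h2 = train_model(g.features.values, adjs, g.labels, self.config(seed=3))
        assert h1.drop(columns="best").equals(h2.drop(columns="best"))

    def test_patience_one_with_flat_metrics_stops_at_epoch_two(self, tiny_population):
        g, adjs = tiny_population
        # learning rate 0 freezes the parameters, so validation loss and
        # accuracy are exactly constant from the first epoch on
        cfg = self.config(lr=0.0, dropout=0.0, patience=1, max_epochs=50)
        _, hist = train_model(g.features.values, adjs, g.labels, cfg)
        assert len(hist) == 2

    def test_best_epoch_never_after_stop(self, tiny_population):
        g, adjs = tiny_population
        cfg = self.config(patience=3, max_epochs=30)
        _, hist = train_model(g.features.values, adjs, g.labels, cfg)
        assert hist.attrs["best_epoch"] <= len(hist)
        best_row = hist[hist["best"]].iloc[-1]
        assert best_row["val_loss"] == hist["val_loss"].min()


class TestLift:
    def test_hand_fixture_full_covisit_pair(self):
        claims = [
            record("p1", "2018-01-05", "d1", {"m1"}, 1),
            record("p2", "2018-01-05", "d1", {"m1"}, 1),
            record("p3", "2018-01-06", "d2", {"m2"}, 0),
        ]
        g = build_hetero_graph(claims)
        adjs = build_all_relation_graphs(g)
        lt = fraud_lift_analysis(adjs, g.labels)
        groups = lt.table["PDTMP"]
        assert groups["1"]["size"] == 2 and groups["1"]["rate"] == 1.0
        assert groups["0"]["size"] == 1 and groups["0"]["rate"] == 0.0

    def test_zero_group_lift_is_one_when_defined(self):
        cfg = SynthConfig(n_fraud=10, n_normal=30, ring_size=5, seed=2)
        claims, labels = generate_claims(cfg)
        g = build_hetero_graph(claims, generate_features(labels, cfg))
        lt = fraud_lift_analysis(build_all_relation_graphs(g), g.labels)
        for name, groups in lt.table.items():
            zero = groups["0"]
            if zero["size"] > 0 and zero["rate"] > 0 and name not in lt.flags:
                assert zero["lift"] == pytest.approx(1.0)

    def test_requires_a_labelled_fraud_node(self):
        g = build_hetero_graph([record("p1", "2018-01-01", "d1", label=0)])
        with pytest.raises(ValueError, match="fraud"):
            fraud_lift_analysis(build_all_relation_graphs(g), g.labels)

    def test_empty_zero_group_flagged_with_overall_reference(self):
        claims = [  # both patients fraud: nobody has zero fraudulent neighbours
            record("p1", "2018-01-05", "d1", {"m1"}, 1),
            record("p2", "2018-01-05", "d1", {"m1"}, 1),
        ]
        g = build_hetero_graph(claims)
        lt = fraud_lift_analysis(build_all_relation_graphs(g), g.labels)
        assert "PDP" in lt.flags
        text = lt.to_text()
        assert "PDP" in text and "lift" in text
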