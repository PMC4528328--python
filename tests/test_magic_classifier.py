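"""ADTree training/scoring, MaGIC filters, dynamic-range QC."""

import json

import numpy as np
import pandas as pd
import pytest

from magic_mae.magic_classifier import (
    ADTreeClassifier,
    ADTreeNode,
    QcError,
    apply_filters,
    classify,
    qc_dynamic_range,
    run_magic,
    train_adtree,
)
from magic_mae.synthetic_data import simulate_training_table


def qrank_features(rng, n):
    return rng.uniform(0, 1, (n, 2)) + 1e-12


class TestTraining:
    def test_balanced_root_is_zero(self, rng):
        X = qrank_features(rng, 12)
        y = np.array(["MAE"] * 6 + ["BAE"] * 6)
        model = ADTreeClassifier(n_boost=1).fit(X, y)
        assert model.root_prediction_ == 0.0

    def test_root_log_odds_closed_form(self, rng):
        X = qrank_features(rng, 10)
        y = np.array(["MAE"] * 8 + ["BAE"] * 2)
        model = ADTreeClassifier(n_boost=1).fit(X, y)
        assert model.root_prediction_ == pytest.approx(0.5 * np.log(9 / 3))

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError, match="2 classes"):
            ADTreeClassifier().fit(qrank_features(rng, 5), ["MAE"] * 5)

    def test_invalid_n_boost_rejected(self, rng):
        with pytest.raises(ValueError, match="n_boost"):
            ADTreeClassifier(n_boost=0).fit(
                qrank_features(rng, 4), ["MAE", "MAE", "BAE", "BAE"]
            )

    def test_weight_sum_non_increasing_every_round(self):
        table = simulate_training_table(500, seed=3)
        model = train_adtree(table, n_boost=10)
        diffs = np.diff(model.weight_sums_)
        assert np.all(diffs <= 1e-9)

    def test_planted_rule_heldout_accuracy(self):
        table = simulate_training_table(2000, seed=11)
        train, test = table.iloc[:1000], table.iloc[1000:]
        model = train_adtree(train, n_boost=10)
        pred = model.predict(test[["k27_qrank", "k36_qrank"]].to_numpy())
        assert np.mean(pred == test["truth"]) >= 0.90

    def test_separable_training_accuracy(self, rng):
        # linearly separable in one feature
        X = qrank_features(rng, 400)
        y = np.where(X[:, 1] > 0.5, "MAE", "BAE")
        model = ADTreeClassifier(n_boost=5).fit(X, y)
        assert np.mean(model.predict(X) == y) >= 0.95


class TestScoring:
    def manual_model(self, nodes, root=0.0):
        m = ADTreeClassifier()
        m.classes_ = np.array(["BAE", "MAE"])
        m.positive_class_ = "MAE"
        m.n_features_in_ = 2
        m.root_prediction_ = root
        m.nodes_ = nodes
        return m

    def test_empty_tree_scores_root(self):
        m = self.manual_model([], root=-0.3)
        X = np.array([[0.1, 0.9], [0.5, 0.5]])
        np.testing.assert_allclose(m.decision_function(X), [-0.3, -0.3])
        assert list(m.predict(X)) == ["BAE", "BAE"]

    def test_zero_score_is_bae(self):
        m = self.manual_model([], root=0.0)
        assert list(m.predict(np.array([[0.5, 0.5]]))) == ["BAE"]

    def test_single_node_trace(self):
        node = ADTreeNode(1, (), feature=1, threshold=0.5,
                          pred_true=-1.0, pred_false=1.0)
        m = self.manual_model([node], root=0.0)
        X = np.array([[0.2, 0.8], [0.2, 0.4]])
        np.testing.assert_allclose(m.decision_function(X), [1.0, -1.0])
        assert list(m.predict(X)) == ["MAE", "BAE"]

    def test_precondition_gates_contribution(self):
        n1 = ADTreeNode(1, (), feature=0, threshold=0.5,
                        pred_true=0.1, pred_false=-0.1)
        n2 = ADTreeNode(2, ((1, True),), feature=1, threshold=0.5,
                        pred_true=2.0, pred_false=-2.0)
        m = self.manual_model([n1, n2])
        # x0 > 0.5: node2's precondition unsatisfied, only n1's false branch
        np.testing.assert_allclose(
            m.decision_function(np.array([[0.9, 0.1]])), [-0.1]
        )
        # x0 <= 0.5 satisfies node2's precondition; x1 <= 0.5 takes its
        # true branch: 0.1 + 2.0
        np.testing.assert_allclose(
            m.decision_function(np.array([[0.1, 0.1]])), [2.1]
        )

    def test_deterministic_and_order_independent(self):
        table = simulate_training_table(300, seed=5)
        model = train_adtree(table, n_boost=8)
        X = table[["k27_qrank", "k36_qrank"]].to_numpy()
        s1 = model.decision_function(X)
        s2 = model.decision_function(X[::-1])[::-1]
        np.testing.assert_array_equal(s1, s2)


class TestSerialization:
    def test_round_trip_scores_bit_identical(self, tmp_path):
        table = simulate_training_table(400, seed=9)
        model = train_adtree(table, n_boost=10)
        path = tmp_path / "model.json"
        model.save(path)
        back = ADTreeClassifier.load(path)
        X = table[["k27_qrank", "k36_qrank"]].to_numpy()
        np.testing.assert_array_equal(
            model.decision_function(X), back.decision_function(X)
        )
        assert back.to_dict() == model.to_dict()

    def test_unsupported_format_rejected(self):
        with pytest.raises(ValueError, match="format"):
            ADTreeClassifier.from_dict({"format_version": 99})


class TestFilters:
    @pytest.fixture()
    def calls_features(self):
        features = pd.DataFrame({
            "gene_id": ["a", "b", "c", "d"],
            "length_bp": [2499, 3000, 2500, 9000],
            "expr_qrank": [0.9, 0.49, 0.5, 0.9],
        })
        calls = pd.DataFrame({
            "gene_id": ["a", "b", "c", "d"],
            "score": [1.0, 1.0, -1.0, 2.0],
            "call": ["MAE", "MAE", "BAE", "MAE"],
        })
        return calls, features

    def test_filter_categories(self, calls_features):
        out = apply_filters(*calls_features).set_index("gene_id")
        assert out.loc["a", "filtered"] == "short_gene"  # 2499 < 2.5 kb
        assert out.loc["b", "filtered"] == "low_expression"  # qrank 0.49
        assert out.loc["c", "filtered"] == "kept"  # inclusive keep at median
        assert out.loc["d", "filtered"] == "kept"

    def test_final_call_only_for_kept(self, calls_features):
        out = apply_filters(*calls_features).set_index("gene_id")
        assert out.loc["a", "final_call"] == "not_assessed"
        assert out.loc["d", "final_call"] == "MAE"
        kept = out["filtered"] == "kept"
        assert (out.loc[kept, "final_call"] == out.loc[kept, "call"]).all()


class TestQc:
    def make_features(self, counts):
        # quadrant order: (low27,high36), (high27,low36), (low27,low36), (high27,high36)
        rows = []
        n1, n2, n3, n4 = counts
        rows += [(0.0, 10.0)] * n1 + [(10.0, 0.0)] * n2
        rows += [(0.0, 0.0)] * n3 + [(10.0, 10.0)] * n4
        df = pd.DataFrame(rows, columns=["k27_norm", "k36_norm"])
        df["gene_id"] = [f"g{i}" for i in range(len(df))]
        return df

    def test_boundary_of_fifty_percent_rule(self):
        qc = qc_dynamic_range(self.make_features((60, 60, 40, 40)))
        assert qc.counts == (60, 60, 40, 40)
        assert qc.passed  # 120 >= 1.5 * 80

    def test_failing_dataset(self):
        assert not qc_dynamic_range(self.make_features((30, 30, 50, 50))).passed

    def test_anticorrelated_marks_pass(self):
        assert qc_dynamic_range(self.make_features((50, 50, 0, 0))).passed

    def test_counts_sum_to_assessed_genes(self, small_features):
        qc = qc_dynamic_range(small_features)
        assert sum(qc.counts) == len(small_features)


class TestRunMagic:
    def test_qc_refusal_names_counts(self, rng):
        features = pd.DataFrame({
            "gene_id": [f"g{i}" for i in range(40)],
            "length_bp": 5000,
            "k27_norm": np.repeat([0.0, 10.0], 20),
            "k36_norm": np.repeat([0.0, 10.0], 20),
            "k27_qrank": rng.uniform(size=40),
            "k36_qrank": rng.uniform(size=40),
            "expr_qrank": rng.uniform(size=40),
        })
        table = simulate_training_table(200, seed=2)
        model = train_adtree(table, n_boost=3)
        with pytest.raises(QcError, match="low27/high36=0"):
            run_magic(features, model)
        calls, qc = run_magic(features, model, force=True)
        assert not qc.passed
        assert len(calls) == 40

    def test_scale_tag_mismatch_rejected(self, small_features):
        table = simulate_training_table(200, seed=2)
        model = train_adtree(table, n_boost=2)
        model.feature_scale_tag = "log2"
        with pytest.raises(ValueError, match="scale"):
            classify(model, small_features)
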