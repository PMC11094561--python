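"""Decision-tree integration: greedy recursive partitioning, the
published tree's stored counts, three-way decision evaluation, and
cross-validation behavior."""

import numpy as np
import pandas as pd
import pytest

from gazedx.cart import (
    FEATURES,
    PUBLISHED_POLICY,
    cross_validate,
    evaluate_decided,
    fit_cart,
    majority_policy,
    predict_terminal,
    published_tree,
    render_tree_text,
    tree_from_dict,
    tree_to_dict,
    tree_to_dot,
)
from gazedx.composite import compose_table, derive_all_cutoffs
from gazedx.cohort import SimulationSpec, simulate_biomarker_table


def feature_frame(rng, n):
    return pd.DataFrame({
        "composite": rng.integers(0, 2, n),
        "frequency": rng.integers(0, 7, n),
        "eae_dx": rng.integers(0, 2, n),
        "certainty": rng.integers(0, 2, n),
    })


def generative_labels(X):
    """A fixed 3-split generating tree: composite positives are autism;
    among composite negatives, a PCP autism call rules the label out and
    the rest follow frequency > 2.  Each split is the uniquely dominant
    one at its node, so a faithful fit must recover this hierarchy."""
    y = np.zeros(len(X), int)
    y[(X.composite == 1)] = 1
    y[(X.composite == 0) & (X.eae_dx == 0) & (X.frequency > 2)] = 1
    return y


class TestFitCart:
    def test_recovers_generating_structure_noiselessly(self):
        rng = np.random.default_rng(0)
        X = feature_frame(rng, 400)
        y = generative_labels(X)
        tree = fit_cart(X, y, max_splits=5)
        assert tree.split_variable == "composite"
        neg = tree.left  # composite == 0
        assert neg.split_variable == "eae_dx"
        assert neg.left.split_variable == "frequency"  # eae_dx == 0 arm
        assert neg.left.threshold == pytest.approx(2.0)
        assert neg.right.is_terminal  # PCP autism call -> pure
        # purity at the generating leaves
        for leaf in tree.terminals():
            assert leaf.p_autism in (0.0, 1.0)

    def test_null_feature_gives_root_only_tree(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame({
            "composite": rng.integers(0, 2, 1000),
            "frequency": np.zeros(1000, int),
            "eae_dx": np.zeros(1000, int),
            "certainty": np.zeros(1000, int),
        })
        y = rng.integers(0, 2, 1000)  # independent of every feature
        tree = fit_cart(X, y)
        assert tree.is_terminal

    def test_single_class_gives_root_only(self):
        rng = np.random.default_rng(2)
        X = feature_frame(rng, 50)
        tree = fit_cart(X, np.ones(50, int))
        assert tree.is_terminal

    def test_split_budget_bounds_leaves(self):
        rng = np.random.default_rng(3)
        X = feature_frame(rng, 600)
        y = (rng.random(600) < 0.3 + 0.4 * X.composite).astype(int)
        for m in (1, 2, 3):
            tree = fit_cart(X, y, max_splits=m, min_gain=0.0)
            assert len(tree.terminals()) <= m + 1

    def test_child_counts_sum_to_parent_everywhere(self):
        rng = np.random.default_rng(4)
        X = feature_frame(rng, 300)
        y = generative_labels(X)
        tree = fit_cart(X, y)

        def walk(node):
            if node.is_terminal:
                return
            assert node.left.counts[0] + node.right.counts[0] == node.counts[0]
            assert node.left.counts[1] + node.right.counts[1] == node.counts[1]
            walk(node.left)
            walk(node.right)

        walk(tree)

    def test_missing_feature_rejected(self):
        with pytest.raises(ValueError, match="missing feature"):
            fit_cart(pd.DataFrame({"composite": [0, 1]}), [0, 1])

    def test_first_split_is_composite_on_study_like_cohorts(self):
        """With the study's effect sizes, the composite biomarker is the
        strongest baseline predictor in nearly every seeded replicate."""
        hits = 0
        n_rep = 20
        for seed in range(n_rep):
            table = simulate_biomarker_table(SimulationSpec(seed=100 + seed))
            rules = derive_all_cutoffs(table)
            composed = compose_table(table, rules)
            X = pd.DataFrame({
                "composite": composed["composite_positive"],
                "frequency": composed["biomarker_frequency"],
                "eae_dx": (table["eae_dx"] == "autism").astype(int),
                "certainty": (table["certainty"] == "certain").astype(int),
            })
            y = (table["group"] == "autism").astype(int)
            tree = fit_cart(X, y)
            hits += int(not tree.is_terminal
                        and tree.split_variable in ("composite", "frequency"))
        assert hits >= 0.9 * n_rep


class TestPublishedTree:
    def test_stored_terminal_counts(self):
        tree = published_tree()
        nodes = {t.node_id: t for t in tree.terminals()}
        assert nodes[6].counts == (57, 0)
        assert nodes[12].counts == (9, 1)
        assert nodes[10].counts == (10, 0)
        assert nodes[5].counts == (9, 26)
        assert nodes[13].counts == (3, 9)

    def test_counts_consistent_down_the_tree(self):
        tree = published_tree()
        assert tree.counts == (102, 44)

        def walk(node):
            if node.is_terminal:
                return
            for k in (0, 1):
                assert node.left.counts[k] + node.right.counts[k] == node.counts[k]
            walk(node.left)
            walk(node.right)

        walk(tree)

    def test_routing_matches_node_semantics(self):
        tree = published_tree()
        case = {"composite": 1, "frequency": 2, "eae_dx": 1, "certainty": 1}
        assert predict_terminal(tree, case).node_id == 6
        case = {"composite": 1, "frequency": 3, "eae_dx": 0, "certainty": 0}
        assert predict_terminal(tree, case).node_id == 10
        case = {"composite": 1, "frequency": 1, "eae_dx": 0, "certainty": 1}
        assert predict_terminal(tree, case).node_id == 13
        case = {"composite": 0, "frequency": 0, "eae_dx": 0, "certainty": 1}
        assert predict_terminal(tree, case).node_id == 5
        case = {"composite": 0, "frequency": 0, "eae_dx": 1, "certainty": 0}
        assert predict_terminal(tree, case).node_id == 8


class TestEvaluateDecided:
    def test_worked_example_confusion(self):
        stats, referred = evaluate_decided(published_tree(), PUBLISHED_POLICY)
        assert referred == 19
        assert stats.n == 127
        assert stats.concordant == 114

    def test_refer_all_policy_gives_missing_stats(self):
        tree = published_tree()
        policy = {t.node_id: "refer" for t in tree.terminals()}
        stats, referred = evaluate_decided(tree, policy)
        assert referred == 146
        assert stats.n == 0
        assert np.isnan(stats.sensitivity)

    def test_majority_policy_decides_every_case(self):
        rng = np.random.default_rng(5)
        X = feature_frame(rng, 200)
        y = generative_labels(X)
        tree = fit_cart(X, y)
        stats, referred = evaluate_decided(tree, majority_policy(tree), X, y)
        assert referred == 0
        assert stats.n == 200

    def test_decided_plus_referred_equals_total_on_cases(self):
        rng = np.random.default_rng(6)
        X = feature_frame(rng, 150)
        y = generative_labels(X)
        tree = published_tree()
        policy = dict(PUBLISHED_POLICY)
        stats, referred = evaluate_decided(tree, policy, X, y)
        assert stats.n + referred == 150

    def test_incomplete_policy_rejected(self):
        with pytest.raises(ValueError, match="policy lacks"):
            evaluate_decided(published_tree(), {6: "autism"})


class TestCrossValidate:
    def test_noiseless_structure_stable_across_folds(self):
        rng = np.random.default_rng(7)
        X = feature_frame(rng, 2000)
        y = generative_labels(X)
        cv = cross_validate(X, y, k=5, seed=0)
        assert cv.modal_structure_count == 5
        assert all(a == 1.0 for a in cv.valid_auc)

    def test_shuffled_labels_auc_near_half(self):
        rng = np.random.default_rng(8)
        X = feature_frame(rng, 400)
        y = generative_labels(X)
        rng.shuffle(y)
        cv = cross_validate(X, y, k=5, seed=1)
        assert abs(cv.mean_valid_auc - 0.5) < 0.15

    def test_validation_auc_tracks_training_auc(self):
        """On study-sized cohorts the held-out AUC stays within 0.08 of
        the training AUC (limited overfitting with four coarse features)."""
        gaps = []
        for seed in range(5):
            table = simulate_biomarker_table(SimulationSpec(seed=200 + seed))
            rules = derive_all_cutoffs(table)
            composed = compose_table(table, rules)
            X = pd.DataFrame({
                "composite": composed["composite_positive"],
                "frequency": composed["biomarker_frequency"],
                "eae_dx": (table["eae_dx"] == "autism").astype(int),
                "certainty": (table["certainty"] == "certain").astype(int),
            })
            y = (table["group"] == "autism").astype(int).to_numpy()
            cv = cross_validate(X, y, k=5, seed=seed)
            gaps.append(cv.mean_train_auc - cv.mean_valid_auc)
        assert np.mean(gaps) < 0.08

    def test_k_less_than_two_rejected(self):
        with pytest.raises(ValueError):
            cross_validate(feature_frame(np.random.default_rng(0), 20),
                           np.r_[np.ones(10), np.zeros(10)], k=1)


def test_tree_serialization_roundtrip():
    tree = published_tree()
    d = tree_to_dict(tree, PUBLISHED_POLICY)
    back = tree_from_dict(d)
    assert back.structure() == tree.structure()
    assert {t.node_id: t.counts for t in back.terminals()} \
        == {t.node_id: t.counts for t in tree.terminals()}
    txt = render_tree_text(tree, PUBLISHED_POLICY)
    for nid in (6, 10, 12, 13, 5, 8, 9):
        assert f"node {nid}" in txt
    dot = tree_to_dot(tree, PUBLISHED_POLICY)
    assert dot.startswith("digraph") and "decision: refer" in dot
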