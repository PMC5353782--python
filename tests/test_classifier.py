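"""Decision trees over eigengenes, prediction, confusion, and compaction."""

import copy
import itertools
import math

import numpy as np
import pandas as pd
import pytest

from eigennet import classifier as cl
from eigennet import eigengene as eg
from eigennet.coexpression import ModuleAssignment
from eigennet.synthetic import SyntheticSpec, generate_modular_expression

from conftest import make_dataset


def _eig(cols, prefix="s"):
    df = pd.DataFrame(cols)
    df.index = [f"{prefix}{i}" for i in range(len(df))]
    return df


def _labels(eig, labels):
    return pd.Series(labels, index=eig.index)


class TestFitTree:
    def test_separable_feature_yields_depth_one_tree(self):
        eig = _eig({1: [-3.0, -2.0, -1.5, 1.0, 2.0, 3.5]})
        y = _labels(eig, ["a", "a", "a", "b", "b", "b"])
        tree = cl.fit_tree(eig, y, min_per_leaf_fraction=0.1)
        root = tree.root
        assert isinstance(root, cl.Split) and root.feature == 1
        assert root.threshold == pytest.approx((-1.5 + 1.0) / 2)
        assert isinstance(root.left, cl.Leaf) and isinstance(root.right, cl.Leaf)
        assert (cl.predict(tree, eig) == y).all()

    def test_pure_labels_give_single_leaf(self):
        eig = _eig({1: [1.0, 2.0, 3.0, 4.0]})
        y = _labels(eig, ["a", "a", "a", "a"])
        tree = cl.fit_tree(eig, y)
        assert isinstance(tree.root, cl.Leaf) and tree.root.label == "a"
        y2 = _labels(eig, ["a", "a", "a", "b"])
        tree = cl.fit_tree(eig, y2, min_per_leaf_fraction=0.5)
        # the floor allows only a 2|2 split; the mixed right leaf ties 1:1
        # and the tie goes to the smaller label code
        assert isinstance(tree.root, cl.Split)
        assert tree.root.right.counts == {"a": 1, "b": 1}
        assert tree.root.right.label == "a"

    def test_matches_exhaustive_split_search_on_planted_rule(self):
        rng = np.random.default_rng(0)
        n = 60
        f1 = rng.normal(size=n)
        f2 = rng.normal(size=n)
        y = np.where((f1 <= 0.2) | (f2 > 0.5), "a", "b")
        eig = _eig({1: f1, 2: f2})
        labels = _labels(eig, y)
        tree = cl.fit_tree(eig, labels, min_per_leaf_fraction=0.1)
        acc_tree = (cl.predict(tree, eig) == labels).mean()
        acc_oracle = _best_depth2_accuracy(eig, labels, floor=6)
        assert acc_tree == pytest.approx(acc_oracle, abs=1e-12)

    def test_every_leaf_respects_floor(self):
        rng = np.random.default_rng(1)
        eig = _eig({1: rng.normal(size=80), 2: rng.normal(size=80)})
        y = _labels(eig, rng.choice(["a", "b"], size=80))
        tree = cl.fit_tree(eig, y, min_per_leaf_fraction=0.10)
        floor = math.ceil(0.10 * 80)

        def check(node):
            if isinstance(node, cl.Leaf):
                assert sum(node.counts.values()) >= floor
            else:
                check(node.left)
                check(node.right)

        check(tree.root)

    def test_too_few_samples_warns_single_leaf(self):
        eig = _eig({1: [0.0, 1.0, 2.0]})
        y = _labels(eig, ["a", "a", "b"])
        with pytest.warns(UserWarning, match="single leaf"):
            tree = cl.fit_tree(eig, y, min_per_leaf_fraction=0.9)
        assert isinstance(tree.root, cl.Leaf)


def _best_depth2_accuracy(eig, labels, floor):
    """Exhaustive search over depth<=2 threshold trees (accuracy oracle)."""
    X = eig.to_numpy()
    y = labels.to_numpy()
    n = len(y)

    def candidates(idx, f):
        xs = np.unique(X[idx, f])
        return (xs[:-1] + xs[1:]) / 2

    def leaf_acc(idx):
        if len(idx) == 0:
            return 0
        _, counts = np.unique(y[idx], return_counts=True)
        return counts.max()

    def best_child(idx):
        best = leaf_acc(idx)
        for f in range(X.shape[1]):
            for thr in candidates(idx, f):
                l = idx[X[idx, f] <= thr]
                r = idx[X[idx, f] > thr]
                if len(l) < floor or len(r) < floor:
                    continue
                best = max(best, leaf_acc(l) + leaf_acc(r))
        return best

    idx = np.arange(n)
    best = leaf_acc(idx)
    for f in range(X.shape[1]):
        for thr in candidates(idx, f):
            l = idx[X[idx, f] <= thr]
            r = idx[X[idx, f] > thr]
            if len(l) < floor or len(r) < floor:
                continue
            best = max(best, best_child(l) + best_child(r))
    return best / n


def _printed_tree():
    """The published AML/MDS rule: ECM <= -0.001 -> AML; else HOXA&B decides."""
    return cl.DecisionTree(
        root=cl.Split(
            feature="ECM",
            threshold=-0.001,
            left=cl.Leaf("AML"),
            right=cl.Split(
                feature="HOXA&B",
                threshold=-0.004,
                left=cl.Leaf("MDS"),
                right=cl.Leaf("AML"),
            ),
        ),
        classes=["AML", "MDS"],
    )


class TestPredict:
    def test_published_tree_routes_cases_to_printed_leaves(self):
        tree = _printed_tree()
        eig = _eig({"ECM": [-0.5, 0.1, 0.1], "HOXA&B": [0.0, -0.5, 0.5]})
        assert list(cl.predict(tree, eig)) == ["AML", "MDS", "AML"]

    def test_missing_feature_column_rejected(self):
        tree = _printed_tree()
        eig = _eig({"ECM": [0.0]})
        with pytest.raises(ValueError, match="HOXA&B"):
            cl.predict(tree, eig)

    def test_boundary_goes_left(self):
        tree = _printed_tree()
        eig = _eig({"ECM": [-0.001], "HOXA&B": [1.0]})
        assert list(cl.predict(tree, eig)) == ["AML"]


class TestConfusion:
    def test_perfect_and_inverted_predictions(self):
        truth = pd.Series(["a", "a", "b", "b"], index=list("wxyz"))
        table, sens = cl.confusion(truth.copy(), truth)
        assert table.loc["a", "b"] == 0 and table.loc["b", "a"] == 0
        assert sens == {"a": 1.0, "b": 1.0}
        flipped = truth.map({"a": "b", "b": "a"})
        table, sens = cl.confusion(flipped, truth)
        assert table.loc["a", "a"] == 0 and table.loc["b", "b"] == 0

    def test_hand_tallied_counts(self):
        truth = pd.Series(["a"] * 6 + ["b"] * 4, index=[f"s{i}" for i in range(10)])
        pred = truth.copy()
        pred.iloc[[0, 1, 7]] = ["b", "b", "a"]  # three errors
        table, sens = cl.confusion(pred, truth)
        assert table.loc["a", "a"] == 4 and table.loc["a", "b"] == 2
        assert table.loc["b", "a"] == 1 and table.loc["b", "b"] == 3
        assert sens["a"] == pytest.approx(4 / 6)
        assert sens["b"] == pytest.approx(3 / 4)

    def test_unknown_predicted_label_rejected(self):
        truth = pd.Series(["a", "b"], index=["x", "y"])
        pred = pd.Series(["a", "c"], index=["x", "y"])
        with pytest.raises(ValueError):
            cl.confusion(pred, truth)


def _single_module_setup(n_genes=6, seed=2, zero_weight=False):
    rng = np.random.default_rng(seed)
    f = np.concatenate([rng.normal(1.5, 1, 20), rng.normal(-1.5, 1, 20)])
    X = 0.8 * f[None, :] + rng.normal(0, 0.4, (n_genes, 40))
    ds = make_dataset(X, condition=["a"] * 20 + ["b"] * 20)
    model, eig = eg.compute_eigengenes(
        ds, ModuleAssignment(pd.Series(1, index=ds.gene_ids)), balance=False
    )
    if zero_weight:
        w = model.modules[1].weights
        w[-1] = 0.0
        model.modules[1].weights = w / np.linalg.norm(w)
        eig = eg.project_eigengenes(model, ds)
    labels = ds.condition
    tree = cl.fit_tree(eig, labels, min_per_leaf_fraction=0.1)
    return ds, model, eig, labels, tree


class TestCompactTree:
    def test_single_gene_module_is_irreducible(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=30)
        ds = make_dataset(
            np.vstack([x + 2.0 * np.repeat([1.0, -1.0], 15)]),
            condition=["a"] * 15 + ["b"] * 15,
        )
        model = eg.EigengeneModel({1: eg.ModuleEigengene(["g0"], np.array([1.0]))})
        eig = eg.project_eigengenes(model, ds)
        tree = cl.fit_tree(eig, ds.condition, min_per_leaf_fraction=0.1)
        result = cl.compact_tree(tree, model, ds, ds.condition)
        assert len(result.trajectory) == 1
        assert result.removal_order == []

    def test_zero_weight_gene_removed_first_without_effect(self):
        ds, model, eig, labels, tree = _single_module_setup(zero_weight=True)
        result = cl.compact_tree(tree, model, ds, labels, min_genes=4)
        assert result.removal_order[0][0] == model.modules[1].genes[-1]
        assert result.removal_order[0][1] == 0.0
        after_first = eg.project_eigengenes(
            eg.EigengeneModel(
                {
                    1: eg.ModuleEigengene(
                        model.modules[1].genes[:-1],
                        model.modules[1].weights[:-1]
                        / np.linalg.norm(model.modules[1].weights[:-1]),
                    )
                }
            ),
            ds,
        )
        pd.testing.assert_frame_equal(after_first, eig, atol=1e-9, rtol=0)

    def test_tree_is_untouched_and_accuracy_bounded(self):
        ds, model, eig, labels, tree = _single_module_setup(n_genes=12)
        before = copy.deepcopy(tree)
        result = cl.compact_tree(tree, model, ds, labels, max_drop=0.05)
        assert _tree_signature(tree) == _tree_signature(before)
        acc0 = result.trajectory[0][1]
        accf = result.trajectory[-1][1]
        for c in acc0:
            assert accf[c] >= acc0[c] - 0.05 - 1e-12

    def test_removal_order_follows_weights_within_module(self):
        ds, model, eig, labels, tree = _single_module_setup(n_genes=10, seed=4)
        result = cl.compact_tree(tree, model, ds, labels, min_genes=2)
        original = dict(zip(model.modules[1].genes, np.abs(model.modules[1].weights)))
        removed = [g for g, _ in result.removal_order]
        ranks = [original[g] for g in removed]
        assert all(a <= b + 1e-12 for a, b in zip(ranks, ranks[1:]))

    def test_redundant_module_compacts_deeply(self):
        # 20 informative genes plus 80 near-zero-weight genes: compaction
        # strips the uninformative tail without hurting accuracy
        rng = np.random.default_rng(5)
        f = np.concatenate([rng.normal(1.8, 1, 40), rng.normal(-1.8, 1, 40)])
        strong = 0.9 * f[None, :] + rng.normal(0, 0.3, (20, 80))
        weak = 0.02 * f[None, :] + rng.normal(0, 1.0, (80, 80))
        ds = make_dataset(np.vstack([strong, weak]), condition=["a"] * 40 + ["b"] * 40)
        model, eig = eg.compute_eigengenes(
            ds, ModuleAssignment(pd.Series(1, index=ds.gene_ids)), balance=False
        )
        tree = cl.fit_tree(eig, ds.condition, min_per_leaf_fraction=0.1)
        result = cl.compact_tree(tree, model, ds, ds.condition, max_drop=0.05)
        assert len(result.selected_genes) <= 25
        acc0 = result.trajectory[0][1]
        accf = result.trajectory[-1][1]
        for c in acc0:
            assert accf[c] >= acc0[c] - 0.05 - 1e-12

    def test_min_genes_validated(self):
        ds, model, eig, labels, tree = _single_module_setup()
        with pytest.raises(ValueError):
            cl.compact_tree(tree, model, ds, labels, min_genes=0)


def _tree_signature(tree):
    out = []

    def walk(node):
        if isinstance(node, cl.Leaf):
            out.append(("leaf", node.label))
        else:
            out.append(("split", node.feature, node.threshold))
            walk(node.left)
            walk(node.right)

    walk(tree.root)
    return out


def test_tree_json_round_trip_and_render(tmp_path):
    tree = _printed_tree()
    path = tmp_path / "tree.json"
    tree.to_json(path)
    back = cl.DecisionTree.from_json(path)
    assert _tree_signature(back) == _tree_signature(tree)
    text = back.render()
    assert "ECM" in text and "-0.001" in text and "MDS" in text
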